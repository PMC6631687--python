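"""Plasma protein binding by ultrafiltration.

Simulates ultrafiltration of tracer-spiked plasma (5-6 kBq spikes, Poisson
counting) for each compound and summarizes the free fraction, which feeds
the well-stirred prediction.
"""

from ivivekit import (
    NoiseConfig,
    PROFILES,
    generate_ultrafiltration,
    summarize_free_fraction,
)

print(f"{'compound':8s} {'f_p mean':>9s} {'SD':>8s} {'n':>3s} {'truth':>7s}")
for cid, profile in PROFILES.items():
    ms = generate_ultrafiltration(profile, NoiseConfig(seed=21), n_animals=7)
    mean, sd, n = summarize_free_fraction(ms)
    print(f"{cid:8s} {mean:9.4f} {sd:8.4f} {n:3d} {profile.f_p_true:7.3f}")

print()
print("All three tracers are highly protein bound (free fraction < 5%),")
print("which is why the predicted-clearance rank order differs from the")
print("metabolic-stability rank order.")
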