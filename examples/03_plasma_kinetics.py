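"""In vivo plasma kinetics: corrections, triexponential fit, PK parameters.

Simulates an 8-animal arterial sampling study for one tracer, undoes
radioactive decay and metabolite contamination (population Hill
parent-fraction correction), aggregates to a mean curve, fits the
triexponential bolus model and derives clearance, distribution volume and
terminal half-life.
"""

import numpy as np

from ivivekit import (
    NoiseConfig,
    PROFILES,
    aggregate_mean_curve,
    generate_pk_study,
    mean_curve_pk,
    smooth_parent_fractions,
    study_pk,
)

profile = PROFILES["CBX"]
studies = generate_pk_study(profile, NoiseConfig(seed=1), n_animals=8)

pk, fit = mean_curve_pk(studies, seed=0)
print(f"triexponential macroconstants (mean curve, n={len(studies)}):")
for i, (a, lam) in enumerate(zip(fit.a, fit.lam), start=1):
    print(f"  A{i} = {a:10.0f} Bq/mL   lambda{i} = {lam:.4f} /min "
          f"(t1/2 {np.log(2)/lam:6.1f} min)")

print(f"\nCL_p        = {pk.cl_p:6.2f} mL/min/kg   (truth {profile.cl_p_true})")
print(f"V_d         = {pk.v_d:6.0f} mL/kg       (truth {profile.v_d_true:.0f})")
print(f"t1/2,term   = {pk.t_half_term:6.1f} min       "
      f"(truth {profile.t_half_term_true})")

pooled = smooth_parent_fractions([s.parent_fractions for s in studies])
individual = [study_pk(s, parent_fractions=pooled, seed=0).cl_p
              for s in studies]
dev = abs(pk.cl_p - np.mean(individual)) / pk.cl_p * 100
print(f"\nmean of individual-animal CL_p = {np.mean(individual):.2f} "
      f"mL/min/kg -> {dev:.1f}% deviation from the mean-curve estimate")
print("(aggregating before fitting stabilizes the terminal phase; the two")
print(" clearance routes should agree within a few percent)")

mc = aggregate_mean_curve(studies, parent_fractions=pooled)
print(f"\nmean curve spans {mc.conc[0]:,.0f} -> {mc.conc[-1]:,.0f} Bq/mL "
      f"over {mc.times[0]:g}-{mc.times[-1]:g} min p.i.")
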