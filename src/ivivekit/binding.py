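"""Plasma protein binding by ultrafiltration.

Plasma spiked with a trace amount of radiotracer is centrifuged through a
filter; comparing radioactivity in equal volumes of spiked plasma and
filtrate gives the free (unbound) fraction directly:

    f_p = counts_filtrate / counts_plasma

Nonspecific binding of tracer to the filtration device is not corrected for
(a known limitation of the assay as modeled here).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataQualityError, InvalidInputError


@dataclass(frozen=True)
class UltrafiltrationMeasurement:
    """Paired counts from equal volumes (50 uL) of spiked plasma and filtrate."""

    animal_id: str
    counts_plasma: float
    counts_filtrate: float

    def __post_init__(self):
        if self.counts_plasma <= 0:
            raise InvalidInputError("counts_plasma must be > 0")
        if self.counts_filtrate < 0:
            raise InvalidInputError("counts_filtrate must be >= 0")


def free_fraction(m: UltrafiltrationMeasurement) -> float:
    """Fraction of tracer unbound in plasma, in [0, 1].

    A filtrate count exceeding the plasma count is physically impossible
    (free concentration cannot exceed total) and raises rather than being
    clamped — it indicates a pipetting or counting problem.
    """
    if m.counts_filtrate > m.counts_plasma:
        raise DataQualityError(
            f"{m.animal_id}: filtrate counts ({m.counts_filtrate}) exceed "
            f"plasma counts ({m.counts_plasma})"
        )
    return m.counts_filtrate / m.counts_plasma


def summarize_free_fraction(
    ms: list[UltrafiltrationMeasurement],
) -> tuple[float, float | None, int]:
    """Arithmetic mean, sample SD and n of per-animal free fractions.

    SD is ``None`` for a single measurement (undefined, reported missing).
    """
    if not ms:
        raise InvalidInputError("no ultrafiltration measurements")
    fps = np.array([free_fraction(m) for m in ms])
    n = fps.size
    sd = float(fps.std(ddof=1)) if n > 1 else None
    return float(fps.mean()), sd, n
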