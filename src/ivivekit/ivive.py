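"""Well-stirred liver model and prediction-accuracy metrics.

The well-stirred model treats the liver as a single well-mixed compartment:

    CL_p = Q * f_p * CL_int / (Q + f_p * CL_int)

with Q the hepatic blood flow (mL/min/kg) and f_p the fraction unbound in
plasma. Prediction accuracy against observed clearance is summarized by the
fold error (predicted/observed), its geometric mean (average fold error,
AFE), and the root mean square error (RMSE).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError


@dataclass(frozen=True)
class ClearancePrediction:
    compound_id: str
    cl_int: float          # mL/min/kg
    f_p: float             # fraction unbound in plasma
    q: float               # hepatic blood flow, mL/min/kg
    cl_p_predicted: float  # mL/min/kg


@dataclass(frozen=True)
class AccuracyReport:
    """Per-compound fold errors plus the overall bias/precision metrics."""

    per_compound: list[tuple[str, float, float, float]]  # (id, pred, obs, fold)
    afe: float
    rmse: float

    @property
    def fold_underprediction(self) -> float:
        return 1.0 / self.afe


def well_stirred_clearance(cl_int: float, f_p: float, q: float) -> float:
    """Predicted plasma clearance (mL/min/kg), bounded above by Q."""
    if cl_int <= 0:
        raise InvalidInputError("cl_int must be > 0")
    if not 0 < f_p <= 1:
        raise InvalidInputError("f_p must be in (0, 1]")
    if q <= 0:
        raise InvalidInputError("q must be > 0")
    fu_clint = f_p * cl_int
    return q * fu_clint / (q + fu_clint)


def invert_well_stirred_fp(cl_p: float, cl_int: float, q: float) -> float:
    """Back-solve the plasma free fraction from a (CL_p, CL_int, Q) triple.

    Algebraic inverse of the well-stirred model; only defined for CL_p < Q
    (clearance cannot exceed hepatic blood flow).
    """
    if cl_int <= 0 or q <= 0:
        raise InvalidInputError("cl_int and q must be > 0")
    if not 0 < cl_p < q:
        raise InvalidInputError(
            f"no solution: cl_p must lie strictly between 0 and q={q}"
        )
    return cl_p * q / (cl_int * (q - cl_p))


def fold_error(predicted: float, observed: float) -> float:
    """Ratio predicted/observed; <1 means underprediction."""
    if predicted <= 0 or observed <= 0:
        raise InvalidInputError("predicted and observed must be > 0")
    return predicted / observed


def afe(pairs: list[tuple[float, float]]) -> float:
    """Average fold error: 10**(mean log10(predicted/observed)).

    Equals the geometric mean of the individual fold errors; an overall
    bias measure (symmetric on the log scale).
    """
    if not pairs:
        raise InvalidInputError("afe of an empty list")
    logs = [np.log10(fold_error(p, o)) for p, o in pairs]
    return float(10.0 ** np.mean(logs))


def rmse(pairs: list[tuple[float, float]]) -> float:
    """Root mean square error of predicted vs observed, in input units."""
    if not pairs:
        raise InvalidInputError("rmse of an empty list")
    diffs = np.array([p - o for p, o in pairs], dtype=float)
    return float(np.sqrt(np.mean(diffs**2)))


def accuracy_report(
    triples: list[tuple[str, float, float]],
) -> AccuracyReport:
    """Build the full accuracy report from (compound_id, predicted, observed)."""
    if not triples:
        raise InvalidInputError("accuracy report needs at least one compound")
    per = [
        (cid, pred, obs, fold_error(pred, obs)) for cid, pred, obs in triples
    ]
    pairs = [(pred, obs) for _, pred, obs in triples]
    return AccuracyReport(per_compound=per, afe=afe(pairs), rmse=rmse(pairs))
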