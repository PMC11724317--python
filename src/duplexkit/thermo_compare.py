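"""Stability comparisons between modified duplexes and their A-X references.

ddG37 = dG37(Y-X) - dG37(A-X) on formation-signed values, so a positive
ddG37 is a destabilization.  SDs propagate in quadrature because the two
duplexes are measured independently.  The 15% consistency rule compares the
van't Hoff-plot dH against the average of per-curve fits, the expected
agreement under a genuinely two-state transition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class ComparisonRecord:
    duplex_id: str
    reference_id: str
    ddG37: float              # kcal/mol, positive = destabilization
    sd_ddG37: float
    dTm: float                # degC at the common C_T
    ddG_pred: float | None = None
    overstab: float | None = None  # ddG37 - ddG_pred


def ddg(dg_y: float, dg_ref: float) -> float:
    """ddG = dG(Y-X) - dG(A-X), formation-signed inputs."""
    return dg_y - dg_ref


def sd_propagate(sd_a: float, sd_b: float) -> float:
    """sqrt(sd_a^2 + sd_b^2) for independent measurements."""
    if sd_a < 0 or sd_b < 0:
        raise ValueError("standard deviations must be >= 0")
    return float(np.hypot(sd_a, sd_b))


def delta_tm(tm_y: float, tm_ref: float) -> float:
    """dT_M = T_M(Y-X) - T_M(A-X), both at the same C_T."""
    return tm_y - tm_ref


def two_state_check(dh_vh: float, dh_avg: float,
                    threshold_pct: float = 15.0) -> tuple[bool, float]:
    """Relative dH disagreement between the two analysis routes.

    Returns (pass, percentage) with pct = 100*|dh_vh - dh_avg|/|dh_avg|;
    agreement within the threshold is the expected signature of a two-state
    transition.
    """
    if dh_avg == 0:
        raise ValueError("zero reference dH")
    pct = 100.0 * abs(dh_vh - dh_avg) / abs(dh_avg)
    return pct <= threshold_pct, pct


def pred_exp_correlation(pairs, include_references: bool = False) -> float:
    """Pearson r between experimental and predicted ddG values.

    ``pairs`` is a sequence of (ddg_exp, ddg_pred).  Reference duplexes
    enter as identically-(0, 0) pairs and are excluded by default.
    """
    arr = np.asarray(list(pairs), dtype=float)
    if not include_references:
        arr = arr[~np.all(arr == 0.0, axis=1)]
    if len(arr) < 3:
        raise ValueError("need >= 3 pairs")
    if np.ptp(arr[:, 0]) == 0 or np.ptp(arr[:, 1]) == 0:
        raise ValueError("zero variance in one coordinate")
    return float(stats.pearsonr(arr[:, 0], arr[:, 1]).statistic)


def compare_to_reference(dg_y, sd_y, tm_y, dg_ref, sd_ref, tm_ref,
                         duplex_id: str, reference_id: str,
                         ddg_pred: float | None = None) -> ComparisonRecord:
    """Assemble one comparison row (ddG37 +/- SD, dT_M, optional ddG_pred)."""
    d = ddg(dg_y, dg_ref)
    rec = ComparisonRecord(
        duplex_id=duplex_id, reference_id=reference_id,
        ddG37=d, sd_ddG37=sd_propagate(sd_y, sd_ref),
        dTm=delta_tm(tm_y, tm_ref), ddG_pred=ddg_pred,
        overstab=None if ddg_pred is None else d - ddg_pred)
    return rec
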