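"""Aggregation of per-frame binding-energy components into per-state dG_pred.

Per frame, the single-trajectory decomposition gives the interaction term
E_complex - E_strand1 - E_strand2 for the molecular-mechanics + solvation
(MM/3D-RISM) totals and for the normal-mode vibrational/entropic terms.
Per conformational state, dG_pred = <dG_MM/3D-RISM> - <dG_NMODE>, and
states are ranked by dG_pred; alternates within a window of the global
minimum (default 2.5 kcal/mol) are co-populated low-energy states.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

ENERGY_COLUMNS = ["frame", "state", "e_complex", "e_s1", "e_s2",
                  "g_nm_complex", "g_nm_s1", "g_nm_s2"]


@dataclass(frozen=True)
class FrameEnergies:
    frame: int
    state: str
    e_complex: float
    e_s1: float
    e_s2: float
    g_nm_complex: float
    g_nm_s1: float
    g_nm_s2: float


@dataclass(frozen=True)
class EnergyState:
    state: str
    dG_rism: float   # kcal/mol, <E_complex - E_s1 - E_s2>
    dG_nmode: float  # kcal/mol, <G_nm_complex - G_nm_s1 - G_nm_s2>
    n_frames: int

    @property
    def dG_pred(self) -> float:
        return self.dG_rism - self.dG_nmode


def _as_frame(frames) -> pd.DataFrame:
    if isinstance(frames, pd.DataFrame):
        df = frames
    else:
        df = pd.DataFrame([f.__dict__ for f in frames])
    missing = [c for c in ENERGY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"energy table missing columns {missing}")
    if not np.all(np.isfinite(df[ENERGY_COLUMNS[2:]].to_numpy(dtype=float))):
        raise ValueError("nonfinite energy components")
    return df


def aggregate_state(frames, state: str) -> EnergyState:
    """Mean per-frame interaction energies of one conformational state."""
    df = _as_frame(frames)
    sub = df[df["state"] == state]
    if len(sub) == 0:
        raise ValueError(f"no frames for state {state!r}")
    rism = (sub["e_complex"] - sub["e_s1"] - sub["e_s2"]).mean()
    nmode = (sub["g_nm_complex"] - sub["g_nm_s1"] - sub["g_nm_s2"]).mean()
    return EnergyState(state=state, dG_rism=float(rism),
                       dG_nmode=float(nmode), n_frames=len(sub))


def aggregate_all(frames) -> list:
    """One EnergyState per state label present in the table, sorted by dG_pred."""
    df = _as_frame(frames)
    states = [aggregate_state(df, s) for s in df["state"].unique()]
    return sorted(states, key=lambda s: s.dG_pred)


def ddg_pred(state: EnergyState, reference: EnergyState) -> float:
    """Predicted stability difference dG_pred(state) - dG_pred(reference)."""
    return state.dG_pred - reference.dG_pred


def global_minimum(states, tie_window: float = 2.5):
    """The state of minimal dG_pred plus near-tie alternates.

    Alternates are states whose dG_pred lies within ``tie_window`` kcal/mol
    of the minimum: conformations that remain appreciably populated rather
    than being excluded by the ranking.
    """
    states = list(states)
    if not states:
        raise ValueError("empty state list")
    best = min(states, key=lambda s: s.dG_pred)
    alternates = [s for s in states
                  if s is not best and s.dG_pred - best.dG_pred <= tie_window]
    return best, alternates


def overstabilization(ddg_exp: float, ddg_pred_value: float) -> float:
    """ddG37(experiment) - ddG_pred: how much the prediction overstabilizes."""
    return ddg_exp - ddg_pred_value
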