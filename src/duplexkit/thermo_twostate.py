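"""Two-state UV-melting thermodynamics of non-self-complementary duplexes.

A bimolecular duplex ``D <=> S1 + S2`` with association constant
``K(T) = exp(-dH/(R T) + dS/R)`` (van't Hoff, dCp = 0) produces an
absorbance-versus-temperature melting curve at 260 nm that interpolates
between a double-strand and a single-strand linear baseline according to
the duplex fraction f(T).  This module provides the forward model, the
per-curve six-parameter least-squares fit, the averaging of per-curve fits,
and the 1/T_M versus ln(C_T/4) concentration-dependence route to dH and dS.

All enthalpies are kcal/mol and entropies eu (cal mol^-1 K^-1),
formation-signed (negative for duplex formation).  Report layers print
magnitudes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.signal import savgol_filter

logger = logging.getLogger(__name__)

#: gas constant, cal mol^-1 K^-1
R_CAL = 1.9872
#: 0 degC in kelvin
KELVIN = 273.15
#: temperature at which hybridization free energies are reported
T37 = 310.15


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MeltCurve:
    """One absorbance-vs-temperature series at total strand concentration ct."""

    duplex_id: str
    temps: np.ndarray       # degC, strictly increasing
    absorbance: np.ndarray  # AU at 260 nm
    ct: float               # total strand concentration, mol/L

    def __post_init__(self):
        temps = np.asarray(self.temps, dtype=float)
        absorbance = np.asarray(self.absorbance, dtype=float)
        object.__setattr__(self, "temps", temps)
        object.__setattr__(self, "absorbance", absorbance)
        if temps.ndim != 1 or temps.shape != absorbance.shape:
            raise ValueError("temps and absorbance must be 1-D and equal length")
        if len(temps) < 20:
            raise ValueError(f"melting curve needs >= 20 points, got {len(temps)}")
        if not np.all(np.diff(temps) > 0):
            raise ValueError("temperatures must be strictly increasing")
        if not (np.isfinite(self.ct) and self.ct > 0):
            raise ValueError(f"ct must be positive, got {self.ct}")


@dataclass(frozen=True)
class ThermoParams:
    """dH/dS/dG37 (formation-signed) with sample SDs, for one duplex."""

    dH: float
    dS: float
    dG37: float
    sd_dH: float = 0.0
    sd_dS: float = 0.0
    sd_dG37: float = 0.0
    source: str = "vant_hoff"  # or "curve_fit_average"

    def __post_init__(self):
        if self.dH != 0 and self.dS != 0 and np.sign(self.dH) != np.sign(self.dS):
            warnings.warn(
                f"dH ({self.dH}) and dS ({self.dS}) have opposite signs",
                stacklevel=2,
            )


@dataclass(frozen=True)
class CurveFitResult:
    """Per-curve two-state fit: dH, dS, four baseline coefficients."""

    dH: float
    dS: float
    tm: float                       # degC at this curve's ct
    baseline_ss: tuple[float, float]  # slope (AU/degC), intercept (AU)
    baseline_ds: tuple[float, float]
    rms_residual: float             # AU
    converged: bool
    ct: float = np.nan
    message: str = ""

    @property
    def dG37(self) -> float:
        return dg_at_temperature(self.dH, self.dS, T37)


@dataclass(frozen=True)
class VantHoffFit:
    """OLS of 1/T_M on ln(C_T/4) and the derived dH, dS."""

    slope: float      # K^-1 per ln unit
    intercept: float  # K^-1
    dH: float         # kcal/mol
    dS: float         # eu
    r_squared: float
    n_points: int

    @property
    def dG37(self) -> float:
        return dg_at_temperature(self.dH, self.dS, T37)


@dataclass(frozen=True)
class ExtinctionTable:
    """260 nm nearest-neighbour molar extinction coefficients (M^-1 cm^-1)."""

    monomer: dict
    dimer: dict

    def __post_init__(self):
        bad = [k for k, v in {**self.monomer, **self.dimer}.items() if not v > 0]
        if bad:
            raise ValueError(f"non-positive extinction coefficients for {bad}")


#: residue codes whose extinction coefficients are approximated by A's
MODIFIED_ALIASES = {"7A": "A", "AL": "A", "7AL": "A"}


def load_extinction_table() -> ExtinctionTable:
    """The embedded standard 260 nm monomer/dimer coefficient table."""
    with resources.files("duplexkit.data").joinpath("extinction_nn_260.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    mono = {r.key: float(r.epsilon) for r in df.itertuples() if r.kind == "monomer"}
    dim = {r.key: float(r.epsilon) for r in df.itertuples() if r.kind == "dimer"}
    return ExtinctionTable(monomer=mono, dimer=dim)


# ---------------------------------------------------------------------------
# the two-state model
# ---------------------------------------------------------------------------

def equilibrium_constant(dH: float, dS: float, temp_k):
    """Association constant K(T) = exp(-dH*1000/(R T) + dS/R), dCp = 0."""
    temp_k = np.asarray(temp_k, dtype=float)
    return np.exp(-dH * 1000.0 / (R_CAL * temp_k) + dS / R_CAL)


def fraction_duplex(K, ct: float):
    """Fraction of strands in duplex for K = 2f / ((1-f)^2 ct).

    Closed form of the two-state bimolecular equilibrium for a
    non-self-complementary duplex at total strand concentration ct:
    with a = K*ct, f = ((a+1) - sqrt(2a+1)) / a, the root in [0, 1].
    """
    K = np.asarray(K, dtype=float)
    if not np.all(np.isfinite(K)) or not np.isfinite(ct):
        raise ValueError("nonfinite K or ct")
    if np.any(K < 0) or ct <= 0:
        raise ValueError("require K >= 0 and ct > 0")
    a = K * ct
    with np.errstate(invalid="ignore", divide="ignore", over="ignore"):
        f = np.where(
            a > 1e-8,
            ((a + 1.0) - np.sqrt(2.0 * a + 1.0)) / np.where(a == 0, 1.0, a),
            a / 2.0,  # series limit as a -> 0
        )
        f = np.where(np.isinf(a), 1.0, f)
    return np.clip(f, 0.0, 1.0)[()] if f.ndim == 0 else np.clip(f, 0.0, 1.0)


def simulate_absorbance(params: ThermoParams, ct: float, temps,
                        baselines=(0.0, 1.0, 0.0, 0.6)) -> MeltCurve:
    """Forward model A(T) = (1-f) * ss_baseline(T) + f * ds_baseline(T).

    ``baselines`` is (m_ss, b_ss, m_ds, b_ds) in AU/degC and AU; temperatures
    are degC.  The duplex fraction f comes from :func:`fraction_duplex` with
    the van't Hoff K(T).
    """
    if params.dH == 0:
        raise ValueError("dH = 0 gives no melting transition")
    temps = np.asarray(temps, dtype=float)
    m_ss, b_ss, m_ds, b_ds = baselines
    K = equilibrium_constant(params.dH, params.dS, temps + KELVIN)
    f = fraction_duplex(K, ct)
    absorbance = (1.0 - f) * (m_ss * temps + b_ss) + f * (m_ds * temps + b_ds)
    return MeltCurve(duplex_id="simulated", temps=temps,
                     absorbance=absorbance, ct=ct)


def dg_at_temperature(dH: float, dS: float, temp_k: float = T37) -> float:
    """dG(T) = dH - T*dS/1000, kcal/mol."""
    return dH - temp_k * dS / 1000.0


def tm_at_concentration(dH: float, dS: float, ct: float,
                        self_complementary: bool = False) -> float:
    """Melting temperature in degC where K(T_M) = 4/C_T (or 1/C_T).

    T_M(K) = dH*1000 / (dS + R ln(ct/4)) with formation-signed dH, dS.
    """
    if dH == 0 or dS == 0 or np.sign(dH) != np.sign(dS):
        raise ValueError("dH and dS must be nonzero with the same sign")
    factor = 1.0 if self_complementary else 4.0
    denom = dS + R_CAL * np.log(ct / factor)
    if dH < 0 and denom >= 0:
        raise ValueError("no physical melting temperature (denominator >= 0)")
    return dH * 1000.0 / denom - KELVIN


# ---------------------------------------------------------------------------
# per-curve fitting
# ---------------------------------------------------------------------------

def _baseline_guesses(curve: MeltCurve, frac: float = 0.15):
    """Linear fits to the first/last `frac` of points (ds low-T, ss high-T)."""
    n = max(2, int(round(frac * len(curve.temps))))
    lo = np.polyfit(curve.temps[:n], curve.absorbance[:n], 1)
    hi = np.polyfit(curve.temps[-n:], curve.absorbance[-n:], 1)
    # (m_ds, b_ds), (m_ss, b_ss): duplex dominates the low-T end
    return (hi[0], hi[1]), (lo[0], lo[1])


def _tm_guess(curve: MeltCurve) -> float:
    """Temperature of the max of the smoothed dA/dT."""
    window = min(11, len(curve.temps) - (1 - len(curve.temps) % 2))
    absorb = curve.absorbance
    if window >= 5:
        absorb = savgol_filter(curve.absorbance, window, 3)
    dadt = np.gradient(absorb, curve.temps)
    return float(curve.temps[np.argmax(np.abs(dadt))])


def fit_single_curve(curve: MeltCurve, init: dict | None = None,
                     window: tuple[float, float] | None = None) -> CurveFitResult:
    """Six-parameter (dH, dS, two linear baselines) least-squares fit.

    ``window`` optionally truncates the curve to a [t_low, t_high] degC range
    before fitting (baseline-truncation flexibility; changing it can move the
    fitted parameters by a few percent).  Non-convergence or a featureless
    curve is reported with ``converged=False``, never silently.
    """
    temps, absorb = curve.temps, curve.absorbance
    if window is not None:
        mask = (temps >= window[0]) & (temps <= window[1])
        if mask.sum() < 20:
            raise ValueError("temperature window leaves fewer than 20 points")
        curve = MeltCurve(curve.duplex_id, temps[mask], absorb[mask], curve.ct)
        temps, absorb = curve.temps, curve.absorbance

    init = dict(init or {})
    bl_ss, bl_ds = _baseline_guesses(curve)
    dh0 = init.get("dH", -70.0)
    tm0 = init.get("tm", _tm_guess(curve)) + KELVIN
    # dS consistent with K(tm0) = 4/ct
    ds0 = init.get("dS", dh0 * 1000.0 / tm0 - R_CAL * np.log(curve.ct / 4.0))

    def residuals(theta):
        dh, ds, m_ss, b_ss, m_ds, b_ds = theta
        with np.errstate(over="ignore"):
            K = equilibrium_constant(dh, ds, temps + KELVIN)
        f = fraction_duplex(K, curve.ct)
        model = (1.0 - f) * (m_ss * temps + b_ss) + f * (m_ds * temps + b_ds)
        return model - absorb

    theta0 = np.array([dh0, ds0, bl_ss[0], bl_ss[1], bl_ds[0], bl_ds[1]])
    sol = optimize.least_squares(residuals, theta0, method="lm",
                                 ftol=1e-10, xtol=1e-12, max_nfev=500 * 7)
    dh, ds, m_ss, b_ss, m_ds, b_ds = sol.x
    rms = float(np.sqrt(np.mean(sol.fun ** 2)))

    converged = bool(sol.success) and np.all(np.isfinite(sol.x))
    message = sol.message
    tm = np.nan
    if converged:
        # a real transition must sweep the duplex fraction inside the window
        f = fraction_duplex(equilibrium_constant(dh, ds, temps + KELVIN), curve.ct)
        delta = (m_ds - m_ss) * temps + (b_ds - b_ss)
        amplitude = np.max(np.abs(f * delta))
        span = max(np.ptp(absorb), 1e-12)
        if f.max() - f.min() < 0.2 or amplitude < 0.01 * span:
            converged, message = False, "no melting transition in window"
        elif np.sign(dh) != np.sign(ds) or dh == 0:
            converged, message = False, "unphysical dH/dS signs"
        else:
            tm = tm_at_concentration(dh, ds, curve.ct)
            if not (temps[0] <= tm <= temps[-1]):
                warnings.warn(
                    f"{curve.duplex_id}: fitted T_M {tm:.1f} degC outside the "
                    f"measured span", stacklevel=2)
    return CurveFitResult(dH=float(dh), dS=float(ds), tm=float(tm),
                          baseline_ss=(float(m_ss), float(b_ss)),
                          baseline_ds=(float(m_ds), float(b_ds)),
                          rms_residual=rms, converged=converged,
                          ct=curve.ct, message=message)


def average_curve_fits(fits: list[CurveFitResult]) -> ThermoParams:
    """Per-parameter mean and sample SD over converged per-curve fits.

    dG37 is averaged over the per-curve dG37 values, not recomputed from the
    mean dH and dS (the two differ because dG37 is a correlated combination).
    """
    good = [f for f in fits if f.converged]
    if len(good) < 2:
        raise ValueError(f"need >= 2 converged fits, got {len(good)}")
    dh = np.array([f.dH for f in good])
    ds = np.array([f.dS for f in good])
    dg = np.array([f.dG37 for f in good])
    return ThermoParams(
        dH=float(dh.mean()), dS=float(ds.mean()), dG37=float(dg.mean()),
        sd_dH=float(dh.std(ddof=1)), sd_dS=float(ds.std(ddof=1)),
        sd_dG37=float(dg.std(ddof=1)), source="curve_fit_average")


# ---------------------------------------------------------------------------
# concentration-dependence (van't Hoff plot) route
# ---------------------------------------------------------------------------

def vant_hoff_fit(points, self_complementary: bool = False) -> VantHoffFit:
    """OLS of 1/T_M on ln(C_T/4) over (ct mol/L, tm K) points.

    1/T_M = (R / (dH*1000)) ln(C_T/4) + dS/(dH*1000), hence
    dH = R/slope (converted to kcal/mol) and dS = intercept * dH * 1000.
    """
    cts = np.array([p[0] for p in points], dtype=float)
    tms = np.array([p[1] for p in points], dtype=float)
    if len(np.unique(cts)) != len(cts):
        warnings.warn("duplicate ct values collapsed by averaging 1/T_M",
                      stacklevel=2)
        uniq = np.unique(cts)
        inv = np.array([np.mean(1.0 / tms[cts == c]) for c in uniq])
        cts, inv_tm = uniq, inv
    else:
        inv_tm = 1.0 / tms
    if len(cts) < 3:
        raise ValueError("need >= 3 distinct concentrations")
    factor = 1.0 if self_complementary else 4.0
    x = np.log(cts / factor)
    res = stats.linregress(x, inv_tm)
    if res.slope == 0:
        raise ValueError("zero slope: no concentration dependence")
    dH = R_CAL / res.slope / 1000.0          # kcal/mol
    dS = res.intercept * dH * 1000.0         # eu
    return VantHoffFit(slope=float(res.slope), intercept=float(res.intercept),
                       dH=float(dH), dS=float(dS),
                       r_squared=float(res.rvalue ** 2), n_points=len(cts))


# ---------------------------------------------------------------------------
# strand concentration from absorbance
# ---------------------------------------------------------------------------

def extinction_nn(sequence, table: ExtinctionTable | None = None) -> float:
    """Nearest-neighbour 260 nm extinction coefficient of a single strand.

    eps = sum_i 2*eps(pair i, i+1) - sum over internal residues of
    eps(monomer).  ``sequence`` is a string of one-letter codes or a list of
    codes; the modified codes 7A, AL and 7AL are approximated by A's
    coefficients (logged, since no coefficients exist for them).
    """
    table = table or load_extinction_table()
    codes = list(sequence) if isinstance(sequence, str) else [str(c) for c in sequence]
    mapped = []
    for code in codes:
        if code in MODIFIED_ALIASES:
            logger.warning("extinction: approximating %s by A", code)
            mapped.append(MODIFIED_ALIASES[code])
        elif code in table.monomer:
            mapped.append(code)
        else:
            raise KeyError(f"no extinction coefficient for residue code {code!r}")
    if len(mapped) == 1:
        return table.monomer[mapped[0]]
    eps = 0.0
    for a, b in zip(mapped[:-1], mapped[1:]):
        pair = a + b
        if pair not in table.dimer:
            raise KeyError(f"no dimer extinction coefficient for {pair!r}")
        eps += 2.0 * table.dimer[pair]
    for code in mapped[1:-1]:
        eps -= table.monomer[code]
    return eps


def strand_concentration(absorbance: float, epsilon: float, path: float = 1.0) -> float:
    """Beer-Lambert c = A/(eps*l), mol/L (absorbance read at 80 degC)."""
    if not (absorbance > 0 and epsilon > 0 and path > 0):
        raise ValueError("absorbance, epsilon and path length must be positive")
    return absorbance / (epsilon * path)
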