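"""Synthetic inputs with the statistical structure the analysis assumes.

Three generators stand in for the raw instrument and trajectory data, which
are not deposited:

* melting-curve datasets: nine-concentration (1-100 uM) absorbance series
  from the two-state forward model with linear baselines plus i.i.d.
  Gaussian noise;
* duplex coordinate frames: a 9-bp duplex with correct residue/atom naming
  (including the N7-glycosylated 7A/7AL conventions) whose middle base pair
  is posed in prescribed chi states and hydrogen-bond patterns, plus
  Gaussian coordinate jitter;
* per-frame energy-component tables with known per-state means.

Every generator is deterministic given its seed and emits a ground-truth
record alongside the data so downstream recovery is testable.

The duplex geometry is idealized (computed ring polygons, stacked residues,
no helical twist): every consuming operation here is geometric - torsions,
hydrogen-bond geometry, RMSD - not energetic, so plausible bond lengths and
exact prescribed torsions are what matters, not a faithful A-form builder.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .thermo_twostate import MeltCurve, ThermoParams, simulate_absorbance
from .traj_conformation import (ACCEPTORS, DONORS, FrameSet, chi_for_residue,
                                dihedral, superpose_rmsd, wrap_chi)

DEFAULT_CT_LIST = tuple(np.geomspace(1e-6, 1e-4, 9))

#: strand sequences of the study duplexes, 5'->3'; X and Y are the middle
#: mismatch residues (strand B pairs antiparallel, so B residue j faces
#: A residue 10-j)
STRAND_A = ("U", "C", "A", "G", None, "C", "A", "G", "U")
STRAND_B = ("A", "C", "U", "G", None, "C", "U", "G", "A")


# ---------------------------------------------------------------------------
# truth records
# ---------------------------------------------------------------------------

@dataclass
class MeltTruth:
    """Ground truth for a melting dataset (formation-signed dH, dS)."""

    dH: float = -68.4
    dS: float = -195.4
    baselines: tuple = (0.0008, 0.95, 0.0002, 0.70)  # m_ss, b_ss, m_ds, b_ds
    noise_sd: float = 0.002  # AU
    ct_list: tuple = DEFAULT_CT_LIST
    seed: int = 0
    duplex_id: str = "synthetic"

    @property
    def params(self) -> ThermoParams:
        from .thermo_twostate import dg_at_temperature
        return ThermoParams(dH=self.dH, dS=self.dS,
                            dG37=dg_at_temperature(self.dH, self.dS))


@dataclass
class ConformerTruth:
    """Per-state middle-pair geometry targets and per-frame schedule.

    ``states`` maps a loop-orientation label to (chi of the 5'-strand
    middle residue, chi of the 3'-strand middle residue, number of
    middle-pair hydrogen bonds), chi in degrees in [-90, 270).
    ``schedule`` gives the population fraction of each state; frames are
    assigned by quota (round(fraction * n)) and shuffled by the seed so the
    realized populations match the nominal ones.
    """

    states: dict = field(default_factory=lambda: {
        "anti-anti": (210.0, 210.0, 2),
        "syn-anti": (30.0, 210.0, 2),
    })
    schedule: dict = field(default_factory=lambda: {
        "anti-anti": 0.7, "syn-anti": 0.3,
    })
    x_code: str = "7A"
    y_code: str = "A"
    jitter_sd: float = 0.05  # angstrom
    seed: int = 0


# ---------------------------------------------------------------------------
# melting curves
# ---------------------------------------------------------------------------

def gen_melt_dataset(truth: MeltTruth, t_min: float = 0.0, t_max: float = 90.0,
                     t_step: float = 0.5):
    """One noisy MeltCurve per concentration plus a manifest and the truth.

    Returns (curves, manifest, truth) where manifest is a DataFrame with
    columns duplex_id, ct_molar, run_id and truth is a plain dict suitable
    for a structured-text sidecar.
    """
    rng = np.random.default_rng(truth.seed)
    temps = np.arange(t_min, t_max + t_step / 2, t_step)
    curves, rows = [], []
    for i, ct in enumerate(truth.ct_list):
        clean = simulate_absorbance(truth.params, ct, temps, truth.baselines)
        noisy = clean.absorbance + rng.normal(0.0, truth.noise_sd, len(temps))
        curves.append(MeltCurve(duplex_id=truth.duplex_id, temps=temps,
                                absorbance=noisy, ct=ct))
        rows.append({"duplex_id": truth.duplex_id, "ct_molar": ct,
                     "run_id": f"run{i + 1}"})
    manifest = pd.DataFrame(rows)
    record = {"dH": truth.dH, "dS": truth.dS, "dG37": truth.params.dG37,
              "baselines": list(truth.baselines), "noise_sd": truth.noise_sd,
              "ct_list": list(truth.ct_list), "seed": truth.seed}
    return curves, manifest, record


# ---------------------------------------------------------------------------
# duplex frame geometry
# ---------------------------------------------------------------------------

def _polygon(n: int, side: float) -> np.ndarray:
    """Regular n-gon vertices (2D) with given side length, centred at 0."""
    radius = side / (2.0 * np.sin(np.pi / n))
    ang = np.pi / 2 + 2 * np.pi * np.arange(n) / n
    return np.stack([radius * np.cos(ang), radius * np.sin(ang)], axis=1)


def _fused_hexagon(p: np.ndarray, q: np.ndarray, away_from: np.ndarray):
    """Hexagon vertices starting with edge p->q, built away from a point."""
    out = None
    for sign in (1.0, -1.0):
        verts = [p, q]
        d = q - p
        rot = np.array([[np.cos(sign * np.pi / 3), -np.sin(sign * np.pi / 3)],
                        [np.sin(sign * np.pi / 3), np.cos(sign * np.pi / 3)]])
        for _ in range(4):
            d = rot @ d
            verts.append(verts[-1] + d)
        verts = np.array(verts)
        centroid = verts.mean(axis=0)
        if out is None or (np.linalg.norm(centroid - away_from)
                           > np.linalg.norm(out.mean(axis=0) - away_from)):
            out = verts
    return out


def _exocyclic(host: np.ndarray, centroid: np.ndarray, length: float):
    u = host - centroid
    return host + length * u / np.linalg.norm(u)


def _base_2d(code: str) -> dict:
    """In-plane base atom coordinates keyed by atom name."""
    atoms = {}
    if code in ("A", "7A", "AL", "7AL", "G"):
        penta = _polygon(5, 1.37)  # N9, C8, N7, C5, C4 around the ring
        for name, xy in zip(("N9", "C8", "N7", "C5", "C4"), penta):
            atoms[name] = xy
        hexa = _fused_hexagon(atoms["C4"], atoms["C5"],
                              away_from=penta.mean(axis=0))
        # walk C4 -> C5 -> C6 -> N1 -> C2 -> N3
        for name, xy in zip(("C4", "C5", "C6", "N1", "C2", "N3"), hexa):
            atoms[name] = xy
        centroid = hexa.mean(axis=0)
        if code == "G":
            atoms["O6"] = _exocyclic(atoms["C6"], centroid, 1.23)
            atoms["N2"] = _exocyclic(atoms["C2"], centroid, 1.35)
            n2c = atoms["N2"] - centroid
            perp = np.array([-n2c[1], n2c[0]]) / np.linalg.norm(n2c)
            atoms["H21"] = atoms["N2"] + 0.88 * n2c / np.linalg.norm(n2c) + 0.5 * perp
            atoms["H22"] = atoms["N2"] + 0.88 * n2c / np.linalg.norm(n2c) - 0.5 * perp
            atoms["H1"] = _exocyclic(atoms["N1"], centroid, 1.01)
        else:
            atoms["N6"] = _exocyclic(atoms["C6"], centroid, 1.35)
            n6c = atoms["N6"] - centroid
            perp = np.array([-n6c[1], n6c[0]]) / np.linalg.norm(n6c)
            unit = n6c / np.linalg.norm(n6c)
            atoms["H61"] = atoms["N6"] + 0.88 * unit + 0.5 * perp
            atoms["H62"] = atoms["N6"] + 0.88 * unit - 0.5 * perp
    elif code in ("C", "U"):
        hexa = _polygon(6, 1.37)  # N1, C2, N3, C4, C5, C6
        for name, xy in zip(("N1", "C2", "N3", "C4", "C5", "C6"), hexa):
            atoms[name] = xy
        centroid = hexa.mean(axis=0)
        atoms["O2"] = _exocyclic(atoms["C2"], centroid, 1.23)
        if code == "U":
            atoms["O4"] = _exocyclic(atoms["C4"], centroid, 1.23)
            atoms["H3"] = _exocyclic(atoms["N3"], centroid, 1.01)
        else:
            atoms["N4"] = _exocyclic(atoms["C4"], centroid, 1.35)
            n4c = atoms["N4"] - centroid
            perp = np.array([-n4c[1], n4c[0]]) / np.linalg.norm(n4c)
            unit = n4c / np.linalg.norm(n4c)
            atoms["H41"] = atoms["N4"] + 0.88 * unit + 0.5 * perp
            atoms["H42"] = atoms["N4"] + 0.88 * unit - 0.5 * perp
    else:
        raise KeyError(f"unknown residue code {code!r}")
    return atoms


#: atom the ribose attaches to, per residue code
GLYCO_ATOM = {"A": "N9", "G": "N9", "AL": "N9", "C": "N1", "U": "N1",
              "7A": "N7", "7AL": "N7"}

#: approximate ribofuranose ring (angstrom), C1' at the origin
SUGAR = {
    "C1'": np.array([0.0, 0.0, 0.0]),
    "O4'": np.array([-0.70, 1.17, 0.20]),
    "C4'": np.array([-2.07, 0.77, -0.10]),
    "C3'": np.array([-2.18, -0.75, 0.20]),
    "C2'": np.array([-0.87, -1.20, -0.20]),
}


def _element(name: str) -> str:
    return name[0]


def _build_residue(code: str, chi: float) -> tuple[list, np.ndarray]:
    """One residue with its glycosidic torsion set exactly to ``chi``.

    The sugar sits in a local frame with C1' at the origin; the base plane
    is embedded along the glycosidic bond (+x) and then rotated rigidly
    about the C1'->N axis until dihedral(O4', C1', N, C_ref) equals the
    requested chi.
    """
    from .traj_conformation import CHI_ATOMS

    names = list(SUGAR)
    coords = [SUGAR[n] for n in names]
    glyco = GLYCO_ATOM[code]
    n_pos = np.array([1.47, 0.0, 0.0])
    base2d = _base_2d(code)
    origin2d = base2d[glyco]
    # keep the chi reference atom off the glycosidic-bond axis: rotate the
    # base in its own plane if the N->C_ref direction lies along the bond
    ref_rel = base2d[CHI_ATOMS[code][1]] - origin2d
    if abs(ref_rel[1]) < 0.3 * np.linalg.norm(ref_rel):
        # large in-plane rotation keeps the reference atom's lever arm about
        # the glycosidic axis long, so jitter propagates weakly into chi
        ang = np.radians(110.0)
        rot2 = np.array([[np.cos(ang), -np.sin(ang)],
                         [np.sin(ang), np.cos(ang)]])
        base2d = {k: origin2d + rot2 @ (v - origin2d) for k, v in base2d.items()}
    e1, e2 = np.array([1.0, 0.0, 0.0]), np.array([0.0, 0.6, 0.8])
    base_names, base_xyz = [], []
    for name, xy in base2d.items():
        rel = xy - origin2d
        base_names.append(name)
        base_xyz.append(n_pos + rel[0] * e1 + rel[1] * e2)
    base_xyz = np.array(base_xyz)

    ref_atom = CHI_ATOMS[code][1]
    current = wrap_chi(dihedral(SUGAR["O4'"], SUGAR["C1'"], n_pos,
                                base_xyz[base_names.index(ref_atom)]))
    axis = n_pos / np.linalg.norm(n_pos)  # C1' at origin
    for delta in (chi - current, -(chi - current)):
        rot = Rotation.from_rotvec(np.radians(delta) * axis)
        trial = rot.apply(base_xyz - n_pos) + n_pos
        got = wrap_chi(dihedral(SUGAR["O4'"], SUGAR["C1'"], n_pos,
                                trial[base_names.index(ref_atom)]))
        if abs((got - chi + 180) % 360 - 180) < 1e-6:
            base_xyz = trial
            break
    else:
        raise RuntimeError("failed to pose chi")  # pragma: no cover

    names.extend(base_names)
    coords = np.vstack([np.array(coords), base_xyz])
    return names, coords


#: inter-strand C1'-C1' separation along x, angstrom; generous so that only
#: explicitly posed donor/acceptor pairs can satisfy hydrogen-bond geometry
STRAND_SEP = 18.0
RISE = 3.5


def _reference_frame(truth: ConformerTruth, label: str):
    """Atom table plus coordinates of one state's reference conformation."""
    chi1, chi2, n_hb = truth.states[label]
    seq_a = [truth.x_code if s is None else s for s in STRAND_A]
    seq_b = [truth.y_code if s is None else s for s in STRAND_B]
    rows, xyz = [], []
    flip = Rotation.from_euler("z", 180, degrees=True)
    for chain, seq in (("A", seq_a), ("B", seq_b)):
        for j, code in enumerate(seq, start=1):
            mid = (j == 5)
            chi = (chi1 if chain == "A" else chi2) if mid else 200.0
            names, coords = _build_residue(code, chi)
            if chain == "A":
                coords = coords + np.array([0.0, 0.0, RISE * j])
            else:
                coords = flip.apply(coords)
                coords = coords + np.array([STRAND_SEP, 0.0, RISE * (10 - j)])
            for name, c in zip(names, coords):
                rows.append({"name": name, "resid": j, "resname": code,
                             "chain": chain, "element": _element(name)})
                xyz.append(c)
    atoms = pd.DataFrame(rows)
    xyz = np.array(xyz)

    # pose the prescribed number of middle-pair hydrogen bonds by placing
    # acceptor atoms along the donor-H directions (on) or far away (off)
    def _locate(chain, resid, name):
        m = ((atoms["chain"] == chain) & (atoms["resid"] == resid)
             & (atoms["name"] == name))
        (i,) = np.flatnonzero(m.to_numpy())
        return i

    slots = []
    for dch, ach in (("A", "B"), ("B", "A")):
        dcode = truth.x_code if dch == "A" else truth.y_code
        acode = truth.y_code if dch == "A" else truth.x_code
        donor, hyds = next(iter(DONORS[dcode].items()))
        acceptor = ACCEPTORS[acode][0]
        slots.append((dch, donor, hyds[0], ach, acceptor))
    for k, (dch, donor, hyd, ach, acceptor) in enumerate(slots):
        d = xyz[_locate(dch, 5, donor)]
        h = xyz[_locate(dch, 5, hyd)]
        u = (h - d) / np.linalg.norm(h - d)
        reach = 1.9 if k < n_hb else 6.0
        xyz[_locate(ach, 5, acceptor)] = h + reach * u
    return atoms, xyz


def gen_duplex_frames(truth: ConformerTruth, n_frames: int):
    """FrameSet of jittered snapshots plus per-frame ground-truth labels.

    Returns (frameset, labels) where labels is a DataFrame with columns
    frame, state, n_hbonds.  State counts follow the quota schedule; frame
    order groups states in the order they appear in ``truth.schedule``
    (mimicking concatenated per-start trajectories) unless shuffled
    downstream.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(truth.seed)
    refs = {label: _reference_frame(truth, label) for label in truth.states}

    atoms = next(iter(refs.values()))[0]
    heavy_mid = FrameSet(coords=np.zeros((1, len(atoms), 3)), atoms=atoms,
                         provenance=()).middle_pair_heavy_indices()
    labels_list = list(refs)
    for i, a in enumerate(labels_list):
        for b in labels_list[i + 1:]:
            sep = superpose_rmsd(refs[a][1][heavy_mid], refs[b][1][heavy_mid])
            if sep < 4.0 * truth.jitter_sd:
                warnings.warn(
                    f"states {a}/{b} separated by only {sep:.2f} A at jitter "
                    f"{truth.jitter_sd}: clustering is ill-posed", stacklevel=2)

    quotas = {lab: int(round(frac * n_frames))
              for lab, frac in truth.schedule.items()}
    # adjust the last quota so the total is exactly n_frames
    drift = n_frames - sum(quotas.values())
    quotas[list(quotas)[-1]] += drift
    schedule = [lab for lab in truth.schedule for _ in range(quotas[lab])]

    coords, rows = [], []
    for i, lab in enumerate(schedule):
        ref = refs[lab][1]
        coords.append(ref + rng.normal(0.0, truth.jitter_sd, ref.shape))
        rows.append({"frame": i, "state": lab,
                     "n_hbonds": truth.states[lab][2]})
    fs = FrameSet(coords=np.array(coords), atoms=atoms,
                  provenance=tuple(truth.schedule))
    return fs, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# energy tables
# ---------------------------------------------------------------------------

def gen_energy_table(state_means: dict, noise_sd: float = 0.5,
                     n_per_state: int = 100, seed: int = 0):
    """Per-frame energy components with prescribed per-state means.

    ``state_means`` maps state label -> (dG_rism, dG_nmode); components are
    drawn so that the per-state mean differences equal the prescribed
    values.  Returns (table, truth) with the table in the delimited-text
    column dialect the aggregation stage reads.
    """
    if n_per_state < 1:
        raise ValueError("n_per_state must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    frame = 0
    for state, (rism, nmode) in state_means.items():
        for _ in range(n_per_state):
            e_s1 = -60.0 + rng.normal(0, noise_sd)
            e_s2 = -45.0 + rng.normal(0, noise_sd)
            e_complex = -105.0 + rism + rng.normal(0, noise_sd)
            g_s1 = -20.0 + rng.normal(0, noise_sd)
            g_s2 = -15.0 + rng.normal(0, noise_sd)
            g_complex = -35.0 + nmode + rng.normal(0, noise_sd)
            rows.append({"frame": frame, "state": state,
                         "e_complex": e_complex, "e_s1": e_s1, "e_s2": e_s2,
                         "g_nm_complex": g_complex, "g_nm_s1": g_s1,
                         "g_nm_s2": g_s2})
            frame += 1
    truth = {s: {"dG_rism": v[0], "dG_nmode": v[1], "dG_pred": v[0] - v[1]}
             for s, v in state_means.items()}
    return pd.DataFrame(rows), truth
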