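"""Conformational-state analysis of duplex coordinate frames.

Given an ordered set of duplex snapshots (e.g. concatenated MD trajectories
started from anti-anti, syn-anti, anti-syn and syn-syn middle-pair states),
this module computes glycosidic chi torsions and syn/anti calls, middle
base-pair hydrogen bonds, optimally-superposed RMSDs, single-pass leader
clustering at a fixed RMSD threshold, per-cluster average structures and
joint loop-orientation labels.

chi is defined over O4'-C1'-N9-C4 for N9 purines, O4'-C1'-N1-C2 for
pyrimidines and O4'-C1'-N7-C5 for the N7-glycosylated adenosines (the base
atom adjacent to the six-membered ring, by analogy with the N9 case), and
reported in [-90, 270) so that syn is [-90, 90) and anti (including
high-anti) is [90, 270).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

#: chi-defining (glycosidic N, base C) atoms per residue code
CHI_ATOMS = {
    "A": ("N9", "C4"), "G": ("N9", "C4"), "AL": ("N9", "C4"),
    "C": ("N1", "C2"), "U": ("N1", "C2"),
    "7A": ("N7", "C5"), "7AL": ("N7", "C5"),
}

#: base hydrogen-bond donors: heavy atom -> attached hydrogens
DONORS = {
    "A": {"N6": ("H61", "H62")},
    "7A": {"N6": ("H61", "H62")},
    "AL": {"N6": ("H61", "H62")},
    "7AL": {"N6": ("H61", "H62")},
    "G": {"N1": ("H1",), "N2": ("H21", "H22")},
    "C": {"N4": ("H41", "H42")},
    "U": {"N3": ("H3",)},
}

#: base hydrogen-bond acceptors (ring nitrogens / carbonyl oxygens)
ACCEPTORS = {
    "A": ("N1", "N3", "N7"),
    "7A": ("N1", "N3", "N9"),
    "AL": ("N1", "N3", "N7"),
    "7AL": ("N1", "N3", "N9"),
    "G": ("O6", "N3", "N7"),
    "C": ("O2", "N3"),
    "U": ("O2", "O4"),
}


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class FrameSet:
    """Ordered duplex coordinate frames with shared atom metadata.

    ``coords`` has shape (n_frames, n_atoms, 3) in angstroms; ``atoms`` is a
    DataFrame with columns name, resid, resname, chain, element sharing the
    coordinate row order; ``provenance`` records the source trajectory
    labels in concatenation order.
    """

    coords: np.ndarray
    atoms: pd.DataFrame
    provenance: tuple = ()

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != len(self.atoms):
            raise ValueError("atom table does not match coordinate width")
        lengths = {c: g["resid"].nunique() for c, g in self.atoms.groupby("chain")}
        if len(lengths) != 2 or len(set(lengths.values())) != 1:
            raise ValueError("FrameSet requires two equal-length strands")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def chains(self) -> list:
        return sorted(self.atoms["chain"].unique())

    def strand_resids(self, chain) -> list:
        sub = self.atoms[self.atoms["chain"] == chain]
        return sorted(sub["resid"].unique())

    def residue_atom_indices(self, chain, resid) -> np.ndarray:
        mask = (self.atoms["chain"] == chain) & (self.atoms["resid"] == resid)
        return np.flatnonzero(mask.to_numpy())

    def residue_code(self, chain, resid) -> str:
        idx = self.residue_atom_indices(chain, resid)
        if len(idx) == 0:
            raise KeyError(f"no residue {chain}:{resid}")
        return str(self.atoms.iloc[idx[0]]["resname"])

    def atom_index(self, chain, resid, name) -> int:
        mask = ((self.atoms["chain"] == chain) & (self.atoms["resid"] == resid)
                & (self.atoms["name"] == name))
        idx = np.flatnonzero(mask.to_numpy())
        if len(idx) != 1:
            raise KeyError(f"atom {name} of residue {chain}:{resid} "
                           f"{'missing' if len(idx) == 0 else 'ambiguous'}")
        return int(idx[0])

    def middle_pair(self) -> list:
        """(chain, resid) of the middle residue of each strand (5' strand first)."""
        out = []
        for chain in self.chains:
            resids = self.strand_resids(chain)
            out.append((chain, resids[int(np.ceil(len(resids) / 2)) - 1]))
        return out

    def middle_pair_heavy_indices(self) -> np.ndarray:
        idx = []
        for chain, resid in self.middle_pair():
            res_idx = self.residue_atom_indices(chain, resid)
            elements = self.atoms.iloc[res_idx]["element"].to_numpy()
            idx.extend(res_idx[elements != "H"])
        return np.array(sorted(idx))


@dataclass(frozen=True)
class TorsionRecord:
    frame: int
    chain: str
    resid: int
    chi: float   # degrees in [-90, 270)
    state: str   # "syn" | "anti"


@dataclass(frozen=True)
class HBondRecord:
    frame: int
    donor: str      # "chain:resid:atom"
    hydrogen: str
    acceptor: str
    distance: float  # donor-acceptor, angstrom
    angle: float     # donor-H-acceptor, degrees


@dataclass
class Cluster:
    leader: int
    members: list
    population: float
    average: np.ndarray | None = None
    orientation: str | None = None


@dataclass(frozen=True)
class OrientationCall:
    label: str
    fraction: float
    tied: tuple = ()

    @property
    def is_tie(self) -> bool:
        return len(self.tied) > 1


# ---------------------------------------------------------------------------
# torsions
# ---------------------------------------------------------------------------

def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle, right-handed convention, range (-180, 180]."""
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise ValueError("collinear points: dihedral undefined")
    y = np.dot(np.cross(n1, n2), b2 / np.linalg.norm(b2))
    angle = np.degrees(np.arctan2(y, np.dot(n1, n2)))
    return 180.0 if np.isclose(angle, -180.0) else float(angle)


def wrap_chi(angle: float) -> float:
    """Map any angle in degrees into the chi convention range [-90, 270)."""
    return float((angle + 90.0) % 360.0 - 90.0)


def chi_for_residue(fs: FrameSet, frame: int, chain, resid) -> TorsionRecord:
    """Glycosidic chi of one residue in one frame, with its syn/anti call."""
    code = fs.residue_code(chain, resid)
    if code not in CHI_ATOMS:
        raise KeyError(f"no chi definition for residue code {code!r}")
    n_atom, c_atom = CHI_ATOMS[code]
    names = ("O4'", "C1'", n_atom, c_atom)
    try:
        idx = [fs.atom_index(chain, resid, nm) for nm in names]
    except KeyError as exc:
        raise KeyError(f"residue {chain}:{resid} ({code}): {exc}") from None
    chi = wrap_chi(dihedral(*fs.coords[frame, idx]))
    return TorsionRecord(frame=frame, chain=str(chain), resid=int(resid),
                         chi=chi, state=classify_syn_anti(chi))


def classify_syn_anti(chi: float) -> str:
    """syn for chi in [-90, 90), anti for [90, 270); high-anti folds into anti."""
    if not (-90.0 <= chi < 270.0):
        raise ValueError(f"chi {chi} outside [-90, 270)")
    return "syn" if chi < 90.0 else "anti"


# ---------------------------------------------------------------------------
# hydrogen bonds
# ---------------------------------------------------------------------------

def detect_hbonds(fs: FrameSet, frame: int, dist_cutoff: float = 3.5,
                  angle_cutoff: float = 135.0) -> list:
    """Inter-strand base-base hydrogen bonds of the middle pair in one frame.

    A bond requires donor-acceptor distance <= dist_cutoff and
    donor-H-acceptor angle >= angle_cutoff.  A declared donor without any
    hydrogen present in the frame is an error, not a silent zero.
    """
    (ch1, r1), (ch2, r2) = fs.middle_pair()
    records = []
    for (dch, dres), (ach, ares) in [((ch1, r1), (ch2, r2)), ((ch2, r2), (ch1, r1))]:
        dcode, acode = fs.residue_code(dch, dres), fs.residue_code(ach, ares)
        for donor, hydrogens in DONORS.get(dcode, {}).items():
            try:
                d_idx = fs.atom_index(dch, dres, donor)
            except KeyError:
                continue  # donor heavy atom not present in this representation
            h_indices = []
            for h in hydrogens:
                try:
                    h_indices.append((h, fs.atom_index(dch, dres, h)))
                except KeyError:
                    pass
            if not h_indices:
                raise ValueError(
                    f"donor {dch}:{dres}:{donor} has no hydrogens in frame")
            for acceptor in ACCEPTORS.get(acode, ()):
                try:
                    a_idx = fs.atom_index(ach, ares, acceptor)
                except KeyError:
                    continue
                d_xyz = fs.coords[frame, d_idx]
                a_xyz = fs.coords[frame, a_idx]
                dist = float(np.linalg.norm(d_xyz - a_xyz))
                if dist > dist_cutoff:
                    continue
                best = None
                for hname, h_idx in h_indices:
                    h_xyz = fs.coords[frame, h_idx]
                    v1, v2 = d_xyz - h_xyz, a_xyz - h_xyz
                    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                    ang = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
                    if ang >= angle_cutoff and (best is None or ang > best[1]):
                        best = (hname, ang)
                if best is not None:
                    records.append(HBondRecord(
                        frame=frame,
                        donor=f"{dch}:{dres}:{donor}", hydrogen=best[0],
                        acceptor=f"{ach}:{ares}:{acceptor}",
                        distance=dist, angle=best[1]))
    return records


def mean_hbond_count(fs: FrameSet, dist_cutoff: float = 3.5,
                     angle_cutoff: float = 135.0) -> float:
    """Average number of middle-pair hydrogen bonds over all frames."""
    if fs.n_frames == 0:
        raise ValueError("empty frame set")
    counts = [len(detect_hbonds(fs, i, dist_cutoff, angle_cutoff))
              for i in range(fs.n_frames)]
    return float(np.mean(counts))


# ---------------------------------------------------------------------------
# superposition, clustering, averaging
# ---------------------------------------------------------------------------

def superpose_rmsd(ref: np.ndarray, mob: np.ndarray) -> float:
    """Minimal RMSD after optimal rigid-body superposition (Kabsch)."""
    ref = np.asarray(ref, dtype=float)
    mob = np.asarray(mob, dtype=float)
    if ref.shape != mob.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise ValueError("coordinate sets must both be (n, 3)")
    n = len(ref)
    if n < 3:
        raise ValueError("need >= 3 atoms for superposition")
    a = ref - ref.mean(axis=0)
    b = mob - mob.mean(axis=0)
    _, rssd = Rotation.align_vectors(a, b)
    return float(rssd / np.sqrt(n))


def _superpose_transform(ref_sub, mob_sub):
    """Rotation + translation mapping mob onto ref using a subset of atoms."""
    c_ref = ref_sub.mean(axis=0)
    c_mob = mob_sub.mean(axis=0)
    rot, _ = Rotation.align_vectors(ref_sub - c_ref, mob_sub - c_mob)
    return rot, c_ref, c_mob


def leader_cluster(fs: FrameSet, threshold: float = 0.5,
                   atom_indices: np.ndarray | None = None,
                   with_averages: bool = True,
                   with_orientation: bool = True) -> list:
    """Single-pass leader clustering of frames by superposed RMSD.

    The first frame seeds cluster 1; each subsequent frame joins the first
    existing cluster whose leader is within ``threshold`` angstrom RMSD
    (inclusive) over ``atom_indices`` (default: middle-pair heavy atoms),
    else seeds a new cluster.  Frame order is the concatenation order of the
    source trajectories and is part of the result's provenance.
    """
    if fs.n_frames < 1:
        raise ValueError("need >= 1 frame")
    if atom_indices is None:
        atom_indices = fs.middle_pair_heavy_indices()
    sub = fs.coords[:, atom_indices]
    clusters: list[Cluster] = []
    for i in range(fs.n_frames):
        for cl in clusters:
            if superpose_rmsd(sub[cl.leader], sub[i]) <= threshold:
                cl.members.append(i)
                break
        else:
            clusters.append(Cluster(leader=i, members=[i], population=0.0))
    for cl in clusters:
        cl.population = len(cl.members) / fs.n_frames
        if with_averages:
            cl.average = average_structure(cl, fs, atom_indices)
        if with_orientation:
            cl.orientation = loop_orientation(fs, frames=cl.members).label
    return clusters


def average_structure(cluster: Cluster, fs: FrameSet,
                      align_indices: np.ndarray | None = None) -> np.ndarray:
    """Per-atom mean of member frames after superposition onto the leader."""
    if not cluster.members:
        raise ValueError("empty cluster")
    if align_indices is None:
        align_indices = fs.middle_pair_heavy_indices()
    ref_sub = fs.coords[cluster.leader][align_indices]
    acc = np.zeros_like(fs.coords[0])
    for i in cluster.members:
        rot, c_ref, c_mob = _superpose_transform(ref_sub, fs.coords[i][align_indices])
        acc += rot.apply(fs.coords[i] - c_mob) + c_ref
    return acc / len(cluster.members)


def loop_orientation(fs: FrameSet, frames=None) -> OrientationCall:
    """Joint syn/anti label of the middle pair (5'-strand residue first).

    For a set of frames, returns the modal label with its fraction; exact
    ties are reported through ``tied`` rather than broken silently.
    """
    if frames is None:
        frames = range(fs.n_frames)
    (ch1, r1), (ch2, r2) = fs.middle_pair()
    labels = [
        f"{chi_for_residue(fs, i, ch1, r1).state}-"
        f"{chi_for_residue(fs, i, ch2, r2).state}"
        for i in frames
    ]
    counts = Counter(labels)
    top = counts.most_common()
    best = top[0][1]
    tied = tuple(sorted(lbl for lbl, c in top if c == best))
    return OrientationCall(label=tied[0], fraction=best / len(labels), tied=tied)


def per_frame_states(fs: FrameSet) -> pd.DataFrame:
    """Per-frame chi, syn/anti states, joint label and H-bond count table."""
    (ch1, r1), (ch2, r2) = fs.middle_pair()
    rows = []
    for i in range(fs.n_frames):
        t1 = chi_for_residue(fs, i, ch1, r1)
        t2 = chi_for_residue(fs, i, ch2, r2)
        rows.append({
            "frame": i, "chi_5p": t1.chi, "state_5p": t1.state,
            "chi_3p": t2.chi, "state_3p": t2.state,
            "label": f"{t1.state}-{t2.state}",
            "n_hbonds": len(detect_hbonds(fs, i)),
        })
    return pd.DataFrame(rows)


def trim_terminal_pairs(fs: FrameSet, n_pairs: int = 2) -> FrameSet:
    """Remove n_pairs base pairs from each duplex end (both strands).

    Original residue numbering is preserved in the atom table so trimmed
    cores stay addressable by their source positions.
    """
    keep = np.zeros(len(fs.atoms), dtype=bool)
    for chain in fs.chains:
        resids = fs.strand_resids(chain)
        if len(resids) <= 2 * n_pairs:
            raise ValueError(
                f"duplex of {len(resids)} bp too short to trim {n_pairs} "
                f"pairs from each end")
        core = set(resids[n_pairs:len(resids) - n_pairs])
        mask = (fs.atoms["chain"] == chain) & fs.atoms["resid"].isin(core)
        keep |= mask.to_numpy()
    atoms = fs.atoms[keep].reset_index(drop=True)
    return FrameSet(coords=fs.coords[:, keep], atoms=atoms,
                    provenance=fs.provenance)
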