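"""Torsions, syn/anti calls, H-bond geometry, RMSD and leader clustering."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from duplexkit import traj_conformation as tc
from duplexkit.synthetic_data import ConformerTruth, gen_duplex_frames


def brute_force_rmsd(a, b, n_starts=12, seed=0):
    """Independent oracle: numerically minimize RMSD over explicit rotations."""
    from scipy.optimize import minimize

    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)

    def cost(angles):
        r = Rotation.from_euler("xyz", angles)
        return np.sqrt(np.mean(np.sum((a - r.apply(b)) ** 2, axis=1)))

    rng = np.random.default_rng(seed)
    best = np.inf
    for _ in range(n_starts):
        res = minimize(cost, rng.uniform(-np.pi, np.pi, 3), method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000})
        best = min(best, res.fun)
    return best


class TestDihedral:
    def test_planar_cis_is_zero(self):
        assert tc.dihedral((0, 1, 0), (0, 0, 0), (1, 0, 0), (1, 1, 0)) == pytest.approx(0.0)

    def test_planar_trans_is_180(self):
        assert tc.dihedral((0, 1, 0), (0, 0, 0), (1, 0, 0), (1, -1, 0)) == pytest.approx(180.0)

    def test_right_handed_sign(self):
        # +90: the far bond rotates clockwise viewed down the central bond
        assert tc.dihedral((0, 1, 0), (0, 0, 0), (1, 0, 0), (1, 0, 1)) == pytest.approx(90.0)

    def test_collinear_rejected(self):
        with pytest.raises(ValueError):
            tc.dihedral((0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 1, 0))

    def test_matches_established_implementation(self, rng):
        from MDAnalysis.lib.distances import calc_dihedrals

        for _ in range(50):
            pts = rng.normal(size=(4, 3)) * 3
            try:
                ours = tc.dihedral(*pts)
            except ValueError:
                continue
            other = np.degrees(calc_dihedrals(*[p[None] for p in pts]))[0]
            assert abs((ours - other + 180) % 360 - 180) < 1e-3


class TestChi:
    def test_generator_round_trip_exact(self, clean_frames):
        truth, fs, labels = clean_frames
        (c1, r1), (c2, r2) = fs.middle_pair()
        for i, state in enumerate(labels["state"]):
            chi1, chi2, _ = truth.states[state]
            assert tc.chi_for_residue(fs, i, c1, r1).chi == pytest.approx(chi1, abs=0.01)
            assert tc.chi_for_residue(fs, i, c2, r2).chi == pytest.approx(chi2, abs=0.01)

    def test_jittered_chi_tracks_truth(self, jittered_frames):
        # 0.05 A coordinate jitter on ~1.4 A bond lever arms propagates to
        # roughly 5 degrees of chi noise per frame: the mean absolute error
        # stays below 5 degrees and no frame strays past the syn/anti margin
        truth, fs, labels = jittered_frames
        (c1, r1), _ = fs.middle_pair()
        errors = []
        for i in range(fs.n_frames):
            target = truth.states[labels["state"][i]][0]
            got = tc.chi_for_residue(fs, i, c1, r1).chi
            errors.append(abs((got - target + 180) % 360 - 180))
        assert np.mean(errors) < 5.0
        assert np.max(errors) < 30.0

    def test_missing_atom_named_in_error(self, clean_frames):
        _, fs, _ = clean_frames
        (c1, r1), _ = fs.middle_pair()
        keep = ~((fs.atoms["chain"] == c1) & (fs.atoms["resid"] == r1)
                 & (fs.atoms["name"] == "N7")).to_numpy()
        broken = tc.FrameSet(coords=fs.coords[:, keep],
                             atoms=fs.atoms[keep].reset_index(drop=True))
        with pytest.raises(KeyError, match="N7"):
            tc.chi_for_residue(broken, 0, c1, r1)


class TestClassify:
    @pytest.mark.parametrize("chi, state", [
        (60.0, "syn"), (200.0, "anti"), (265.0, "anti"),  # high-anti is anti
        (-90.0, "syn"), (89.99, "syn"), (90.0, "anti"), (269.99, "anti"),
    ])
    def test_convention(self, chi, state):
        assert tc.classify_syn_anti(chi) == state

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            tc.classify_syn_anti(290.0)


class TestHbonds:
    def test_pattern_round_trip(self, clean_frames):
        _, fs, labels = clean_frames
        for i in range(fs.n_frames):
            assert len(tc.detect_hbonds(fs, i)) == labels["n_hbonds"][i]

    def test_distance_cutoff_excludes(self, clean_frames):
        _, fs, _ = clean_frames
        bonds = tc.detect_hbonds(fs, 0)
        assert all(b.distance <= 3.5 and b.angle >= 135.0 for b in bonds)
        # tighten the distance cutoff below the posed 2.9 A: no bonds remain
        assert tc.detect_hbonds(fs, 0, dist_cutoff=2.5) == []

    def test_angle_cutoff_excludes(self, clean_frames):
        _, fs, _ = clean_frames
        assert tc.detect_hbonds(fs, 0, angle_cutoff=179.95) != []
        # bend the hydrogen: move it perpendicular so the D-H...A angle drops
        fs2 = tc.FrameSet(coords=fs.coords.copy(), atoms=fs.atoms)
        (c1, r1), _ = fs2.middle_pair()
        h_idx = fs2.atom_index(c1, r1, "H61")
        d_idx = fs2.atom_index(c1, r1, "N6")
        bond = fs2.coords[0, h_idx] - fs2.coords[0, d_idx]
        perp = np.cross(bond, [0.0, 0.0, 1.0])
        fs2.coords[0, h_idx] = fs2.coords[0, d_idx] + perp / np.linalg.norm(perp)
        donors = {b.donor for b in tc.detect_hbonds(fs2, 0)}
        assert f"{c1}:{r1}:N6" not in donors

    def test_mean_count_order_invariant(self):
        truth = ConformerTruth(
            jitter_sd=0.0, seed=5,
            states={"anti-anti": (210.0, 210.0, 2), "open": (210.0, 210.0, 0)},
            schedule={"anti-anti": 0.8, "open": 0.2})
        fs, labels = gen_duplex_frames(truth, 20)
        mean = tc.mean_hbond_count(fs)
        assert mean == pytest.approx(0.8 * 2, abs=1e-12)
        reversed_fs = tc.FrameSet(coords=fs.coords[::-1].copy(), atoms=fs.atoms)
        assert tc.mean_hbond_count(reversed_fs) == pytest.approx(mean)

    def test_mixed_counts_mean(self):
        truth = ConformerTruth(
            jitter_sd=0.0, seed=5,
            states={"two": (210.0, 210.0, 2), "one": (210.0, 210.0, 1)},
            schedule={"two": 0.75, "one": 0.25})
        fs, _ = gen_duplex_frames(truth, 4)
        # counts [2, 2, 2, 1] -> 1.75
        assert tc.mean_hbond_count(fs) == pytest.approx(1.75)


class TestSuperposeRmsd:
    def test_identical_is_zero(self, rng):
        a = rng.normal(size=(10, 3))
        assert tc.superpose_rmsd(a, a) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_invariance(self, rng):
        a = rng.normal(size=(10, 3))
        moved = Rotation.random(random_state=3).apply(a) + [5.0, -2.0, 1.0]
        assert tc.superpose_rmsd(a, moved) == pytest.approx(0.0, abs=1e-7)
        b = rng.normal(size=(10, 3))
        assert tc.superpose_rmsd(a, b) == pytest.approx(
            tc.superpose_rmsd(Rotation.random(random_state=4).apply(a), b), abs=1e-9)

    def test_symmetry(self, rng):
        a, b = rng.normal(size=(2, 8, 3))
        assert tc.superpose_rmsd(a, b) == pytest.approx(tc.superpose_rmsd(b, a), abs=1e-9)

    def test_against_mdanalysis(self, rng):
        from MDAnalysis.analysis import rms

        for _ in range(20):
            a, b = rng.normal(size=(2, 9, 3))
            assert tc.superpose_rmsd(a, b) == pytest.approx(
                rms.rmsd(b, a, center=True, superposition=True), abs=1e-9)

    def test_against_brute_force(self, rng):
        a = rng.normal(size=(6, 3))
        b = a.copy()
        b[0] += [1.0, 0.0, 0.0]  # known single-atom perturbation
        assert tc.superpose_rmsd(a, b) == pytest.approx(
            brute_force_rmsd(a, b), abs=1e-5)

    def test_too_few_atoms(self):
        with pytest.raises(ValueError):
            tc.superpose_rmsd(np.zeros((2, 3)), np.zeros((2, 3)))


class TestLeaderCluster:
    def test_identical_frames_single_cluster(self, clean_frames):
        _, fs, _ = clean_frames
        sub = tc.FrameSet(coords=np.repeat(fs.coords[:1], 5, axis=0), atoms=fs.atoms)
        clusters = tc.leader_cluster(sub)
        assert len(clusters) == 1
        assert clusters[0].population == 1.0

    def test_two_state_populations(self, jittered_frames):
        truth, fs, labels = jittered_frames
        clusters = tc.leader_cluster(fs)
        assert len(clusters) == 2
        pops = sorted((c.population for c in clusters), reverse=True)
        assert pops[0] == pytest.approx(0.70, abs=0.02)
        assert pops[1] == pytest.approx(0.30, abs=0.02)
        # post-hoc: every member within the threshold of its leader
        mid = fs.middle_pair_heavy_indices()
        for c in clusters:
            for m in c.members:
                assert tc.superpose_rmsd(fs.coords[c.leader][mid],
                                         fs.coords[m][mid]) <= 0.5

    def test_partition_properties(self, jittered_frames):
        _, fs, _ = jittered_frames
        clusters = tc.leader_cluster(fs, with_averages=False,
                                     with_orientation=False)
        all_members = sorted(m for c in clusters for m in c.members)
        assert all_members == list(range(fs.n_frames))
        assert sum(c.population for c in clusters) == pytest.approx(1.0)

    def test_threshold_is_inclusive(self, clean_frames):
        _, fs, _ = clean_frames
        mid = fs.middle_pair_heavy_indices()
        a = fs.coords[0]
        b = a.copy()
        b[mid[0]] += 0.8
        pair = tc.FrameSet(coords=np.stack([a, b]), atoms=fs.atoms)
        d = tc.superpose_rmsd(a[mid], b[mid])
        joined = tc.leader_cluster(pair, threshold=d, with_averages=False,
                                   with_orientation=False)
        assert len(joined) == 1
        split = tc.leader_cluster(pair, threshold=d * 0.999, with_averages=False,
                                  with_orientation=False)
        assert len(split) == 2

    def test_orientation_labels_match_truth(self, jittered_frames):
        truth, fs, labels = jittered_frames
        clusters = tc.leader_cluster(fs)
        got = {c.orientation: c.population for c in clusters}
        want = labels["state"].value_counts(normalize=True).to_dict()
        assert set(got) == set(want)
        for k in got:
            assert got[k] == pytest.approx(want[k], abs=0.02)


class TestAverageStructure:
    def test_singleton_is_the_frame(self, clean_frames):
        _, fs, _ = clean_frames
        cl = tc.Cluster(leader=0, members=[0], population=1.0)
        avg = tc.average_structure(cl, fs)
        assert np.allclose(avg, fs.coords[0], atol=1e-9)

    def test_symmetric_perturbation_averages_to_midpoint(self, clean_frames):
        _, fs, _ = clean_frames
        base = fs.coords[0]
        up, down = base.copy(), base.copy()
        up[10] += [0.05, 0, 0]
        down[10] -= [0.05, 0, 0]
        pair = tc.FrameSet(coords=np.stack([up, down]), atoms=fs.atoms)
        cl = tc.Cluster(leader=0, members=[0, 1], population=1.0)
        avg = tc.average_structure(cl, pair, align_indices=np.arange(len(fs.atoms)))
        assert np.abs(avg[10] - up[10]).max() < 0.06
        assert np.abs(avg - up).max() < 0.06

    def test_jitter_averages_toward_reference(self):
        truth = ConformerTruth(jitter_sd=0.05, seed=9,
                               schedule={"anti-anti": 1.0})
        fs, _ = gen_duplex_frames(truth, 200)
        clean, _ = gen_duplex_frames(
            ConformerTruth(jitter_sd=0.0, seed=9, schedule={"anti-anti": 1.0}), 1)
        cl = tc.Cluster(leader=0, members=list(range(200)), population=1.0)
        avg = tc.average_structure(cl, fs, align_indices=np.arange(len(fs.atoms)))
        # align the averaged structure onto the clean reference and compare
        rot, c_ref, c_mob = tc._superpose_transform(clean.coords[0], avg)
        aligned = rot.apply(avg - c_mob) + c_ref
        per_atom = np.linalg.norm(aligned - clean.coords[0], axis=1)
        assert per_atom.mean() < 0.01
        assert per_atom.max() < 0.025

    def test_empty_cluster_rejected(self, clean_frames):
        _, fs, _ = clean_frames
        with pytest.raises(ValueError):
            tc.average_structure(tc.Cluster(leader=0, members=[], population=0), fs)


class TestLoopOrientation:
    def test_uniform_labels(self, clean_frames):
        _, fs, labels = clean_frames
        aa_frames = [i for i, s in enumerate(labels["state"]) if s == "anti-anti"]
        call = tc.loop_orientation(fs, frames=aa_frames)
        assert call.label == "anti-anti"
        assert call.fraction == 1.0
        assert not call.is_tie

    def test_five_prime_residue_listed_first(self):
        truth = ConformerTruth(jitter_sd=0.0, seed=2,
                               states={"syn-anti": (30.0, 210.0, 2)},
                               schedule={"syn-anti": 1.0})
        fs, _ = gen_duplex_frames(truth, 2)
        assert tc.loop_orientation(fs).label == "syn-anti"

    def test_even_mixture_flagged_as_tie(self):
        truth = ConformerTruth(jitter_sd=0.0, seed=2,
                               schedule={"anti-anti": 0.5, "syn-anti": 0.5})
        fs, _ = gen_duplex_frames(truth, 10)
        call = tc.loop_orientation(fs)
        assert call.is_tie
        assert set(call.tied) == {"anti-anti", "syn-anti"}


class TestTrim:
    def test_nine_bp_to_five_bp_core(self, clean_frames):
        _, fs, _ = clean_frames
        core = tc.trim_terminal_pairs(fs)
        for chain in core.chains:
            assert core.strand_resids(chain) == [3, 4, 5, 6, 7]
        assert core.middle_pair() == fs.middle_pair()

    def test_five_bp_to_single_pair(self, clean_frames):
        _, fs, _ = clean_frames
        core = tc.trim_terminal_pairs(fs)          # 5 bp
        single = tc.trim_terminal_pairs(core)      # 1 bp
        for chain in single.chains:
            assert single.strand_resids(chain) == [5]

    def test_too_short_rejected(self, clean_frames):
        _, fs, _ = clean_frames
        core = tc.trim_terminal_pairs(fs)  # 5 bp
        with pytest.raises(ValueError):
            tc.trim_terminal_pairs(core, n_pairs=3)
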