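"""RMSF/Rg/RMSD numerics and susceptibility classification."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from drpcore import (
    ConfusionSummary,
    FlexProfile,
    SiteLabelSet,
    Trajectory,
    classify_sites,
    compute_rg,
    compute_rmsd,
    compute_rmsf,
    evaluate_classifier,
)
from drpcore.errors import InputError
from drpcore.flexibility import RESISTANT, SUSCEPTIBLE


def make_traj(coords, residues=None, names=None, masses=None):
    coords = np.asarray(coords, dtype=float)
    n_atoms = coords.shape[1]
    return Trajectory(
        coords=coords,
        residue_index=residues
        if residues is not None
        else np.arange(1, n_atoms + 1),
        atom_names=tuple(names) if names else ("CA",) * n_atoms,
        masses=masses if masses is not None else np.ones(n_atoms),
    )


def naive_rmsf(coords, window):
    """Two-pass per-window oracle, per atom."""
    F, A, _ = coords.shape
    vals = []
    for w0 in range(F - window + 1):
        win = coords[w0 : w0 + window]
        mu = win.mean(axis=0)
        disp = ((win - mu) ** 2).sum(axis=2).mean(axis=0)
        vals.append(np.sqrt(disp))
    return np.mean(vals, axis=0)


class TestRmsf:
    def test_static_trajectory_is_zero(self):
        frame = np.arange(30, dtype=float).reshape(10, 3)
        traj = make_traj(np.repeat(frame[None], 5, axis=0))
        profile = compute_rmsf(traj, window_frames=3)
        assert np.allclose(profile.rmsf, 0.0)

    def test_alternating_atom_rmsf_equals_amplitude(self):
        d = 0.8
        coords = np.zeros((6, 1, 3))
        coords[::2, 0, 0] = d
        coords[1::2, 0, 0] = -d
        traj = make_traj(coords)
        profile = compute_rmsf(traj, window_frames=2, selection="all")
        assert profile.rmsf[0] == pytest.approx(d, abs=1e-12)

    def test_matches_naive_oracle(self, rng):
        coords = rng.normal(size=(50, 12, 3))
        residues = np.repeat(np.arange(1, 5), 3)
        traj = make_traj(coords, residues=residues)
        profile = compute_rmsf(traj, window_frames=20, selection="all")
        oracle_atom = naive_rmsf(coords, 20)
        oracle = [oracle_atom[residues == r].mean() for r in range(1, 5)]
        assert np.allclose(profile.rmsf, oracle, atol=1e-10)

    def test_window_equal_to_frames_is_whole_trajectory(self, rng):
        coords = rng.normal(size=(30, 5, 3))
        traj = make_traj(coords)
        windowed = compute_rmsf(traj, window_frames=30, selection="all")
        mu = coords.mean(axis=0)
        whole = np.sqrt(((coords - mu) ** 2).sum(axis=2).mean(axis=0))
        assert np.allclose(windowed.rmsf, whole, atol=1e-12)

    def test_rigid_motion_invariance(self, rng):
        coords = rng.normal(size=(25, 8, 3))
        traj = make_traj(coords)
        base = compute_rmsf(traj, 10, "all").rmsf
        rot = Rotation.random(random_state=3).as_matrix()
        moved = coords @ rot.T + np.array([5.0, -2.0, 9.0])
        assert np.allclose(
            compute_rmsf(make_traj(moved), 10, "all").rmsf, base, atol=1e-10
        )

    def test_too_few_frames_rejected(self, rng):
        traj = make_traj(rng.normal(size=(3, 4, 3)))
        with pytest.raises(InputError):
            compute_rmsf(traj, window_frames=10)

    def test_backbone_selection_uses_named_atoms(self, rng):
        coords = rng.normal(size=(10, 4, 3))
        traj = make_traj(
            coords,
            residues=np.array([1, 1, 1, 1]),
            names=("N", "CA", "C", "CB"),
        )
        backbone = compute_rmsf(traj, 5, "backbone")
        oracle = naive_rmsf(coords[:, :3], 5).mean()
        assert backbone.rmsf[0] == pytest.approx(oracle, abs=1e-12)


class TestRgRmsd:
    def test_single_atom_rg_zero(self):
        assert compute_rg([[1.0, 2.0, 3.0]], [12.0]) == 0.0

    def test_two_point_rg(self):
        frame = [[0.0, 0.0, 0.0], [2.0, 0.0, 0.0]]
        assert compute_rg(frame, [1.0, 1.0]) == pytest.approx(1.0)

    def test_rg_matches_direct_sum_oracle(self, rng):
        for _ in range(20):
            frame = rng.normal(size=(100, 3))
            masses = rng.uniform(1, 20, size=100)
            com = (frame * masses[:, None]).sum(0) / masses.sum()
            oracle = np.sqrt(
                (masses * ((frame - com) ** 2).sum(1)).sum() / masses.sum()
            )
            assert compute_rg(frame, masses) == pytest.approx(oracle, abs=1e-10)

    def test_identical_frames_rmsd_zero(self, rng):
        frame = rng.normal(size=(10, 3))
        assert compute_rmsd(frame, frame) == pytest.approx(0.0, abs=1e-12)

    def test_translation_removed_by_superposition(self, rng):
        frame = rng.normal(size=(10, 3))
        moved = frame + np.array([5.0, 0.0, 0.0])
        assert compute_rmsd(moved, frame, superpose=True) == pytest.approx(
            0.0, abs=1e-9
        )
        assert compute_rmsd(moved, frame, superpose=False) == pytest.approx(
            5.0, abs=1e-9
        )

    def test_superposed_never_exceeds_unsuperposed(self, rng):
        for _ in range(20):
            a, b = rng.normal(size=(2, 15, 3))
            assert compute_rmsd(a, b, True) <= compute_rmsd(a, b, False) + 1e-12

    def test_matches_svd_alignment_oracle(self, rng):
        for seed in range(20):
            r = np.random.default_rng(seed)
            ref = r.normal(size=(25, 3))
            rot = Rotation.random(random_state=seed).as_matrix()
            frame = (ref + r.normal(scale=0.05, size=ref.shape)) @ rot.T + 3.0
            # independent oracle: scipy's Kabsch via align_vectors on
            # centred coordinates
            pc = frame - frame.mean(0)
            qc = ref - ref.mean(0)
            rot_est, _ = Rotation.align_vectors(qc, pc)
            oracle = np.sqrt(
                ((rot_est.apply(pc) - qc) ** 2).sum(1).mean()
            )
            assert compute_rmsd(frame, ref, True) == pytest.approx(
                oracle, abs=1e-8
            )

    def test_atom_count_mismatch_rejected(self, rng):
        with pytest.raises(InputError):
            compute_rmsd(rng.normal(size=(5, 3)), rng.normal(size=(6, 3)))


class TestClassification:
    def _profile(self, values):
        return FlexProfile(
            residues=np.arange(1, len(values) + 1), rmsf=np.array(values)
        )

    @pytest.mark.parametrize(
        "value,expected",
        [(0.70, SUSCEPTIBLE), (0.60, RESISTANT), (0.65, RESISTANT)],
    )
    def test_cutoff_convention(self, value, expected):
        labels = classify_sites(self._profile([value]), [1], cutoff=0.65)
        assert labels[1] == expected

    def test_site_outside_profile_rejected(self):
        with pytest.raises(InputError):
            classify_sites(self._profile([0.5]), [7])

    def test_threshold_monotonicity(self, rng):
        profile = self._profile(rng.uniform(0.2, 1.2, size=40))
        sites = list(range(1, 41))
        counts = []
        for cutoff in np.linspace(0.2, 1.2, 21):
            labels = classify_sites(profile, sites, cutoff)
            counts.append(
                sum(labels[p] == SUSCEPTIBLE for p in sites)
            )
        assert counts == sorted(counts, reverse=True)


class TestEvaluation:
    def test_perfect_prediction(self):
        labels = SiteLabelSet({1: SUSCEPTIBLE, 2: RESISTANT})
        summary = evaluate_classifier(labels, labels)
        assert summary.ppv_susceptible_pct == 100
        assert summary.ppv_resistant_pct == 100

    def test_reported_toy_counts(self):
        summary = ConfusionSummary(tp=5, fp=1, tn=13, fn=2)
        assert summary.ppv_susceptible_pct == 83
        assert summary.ppv_resistant_pct == 87

    def test_zero_denominator_reported_as_none(self):
        summary = ConfusionSummary(tp=0, fp=0, tn=3, fn=1)
        assert summary.ppv_susceptible is None
        assert summary.ppv_resistant == pytest.approx(0.75)

    def test_site_set_mismatch_rejected(self):
        a = SiteLabelSet({1: SUSCEPTIBLE})
        b = SiteLabelSet({2: SUSCEPTIBLE})
        with pytest.raises(InputError):
            evaluate_classifier(a, b)

    def test_agrees_with_bruteforce_confusion_oracle(self, rng):
        for _ in range(1000):
            n = int(rng.integers(1, 25))
            pos = list(range(1, n + 1))
            pred = {
                p: SUSCEPTIBLE if rng.random() < 0.5 else RESISTANT
                for p in pos
            }
            obs = {
                p: SUSCEPTIBLE if rng.random() < 0.5 else RESISTANT
                for p in pos
            }
            s = evaluate_classifier(SiteLabelSet(pred), SiteLabelSet(obs))
            tp = sum(
                pred[p] == SUSCEPTIBLE and obs[p] == SUSCEPTIBLE for p in pos
            )
            fp = sum(
                pred[p] == SUSCEPTIBLE and obs[p] == RESISTANT for p in pos
            )
            tn = sum(
                pred[p] == RESISTANT and obs[p] == RESISTANT for p in pos
            )
            fn = sum(
                pred[p] == RESISTANT and obs[p] == SUSCEPTIBLE for p in pos
            )
            assert (s.tp, s.fp, s.tn, s.fn) == (tp, fp, tn, fn)
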