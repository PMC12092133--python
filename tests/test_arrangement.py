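"""Arrangement RSA: Procrustes, RDMs, agreement formulas, class models.

Formula-fidelity tests compare each statistic against an independent literal
transcription of its defining formula (average first, then Pearson
correlations on strict upper triangles), computed with plain numpy.
"""

import numpy as np
import pytest
from scipy import stats

from morphorsa import (
    Arrangement,
    ClassModel,
    DegenerateInputError,
    RDM,
    SimulationConfig,
    analyze_arrangements,
    average_rdm,
    between_participant_agreement,
    bootstrap_ci,
    class_agreement,
    class_rdm,
    compare_sessions,
    compute_rdm,
    generate_stimulus_set,
    noise_ceiling,
    procrustes_align,
    session_agreement,
    simulate_cohort,
    upper_triangle,
    within_participant_agreement,
)
from tests.conftest import random_rigid


def _random_arrangement(rng, n=12, pid="P01", session=1):
    ids = tuple(f"s{i}" for i in range(n))
    return Arrangement(pid, session, ids, rng.uniform(0, 60, size=(n, 2)))


def _random_rdm(rng, n=8):
    labels = tuple(f"s{i}" for i in range(n))
    pts = rng.normal(size=(n, 3))
    d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
    return RDM(labels, d / d.max())


def _corr(x, y):
    return np.corrcoef(x, y)[0, 1]


class TestProcrustes:
    def test_self_alignment_zero_disparity(self):
        rng = np.random.default_rng(1)
        arr = _random_arrangement(rng)
        aligned, disp = procrustes_align([arr], reference=arr)
        assert disp[0] == pytest.approx(0.0, abs=1e-18)
        assert np.allclose(aligned[0].coords, arr.coords, atol=1e-9)

    def test_mirror_image_zero_disparity(self):
        rng = np.random.default_rng(2)
        arr = _random_arrangement(rng)
        mirrored = arr.with_coords(arr.coords @ np.diag([-1.0, 1.0]))
        _, disp = procrustes_align([mirrored], reference=arr)
        assert disp[0] == pytest.approx(0.0, abs=1e-16)

    def test_rigid_transform_recovered_to_1e9(self):
        """A rotated/translated copy aligns back onto the original.

        Closed-form oracle: the optimal orthogonal map is the SVD polar
        factor of the cross-covariance of the centred configurations."""
        rng = np.random.default_rng(3)
        arr = _random_arrangement(rng)
        theta = np.deg2rad(37.0)
        rot = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        moved = arr.with_coords(arr.coords @ rot.T + np.array([5.0, -3.0]))
        aligned, disp = procrustes_align([moved], reference=arr)
        assert np.allclose(aligned[0].coords, arr.coords, atol=1e-9)
        # independent SVD oracle
        a = moved.coords - moved.coords.mean(axis=0)
        b = arr.coords - arr.coords.mean(axis=0)
        u, _, vt = np.linalg.svd(a.T @ b)
        oracle = a @ (u @ vt) + arr.coords.mean(axis=0)
        assert np.allclose(aligned[0].coords, oracle, atol=1e-9)
        assert disp[0] == pytest.approx(0.0, abs=1e-16)

    @pytest.mark.parametrize("reflect", [False, True])
    def test_random_rigid_transforms_recovered(self, reflect):
        rng = np.random.default_rng(4)
        arr = _random_arrangement(rng)
        for _ in range(10):
            rot, shift = random_rigid(rng, reflect=reflect)
            moved = arr.with_coords(arr.coords @ rot.T + shift)
            aligned, _ = procrustes_align([moved], reference=arr)
            assert np.allclose(aligned[0].coords, arr.coords, atol=1e-9)

    def test_generalized_alignment_collapses_rigid_copies(self):
        """GPA of rigid copies of one shape recovers identical shapes."""
        rng = np.random.default_rng(5)
        arr = _random_arrangement(rng)
        copies = []
        for s in range(4):
            rot, shift = random_rigid(rng)
            copies.append(arr.with_coords(arr.coords @ rot.T + shift))
        aligned, disp = procrustes_align(copies)
        for a in aligned[1:]:
            assert np.allclose(a.coords, aligned[0].coords, atol=1e-6)
        assert max(disp) < 1e-12

    def test_mismatched_stimulus_sets_rejected(self):
        rng = np.random.default_rng(6)
        a = _random_arrangement(rng, n=10)
        b = _random_arrangement(rng, n=11)
        with pytest.raises(ValueError, match="stimulus set"):
            procrustes_align([a, b])


class TestComputeRdm:
    def test_collinear_analytic_case(self):
        arr = Arrangement(
            "P01", 1, ("a", "b", "c"), np.array([[0, 0], [0, 1], [0, 2.0]])
        )
        rdm = compute_rdm(arr)
        assert rdm.matrix[0, 1] == pytest.approx(0.5)
        assert rdm.matrix[0, 2] == pytest.approx(1.0)
        assert rdm.matrix[1, 2] == pytest.approx(0.5)

    def test_unit_max_normalization(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            rdm = compute_rdm(_random_arrangement(rng, n=30))
            assert upper_triangle(rdm).max() == pytest.approx(1.0)

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(8)
        arr = _random_arrangement(rng, n=30)
        rdm = compute_rdm(arr)
        n = 30
        brute = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                brute[i, j] = np.sqrt(np.sum((arr.coords[i] - arr.coords[j]) ** 2))
        brute /= brute[np.triu_indices(n, 1)].max()
        assert np.allclose(rdm.matrix, brute, atol=1e-12)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(9)
        arr = _random_arrangement(rng)
        base = compute_rdm(arr).matrix
        for _ in range(10):
            rot, shift = random_rigid(rng)
            moved = arr.with_coords(arr.coords @ rot.T + shift)
            assert np.allclose(compute_rdm(moved).matrix, base, atol=1e-9)

    def test_coincident_points_degenerate(self):
        arr = Arrangement("P01", 1, ("a", "b"), np.zeros((2, 2)))
        with pytest.raises(DegenerateInputError):
            compute_rdm(arr)


class TestAgreementFormulas:
    def test_identical_sessions_give_w_of_one(self):
        rng = np.random.default_rng(10)
        rdm = _random_rdm(rng)
        assert within_participant_agreement(rdm, rdm) == pytest.approx(1.0)

    def test_w_matches_stepwise_oracle_on_random_rdms(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            r1, r2 = _random_rdm(rng, n=4), _random_rdm(rng, n=4)
            r2 = RDM(r1.labels, r2.matrix)
            w = within_participant_agreement(r1, r2)
            avg = (r1.matrix + r2.matrix) / 2
            v_avg = avg[np.triu_indices(4, 1)]
            oracle = (
                _corr(r1.matrix[np.triu_indices(4, 1)], v_avg)
                + _corr(r2.matrix[np.triu_indices(4, 1)], v_avg)
            ) / 2
            assert w == pytest.approx(oracle, abs=1e-12)

    def test_noise_free_participant_w_is_one(self):
        cfg = SimulationConfig(
            participant_noise_sd=0.0, session_noise_sd=0.0, seed=12
        )
        stimset, arrangements, _ = simulate_cohort(cfg)
        p0 = [a for a in arrangements if a.participant_id == "P01"]
        w = within_participant_agreement(
            compute_rdm(p0[0]), compute_rdm(p0[1])
        )
        assert w == pytest.approx(1.0, abs=1e-12)

    def test_identical_participants_b_is_one(self):
        rng = np.random.default_rng(13)
        rdm = _random_rdm(rng)
        b = between_participant_agreement([rdm, rdm, rdm])
        assert np.allclose(b, 1.0)

    def test_b_matches_direct_oracle(self):
        rng = np.random.default_rng(14)
        for _ in range(100):
            rdms = [_random_rdm(rng, n=5) for _ in range(3)]
            rdms = [RDM(rdms[0].labels, r.matrix) for r in rdms]
            b = between_participant_agreement(rdms)
            mean = np.mean([r.matrix for r in rdms], axis=0)
            iu = np.triu_indices(5, 1)
            oracle = [_corr(r.matrix[iu], mean[iu]) for r in rdms]
            assert np.allclose(b, oracle, atol=1e-12)

    def test_participant_exchange_symmetry(self):
        """Swapping the two participants swaps (only) their B values."""
        labels = ("a", "b", "c", "d")
        rng = np.random.default_rng(42)
        def mk(v):
            m = np.zeros((4, 4))
            m[np.triu_indices(4, 1)] = v
            return RDM(labels, m + m.T)
        r1, r2 = mk(rng.uniform(0, 1, 6)), mk(rng.uniform(0, 1, 6))
        b = between_participant_agreement([r1, r2])
        b_swapped = between_participant_agreement([r2, r1])
        assert np.allclose(b, b_swapped[::-1], atol=1e-12)

    def test_perfectly_anticorrelated_pair_flagged_undefined(self):
        """Exact complements average to a constant RDM: both B are flagged.

        The grand mean has zero variance, so both correlations are undefined
        and both participants are treated identically (NaN, not 0)."""
        from morphorsa.core import DegenerateInputWarning

        labels = ("a", "b", "c", "d")
        v1 = np.array([0.2, 0.4, 0.6, 0.8, 1.0, 0.3])
        v2 = 1.2 - v1
        def mk(v):
            m = np.zeros((4, 4))
            m[np.triu_indices(4, 1)] = v
            return RDM(labels, m + m.T)
        with pytest.warns(DegenerateInputWarning):
            b = between_participant_agreement([mk(v1), mk(v2)])
        assert np.all(np.isnan(b))

    def test_session_agreement_matches_oracle_and_duplication(self):
        rng = np.random.default_rng(15)
        s1 = [_random_rdm(rng, n=6) for _ in range(4)]
        s1 = [RDM(s1[0].labels, r.matrix) for r in s1]
        b1, b2 = session_agreement(s1, s1)
        assert np.allclose(b1, b2)
        iu = np.triu_indices(6, 1)
        mean = np.mean([r.matrix for r in s1], axis=0)
        oracle = [_corr(r.matrix[iu], mean[iu]) for r in s1]
        assert np.allclose(b1, oracle, atol=1e-12)


class TestClassModels:
    def test_simple_rdm_counts_on_24_stimuli(self, default_stimset):
        rdm = class_rdm(default_stimset, "simple", include_indeterminate=False)
        assert rdm.n == 24
        tri = upper_triangle(rdm)
        assert tri.size == 276
        assert np.sum(tri == 0) == 60  # 4 classes x C(6,2)
        assert np.sum(tri == 1) == 216

    def test_all_same_class_gives_zero_rdm(self):
        from morphorsa import StimulusSet

        stimset = StimulusSet(("a", "b", "c"), ("BC", "BC", "BC"))
        rdm = class_rdm(stimset, "simple", include_indeterminate=True)
        assert np.all(rdm.matrix == 0)

    def test_complex_default_satisfies_ordinal_constraints(self):
        model = ClassModel.complex_default()
        d = model.distance
        assert d("BC", "DC") < min(d("BC", "SC"), d("BC", "OSN"))
        assert d("DC", "SC") < d("DC", "OSN")
        assert d("I", "OSN") < min(d("I", "BC"), d("I", "DC"), d("I", "SC"))

    def test_violating_table_rejected(self):
        bad = {frozenset({"BC", "DC"}): 1.0}  # BC-DC no closer than the rest
        with pytest.raises(ValueError, match="ordinal"):
            ClassModel("complex", bad)

    def test_class_agreement_is_one_for_model_itself(self, default_stimset):
        rdm = class_rdm(default_stimset, "simple")
        assert class_agreement(rdm, rdm) == pytest.approx(1.0)


class TestNoiseCeiling:
    def test_identical_participants_ceiling_is_one(self):
        rng = np.random.default_rng(16)
        rdm = _random_rdm(rng)
        lower, upper = noise_ceiling([rdm, rdm, rdm])
        assert lower == pytest.approx(1.0)
        assert upper == pytest.approx(1.0)

    def test_lower_below_upper_with_noise(self):
        cfg = SimulationConfig(n_participants=8, seed=17)
        stimset, arrangements, _ = simulate_cohort(cfg)
        by = {}
        for a in arrangements:
            by.setdefault(a.participant_id, []).append(a)
        avg = [
            average_rdm([compute_rdm(x) for x in pair])
            for pair in by.values()
        ]
        lower, upper = noise_ceiling(avg)
        assert lower < upper

    def test_three_participants_vs_pairwise_average_oracle(self):
        rng = np.random.default_rng(18)
        rdms = [_random_rdm(rng, n=5) for _ in range(3)]
        rdms = [RDM(rdms[0].labels, r.matrix) for r in rdms]
        lower, _ = noise_ceiling(rdms)
        iu = np.triu_indices(5, 1)
        oracle = np.mean(
            [
                _corr(
                    rdms[p].matrix[iu],
                    ((rdms[(p + 1) % 3].matrix + rdms[(p + 2) % 3].matrix) / 2)[iu],
                )
                for p in range(3)
            ]
        )
        assert lower == pytest.approx(oracle, abs=1e-12)

    def test_too_few_participants_rejected(self):
        rng = np.random.default_rng(19)
        rdm = _random_rdm(rng)
        with pytest.raises(ValueError):
            noise_ceiling([rdm, rdm])


class TestSessionComparison:
    def test_identical_vectors_t_zero_p_one(self):
        v = np.array([0.6, 0.7, 0.8, 0.9])
        res = compare_sessions(v, v)
        assert res.t == 0.0
        assert res.p == 1.0
        assert res.df == 3

    def test_df_is_n_minus_one(self):
        rng = np.random.default_rng(20)
        a, b = rng.uniform(0, 1, size=(2, 16))
        assert compare_sessions(a, b).df == 15

    def test_matches_textbook_paired_t_oracle(self):
        a = np.array([0.61, 0.55, 0.70, 0.48])
        b = np.array([0.58, 0.60, 0.66, 0.50])
        res = compare_sessions(a, b)
        d = a - b
        t_oracle = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        p_oracle = 2 * stats.t.sf(abs(t_oracle), df=len(d) - 1)
        assert res.t == pytest.approx(t_oracle, abs=1e-12)
        assert res.p == pytest.approx(p_oracle, abs=1e-12)

    def test_matches_scipy_on_random_pairs(self):
        rng = np.random.default_rng(21)
        for _ in range(50):
            a, b = rng.uniform(0, 1, size=(2, 16))
            res = compare_sessions(a, b)
            ref = stats.ttest_rel(a, b)
            assert res.t == pytest.approx(ref.statistic, abs=1e-12)
            assert res.p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compare_sessions(np.ones(3), np.ones(4))


class TestBootstrap:
    def test_constant_vector_degenerate_ci(self):
        lo, hi = bootstrap_ci(np.full(10, 0.4), n_boot=100, seed=0)
        assert lo == pytest.approx(0.4)
        assert hi == pytest.approx(0.4)

    def test_ci_contains_sample_mean(self):
        rng = np.random.default_rng(22)
        v = rng.uniform(0, 1, size=16)
        lo, hi = bootstrap_ci(v, n_boot=2000, seed=1)
        assert lo <= v.mean() <= hi

    def test_reproducible_and_near_independent_implementation(self):
        rng = np.random.default_rng(23)
        v = rng.uniform(0, 1, size=16)
        a = bootstrap_ci(v, n_boot=10_000, seed=5)
        b = bootstrap_ci(v, n_boot=10_000, seed=5)
        assert a == b
        # independent re-implementation with a different resampling stream
        rng2 = np.random.default_rng(99)
        means = [rng2.choice(v, size=16, replace=True).mean() for _ in range(10_000)]
        lo2, hi2 = np.percentile(means, [2.5, 97.5])
        assert a[0] == pytest.approx(lo2, abs=0.02)
        assert a[1] == pytest.approx(hi2, abs=0.02)


class TestFullReport:
    def test_report_is_rigid_invariant(self, small_cohort, small_config):
        """Pre-rotating any input arrangement leaves the report unchanged."""
        stimset, arrangements, _ = small_cohort
        base = analyze_arrangements(
            arrangements, stimset, n_boot=200, seed=0
        )
        rng = np.random.default_rng(24)
        moved = []
        for a in arrangements:
            rot, shift = random_rigid(rng)
            moved.append(a.with_coords(a.coords @ rot.T + shift))
        alt = analyze_arrangements(moved, stimset, n_boot=200, seed=0)
        assert np.allclose(base.within, alt.within, atol=1e-9)
        assert np.allclose(base.between, alt.between, atol=1e-9)
        assert base.class_agreement_simple == pytest.approx(
            alt.class_agreement_simple, abs=1e-9
        )
        assert base.session_test.t == pytest.approx(alt.session_test.t, abs=1e-9)

    def test_report_structure(self, small_cohort):
        stimset, arrangements, _ = small_cohort
        rep = analyze_arrangements(arrangements, stimset, n_boot=200, seed=0)
        n = len(rep.participant_ids)
        assert rep.session_test.df == n - 1
        assert rep.within_mean_ci[0] <= rep.within_mean <= rep.within_mean_ci[1]
        assert rep.between_mean_ci[0] <= rep.between_mean <= rep.between_mean_ci[1]
        assert rep.noise_ceiling[0] <= rep.noise_ceiling[1]
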