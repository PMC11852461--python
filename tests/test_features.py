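"""Featurization: oracle equivalence, composition, invariances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oculoscreen.exceptions import AlignmentError, InvalidInputError, UndefinedEError
from oculoscreen.features import (
    FEATURE_NAMES,
    GazeFeaturizer,
    StandardCurve,
    SubjectSeries,
    build_feature_vector,
    build_standard_curve,
    deviation_series,
    features_deviation,
    features_fixation_mode,
    features_global,
    impute_series,
    quantized_mode,
)
from oculoscreen.geometry import compute_E
from oculoscreen.simulator import generate_cohort, simulate_target_template

# ---------------------------------------------------------------------------
# independent direct-summation oracles (explicit loops, no numpy reductions)


def oracle_f1_to_f6(e):
    n = len(e)
    f1 = sum(e) / n
    f2 = (sum((x - f1) ** 2 for x in e) / n) ** 0.5
    f3 = max(e)
    f4 = min(e)
    diffs = [abs(e[m] - e[m - 1]) for m in range(1, n)]
    f5 = sum(diffs) / (n - 1)
    f6 = (sum((d - f5) ** 2 for d in diffs) / (n - 1)) ** 0.5
    return f1, f2, f3, f4, f5, f6


def oracle_f11_to_f16(dl, dr):
    n = len(dl)
    f11 = sum(abs(x) for x in dl) / n
    f12 = sum(abs(x) for x in dr) / n
    adl = [abs(dl[m] - dl[m - 1]) for m in range(1, n)]
    adr = [abs(dr[m] - dr[m - 1]) for m in range(1, n)]
    f13 = sum(adl) / (n - 1)
    f14 = sum(adr) / (n - 1)
    f15 = (sum((d - f13) ** 2 for d in adl) / (n - 1)) ** 0.5
    f16 = (sum((d - f14) ** 2 for d in adr) / (n - 1)) ** 0.5
    return f11, f12, f13, f14, f15, f16


def oracle_mode(values, width=0.01):
    """Brute-force histogram argmax with median-nearest tie-break."""
    from collections import Counter

    bins = [round(v / width) for v in values]
    counts = Counter(bins)
    top = max(counts.values())
    cands = [b for b, c in counts.items() if c == top]
    med = float(np.median(values))
    return min(cands, key=lambda b: abs(b * width - med)) * width


# ---------------------------------------------------------------------------


class TestProjectionStatistic:
    def test_pupil_at_inner_canthus_projects_to_zero(self):
        assert compute_E((0, 0), (0, 0), (10, 0)) == 0.0

    def test_pupil_at_outer_canthus_projects_to_one(self):
        assert compute_E((10, 0), (0, 0), (10, 0)) == 1.0

    def test_orthogonal_component_is_discarded(self):
        assert compute_E((4, 3), (0, 0), (10, 0)) == pytest.approx(0.4)

    def test_coincident_canthi_are_rejected(self):
        with pytest.raises(UndefinedEError):
            compute_E((1, 1), (5, 5), (5, 5))


class TestGlobalFeatures:
    def test_constant_series(self):
        f = features_global(np.full(4, 0.5))
        assert f == (0.5, 0.0, 0.5, 0.5, 0.0, 0.0)

    def test_alternating_series(self):
        f1, f2, f3, f4, f5, f6 = features_global(np.array([0.0, 1.0, 0.0, 1.0]))
        assert (f1, f3, f4, f5) == (0.5, 1.0, 0.0, 1.0)
        assert f6 == 0.0

    def test_matches_direct_summation_oracle(self, rng):
        e = rng.uniform(size=1000)
        assert features_global(e) == pytest.approx(oracle_f1_to_f6(list(e)), abs=1e-12)

    def test_missing_values_rejected(self):
        with pytest.raises(InvalidInputError):
            features_global(np.array([0.1, np.nan, 0.3]))


class TestFixationMode:
    def test_constant_window(self):
        e = np.full(80, 0.50)
        assert features_fixation_mode(e, e) == (0.50, 0.50)

    def test_majority_bin_wins(self):
        e = np.concatenate([np.full(40, 0.50), np.full(30, 0.60), np.full(10, 0.9)])
        f9, _ = features_fixation_mode(e, e)
        assert f9 == pytest.approx(0.50)

    def test_matches_bruteforce_histogram_oracle(self, rng):
        for _ in range(20):
            v = rng.uniform(0.3, 0.7, size=70)
            assert quantized_mode(v) == pytest.approx(oracle_mode(list(v)), abs=1e-12)

    def test_window_shorter_than_70_rejected(self):
        with pytest.raises(InvalidInputError):
            features_fixation_mode(np.zeros(50), np.zeros(50))


class TestDeviationFeatures:
    def test_zero_deviation_gives_zero_features(self):
        z = np.zeros(100)
        assert features_deviation(z, z) == (0.0,) * 6

    def test_alternating_deviation(self):
        d = np.tile([0.0, 0.2], 270)  # N=540
        f11, _, f13, _, f15, _ = features_deviation(d, np.zeros(540))
        assert f11 == pytest.approx(0.1)
        assert f13 == pytest.approx(0.2 * 539 / 539)
        assert f15 == pytest.approx(0.0, abs=1e-12)

    def test_matches_direct_summation_oracle(self, rng):
        dl, dr = rng.normal(size=540), rng.normal(size=540)
        assert features_deviation(dl, dr) == pytest.approx(
            oracle_f11_to_f16(list(dl), list(dr)), abs=1e-12
        )

    def test_series_equal_to_standard_gives_zero(self):
        tpl = simulate_target_template(200, 30)
        s = SubjectSeries(E_left=tpl[0], E_right=tpl[1], canthus_dists=(60, 180))
        std = StandardCurve(tpl[0], tpl[1])
        dml, dmr = deviation_series(s, std)
        assert np.allclose(dml, 0) and np.allclose(dmr, 0)

    def test_constant_offset_appears_on_one_eye_only(self):
        tpl = simulate_target_template(200, 30)
        s = SubjectSeries(E_left=tpl[0] + 0.1, E_right=tpl[1], canthus_dists=(60, 180))
        dml, dmr = deviation_series(s, StandardCurve(tpl[0], tpl[1]))
        assert np.allclose(dml, 0.1) and np.allclose(dmr, 0)

    def test_length_mismatch_rejected(self):
        s = SubjectSeries(E_left=np.zeros(10), E_right=np.zeros(10), canthus_dists=(60, 180))
        with pytest.raises(AlignmentError):
            deviation_series(s, StandardCurve(np.zeros(9), np.zeros(9)))


class TestStandardCurve:
    def test_identical_normals_reproduce_their_series(self):
        tpl = simulate_target_template(120, 20)
        subs = [
            SubjectSeries(E_left=tpl[0], E_right=tpl[1], canthus_dists=(60, 180), label="normal")
            for _ in range(3)
        ]
        std = build_standard_curve(subs)
        assert np.allclose(std.E_left_std, tpl[0])
        assert std.provenance == "cohort-median"

    def test_cohort_median_is_permutation_invariant(self, rng):
        tpl = simulate_target_template(120, 20)
        subs = [
            SubjectSeries(
                E_left=tpl[0] + rng.normal(0, 0.02, 120),
                E_right=tpl[1] + rng.normal(0, 0.02, 120),
                canthus_dists=(60, 180),
                label="normal",
            )
            for _ in range(5)
        ]
        a = build_standard_curve(subs)
        b = build_standard_curve(subs[::-1])
        assert np.array_equal(a.E_left_std, b.E_left_std)

    def test_median_curve_tracks_noise_free_template(self):
        series, labels, _ = generate_cohort(n_normal=15, n_patient=1, seed=42)
        tpl = simulate_target_template()
        std = build_standard_curve([s for s in series if s.label == "normal"])
        rmse = np.sqrt(np.mean((std.E_left_std - tpl[0]) ** 2))
        assert rmse < 0.02

    def test_too_few_normals_falls_back_to_analytic(self):
        tpl = simulate_target_template(120, 20)
        subs = [
            SubjectSeries(E_left=tpl[0], E_right=tpl[1], canthus_dists=(60, 180), label="normal")
        ]
        std = build_standard_curve(subs)
        assert std.provenance == "analytic-template"


class TestFeatureVector:
    def test_constant_composition(self):
        c = 0.5
        s = SubjectSeries(
            E_left=np.full(100, c), E_right=np.full(100, c), canthus_dists=(60.0, 180.0)
        )
        std = StandardCurve(np.full(100, c), np.full(100, c))
        v = build_feature_vector(s, std)
        expected = [c, 0, c, c, 0, 0, 60.0, 180.0, c, c] + [0.0] * 6
        assert v == pytest.approx(expected)

    def test_vector_length_is_16(self):
        tpl = simulate_target_template(100, 20)
        s = SubjectSeries(E_left=tpl[0], E_right=tpl[1], canthus_dists=(60, 180))
        assert build_feature_vector(s, StandardCurve(*tpl)).size == 16

    def test_left_episode_moves_only_left_eye_deviation_features(self):
        tpl = simulate_target_template(200, 30)
        base = SubjectSeries(E_left=tpl[0].copy(), E_right=tpl[1], canthus_dists=(60, 180))
        shifted_left = tpl[0].copy()
        shifted_left[100:160] += 0.15
        ep = SubjectSeries(E_left=shifted_left, E_right=tpl[1], canthus_dists=(60, 180))
        std = StandardCurve(*tpl)
        v0, v1 = build_feature_vector(base, std), build_feature_vector(ep, std)
        moved = {FEATURE_NAMES[i] for i in np.nonzero(~np.isclose(v0, v1))[0]}
        assert {"F11", "F13", "F15"} <= moved
        assert not moved & {"F12", "F14", "F16", "F7", "F8", "F9", "F10"}

    def test_scale_invariance_of_dimensionless_features(self, rng):
        tpl = simulate_target_template(150, 30)
        e_l = tpl[0] + rng.normal(0, 0.02, 150)
        e_r = tpl[1] + rng.normal(0, 0.02, 150)
        std = StandardCurve(*tpl)
        scale = 2.5
        v1 = build_feature_vector(
            SubjectSeries(E_left=e_l, E_right=e_r, canthus_dists=(60.0, 180.0)), std
        )
        v2 = build_feature_vector(
            SubjectSeries(
                E_left=e_l, E_right=e_r, canthus_dists=(60.0 * scale, 180.0 * scale)
            ),
            std,
        )
        dimless = [i for i, n in enumerate(FEATURE_NAMES) if n not in ("F7", "F8")]
        assert v2[dimless] == pytest.approx(v1[dimless])
        assert v2[6:8] == pytest.approx(v1[6:8] * scale)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(-1, 2), min_size=2, max_size=200))
    def test_min_mean_max_ordering_invariant(self, values):
        f1, _, f3, f4, _, _ = features_global(np.asarray(values))
        assert f4 <= f1 + 1e-12 and f1 <= f3 + 1e-12


class TestImputation:
    def test_short_gap_linearly_interpolated(self):
        v = np.array([0.4, np.nan, 0.6])
        assert impute_series(v) == pytest.approx([0.4, 0.5, 0.6])

    def test_long_gap_left_missing(self):
        v = np.concatenate([[0.4], np.full(11, np.nan), [0.6]])
        out = impute_series(v, max_gap=10)
        assert np.isnan(out[1:12]).all()

    def test_light_imputation_barely_changes_mean(self):
        series, _, _ = generate_cohort(n_normal=2, n_patient=1, seed=7)
        e = series[0].E_avg.copy()
        f1_clean = features_global(e)[0]
        e_miss = e.copy()
        e_miss[100:105] = np.nan  # < 1% of 540 frames
        f1_imp = features_global(impute_series(e_miss))[0]
        assert abs(f1_imp - f1_clean) < 1e-3


class TestGazeFeaturizer:
    def test_fold_fit_transform_shapes(self):
        series, labels, _ = generate_cohort(n_normal=5, n_patient=3, seed=0)
        feat = GazeFeaturizer().fit(series, labels)
        X = feat.transform(series)
        assert X.shape == (8, 16)
        assert list(feat.get_feature_names_out()) == list(FEATURE_NAMES)

    def test_transform_before_fit_rejected(self):
        with pytest.raises(InvalidInputError):
            GazeFeaturizer().transform([])
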