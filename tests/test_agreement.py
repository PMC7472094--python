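"""Windowing, panels and cross-modality agreement statistics."""

import numpy as np
import pytest
from scipy import special

from mechanohrv import (HRVTruthParams, PANEL_KEYS, WindowSpec,
                        generate_record, panel, pearson, relative_error,
                        window_nn)
from mechanohrv.agreement import _aggregate, analyze_record, compare_cohort
from tests.conftest import make_nn, random_nn


def regular_nn(duration_s, nn_ms=800.0):
    n = int(duration_s * 1000 / nn_ms)
    return make_nn([nn_ms] * n)


class TestWindowing:
    @pytest.mark.parametrize("duration,expected", [(600, 29), (179, 1),
                                                   (180, 1), (178, 0)])
    def test_full_window_count_formula(self, duration, expected):
        nn = regular_nn(duration)
        wins = window_nn(nn, WindowSpec(), duration=duration, min_beats=5)
        assert len(wins) == expected

    def test_membership_is_by_onset_time_half_open(self):
        nn = regular_nn(400)
        wins = window_nn(nn, WindowSpec(length_s=179, step_s=15),
                         duration=400, min_beats=5)
        for k, w in enumerate(wins):
            assert np.all(w.onset_times >= k * 15)
            assert np.all(w.onset_times < k * 15 + 179)

    def test_sparse_windows_are_dropped(self):
        nn = make_nn([1800.0] * 100)  # ~99 beats per 179 s window
        wins = window_nn(nn, WindowSpec(), duration=180, min_beats=150)
        assert wins == []

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            WindowSpec(length_s=10, step_s=15)


class TestPanel:
    def test_panel_keys_match_index_set(self, rng):
        p = panel(random_nn(rng, n=300))
        assert tuple(p) == PANEL_KEYS

    def test_constant_series_panel(self):
        p = panel(make_nn([900.0] * 200))
        assert p["avnn"] == 900.0
        for k in ("sdnn", "rmssd", "pnn50", "sd1", "sd2", "ea", "vai", "vli"):
            assert p[k] == 0.0
        assert p["tp"] == pytest.approx(0.0, abs=1e-9)
        assert np.isnan(p["lf_hf"])  # undefined, never silently zero

    def test_too_few_beats_rejected(self, rng):
        with pytest.raises(ValueError, match="at least"):
            panel(random_nn(rng, n=10))


class TestRelativeError:
    def test_identical_panels_zero(self, rng):
        p = panel(random_nn(rng, n=200))
        rel, absd = relative_error(p, p)
        for k in PANEL_KEYS:
            if np.isfinite(p[k]):
                assert rel[k] == 0.0
                assert absd[k] == 0.0

    def test_ten_percent_example(self):
        rel, _ = relative_error({"x": 100.0}, {"x": 110.0})
        assert rel["x"] == pytest.approx(0.10)

    def test_zero_reference_marked_undefined(self):
        rel, _ = relative_error({"x": 0.0}, {"x": 1.0})
        assert np.isnan(rel["x"])

    def test_mismatched_keys_rejected(self):
        with pytest.raises(ValueError):
            relative_error({"x": 1.0}, {"y": 1.0})


class TestPearson:
    def test_perfect_linear_relations(self, rng):
        x = rng.normal(0, 1, 50)
        rho, p = pearson(x, 2 * x + 3)
        assert rho == pytest.approx(1.0)
        assert p < 1e-10
        rho, _ = pearson(x, -x)
        assert rho == pytest.approx(-1.0)

    def test_matches_textbook_formula(self, rng):
        x, y = rng.normal(0, 1, 40), rng.normal(0, 1, 40)
        rho, p = pearson(x, y)
        # independent oracle: covariance/sigma-sigma and the t transform
        r = (np.mean(x * y) - np.mean(x) * np.mean(y)) / (np.std(x) * np.std(y))
        assert abs(rho - r) < 1e-12
        n = x.size
        t = r * np.sqrt((n - 2) / (1 - r * r))
        p_oracle = 2 * special.stdtr(n - 2, -abs(t))
        assert abs(p - p_oracle) < 1e-12

    def test_zero_variance_undefined(self):
        rho, p = pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert np.isnan(rho) and np.isnan(p)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            pearson([1.0, 2.0], [3.0, 4.0])


@pytest.fixture(scope="module")
def mini_cohort():
    recs = []
    for seed, mean_nn in [(1, 850), (2, 950), (3, 1050), (4, 900)]:
        p = HRVTruthParams(mean_nn=mean_nn, sd_nn=30 + 5 * seed,
                           duration=240, seed=seed)
        rec, _ = generate_record(p, subject_id=f"M{seed}")
        recs.append(rec)
    return recs


class TestCohort:
    def test_self_comparison_is_exact(self, mini_cohort):
        panels = [analyze_record(r)["full"]["ecg"] for r in mini_cohort]
        table = _aggregate(panels, panels)
        finite = table["pearson_rho"].notna()
        assert np.all(table.loc[finite, "pearson_rho"] == 1.0)
        assert np.all(table["rel_err_mean"].fillna(0.0) == 0.0)

    def test_full_variant_table_structure(self, mini_cohort):
        tables = compare_cohort(mini_cohort, variant="full")
        assert set(tables) == {"ecg_scg", "ecg_gcg"}
        for table in tables.values():
            assert list(table.index) == list(PANEL_KEYS)
            assert {"rel_err_mean", "rel_err_sd", "pearson_rho",
                    "pearson_p", "strong"} <= set(table.columns)

    def test_windowed_variant_pools_windows(self, mini_cohort):
        tables = compare_cohort(mini_cohort, spec=WindowSpec(),
                                variant="windowed")
        # 240 s records: floor((240-179)/15)+1 = 5 windows each, 4 records
        assert int(tables["ecg_gcg"]["n_pairs"].iloc[0]) == 20

    def test_noise_free_agreement_is_tight(self, mini_cohort):
        tables = compare_cohort(mini_cohort, variant="full")
        for key in ("avnn", "sdnn", "rmssd"):
            assert tables["ecg_gcg"].loc[key, "pearson_rho"] > 0.99
            assert tables["ecg_gcg"].loc[key, "rel_err_mean"] < 0.02

    def test_invalid_record_skipped_with_warning(self, mini_cohort):
        broken = generate_record(HRVTruthParams(duration=240, seed=9))[0]
        del broken.channels["gcg_y"]
        with pytest.warns(UserWarning, match="skipping record"):
            tables = compare_cohort(mini_cohort + [broken], variant="full")
        assert int(tables["ecg_gcg"]["n_pairs"].iloc[0]) == len(mini_cohort)

    def test_unknown_variant_rejected(self, mini_cohort):
        with pytest.raises(ValueError):
            compare_cohort(mini_cohort, variant="weekly")
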