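import numpy as np
import pytest

from wildri.partition import (
    aicc,
    analysis_frame,
    compare_groups,
    default_candidate_set,
    fit_linear_model,
    select_model,
    summarize_groups,
)
from wildri.synthetic import simulate

from conftest import grouped_dataset, one_analyte_config


class TestSummarizeGroups:
    def test_single_level_basics(self):
        ds = grouped_dataset({"adult": [1, 2, 3, 4, 5]})
        (row,) = summarize_groups(ds, "A", "age_class")
        assert row.n == 5
        assert row.center == pytest.approx(3.0)
        assert (row.min, row.max) == (1.0, 5.0)

    def test_degenerate_equal_values(self):
        ds = grouped_dataset({"adult": [2, 2, 2]})
        (row,) = summarize_groups(ds, "A", "age_class")
        assert row.center == 2.0
        assert row.spread_low <= row.center <= row.spread_high

    def test_normal_level_reports_mean_ci(self, rng):
        ds = grouped_dataset({"adult": rng.normal(10, 1, 80)})
        (row,) = summarize_groups(ds, "A", "age_class")
        assert row.normal
        assert row.spread_low < row.center < row.spread_high
        # t-based CI of the mean is much narrower than the data range
        assert row.spread_high - row.spread_low < 1.0

    def test_skewed_level_reports_median_and_deciles(self, rng):
        vals = rng.lognormal(0, 1, 200)
        ds = grouped_dataset({"adult": vals})
        (row,) = summarize_groups(ds, "A", "age_class")
        assert not row.normal
        assert row.center == pytest.approx(np.median(vals))
        assert row.spread_low == pytest.approx(np.percentile(vals, 10))
        assert row.spread_high == pytest.approx(np.percentile(vals, 90))

    def test_generated_age_shift_recovered(self):
        cfg = one_analyte_config(
            4, n_single=300, mean=8.0, sd_between=1.0, sd_within=1.0,
            shifts={("age_class", "adult"): 4.0},
            age_probs={"adult": 0.5, "juvenile": 0.5},
        )
        ds = simulate(cfg)
        rows = {r.level: r for r in summarize_groups(ds, "A", "age_class")}
        assert rows["adult"].center > rows["juvenile"].center

    def test_unknown_factor_rejected(self):
        ds = grouped_dataset({"adult": [1, 2, 3]})
        with pytest.raises(ValueError):
            summarize_groups(ds, "A", "mass")

    def test_singleton_level_dropped(self):
        ds = grouped_dataset({"May": [1, 2, 3, 4], "August": [9]},
                             factor="month")
        with pytest.warns(UserWarning, match="dropped"):
            rows = summarize_groups(ds, "A", "month")
        assert [r.level for r in rows] == ["May"]


class TestCompareGroups:
    def test_identical_groups_null_result(self):
        vals = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0]
        ds = grouped_dataset({"female": vals, "male": vals}, factor="sex")
        res = compare_groups(ds, "A", "sex")
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_large_effect_detected(self, rng):
        ds = grouped_dataset(
            {"female": rng.normal(0, 1, 50), "male": rng.normal(5, 1, 50)},
            factor="sex",
        )
        res = compare_groups(ds, "A", "sex")
        assert res.test == "t"
        assert res.p < 1e-6

    def test_rank_branch_when_any_level_non_normal(self, rng):
        ds = grouped_dataset(
            {"female": rng.normal(10, 1, 60), "male": rng.lognormal(0, 1.5, 60)},
            factor="sex",
        )
        assert compare_groups(ds, "A", "sex").test == "mann_whitney"

    def test_three_level_dispatch(self, rng):
        normal = {
            lvl: rng.normal(m, 1, 40)
            for lvl, m in [("adult", 0), ("subadult", 3), ("juvenile", 6)]
        }
        res = compare_groups(grouped_dataset(normal), "A", "age_class")
        assert res.test == "anova"
        assert res.p < 1e-6
        assert len(res.pairwise) == 3

        skewed = {lvl: np.exp(v) for lvl, v in normal.items()}
        res2 = compare_groups(grouped_dataset(skewed), "A", "age_class")
        assert res2.test == "kruskal_wallis"

    def test_pairwise_only_when_omnibus_significant(self, rng):
        ds = grouped_dataset(
            {lvl: rng.normal(0, 1, 30)
             for lvl in ("adult", "subadult", "juvenile")})
        res = compare_groups(ds, "A", "age_class")
        if res.p >= 0.05:
            assert res.pairwise == ()

    def test_sex_pairwise_restricted_to_female_male(self, rng):
        ds = grouped_dataset(
            {"female": rng.normal(0, 1, 40), "male": rng.normal(4, 1, 40),
             "unknown": rng.normal(8, 1, 40)},
            factor="sex",
        )
        res = compare_groups(ds, "A", "sex")
        assert res.p < 0.05
        assert len(res.pairwise) == 1
        assert set(res.pairwise[0][:2]) == {"female", "male"}

    def test_august_singleton_dropped(self, rng):
        ds = grouped_dataset(
            {"May": rng.normal(0, 1, 30), "June": rng.normal(0, 1, 30),
             "August": [99.0]},
            factor="month",
        )
        with pytest.warns(UserWarning, match="dropped"):
            res = compare_groups(ds, "A", "month")
        assert res.test in ("t", "mann_whitney")  # only two usable levels


class TestFitLinearModel:
    def test_intercept_only_closed_form(self, rng):
        vals = rng.normal(10, 2, 50)
        ds = grouped_dataset({"adult": vals})
        fit = fit_linear_model(ds, "A", (), dedup="all")
        assert fit.coefficients["Intercept"] == pytest.approx(vals.mean())
        assert fit.rss == pytest.approx(((vals - vals.mean()) ** 2).sum())
        assert fit.k == 2

    def test_binary_factor_closed_form(self, rng):
        a, b = rng.normal(10, 1, 30), rng.normal(14, 1, 30)
        ds = grouped_dataset({"SBCP": a, "IBSP": b}, factor="site")
        fit = fit_linear_model(ds, "A", (("site",),), dedup="all")
        coef = [v for k, v in fit.coefficients.items() if "site" in k]
        assert len(coef) == 1
        assert abs(coef[0]) == pytest.approx(abs(a.mean() - b.mean()))

    def test_rss_matches_brute_force(self, study_dataset):
        terms = (("age_class",), ("sex",), ("site",), ("age_class", "sex"))
        fit = fit_linear_model(study_dataset, "Calcium", terms)
        frame = analysis_frame(study_dataset, "Calcium", dedup="first")
        # brute-force OLS on an explicitly built dummy matrix
        import pandas as pd

        X = pd.get_dummies(
            frame[["age_class", "sex", "site"]], drop_first=True, dtype=float)
        inter = pd.get_dummies(
            frame["age_class"] + ":" + frame["sex"], drop_first=False,
            dtype=float)
        X = pd.concat([X, inter], axis=1)
        X.insert(0, "const", 1.0)
        y = frame["value"].to_numpy()
        beta, *_ = np.linalg.lstsq(X.to_numpy(), y, rcond=None)
        rss = ((y - X.to_numpy() @ beta) ** 2).sum()
        assert fit.rss == pytest.approx(rss, abs=1e-8 * max(1.0, rss))


class TestSelectModel:
    def test_weights_sum_to_one(self, study_dataset):
        ranked = select_model(study_dataset, "PCV")
        assert sum(m.weight for m in ranked) == pytest.approx(1.0, abs=1e-9)
        assert ranked[0].delta_aicc == 0.0
        assert all(
            ranked[i].aicc <= ranked[i + 1].aicc for i in range(len(ranked) - 1))

    def test_duplicate_candidates_tie(self, study_dataset):
        ranked = select_model(
            study_dataset, "PCV", candidates=[(("site",),), (("site",),)])
        assert ranked[0].aicc == ranked[1].aicc
        assert ranked[0].delta_aicc == ranked[1].delta_aicc == 0.0

    def test_parsimony_under_null(self):
        simpler_wins = 0
        for seed in range(50):
            cfg = one_analyte_config(
                seed, n_single=40, mean=10, sd_between=0.0, sd_within=1.0,
                site_probs={"SBCP": 0.5, "IBSP": 0.5})
            ds = simulate(cfg)
            ranked = select_model(
                ds, "A", candidates=[(), (("site",),)], dedup="all")
            if ranked[0].terms == ():
                simpler_wins += 1
        assert simpler_wins > 25

    def test_strong_site_effect_recovered(self):
        cfg = one_analyte_config(
            2, n_single=200, mean=10, sd_between=0.0, sd_within=1.0,
            shifts={("site", "IBSP"): 5.0},
            site_probs={"SBCP": 0.5, "IBSP": 0.5},
            sex_probs={"female": 0.5, "male": 0.5},
        )
        ds = simulate(cfg)
        ranked = select_model(
            ds, "A",
            candidates=[(), (("sex",),), (("site",),), (("site",), ("sex",))],
            dedup="all",
        )
        assert ("site",) in ranked[0].terms

    def test_reordering_does_not_change_weights(self, study_dataset):
        c1 = [(), (("site",),), (("year",),)]
        r1 = select_model(study_dataset, "TS", candidates=c1)
        r2 = select_model(study_dataset, "TS", candidates=c1[::-1])
        w1 = {m.terms: m.weight for m in r1}
        w2 = {m.terms: m.weight for m in r2}
        assert w1 == pytest.approx(w2)

    def test_overparameterised_candidate_skipped(self):
        cfg = one_analyte_config(
            1, n_single=8, mean=10, sd_between=0, sd_within=1,
            site_probs={"SBCP": 0.5, "IBSP": 0.5},
            sex_probs={"female": 0.4, "male": 0.4, "unknown": 0.2},
            age_probs={"adult": 0.4, "subadult": 0.3, "juvenile": 0.3},
        )
        ds = simulate(cfg)
        big = tuple((f,) for f in ("site", "sex", "age_class")) + (
            ("site", "sex"), ("site", "age_class"), ("sex", "age_class"))
        with pytest.warns(UserWarning, match="skipped"):
            ranked = select_model(ds, "A", candidates=[(), big], dedup="all")
        assert len(ranked) == 1


def test_default_candidate_set_shape():
    cands = default_candidate_set()
    assert len(cands) == 33  # 2^5 main-effect subsets + global model
    global_model = max(cands, key=len)
    assert len(global_model) == 15  # 5 mains + C(5,2) interactions


def test_aicc_formula():
    # AICc = n ln(rss/n) + 2k + 2k(k+1)/(n-k-1)
    assert aicc(100.0, 50, 3) == pytest.approx(
        50 * np.log(2.0) + 6 + 24 / 46)
    with pytest.raises(ValueError):
        aicc(1.0, 5, 4)


def test_analysis_frame_dedup_first_capture(study_dataset):
    all_rows = analysis_frame(study_dataset, "PCV", dedup="all")
    first = analysis_frame(study_dataset, "PCV", dedup="first")
    assert len(first) == first["animal_id"].nunique() == 227
    assert len(all_rows) > len(first)
    # the kept row is each animal's earliest capture
    one = all_rows.sort_values("date").groupby("animal_id").first()
    sub = first.set_index("animal_id")
    assert (sub["date"] == one.loc[sub.index, "date"]).all()
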