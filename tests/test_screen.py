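"""Variant screen: aggregation, normalization, filtering, tests, selection."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.multivariate.manova import MANOVA

import macrotol as mt
from macrotol.screen import (
    LinePhenotypeMatrix,
    ScreenThresholds,
    pillai_trace_p,
    ranksum_p,
)
from _oracles import brute_force_filter_count, exact_permutation_manova_p


def _panel_from_counts(counts):
    """counts: {(strain, diet): [(pupated, seeded), ...]}"""
    rows = []
    for (s, d), vials in counts.items():
        for v, (p, n) in enumerate(vials):
            rows.append(
                {"strain": s, "diet": d, "vial": v, "n_seeded": n, "n_pupated": p,
                 "n_eclosed": 0}
            )
    return pd.DataFrame(rows)


class TestAggregation:
    @pytest.mark.parametrize(
        "vials,expected",
        [
            ([(15, 30)] * 4, 0.5),
            ([(30, 30), (0, 30)], 0.5),
            ([(10, 30), (20, 30), (30, 30), (0, 30)], 0.5),
        ],
    )
    def test_mean_of_vial_proportions(self, vials, expected):
        panel = _panel_from_counts({("s1", "HPD"): vials})
        phen = mt.aggregate_line_phenotypes(panel)
        assert phen.table.loc["s1", "HPD"] == pytest.approx(expected)

    def test_eclosion_denominators(self):
        panel = _panel_from_counts({("s1", "HPD"): [(20, 30)]})
        panel["n_eclosed"] = 10
        by_seeded = mt.aggregate_line_phenotypes(panel, stage="eclosion")
        assert by_seeded.table.loc["s1", "HPD"] == pytest.approx(10 / 30)
        by_pupae = mt.aggregate_line_phenotypes(
            panel, stage="eclosion", eclosion_denominator="pupae"
        )
        assert by_pupae.table.loc["s1", "HPD"] == pytest.approx(10 / 20)

    def test_missing_cell_stays_missing(self):
        panel = _panel_from_counts(
            {("s1", "HPD"): [(15, 30)], ("s1", "HSD"): [(10, 30)], ("s2", "HPD"): [(20, 30)]}
        )
        phen = mt.aggregate_line_phenotypes(panel)
        assert np.isnan(phen.table.loc["s2", "HSD"])


class TestNormalization:
    def test_reference_subtraction(self):
        table = pd.DataFrame(
            {"HPD": [0.9, 0.5], "HSD": [0.2, 0.5]}, index=["s1", "s2"]
        )
        m = LinePhenotypeMatrix(table, stage="pupation", reference_diet="HPD")
        norm = mt.normalize_phenotypes(m)
        assert norm.table.loc["s1", "HSD"] == pytest.approx(-0.7)
        assert norm.table.loc["s2", "HSD"] == pytest.approx(0.0)
        assert "HPD" not in norm.table.columns
        assert norm.normalized

    def test_double_normalization_rejected(self):
        table = pd.DataFrame({"HPD": [0.9], "HSD": [0.2]}, index=["s1"])
        m = LinePhenotypeMatrix(table, stage="pupation", reference_diet="HPD")
        norm = mt.normalize_phenotypes(m)
        with pytest.raises(ValueError, match="already normalized"):
            mt.normalize_phenotypes(norm)

    def test_missing_reference_rejected(self):
        table = pd.DataFrame({"HSD": [0.2]}, index=["s1"])
        m = LinePhenotypeMatrix(table, stage="pupation", reference_diet="HPD")
        with pytest.raises(ValueError, match="reference diet"):
            mt.normalize_phenotypes(m)


class TestFiltering:
    def test_boundary_counts(self):
        calls = np.full((2, 100), -1, dtype=np.int8)
        calls[0, :4] = 1
        calls[0, 4:] = 0  # 4 alt lines -> removed
        calls[1, :5] = 1
        calls[1, 5:10] = 0  # 5 alt, 5 ref, 90 missing -> kept
        g = mt.GenotypeMatrix(
            pd.DataFrame(
                {"id": ["v1", "v2"], "chrom": "2L", "pos": [1, 2], "ref": "A", "alt": "T"}
            ),
            calls,
            [f"line_{i:03d}" for i in range(100)],
            pd.Series(False, index=[f"line_{i:03d}" for i in range(100)]),
        )
        filtered = mt.filter_variants(g, g.lines)
        assert list(filtered.variants["id"]) == ["v2"]

    def test_matches_brute_force_count(self, small_config):
        cfg = mt.SimulationConfig(
            n_strains=60, diets=("HPD", "HSD"), n_variants=500,
            minor_line_count_distribution=(0, 12), missing_call_rate=0.05, seed=9,
        )
        g, _ = mt.simulate_genotypes(cfg)
        filtered = mt.filter_variants(g, g.lines)
        assert filtered.n_variants == brute_force_filter_count(g.calls)

    def test_no_common_lines_rejected(self, small_config):
        g, _ = mt.simulate_genotypes(small_config)
        with pytest.raises(ValueError, match="no lines in common"):
            mt.filter_variants(g, ["unknown_line"])


def _pheno_matrix(Y, lines, diets=("HSD", "WD", "HStD")):
    return LinePhenotypeMatrix(
        pd.DataFrame(Y, index=lines, columns=list(diets)),
        stage="pupation",
        reference_diet="HPD",
        normalized=True,
    )


class TestManova:
    def test_matches_statsmodels_pillai(self):
        rng = np.random.default_rng(4)
        n = 30
        lines = [f"l{i}" for i in range(n)]
        Y = rng.normal(scale=0.2, size=(n, 3)).clip(-1, 1)
        geno = pd.Series((rng.random(n) < 0.4).astype(float), index=lines)
        geno.iloc[:3] = 1.0
        geno.iloc[3:6] = 0.0
        wolb = pd.Series(rng.random(n) < 0.5, index=lines)
        p_mine = mt.manova_test(_pheno_matrix(Y, lines), geno, wolb)
        df = pd.DataFrame(Y, columns=["y1", "y2", "y3"])
        df["g"] = geno.to_numpy()
        df["w"] = wolb.to_numpy(dtype=float)
        tab = MANOVA.from_formula("y1 + y2 + y3 ~ g + w", data=df).mv_test()
        p_sm = float(tab.results["g"]["stat"].loc["Pillai's trace", "Pr > F"])
        assert p_mine == pytest.approx(p_sm, abs=1e-10)

    def test_univariate_degenerates_to_anova(self):
        rng = np.random.default_rng(5)
        n = 24
        lines = [f"l{i}" for i in range(n)]
        Y = rng.normal(scale=0.2, size=(n, 1)).clip(-1, 1)
        geno = pd.Series(np.repeat([0.0, 1.0], n // 2), index=lines)
        wolb = pd.Series(rng.random(n) < 0.5, index=lines)
        phen = LinePhenotypeMatrix(
            pd.DataFrame(Y, index=lines, columns=["HSD"]),
            stage="pupation", reference_diet="HPD", normalized=True,
        )
        p_manova = mt.manova_test(phen, geno, wolb)
        import statsmodels.api as sm

        X = sm.add_constant(np.column_stack([geno, wolb.astype(float)]))
        res = sm.OLS(Y[:, 0], X).fit()
        assert p_manova == pytest.approx(res.pvalues[1], abs=1e-9)

    def test_type_i_error_calibrated(self):
        """Null rejection rate at alpha=0.05 stays within its binomial CI
        over 200 simulated null datasets."""
        rng = np.random.default_rng(6)
        n = 60
        lines = [f"l{i}" for i in range(n)]
        rej = 0
        n_sim = 200
        for _ in range(n_sim):
            Y = rng.normal(scale=0.2, size=(n, 3)).clip(-1, 1)
            geno = pd.Series(np.repeat([0.0, 1.0], n // 2), index=lines)
            wolb = pd.Series(rng.random(n) < 0.5, index=lines)
            rej += mt.manova_test(_pheno_matrix(Y, lines), geno, wolb) < 0.05
        lo = 0.05 * n_sim - 1.96 * np.sqrt(n_sim * 0.05 * 0.95)
        hi = 0.05 * n_sim + 1.96 * np.sqrt(n_sim * 0.05 * 0.95)
        assert lo <= rej <= hi

    def test_agrees_with_exact_permutation_oracle(self):
        """On a 12-line instance the Pillai F p-value tracks the exactly
        enumerated permutation distribution."""
        rng = np.random.default_rng(12)
        n = 12
        lines = [f"l{i}" for i in range(n)]
        Y = rng.normal(scale=0.2, size=(n, 3)).clip(-1, 1)
        geno = pd.Series(np.repeat([1.0, 0.0], 6), index=lines)
        p_f = mt.manova_test(_pheno_matrix(Y, lines), geno, wolbachia=None)
        p_perm = exact_permutation_manova_p(Y, geno.to_numpy())
        assert abs(p_f - p_perm) <= 0.03

    def test_constant_genotype_rejected(self):
        n = 10
        lines = [f"l{i}" for i in range(n)]
        Y = np.zeros((n, 2))
        geno = pd.Series(np.ones(n), index=lines)
        with pytest.raises(ValueError, match="constant"):
            mt.manova_test(_pheno_matrix(Y, lines, diets=("HSD", "WD")), geno)

    def test_rank_deficiency_rejected(self):
        n = 5
        lines = [f"l{i}" for i in range(n)]
        rng = np.random.default_rng(0)
        Y = rng.normal(scale=0.1, size=(n, 4)).clip(-1, 1)
        geno = pd.Series([0, 0, 1, 1, 1.0], index=lines)
        with pytest.raises(ValueError, match="rank"):
            mt.manova_test(
                _pheno_matrix(Y, lines, diets=("HSD", "WD", "HStD", "HFDcoco")), geno
            )


class TestWilcoxon:
    def test_complete_separation_exact_p(self):
        assert ranksum_p([1, 2, 3, 4, 5], [6, 7, 8, 9, 10], method="exact") == (
            pytest.approx(2 / 252)
        )

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=7), rng.normal(size=9)
        assert ranksum_p(x, y, method="exact") == pytest.approx(
            ranksum_p(y, x, method="exact")
        )
        assert ranksum_p(x, y, method="approx") == pytest.approx(
            ranksum_p(y, x, method="approx")
        )

    def test_identical_multisets_p_one(self):
        assert ranksum_p([1, 2, 3], [1, 2, 3], method="exact") == pytest.approx(1.0)

    def test_exact_approx_agreement(self):
        """Tie-corrected normal approximation within 0.01 of the exact
        enumeration for groups of >=16 observations (1,000 instances)."""
        rng = np.random.default_rng(8)
        worst = 0.0
        for _ in range(1000):
            n1 = int(rng.integers(16, 21))
            n2 = int(rng.integers(16, 21))
            pooled = rng.normal(size=n1 + n2)
            if rng.random() < 0.4:
                pooled = np.round(pooled, 1)  # induce ties
            pe = ranksum_p(pooled[:n1], pooled[n1:], method="exact")
            pa = ranksum_p(pooled[:n1], pooled[n1:], method="approx")
            worst = max(worst, abs(pe - pa))
        assert worst <= 0.01

    def test_empty_group_gives_missing(self):
        lines = ["a", "b", "c"]
        phen = LinePhenotypeMatrix(
            pd.DataFrame({"HSD": [0.1, 0.2, 0.3]}, index=lines),
            stage="pupation", reference_diet="HPD", normalized=True,
        )
        geno = pd.Series([1.0, 1.0, 1.0], index=lines)
        p = mt.wilcoxon_per_diet(phen, geno)
        assert np.isnan(p["HSD"])


class TestEffectSizes:
    def test_median_difference(self):
        lines = [f"l{i}" for i in range(6)]
        phen = LinePhenotypeMatrix(
            pd.DataFrame({"HSD": [0.1, 0.2, 0.9, 0.5, 0.6, 0.7]}, index=lines),
            stage="pupation", reference_diet="HPD",
        )
        geno = pd.Series([1, 1, 1, 0, 0, 0.0], index=lines)
        assert mt.effect_sizes(phen, geno)["HSD"] == pytest.approx(-0.4)

    def test_identical_groups_zero(self):
        lines = list("abcd")
        phen = LinePhenotypeMatrix(
            pd.DataFrame({"HSD": [0.3, 0.4, 0.3, 0.4]}, index=lines),
            stage="pupation", reference_diet="HPD",
        )
        geno = pd.Series([1, 1, 0, 0.0], index=lines)
        assert mt.effect_sizes(phen, geno)["HSD"] == pytest.approx(0.0)

    def test_single_element_groups(self):
        lines = ["a", "b"]
        phen = LinePhenotypeMatrix(
            pd.DataFrame({"HSD": [0.8, 0.5]}, index=lines),
            stage="pupation", reference_diet="HPD",
        )
        geno = pd.Series([1, 0.0], index=lines)
        assert mt.effect_sizes(phen, geno)["HSD"] == pytest.approx(0.3)


@pytest.fixture(scope="module")
def screened():
    cfg = mt.SimulationConfig(
        n_strains=80,
        diets=("HPD", "HSD", "WD"),
        n_vials_per_diet=4,
        n_variants=60,
        minor_line_count_distribution=(3, 40),
        causal_variants=(mt.CausalVariant(5, {"HSD": -0.4}, n_alt_lines=20),),
        seed=21,
    )
    panel, geno, truth = mt.simulate_panel_with_genotypes(cfg)
    phen = mt.aggregate_line_phenotypes(panel)
    filtered = mt.filter_variants(geno, phen.lines)
    return cfg, filtered, phen, mt.screen_variants(filtered, phen)


class TestScreen:

    def test_planted_variant_selected(self, screened):
        _, _, _, res = screened
        row = res[res["variant_id"] == "var_000006"]
        assert len(row) == 1 and bool(row["selected"].iloc[0])
        assert "HSD" in row["selection_reasons"].iloc[0]

    def test_null_variants_mostly_unselected(self, screened):
        _, _, _, res = screened
        null = res[res["variant_id"] != "var_000006"]
        assert (~null["selected"]).mean() >= 0.95

    def test_vacuous_thresholds_select_everything(self, screened):
        _, filtered, phen, _ = screened
        res = mt.screen_variants(
            filtered, phen,
            ScreenThresholds(manova_p=1.0, wilcoxon_p=1.0, effect_raw=0.0, effect_normalized=0.0),
        )
        testable = res["error"] == ""
        assert res.loc[testable, "selected"].all()

    def test_selection_conjunction_reasons(self, screened):
        """A variant passing MANOVA+Wilcoxon but failing the effect-size
        criterion is unselected, with per-diet reasons showing why."""
        _, filtered, phen, res = screened
        strict = mt.screen_variants(
            filtered, phen,
            ScreenThresholds(manova_p=1.0, wilcoxon_p=1.0, effect_raw=2.0, effect_normalized=2.0),
        )
        assert not strict["selected"].any()
        assert not strict[[c for c in strict.columns if c.startswith("diet_hit")]].any().any()

    def test_selection_monotone_in_thresholds(self, screened):
        _, filtered, phen, res = screened
        loose = mt.screen_variants(
            filtered, phen,
            ScreenThresholds(manova_p=1e-3, wilcoxon_p=0.05, effect_raw=0.2, effect_normalized=0.1),
        )
        tight_sel = set(res.loc[res["selected"], "variant_id"])
        loose_sel = set(loose.loc[loose["selected"], "variant_id"])
        assert tight_sel <= loose_sel

    def test_order_and_label_invariance(self, screened):
        _, filtered, phen, res = screened
        # reverse variant order
        rev = filtered.subset(variant_mask=np.arange(filtered.n_variants)[::-1])
        res_rev = mt.screen_variants(rev, phen)
        merged = res.set_index("variant_id").join(
            res_rev.set_index("variant_id"), rsuffix="_rev"
        )
        np.testing.assert_allclose(merged["manova_p"], merged["manova_p_rev"], rtol=1e-10)
        # relabel lines consistently in genotypes and phenotypes
        mapping = {l: f"x_{l}" for l in filtered.lines}
        relabeled = mt.GenotypeMatrix(
            filtered.variants.copy(),
            filtered.calls.copy(),
            [mapping[l] for l in filtered.lines],
            filtered.wolbachia.rename(index=mapping),
        )
        phen2 = LinePhenotypeMatrix(
            phen.table.rename(index=mapping), stage=phen.stage,
            reference_diet=phen.reference_diet, normalized=phen.normalized,
        )
        res_rel = mt.screen_variants(relabeled, phen2)
        np.testing.assert_allclose(res["manova_p"], res_rel["manova_p"], rtol=1e-10)

    def test_wilks_alternative_matches_statsmodels(self):
        rng = np.random.default_rng(13)
        n = 30
        lines = [f"l{i}" for i in range(n)]
        Y = rng.normal(scale=0.2, size=(n, 3)).clip(-1, 1)
        geno = pd.Series(np.repeat([0.0, 1.0], n // 2), index=lines)
        wolb = pd.Series(rng.random(n) < 0.5, index=lines)
        p_w = mt.manova_test(_pheno_matrix(Y, lines), geno, wolb, statistic="wilks")
        df = pd.DataFrame(Y, columns=["y1", "y2", "y3"])
        df["g"] = geno.to_numpy()
        df["w"] = wolb.to_numpy(dtype=float)
        tab = MANOVA.from_formula("y1 + y2 + y3 ~ g + w", data=df).mv_test()
        p_sm = float(tab.results["g"]["stat"].loc["Wilks' lambda", "Pr > F"])
        assert p_w == pytest.approx(p_sm, abs=1e-10)
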