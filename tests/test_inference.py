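"""Correlation screen, design build, good-gene test, randomization."""

import numpy as np
import pandas as pd
import pytest

from matechoice.errors import InsufficientDataError, ValidationError
from matechoice.inference import (
    AnalysisConfig,
    MatingSite,
    build_design,
    correlation_screen,
    good_gene_test,
    parent_pair_randomization,
    run_full_analysis,
)


class TestCorrelationScreen:
    def test_collinear_pair_keeps_higher_priority(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        df = pd.DataFrame({"a": x, "b": 2 * x + 1, "c": rng.normal(size=50)})
        retained, report = correlation_screen(df, priority=["a", "b"])
        assert retained == ["a", "c"]
        row = report.query("col_a == 'a' and col_b == 'b'").iloc[0]
        assert row["dropped"] == "b"
        assert row["r"] == pytest.approx(1.0)

    def test_constant_column_inapplicable_never_drops(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(
            {"a": rng.normal(size=30), "const": np.ones(30)}
        )
        retained, report = correlation_screen(df)
        assert retained == ["a", "const"]
        assert not report["applicable"].iloc[0]

    def test_null_flag_rate_matches_alpha(self):
        # independent standard normals: flagged fraction ~ alpha
        rng = np.random.default_rng(2)
        flags = []
        for _ in range(30):
            df = pd.DataFrame(rng.normal(size=(200, 10)))
            df.columns = [f"v{i}" for i in range(10)]
            _, report = correlation_screen(df, alpha=0.05)
            flags.extend(report["p"] < 0.05)
        frac = np.mean(flags)
        se = np.sqrt(0.05 * 0.95 / len(flags))
        assert frac == pytest.approx(0.05, abs=3 * se)

    def test_too_few_rows(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "b": [2.0, 1.0]})
        with pytest.raises(InsufficientDataError):
            correlation_screen(df)


def _site(site_id, female, males, year=2010):
    return MatingSite(site_id=site_id, year=year, female=female,
                      males=tuple(males))


class TestMatingSiteValidation:
    def test_two_dominants_rejected(self):
        with pytest.raises(ValidationError):
            _site("s", "f", [("m1", "dominant"), ("m2", "dominant")])

    def test_no_dominant_rejected(self):
        with pytest.raises(ValidationError):
            _site("s", "f", [("m1", "subordinate")])

    def test_seven_males_rejected(self):
        with pytest.raises(ValidationError):
            _site("s", "f", [("m1", "dominant")] + [
                (f"x{i}", "subordinate") for i in range(6)
            ])


class TestBuildDesign:
    @pytest.fixture
    def tables(self):
        ind = pd.DataFrame(
            {"SH": [1.0, 1.1, 0.9, 1.2]},
            index=pd.Index(["m1", "m2", "m3", "m4"], name="individual"),
        )
        pairs = pd.DataFrame(
            {
                "female": ["f1"] * 4 + ["f2"] * 4,
                "male": ["m1", "m2", "m3", "m4"] * 2,
                "comp": [0.5, 1.0, np.nan, 2.0, 0.1, 0.2, 0.3, 0.4],
            }
        )
        return ind, pairs

    def test_row_per_candidate_with_response(self, tables):
        ind, pairs = tables
        sites = [
            _site("s1", "f1", [("m1", "dominant"), ("m2", "subordinate"),
                               ("m3", "subordinate")]),
        ]
        df = build_design(sites, ind, pairs, variables=["SH"])
        assert len(df) == 3
        assert df["response"].tolist() == [1, 0, 0]

    def test_missing_variable_rows_dropped(self, tables):
        ind, pairs = tables
        sites = [
            _site("s1", "f1", [("m1", "dominant"), ("m3", "subordinate")]),
        ]
        df = build_design(sites, ind, pairs, variables=["SH", "comp"])
        assert len(df) == 1  # f1-m3 comp is missing
        assert df["male_id"].tolist() == ["m1"]

    def test_row_count_matches_enumeration(self, tables):
        ind, pairs = tables
        rng = np.random.default_rng(4)
        sites = []
        total = 0
        for i in range(13):
            m = int(rng.integers(2, 5))
            males = [(f"m{j + 1}", "subordinate") for j in range(min(m, 4))]
            males[0] = (males[0][0], "dominant")
            female = "f1" if i % 2 else "f2"
            sites.append(_site(f"s{i}", female, males, year=2010 + i % 3))
            total += len(males)
        df = build_design(sites, ind, pairs, variables=["SH"])
        assert len(df) == total
        # a male competing at several sites appears once per site
        assert (df["male_id"] == "m1").sum() == 13


class TestGoodGeneTest:
    def test_identical_distributions(self):
        counts = {"a": 10, "b": 10, "c": 10}
        res = good_gene_test(counts, dict(counts))
        assert res.chi2 == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)
        assert res.df == 2

    def test_disjoint_two_by_two(self):
        # rows (10,0) / (0,10): Pearson chi-square without correction = 20
        res = good_gene_test({"a": 10}, {"b": 10})
        assert res.chi2 == pytest.approx(20.0)
        assert res.df == 1

    def test_collapsing_reduces_classes(self):
        dom = {"a1": 5, "a2": 3, "b": 2}
        sub = {"a1": 4, "a2": 4, "b": 2}
        full = good_gene_test(dom, sub)
        collapsed = good_gene_test(dom, sub, collapse={"a1": "A", "a2": "A"})
        assert full.df == 2
        assert collapsed.df == 1
        assert set(collapsed.table.index) == {"A", "b"}

    def test_label_swap_invariance(self):
        dom = {"a": 7, "b": 1, "c": 4}
        sub = {"a": 2, "b": 6, "c": 3}
        assert good_gene_test(dom, sub).chi2 == pytest.approx(
            good_gene_test(sub, dom).chi2
        )

    def test_zero_count_class_dropped(self):
        res = good_gene_test({"a": 5, "ghost": 0}, {"a": 5})
        assert list(res.table.index) == ["a"]

    def test_empty_table(self):
        with pytest.raises(InsufficientDataError):
            good_gene_test({}, {})


class TestParentPairRandomization:
    FEMALES = [f"f{i}" for i in range(10)]
    MALES = [f"m{i}" for i in range(15)]

    def test_constant_metric_gives_p_one(self):
        res = parent_pair_randomization(
            [("f0", "m0"), ("f1", "m1")], self.FEMALES, self.MALES,
            lambda f, m: 3.0, n_shuffles=200, seed=0,
        )
        assert res.p_value == 1.0
        assert res.observed_mean == 3.0

    def test_counting_rule_when_observed_beyond_all_null(self):
        # observed pair value strictly below anything a shuffle can reach
        def metric(f, m):
            return -100.0 if (f, m) == ("f0", "m0") else float(hash((f, m)) % 7)

        res = parent_pair_randomization(
            [("f0", "m0")], self.FEMALES[1:], self.MALES[1:], metric,
            n_shuffles=999, seed=1, tail="lower",
        )
        assert res.p_value == pytest.approx(1 / 1000)

    def test_more_extreme_observed_never_increases_p(self):
        rng = np.random.default_rng(2)
        vals = {
            (f, m): float(rng.normal()) for f in self.FEMALES for m in self.MALES
        }

        def metric(f, m):
            return vals[(f, m)]

        res = parent_pair_randomization(
            [("f0", "m0"), ("f1", "m2")], self.FEMALES, self.MALES, metric,
            n_shuffles=500, seed=3, tail="lower",
        )
        null = res.null_means
        med = np.median(null)
        prev = None
        for obs in np.linspace(med, null.min() - 1, 8):
            k = int(np.sum(null <= obs + 1e-12))
            p = (k + 1) / (len(null) + 1)
            if prev is not None:
                assert p <= prev + 1e-12
            prev = p

    def test_reproducible_given_seed(self):
        def metric(f, m):
            return float(hash((f, m)) % 11)

        a = parent_pair_randomization(
            [("f0", "m0")], self.FEMALES, self.MALES, metric,
            n_shuffles=300, seed=9,
        )
        b = parent_pair_randomization(
            [("f0", "m0")], self.FEMALES, self.MALES, metric,
            n_shuffles=300, seed=9,
        )
        assert np.array_equal(a.null_means, b.null_means)
        assert a.p_value == b.p_value

    def test_individual_with_missing_metric_excluded(self):
        def metric(f, m):
            if f == "f9" or m == "m9":
                return None
            return 1.0

        res = parent_pair_randomization(
            [("f0", "m0"), ("f9", "m1")], self.FEMALES, self.MALES, metric,
            n_shuffles=100, seed=0,
        )
        assert res.n_real_pairs == 1  # (f9, m1) dropped
        assert res.n_candidates == len(self.FEMALES) + len(self.MALES) - 2


class TestFullAnalysis:
    def test_report_shape_and_roundtrip(self, study_scale_sim):
        cfg = AnalysisConfig(n_shuffles=500)
        report = run_full_analysis(study_scale_sim.dataset, cfg, seed=5)
        assert list(report.glmm.fixed_effects.columns) == [
            "term", "estimate", "std_error", "z_value", "p_value",
        ]
        assert set(report.good_gene) == set(study_scale_sim.dataset.dbs)
        assert {"all_sites", "abs"} <= set(report.permutation)
        d = report.to_dict()
        import json

        assert json.loads(json.dumps(d)) == json.loads(json.dumps(d))

    def test_deterministic_given_seed(self, study_scale_sim):
        cfg = AnalysisConfig(n_shuffles=300)
        r1 = run_full_analysis(study_scale_sim.dataset, cfg, seed=2)
        r2 = run_full_analysis(study_scale_sim.dataset, cfg, seed=2)
        import json

        assert json.dumps(r1.to_dict(), sort_keys=True) == json.dumps(
            r2.to_dict(), sort_keys=True
        )
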