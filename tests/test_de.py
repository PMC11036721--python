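"""Dispersion fitting, the NB exact test, DEG calling and aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from txdyn.containers import CountMatrix
from txdyn.de import (
    DispersionModel,
    _conditional_pvalue,
    bh_adjust,
    deg_table,
    fit_dispersion_blind,
)
from txdyn.de import test_adjacent as de_test_adjacent
from txdyn.de import test_all_adjacent as de_test_all_adjacent
from txdyn.simulate import SimConfig, simulate_counts


def _flat_model(genes, alpha=0.0):
    idx = pd.Index(genes)
    return DispersionModel(
        alpha_hat=pd.Series(alpha, index=idx),
        mean=pd.Series(100.0, index=idx),
        a0=0.0,
        a1=alpha,
    )


class TestDispersion:
    def test_constant_gene_has_zero_alpha(self):
        frame = pd.DataFrame({f"s{i}": [7, 30] for i in range(9)}, index=["a", "b"])
        model = fit_dispersion_blind(CountMatrix(frame))
        assert model.alpha_hat["a"] == 0.0

    def test_needs_three_samples(self):
        frame = pd.DataFrame({"s1": [5], "s2": [5]}, index=["g"])
        with pytest.raises(ValueError, match="3 samples"):
            fit_dispersion_blind(CountMatrix(frame))

    def test_poisson_truth_gives_small_trend_intercept(self):
        patterns = {f"g{i}": "M" * 8 for i in range(500)}
        rng = np.random.default_rng(1)
        means = {g: float(rng.uniform(200, 2000)) for g in patterns}
        cfg = SimConfig(
            pattern_assignments=patterns, baseline_means=means, dispersion=0.0, seed=2
        )
        counts, _ = simulate_counts(cfg)
        model = fit_dispersion_blind(counts)
        assert model.a1 == pytest.approx(0.0, abs=0.01)

    def test_dispersion_recovery_band(self):
        patterns = {f"g{i}": "M" * 8 for i in range(2000)}
        rng = np.random.default_rng(3)
        means = {g: float(rng.uniform(100, 5000)) for g in patterns}
        cfg = SimConfig(
            pattern_assignments=patterns, baseline_means=means, dispersion=0.1, seed=4
        )
        counts, _ = simulate_counts(cfg)
        model = fit_dispersion_blind(counts)
        assert 0.05 <= model.working.median() <= 0.2

    def test_maximum_sharing_is_at_least_fit_only(self):
        patterns = {f"g{i}": "M" * 8 for i in range(50)}
        cfg = SimConfig(pattern_assignments=patterns, dispersion=0.05, seed=5)
        counts, _ = simulate_counts(cfg)
        fit_only = fit_dispersion_blind(counts, sharing="fit-only")
        maximum = fit_dispersion_blind(counts, sharing="maximum")
        assert (maximum.working >= fit_only.working - 1e-12).all()


class TestExactTest:
    def test_identical_counts_are_maintained(self):
        frame = pd.DataFrame({"s1": [50, 200], "s2": [50, 200]}, index=["a", "b"])
        cm = CountMatrix(frame)
        sf = pd.Series(1.0, index=["s1", "s2"])
        rec = de_test_adjacent(cm, sf, _flat_model(["a", "b"]), 0)
        assert (rec["log2fc"] == 0).all()
        assert (rec["status"] == "M").all()

    def test_swap_antisymmetry(self):
        frame = pd.DataFrame({"s1": [50, 700], "s2": [160, 300]}, index=["a", "b"])
        swapped = frame[["s2", "s1"]].rename(columns={"s2": "s1", "s1": "s2"})
        sf = pd.Series(1.0, index=["s1", "s2"])
        model = _flat_model(["a", "b"], alpha=0.02)
        fwd = de_test_adjacent(CountMatrix(frame), sf, model, 0)
        rev = de_test_adjacent(CountMatrix(swapped), sf, model, 0)
        assert np.allclose(fwd["log2fc"], -rev["log2fc"])
        assert np.allclose(fwd["p_value"], rev["p_value"])

    def test_nonadjacent_interval_rejected(self):
        frame = pd.DataFrame({"s1": [5], "s2": [5], "s3": [5]}, index=["g"])
        cm = CountMatrix(frame)
        sf = pd.Series(1.0, index=frame.columns)
        with pytest.raises(ValueError, match="adjacent"):
            de_test_adjacent(cm, sf, _flat_model(["g"]), 5)

    def test_status_rule_requires_both_gates(self):
        # large fold change but tiny counts: p not significant => M
        frame = pd.DataFrame({"s1": [1], "s2": [4]}, index=["g"])
        sf = pd.Series(1.0, index=frame.columns)
        rec = de_test_adjacent(CountMatrix(frame), sf, _flat_model(["g"]), 0)
        assert rec.loc[0, "log2fc"] > 1
        assert rec.loc[0, "status"] == "M"

    def test_planted_eightfold_power(self):
        # 8-fold step at mu=500, alpha=0.01: called U in >= 95% of seeded runs
        calls = 0
        n_runs = 200
        for seed in range(n_runs):
            patterns = {"hit": "UMMMMMMM", **{f"bg{i}": "M" * 8 for i in range(10)}}
            cfg = SimConfig(
                pattern_assignments=patterns,
                baseline_means={g: 500.0 for g in patterns},
                dispersion=0.01,
                fold_step=8.0,
                seed=seed,
            )
            counts, _ = simulate_counts(cfg)
            records = de_test_all_adjacent(counts)
            first = records[(records["gene"] == "hit") & (records["interval"] == "3w-4w")]
            calls += (first["status"] == "U").all()
        assert calls / n_runs >= 0.95

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        ka=st.integers(0, 400),
        kb=st.integers(0, 400),
        alpha=st.sampled_from([0.0, 0.01, 0.1, 0.5]),
    )
    def test_conditional_pvalue_is_symmetric_probability(self, ka, kb, alpha):
        p = _conditional_pvalue(ka, kb, alpha)
        assert 0 < p <= 1
        assert p == pytest.approx(_conditional_pvalue(kb, ka, alpha), rel=1e-9)

    def test_poisson_reduction_matches_binomial_test(self):
        from scipy import stats

        ka, kb = 30, 60
        p_pkg = _conditional_pvalue(ka, kb, 0.0)
        p_binom = stats.binomtest(ka, ka + kb, 0.5).pvalue
        assert p_pkg == pytest.approx(p_binom, rel=1e-9)


class TestCallsAndAggregation:
    def test_type_one_error_controlled_under_null(self):
        # all-M truth: non-M calls at the |log2fc|>1 gate stay below 5%
        total = wrong = 0
        for seed in range(20):
            patterns = {f"g{i}": "M" * 8 for i in range(50)}
            cfg = SimConfig(
                pattern_assignments=patterns,
                baseline_means={g: 400.0 for g in patterns},
                dispersion=0.01,
                seed=seed,
            )
            counts, _ = simulate_counts(cfg)
            records = de_test_all_adjacent(counts)
            wrong += (records["status"] != "M").sum()
            total += len(records)
        assert wrong / total <= 0.05

    def test_direction_never_flipped(self, small_sim):
        counts, truth = small_sim
        records = de_test_all_adjacent(counts)
        by_gene = records.set_index(["gene", "interval"])["status"]
        for gene, pattern in truth.patterns.items():
            for t, expected in enumerate(pattern):
                got = by_gene[(gene, counts.interval_label(t))]
                if expected == "U":
                    assert got != "D"
                elif expected == "D":
                    assert got != "U"

    def test_deg_table_totals_are_additive(self):
        records = pd.DataFrame(
            {
                "gene": ["a", "b", "c", "d"],
                "interval": ["i1", "i1", "i2", "i2"],
                "log2fc": [2.0, -2.0, 1.5, 0.0],
                "p_value": [0.01, 0.01, 0.04, 0.9],
                "status": ["U", "D", "U", "M"],
            }
        )
        table = deg_table(records)
        assert table.loc["i1", "total"] == 2
        assert table.loc["all", "total"] == 3
        assert (table["up"] + table["down"] == table["total"]).all()

    def test_deg_table_empty_and_single(self):
        empty = deg_table(pd.DataFrame(columns=["gene", "interval", "status"]))
        assert empty.loc["all", "total"] == 0
        one = deg_table(
            pd.DataFrame({"gene": ["a"], "interval": ["i"], "status": ["U"]})
        )
        assert one.loc["all"].tolist() == [1, 0, 1]

    def test_deg_table_class_totals_sum_to_grand_total(self):
        rows = []
        for cls, n in [("mRNA", 5), ("lncRNA", 7), ("circRNA", 2), ("miRNA", 1)]:
            rows += [{"gene": f"{cls}{i}", "interval": "i1", "status": "U", "rna_class": cls} for i in range(n)]
        table = deg_table(pd.DataFrame(rows))
        assert table.loc["all", "total"] == 15
        class_totals = [table.loc[f"{c} / all", "total"] for c in ("mRNA", "lncRNA", "circRNA", "miRNA")]
        assert sum(class_totals) == 15

    def test_bh_adjust_monotone(self):
        p = np.array([0.001, 0.01, 0.02, 0.5, 0.9])
        adj = bh_adjust(p)
        assert (np.diff(adj[np.argsort(p)]) >= -1e-12).all()
        assert (adj >= p - 1e-12).all()
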