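"""Normalization definitions, abundance binning, library rates, PCA, correlation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from txdyn.containers import CountMatrix, LibrarySummary, NormalizedMatrix
from txdyn.quantify import (
    ABUNDANCE_LABELS,
    abundance_bins,
    correlation_matrix,
    cpm,
    fpkm,
    library_rates,
    pca_scores,
    size_factors,
    tpm,
)


def _cm(data, lengths=None, index=None):
    frame = pd.DataFrame(data, index=index or [f"g{i}" for i in range(len(next(iter(data.values()))))])
    return CountMatrix(frame, lengths=lengths)


class TestSizeFactors:
    def test_doubled_sample_gives_sqrt2_factors(self):
        cm = _cm({"s1": [1, 2, 3], "s2": [2, 4, 6]})
        sf = size_factors(cm)
        assert sf["s1"] == pytest.approx(1 / np.sqrt(2))
        assert sf["s2"] == pytest.approx(np.sqrt(2))

    def test_identical_samples_give_unit_factors(self):
        cm = _cm({"a": [5, 10, 1], "b": [5, 10, 1], "c": [5, 10, 1]})
        assert np.allclose(size_factors(cm), 1.0)

    def test_scaled_samples_recover_scaling(self):
        rng = np.random.default_rng(0)
        base = rng.integers(10, 500, size=50)
        data = {f"s{j}": base * j for j in (1, 2, 3, 4)}
        sf = size_factors(_cm(data))
        ratios = sf.to_numpy() / sf.to_numpy()[0]
        assert np.allclose(ratios, [1, 2, 3, 4])

    def test_no_common_gene_raises_with_fallback_hint(self):
        cm = _cm({"s1": [3, 0], "s2": [0, 3]})
        with pytest.raises(ValueError, match="pseudo_reference_all"):
            size_factors(cm)
        assert (size_factors(cm, pseudo_reference_all=True) > 0).all()


class TestUnitDefinitions:
    def test_cpm_definition_and_identity(self):
        counts = {"s1": [500, 10**6 - 500], "s2": [3, 1_500_000 - 3]}
        norm = cpm(_cm(counts))
        assert norm.values.loc["g0", "s1"] == pytest.approx(500.0)
        assert norm.values.loc["g0", "s2"] == pytest.approx(2.0)
        assert np.allclose(norm.values.sum(axis=0), 1e6, rtol=1e-9)

    def test_cpm_zero_total_names_sample(self):
        with pytest.raises(ValueError, match="s2"):
            cpm(_cm({"s1": [1, 2], "s2": [0, 0]}))

    def test_tpm_equal_rates_split_evenly(self):
        norm = tpm(_cm({"s1": [30, 10]}, lengths={"g0": 3000, "g1": 1000}))
        assert np.allclose(norm.values["s1"], [5e5, 5e5])

    def test_tpm_single_gene_is_million(self):
        norm = tpm(_cm({"s1": [7]}, lengths={"g0": 1234}))
        assert norm.values.loc["g0", "s1"] == pytest.approx(1e6)

    def test_tpm_missing_length_lists_gene(self):
        with pytest.raises(ValueError, match="g1"):
            tpm(_cm({"s1": [1, 1]}, lengths={"g0": 100}))

    def test_fpkm_definition(self):
        counts = {"s1": [100, 10**6 - 100]}
        norm = fpkm(_cm(counts, lengths={"g0": 2000, "g1": 1000}))
        assert norm.values.loc["g0", "s1"] == pytest.approx(50.0)

    def test_fpkm_ratio_invariance(self):
        lengths = {"g0": 500, "g1": 1500, "g2": 4000}
        a = fpkm(_cm({"s1": [10, 20, 30]}, lengths=lengths))
        b = fpkm(_cm({"s1": [20, 40, 60]}, lengths=lengths))
        pd.testing.assert_frame_equal(a.values, b.values)

    def test_fpkm_rescaled_is_tpm(self):
        lengths = {"g0": 500, "g1": 1500, "g2": 4000}
        cm = _cm({"s1": [11, 20, 35], "s2": [4, 90, 3]}, lengths=lengths)
        f = fpkm(cm).values
        t = tpm(cm).values
        rescaled = f * 1e6 / f.sum(axis=0)
        assert np.allclose(rescaled, t, rtol=1e-9)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(
        st.lists(
            st.lists(st.integers(0, 10_000), min_size=3, max_size=3),
            min_size=2,
            max_size=8,
        )
    )
    def test_cpm_column_sum_identity_property(self, rows):
        frame = pd.DataFrame(rows, columns=["s1", "s2", "s3"], index=[f"g{i}" for i in range(len(rows))])
        if (frame.sum(axis=0) == 0).any():
            return
        norm = cpm(CountMatrix(frame))
        assert np.allclose(norm.values.sum(axis=0), 1e6, rtol=1e-6)


class TestAbundanceBins:
    def test_direct_placement(self):
        norm = NormalizedMatrix(
            pd.DataFrame({"s1": [0.005, 5, 5000]}, index=["a", "b", "c"]), unit="FPKM"
        )
        bins = abundance_bins(norm)
        assert bins.loc["s1", "0-0.01"] == 1
        assert bins.loc["s1", "1-10"] == 1
        assert bins.loc["s1", ">1000"] == 1

    def test_left_closed_boundaries(self):
        norm = NormalizedMatrix(pd.DataFrame({"s1": [1.0, 1.0]}, index=["a", "b"]), unit="TPM")
        bins = abundance_bins(norm)
        assert bins.loc["s1", "1-10"] == 2

    def test_bins_partition_the_genes(self):
        rng = np.random.default_rng(1)
        values = pd.DataFrame(
            rng.lognormal(0, 4, size=(200, 3)), columns=list("abc"),
            index=[f"g{i}" for i in range(200)],
        )
        bins = abundance_bins(NormalizedMatrix(values, unit="CPM"))
        assert (bins.sum(axis=1) == 200).all()
        assert list(bins.columns) == list(ABUNDANCE_LABELS)


class TestLibraryRates:
    def test_reported_clean_rate(self):
        rates = library_rates(LibrarySummary(996_302_214, 899_835_270))
        assert rates["clean_rate"] == 90.32

    def test_perfect_and_half(self):
        assert library_rates(LibrarySummary(200, 200))["clean_rate"] == 100.00
        assert library_rates(LibrarySummary(200, 100))["clean_rate"] == 50.00

    def test_mapping_rate_and_zero_raw(self):
        rates = library_rates(LibrarySummary(1000, 800, 600))
        assert rates["mapping_rate"] == 75.00
        with pytest.raises(ValueError):
            library_rates(LibrarySummary(0, 0))


class TestPCAAndCorrelation:
    def test_duplicated_samples_coincide(self):
        rng = np.random.default_rng(2)
        x = rng.integers(0, 100, size=30)
        frame = pd.DataFrame({"s1": x, "s2": x, "s3": rng.integers(0, 100, 30)})
        norm = NormalizedMatrix(frame.astype(float), unit="CPM")
        scores, var = pca_scores(norm, 2)
        assert np.allclose(scores.loc["s1"], scores.loc["s2"])
        assert var.is_monotonic_decreasing

    def test_collinear_samples_have_one_component(self):
        rng = np.random.default_rng(3)
        base = rng.uniform(0, 8, size=40)
        # log2(x+1) rows lie on a line across samples
        frame = pd.DataFrame(
            {
                "s1": 2**base - 1,
                "s2": 2 ** (base + 1) - 1,
                "s3": 2 ** (base + 2) - 1,
            }
        )
        norm = NormalizedMatrix(frame, unit="CPM")
        _, var = pca_scores(norm, 3)
        assert var.iloc[1] == pytest.approx(0.0, abs=1e-18)

    def test_truncation_warns(self):
        norm = NormalizedMatrix(
            pd.DataFrame({"s1": [1.0, 2.0], "s2": [2.0, 1.0]}), unit="CPM"
        )
        with pytest.warns(UserWarning, match="truncating"):
            scores, _ = pca_scores(norm, 5)
        assert scores.shape[1] == 2

    def test_correlation_matrix_properties(self):
        rng = np.random.default_rng(4)
        frame = pd.DataFrame(rng.integers(0, 1000, size=(50, 4)).astype(float), columns=list("abcd"))
        r = correlation_matrix(NormalizedMatrix(frame, unit="CPM"))
        assert np.allclose(r, r.T)
        assert np.allclose(np.diag(r), 1.0)
        assert (r.to_numpy() <= 1 + 1e-12).all() and (r.to_numpy() >= -1 - 1e-12).all()
        dup = correlation_matrix(
            NormalizedMatrix(pd.DataFrame({"a": frame["a"], "b": frame["a"]}), unit="CPM")
        )
        assert dup.loc["a", "b"] == pytest.approx(1.0)

    def test_zero_variance_sample_named(self):
        frame = pd.DataFrame({"a": [1.0, 2.0], "flat": [3.0, 3.0]})
        with pytest.raises(ValueError, match="flat"):
            correlation_matrix(NormalizedMatrix(frame, unit="CPM"))
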