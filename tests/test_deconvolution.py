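"""Reference building, NNLS recovery, benchmarking, TMC and clustering."""

import numpy as np
import pandas as pd
import pytest

import anndata as ad

from icibiomarkers import (
    NNLSDeconvolution,
    benchmark_deconvolution,
    build_reference,
    cluster_compartment,
    deconvolve_nnls,
    extract_tmc,
    normalize_linear,
    rna_to_cell_fraction,
    simulate_pseudobulk_panel,
    simulate_spike_in,
    spike_in_validation,
)
from icibiomarkers.datatypes import CompositionEstimate, ExpressionMatrix
from icibiomarkers.deconvolution import cell_to_rna_fraction


@pytest.fixture(scope="module")
def reference(small_reference):
    return build_reference(small_reference, top_n=400)


def _em(profile_dict, genes, scale="linear"):
    return ExpressionMatrix(pd.DataFrame(profile_dict, index=genes), scale=scale)


class TestBuildReference:
    def test_top_n_exceeding_genes_keeps_all_nonconfounders(self, small_reference):
        ref = build_reference(small_reference, top_n=10_000)
        assert len(ref.genes) == small_reference.n_vars  # synthetic IDs match no pattern

    def test_identical_cells_give_member_profile(self):
        genes = [f"g{i}" for i in range(20)]
        X = np.tile(np.arange(1.0, 21.0), (12, 1))
        obs = pd.DataFrame({"cell_type": ["A"] * 12}, index=[f"c{i}" for i in range(12)])
        adata = ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=genes))
        ref = build_reference(adata, top_n=20)
        assert np.allclose(ref.profiles.loc["A"], X[0])

    def test_type_markers_are_among_top_variable_genes(self, small_reference, reference):
        markers = small_reference.var_names[(small_reference.var["marker_of"] != "").to_numpy()]
        top = build_reference(small_reference, top_n=100).genes
        overlap = len(set(markers) & set(top)) / len(markers)
        assert overlap > 0.8

    def test_confounder_patterns_are_excluded(self):
        genes = ["MT-CO1", "RPL13", "RPS4Y1", "TRBV2", "IGHV1", "XIST", "CD8A", "GZMK"]
        rng = np.random.default_rng(0)
        X = rng.uniform(1, 100, size=(20, len(genes)))
        obs = pd.DataFrame({"cell_type": ["A"] * 10 + ["B"] * 10}, index=[f"c{i}" for i in range(20)])
        adata = ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=genes))
        ref = build_reference(adata, top_n=10)
        assert set(ref.genes) == {"CD8A", "GZMK"}

    def test_small_types_are_excluded_with_warning(self, small_reference):
        sub = small_reference[: 80 + 5].copy()  # 80 of the first type, 5 of the next
        with pytest.warns(UserWarning, match="excluded"):
            ref = build_reference(sub, top_n=100, min_cells=10)
        assert len(ref.cell_types) == 1


class TestNNLS:
    def test_single_type_bulk_recovers_unit_vector(self, reference):
        t = reference.cell_types[1]
        em = _em({"s": reference.profiles.loc[t]}, reference.profiles.columns)
        comp = deconvolve_nnls(em, reference)
        assert comp.rna_fraction.loc["s", t] == pytest.approx(1.0, abs=1e-8)
        assert comp.residual["s"] == pytest.approx(0.0, abs=1e-6)

    def test_even_mixture_recovers_exact_fractions(self, reference):
        a, b = reference.cell_types[0], reference.cell_types[2]
        mix = 0.5 * reference.profiles.loc[a] + 0.5 * reference.profiles.loc[b]
        comp = deconvolve_nnls(_em({"s": mix}, reference.profiles.columns), reference)
        assert comp.rna_fraction.loc["s", a] == pytest.approx(0.5, abs=1e-8)
        assert comp.rna_fraction.loc["s", b] == pytest.approx(0.5, abs=1e-8)

    def test_scale_invariance(self, reference):
        a, b = reference.cell_types[0], reference.cell_types[1]
        mix = 0.3 * reference.profiles.loc[a] + 0.7 * reference.profiles.loc[b]
        c1 = deconvolve_nnls(_em({"s": mix}, reference.profiles.columns), reference)
        c2 = deconvolve_nnls(_em({"s": mix * 37.0}, reference.profiles.columns), reference)
        assert np.allclose(c1.rna_fraction, c2.rna_fraction, atol=1e-10)

    def test_insufficient_overlap_is_an_error(self, reference):
        em = _em({"s": [1.0, 2.0]}, ["x1", "x2"])
        with pytest.raises(ValueError, match="overlap"):
            deconvolve_nnls(em, reference)

    def test_estimator_api_roundtrip(self, small_reference):
        est = NNLSDeconvolution(top_n=200)
        assert est.get_params()["top_n"] == 200
        est.fit(small_reference)
        assert hasattr(est, "reference_")


class TestFractionConversion:
    def test_equal_rna_content_is_identity(self):
        f = pd.Series([0.2, 0.3, 0.5], index=list("abc"))
        s = pd.Series([2.0, 2.0, 2.0], index=list("abc"))
        assert np.allclose(rna_to_cell_fraction(f, s), f)

    def test_two_type_closed_form(self):
        f = pd.Series([0.5, 0.5], index=list("ab"))
        s = pd.Series([2.0, 1.0], index=list("ab"))
        assert np.allclose(rna_to_cell_fraction(f, s), [1 / 3, 2 / 3])

    def test_round_trip_recovers_rna_fractions(self, rng):
        f = pd.DataFrame(rng.dirichlet(np.ones(5), size=8), columns=list("abcde"))
        s = pd.Series(rng.uniform(0.5, 3.0, 5), index=list("abcde"))
        back = cell_to_rna_fraction(rna_to_cell_fraction(f, s), s)
        assert np.allclose(back, f, atol=1e-12)

    def test_cell_scale_beats_rna_scale_on_heterogeneous_library_sizes(
        self, small_config, small_reference, reference
    ):
        panel, truth = simulate_pseudobulk_panel(small_reference, 15, small_config)
        comp = deconvolve_nnls(normalize_linear(panel), reference)
        cols = truth.cell_fractions.columns
        rna_err = np.sqrt(((comp.rna_fraction[cols] - truth.cell_fractions) ** 2).to_numpy().mean())
        cell_err = np.sqrt(((comp.cell_fraction[cols] - truth.cell_fractions) ** 2).to_numpy().mean())
        assert cell_err < rna_err


class TestBenchmark:
    def test_perfect_prediction_scores_rho_one_nrmse_zero(self, small_panel):
        panel, truth = small_panel

        def perfect(bulk):
            return CompositionEstimate(
                truth.rna_fractions.copy(), truth.cell_fractions.copy()
            )

        res = benchmark_deconvolution({"perfect": perfect}, panel, truth)
        assert np.allclose(res["per_sample"]["spearman"], 1.0)
        assert np.allclose(res["per_sample"]["nrmse"], 0.0)

    def test_reversed_prediction_scores_rho_minus_one(self, small_panel):
        panel, truth = small_panel

        def reverse(bulk):
            rev = truth.rna_fractions.copy()
            arr = rev.to_numpy()
            for i in range(arr.shape[0]):  # assign truth values in opposite rank order
                order = np.argsort(arr[i])
                arr[i, order] = arr[i, order[::-1]]
            rev.iloc[:, :] = arr
            return CompositionEstimate(rev, None)

        res = benchmark_deconvolution({"rev": reverse}, panel, truth)
        assert np.allclose(res["per_sample"]["spearman"], -1.0)

    def test_nnls_beats_degenerate_uniform_dummy(self, small_config, small_reference, reference):
        panel, truth = simulate_pseudobulk_panel(small_reference, 10, small_config)
        lin = normalize_linear(panel)
        est = NNLSDeconvolution().fit(reference)

        def uniform(bulk):
            n = len(reference.cell_types)
            df = pd.DataFrame(1.0 / n, index=bulk.sample_ids, columns=reference.cell_types)
            return CompositionEstimate(df, df.copy())

        res = benchmark_deconvolution({"nnls": est.predict, "uniform": uniform}, lin, truth)
        assert res["summary"].attrs["ranking"][0] == "nnls"
        summ = res["summary"]
        nnls_rho = summ.loc[(summ["method"] == "nnls") & (summ["scale"] == "rna"), "median_spearman"]
        assert float(nnls_rho.iloc[0]) > 0.9
        # constant predictions are recorded as missing, not crashes
        uni = res["per_sample"][res["per_sample"]["method"] == "uniform"]
        assert uni["spearman"].isna().all() and uni["degenerate"].all()

    def test_medians_invariant_to_sample_order(self, small_panel):
        panel, truth = small_panel

        def perfect(bulk):
            return CompositionEstimate(truth.rna_fractions.loc[bulk.sample_ids], None)

        r1 = benchmark_deconvolution({"m": perfect}, panel, truth)
        perm = panel.subset_samples(panel.sample_ids[::-1])
        r2 = benchmark_deconvolution({"m": perfect}, perm, truth)
        assert r1["summary"]["median_nrmse"].equals(r2["summary"]["median_nrmse"])


class TestTmc:
    def test_pure_monocyte_sample(self):
        comp = CompositionEstimate(
            pd.DataFrame({"Monocyte": [1.0], "EAC": [0.0]}, index=["s"]), None
        )
        out = extract_tmc(comp)
        assert out.loc["s", "tmc"] == 1.0
        assert out.loc["s", "log10_tmc"] == 0.0

    def test_zero_monocyte_is_floored_and_flagged(self):
        comp = CompositionEstimate(
            pd.DataFrame({"Monocyte": [0.0, 0.2], "EAC": [1.0, 0.8]}, index=["a", "b"]), None
        )
        out = extract_tmc(comp)
        assert out.loc["a", "floored"]
        assert out.loc["a", "log10_tmc"] == pytest.approx(np.log10(0.1))

    def test_missing_label_is_an_error(self):
        comp = CompositionEstimate(pd.DataFrame({"EAC": [1.0]}, index=["s"]), None)
        with pytest.raises(ValueError, match="Monocyte"):
            extract_tmc(comp)

    def test_spiked_series_yields_increasing_tmc(self, small_reference, reference):
        prof = reference.profiles
        bulk = 0.7 * prof.loc["EAC"] + 0.3 * prof.loc["Fibroblast"]
        spiked = simulate_spike_in(bulk, prof.loc["Monocyte"], [0, 0.005, 0.01, 0.02, 0.04, 0.08])
        comp = deconvolve_nnls(spiked, reference)
        tmc = extract_tmc(comp)["tmc"].to_numpy()
        assert np.all(np.diff(tmc) > 0)


class TestSpikeInValidation:
    def test_monocyte_free_baseline_recovers_unit_slope(self, reference):
        prof = reference.profiles
        bulk = 0.6 * prof.loc["EAC"] + 0.4 * prof.loc["Fibroblast"]
        spiked = simulate_spike_in(bulk, prof.loc["Monocyte"], [0, 0.02, 0.04, 0.08])
        slope, p, table = spike_in_validation(spiked, reference)
        assert slope == pytest.approx(1.0, abs=0.02)
        assert p < 0.01

    def test_baseline_monocyte_content_sets_intercept(self, reference):
        # TMC(f) = b + f*(1-b) for baseline monocyte mass fraction b
        prof = reference.profiles
        b = 0.1
        bulk = 0.6 * prof.loc["EAC"] + 0.3 * prof.loc["Fibroblast"] + b * prof.loc["Monocyte"]
        spiked = simulate_spike_in(bulk, prof.loc["Monocyte"], [0, 0.02, 0.04, 0.08])
        slope, p, table = spike_in_validation(spiked, reference)
        assert table.loc["spike_0", "tmc"] == pytest.approx(b, abs=0.02)
        assert slope == pytest.approx(1.0 - b, abs=0.03)

    def test_single_spike_level_is_an_error(self, reference):
        prof = reference.profiles
        spiked = simulate_spike_in(prof.loc["EAC"], prof.loc["Monocyte"], [0.02])
        with pytest.raises(ValueError, match="spike levels"):
            spike_in_validation(spiked, reference)


def _ward_oracle(X):
    """Naive O(n^3) Ward agglomeration; returns sorted merge heights."""
    clusters = [[i] for i in range(len(X))]
    heights = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                a, b = X[clusters[i]].mean(axis=0), X[clusters[j]].mean(axis=0)
                na, nb = len(clusters[i]), len(clusters[j])
                d_ess = na * nb / (na + nb) * ((a - b) ** 2).sum()
                if best is None or d_ess < best[0]:
                    best = (d_ess, i, j)
        d_ess, i, j = best
        heights.append(np.sqrt(2 * d_ess))
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return np.sort(heights)


class TestClusterCompartment:
    def _blobs(self, seed=0):
        rng = np.random.default_rng(seed)
        X = np.vstack([rng.uniform(0.3, 0.5, (5, 3)), rng.uniform(0.005, 0.02, (5, 3))])
        return pd.DataFrame(X, index=[f"s{i}" for i in range(10)], columns=list("abc"))

    def test_separated_blobs_are_recovered_exactly(self):
        labels, _ = cluster_compartment(self._blobs(), k=2)
        assert labels.iloc[:5].nunique() == 1 and labels.iloc[5:].nunique() == 1
        assert labels.iloc[0] != labels.iloc[5]

    def test_partition_invariant_to_sample_order(self):
        df = self._blobs(1)
        perm = np.random.default_rng(2).permutation(len(df))
        l1, _ = cluster_compartment(df, k=2)
        l2, _ = cluster_compartment(df.iloc[perm], k=2)
        assert (l2.reindex(l1.index) == l1).all()

    def test_merge_heights_match_brute_force_ward(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(
            rng.uniform(0.05, 0.6, (6, 3)), index=[f"s{i}" for i in range(6)], columns=list("abc")
        )
        _, linkage = cluster_compartment(df, k=2)
        # reproduce the internal preprocessing for the oracle
        L = np.log10(df.to_numpy())
        Z = (L - L.mean(axis=0)) / L.std(axis=0, ddof=1)
        assert np.allclose(np.sort(linkage[:, 2]), _ward_oracle(Z), atol=1e-8)

    def test_constant_column_is_dropped_with_warning(self):
        df = self._blobs()
        df["const"] = 0.25
        with pytest.warns(UserWarning, match="constant"):
            labels, _ = cluster_compartment(df, k=2)
        assert labels.iloc[0] != labels.iloc[5]
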