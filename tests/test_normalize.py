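"""Normalization: geNorm stability, housekeeping scaling, panel merge,
log2 transform and limit-of-detection rules."""

import numpy as np
import pandas as pd
import pytest

import immunopair as ip
from immunopair.containers import ExpressionMatrix
from tests.conftest import make_panel


def brute_force_m(counts: pd.DataFrame) -> pd.Series:
    """Independent geNorm oracle: M_j = mean over k != j of the sample SD
    of log2(a_j / a_k), written as explicit loops."""
    log2a = {g: np.log2(np.maximum(counts.loc[g].to_numpy(float), 0.5))
             for g in counts.index}
    m = {}
    for j in counts.index:
        vs = []
        for k in counts.index:
            if k == j:
                continue
            ratios = log2a[j] - log2a[k]
            mean = sum(ratios) / len(ratios)
            var = sum((r - mean) ** 2 for r in ratios) / (len(ratios) - 1)
            vs.append(var ** 0.5)
        m[j] = sum(vs) / len(vs)
    return pd.Series(m)


def brute_force_elimination(counts: pd.DataFrame) -> list:
    """Oracle elimination order: repeatedly drop the highest-M gene (first
    in index order on ties), then append the final two in index order."""
    remaining = list(counts.index)
    order = []
    while len(remaining) > 2:
        m = brute_force_m(counts.loc[remaining])
        worst = max(remaining, key=lambda g: (m[g],))
        # ties: first occurrence in remaining order, as idxmax does
        best_val = max(m[g] for g in remaining)
        worst = next(g for g in remaining if m[g] == best_val)
        order.append(worst)
        remaining.remove(worst)
    return order + remaining


class TestGeNorm:
    @pytest.mark.parametrize("trial", range(12))
    def test_matches_brute_force_oracle_on_random_matrices(self, trial):
        rng = np.random.default_rng(100 + trial)
        n_genes = int(rng.integers(3, 9))
        n_samples = int(rng.integers(4, 11))
        counts = pd.DataFrame(
            rng.integers(5, 2000, size=(n_genes, n_samples)),
            index=[f"HK{i}" for i in range(n_genes)])
        res = ip.genorm(counts)
        oracle_m = brute_force_m(counts)
        assert np.allclose(res.stability.sort_index(), oracle_m.sort_index(),
                           atol=1e-10)
        assert res.elimination_order == brute_force_elimination(counts)

    def test_noisy_gene_eliminated_before_proportional_pair(self):
        rng = np.random.default_rng(0)
        base = rng.integers(100, 1000, 8)
        counts = pd.DataFrame({
            "stableA": base, "stableB": base * 3,
            "noisy": rng.integers(10, 5000, 8)}).T
        res = ip.genorm(counts)
        assert res.elimination_order[0] == "noisy"
        # the exactly proportional pair has V = 0 between them
        assert set(res.elimination_order[1:]) == {"stableA", "stableB"}

    def test_stability_invariant_to_constant_scaling(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(rng.integers(50, 500, (5, 6)),
                              index=list("abcde"))
        m1 = ip.genorm(counts).stability
        scaled = counts.copy()
        scaled.loc["c"] = counts.loc["c"] * 7
        m2 = ip.genorm(scaled).stability
        assert np.isclose(m1["c"], m2["c"], atol=1e-12)

    def test_rejects_fewer_than_three_candidates(self):
        counts = pd.DataFrame([[1, 2], [3, 4]], index=["a", "b"])
        with pytest.raises(ValueError, match="at least 3"):
            ip.genorm(counts)

    def test_all_zero_candidate_excluded_with_warning(self):
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(rng.integers(10, 100, (4, 5)),
                              index=list("abcd"))
        counts.loc["z"] = 0
        with pytest.warns(UserWarning, match="all-zero"):
            res = ip.genorm(counts)
        assert res.excluded == ["z"]
        assert "z" not in res.stability.index

    def test_v_cutoff_selection_reported(self):
        rng = np.random.default_rng(3)
        base = rng.integers(200, 400, 10).astype(float)
        counts = pd.DataFrame(
            {f"g{i}": base * rng.lognormal(0, 0.01, 10) for i in range(6)}).T
        res = ip.genorm(counts.astype(int))
        assert set(res.pairwise_variation) == {2, 3, 4, 5}
        assert all(v >= 0 for v in res.pairwise_variation.values())


class TestHKNormalize:
    def test_identical_samples_factor_one(self):
        pcm = make_panel(np.array([[10, 10], [40, 40], [90, 90]]), ["s1", "s2"],
                         classes=None)
        _, factors = ip.hk_normalize(pcm, ["G0", "G1", "G2"])
        assert np.allclose(factors, 1.0)

    def test_pure_scale_removed(self):
        a = np.array([10, 40, 90, 7])
        pcm = make_panel(np.column_stack([a, 2 * a]), ["A", "B"])
        scaled, factors = ip.hk_normalize(pcm, ["G0", "G1", "G2", "G3"])
        assert np.isclose(factors["B"] / factors["A"], 0.5)
        genes = [f"G{i}" for i in range(4)]
        assert np.allclose(scaled.loc[genes, "A"], scaled.loc[genes, "B"])

    def test_factors_match_hand_computed_geometric_means(self):
        counts = np.array([[8, 1, 27], [2, 4, 1], [4, 16, 9], [16, 1, 3]])
        pcm = make_panel(counts, ["s1", "s2", "s3"])
        _, factors = ip.hk_normalize(pcm, ["G0", "G1", "G2", "G3"])
        geo = np.array([
            (8 * 2 * 4 * 16) ** 0.25,
            (1 * 4 * 16 * 1) ** 0.25,
            (27 * 1 * 9 * 3) ** 0.25,
        ])
        assert np.allclose(factors.to_numpy(), geo.mean() / geo, atol=1e-12)

    def test_idempotent_on_normalized_matrix(self, desk_cohort):
        panels, _, _ = desk_cohort
        pcm = panels["IP"]
        hks = list(pcm.probe_info.loc[pcm.probes_of_class("housekeeping"), "gene"])[:6]
        scaled, _ = ip.hk_normalize(pcm, hks)
        rescaled = ip.ProbeCountMatrix(
            counts=scaled.round().astype(np.int64), probe_info=pcm.probe_info)
        _, factors2 = ip.hk_normalize(rescaled, hks)
        assert np.allclose(factors2, 1.0, atol=0.01)

    def test_preserves_within_sample_ranking(self, desk_cohort):
        panels, _, _ = desk_cohort
        pcm = panels["MII"]
        hks = list(pcm.probe_info.loc[pcm.probes_of_class("housekeeping"), "gene"])[:6]
        scaled, _ = ip.hk_normalize(pcm, hks)
        for col in pcm.counts.columns[:4]:
            before = pcm.counts[col].rank()
            after = scaled[col].rank()
            assert (before == after).all()


class TestMergePanels:
    def test_identical_overlap_scale_one(self):
        a = pd.DataFrame({"s1": [10.0, 20, 5], "s2": [8.0, 16, 4]},
                         index=["X", "Y", "A1"])
        b = pd.DataFrame({"s1": [10.0, 20, 7], "s2": [8.0, 16, 6]},
                         index=["X", "Y", "B1"])
        merged, panels, scale = ip.merge_panels(a, b)
        assert np.allclose(scale, 1.0)
        assert np.allclose(merged.loc["X"], a.loc["X"])
        assert set(merged.index) == {"X", "Y", "A1", "B1"}
        assert panels["A1"] == "A" and panels["B1"] == "B" and panels["X"] == "both"

    def test_threefold_panel_rescaled_before_averaging(self):
        a = pd.DataFrame({"s1": [10.0, 20]}, index=["X", "Y"])
        b = pd.DataFrame({"s1": [30.0, 60]}, index=["X", "Y"])
        merged, _, scale = ip.merge_panels(a, b)
        assert np.isclose(scale["s1"], 1 / 3)
        assert np.allclose(merged.loc["X"], 10.0)

    def test_merged_gene_count_is_union(self, desk_cfg, desk_cohort):
        panels, _, _ = desk_cohort
        a = panels["IP"].gene_counts("endogenous").astype(float)
        b = panels["MII"].gene_counts("endogenous").astype(float)
        merged, _, _ = ip.merge_panels(a, b)
        expected = 2 * desk_cfg.n_endogenous_per_panel - desk_cfg.n_overlap
        assert len(merged) == expected

    def test_panel_a_only_genes_unchanged(self):
        rng = np.random.default_rng(5)
        a = pd.DataFrame(rng.uniform(1, 100, (4, 3)),
                         index=["o1", "o2", "a1", "a2"], columns=list("xyz"))
        b = pd.DataFrame(rng.uniform(1, 100, (3, 3)),
                         index=["o1", "o2", "b1"], columns=list("xyz"))
        merged, _, _ = ip.merge_panels(a, b)
        assert np.allclose(merged.loc[["a1", "a2"]], a.loc[["a1", "a2"]])

    def test_sample_in_one_panel_rejected(self):
        a = pd.DataFrame({"s1": [1.0], "s2": [2.0]}, index=["X"])
        b = pd.DataFrame({"s1": [1.0]}, index=["X"])
        with pytest.raises(ValueError, match="only one panel"):
            ip.merge_panels(a, b)

    def test_zero_overlap_rejected(self):
        a = pd.DataFrame({"s1": [1.0]}, index=["X"])
        b = pd.DataFrame({"s1": [1.0]}, index=["Y"])
        with pytest.raises(ValueError, match="no genes"):
            ip.merge_panels(a, b)


class TestLog2AndLOD:
    def test_log2_examples_and_inverse(self):
        m = pd.DataFrame({"s": [0.0, 7.0, 100.0]})
        out = ip.log2_transform(m)
        assert out["s"].tolist()[:2] == [0.0, 3.0]
        back = 2 ** out - 1
        assert np.allclose(back, m, atol=1e-12)

    def test_log2_rejects_negative(self):
        with pytest.raises(ValueError, match="non-negative"):
            ip.log2_transform(pd.DataFrame({"s": [-1.0]}))

    def test_lod_constant_negatives(self):
        assert ip.compute_lod(np.array([3.0, 3.0, 3.0])) == 3.0

    def test_lod_hand_arithmetic(self):
        # mean 3, sample SD sqrt(2) -> 3 + 2*sqrt(2)
        assert np.isclose(ip.compute_lod(np.array([2.0, 4.0])),
                          3 + 2 * np.sqrt(2), atol=1e-12)

    def test_lod_requires_two_values(self):
        with pytest.raises(ValueError):
            ip.compute_lod(np.array([1.0]))

    def test_filter_strictly_more_than_half(self):
        n = 100
        fracs = {"g_all": 1.0, "g_60": 0.6, "g_half": 0.5, "g_40": 0.4,
                 "g_none": 0.0, "g_51": 0.51}
        rows = {g: [1.0 if i < f * n else -1.0 for i in range(n)]
                for g, f in fracs.items()}
        expr = ExpressionMatrix(values=pd.DataFrame(rows).T)
        out = ip.filter_by_lod(expr, threshold=0.0)
        kept = set(out.lod_pass.index[out.lod_pass])
        assert kept == {"g_all", "g_60", "g_51"}

    def test_filter_empty_matrix_rejected(self):
        expr = ExpressionMatrix(values=pd.DataFrame())
        with pytest.raises(ValueError, match="empty"):
            ip.filter_by_lod(expr, threshold=0.0)


def test_normalize_cohort_report(desk_expr, desk_cfg):
    expr, report = desk_expr
    assert report["n_genes"] == 2 * desk_cfg.n_endogenous_per_panel - desk_cfg.n_overlap
    assert 0 < report["n_genes_detected"] <= report["n_genes"]
    assert np.isfinite(report["lod_threshold"])
    # every retained gene is flagged, every flag refers to a gene in the matrix
    assert expr.lod_pass.index.equals(expr.values.index)
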