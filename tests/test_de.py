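"""Paired differential expression: model chain, BH step-up, DEG calling,
Tukey filtering and volcano export."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import immunopair as ip
from immunopair.de import DEGCriteria, fit_gene


def bh_oracle(p):
    """Independent step-up oracle: sort ascending, adj_(i) = min_{j>=i}
    p_(j) * n / (j+1), capped at 1, mapped back to input order."""
    p = list(p)
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    adj_sorted = [min(1.0, p[order[j]] * n / (j + 1)) for j in range(n)]
    for j in range(n - 2, -1, -1):
        adj_sorted[j] = min(adj_sorted[j], adj_sorted[j + 1])
    out = [0.0] * n
    for j, i in enumerate(order):
        out[i] = adj_sorted[j]
    return out


class TestBH:
    def test_single_p_unchanged(self):
        assert ip.bh_adjust([0.03]) == [0.03]

    def test_hand_computed_example(self):
        assert np.allclose(ip.bh_adjust([0.01, 0.02, 0.03]),
                           [0.03, 0.03, 0.03])

    @pytest.mark.parametrize("trial", range(40))
    def test_matches_step_up_oracle_random(self, trial):
        rng = np.random.default_rng(trial)
        n = int(rng.integers(1, 9))
        p = rng.uniform(0, 1, n)
        assert np.allclose(ip.bh_adjust(p), bh_oracle(p), atol=1e-12)

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=8))
    def test_oracle_property(self, p):
        adj = ip.bh_adjust(p)
        assert np.allclose(adj, bh_oracle(p), atol=1e-12)
        # adjusted values are monotone in the raw-p ordering and >= raw p
        order = np.argsort(p)
        assert (np.diff(np.asarray(adj)[order]) >= -1e-12).all()
        assert (np.asarray(adj) >= np.asarray(p) - 1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ip.bh_adjust([0.5, 1.5])


def paired_design(n):
    post = np.array([0.0] * n + [1.0] * n)
    patient = np.array([f"P{i}" for i in range(n)] * 2)
    return post, patient


class TestFitGene:
    def test_identical_pre_post_foc_zero(self):
        rng = np.random.default_rng(0)
        y = np.tile(rng.poisson(300, 10), 2)
        post, patient = paired_design(10)
        res = fit_gene(y, post, patient)
        assert res["foc"] == pytest.approx(0.0, abs=1e-8)
        assert res["p"] == pytest.approx(1.0, abs=1e-6)
        assert res["model"] == "neg-binomial"

    def test_all_zero_gene_skipped(self):
        post, patient = paired_design(5)
        res = fit_gene(np.zeros(10), post, patient)
        assert res["skipped"] and res["model"] == "none"

    def test_fallback_fires_on_degenerate_counts(self):
        # a gene that is zero in every pre sample: the NB treatment
        # coefficient diverges (perfect separation), so the log-linear
        # fallback must label the gene and still give a finite p
        post, patient = paired_design(8)
        y = np.concatenate([np.zeros(8), np.full(8, 50.0)])
        res = fit_gene(y, post, patient)
        assert res["model"] == "log-linear"
        assert np.isfinite(res["p"]) and np.isfinite(res["foc"])

    def test_offsets_absorb_library_scale(self):
        rng = np.random.default_rng(3)
        n = 20
        post, patient = paired_design(n)
        scale = np.exp(rng.normal(0, 0.5, 2 * n))
        mu = 500 * scale * 2.0 ** post
        y = rng.poisson(mu)
        res = fit_gene(y, post, patient, offset=np.log(scale))
        assert abs(res["foc"] - 1.0) < 0.15

    def test_mixture_branch_runs_when_enabled(self):
        rng = np.random.default_rng(4)
        n = 20
        post, patient = paired_design(n)
        # bimodal gene: half the samples at 10x the level
        comp = rng.random(2 * n) < 0.5
        mu = np.where(comp, 2000, 200) * 2.0 ** (0.5 * post)
        y = rng.poisson(mu).astype(float)
        res = ip.de_table(
            pd.DataFrame([y], index=["g"],
                         columns=[f"P{i}_pre" for i in range(n)]
                         + [f"P{i}_post" for i in range(n)]),
            _meta(n), use_mixture=True)
        assert res.loc["g", "model"] in {"neg-binomial", "nb-mixture"}
        assert np.isfinite(res.loc["g", "p"])

    def test_nb_and_loglinear_agree_on_well_behaved_gene(self):
        rng = np.random.default_rng(5)
        n = 30
        post, patient = paired_design(n)
        mu = 2 ** (9 + rng.normal(0, 0.2, 2 * n)) * 2 ** (0.8 * post)
        size = 1 / 0.05
        y = rng.negative_binomial(size, size / (size + mu))
        nb = fit_gene(y, post, patient)
        from immunopair.de import _design, _loglinear
        ll = _loglinear(y.astype(float), _design(post, patient),
                        np.zeros(2 * n))
        assert nb["model"] == "neg-binomial"
        assert abs(nb["foc"] - ll["foc"]) < 0.1


def _meta(n):
    rows = []
    for i in range(n):
        for tp in ("pre", "post"):
            rows.append({"sample_id": f"P{i}_{tp}", "patient_id": f"P{i}",
                         "timepoint": tp, "panel": "IP"})
    return pd.DataFrame(rows)


class TestCallDegs:
    def _table(self):
        return pd.DataFrame({
            "foc": [0.5, -0.5, 0.6, -0.7, 0.4, 2.0, -2.0, 0.51, 1.0, -1.0],
            "p_bh": [0.05, 0.05, 0.01, 0.01, 0.01, 0.2, 0.04, 0.06, 0.05, 0.051],
        }, index=[f"g{i}" for i in range(10)])

    def test_inclusive_boundary_partition(self):
        up, down = ip.call_degs(self._table())
        # inclusive convention: FOC >= 0.5 and BH p <= 0.05
        assert set(up) == {"g0", "g2", "g8"}
        assert set(down) == {"g1", "g3", "g6"}

    def test_strict_boundary_configurable(self):
        up, down = ip.call_degs(self._table(),
                                DEGCriteria(inclusive=False))
        assert set(up) == {"g2"}
        assert set(down) == {"g3", "g6"}

    def test_empty_results(self):
        up, down = ip.call_degs(pd.DataFrame(columns=["foc", "p_bh"]))
        assert len(up) == 0 and len(down) == 0

    def test_up_down_disjoint(self):
        up, down = ip.call_degs(self._table())
        assert set(up).isdisjoint(down)


class TestTukey:
    def test_all_equal_nothing_removed(self):
        vals = pd.Series(5.0, index=list("abcdef"))
        assert list(ip.tukey_filter(vals)) == list("abcdef")

    def test_extreme_value_removed(self):
        vals = pd.Series(list(range(1, 21)) + [1000],
                         index=[f"g{i}" for i in range(21)])
        kept = ip.tukey_filter(vals)
        assert "g20" not in kept and len(kept) == 20

    def test_single_pass_contract(self):
        # the rule is applied once; re-applying to its own output may
        # remove more (documented single-pass behavior)
        vals = pd.Series([1.0, 1, 1, 1, 1, 1, 4, 10])
        kept1 = ip.tukey_filter(vals)
        assert 7 not in kept1

    def test_too_few_genes_noop_with_warning(self):
        vals = pd.Series([1.0, 2, 3])
        with pytest.warns(UserWarning, match="no-op"):
            kept = ip.tukey_filter(vals)
        assert list(kept) == [0, 1, 2]


class TestVolcano:
    def test_labels_match_call_degs_and_passthrough(self):
        tab = pd.DataFrame({"foc": [1.0, -1.0, 0.1],
                            "p_bh": [0.01, 0.01, 0.5]},
                           index=["up1", "dn1", "ns1"])
        v = ip.volcano_table(tab)
        assert v.loc["up1", "deg"] == "up"
        assert v.loc["dn1", "deg"] == "down"
        assert v.loc["ns1", "deg"] == "ns"
        assert np.allclose(v["foc"], tab["foc"])
        assert np.allclose(v["neg_log10_p_bh"], -np.log10(tab["p_bh"]))

    def test_empty_input(self):
        v = ip.volcano_table(pd.DataFrame(columns=["foc", "p_bh"]))
        assert v.empty


def test_de_table_planted_effects_recovered():
    """End-to-end on simulated counts: planted +1/-1 log2 genes called, null
    genes not, FOC near truth."""
    rng = np.random.default_rng(6)
    n = 30
    size = 1 / 0.1
    post, patient = paired_design(n)
    genes, truth = {}, {}
    for i in range(12):
        fc = [1.0, -1.0, 0.0, 0.0][i % 4]
        truth[f"g{i}"] = fc
        mu = 2 ** (8 + rng.normal(0, 0.3, 2 * n)) * 2 ** (fc * post)
        genes[f"g{i}"] = rng.negative_binomial(size, size / (size + mu))
    counts = pd.DataFrame(genes).T
    counts.columns = [f"P{i}_pre" for i in range(n)] + [f"P{i}_post" for i in range(n)]
    tab = ip.de_table(counts, _meta(n))
    up, down = ip.call_degs(tab)
    expected_up = {g for g, fc in truth.items() if fc > 0}
    expected_down = {g for g, fc in truth.items() if fc < 0}
    assert set(up) == expected_up
    assert set(down) == expected_down
    for g, fc in truth.items():
        assert abs(tab.loc[g, "foc"] - fc) < 0.35
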