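"""Gene-set pathway scores and their paired pre/post testing.

A pathway score for a sample is the sample's projection on the first
principal axis of the pathway's member genes, computed on standardized
(zero-mean, unit-variance) log2 expression so that highly expressed genes
do not dominate. The sign of the axis is fixed so that the majority of
gene loadings are positive (ties broken by the loading sum), making the
score rise when the pathway's genes rise.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix, paired_samples
from .de import bh_adjust


def pathway_scores(expr: ExpressionMatrix,
                   gene_sets: dict[str, list[str]]):
    """First-principal-component scores per (sample, pathway).

    Genes absent from the matrix are dropped with a warning; pathways with
    no measured genes are omitted with a warning. Returns (scores, info):
    scores is samples x pathways, info maps pathway -> {genes, loadings}.
    """
    values = expr.values
    scores = {}
    info = {}
    for pathway, genes in gene_sets.items():
        genes = list(dict.fromkeys(genes))
        present = [g for g in genes if g in values.index]
        absent = sorted(set(genes) - set(present))
        if absent:
            warnings.warn(f"{pathway}: dropping unmeasured genes {absent}")
        if not present:
            warnings.warn(f"{pathway}: no measured genes, omitted")
            continue
        sub = values.loc[present].to_numpy(dtype=float)
        mean = sub.mean(axis=1, keepdims=True)
        sd = sub.std(axis=1, ddof=1, keepdims=True)
        sd[sd == 0] = 1.0
        z = (sub - mean) / sd
        if len(present) == 1:
            loadings = np.array([1.0])
            proj = z[0]
        else:
            # first right singular vector of the genes x samples z-matrix
            u, s, vt = np.linalg.svd(z, full_matrices=False)
            loadings = u[:, 0]
            proj = s[0] * vt[0]
        n_pos = int((loadings > 0).sum())
        n_neg = int((loadings < 0).sum())
        if n_pos < n_neg or (n_pos == n_neg and loadings.sum() < 0):
            loadings = -loadings
            proj = -proj
        scores[pathway] = pd.Series(proj, index=values.columns)
        info[pathway] = {"genes": present,
                         "loadings": pd.Series(loadings, index=present)}
    if not scores:
        raise ValueError("no pathway had any measured genes")
    table = pd.DataFrame(scores)
    table.index.name = "sample_id"
    return table, info


def paired_pathway_test(scores: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Paired two-sided t-test of post - pre per pathway, BH-corrected;
    direction is the sign of the mean paired difference."""
    pairs = paired_samples(meta)
    n_patients = meta["patient_id"].nunique()
    if len(pairs) < n_patients:
        warnings.warn(f"excluding {n_patients - len(pairs)} unpaired patient(s)")
    if len(pairs) < 2:
        raise ValueError("need at least 2 paired patients")
    rows = []
    for pathway in scores.columns:
        pre = scores.loc[pairs["pre"], pathway].to_numpy()
        post = scores.loc[pairs["post"], pathway].to_numpy()
        diff = post - pre
        if np.std(diff, ddof=1) == 0:
            t, p = (0.0, 1.0) if diff.mean() == 0 else (np.inf * np.sign(diff.mean()), 0.0)
        else:
            t, p = stats.ttest_rel(post, pre)
        rows.append({"pathway": pathway, "n_pairs": len(diff),
                     "mean_diff": float(diff.mean()), "t": float(t),
                     "p": float(p)})
    out = pd.DataFrame(rows).set_index("pathway")
    out["p_bh"] = bh_adjust(out["p"].to_numpy())
    out["direction"] = np.sign(out["mean_diff"]).astype(int)
    return out
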