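"""Count normalization: reference-gene stability ranking (geNorm),
housekeeping scaling, cross-panel merge, log2 transform and
limit-of-detection filtering.

The normalization chain mirrors the standard targeted-count workflow:

1. rank housekeeping candidates by the geNorm stability measure M (the
   average standard deviation of pairwise log2 expression ratios) and keep
   the most stable n (default 19);
2. scale each sample so the geometric mean of the selected housekeepers is
   equal across samples;
3. put the two panels on a common scale per biological sample using the
   endogenous genes they share, averaging the shared genes;
4. log2-transform (offset 1);
5. compute the limit of detection from the negative-control probes
   (mean + 2*SD on the same log2 scale) and keep genes that exceed it in
   more than half of the profiles.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GeNormResult, ProbeCountMatrix

#: zeros are floored at this value before ratios / geometric means
ZERO_FLOOR = 0.5


def _floored(values: pd.DataFrame) -> np.ndarray:
    return np.maximum(values.to_numpy(dtype=float), ZERO_FLOOR)


def genorm(candidates: pd.DataFrame, n_select: int | None = None,
           v_cutoff: float = 0.15) -> GeNormResult:
    """Rank candidate reference genes by expression stability.

    For each pair (j, k) the pairwise variation V_jk is the sample standard
    deviation (n-1 denominator) of log2(a_j / a_k) across samples; the
    stability measure M_j is the mean of V_jk over all k != j. The gene with
    the highest M is eliminated and M is recomputed on the survivors, down
    to the final two. The selected set is the ``n_select`` most stable genes
    when given, otherwise the smallest n whose pairwise variation
    V(n/n+1) of successive normalization factors drops below ``v_cutoff``.

    Parameters
    ----------
    candidates
        Counts (genes x samples) of the housekeeping candidates.
    """
    candidates = candidates.copy()
    all_zero = (candidates.sum(axis=1) == 0)
    excluded = list(candidates.index[all_zero])
    if excluded:
        warnings.warn(f"excluding all-zero candidates: {excluded}")
        candidates = candidates.loc[~all_zero]
    if len(candidates) < 3:
        raise ValueError("geNorm needs at least 3 usable candidate genes")

    log2a = np.log2(_floored(candidates))
    genes = list(candidates.index)

    def m_values(idx: list[int]) -> pd.Series:
        sub = log2a[idx]
        # V_jk = SD over samples of (log2 a_j - log2 a_k)
        m = {}
        for a, j in enumerate(idx):
            vs = [np.std(sub[a] - sub[b], ddof=1)
                  for b in range(len(idx)) if b != a]
            m[genes[j]] = float(np.mean(vs))
        return pd.Series(m)

    remaining = list(range(len(genes)))
    initial_m = m_values(remaining)
    elimination: list[str] = []
    while len(remaining) > 2:
        m = m_values(remaining)
        worst = m.idxmax()
        elimination.append(worst)
        remaining = [i for i in remaining if genes[i] != worst]
    # the final two are tied for most stable; append in index order
    elimination.extend(genes[i] for i in remaining)

    ranked = elimination[::-1]  # most stable first
    # V(n/n+1): SD of log2(NF_n / NF_{n+1}) where NF_n is the geometric mean
    # of the n most stable genes per sample
    pairwise_variation: dict[int, float] = {}
    for n in range(2, len(ranked)):
        idx_n = [genes.index(g) for g in ranked[:n]]
        idx_n1 = [genes.index(g) for g in ranked[: n + 1]]
        nf_n = log2a[idx_n].mean(axis=0)
        nf_n1 = log2a[idx_n1].mean(axis=0)
        pairwise_variation[n] = float(np.std(nf_n - nf_n1, ddof=1))

    if n_select is not None:
        n_sel = min(max(2, int(n_select)), len(ranked))
    else:
        n_sel = len(ranked)
        for n, v in sorted(pairwise_variation.items()):
            if v < v_cutoff:
                n_sel = n
                break
    return GeNormResult(
        stability=initial_m,
        elimination_order=elimination,
        selected=ranked[:n_sel],
        pairwise_variation=pairwise_variation,
        excluded=excluded,
    )


def hk_normalize(matrix: ProbeCountMatrix, selected_hks: list[str]):
    """Scale each sample so its housekeeping geometric mean matches the
    cohort mean of those geometric means.

    Returns
    -------
    scaled : pandas.DataFrame
        Scaled counts (floats), probes x samples, same index as the input.
    factors : pandas.Series
        Per-sample scaling factor applied.
    """
    hk_genes = matrix.probe_info.index[matrix.probe_info["gene"].isin(selected_hks)]
    missing = set(selected_hks) - set(matrix.probe_info.loc[hk_genes, "gene"])
    if missing:
        raise ValueError(f"selected housekeeping genes absent: {sorted(missing)}")
    hk = matrix.counts.loc[hk_genes]
    geo = np.exp(np.log(_floored(hk)).mean(axis=0))
    geo = pd.Series(geo, index=matrix.counts.columns)
    if (geo <= 0).any():
        bad = list(geo.index[geo <= 0])
        raise ValueError(f"zero housekeeping geometric mean for samples: {bad}")
    factors = geo.mean() / geo
    scaled = matrix.counts.astype(float).mul(factors, axis=1)
    return scaled, factors


def merge_panels(panel_a: pd.DataFrame, panel_b: pd.DataFrame,
                 strict: bool = True):
    """Merge two normalized endogenous count matrices (genes x samples).

    Per biological sample, panel B is rescaled by the ratio of the two
    panels' mean normalized counts over the shared genes; shared genes are
    then reported once as the average of the two rescaled measurements.

    Returns
    -------
    merged : pandas.DataFrame
        Union of genes x common samples.
    gene_panels : pandas.Series
        "A", "B" or "both" per merged gene.
    scale : pandas.Series
        Per-sample factor applied to panel B.
    """
    overlap = panel_a.index.intersection(panel_b.index)
    if len(overlap) == 0:
        raise ValueError("panels share no genes; cannot merge")
    common = panel_a.columns.intersection(panel_b.columns)
    only = set(panel_a.columns).symmetric_difference(panel_b.columns)
    if only:
        msg = f"samples present in only one panel: {sorted(only)}"
        if strict:
            raise ValueError(msg)
        warnings.warn(msg + " (excluded)")
    a = panel_a[common]
    b = panel_b[common]
    scale = a.loc[overlap].mean(axis=0) / b.loc[overlap].mean(axis=0)
    b_scaled = b.mul(scale, axis=1)

    a_only = panel_a.index.difference(overlap)
    b_only = panel_b.index.difference(overlap)
    shared = (a.loc[overlap] + b_scaled.loc[overlap]) / 2.0
    merged = pd.concat([a.loc[a_only], b_scaled.loc[b_only], shared])
    merged = merged.sort_index()
    gene_panels = pd.Series("both", index=merged.index)
    gene_panels.loc[a_only] = "A"
    gene_panels.loc[b_only] = "B"
    return merged, gene_panels, scale


def log2_transform(matrix: pd.DataFrame, offset: float = 1.0) -> pd.DataFrame:
    """value -> log2(value + offset); rejects negative inputs."""
    vals = matrix.to_numpy(dtype=float)
    if vals.size and (vals < 0).any():
        raise ValueError("log2_transform requires non-negative values")
    return pd.DataFrame(np.log2(vals + offset), index=matrix.index,
                        columns=matrix.columns)


def compute_lod(neg_log2: pd.DataFrame | np.ndarray) -> float:
    """Limit of detection: mean + 2*SD of the negative-control values.

    The input must already be on the scale of the expression matrix
    (normalized, log2). SD uses the n-1 denominator.
    """
    vals = np.asarray(neg_log2, dtype=float).ravel()
    if vals.size < 2:
        raise ValueError("need at least 2 negative-control measurements")
    return float(vals.mean() + 2.0 * vals.std(ddof=1))


def filter_by_lod(expr: ExpressionMatrix, threshold: float,
                  min_fraction: float = 0.5) -> ExpressionMatrix:
    """Keep genes detected above ``threshold`` in MORE than ``min_fraction``
    of profiles (strict inequality on the fraction and on the value)."""
    if not np.isfinite(threshold):
        raise ValueError("LOD threshold must be finite")
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    if expr.values.empty:
        raise ValueError("empty expression matrix")
    frac = (expr.values > threshold).mean(axis=1)
    lod_pass = frac > min_fraction
    return ExpressionMatrix(
        values=expr.values,
        lod_pass=lod_pass,
        norm_factors=expr.norm_factors,
        gene_panels=expr.gene_panels,
    )


def normalize_cohort(panels: dict[str, ProbeCountMatrix],
                     hk_n: int | None = 19,
                     lod_min_fraction: float = 0.5,
                     log2_offset: float = 1.0):
    """Run the full normalization chain on a two-panel cohort.

    geNorm runs per panel on that panel's housekeeping candidates and the
    per-panel selections are pooled (``hk_n`` caps the total; half per
    panel). Returns the LOD-annotated merged ExpressionMatrix and a report
    dict (geNorm results, factors, LOD threshold, detection counts).
    """
    if len(panels) != 2:
        raise ValueError("normalize_cohort expects exactly two panels")
    (name_a, pcm_a), (name_b, pcm_b) = sorted(panels.items())

    report: dict = {"panels": [name_a, name_b]}
    normalized = {}
    neg_log2_blocks = []
    genorm_results = {}
    per_panel_n = None if hk_n is None else max(2, hk_n // 2 + hk_n % 2)
    for name, pcm in ((name_a, pcm_a), (name_b, pcm_b)):
        hk_counts = pcm.gene_counts("housekeeping")
        gres = genorm(hk_counts, n_select=per_panel_n)
        genorm_results[name] = gres
        scaled, factors = hk_normalize(pcm, gres.selected)
        endo = scaled.loc[pcm.probes_of_class("endogenous")]
        endo.index = pd.Index(
            pcm.probe_info.loc[endo.index, "gene"], name="gene")
        normalized[name] = endo
        neg = scaled.loc[pcm.probes_of_class("negative")]
        neg_log2_blocks.append(log2_transform(neg, log2_offset))
        report[f"factors_{name}"] = factors
    report["genorm"] = genorm_results

    merged, gene_panels, panel_scale = merge_panels(
        normalized[name_a], normalized[name_b])
    gene_panels = gene_panels.replace({"A": name_a, "B": name_b})
    log2_expr = log2_transform(merged, log2_offset)

    lod = compute_lod(pd.concat(neg_log2_blocks).to_numpy())
    expr = ExpressionMatrix(values=log2_expr, gene_panels=gene_panels)
    expr = filter_by_lod(expr, lod, lod_min_fraction)
    report["panel_scale"] = panel_scale
    report["lod_threshold"] = lod
    report["n_genes"] = int(len(expr.values))
    report["n_genes_detected"] = int(expr.lod_pass.sum())
    return expr, report
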