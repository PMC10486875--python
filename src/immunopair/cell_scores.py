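"""Marker-based immune cell abundance scoring.

Candidate marker genes are validated by co-expression: within each cell
type, a candidate is retained only if it is unique to that type, passed the
limit of detection, and its pairwise similarity (Pearson correlation of
log2 expression across all samples, both time points pooled) to at least
one other same-type candidate exceeds a threshold (default 0.6). A cell
type is scorable when at least two markers survive. The abundance score of
a cell type in a sample is the mean log2 expression of its retained
markers; the relative score subtracts the total-leukocyte (CD45) score.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix, MarkerSelection, paired_samples
from .de import bh_adjust

#: default total-leukocyte marker set (CD45)
CD45_MARKERS = ["PTPRC"]
TOTAL_LEUKOCYTES = "total_leukocytes"


def similarity_matrix(expr: ExpressionMatrix | pd.DataFrame,
                      genes: list[str], method: str = "pearson") -> pd.DataFrame:
    """Pairwise co-expression similarity of ``genes`` across all samples.

    Zero-variance genes have undefined correlation; they are excluded with a
    warning and simply absent from the returned matrix.
    """
    values = expr.values if isinstance(expr, ExpressionMatrix) else expr
    genes = list(dict.fromkeys(genes))
    missing = [g for g in genes if g not in values.index]
    if missing:
        raise KeyError(f"genes absent from expression matrix: {missing}")
    if len(genes) < 2:
        raise ValueError("need at least 2 genes for a similarity matrix")
    if values.shape[1] < 3:
        raise ValueError("need at least 3 samples for a similarity matrix")
    sub = values.loc[genes]
    sd = sub.std(axis=1, ddof=1)
    flat = list(sub.index[sd == 0])
    if flat:
        warnings.warn(f"zero-variance genes excluded from similarity: {flat}")
        sub = sub.loc[sd > 0]
    sim = sub.T.corr(method=method)
    np.fill_diagonal(sim.values, 1.0)
    return sim


def select_markers(marker_map: dict[str, list[str]],
                   expr: ExpressionMatrix,
                   threshold: float = 0.6,
                   method: str = "pearson") -> MarkerSelection:
    """Validate candidate markers per cell type.

    Rules, in order: drop genes assigned to more than one cell type
    ("unique" markers only); drop genes that failed the LOD rule or are
    absent from the matrix; within each type keep genes whose similarity to
    at least one other surviving same-type candidate is strictly above
    ``threshold``. Types with fewer than two retained markers are marked
    unscorable.
    """
    counts: dict[str, int] = {}
    for genes in marker_map.values():
        for g in set(genes):
            counts[g] = counts.get(g, 0) + 1
    lod = expr.lod_pass if expr.lod_pass is not None else pd.Series(
        True, index=expr.values.index)

    dropped_rows = []
    eligible: dict[str, list[str]] = {}
    for cell_type, genes in marker_map.items():
        keep = []
        for g in dict.fromkeys(genes):
            if counts[g] > 1:
                dropped_rows.append((cell_type, g, "not unique"))
            elif g not in expr.values.index:
                dropped_rows.append((cell_type, g, "not measured"))
            elif not bool(lod.get(g, False)):
                dropped_rows.append((cell_type, g, "below LOD"))
            else:
                keep.append(g)
        eligible[cell_type] = keep

    all_eligible = [g for genes in eligible.values() for g in genes]
    sim = similarity_matrix(expr, all_eligible, method=method) if len(all_eligible) >= 2 \
        else pd.DataFrame(dtype=float)

    retained: dict[str, list[str]] = {}
    unscorable: list[str] = []
    for cell_type, genes in eligible.items():
        present = [g for g in genes if g in sim.index]
        kept = []
        for g in present:
            others = [h for h in present if h != g]
            if others and (sim.loc[g, others] > threshold).any():
                kept.append(g)
        for g in genes:
            if g not in kept:
                reason = ("no similar same-type marker" if g in present
                          else "zero variance")
                dropped_rows.append((cell_type, g, reason))
        retained[cell_type] = kept
        if len(kept) < 2:
            unscorable.append(cell_type)

    dropped = pd.DataFrame(dropped_rows, columns=["cell_type", "gene", "reason"])
    return MarkerSelection(similarity=sim, candidates=dict(marker_map),
                           retained=retained, unscorable=unscorable,
                           dropped=dropped)


def abundance_scores(expr: ExpressionMatrix,
                     selection: MarkerSelection | dict[str, list[str]],
                     cd45_markers: list[str] | None = None) -> pd.DataFrame:
    """Per-sample abundance scores: mean log2 marker expression per cell
    type, plus the total-leukocyte (CD45) score. Samples are rows."""
    retained = selection.retained if isinstance(selection, MarkerSelection) else selection
    unscorable = set(selection.unscorable) if isinstance(selection, MarkerSelection) else set()
    cd45 = cd45_markers or CD45_MARKERS

    scorable = {t: genes for t, genes in retained.items()
                if t not in unscorable and genes}
    if not scorable:
        raise ValueError("no scorable cell types")

    cols = {}
    for cell_type, genes in scorable.items():
        missing = [g for g in genes if g not in expr.values.index]
        if missing:
            raise KeyError(
                f"markers for {cell_type!r} absent from matrix: {missing}")
        cols[cell_type] = expr.values.loc[genes].mean(axis=0)
    missing_cd45 = [g for g in cd45 if g not in expr.values.index]
    if missing_cd45:
        raise KeyError(f"total-leukocyte markers absent: {missing_cd45}")
    cols[TOTAL_LEUKOCYTES] = expr.values.loc[cd45].mean(axis=0)
    scores = pd.DataFrame(cols)
    scores.index.name = "sample_id"
    return scores


def relative_scores(scores: pd.DataFrame) -> pd.DataFrame:
    """Cell-type score minus the total-leukocyte score (log2 scale)."""
    if TOTAL_LEUKOCYTES not in scores.columns:
        raise ValueError(f"scores lack a {TOTAL_LEUKOCYTES!r} column")
    rel = scores.drop(columns=TOTAL_LEUKOCYTES).sub(
        scores[TOTAL_LEUKOCYTES], axis=0)
    return rel


def paired_score_test(scores: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Paired two-sided t-test of post - pre per cell type, BH-corrected.

    Patients missing either time point are excluded with a warning. Zero
    within-pair variance with a nonzero shift is a degenerate case reported
    as p = 0 with the ``degenerate`` flag set.
    """
    pairs = paired_samples(meta)
    n_patients = meta["patient_id"].nunique()
    if len(pairs) < n_patients:
        warnings.warn(
            f"excluding {n_patients - len(pairs)} unpaired patient(s)")
    if len(pairs) < 2:
        raise ValueError("need at least 2 paired patients")
    rows = []
    for cell_type in scores.columns:
        pre = scores.loc[pairs["pre"], cell_type].to_numpy()
        post = scores.loc[pairs["post"], cell_type].to_numpy()
        diff = post - pre
        mean_diff = float(diff.mean())
        degenerate = bool(np.std(diff, ddof=1) == 0)
        if degenerate:
            t = 0.0 if mean_diff == 0 else float(np.inf) * np.sign(mean_diff)
            p = 1.0 if mean_diff == 0 else 0.0
        else:
            t, p = stats.ttest_rel(post, pre)
        rows.append({"cell_type": cell_type, "n_pairs": len(diff),
                     "mean_diff": mean_diff, "t": float(t), "p": float(p),
                     "degenerate": degenerate})
    out = pd.DataFrame(rows).set_index("cell_type")
    out["p_bh"] = bh_adjust(out["p"].to_numpy())
    out["direction"] = np.sign(out["mean_diff"]).astype(int)
    return out
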