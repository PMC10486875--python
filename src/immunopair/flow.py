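"""Flow-cytometry population counts: paired testing, leukocyte-relative
fractions, and concordance with marker-gene expression scores.

The module consumes gated absolute population counts (cells per volume) and
CBC values; it never touches raw cytometry events. Counts are
log2-transformed (offset 1) before t-tests and correlations by default —
absolute gated counts are strongly right-skewed — and the correlation with
expression scores is computed per time point separately, which is what
exposes treatment-induced decoupling of the two modalities.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .containers import paired_samples
from .de import bh_adjust
from . import datasets

CBC_COLUMNS = ("lymphocytes_cbc", "neutrophils_cbc", "thrombocytes")


def validate_hierarchy(flow: pd.DataFrame,
                       hierarchy: dict[str, str] | None = None,
                       tol: float = 1e-9) -> None:
    """Raise if any child population exceeds its parent."""
    hierarchy = hierarchy or datasets.default_flow_hierarchy()
    if (flow.select_dtypes("number") < 0).any().any():
        raise ValueError("flow counts must be non-negative")
    for child, parent in hierarchy.items():
        if child in flow.columns and parent in flow.columns:
            bad = flow.index[flow[child] > flow[parent] * (1 + tol)]
            if len(bad):
                raise ValueError(
                    f"population {child!r} exceeds parent {parent!r} "
                    f"in samples {list(bad)[:5]}")


def paired_population_test(flow: pd.DataFrame, meta: pd.DataFrame,
                           log_scale: bool = True,
                           missing_threshold: float = 0.2) -> pd.DataFrame:
    """Paired two-sided t-test of post vs pre per population.

    Counts are log2(x+1)-transformed by default. Populations missing for
    more than ``missing_threshold`` of patients are flagged in the output.
    """
    pairs = paired_samples(meta)
    if len(pairs) < 2:
        raise ValueError("need at least 2 paired patients")
    rows = []
    for pop in flow.columns:
        pre = flow[pop].reindex(pairs["pre"]).to_numpy(dtype=float)
        post = flow[pop].reindex(pairs["post"]).to_numpy(dtype=float)
        ok = np.isfinite(pre) & np.isfinite(post)
        flagged = (1 - ok.mean()) > missing_threshold
        if flagged:
            warnings.warn(f"population {pop!r} missing for "
                          f"{(1 - ok.mean()):.0%} of patients")
        x_pre, x_post = pre[ok], post[ok]
        if log_scale:
            x_pre, x_post = np.log2(x_pre + 1), np.log2(x_post + 1)
        diff = x_post - x_pre
        if len(diff) < 2 or np.std(diff, ddof=1) == 0:
            t, p = (0.0, 1.0) if diff.mean() == 0 else (np.inf * np.sign(diff.mean()), 0.0)
        else:
            t, p = stats.ttest_rel(x_post, x_pre)
        rows.append({"population": pop, "n_pairs": int(ok.sum()),
                     "mean_diff": float(diff.mean()), "t": float(t),
                     "p": float(p), "flagged_missing": flagged})
    out = pd.DataFrame(rows).set_index("population")
    out["p_bh"] = bh_adjust(out["p"].to_numpy())
    out["direction"] = np.sign(out["mean_diff"]).astype(int)
    return out


def leukocyte_fractions(flow: pd.DataFrame,
                        top_level: list[str] | None = None,
                        total_column: str | None = None) -> pd.DataFrame:
    """Per-sample population fractions of total leukocytes.

    The total is either a named column (``total_column``, e.g. a CBC-derived
    count) or the sum of the top-level populations (default: granulocytes,
    monocytes, lymphocytes, dendritic cells, MDSC).
    """
    populations = [c for c in flow.columns if c not in CBC_COLUMNS]
    if total_column is not None:
        total = flow[total_column]
    else:
        top_level = top_level or ["granulocytes", "monocytes", "lymphocytes",
                                  "dendritic_cells", "MDSC"]
        present = [c for c in top_level if c in flow.columns]
        if not present:
            raise ValueError("no top-level populations found to form a total")
        total = flow[present].sum(axis=1)
    if (total <= 0).any():
        bad = list(total.index[total <= 0])
        raise ValueError(f"zero total leukocyte count for samples: {bad}")
    return flow[populations].div(total, axis=0)


def correlate_modalities(flow: pd.DataFrame, scores: pd.DataFrame,
                         meta: pd.DataFrame,
                         mapping: dict[str, str] | None = None,
                         log_scale: bool = True) -> pd.DataFrame:
    """Correlate flow counts with matched cell-type scores per time point.

    For every mapped (population, cell type) pair and each time point
    separately, computes Pearson and Spearman correlations across patients
    between the (log2) flow count and the expression abundance score. Rows
    with fewer than 3 matched patients are omitted with a warning.
    """
    mapping = mapping or datasets.default_flow_mapping()
    pairs = paired_samples(meta)
    tp_samples = {"pre": list(pairs["pre"]), "post": list(pairs["post"])}
    rows = []
    for pop, cell_type in mapping.items():
        if pop not in flow.columns or cell_type not in scores.columns:
            warnings.warn(f"no match for population {pop!r} -> {cell_type!r}")
            continue
        for tp, samples in tp_samples.items():
            x = flow[pop].reindex(samples).to_numpy(dtype=float)
            y = scores[cell_type].reindex(samples).to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 3:
                warnings.warn(
                    f"{pop}/{tp}: fewer than 3 matched patients, row omitted")
                continue
            xv = np.log2(x[ok] + 1) if log_scale else x[ok]
            yv = y[ok]
            pearson = float(stats.pearsonr(xv, yv)[0])
            spearman = float(stats.spearmanr(xv, yv)[0])
            rows.append({"population": pop, "cell_type": cell_type,
                         "timepoint": tp, "n": int(ok.sum()),
                         "pearson": pearson, "spearman": spearman})
    return pd.DataFrame(rows)
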