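"""Simulation studies that measure the pipeline's operating
characteristics on synthetic cohorts with known truth.

Each function regenerates its data from scratch under a seed and returns
plain numbers: effect-recovery coverage and error of the paired NB fit,
sensitivity/FDR of DEG calling, type-I error of the paired score and
population tests, marker-block recovery, and the planted
flow-up/expression-down discordance pattern. They are deliberately sized
for a single desktop CPU (the methods note states the problem sizes).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import datasets
from .cell_scores import abundance_scores, paired_score_test, select_markers
from .containers import paired_samples
from .de import DEGCriteria, call_degs, de_table, fit_gene
from .flow import leukocyte_fractions, paired_population_test
from .normalize import normalize_cohort
from .synthetic import (
    DEFAULT_FLOW_EFFECTS,
    CohortConfig,
    simulate_cohort,
    simulate_flow_counts,
)

NULL_EFFECTS = {"myeloid": 0.0, "lymphocyte": 0.0, "hla_ii": 0.0,
                "leukocyte": 0.0, "null": 0.0}


def _paired_arrays(n_pairs: int):
    post = np.array([0.0] * n_pairs + [1.0] * n_pairs)
    patient = np.array([f"P{i}" for i in range(n_pairs)] * 2)
    return post, patient


def de_effect_recovery(seed: int = 0, n_reps: int = 200, n_pairs: int = 40,
                       true_log2_fc: float = 1.0, dispersion: float = 0.1,
                       baseline_log2: float = 10.0,
                       patient_sd_log2: float = 0.5) -> dict:
    """Single-gene paired NB recovery study.

    Simulates ``n_reps`` independent NB genes with the given true log2 fold
    change, dispersion and per-patient baseline shifts (which the blocking
    covariates absorb), fits each, and reports the fraction of estimates
    inside [true - 0.2, true + 0.2] plus the mean absolute error.
    """
    rng = np.random.default_rng(seed)
    post, patient = _paired_arrays(n_pairs)
    size = 1.0 / dispersion
    focs = np.empty(n_reps)
    for r in range(n_reps):
        shifts = rng.normal(0, patient_sd_log2, n_pairs)
        mu = 2.0 ** (baseline_log2 + np.tile(shifts, 2)) \
            * 2.0 ** (true_log2_fc * post)
        y = rng.negative_binomial(size, size / (size + mu))
        focs[r] = fit_gene(y, post, patient)["foc"]
    within = float(np.mean(np.abs(focs - true_log2_fc) <= 0.2))
    return {"coverage": within,
            "mean_abs_error": float(np.mean(np.abs(focs - true_log2_fc))),
            "mean_foc": float(focs.mean()), "n_reps": n_reps}


def de_sensitivity_fdr(seed: int = 0, n_reps: int = 200, n_pairs: int = 40,
                       n_genes: int = 30, deg_fraction: float = 0.1,
                       true_log2_fc: float = 1.0,
                       dispersion: float = 0.1) -> dict:
    """DEG-calling operating characteristics with planted effects.

    Each replicate simulates ``n_genes`` genes of which ``deg_fraction``
    carry |log2 FC| = ``true_log2_fc`` (alternating sign), runs the paired
    NB fit with per-replicate BH correction, and calls DEGs at the default
    criteria (|log2 FC| >= 0.5, BH p <= 0.05). Sensitivity and empirical
    FDR are averaged over replicates.
    """
    rng = np.random.default_rng(seed)
    post, patient = _paired_arrays(n_pairs)
    size = 1.0 / dispersion
    n_deg = max(1, int(round(deg_fraction * n_genes)))
    samples = [f"P{i}_pre" for i in range(n_pairs)] \
        + [f"P{i}_post" for i in range(n_pairs)]
    meta = pd.DataFrame(
        [{"sample_id": s, "patient_id": s.rsplit("_", 1)[0],
          "timepoint": s.rsplit("_", 1)[1], "panel": "IP"} for s in samples])
    criteria = DEGCriteria()
    tp = fp = fn = 0
    for r in range(n_reps):
        fcs = np.zeros(n_genes)
        fcs[:n_deg] = true_log2_fc * np.where(np.arange(n_deg) % 2 == 0, 1, -1)
        rows = {}
        for g in range(n_genes):
            mu = 2.0 ** (8.0 + rng.normal(0, 0.3, 2 * n_pairs)) \
                * 2.0 ** (fcs[g] * post)
            rows[f"g{g}"] = rng.negative_binomial(size, size / (size + mu))
        counts = pd.DataFrame(rows, index=samples).T
        tab = de_table(counts, meta)
        up, down = call_degs(tab, criteria)
        called = set(up) | set(down)
        truth = {f"g{g}" for g in range(n_deg)}
        tp += len(called & truth)
        fp += len(called - truth)
        fn += len(truth - called)
    sensitivity = tp / (tp + fn) if tp + fn else float("nan")
    fdr = fp / (tp + fp) if tp + fp else 0.0
    return {"sensitivity": float(sensitivity), "fdr": float(fdr),
            "n_reps": n_reps, "n_genes": n_genes}


def type_i_error(seed: int = 0, n_reps: int = 200, alpha: float = 0.05) -> dict:
    """Null-cohort type-I error of the paired score and population tests.

    Simulates scaled-down cohorts with every planted effect at zero (and no
    flow/expression coupling), runs the full normalize -> marker selection
    -> score chain and the flow population tests, and pools raw-p rejections
    at level ``alpha`` across replicates and cell types / populations.
    """
    rng = np.random.default_rng(seed)
    flow_null = {k: 0.0 for k in DEFAULT_FLOW_EFFECTS}
    flow_null["thrombocytes"] = 0.0
    score_rej = []
    flow_rej = []
    marker_map = datasets.default_marker_map()
    for r in range(n_reps):
        cfg = CohortConfig.desk_scale(
            seed=int(rng.integers(2 ** 31 - 1)),
            effect_table=dict(NULL_EFFECTS),
            flow_effect_table=dict(flow_null),
            flow_coupling=(0.0, 0.0))
        panels, meta, truth = simulate_cohort(cfg)
        expr, _ = normalize_cohort(panels, hk_n=8)
        sel = select_markers(marker_map, expr)
        scores = abundance_scores(expr.detected(), sel)
        stests = paired_score_test(scores, meta)
        score_rej.extend((stests["p"] <= alpha).tolist())
        flow = simulate_flow_counts(cfg, truth)
        ftests = paired_population_test(flow, meta)
        flow_rej.extend((ftests["p"] <= alpha).tolist())
    return {"score_rejection_rate": float(np.mean(score_rej)),
            "population_rejection_rate": float(np.mean(flow_rej)),
            "n_reps": n_reps}


def marker_recovery(seed: int = 0) -> dict:
    """Exact recovery of planted marker blocks at the 0.6 threshold.

    Within-type marker correlation is planted at 0.9 and cross-type at 0;
    reports the fraction of cell types whose retained marker set equals the
    planted set exactly, and the fraction of genes recovered.
    """
    cfg = CohortConfig.desk_scale(seed=seed)
    panels, _, _ = simulate_cohort(cfg)
    expr, _ = normalize_cohort(panels, hk_n=8)
    sel = select_markers(cfg.marker_map, expr, threshold=0.6)
    exact = [sel.retained.get(t, []) == list(genes)
             for t, genes in cfg.marker_map.items()]
    n_total = sum(len(v) for v in cfg.marker_map.values())
    n_kept = sum(len(set(sel.retained.get(t, [])) & set(genes))
                 for t, genes in cfg.marker_map.items())
    return {"block_recovery": float(np.mean(exact)),
            "gene_recovery": n_kept / n_total,
            "n_types": len(cfg.marker_map)}


def discordance_study(seed: int = 0, n_patients: int = 40) -> dict:
    """The planted flow-up / expression-down lymphocyte scenario.

    Lymphocyte gene expression is planted at -0.5 log2 while lymphocyte
    flow counts rise +0.5 log2 and granulocytes surge; reports the signed
    directions of the expression score change and the flow count change for
    lymphocyte populations, plus the change in the lymphocyte share of
    total leukocytes.
    """
    cfg = CohortConfig.desk_scale(
        seed=seed, n_patients=n_patients,
        effect_table={"myeloid": 1.5, "lymphocyte": -0.5, "hla_ii": -0.5,
                      "leukocyte": 0.4, "null": 0.0})
    panels, meta, truth = simulate_cohort(cfg)
    flow = simulate_flow_counts(cfg, truth)
    expr, _ = normalize_cohort(panels, hk_n=8)
    sel = select_markers(cfg.marker_map, expr)
    scores = abundance_scores(expr.detected(), sel)
    stests = paired_score_test(scores, meta)
    ftests = paired_population_test(flow, meta)

    lymph_types = ["T_cells", "B_cells", "NK_cells"]
    score_dir = int(np.sign(stests.loc[lymph_types, "mean_diff"].mean()))
    flow_dir = int(np.sign(ftests.loc["lymphocytes", "mean_diff"]))

    pairs = paired_samples(meta)
    fr = leukocyte_fractions(flow)
    frac_change = float(
        fr.loc[pairs["post"], "lymphocytes"].to_numpy().mean()
        - fr.loc[pairs["pre"], "lymphocytes"].to_numpy().mean())
    abs_change = float(
        np.log2(flow.loc[pairs["post"], "lymphocytes"].to_numpy()).mean()
        - np.log2(flow.loc[pairs["pre"], "lymphocytes"].to_numpy()).mean())
    return {"expression_score_direction": score_dir,
            "flow_count_direction": flow_dir,
            "lymphocyte_abs_log2_change": abs_change,
            "lymphocyte_fraction_change": frac_change}
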