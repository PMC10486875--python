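"""End-to-end run: (simulate | load) -> normalize -> cell scores -> DE ->
pathway scores -> flow concordance, with a structured, reproducible report.

The pipeline is a pure function of (inputs, thresholds, seed): running it
twice with the same configuration produces byte-identical reports. Every
stage logs the counts that matter downstream (genes above the detection
limit, markers retained, DEGs up/down, test directions) and every threshold
is echoed into the report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cell_scores as cs
from . import datasets, de, flow as fl, io as npio, normalize as norm
from . import pathways as pw
from .containers import biological_meta
from .synthetic import CohortConfig, simulate_cohort, simulate_flow_counts

STAGES = ["input", "normalize", "markers", "cell_scores", "de", "pathways",
          "concordance"]


@dataclass
class RunConfig:
    """Full-run configuration: exactly one of ``simulation`` (a synthetic
    cohort) or ``inputs`` (paths to counts/meta/flow CSVs) must be set."""

    simulation: CohortConfig | None = None
    inputs: dict | None = None
    hk_n: int = 19
    lod_min_fraction: float = 0.5
    similarity_threshold: float = 0.6
    fc_cutoff: float = 0.5
    alpha: float = 0.05
    cd45_markers: list = field(default_factory=lambda: list(cs.CD45_MARKERS))
    marker_map_path: str | None = None
    gene_sets_path: str | None = None
    flow_mapping_path: str | None = None
    use_mixture: bool = False
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        if (self.simulation is None) == (self.inputs is None):
            raise ValueError("set exactly one of simulation or inputs")
        for name in ("hk_n", "lod_min_fraction", "similarity_threshold",
                     "fc_cutoff", "alpha"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "simulation" in raw and raw["simulation"] is not None:
            raw["simulation"] = CohortConfig(**raw["simulation"])
        return cls(**raw)

    def thresholds(self) -> dict:
        return {"hk_n": self.hk_n, "lod_min_fraction": self.lod_min_fraction,
                "similarity_threshold": self.similarity_threshold,
                "fc_cutoff": self.fc_cutoff, "alpha": self.alpha,
                "seed": self.seed}


class StageError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"stage {stage!r} failed: {err}")
        self.stage = stage


def _round(obj, nd=6):
    if isinstance(obj, float):
        return round(obj, nd)
    if isinstance(obj, dict):
        return {k: _round(v, nd) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round(v, nd) for v in obj]
    return obj


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in order; returns the run report dict.

    When ``config.outdir`` is set, every intermediate table plus
    ``report.json`` / ``report.txt`` is written there.
    """
    report: dict = {"thresholds": config.thresholds(), "stages": {}}
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except Exception as err:  # annotate with the failing stage
                raise StageError(name, err) from err
        return deco

    # --- input -----------------------------------------------------------
    @stage("input")
    def inputs():
        if config.simulation is not None:
            sim = config.simulation
            panels, meta, truth = simulate_cohort(sim)
            flow_table = simulate_flow_counts(sim, truth)
            return panels, meta, flow_table, truth
        paths = config.inputs
        panels = {}
        for key, path in paths.items():
            if key.startswith("counts_"):
                panels[key.removeprefix("counts_")] = npio.read_panel_csv(path)
        meta = npio.read_meta(paths["meta"])
        flow_table = npio.read_flow_table(paths["flow"]) if "flow" in paths else None
        return panels, meta, flow_table, None

    panels, meta, flow_table, truth = inputs
    bio_meta = biological_meta(meta)
    report["stages"]["input"] = {
        "panels": sorted(panels),
        "n_samples": int(len(bio_meta)),
        "n_patients": int(bio_meta["patient_id"].nunique()),
        "probes_per_panel": {p: int(len(m.counts)) for p, m in sorted(panels.items())},
        "simulated": config.simulation is not None,
    }

    # --- normalize -------------------------------------------------------
    @stage("normalize")
    def normalized():
        return norm.normalize_cohort(
            panels, hk_n=config.hk_n, lod_min_fraction=config.lod_min_fraction)

    expr, nrep = normalized
    report["stages"]["normalize"] = {
        "selected_housekeepers": {p: g.selected for p, g in nrep["genorm"].items()},
        "n_housekeepers_selected": int(sum(len(g.selected)
                                           for g in nrep["genorm"].values())),
        "lod_threshold_log2": float(nrep["lod_threshold"]),
        "n_genes": nrep["n_genes"],
        "n_genes_detected": nrep["n_genes_detected"],
    }
    detected = expr.detected()

    # --- marker selection ------------------------------------------------
    @stage("markers")
    def selection():
        marker_map = (npio.read_marker_map(config.marker_map_path)
                      if config.marker_map_path else datasets.default_marker_map())
        return cs.select_markers(marker_map, expr,
                                 threshold=config.similarity_threshold)

    sel = selection
    report["stages"]["markers"] = {
        "n_candidates": int(sum(len(set(v)) for v in sel.candidates.values())),
        "n_retained": int(sum(len(v) for v in sel.retained.values())),
        "retained": {t: sorted(v) for t, v in sel.retained.items()},
        "unscorable_types": sorted(sel.unscorable),
        "n_scorable_types": len(sel.scorable_types()),
    }

    # --- cell scores -----------------------------------------------------
    @stage("cell_scores")
    def scored():
        scores = cs.abundance_scores(detected, sel,
                                     cd45_markers=config.cd45_markers)
        rel = cs.relative_scores(scores)
        tests = cs.paired_score_test(scores, meta)
        return scores, rel, tests

    scores, rel_scores, score_tests = scored
    report["stages"]["cell_scores"] = {
        "directions": score_tests["direction"].to_dict(),
        "p_bh": _round(score_tests["p_bh"].to_dict()),
        "n_significant": int((score_tests["p_bh"] <= config.alpha).sum()),
    }

    # --- differential expression ----------------------------------------
    @stage("de")
    def de_results():
        frames = []
        seen: set[str] = set()
        for name in sorted(panels):
            pcm = panels[name]
            counts = pcm.gene_counts("endogenous")
            counts = counts.loc[[g for g in counts.index if g not in seen]]
            seen.update(counts.index)
            factors = nrep[f"factors_{name}"]
            offsets = -np.log(factors)
            # analyze only detected genes
            counts = counts.loc[counts.index.intersection(detected.genes)]
            frames.append(de.de_table(counts, meta, offsets=offsets,
                                      use_mixture=config.use_mixture))
        return pd.concat(frames).sort_index()

    de_tab = de_results
    criteria = de.DEGCriteria(fc_cutoff=config.fc_cutoff, p_cutoff=config.alpha)
    up, down = de.call_degs(de_tab, criteria)
    report["stages"]["de"] = {
        "n_genes_analyzed": int((~de_tab["skipped"]).sum()),
        "n_up": int(len(up)),
        "n_down": int(len(down)),
        "models_used": de_tab["model"].value_counts().to_dict(),
        "top_up": list(de_tab.loc[up, "foc"].sort_values(ascending=False).head(5).index),
        "top_down": list(de_tab.loc[down, "foc"].sort_values().head(5).index),
    }

    # --- pathways --------------------------------------------------------
    @stage("pathways")
    def pathway_results():
        sets = (npio.read_gene_sets(config.gene_sets_path)
                if config.gene_sets_path else datasets.default_pathway_sets())
        pscores, info = pw.pathway_scores(detected, sets)
        ptests = pw.paired_pathway_test(pscores, meta)
        return pscores, ptests

    pscores, ptests = pathway_results
    report["stages"]["pathways"] = {
        "directions": ptests["direction"].to_dict(),
        "p_bh": _round(ptests["p_bh"].to_dict()),
    }

    # --- flow concordance ------------------------------------------------
    if flow_table is not None:
        @stage("concordance")
        def concordance():
            fl.validate_hierarchy(flow_table)
            ptest = fl.paired_population_test(flow_table, meta)
            fractions = fl.leukocyte_fractions(flow_table)
            mapping = (dict(pd.read_csv(config.flow_mapping_path).values)
                       if config.flow_mapping_path else None)
            concord = fl.correlate_modalities(flow_table, scores, meta,
                                              mapping=mapping)
            return ptest, fractions, concord

        flow_tests, fractions, concord = concordance
        pre_r = concord.loc[concord["timepoint"] == "pre", "pearson"]
        post_r = concord.loc[concord["timepoint"] == "post", "pearson"]
        report["stages"]["concordance"] = {
            "flow_directions": flow_tests["direction"].to_dict(),
            "n_populations_significant": int(
                (flow_tests["p_bh"] <= config.alpha).sum()),
            "mean_pearson_pre": _round(float(pre_r.mean())),
            "mean_pearson_post": _round(float(post_r.mean())),
        }
    else:
        flow_tests = fractions = concord = None
        report["stages"]["concordance"] = {"skipped": "no flow data"}

    if outdir:
        expr.values.to_csv(outdir / "matrix.csv")
        scores.to_csv(outdir / "scores.csv")
        rel_scores.to_csv(outdir / "relative_scores.csv")
        score_tests.to_csv(outdir / "score_tests.csv")
        de_tab.to_csv(outdir / "de.csv")
        de.volcano_table(de_tab, criteria).to_csv(outdir / "volcano.csv")
        pscores.to_csv(outdir / "pathway_scores.csv")
        ptests.to_csv(outdir / "pathway_tests.csv")
        if flow_tests is not None:
            flow_tests.to_csv(outdir / "flow_tests.csv")
            fractions.to_csv(outdir / "leukocyte_fractions.csv")
            concord.to_csv(outdir / "concordance.csv", index=False)
        (outdir / "report.json").write_text(report_json(report))
        (outdir / "report.txt").write_text(report_text(report))
    return report


def report_json(report: dict) -> str:
    return json.dumps(_round(report), indent=1, sort_keys=True,
                      default=str) + "\n"


def report_text(report: dict) -> str:
    lines = ["immunopair run report", "=" * 21, ""]
    lines.append("thresholds: " + json.dumps(report["thresholds"], sort_keys=True))
    for stage_name in STAGES:
        body = report["stages"].get(stage_name, {})
        lines.append("")
        lines.append(f"[{stage_name}]")
        for key, val in body.items():
            lines.append(f"  {key}: {json.dumps(_round(val), sort_keys=True, default=str)}")
    return "\n".join(lines) + "\n"
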