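"""Synthetic paired two-panel cohort generator.

Emulates the structure of a paired pre/post-treatment whole-blood immune
profiling study: 44 patients sampled at baseline and at day 14, each sample
hybridized to two ~770-probe targeted panels (730 endogenous + 40
housekeeping probes, ~265 endogenous genes shared between panels, plus
negative-control probes), together with matched gated flow-cytometry
population counts and complete-blood-count values.

Count model
-----------
Counts are negative-binomial with mean

    mu[g, s] = baseline[g] * scale[s, panel] * 2**(bio[g, s] + fc[g] * post[s])

where ``scale`` is a per-sample log-normal library-size factor, ``bio`` is
log2-scale biological variation (marker genes of the same cell type share a
latent per-sample abundance factor, which is what makes within-type marker
co-expression detectable), ``fc`` is the planted treatment log2 fold change
of the gene's group, and the variance is mu + dispersion * mu**2
(``dispersion`` is the quadratic overdispersion coefficient alpha, i.e. the
reciprocal of the NB size parameter). Negative-control probes are Poisson
with a small constant mean, independent of timepoint.

Flow counts are log-normal around population baselines, built leaf-first so
that every parent population is the sum of its children. Their treatment
effects are configured independently of the expression effects, so
discordant scenarios (lymphocyte counts rising while lymphocyte gene
expression falls) can be planted deliberately.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import ProbeCountMatrix
from . import datasets

PANELS = ("IP", "MII")

#: default planted treatment log2 fold changes per gene group
DEFAULT_EFFECTS = {
    "myeloid": 1.5,
    "lymphocyte": -0.6,
    "hla_ii": -0.7,
    "leukocyte": 0.4,
    "null": 0.0,
}

#: genes outside the marker map that still carry a planted group effect
EXTRA_GENE_GROUPS = {
    "PTPRC": "leukocyte",
    "ITGB2": "leukocyte",
    "ITGB4": "myeloid",
    "GZMB": "lymphocyte",
    "HLA-DPB1": "hla_ii",
    "HLA-DRB3": "hla_ii",
    "HLA-DRA": "hla_ii",
    "HLA-DPA1": "hla_ii",
    "HLA-DMB": "hla_ii",
    "CD74": "hla_ii",
}

#: cell types whose markers carry the myeloid planted effect
MYELOID_TYPES = {"neutrophils", "monocytes", "dendritic_cells", "eosinophils"}
#: cell types whose markers carry the lymphocyte planted effect
LYMPHOID_TYPES = {
    "T_cells", "CD4_T_cells", "CD8_T_cells", "gamma_delta_T_cells",
    "Tregs", "B_cells", "NK_cells",
}
# plasma_B_cells and mast_cells deliberately carry no effect (the study saw
# no significant change in either).

#: leaf flow populations and their baseline absolute counts (cells/uL)
FLOW_LEAF_BASELINES = {
    "eosinophils": 150.0,
    "mature_neutrophils": 3500.0,
    "immature_neutrophils": 150.0,
    "classical_monocytes": 300.0,
    "intermediate_monocytes": 40.0,
    "non_classical_monocytes": 60.0,
    "dendritic_cells": 30.0,
    "MDSC": 20.0,
    "B_cells": 200.0,
    "CD16_pos_NK_cells": 150.0,
    "_NK_other": 100.0,
    "CD4_T_cells": 800.0,
    "CD8_T_cells": 400.0,
    "gamma_delta_T_cells": 60.0,
    "_T_other": 80.0,
}

#: parent -> children (parents are sums of their leaves)
FLOW_DERIVED = {
    "granulocytes": ["eosinophils", "mature_neutrophils", "immature_neutrophils"],
    "monocytes": ["classical_monocytes", "intermediate_monocytes", "non_classical_monocytes"],
    "NK_cells": ["CD16_pos_NK_cells", "_NK_other"],
    "T_cells": ["CD4_T_cells", "CD8_T_cells", "gamma_delta_T_cells", "_T_other"],
    "lymphocytes": ["B_cells", "CD16_pos_NK_cells", "_NK_other",
                    "CD4_T_cells", "CD8_T_cells", "gamma_delta_T_cells", "_T_other"],
}

#: default planted log2 change of each LEAF population after treatment;
#: granulocyte/monocyte surge, modest lymphocyte rise, CD16+ NK unchanged
DEFAULT_FLOW_EFFECTS = {
    "eosinophils": 0.5,
    "mature_neutrophils": 1.8,
    "immature_neutrophils": 1.5,
    "classical_monocytes": 1.0,
    "intermediate_monocytes": 1.0,
    "non_classical_monocytes": 1.0,
    "dendritic_cells": 0.5,
    "MDSC": 0.5,
    "B_cells": 0.5,
    "CD16_pos_NK_cells": 0.0,
    "_NK_other": 0.5,
    "CD4_T_cells": 0.5,
    "CD8_T_cells": 0.5,
    "gamma_delta_T_cells": 0.5,
    "_T_other": 0.5,
}

FLOW_POPULATIONS = [
    "granulocytes", "mature_neutrophils", "immature_neutrophils", "eosinophils",
    "monocytes", "classical_monocytes", "intermediate_monocytes",
    "non_classical_monocytes", "lymphocytes", "B_cells", "T_cells", "NK_cells",
    "CD4_T_cells", "CD8_T_cells", "gamma_delta_T_cells", "CD16_pos_NK_cells",
    "dendritic_cells", "MDSC",
]

CBC_COLUMNS = ["lymphocytes_cbc", "neutrophils_cbc", "thrombocytes"]


@dataclass
class CohortConfig:
    """Parameters of the synthetic paired cohort.

    dispersion is the negative-binomial overdispersion alpha
    (variance = mu + alpha * mu^2); library_size_sd is the natural-log SD of
    the per-sample scale factor; effect_table maps gene groups to planted
    post-vs-pre log2 fold changes; flow_effect_table maps leaf flow
    populations to planted log2 count changes; flow_coupling gives the
    (pre, post) strength with which flow counts follow the latent cell-type
    abundance factors that also drive marker-gene expression — a larger pre
    value plants the "concordant before, discordant after" pattern.
    """

    n_patients: int = 44
    n_endogenous_per_panel: int = 730
    n_housekeeping_per_panel: int = 40
    n_overlap: int = 265
    n_negative_controls: int = 8
    dispersion: float = 0.05
    library_size_sd: float = 0.25
    effect_table: dict = field(default_factory=lambda: dict(DEFAULT_EFFECTS))
    marker_map: dict | None = None
    seed: int = 0
    within_type_correlation: float = 0.9
    marker_sigma: float = 1.0
    bio_sigma: float = 0.35
    hk_sigma_range: tuple = (0.02, 0.25)
    n_noisy_hk: int = 5
    noisy_hk_sigma_range: tuple = (0.5, 1.0)
    low_expr_fraction: float = 0.1
    negative_control_mean: float = 5.0
    flow_effect_table: dict | None = None
    flow_coupling: tuple = (0.6, 0.15)
    flow_patient_sd: float = 0.3
    flow_within_sd: float = 0.25

    def __post_init__(self) -> None:
        for name in ("n_patients", "n_endogenous_per_panel",
                     "n_housekeeping_per_panel", "n_overlap",
                     "n_negative_controls"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_overlap > self.n_endogenous_per_panel:
            raise ValueError("n_overlap cannot exceed n_endogenous_per_panel")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.library_size_sd < 0:
            raise ValueError("library_size_sd must be non-negative")
        for grp, fc in self.effect_table.items():
            if not np.isfinite(fc):
                raise ValueError(f"non-finite log2 fold change for group {grp!r}")
        if self.marker_map is None:
            self.marker_map = datasets.default_marker_map()
        if not 0 <= self.within_type_correlation <= 1:
            raise ValueError("within_type_correlation must be in [0, 1]")
        if self.flow_effect_table is None:
            self.flow_effect_table = dict(DEFAULT_FLOW_EFFECTS)

    @classmethod
    def desk_scale(cls, **overrides) -> "CohortConfig":
        """Scaled-down cohort (12 patients, 120 genes/panel) for fast tests."""
        defaults = dict(
            n_patients=12,
            n_endogenous_per_panel=120,
            n_housekeeping_per_panel=16,
            n_overlap=80,
            n_noisy_hk=3,
        )
        defaults.update(overrides)
        return cls(**defaults)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "flow_coupling" in raw:
            raw["flow_coupling"] = tuple(raw["flow_coupling"])
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticTruth:
    """Ground truth behind one simulated cohort.

    baseline_log2_mean / log2_fc / gene_group are per-gene; sample_scale is
    the per-(sample, panel) library factor; cell_factors are the latent
    per-(sample, cell type) abundance factors shared between marker
    expression and (optionally) flow counts.
    """

    baseline_log2_mean: pd.Series
    log2_fc: pd.Series
    gene_group: pd.Series
    sample_scale: pd.DataFrame
    cell_factors: pd.DataFrame
    marker_map: dict

    def __post_init__(self) -> None:
        hk = self.gene_group == "housekeeping"
        if hk.any() and (self.log2_fc[hk] != 0).any():
            raise ValueError("housekeeping genes must have true log2 fold change 0")

    def to_json(self, path) -> None:
        payload = {
            "baseline_log2_mean": self.baseline_log2_mean.round(6).to_dict(),
            "log2_fc": self.log2_fc.round(6).to_dict(),
            "gene_group": self.gene_group.to_dict(),
            "sample_scale": {p: self.sample_scale[p].round(6).to_dict()
                             for p in self.sample_scale.columns},
            "cell_factors": {c: self.cell_factors[c].round(6).to_dict()
                             for c in self.cell_factors.columns},
            "marker_map": {k: list(v) for k, v in self.marker_map.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def _gene_group_of_type(cell_type: str) -> str:
    if cell_type in MYELOID_TYPES:
        return "myeloid"
    if cell_type in LYMPHOID_TYPES:
        return "lymphocyte"
    return "null"


def _build_manifest(config: CohortConfig, rng: np.random.Generator):
    """Assign genes to panels.

    Special genes (markers, pathway members, CD45) go into the overlap set
    first; any that do not fit spill into panel-specific slots. Remaining
    slots are filled with anonymous genes, a fraction of which are planted
    below the limit of detection.
    """
    marker_map = config.marker_map
    special: dict[str, str] = {}
    for cell_type, genes in marker_map.items():
        grp = _gene_group_of_type(cell_type)
        for g in genes:
            special.setdefault(g, grp)
    for g, grp in EXTRA_GENE_GROUPS.items():
        special.setdefault(g, grp)
    for genes in datasets.default_pathway_sets().values():
        for g in genes:
            special.setdefault(g, "null")

    special_genes = list(special)
    if len(special_genes) > 2 * config.n_endogenous_per_panel - config.n_overlap:
        raise ValueError("panels too small to hold the marker/pathway gene set")

    overlap = special_genes[: config.n_overlap]
    spill = special_genes[config.n_overlap:]
    n_fill_overlap = config.n_overlap - len(overlap)
    overlap = overlap + [f"OVL_{i:04d}" for i in range(n_fill_overlap)]

    # spill alternates between panels: lymphoid-leaning genes to IP,
    # myeloid-leaning to MII, the rest round-robin
    ip_extra, mii_extra = [], []
    for i, g in enumerate(spill):
        grp = special[g]
        if grp == "lymphocyte":
            ip_extra.append(g)
        elif grp == "myeloid":
            mii_extra.append(g)
        elif i % 2 == 0:
            ip_extra.append(g)
        else:
            mii_extra.append(g)

    n_ip_fill = config.n_endogenous_per_panel - config.n_overlap - len(ip_extra)
    n_mii_fill = config.n_endogenous_per_panel - config.n_overlap - len(mii_extra)
    if n_ip_fill < 0 or n_mii_fill < 0:
        raise ValueError("panel-specific slots exhausted by marker/pathway genes")
    ip_only = ip_extra + [f"IPG_{i:04d}" for i in range(n_ip_fill)]
    mii_only = mii_extra + [f"MIIG_{i:04d}" for i in range(n_mii_fill)]

    groups = dict(special)
    for g in overlap + ip_only + mii_only:
        groups.setdefault(g, "null")
    # keep insertion order: iteration order must not depend on string
    # hashing, or fixed seeds would not reproduce across processes

    hk = {
        "IP": [f"HK_IP_{i:02d}" for i in range(config.n_housekeeping_per_panel)],
        "MII": [f"HK_MII_{i:02d}" for i in range(config.n_housekeeping_per_panel)],
    }
    neg = [f"NEG_{chr(65 + i)}" for i in range(config.n_negative_controls)]
    return {
        "overlap": overlap,
        "IP": overlap + ip_only,
        "MII": overlap + mii_only,
        "groups": groups,
        "hk": hk,
        "neg": neg,
        "special": special_genes,
    }


def simulate_cohort(config: CohortConfig):
    """Simulate paired two-panel count data.

    Returns
    -------
    panels : dict[str, ProbeCountMatrix]
        Raw counts for panels "IP" and "MII" over the same biological
        samples.
    meta : pandas.DataFrame
        Sample metadata with columns sample_id, patient_id, timepoint,
        panel (one row per sample per panel).
    truth : SyntheticTruth
    """
    rng = np.random.default_rng(config.seed)
    manifest = _build_manifest(config, rng)
    marker_map = config.marker_map

    patients = [f"P{i + 1:02d}" for i in range(config.n_patients)]
    samples = [f"{p}_{tp}" for p in patients for tp in ("pre", "post")]
    post = np.array([s.endswith("_post") for s in samples], dtype=float)

    genes = sorted(set(manifest["IP"]) | set(manifest["MII"]))
    gene_idx = pd.Index(genes, name="gene")

    # baseline log2 means: special genes comfortably detected, a fraction of
    # anonymous filler genes planted near background
    base = pd.Series(rng.normal(7.0, 1.5, len(gene_idx)), index=gene_idx)
    for g in manifest["special"]:
        base[g] = rng.normal(7.5, 0.8)
    filler = [g for g in genes if g.startswith(("OVL_", "IPG_", "MIIG_"))]
    n_low = int(round(config.low_expr_fraction * len(filler)))
    if n_low:
        low = rng.choice(filler, size=n_low, replace=False)
        base[low] = rng.normal(1.0, 1.0, n_low)

    group = pd.Series("null", index=gene_idx)
    for g in genes:
        group[g] = manifest["groups"].get(g, "null")
    fc = group.map(lambda grp: config.effect_table.get(grp, 0.0)).astype(float)

    # latent per-(cell type, sample) abundance factors
    cell_types = list(marker_map)
    cell_factors = pd.DataFrame(
        rng.standard_normal((len(samples), len(cell_types))),
        index=pd.Index(samples, name="sample_id"), columns=cell_types,
    )

    # log2-scale biological variation
    rho = config.within_type_correlation
    bio = pd.DataFrame(
        rng.standard_normal((len(gene_idx), len(samples))) * config.bio_sigma,
        index=gene_idx, columns=samples,
    )
    gene_of_type: dict[str, str] = {}
    for cell_type, mgenes in marker_map.items():
        for g in mgenes:
            gene_of_type.setdefault(g, cell_type)
    for g, cell_type in gene_of_type.items():
        if g not in bio.index:
            continue
        eps = rng.standard_normal(len(samples))
        bio.loc[g] = config.marker_sigma * (
            np.sqrt(rho) * cell_factors[cell_type].to_numpy()
            + np.sqrt(1 - rho) * eps
        )

    # per-(sample, panel) library scale
    scale = pd.DataFrame(
        np.exp(rng.normal(0.0, config.library_size_sd, (len(samples), 2))),
        index=pd.Index(samples, name="sample_id"), columns=list(PANELS),
    )

    size = 1.0 / config.dispersion

    def _nb(mean: np.ndarray) -> np.ndarray:
        mean = np.maximum(mean, 1e-9)
        p = size / (size + mean)
        return rng.negative_binomial(size, p)

    panels: dict[str, ProbeCountMatrix] = {}
    meta_rows = []
    hk_sigma: dict[str, float] = {}
    hk_base: dict[str, float] = {}
    for panel in PANELS:
        endo = manifest[panel]
        hks = manifest["hk"][panel]
        lo, hi = config.hk_sigma_range
        sig = rng.uniform(lo, hi, len(hks))
        nlo, nhi = config.noisy_hk_sigma_range
        if config.n_noisy_hk:
            sig[-config.n_noisy_hk:] = rng.uniform(nlo, nhi, config.n_noisy_hk)
        for h, s in zip(hks, sig):
            hk_sigma[h] = s
            hk_base[h] = rng.normal(9.0, 0.8)

        probe_names = endo + hks + manifest["neg"]
        mat = np.zeros((len(probe_names), len(samples)))

        endo_base = base[endo].to_numpy()[:, None]
        endo_bio = bio.loc[endo, samples].to_numpy()
        endo_fc = fc[endo].to_numpy()[:, None]
        s_vec = scale[panel].to_numpy()[None, :]
        mu = 2.0 ** (endo_base + endo_bio + endo_fc * post[None, :]) * s_vec
        mat[: len(endo)] = _nb(mu)

        hk_bio = rng.standard_normal((len(hks), len(samples)))
        hk_mu = 2.0 ** (
            np.array([hk_base[h] for h in hks])[:, None]
            + np.array([hk_sigma[h] for h in hks])[:, None] * hk_bio
        ) * s_vec
        mat[len(endo): len(endo) + len(hks)] = _nb(hk_mu)

        mat[len(endo) + len(hks):] = rng.poisson(
            config.negative_control_mean, (len(manifest["neg"]), len(samples))
        )

        counts = pd.DataFrame(
            mat.astype(np.int64),
            index=pd.Index(probe_names, name="probe"),
            columns=samples,
        )
        probe_info = pd.DataFrame(
            {
                "gene": probe_names,
                "probe_class": (["endogenous"] * len(endo)
                                + ["housekeeping"] * len(hks)
                                + ["negative"] * len(manifest["neg"])),
                "panel": panel,
            },
            index=counts.index,
        )
        panels[panel] = ProbeCountMatrix(counts=counts, probe_info=probe_info)
        for p in patients:
            for tp in ("pre", "post"):
                meta_rows.append(
                    {"sample_id": f"{p}_{tp}", "patient_id": p,
                     "timepoint": tp, "panel": panel}
                )

    meta = pd.DataFrame(meta_rows)

    all_idx = pd.Index(sorted(set(genes) | set(hk_base)), name="gene")
    truth = SyntheticTruth(
        baseline_log2_mean=pd.concat(
            [base, pd.Series(hk_base)]
        ).reindex(all_idx),
        log2_fc=pd.concat(
            [fc, pd.Series(0.0, index=list(hk_base))]
        ).reindex(all_idx),
        gene_group=pd.concat(
            [group, pd.Series("housekeeping", index=list(hk_base))]
        ).reindex(all_idx),
        sample_scale=scale,
        cell_factors=cell_factors,
        marker_map={k: list(v) for k, v in marker_map.items()},
    )
    return panels, meta, truth


def simulate_flow_counts(config: CohortConfig, truth: SyntheticTruth) -> pd.DataFrame:
    """Simulate gated flow-cytometry absolute counts and CBC values.

    One row per biological sample; 18 population columns plus CBC columns.
    Leaf populations are drawn log-normal; every parent population is the
    sum of its leaves, so the hierarchy invariant holds by construction.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 104729]))
    samples = list(truth.cell_factors.index)
    patients = sorted({s.rsplit("_", 1)[0] for s in samples})
    post = np.array([s.endswith("_post") for s in samples], dtype=float)
    pat_eff = {p: rng.normal(0.0, config.flow_patient_sd) for p in patients}
    mapping = datasets.default_flow_mapping()

    kappa_pre, kappa_post = config.flow_coupling
    leaf_cols = {}
    for pop, baseline in FLOW_LEAF_BASELINES.items():
        eff = config.flow_effect_table.get(pop, 0.0)
        noise = rng.normal(0.0, config.flow_within_sd, len(samples))
        logc = np.log(baseline) + noise
        logc += np.array([pat_eff[s.rsplit("_", 1)[0]] for s in samples])
        logc += np.log(2.0) * eff * post
        cell_type = mapping.get(pop)
        if cell_type is not None and cell_type in truth.cell_factors.columns:
            f = truth.cell_factors[cell_type].to_numpy()
            kappa = np.where(post > 0, kappa_post, kappa_pre)
            # centered so the coupling adds variance without shifting the
            # expected count (keeps trajectories independent of coupling)
            logc += kappa * f - kappa ** 2 / 2.0
        leaf_cols[pop] = np.exp(logc)

    flow = pd.DataFrame(leaf_cols, index=pd.Index(samples, name="sample_id"))
    for parent, children in FLOW_DERIVED.items():
        flow[parent] = flow[list(children)].sum(axis=1)
    flow = flow[FLOW_POPULATIONS]

    flow["lymphocytes_cbc"] = flow["lymphocytes"] * np.exp(
        rng.normal(0.0, 0.05, len(samples)))
    flow["neutrophils_cbc"] = (
        flow["mature_neutrophils"] + flow["immature_neutrophils"]
    ) * np.exp(rng.normal(0.0, 0.05, len(samples)))
    thrombo_eff = config.flow_effect_table.get("thrombocytes", -0.3)
    flow["thrombocytes"] = np.exp(
        np.log(250_000.0)
        + rng.normal(0.0, 0.15, len(samples))
        + np.log(2.0) * thrombo_eff * post
    )
    return flow


def write_cohort(outdir, panels, meta, truth, flow=None, rcc: bool = False) -> dict:
    """Write a simulated cohort to disk (CSV per panel, metadata, truth JSON,
    optional flow CSV and per-sample RCC-style files). Returns written paths."""
    from . import io as npio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for panel, pcm in panels.items():
        p = outdir / f"counts_{panel}.csv"
        npio.write_panel_csv(p, pcm)
        paths[f"counts_{panel}"] = str(p)
        if rcc:
            rcc_dir = outdir / f"rcc_{panel}"
            rcc_dir.mkdir(exist_ok=True)
            for sample in pcm.samples:
                npio.write_rcc(rcc_dir / f"{sample}_{panel}.RCC", pcm, sample)
            paths[f"rcc_{panel}"] = str(rcc_dir)
    mp = outdir / "meta.csv"
    meta.to_csv(mp, index=False)
    paths["meta"] = str(mp)
    tp = outdir / "truth.json"
    truth.to_json(tp)
    paths["truth"] = str(tp)
    if flow is not None:
        fp = outdir / "flow.csv"
        flow.to_csv(fp)
        paths["flow"] = str(fp)
    return paths
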