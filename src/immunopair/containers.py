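"""Core in-memory containers shared across the pipeline.

Counts and expression values live in pandas DataFrames (rows = probes or
genes, columns = samples); the thin dataclasses here bundle them with the
annotations the analysis needs (probe classes, panel identity, LOD flags,
normalization factors) and validate the structural invariants once, at
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PROBE_CLASSES = ("endogenous", "housekeeping", "negative", "positive")


@dataclass
class ProbeCountMatrix:
    """Raw probe-level counts for one panel.

    Parameters
    ----------
    counts
        Probes x samples matrix of non-negative integer counts.
    probe_info
        One row per probe (same index as ``counts``), columns
        ``gene`` (gene symbol), ``probe_class`` (one of endogenous,
        housekeeping, negative, positive) and ``panel``.
    """

    counts: pd.DataFrame
    probe_info: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.probe_info.index):
            raise ValueError("counts and probe_info must share the same probe index")
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate probe names in count matrix")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate sample ids in count matrix")
        missing = {"gene", "probe_class", "panel"} - set(self.probe_info.columns)
        if missing:
            raise ValueError(f"probe_info missing columns: {sorted(missing)}")
        bad = set(self.probe_info["probe_class"]) - set(PROBE_CLASSES)
        if bad:
            raise ValueError(f"unknown probe classes: {sorted(bad)}")
        vals = self.counts.to_numpy()
        if vals.size and (vals < 0).any():
            raise ValueError("counts must be non-negative")
        if (self.probe_info["probe_class"] == "negative").sum() < 1:
            raise ValueError("panel must contain at least one negative-control probe")

    @property
    def panel(self) -> str:
        return str(self.probe_info["panel"].iloc[0])

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def probes_of_class(self, probe_class: str) -> pd.Index:
        return self.probe_info.index[self.probe_info["probe_class"] == probe_class]

    def class_counts(self, probe_class: str) -> pd.DataFrame:
        """Count sub-matrix for one probe class."""
        return self.counts.loc[self.probes_of_class(probe_class)]

    def gene_counts(self, probe_class: str = "endogenous") -> pd.DataFrame:
        """Counts of one class re-indexed by gene symbol."""
        sub = self.class_counts(probe_class)
        genes = self.probe_info.loc[sub.index, "gene"]
        out = sub.copy()
        out.index = pd.Index(genes, name="gene")
        return out


@dataclass
class ExpressionMatrix:
    """Normalized log2 expression, genes x samples.

    ``lod_pass`` flags which genes exceeded the limit of detection in the
    required fraction of profiles; ``norm_factors`` records the per-sample
    housekeeping scaling applied upstream; ``gene_panels`` records which
    panel(s) each gene was measured on ("IP", "MII" or "both").
    """

    values: pd.DataFrame
    lod_pass: pd.Series | None = None
    norm_factors: pd.Series | None = None
    gene_panels: pd.Series | None = None

    def __post_init__(self) -> None:
        vals = self.values.to_numpy(dtype=float)
        if vals.size and not np.isfinite(vals).all():
            raise ValueError("expression values must be finite")
        if self.values.index.has_duplicates:
            raise ValueError("merged matrix must contain each gene exactly once")
        if self.lod_pass is not None:
            self.lod_pass = self.lod_pass.reindex(self.values.index)

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def detected(self) -> "ExpressionMatrix":
        """Restrict to genes that passed the LOD rule."""
        if self.lod_pass is None:
            return self
        keep = self.lod_pass.fillna(False).astype(bool)
        return ExpressionMatrix(
            values=self.values.loc[keep],
            lod_pass=self.lod_pass.loc[keep],
            norm_factors=self.norm_factors,
            gene_panels=None if self.gene_panels is None else self.gene_panels.loc[keep[keep].index],
        )


@dataclass
class GeNormResult:
    """Output of the housekeeping stability ranking.

    ``stability`` holds the initial stability measure M per candidate
    (average SD of pairwise log2 expression ratios); ``elimination_order``
    lists candidates from least to most stable (first eliminated first);
    ``pairwise_variation`` maps n -> V(n/n+1), the SD of the log2 ratio of
    normalization factors built from the n and n+1 most stable genes.
    """

    stability: pd.Series
    elimination_order: list[str]
    selected: list[str]
    pairwise_variation: dict[int, float] = field(default_factory=dict)
    excluded: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.stability < 0).any():
            raise ValueError("stability measure M must be non-negative")
        if len(self.selected) < 2:
            raise ValueError("selected housekeeping set must contain >= 2 genes")
        if sorted(self.elimination_order) != sorted(self.stability.index):
            raise ValueError("elimination order must be a permutation of candidates")


@dataclass
class MarkerSelection:
    """Per-cell-type marker validation result.

    ``similarity`` is the pairwise co-expression matrix over all candidate
    genes; ``retained`` maps each cell type to the markers that survived the
    uniqueness + similarity + LOD rules; types with fewer than two survivors
    are listed in ``unscorable``.
    """

    similarity: pd.DataFrame
    candidates: dict[str, list[str]]
    retained: dict[str, list[str]]
    unscorable: list[str] = field(default_factory=list)
    dropped: pd.DataFrame | None = None

    def scorable_types(self) -> list[str]:
        return [t for t in self.retained if t not in self.unscorable]


def validate_meta(meta: pd.DataFrame, require_panel: bool = False) -> pd.DataFrame:
    """Validate a sample metadata table.

    Required columns: sample_id, patient_id, timepoint (pre/post); panel is
    required only when ``require_panel``. Returns the table with a clean
    RangeIndex.
    """
    required = {"sample_id", "patient_id", "timepoint"}
    if require_panel:
        required.add("panel")
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    bad_tp = set(meta["timepoint"]) - {"pre", "post"}
    if bad_tp:
        raise ValueError(f"timepoint must be 'pre' or 'post', got {sorted(bad_tp)}")
    key = ["patient_id", "timepoint"] + (["panel"] if "panel" in meta.columns else [])
    if meta.duplicated(subset=key).any():
        raise ValueError("(patient, timepoint, panel) must be unique in metadata")
    return meta.reset_index(drop=True)


def biological_meta(meta: pd.DataFrame) -> pd.DataFrame:
    """One row per biological sample (collapses the per-panel rows)."""
    cols = ["sample_id", "patient_id", "timepoint"]
    return meta[cols].drop_duplicates("sample_id").reset_index(drop=True)


def paired_samples(meta: pd.DataFrame) -> pd.DataFrame:
    """Patients with both a pre and a post sample.

    Returns a table with columns patient_id, pre, post (sample ids);
    unpaired patients are silently dropped (callers warn where the contract
    requires it).
    """
    bio = biological_meta(meta)
    wide = bio.pivot_table(
        index="patient_id", columns="timepoint", values="sample_id", aggfunc="first"
    )
    for col in ("pre", "post"):
        if col not in wide.columns:
            wide[col] = np.nan
    wide = wide.dropna(subset=["pre", "post"])
    return (
        wide.reset_index()[["patient_id", "pre", "post"]]
        .rename_axis(columns=None)
        .sort_values("patient_id")
        .reset_index(drop=True)
    )
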