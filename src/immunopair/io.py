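"""Reading and writing probe counts, metadata, marker maps and gene sets.

Two on-disk dialects are supported for counts: per-sample RCC-style text
files (the reporter-code-count format produced by the counting instrument,
with Header / Sample_Attributes / Lane_Attributes / Code_Summary sections)
and a single wide CSV per panel. ``read(write(x)) == x`` for both.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import pandas as pd

from .containers import ProbeCountMatrix, validate_meta

CODECLASS_MAP = {
    "Endogenous": "endogenous",
    "Housekeeping": "housekeeping",
    "Negative": "negative",
    "Positive": "positive",
}
_INV_CODECLASS = {v: k for k, v in CODECLASS_MAP.items()}


class RCCFormatError(ValueError):
    """Malformed RCC-style file (missing section, bad row)."""


def read_rcc(path):
    """Parse one RCC-style file.

    Returns
    -------
    table : pandas.DataFrame
        Indexed by probe name with columns gene, probe_class, count.
    attrs : dict
        Header, sample and lane attributes (FOV counts, binding density,
        sample id) as flat key -> value strings.
    """
    path = Path(path)
    sections: dict[str, list[str]] = {}
    current = None
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("</") and line.endswith(">"):
            current = None
        elif line.startswith("<") and line.endswith(">"):
            current = line[1:-1]
            sections[current] = []
        elif current is not None:
            sections[current].append(line)

    if "Code_Summary" not in sections:
        raise RCCFormatError(f"{path.name}: missing Code_Summary section")

    attrs: dict[str, str] = {}
    for sec in ("Header", "Sample_Attributes", "Lane_Attributes"):
        for line in sections.get(sec, []):
            key, _, value = line.partition(",")
            attrs[f"{sec}.{key}"] = value

    rows = sections["Code_Summary"]
    if not rows or not rows[0].startswith("CodeClass"):
        raise RCCFormatError(f"{path.name}: Code_Summary missing header row")
    records = []
    for i, line in enumerate(rows[1:], start=2):
        parts = line.split(",")
        if len(parts) != 4:
            raise RCCFormatError(
                f"{path.name}: Code_Summary row {i} has {len(parts)} fields, expected 4")
        code_class, name, accession, count_str = parts
        if code_class not in CODECLASS_MAP:
            raise RCCFormatError(
                f"{path.name}: row {i}: unknown CodeClass {code_class!r}")
        try:
            count = int(count_str)
        except ValueError:
            raise RCCFormatError(
                f"{path.name}: row {i}: non-integer count {count_str!r}") from None
        if count < 0:
            raise RCCFormatError(
                f"{path.name}: row {i}: negative count {count} for probe {name!r}")
        records.append((name, name, CODECLASS_MAP[code_class], count))

    table = pd.DataFrame(
        records, columns=["probe", "gene", "probe_class", "count"]
    ).set_index("probe")
    return table, attrs


def write_rcc(path, matrix: ProbeCountMatrix, sample_id: str,
              lane_attrs: dict | None = None) -> None:
    """Write one sample of a panel as an RCC-style file."""
    if sample_id not in matrix.counts.columns:
        raise KeyError(f"sample {sample_id!r} not in count matrix")
    lane = {"ID": "1", "FovCount": "490", "FovCounted": "490",
            "BindingDensity": "1.0"}
    lane.update(lane_attrs or {})
    lines = [
        "<Header>", "FileVersion,1.7", "SoftwareVersion,4.0", "</Header>",
        "<Sample_Attributes>", f"ID,{sample_id}",
        f"GeneRLF,{matrix.panel}", "</Sample_Attributes>",
        "<Lane_Attributes>",
        *[f"{k},{v}" for k, v in lane.items()],
        "</Lane_Attributes>",
        "<Code_Summary>", "CodeClass,Name,Accession,Count",
    ]
    for probe in matrix.counts.index:
        cls = _INV_CODECLASS[matrix.probe_info.loc[probe, "probe_class"]]
        gene = matrix.probe_info.loc[probe, "gene"]
        count = int(matrix.counts.loc[probe, sample_id])
        lines.append(f"{cls},{gene},NA,{count}")
    lines.append("</Code_Summary>")
    Path(path).write_text("\n".join(lines) + "\n")


def assemble_matrix(sample_tables: dict[str, pd.DataFrame],
                    meta: pd.DataFrame) -> ProbeCountMatrix:
    """Combine single-sample tables (as returned by read_rcc) into a
    probes x samples matrix.

    All samples must share the same probe manifest (same probes, classes and
    gene names); every sample id must appear in ``meta``.
    """
    if not sample_tables:
        raise ValueError("no samples to assemble")
    meta = validate_meta(meta, require_panel=True)
    known = set(meta["sample_id"])
    missing_meta = [s for s in sample_tables if s not in known]
    if missing_meta:
        raise ValueError(f"samples without metadata: {missing_meta}")

    items = list(sample_tables.items())
    ref_id, ref = items[0]
    ref_manifest = ref[["gene", "probe_class"]]
    for sid, tab in items[1:]:
        if not tab.index.equals(ref.index) or not tab[["gene", "probe_class"]].equals(ref_manifest):
            raise ValueError(
                f"probe manifest of sample {sid!r} differs from {ref_id!r}")

    counts = pd.DataFrame(
        {sid: tab["count"].astype("int64") for sid, tab in items},
        index=ref.index,
    )
    panel = meta.loc[meta["sample_id"] == ref_id, "panel"].iloc[0]
    probe_info = ref_manifest.copy()
    probe_info["panel"] = panel
    return ProbeCountMatrix(counts=counts, probe_info=probe_info)


def read_rcc_dir(directory, meta: pd.DataFrame) -> ProbeCountMatrix:
    """Read every ``*.RCC`` file in a directory into one panel matrix.

    The sample id is taken from the Sample_Attributes ID field.
    """
    tables = {}
    for path in sorted(Path(directory).glob("*.RCC")):
        table, attrs = read_rcc(path)
        sid = attrs.get("Sample_Attributes.ID", path.stem)
        tables[sid] = table
    return assemble_matrix(tables, meta)


def write_panel_csv(path, matrix: ProbeCountMatrix) -> None:
    out = matrix.probe_info.join(matrix.counts)
    out.to_csv(path, index_label="probe")


def read_panel_csv(path) -> ProbeCountMatrix:
    df = pd.read_csv(path, index_col="probe")
    anno_cols = ["gene", "probe_class", "panel"]
    missing = set(anno_cols) - set(df.columns)
    if missing:
        raise ValueError(f"panel CSV missing columns: {sorted(missing)}")
    sample_cols = [c for c in df.columns if c not in anno_cols]
    counts = df[sample_cols].astype("int64")
    return ProbeCountMatrix(counts=counts, probe_info=df[anno_cols])


def read_meta(path) -> pd.DataFrame:
    return validate_meta(pd.read_csv(path), require_panel=True)


def read_marker_map(path) -> dict[str, list[str]]:
    """Read a cell_type,gene CSV into a marker map.

    Duplicate (cell_type, gene) rows are collapsed. A gene listed under two
    cell types triggers a warning but is kept under both — the uniqueness
    rule is applied later, during marker selection.
    """
    df = pd.read_csv(path)
    if set(df.columns) != {"cell_type", "gene"}:
        raise ValueError(
            f"marker map must have columns cell_type,gene; got {list(df.columns)}")
    if df.empty:
        raise ValueError("marker map is empty")
    df = df.drop_duplicates()
    shared = df.groupby("gene")["cell_type"].nunique()
    multi = list(shared.index[shared > 1])
    if multi:
        warnings.warn(f"genes listed under multiple cell types: {multi}")
    return {t: list(g["gene"]) for t, g in df.groupby("cell_type", sort=False)}


def read_gene_sets(path) -> dict[str, list[str]]:
    """Read a pathway,gene CSV into pathway gene sets."""
    df = pd.read_csv(path)
    if set(df.columns) != {"pathway", "gene"}:
        raise ValueError(
            f"gene sets must have columns pathway,gene; got {list(df.columns)}")
    if df.empty:
        raise ValueError("gene set file is empty")
    df = df.drop_duplicates()
    return {p: list(g["gene"]) for p, g in df.groupby("pathway", sort=False)}


def read_flow_table(path) -> pd.DataFrame:
    """Read flow counts, either long (sample_id,population,count) or wide
    (sample_id index, one column per population/CBC value)."""
    df = pd.read_csv(path)
    if set(df.columns) == {"sample_id", "population", "count"}:
        wide = df.pivot(index="sample_id", columns="population", values="count")
        wide.columns.name = None
        return wide
    if "sample_id" not in df.columns:
        raise ValueError("flow CSV must contain a sample_id column")
    return df.set_index("sample_id")
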