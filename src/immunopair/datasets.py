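"""Bundled editable fixtures: marker map, pathway gene sets, flow panel.

These CSVs are illustrative stand-ins for resources the analysis consumes
but that are not published in machine-readable form (the candidate
marker-gene list, the vendor's pathway gene sets, the gating panel's
population/marker-gene correspondence). They use real immune gene symbols
and the standard 18-population gating scheme, and can be replaced by the
user's own CSVs at every call site.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _data_path(name: str):
    return resources.files("immunopair.data").joinpath(name)


def _read(name: str) -> pd.DataFrame:
    with resources.as_file(_data_path(name)) as p:
        return pd.read_csv(p)


def default_marker_map() -> dict[str, list[str]]:
    """Cell type -> candidate marker genes (13 types, 61 genes)."""
    df = _read("markers.csv")
    return {t: list(g["gene"]) for t, g in df.groupby("cell_type", sort=False)}


def default_pathway_sets() -> dict[str, list[str]]:
    """Pathway -> member genes (leukocyte/myeloid up, NK/B/T/MHC-II down
    under the default planted treatment program)."""
    df = _read("pathways.csv")
    return {p: list(g["gene"]) for p, g in df.groupby("pathway", sort=False)}


def default_flow_hierarchy() -> dict[str, str]:
    """Flow population child -> parent links."""
    df = _read("flow_hierarchy.csv")
    return dict(zip(df["child"], df["parent"]))


def default_flow_mapping() -> dict[str, str]:
    """Flow population -> matched expression cell type."""
    df = _read("flow_mapping.csv")
    return dict(zip(df["population"], df["cell_type"]))
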