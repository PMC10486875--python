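import numpy as np
import pandas as pd
import pytest

import immunopair as ip
from immunopair import datasets

SEED = 7


@pytest.fixture(scope="session")
def desk_cfg():
    return ip.CohortConfig.desk_scale(seed=SEED)


@pytest.fixture(scope="session")
def desk_cohort(desk_cfg):
    return ip.simulate_cohort(desk_cfg)


@pytest.fixture(scope="session")
def desk_flow(desk_cfg, desk_cohort):
    _, _, truth = desk_cohort
    return ip.simulate_flow_counts(desk_cfg, truth)


@pytest.fixture(scope="session")
def desk_expr(desk_cohort):
    panels, _, _ = desk_cohort
    expr, report = ip.normalize_cohort(panels, hk_n=8)
    return expr, report


@pytest.fixture(scope="session")
def desk_selection(desk_expr):
    expr, _ = desk_expr
    return ip.select_markers(datasets.default_marker_map(), expr)


@pytest.fixture(scope="session")
def desk_scores(desk_expr, desk_selection):
    expr, _ = desk_expr
    return ip.abundance_scores(expr.detected(), desk_selection)


@pytest.fixture()
def toy_meta():
    rows = []
    for p in ("P1", "P2", "P3", "P4"):
        for tp in ("pre", "post"):
            rows.append({"sample_id": f"{p}_{tp}", "patient_id": p,
                         "timepoint": tp, "panel": "IP"})
    return pd.DataFrame(rows)


def make_panel(counts: np.ndarray, samples, panel="IP", n_neg=2,
               classes=None) -> ip.ProbeCountMatrix:
    """Small panel builder: counts rows are endogenous genes G0..; negative
    probes with constant count 5 are appended unless classes is given."""
    counts = np.asarray(counts)
    n = counts.shape[0]
    if classes is None:
        names = [f"G{i}" for i in range(n)] + [f"NEG_{i}" for i in range(n_neg)]
        classes = ["endogenous"] * n + ["negative"] * n_neg
        counts = np.vstack([counts, np.full((n_neg, counts.shape[1]), 5)])
    else:
        names = [f"G{i}" for i in range(n)]
    frame = pd.DataFrame(counts, index=pd.Index(names, name="probe"),
                         columns=list(samples))
    info = pd.DataFrame({"gene": names, "probe_class": classes,
                         "panel": panel}, index=frame.index)
    return ip.ProbeCountMatrix(counts=frame.astype(np.int64), probe_info=info)
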