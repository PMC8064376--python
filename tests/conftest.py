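"""Shared fixtures: one simulated trial at the default study conditions,
reused (read-only) across test modules to keep the suite fast."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import peepkit as pk


@pytest.fixture(scope="session")
def default_trial():
    """Default two-arm trial (10 case / 14 control, planted -3 SD module)."""
    design = pk.TrialDesign(seed=0)
    matrix, meta, truth = pk.simulate_trial(design)
    return design, matrix, meta, truth


@pytest.fixture(scope="session")
def default_analysis(default_trial):
    """DE, panel and profiles for the default trial."""
    _, matrix, meta, truth = default_trial
    case_de = pk.paired_t(matrix, meta, "case")
    control_de = pk.paired_t(matrix, meta, "control")
    panel = pk.placebo_filter(case_de, control_de)
    reference = pk.fit_reference(matrix, meta, panel.panel)
    profiles = pk.compute_profiles(matrix, meta, reference)
    return {
        "case_de": case_de,
        "control_de": control_de,
        "panel": panel,
        "reference": reference,
        "profiles": profiles,
    }


def make_matrix(values, genes=None, samples=None) -> pk.ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    return pk.ExpressionMatrix(
        pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=samples)
    )


def make_metadata(rows) -> pk.TrialMetadata:
    """rows: (sample_id, subject_id, arm, timepoint[, fev1_pre, fev1_post])."""
    records = []
    for row in rows:
        sid, subj, arm, tp, *fev = row
        pre, post = (fev + [np.nan, np.nan])[:2]
        records.append(
            {
                "sample_id": sid,
                "subject_id": subj,
                "arm": arm,
                "timepoint": tp,
                "fev1_pre": pre,
                "fev1_post": post,
            }
        )
    return pk.TrialMetadata(pd.DataFrame(records).set_index("sample_id"))
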