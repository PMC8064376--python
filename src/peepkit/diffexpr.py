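"""Paired pre/post differential expression per arm and the placebo-concordance filter.

Per gene, a one-sample t-test is applied to the per-subject expression deltas
(post − pre) within an arm.  Benjamini–Hochberg q-values are computed and
reported alongside, but the treatment-unique gene panel is gated on the
NOMINAL p ≤ alpha (default 0.05): a gene enters the panel when it is
significant in the treated arm, unless it is also significant in the placebo
arm with the same direction of effect — such concordant genes are presumed
placebo/repeat-measurement effects and removed.

Degenerate genes (zero delta variance) are flagged and assigned p = 1;
genes with missing values are excluded up front (logged count), since
small-sample t statistics are undefined for them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .dataio import ExpressionMatrix, TrialMetadata, ValidationError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DEResult:
    """Per-gene paired-t differential expression for one arm.

    ``table`` is indexed by gene with columns ``mean_delta``, ``t``,
    ``p_value``, ``q_value``, ``n_pairs``, ``direction`` (sign of
    ``mean_delta``) and ``zero_variance``.
    """

    arm: str
    table: pd.DataFrame
    n_pairs: int
    n_excluded_missing: int = 0

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)

    def significant(self, alpha: float, use_q: bool = False) -> set[str]:
        col = "q_value" if use_q else "p_value"
        return set(self.table.index[self.table[col] <= alpha])


def paired_deltas(matrix: ExpressionMatrix, meta: TrialMetadata, arm: str) -> pd.DataFrame:
    """Per-subject post − pre deltas (genes × subjects) for one arm."""
    subjects = meta.paired_subjects(arm)
    if len(subjects) < 2:
        raise ValidationError(f"arm {arm!r} has {len(subjects)} complete pre/post pairs; need >= 2")
    pre = [meta.sample_id(s, "pre") for s in subjects]
    post = [meta.sample_id(s, "post") for s in subjects]
    delta = matrix.data[post].to_numpy() - matrix.data[pre].to_numpy()
    return pd.DataFrame(delta, index=matrix.data.index, columns=subjects)


def paired_t(matrix: ExpressionMatrix, meta: TrialMetadata, arm: str) -> DEResult:
    """Two-sided paired t-test per gene on post − pre deltas within an arm."""
    complete, n_excluded = matrix.complete_genes()
    deltas = paired_deltas(complete, meta, arm)
    n = deltas.shape[1]
    values = deltas.to_numpy()
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    zero_var = sd == 0.0
    t = np.zeros_like(mean)
    np.divide(mean, sd / np.sqrt(n), out=t, where=~zero_var)
    p = np.ones_like(mean)
    p[~zero_var] = 2.0 * stats.t.sf(np.abs(t[~zero_var]), df=n - 1)
    q = bh_adjust(p)
    table = pd.DataFrame(
        {
            "mean_delta": mean,
            "t": t,
            "p_value": p,
            "q_value": q,
            "n_pairs": n,
            "direction": np.sign(mean).astype(int),
            "zero_variance": zero_var,
        },
        index=deltas.index,
    )
    if zero_var.any():
        log.info("arm %s: %d genes with zero delta variance flagged (p=1)", arm, int(zero_var.sum()))
    return DEResult(arm=arm, table=table, n_pairs=n, n_excluded_missing=n_excluded)


def bh_adjust(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (clipped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValidationError("bh_adjust expects a non-empty 1-d array")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class PanelResult:
    """Treatment-unique gene panel after the placebo-concordance filter."""

    panel: tuple[str, ...]
    removed: tuple[str, ...]
    n_case_significant: int
    alpha: float

    @property
    def panel_set(self) -> set[str]:
        return set(self.panel)


def placebo_filter(
    case_de: DEResult,
    control_de: DEResult,
    alpha: float = 0.05,
    control_alpha: float | None = None,
) -> PanelResult:
    """Remove placebo-concordant genes from the treated-arm significant set.

    A gene is removed when it is significant in both arms (nominal p ≤ alpha;
    the placebo arm may use its own ``control_alpha``) AND its mean delta has
    the same sign in both arms.  Genes significant in both arms with opposite
    directions are retained.
    """
    control_alpha = alpha if control_alpha is None else control_alpha
    case_genes = set(case_de.table.index)
    control_genes = set(control_de.table.index)
    if case_genes != control_genes:
        missing = sorted((case_genes ^ control_genes))[:10]
        raise ValidationError(f"DE results cover different gene universes; e.g. {missing}")
    case_tab = case_de.table
    ctrl_tab = control_de.table.loc[case_tab.index]
    sig_case = case_tab["p_value"] <= alpha
    concordant = (
        sig_case
        & (ctrl_tab["p_value"] <= control_alpha)
        & (case_tab["direction"] != 0)
        & (case_tab["direction"] == ctrl_tab["direction"])
    )
    panel_mask = sig_case & ~concordant
    panel = tuple(case_tab.index[panel_mask])
    removed = tuple(case_tab.index[concordant])
    log.info(
        "placebo filter: %d case-significant genes, %d removed as placebo-concordant, %d retained",
        int(sig_case.sum()),
        len(removed),
        len(panel),
    )
    return PanelResult(
        panel=panel, removed=removed, n_case_significant=int(sig_case.sum()), alpha=alpha
    )
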