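"""Responder stratification by FEV1 change and hierarchical clustering of PEEPs.

Subjects are stratified by relative FEV1 percent change,
``100 * (post - pre) / pre``:

* strong responder: change > 20
* weak responder:   5 <= change <= 10
* non-responder:    change < 5
* intermediate:     10 < change <= 20 (a gap interval the emulated trial left
  unpopulated; labelled explicitly rather than silently merged)

Perturbation profiles are clustered agglomeratively with average linkage
(UPGMA) on Euclidean distances between z-score vectors; agreement between a
flat cut of the tree and the FEV1 strata is summarized with the adjusted Rand
index and a contingency table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.metrics import adjusted_rand_score

from .dataio import TrialMetadata, ValidationError
from .peep import PeepProfile, profiles_to_frame

log = logging.getLogger(__name__)

STRATUM_LABELS = ("strong", "weak", "non", "intermediate")


@dataclass(frozen=True)
class StrataCutoffs:
    """FEV1 percent-change boundaries (strong strictly above ``strong_gt``;
    weak closed on ``[weak_low, weak_high]``; non strictly below ``weak_low``)."""

    strong_gt: float = 20.0
    weak_low: float = 5.0
    weak_high: float = 10.0

    def classify(self, change_pct: float) -> str:
        if not np.isfinite(change_pct):
            return "unassigned"
        if change_pct > self.strong_gt:
            return "strong"
        if self.weak_low <= change_pct <= self.weak_high:
            return "weak"
        if change_pct < self.weak_low:
            return "non"
        return "intermediate"


@dataclass(frozen=True)
class ResponderAssignment:
    subject_id: str
    fev1_change_pct: float
    stratum: str


def assign_strata(
    meta: TrialMetadata,
    cutoffs: StrataCutoffs = StrataCutoffs(),
    arm: str | None = "case",
) -> list[ResponderAssignment]:
    """Per-subject FEV1 percent change and stratum label.

    Subjects with missing FEV1 are flagged ``unassigned`` (and logged);
    ``fev1_pre`` must be positive where present.
    """
    fev1 = meta.fev1()
    if arm is not None:
        fev1 = fev1[fev1["arm"] == arm]
    out: list[ResponderAssignment] = []
    for subject, row in fev1.iterrows():
        pre, post = row["fev1_pre"], row["fev1_post"]
        if pd.isna(pre) or pd.isna(post):
            log.warning("subject %s has missing FEV1; unassigned", subject)
            out.append(ResponderAssignment(str(subject), float("nan"), "unassigned"))
            continue
        if pre <= 0:
            raise ValidationError(f"subject {subject}: fev1_pre must be > 0, got {pre}")
        change = 100.0 * (post - pre) / pre
        out.append(ResponderAssignment(str(subject), float(change), cutoffs.classify(change)))
    counts = pd.Series([a.stratum for a in out]).value_counts().to_dict()
    log.info("strata counts: %s", counts)
    return out


def strata_to_frame(assignments: Sequence[ResponderAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": [a.subject_id for a in assignments],
            "fev1_change_pct": [a.fev1_change_pct for a in assignments],
            "stratum": [a.stratum for a in assignments],
        }
    ).set_index("subject_id")


@dataclass(frozen=True)
class ClusterTree:
    """Average-linkage tree over subjects; ``linkage`` is a scipy linkage matrix."""

    linkage: np.ndarray
    leaves: tuple[str, ...]

    def __post_init__(self) -> None:
        heights = self.linkage[:, 2]
        if np.any(np.diff(heights) < -1e-10):
            raise ValidationError("linkage heights must be non-decreasing")

    def cut(self, k: int) -> dict[str, int]:
        """Flat labels (1..k) from a maxclust cut of the tree."""
        if not 1 <= k <= len(self.leaves):
            raise ValidationError(f"k must be in [1, {len(self.leaves)}]")
        labels = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return dict(zip(self.leaves, (int(v) for v in labels)))

    def leaf_order(self) -> list[str]:
        return [self.leaves[i] for i in hierarchy.leaves_list(self.linkage)]


def cluster_profiles(profiles: Sequence[PeepProfile]) -> ClusterTree:
    """UPGMA tree on Euclidean distances between subjects' z-vectors.

    All profiles must cover the same gene panel; the merge order is the
    deterministic order scipy produces for the given input (ties between
    equal distances are resolved by scipy's internal candidate order).
    """
    if len(profiles) < 2:
        raise ValidationError("clustering needs >= 2 profiles")
    panel = set(profiles[0].z.index)
    for profile in profiles[1:]:
        if set(profile.z.index) != panel:
            raise ValidationError(
                f"profile {profile.subject_id!r} covers a different gene panel"
            )
    frame = profiles_to_frame(profiles)
    data = frame.to_numpy().T  # subjects × genes
    linkage = hierarchy.linkage(data, method="average", metric="euclidean")
    return ClusterTree(linkage=linkage, leaves=tuple(str(c) for c in frame.columns))


@dataclass(frozen=True)
class ConcordanceResult:
    ari: float
    contingency: pd.DataFrame
    k: int


def concordance(
    tree: ClusterTree, assignments: Sequence[ResponderAssignment], k: int = 3
) -> ConcordanceResult:
    """Adjusted Rand index and contingency table between a flat cut and strata."""
    strata = {a.subject_id: a.stratum for a in assignments}
    missing = [leaf for leaf in tree.leaves if leaf not in strata]
    if missing:
        raise ValidationError(f"no stratum for subjects: {missing}")
    flat = tree.cut(k)
    cluster_labels = [flat[leaf] for leaf in tree.leaves]
    stratum_labels = [strata[leaf] for leaf in tree.leaves]
    ari = float(adjusted_rand_score(stratum_labels, cluster_labels))
    table = pd.crosstab(
        pd.Series(stratum_labels, name="stratum"), pd.Series(cluster_labels, name="cluster")
    )
    return ConcordanceResult(ari=ari, contingency=table, k=k)


def plot_profile_heatmap(profiles: Sequence[PeepProfile], path: str, tree: ClusterTree | None = None):
    """Optional z-score heatmap (subjects ordered by the tree if given)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = profiles_to_frame(profiles)
    if tree is not None:
        frame = frame[tree.leaf_order()]
    fig, ax = plt.subplots(figsize=(max(4, 0.5 * frame.shape[1]), 6))
    vmax = float(np.nanmax(np.abs(frame.to_numpy()))) or 1.0
    im = ax.imshow(frame.to_numpy(), aspect="auto", cmap="RdBu_r", vmin=-vmax, vmax=vmax)
    ax.set_xticks(range(frame.shape[1]), frame.columns, rotation=90, fontsize=7)
    ax.set_yticks([])
    ax.set_ylabel(f"{frame.shape[0]} panel genes")
    fig.colorbar(im, ax=ax, label="perturbation z-score")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
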