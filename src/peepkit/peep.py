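"""Personalized perturbation profiles (PEEPs).

For every treated subject, each gene of a panel is scored against a reference
distribution of that gene's expression in control samples:

    z(g) = (x_post(g) - mean_ref(g)) / sd_ref(g)

so z is positive when the gene is over-expressed relative to the reference
and negative otherwise.  Genes with |z| >= 2 (inclusive) are called perturbed
— up-regulated at z >= 2, repressed at z <= -2.

Three reference choices are supported, because the methodology is described
both against the placebo group and against the pre-treatment population:

``control_post``
    placebo-arm post-treatment samples (default),
``control_all``
    all placebo-arm samples (pre and post pooled),
``case_pre``
    treated-arm pre-treatment samples.

The reference SD is the sample SD (ddof=1); with few reference samples the
null z is slightly heavy-tailed relative to N(0, 1) — the exact null
exceedance of the |z| >= 2 call is ``2 * P(t_{n-1} > 2 / sqrt(1 + 1/n))``
for n reference samples.  No t-correction is applied: the score is the plain
z the method defines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .dataio import ExpressionMatrix, TrialMetadata, ValidationError

log = logging.getLogger(__name__)

ReferenceMode = Literal["control_post", "control_all", "case_pre"]
REFERENCE_MODES = ("control_post", "control_all", "case_pre")


@dataclass(frozen=True)
class ReferenceDistribution:
    """Per-gene reference mean/SD fitted from control samples.

    ``table`` is indexed by panel gene with columns ``location``, ``scale``,
    ``n_reference`` and ``usable`` (scale > 0 and n_reference >= 3).
    """

    table: pd.DataFrame
    mode: str

    @property
    def usable_genes(self) -> list[str]:
        return list(self.table.index[self.table["usable"]])


def _reference_samples(meta: TrialMetadata, mode: str) -> list[str]:
    if mode == "control_post":
        return meta.samples_for(arm="control", timepoint="post")
    if mode == "control_all":
        return meta.samples_for(arm="control")
    if mode == "case_pre":
        return meta.samples_for(arm="case", timepoint="pre")
    raise ValidationError(f"unknown reference_mode {mode!r}; expected one of {REFERENCE_MODES}")


def fit_reference(
    matrix: ExpressionMatrix,
    meta: TrialMetadata,
    panel: Sequence[str],
    reference_mode: ReferenceMode = "control_post",
) -> ReferenceDistribution:
    """Fit per-gene reference mean and sample SD over the chosen samples."""
    panel = list(panel)
    missing = [g for g in panel if g not in matrix.data.index]
    if missing:
        raise ValidationError(f"panel genes not in matrix: {missing[:10]}")
    samples = _reference_samples(meta, reference_mode)
    if len(samples) < 3:
        raise ValidationError(
            f"reference_mode {reference_mode!r} yields {len(samples)} samples; need >= 3"
        )
    ref = matrix.data.loc[panel, samples]
    n_ref = ref.notna().sum(axis=1)
    location = ref.mean(axis=1)
    scale = ref.std(axis=1, ddof=1)
    usable = (scale > 0) & (n_ref >= 3)
    n_unusable = int((~usable).sum())
    if n_unusable:
        log.info("reference: %d panel genes unusable (zero SD or n < 3)", n_unusable)
    table = pd.DataFrame(
        {"location": location, "scale": scale, "n_reference": n_ref, "usable": usable}
    )
    return ReferenceDistribution(table=table, mode=reference_mode)


@dataclass(frozen=True)
class PeepProfile:
    """One treated subject's perturbation profile over the usable panel."""

    subject_id: str
    z: pd.Series
    threshold: float = 2.0

    def __post_init__(self) -> None:
        if self.up_calls & self.down_calls:
            raise ValidationError("up and down calls overlap")

    @property
    def up_calls(self) -> frozenset[str]:
        finite = self.z[np.isfinite(self.z)]
        return frozenset(finite.index[finite >= self.threshold])

    @property
    def down_calls(self) -> frozenset[str]:
        finite = self.z[np.isfinite(self.z)]
        return frozenset(finite.index[finite <= -self.threshold])

    def calls(self, direction: str) -> frozenset[str]:
        if direction == "up":
            return self.up_calls
        if direction == "down":
            return self.down_calls
        raise ValidationError(f"direction must be 'up' or 'down', got {direction!r}")


def compute_profiles(
    matrix: ExpressionMatrix,
    meta: TrialMetadata,
    reference: ReferenceDistribution,
    z_threshold: float = 2.0,
) -> list[PeepProfile]:
    """One PEEP per treated subject with a post-treatment sample.

    Subjects lacking a post sample are skipped with a warning.  z-scores are
    computed only for usable reference genes; the profile's index is that
    usable panel, identical (and identically ordered) across subjects.
    """
    genes = reference.usable_genes
    if not genes:
        raise ValidationError("reference distribution has no usable genes")
    loc = reference.table.loc[genes, "location"].to_numpy()
    scale = reference.table.loc[genes, "scale"].to_numpy()
    profiles: list[PeepProfile] = []
    for subject in meta.subjects(arm="case"):
        post = meta.sample_id(subject, "post")
        if post is None:
            log.warning("subject %s has no post-treatment sample; skipped", subject)
            continue
        x = matrix.data.loc[genes, post].to_numpy()
        z = pd.Series((x - loc) / scale, index=pd.Index(genes, name="gene"), name=subject)
        profiles.append(PeepProfile(subject_id=subject, z=z, threshold=z_threshold))
    return profiles


def shared_calls(profiles: Iterable[PeepProfile], direction: str = "down") -> frozenset[str]:
    """Genes called in the given direction by EVERY profile (set intersection)."""
    profiles = list(profiles)
    if not profiles:
        raise ValidationError("shared_calls needs at least one profile")
    shared = profiles[0].calls(direction)
    for profile in profiles[1:]:
        shared &= profile.calls(direction)
    return shared


def union_calls(profiles: Iterable[PeepProfile], direction: str = "down") -> frozenset[str]:
    """Genes called in the given direction by ANY profile (set union)."""
    profiles = list(profiles)
    if not profiles:
        raise ValidationError("union_calls needs at least one profile")
    out: frozenset[str] = frozenset()
    for profile in profiles:
        out |= profile.calls(direction)
    return out


def profiles_to_frame(profiles: Sequence[PeepProfile]) -> pd.DataFrame:
    """z-score matrix, genes × subjects, from a list of profiles."""
    if not profiles:
        raise ValidationError("no profiles to assemble")
    frame = pd.concat([p.z for p in profiles], axis=1)
    frame.columns = [p.subject_id for p in profiles]
    frame.index.name = "gene"
    return frame


def profiles_from_frame(frame: pd.DataFrame, z_threshold: float = 2.0) -> list[PeepProfile]:
    """Rebuild profiles from a serialized z-score matrix (genes × subjects)."""
    return [
        PeepProfile(subject_id=str(col), z=frame[col], threshold=z_threshold)
        for col in frame.columns
    ]
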