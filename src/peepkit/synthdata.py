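"""Synthetic placebo-controlled paired expression trials with known ground truth.

The generator emulates the study design this package analyzes: a two-arm
randomized trial (default 10 treated, 14 placebo subjects) with one pre- and
one post-treatment expression sample per subject, a planted treatment-
responsive gene module that is repressed in a subgroup of "responder"
subjects, planted placebo-drift genes that shift in BOTH arms, a continuous
lung-function (FEV1) change per subject consistent with its responder
stratum, and — via :func:`simulate_network` — a functional interaction
network in which the planted module sits within two edges of a designated
target gene family.

Expression model (already-normalized, log-scale values)::

    x[g, (s, t)] = mu_g + b_s + effect[g, s, t] + eps

with per-gene baselines ``mu_g ~ N(baseline_mean, baseline_sd)``, subject
intercepts ``b_s ~ N(0, subject_sd)`` shared between a subject's pre and post
samples, and iid residual noise ``eps ~ N(0, noise_sd)``.  Perturbation
amplitudes (``module_effect``, ``placebo_effect``) are expressed in units of
the total between-sample SD of a gene, ``sqrt(noise_sd^2 + subject_sd^2)`` —
the scale on which perturbation z-scores against a control reference are
defined, so a ``-3`` plant has expected z of ``-3``.

Responder strata scale the module amplitude: strong responders receive the
full ``module_effect``, weak responders one third of it, non-responders none.
FEV1 percent change is drawn uniformly inside each stratum's interval
(strong > 20%, weak 5–10%, non-responder < 5%); the 10–20% "intermediate"
band is left unpopulated, matching the trial this design emulates.

All outputs are deterministic functions of the design's ``seed``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
import networkx as nx
import numpy as np
import pandas as pd

from .dataio import ExpressionMatrix, GeneSet, TrialMetadata, ValidationError

log = logging.getLogger(__name__)

STRATA = ("strong", "weak", "non")

#: module amplitude multiplier per stratum (monotone in clinical response)
STRATUM_SCALE = {"strong": 1.0, "weak": 1.0 / 3.0, "non": 0.0}

#: FEV1 percent-change sampling interval per stratum; strata are defined as
#: strong > 20, weak in [5, 10], non < 5, so the draws keep a safety margin
#: away from the boundaries.
STRATUM_FEV1_RANGE = {"strong": (22.0, 40.0), "weak": (5.5, 9.5), "non": (-4.0, 4.0)}


class DesignError(ValueError):
    """A trial design is internally inconsistent or infeasible."""


@dataclass(frozen=True)
class TrialDesign:
    """Parameters of a simulated two-arm paired trial (see module docstring)."""

    n_case: int = 10
    n_control: int = 14
    n_genes: int = 2000
    n_module_genes: int = 50
    module_effect: float = -3.0
    n_placebo_genes: int = 30
    placebo_effect: float = 2.5
    strata_fractions: tuple[float, float, float] = (0.2, 0.3, 0.5)
    noise_sd: float = 1.0
    subject_sd: float = 0.5
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    n_target_genes: int = 5
    fev1_pre_range: tuple[float, float] = (55.0, 85.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_case", "n_control", "n_genes", "n_module_genes", "n_target_genes"):
            if getattr(self, name) <= 0:
                raise DesignError(f"{name} must be > 0")
        if self.n_placebo_genes < 0:
            raise DesignError("n_placebo_genes must be >= 0")
        if self.n_module_genes + self.n_placebo_genes + self.n_target_genes > self.n_genes:
            raise DesignError("planted gene counts exceed n_genes")
        if len(self.strata_fractions) != len(STRATA):
            raise DesignError(f"strata_fractions needs {len(STRATA)} entries {STRATA}")
        if any(f < 0 for f in self.strata_fractions):
            raise DesignError("strata_fractions must be non-negative")
        if abs(sum(self.strata_fractions) - 1.0) > 1e-9:
            raise DesignError("strata_fractions must sum to 1")
        if self.noise_sd <= 0:
            raise DesignError("noise_sd must be > 0")
        if self.subject_sd < 0:
            raise DesignError("subject_sd must be >= 0")

    @property
    def total_sd(self) -> float:
        """Between-sample SD of a gene: the unit of the planted effects."""
        return float(np.hypot(self.noise_sd, self.subject_sd))

    def stratum_sizes(self) -> dict[str, int]:
        """Largest-remainder apportionment of treated subjects to strata.

        A stratum with positive fraction must receive at least one subject;
        otherwise the design is infeasible.
        """
        raw = [f * self.n_case for f in self.strata_fractions]
        sizes = [int(np.floor(r)) for r in raw]
        remainder = self.n_case - sum(sizes)
        order = np.argsort([-(r - s) for r, s in zip(raw, sizes)], kind="stable")
        for i in range(remainder):
            sizes[order[i]] += 1
        result = dict(zip(STRATA, sizes))
        for stratum, frac in zip(STRATA, self.strata_fractions):
            if frac > 0 and result[stratum] == 0:
                raise DesignError(
                    f"stratum {stratum!r} has fraction {frac} but zero subjects at n_case={self.n_case}"
                )
        return result


@dataclass(frozen=True)
class GroundTruth:
    """What was planted: module/placebo/target genes, strata and FEV1 changes."""

    module_genes: frozenset[str]
    placebo_genes: frozenset[str]
    target_set: frozenset[str]
    subject_strata: dict[str, str]
    subject_fev1_change: dict[str, float]
    gene_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.module_genes & self.placebo_genes:
            raise ValidationError("module and placebo gene sets overlap")
        for subject, stratum in self.subject_strata.items():
            change = self.subject_fev1_change[subject]
            lo, hi = {"strong": (20.0, np.inf), "weak": (5.0, 10.0), "non": (-np.inf, 5.0)}[stratum]
            if not (lo <= change <= hi) and not (stratum == "strong" and change > 20.0):
                raise ValidationError(
                    f"subject {subject}: FEV1 change {change:.2f}% inconsistent with stratum {stratum!r}"
                )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "module_genes": sorted(self.module_genes),
            "placebo_genes": sorted(self.placebo_genes),
            "target_set": sorted(self.target_set),
            "subject_strata": self.subject_strata,
            "subject_fev1_change": self.subject_fev1_change,
            "gene_ids": list(self.gene_ids),
        }
        Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            module_genes=frozenset(payload["module_genes"]),
            placebo_genes=frozenset(payload["placebo_genes"]),
            target_set=frozenset(payload["target_set"]),
            subject_strata=dict(payload["subject_strata"]),
            subject_fev1_change={k: float(v) for k, v in payload["subject_fev1_change"].items()},
            gene_ids=tuple(payload["gene_ids"]),
        )


# ---------------------------------------------------------------------------
# trial simulation
# ---------------------------------------------------------------------------


def simulate_trial(design: TrialDesign) -> tuple[ExpressionMatrix, TrialMetadata, GroundTruth]:
    """Simulate expression, metadata and ground truth for one trial."""
    rng = np.random.default_rng(design.seed)
    genes = [f"G{i:05d}" for i in range(design.n_genes)]

    n_planted = design.n_module_genes + design.n_placebo_genes + design.n_target_genes
    planted = rng.choice(design.n_genes, size=n_planted, replace=False)
    module = [genes[i] for i in planted[: design.n_module_genes]]
    placebo = [genes[i] for i in planted[design.n_module_genes : design.n_module_genes + design.n_placebo_genes]]
    target = [genes[i] for i in planted[design.n_module_genes + design.n_placebo_genes :]]

    case_subjects = [f"case{i + 1:02d}" for i in range(design.n_case)]
    control_subjects = [f"ctrl{i + 1:02d}" for i in range(design.n_control)]
    sizes = design.stratum_sizes()
    strata_labels = [s for s in STRATA for _ in range(sizes[s])]
    subject_strata = dict(zip(case_subjects, strata_labels))

    fev1_change: dict[str, float] = {}
    fev1_pre: dict[str, float] = {}
    for subject in case_subjects + control_subjects:
        lo, hi = STRATUM_FEV1_RANGE[subject_strata.get(subject, "non")]
        fev1_change[subject] = float(rng.uniform(lo, hi))
        fev1_pre[subject] = float(rng.uniform(*design.fev1_pre_range))

    mu = rng.normal(design.baseline_mean, design.baseline_sd, size=design.n_genes)
    subjects = case_subjects + control_subjects
    b = dict(zip(subjects, rng.normal(0.0, design.subject_sd, size=len(subjects))))

    sample_ids: list[str] = []
    rows: list[dict] = []
    for subject in subjects:
        arm = "case" if subject in subject_strata else "control"
        pre = fev1_pre[subject]
        post = pre * (1.0 + fev1_change[subject] / 100.0)
        for tp in ("pre", "post"):
            sid = f"{subject}_{tp}"
            sample_ids.append(sid)
            rows.append(
                {
                    "sample_id": sid,
                    "subject_id": subject,
                    "arm": arm,
                    "timepoint": tp,
                    "fev1_pre": pre,
                    "fev1_post": post,
                }
            )

    module_idx = np.array([genes.index(g) for g in module], dtype=int)
    placebo_idx = np.array([genes.index(g) for g in placebo], dtype=int)

    unit = design.total_sd
    values = np.empty((design.n_genes, len(sample_ids)))
    for j, row in enumerate(rows):
        col = mu + b[row["subject_id"]]
        if row["timepoint"] == "post":
            col = col.copy()
            col[placebo_idx] += design.placebo_effect * unit
            if row["arm"] == "case":
                scale = STRATUM_SCALE[subject_strata[row["subject_id"]]]
                col[module_idx] += design.module_effect * unit * scale
        values[:, j] = col + rng.normal(0.0, design.noise_sd, size=design.n_genes)

    matrix = ExpressionMatrix(pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=sample_ids))
    meta = TrialMetadata(pd.DataFrame(rows).set_index("sample_id"))
    truth = GroundTruth(
        module_genes=frozenset(module),
        placebo_genes=frozenset(placebo),
        target_set=frozenset(target),
        subject_strata=subject_strata,
        subject_fev1_change={s: fev1_change[s] for s in subjects},
        gene_ids=tuple(genes),
    )
    return matrix, meta, truth


# ---------------------------------------------------------------------------
# network simulation
# ---------------------------------------------------------------------------


def simulate_network(
    truth: GroundTruth,
    n_nodes: int | None = None,
    attach_param: int = 3,
    seed: int = 0,
    module_density: float = 0.2,
) -> nx.Graph:
    """Simulate a connected, scale-free-like functional interaction network.

    ``n_nodes`` defaults to the full gene universe: functional interaction
    networks cover essentially the whole measured transcriptome, and partial
    coverage makes closest-distance means degenerate (they would be computed
    over the few mapped genes only).

    Geometry: the planted module forms a star (hub = lexicographically first
    module gene) densified with random intra-module edges (``module_density``
    — functional modules are locally dense, so subsets of the module remain
    largely connected); every target-family gene attaches to the hub, so
    every module gene is within two hops of the target set.  The remaining
    genes form a preferential-attachment core joined to the module by a
    single bridge edge, which keeps unrelated genes strictly farther from
    the target family than the module is.
    """
    module = sorted(truth.module_genes)
    target = sorted(truth.target_set)
    if n_nodes is None:
        n_nodes = len(truth.gene_ids)
    n_core = n_nodes - len(module) - len(target)
    if n_core < attach_param + 1:
        raise DesignError(
            f"n_nodes={n_nodes} too small for {len(module)} module + {len(target)} target genes "
            f"and a preferential-attachment core of >= {attach_param + 1} nodes"
        )
    rng = np.random.default_rng(seed)
    fill_genes = [g for g in truth.gene_ids if g not in truth.module_genes and g not in truth.target_set]
    if len(fill_genes) < n_core:
        raise DesignError("gene universe too small for requested n_nodes")
    core_genes = fill_genes[:n_core]

    core = nx.barabasi_albert_graph(n_core, attach_param, seed=int(rng.integers(2**31)))
    graph: nx.Graph = nx.relabel_nodes(core, dict(enumerate(core_genes)))

    hub = module[0]
    for gene in module[1:]:
        graph.add_edge(hub, gene)
    for i, a in enumerate(module):
        for b in module[i + 1 :]:
            if rng.uniform() < module_density:
                graph.add_edge(a, b)
    for gene in target:
        graph.add_edge(hub, gene)
    bridge = core_genes[int(rng.integers(n_core))]
    graph.add_edge(hub, bridge)

    for a, b in graph.edges:
        graph.edges[a, b]["weight"] = float(rng.uniform(0.5, 1.0))

    assert nx.is_connected(graph)
    return graph


# ---------------------------------------------------------------------------
# gene-set simulation
# ---------------------------------------------------------------------------

PLANTED_SET_NAME = "planted_module_pathway"


def simulate_genesets(
    truth: GroundTruth,
    n_sets: int = 50,
    set_size_range: tuple[int, int] = (10, 50),
    seed: int = 0,
) -> dict[str, GeneSet]:
    """A GMT-style collection whose first set is exactly the planted module.

    The remaining ``n_sets - 1`` sets are drawn uniformly at random (without
    replacement within a set) from the full gene universe.
    """
    if n_sets < 1:
        raise DesignError("n_sets must be >= 1")
    lo, hi = set_size_range
    if lo < 1 or hi < lo:
        raise DesignError("invalid set_size_range")
    universe = list(truth.gene_ids)
    if hi > len(universe):
        raise DesignError(f"set sizes up to {hi} exceed gene universe of {len(universe)}")
    rng = np.random.default_rng(seed)
    collection: dict[str, GeneSet] = {
        PLANTED_SET_NAME: GeneSet(
            PLANTED_SET_NAME, "planted treatment-responsive module", frozenset(truth.module_genes)
        )
    }
    for i in range(n_sets - 1):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(len(universe), size=size, replace=False)
        name = f"random_set_{i + 1:03d}"
        collection[name] = GeneSet(name, "random background set", frozenset(universe[j] for j in members))
    return collection
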