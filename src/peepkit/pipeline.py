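"""End-to-end orchestration of the perturbation-profiling analysis.

Stage order mirrors how the analysis is run on a real trial:

1. paired differential expression in each arm (post − pre, paired t),
2. placebo-concordance filter → the treatment-unique gene panel,
3. personalized perturbation profiles (z vs. control reference) on the panel,
4. FEV1 responder strata + average-linkage clustering of the profiles,
5. per-stratum shared calls and hypergeometric pathway enrichment,
6. network proximity of the strong-responder shared repressed genes, and of
   the non-responders' perturbed genes, to a user-supplied target gene family.

Every stage is also runnable standalone (see :mod:`peepkit.cli`) on the
previous stage's serialized outputs, and every output table carries the
configuration hash in a ``#``-comment header.

``welch_from_summary`` / ``check_baseline_table`` provide the usual
baseline-table sanity check: a Welch two-sample t-test from published
summary statistics (mean ± SD, n per arm), with the Welch–Satterthwaite
degrees of freedom.  ``BASELINE_SUMMARY`` ships the baseline characteristics
of the imatinib vs. placebo severe-asthma trial arms this package's
synthetic generator emulates.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import dataio, diffexpr, enrich, netprox, peep, stratify
from .dataio import ValidationError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Paths and thresholds for a full pipeline run."""

    expression_path: str
    metadata_path: str
    gmt_path: str
    network_path: str
    target_genes: tuple[str, ...]
    output_dir: str
    alpha: float = 0.05
    z_threshold: float = 2.0
    reference_mode: str = "control_post"
    strong_gt: float = 20.0
    weak_low: float = 5.0
    weak_high: float = 10.0
    enrichment_q: float = 0.05
    n_clusters: int = 3
    n_permutations: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.enrichment_q <= 0:
            raise ValidationError("alpha and enrichment_q must be positive")
        if self.z_threshold <= 0:
            raise ValidationError("z_threshold must be positive")
        if self.reference_mode not in peep.REFERENCE_MODES:
            raise ValidationError(f"reference_mode must be one of {peep.REFERENCE_MODES}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        payload["target_genes"] = tuple(payload.get("target_genes", ()))
        return cls(**payload)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


def run_all(config: RunConfig) -> dict:
    """Execute every stage in order; returns (and writes) the run report."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta_header = {"config_hash": config.config_hash()}

    def stage(name):
        log.info("stage: %s", name)

    try:
        stage("load inputs")
        matrix = dataio.read_expression(config.expression_path)
        meta = dataio.read_metadata(config.metadata_path)
        matrix, meta, alignment = dataio.align_samples(matrix, meta)
        collection = dataio.read_gmt(config.gmt_path)
        network = dataio.read_network(config.network_path)
    except Exception as err:
        raise RuntimeError(f"stage 'load inputs' failed: {err}") from err

    try:
        stage("differential expression")
        case_de = diffexpr.paired_t(matrix, meta, "case")
        control_de = diffexpr.paired_t(matrix, meta, "control")
        write_table(case_de.table, out / "de_case.tsv", meta_header, index_label="gene")
        write_table(control_de.table, out / "de_control.tsv", meta_header, index_label="gene")
    except Exception as err:
        raise RuntimeError(f"stage 'differential expression' failed: {err}") from err

    try:
        stage("placebo filter")
        panel = diffexpr.placebo_filter(case_de, control_de, alpha=config.alpha)
        dataio.write_gene_list(panel.panel, out / "panel.txt")
        dataio.write_gene_list(panel.removed, out / "panel_removed.txt")
    except Exception as err:
        raise RuntimeError(f"stage 'placebo filter' failed: {err}") from err

    try:
        stage("perturbation profiles")
        if not panel.panel:
            raise ValidationError("empty treatment-unique panel; nothing to profile")
        reference = peep.fit_reference(matrix, meta, panel.panel, config.reference_mode)
        profiles = peep.compute_profiles(matrix, meta, reference, config.z_threshold)
        zmat = peep.profiles_to_frame(profiles)
        write_table(
            zmat,
            out / "peep_z.tsv",
            {**meta_header, "reference_mode": config.reference_mode, "z_threshold": config.z_threshold},
            index_label="gene",
        )
        calls_rows = [
            {"subject_id": p.subject_id, "direction": d, "gene": g}
            for p in profiles
            for d in ("up", "down")
            for g in sorted(p.calls(d))
        ]
        write_table(
            pd.DataFrame(calls_rows, columns=["subject_id", "direction", "gene"]),
            out / "peep_calls.tsv",
            meta_header,
            index=False,
        )
    except Exception as err:
        raise RuntimeError(f"stage 'perturbation profiles' failed: {err}") from err

    try:
        stage("stratification and clustering")
        cutoffs = stratify.StrataCutoffs(config.strong_gt, config.weak_low, config.weak_high)
        assignments = stratify.assign_strata(meta, cutoffs)
        write_table(stratify.strata_to_frame(assignments), out / "strata.tsv", meta_header, index_label="subject_id")
        tree = stratify.cluster_profiles(profiles)
        linkage_df = pd.DataFrame(tree.linkage, columns=["left", "right", "height", "size"])
        write_table(linkage_df, out / "linkage.tsv", meta_header, index=False)
        flat = tree.cut(config.n_clusters)
        write_table(
            pd.DataFrame({"subject_id": list(flat), "cluster": list(flat.values())}),
            out / "clusters.tsv",
            meta_header,
            index=False,
        )
        agreement = stratify.concordance(tree, assignments, k=config.n_clusters)
    except Exception as err:
        raise RuntimeError(f"stage 'stratification and clustering' failed: {err}") from err

    try:
        stage("pathway enrichment")
        result = enrich.stratum_enrichment(
            profiles, assignments, collection, q_threshold=config.enrichment_q
        )
        for (stratum, direction), table in result.tables.items():
            write_table(table, out / f"enrichment_{stratum}_{direction}.tsv", meta_header, index=False)
        write_table(result.unique_sets, out / "enrichment_unique.tsv", meta_header, index=False)
    except Exception as err:
        raise RuntimeError(f"stage 'pathway enrichment' failed: {err}") from err

    try:
        stage("network proximity")
        strong_shared = set(result.shared_genes.get(("strong", "down"), frozenset()))
        non_profiles = [
            p
            for p in profiles
            if {a.subject_id: a.stratum for a in assignments}.get(p.subject_id) == "non"
        ]
        non_genes = set(peep.union_calls(non_profiles, "down")) if non_profiles else set()
        proximity_report: dict = {}
        if strong_shared and set(config.target_genes):
            module = netprox.disease_module(strong_shared, network)
            comparison = None
            if non_genes & set(network.nodes):
                comparison = netprox.compare_proximity(
                    strong_shared,
                    non_genes,
                    config.target_genes,
                    network,
                    n_permutations=config.n_permutations,
                    seed=config.seed,
                )
                rows = [
                    {"set": "strong_shared", "gene": g, "min_distance_to_target": d}
                    for g, d in sorted(comparison.result_a.distances.items())
                ] + [
                    {"set": "non_responder", "gene": g, "min_distance_to_target": d}
                    for g, d in sorted(comparison.result_b.distances.items())
                ]
                write_table(pd.DataFrame(rows), out / "proximity_distances.tsv", meta_header, index=False)
            proximity_report = {
                "disease_module_size": len(module.genes),
                "strong_to_target": comparison.result_a.closest_distance if comparison else None,
                "non_to_target": comparison.result_b.closest_distance if comparison else None,
                "strong_closer": comparison.a_closer if comparison else None,
                "strong_z": comparison.z_a if comparison else None,
                "non_z": comparison.z_b if comparison else None,
            }
        else:
            log.info("proximity stage skipped: empty strong shared set or no target genes")
    except Exception as err:
        raise RuntimeError(f"stage 'network proximity' failed: {err}") from err

    strata_counts = pd.Series([a.stratum for a in assignments]).value_counts().to_dict()
    report = {
        "config_hash": config.config_hash(),
        "n_genes": matrix.shape[0],
        "n_samples": matrix.shape[1],
        "samples_dropped": list(alignment.matrix_only + alignment.metadata_only),
        "n_case_pairs": case_de.n_pairs,
        "n_control_pairs": control_de.n_pairs,
        "n_case_significant": panel.n_case_significant,
        "n_placebo_concordant_removed": len(panel.removed),
        "panel_size": len(panel.panel),
        "n_profiles": len(profiles),
        "strata_counts": strata_counts,
        "shared_gene_counts": {
            f"{stratum}_{direction}": len(genes)
            for (stratum, direction), genes in sorted(result.shared_genes.items())
        },
        "unique_pathways": result.unique_sets.to_dict(orient="records"),
        "clustering_ari": agreement.ari,
        "proximity": proximity_report,
    }
    (out / "report.json").write_text(json.dumps(report, indent=1, default=str), encoding="utf-8")
    return report


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    header_meta: Mapping[str, object] | None = None,
    index: bool = True,
    index_label: str | None = None,
) -> None:
    """TSV writer adding ``# key=value`` header comments (config hash etc.)."""
    with open(path, "w", encoding="utf-8") as fh:
        for key, value in (header_meta or {}).items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, sep="\t", index=index, index_label=index_label, float_format="%.17g")


# ---------------------------------------------------------------------------
# baseline-table Welch checks
# ---------------------------------------------------------------------------


def welch_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, float, float]:
    """Welch two-sample t from summary statistics: returns (t, df, p).

    df is the Welch–Satterthwaite approximation; p is two-sided.
    """
    if n1 < 2 or n2 < 2:
        raise ValidationError("Welch t needs n >= 2 per group")
    if sd1 <= 0 or sd2 <= 0:
        raise ValidationError("Welch t needs positive SDs")
    t, p = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=False)
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return float(t), float(df), float(p)


#: Baseline characteristics (mean, SD, n per arm) of the treated vs. placebo
#: arms of the severe-asthma imatinib trial the synthetic generator emulates.
#: Some characteristics were measured on fewer subjects than were enrolled.
BASELINE_SUMMARY: tuple[tuple[str, float, float, int, float, float, int], ...] = (
    ("age_years", 44.0, 7.0, 10, 41.7, 12.3, 14),
    ("log2_methacholine_pc20", 1.29, 1.5, 9, 1.47, 1.3, 14),
    ("fev1_percent_predicted", 71.5, 12.4, 10, 68.3, 11.7, 14),
    ("feno_ppb", 23.4, 11.5, 9, 32.4, 11.0, 14),
    ("peripheral_eosinophils_per_mm3", 6.6, 7.2, 10, 2.95, 7.2, 14),
    ("bal_neutrophils", 4.2, 8.8, 8, 2.3, 5.6, 12),
    ("bal_eosinophils", 0.79, 0.81, 7, 0.54, 0.88, 12),
    ("acq6_score", 1.8, 1.1, 10, 2.2, 1.0, 14),
)


def check_baseline_table(
    rows: Sequence[tuple[str, float, float, int, float, float, int]] = BASELINE_SUMMARY,
) -> pd.DataFrame:
    """Welch t, df and two-sided p for every summary row (arm 1 vs. arm 2)."""
    records = []
    for label, m1, s1, n1, m2, s2, n2 in rows:
        t, df, p = welch_from_summary(m1, s1, n1, m2, s2, n2)
        records.append({"characteristic": label, "t": t, "df": df, "p_value": p})
    return pd.DataFrame(records).set_index("characteristic")
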