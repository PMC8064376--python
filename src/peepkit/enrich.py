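"""Hypergeometric over-representation analysis (ORA) of perturbation calls.

Each gene set of a GMT collection is tested for over-representation in a
query gene set (e.g. the genes commonly repressed within a responder
stratum) with the one-sided upper-tail hypergeometric test, conditioning on
a stated gene universe — by default the PEEP panel, i.e. exactly the genes
eligible to be called.  Sets are intersected with the universe before
testing; Benjamini–Hochberg q-values are computed across the collection.

``stratum_enrichment`` runs the shared-call → ORA cascade per responder
stratum and direction, and reports which sets are significant in exactly one
stratum ("unique" pathways).  An empty shared-call set is a reported
outcome, not an error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

from .dataio import GeneSet, ValidationError
from .peep import PeepProfile, shared_calls
from .diffexpr import bh_adjust
from .stratify import ResponderAssignment

log = logging.getLogger(__name__)

ENRICHMENT_COLUMNS = (
    "set_name",
    "overlap_count",
    "set_size",
    "query_size",
    "universe_size",
    "p_value",
    "q_value",
)


def ora(
    query: Iterable[str],
    collection: Mapping[str, GeneSet],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of ``query`` in each set.

    With universe size M, set size K (after intersection with the universe),
    query size N and overlap k, the p-value is ``P[X >= k]`` for
    ``X ~ Hypergeom(M, K, N)``.  Rows are sorted by p-value (stable in set
    name for ties).
    """
    universe = set(universe)
    query = set(query)
    if not query:
        raise ValidationError("empty query gene set")
    if not universe:
        raise ValidationError("empty gene universe")
    stray = query - universe
    if stray:
        raise ValidationError(f"query genes outside the universe: {sorted(stray)[:10]}")
    if not collection:
        raise ValidationError("empty gene-set collection")
    rows = []
    for name in sorted(collection):
        gene_set = collection[name]
        members = gene_set.genes & universe
        overlap = len(members & query)
        p = float(stats.hypergeom.sf(overlap - 1, len(universe), len(members), len(query)))
        rows.append(
            {
                "set_name": name,
                "overlap_count": overlap,
                "set_size": len(members),
                "query_size": len(query),
                "universe_size": len(universe),
                "p_value": min(p, 1.0),
            }
        )
    table = pd.DataFrame(rows, columns=[c for c in ENRICHMENT_COLUMNS if c != "q_value"])
    table["q_value"] = bh_adjust(table["p_value"].to_numpy())
    table = table.sort_values(["p_value", "set_name"], kind="stable").reset_index(drop=True)
    return table[list(ENRICHMENT_COLUMNS)]


@dataclass(frozen=True)
class StratumEnrichment:
    """Per-(stratum, direction) shared calls, enrichment tables, unique sets."""

    tables: dict[tuple[str, str], pd.DataFrame]
    shared_genes: dict[tuple[str, str], frozenset[str]]
    unique_sets: pd.DataFrame
    q_threshold: float

    def significant(self, stratum: str, direction: str) -> list[str]:
        table = self.tables.get((stratum, direction))
        if table is None or table.empty:
            return []
        return list(table.loc[table["q_value"] <= self.q_threshold, "set_name"])


def stratum_enrichment(
    profiles: Sequence[PeepProfile],
    assignments: Sequence[ResponderAssignment],
    collection: Mapping[str, GeneSet],
    universe: Iterable[str] | None = None,
    directions: Sequence[str] = ("down", "up"),
    q_threshold: float = 0.05,
) -> StratumEnrichment:
    """Shared calls per stratum/direction, ORA on each, and stratum-unique sets.

    The universe defaults to the profiles' gene panel.  Strata with no
    profiled subject are skipped; a stratum whose subjects share no calls
    gets an empty table (that absence is itself a finding).
    """
    if universe is None:
        universe = list(profiles[0].z.index) if profiles else []
    universe = set(universe)
    stratum_of = {a.subject_id: a.stratum for a in assignments}
    by_stratum: dict[str, list[PeepProfile]] = {}
    for profile in profiles:
        stratum = stratum_of.get(profile.subject_id)
        if stratum is None:
            log.warning("no stratum for profiled subject %s; skipped", profile.subject_id)
            continue
        by_stratum.setdefault(stratum, []).append(profile)

    tables: dict[tuple[str, str], pd.DataFrame] = {}
    shared: dict[tuple[str, str], frozenset[str]] = {}
    for stratum, members in sorted(by_stratum.items()):
        for direction in directions:
            genes = shared_calls(members, direction) & universe
            shared[(stratum, direction)] = frozenset(genes)
            if genes:
                tables[(stratum, direction)] = ora(genes, collection, universe)
            else:
                log.info("stratum %s: no shared %s-calls", stratum, direction)
                tables[(stratum, direction)] = pd.DataFrame(columns=list(ENRICHMENT_COLUMNS))

    unique_rows = []
    for direction in directions:
        hits: dict[str, list[str]] = {}
        for stratum in by_stratum:
            table = tables[(stratum, direction)]
            if table.empty:
                continue
            for name in table.loc[table["q_value"] <= q_threshold, "set_name"]:
                hits.setdefault(name, []).append(stratum)
        for name, strata in sorted(hits.items()):
            if len(strata) == 1:
                unique_rows.append(
                    {"direction": direction, "set_name": name, "stratum": strata[0]}
                )
    unique = pd.DataFrame(unique_rows, columns=["direction", "set_name", "stratum"])
    return StratumEnrichment(
        tables=tables, shared_genes=shared, unique_sets=unique, q_threshold=q_threshold
    )
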