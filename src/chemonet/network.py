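"""Gene-interaction network ingestion and drug gene-set overlap statistics.

Per-drug hypersensitive gene sets (from the call table) are compared
pairwise on a common universe of screened genes.  The default overlap
statistic is node-set based: Jaccard index plus a one-sided hypergeometric
upper-tail p-value for the intersection, with Benjamini-Hochberg adjustment
across the drug-pair family.  Network edges serve only as an optional
secondary descriptor (shared-edge count between two sets).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .classify import SENSITIVITY_LEVELS
from .errors import InputError, ParseError
from .scoring import WILDTYPE

logger = logging.getLogger(__name__)

#: Default interaction-confidence floor ("medium confidence" in common
#: functional-interaction databases).
DEFAULT_CONFIDENCE_FLOOR = 0.4


def load_network(
    path,
    confidence_floor: float = DEFAULT_CONFIDENCE_FLOOR,
    annotations=None,
) -> nx.Graph:
    """Load an undirected weighted gene network from an edge-list TSV.

    The file needs >= 3 tab-separated columns: gene_a, gene_b, score, with
    or without a header line.  Scores above 1 are interpreted as the
    0-1000 integer confidence convention of STRING exports and rescaled to
    [0, 1].  Rows below ``confidence_floor`` and self-loops are dropped
    (counts logged); duplicate edges keep the higher score.

    ``annotations`` optionally names a 2-column TSV (gene, ontology_group)
    attached as the ``ontology_group`` node attribute.
    """
    edges: list[tuple[str, str, float]] = []
    with open(path) as fh:
        lines = fh.readlines()
    if not [ln for ln in lines if ln.strip()]:
        raise InputError(f"network file {path} is empty")
    start = 0
    first = lines[0].rstrip("\n").split("\t")
    if len(first) >= 3:
        try:
            float(first[2])
        except ValueError:
            start = 1  # header line
    for lineno, line in enumerate(lines[start:], start=start + 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ParseError(f"{path}:{lineno}: expected >= 3 columns")
        try:
            score = float(parts[2])
        except ValueError as exc:
            raise ParseError(
                f"{path}:{lineno}: non-numeric score {parts[2]!r}"
            ) from exc
        edges.append((parts[0], parts[1], score))

    max_score = max(s for _, _, s in edges)
    if max_score > 1:  # STRING integer convention
        logger.info("rescaling scores from 0-1000 to [0, 1]")
        edges = [(a, b, s / 1000.0) for a, b, s in edges]

    graph = nx.Graph()
    n_low = n_self = 0
    for a, b, score in edges:
        if a == b:
            n_self += 1
            logger.warning("dropping self-loop on %s", a)
            continue
        if score < confidence_floor:
            n_low += 1
            continue
        if graph.has_edge(a, b):
            graph[a][b]["score"] = max(graph[a][b]["score"], score)
        else:
            graph.add_edge(a, b, score=score)
    logger.info(
        "loaded %d edges (%d below confidence floor %.2f, %d self-loops dropped)",
        graph.number_of_edges(), n_low, confidence_floor, n_self,
    )

    if annotations is not None:
        ann = pd.read_csv(
            annotations, sep="\t", header=None, names=["gene", "ontology_group"]
        )
        for gene, group in zip(ann["gene"], ann["ontology_group"]):
            if gene in graph:
                graph.nodes[gene]["ontology_group"] = group
    return graph


def drug_gene_set(
    calls: pd.DataFrame,
    drug: str,
    day: int,
    min_level: str = "weak",
    wildtype: str = WILDTYPE,
) -> frozenset[str]:
    """Genes hypersensitive to ``drug`` at ``day``, at or above ``min_level``.

    Levels order weak < medium < strong; the wild-type reference is
    excluded.
    """
    if min_level not in SENSITIVITY_LEVELS:
        raise InputError(f"min_level must be one of {sorted(SENSITIVITY_LEVELS)}")
    if drug not in set(calls["drug"]):
        raise InputError(f"unknown drug {drug!r}")
    sub = calls[(calls["drug"] == drug) & (calls["day"] == day)]
    if sub.empty:
        raise InputError(f"no calls for drug {drug!r} at day {day}")
    floor = SENSITIVITY_LEVELS[min_level]
    keep = sub["call"].map(SENSITIVITY_LEVELS).fillna(0) >= floor
    return frozenset(sub.loc[keep, "strain"]) - {wildtype}


@dataclass(frozen=True)
class OverlapResult:
    """Set overlap between two drugs' hypersensitive gene sets.

    ``p_hyper`` is the one-sided hypergeometric upper-tail probability of
    drawing an intersection of at least ``k`` genes when sets of sizes
    ``n_a`` and ``n_b`` are sampled without replacement from a universe of
    ``n_universe`` screened genes.
    """

    drug_a: str
    drug_b: str
    n_a: int
    n_b: int
    n_universe: int
    k: int
    jaccard: float
    p_hyper: float


def overlap_stats(
    set_a, set_b, universe, drug_a: str = "A", drug_b: str = "B"
) -> OverlapResult:
    """Jaccard index and hypergeometric overlap p for two gene sets."""
    set_a, set_b, universe = frozenset(set_a), frozenset(set_b), frozenset(universe)
    if not universe:
        raise InputError("universe is empty")
    stray = (set_a | set_b) - universe
    if stray:
        raise InputError(f"genes outside the universe: {sorted(stray)}")
    k = len(set_a & set_b)
    union = len(set_a | set_b)
    jaccard = k / union if union else 0.0
    p = float(hypergeom.sf(k - 1, len(universe), len(set_a), len(set_b)))
    return OverlapResult(
        drug_a=drug_a,
        drug_b=drug_b,
        n_a=len(set_a),
        n_b=len(set_b),
        n_universe=len(universe),
        k=k,
        jaccard=jaccard,
        p_hyper=p,
    )


def overlap_table(gene_sets: dict, universe) -> pd.DataFrame:
    """All pairwise overlaps with BH-adjusted q-values.

    ``gene_sets`` maps drug name -> gene set; the universe defaults to the
    screened mutants, passed explicitly by the caller.
    """
    if len(gene_sets) < 2:
        raise InputError("need >= 2 gene sets for pairwise overlap")
    results = [
        overlap_stats(gene_sets[a], gene_sets[b], universe, a, b)
        for a, b in combinations(sorted(gene_sets), 2)
    ]
    table = pd.DataFrame([vars(r) for r in results])
    table["q_hyper"] = multipletests(table["p_hyper"], method="fdr_bh")[1]
    return table


def shared_edge_count(graph: nx.Graph, set_a, set_b) -> int:
    """Secondary descriptor: network edges joining a gene in A to one in B."""
    set_a, set_b = set(set_a), set(set_b)
    return sum(
        1
        for u, v in graph.edges
        if (u in set_a and v in set_b) or (v in set_a and u in set_b)
    )


def color_nodes_by_drug(graph: nx.Graph, gene_sets: dict) -> nx.Graph:
    """Attach per-drug membership attributes for external visualization."""
    out = graph.copy()
    for drug, genes in gene_sets.items():
        for node in out.nodes:
            out.nodes[node][f"hypersensitive_{drug}"] = node in genes
    return out


def write_overlap_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)
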