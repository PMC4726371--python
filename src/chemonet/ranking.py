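"""Drug-combination partner ranking and end-to-end pipeline orchestration.

The combination heuristic: drugs whose resistance gene networks overlap the
target drug's the least are presumed to act through different mechanisms
and are the strongest candidates for a cooperative combination.  Each
candidate is scored by a composite overlap — the mean of its Jaccard rank
and its profile-correlation rank against the target (both ascending, so
low overlap ranks first) — with ties broken by Jaccard and then drug name.

``run_pipeline`` chains every stage: raw growth -> relative fitness ->
WT-normalized folds -> s-scores -> categorical calls (+ transient
resistance) -> per-drug gene sets -> pairwise overlap -> permutation
similarity -> partner ranking, writing each stage's TSV plus a
machine-parseable JSON run report.  Outputs are byte-identical for a fixed
config and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .classify import (
    Thresholds,
    classify,
    flag_transient_resistance,
    summarize_gene_counts,
    write_calls,
)
from .errors import ConfigurationError, InputError
from .network import (
    DEFAULT_CONFIDENCE_FLOOR,
    drug_gene_set,
    load_network,
    overlap_table,
    shared_edge_count,
    write_overlap_table,
)
from .scoring import (
    WILDTYPE,
    read_screen,
    relative_fitness,
    normalize_to_wildtype,
    sscore,
)
from .similarity import (
    DEFAULT_N_PROFILES,
    build_profiles,
    compare_drug_pairs,
    write_similarity_table,
)

logger = logging.getLogger(__name__)

TIERS = ("high", "intermediate", "low")


def rank_partners(
    target: str,
    overlaps: pd.DataFrame,
    similarities: pd.DataFrame,
) -> pd.DataFrame:
    """Rank candidate partner drugs for ``target`` by minimal overlap.

    ``overlaps`` and ``similarities`` are the pairwise tables produced by
    :func:`chemonet.network.overlap_table` and
    :func:`chemonet.similarity.compare_drug_pairs`; every candidate drug
    must appear with the target in both.  Returns one row per candidate,
    sorted ascending by composite overlap (rank 1 = least overlap =
    predicted strongest cooperativity), with a predicted-cooperativity
    tier: ``high`` when both the Jaccard and the correlation fall in the
    bottom tercile of candidates, ``low`` when both fall in the top
    tercile, ``intermediate`` otherwise.
    """

    def versus_target(table: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
        hits = table[(table["drug_a"] == target) | (table["drug_b"] == target)]
        out = hits.copy()
        out["candidate"] = out["drug_a"].where(
            out["drug_b"] == target, out["drug_b"]
        )
        return out.set_index("candidate")[cols]

    ov = versus_target(overlaps, ["jaccard", "p_hyper", "q_hyper", "k"])
    sim = versus_target(
        similarities, ["correlation", "p_value", "q_value", "n_profiles"]
    )
    if ov.empty or sim.empty:
        raise InputError(f"no overlap/similarity records involve {target!r}")
    missing = set(ov.index) ^ set(sim.index)
    if missing:
        raise InputError(
            f"candidates missing an overlap or similarity record vs "
            f"{target!r}: {sorted(missing)}"
        )
    merged = ov.join(sim)
    n = len(merged)
    merged["jaccard_rank"] = merged["jaccard"].rank(method="average")
    merged["correlation_rank"] = merged["correlation"].rank(method="average")
    merged["composite_overlap"] = (
        merged["jaccard_rank"] + merged["correlation_rank"]
    ) / 2.0

    tercile = n / 3.0
    both_low = (merged["jaccard_rank"] <= tercile) & (
        merged["correlation_rank"] <= tercile
    )
    both_high = (merged["jaccard_rank"] > 2 * tercile) & (
        merged["correlation_rank"] > 2 * tercile
    )
    merged["tier"] = "intermediate"
    merged.loc[both_low, "tier"] = "high"
    merged.loc[both_high, "tier"] = "low"

    merged = merged.reset_index().sort_values(
        ["composite_overlap", "jaccard", "candidate"], kind="mergesort"
    )
    merged.insert(0, "rank", range(1, n + 1))
    merged.insert(1, "target", target)
    return merged.reset_index(drop=True)[
        ["rank", "target", "candidate", "jaccard", "correlation",
         "composite_overlap", "tier", "p_hyper", "q_hyper", "p_value",
         "q_value", "k", "n_profiles", "jaccard_rank", "correlation_rank"]
    ]


@dataclass
class PipelineConfig:
    """Everything the end-to-end run needs; mirrors the CLI flags."""

    screen_path: str
    target_drug: str
    network_path: str | None = None
    annotations_path: str | None = None
    day: int = 7
    min_level: str = "weak"
    thresholds: Thresholds = field(default_factory=Thresholds)
    method: str = "pearson"
    n_profiles: int = DEFAULT_N_PROFILES
    confidence_floor: float = DEFAULT_CONFIDENCE_FLOOR
    seed: int = 0
    output_dir: str = "chemonet_out"
    wildtype: str = WILDTYPE

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        thresholds = Thresholds(**raw.pop("thresholds", {}))
        try:
            return cls(thresholds=thresholds, **raw)
        except TypeError as exc:
            raise ConfigurationError(f"bad pipeline config: {exc}") from exc


@dataclass
class PipelineResult:
    """In-memory bundle of every stage's output."""

    sscores: "pd.DataFrame"
    folds: "pd.DataFrame"
    calls: pd.DataFrame
    gene_sets: dict
    overlaps: pd.DataFrame
    similarities: pd.DataFrame
    ranking: pd.DataFrame
    summary: dict
    output_dir: Path


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full analysis and write all stage outputs.

    Raises with the stage name attached if any stage fails.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "chemonet_version": __version__,
        "config": {
            **{k: v for k, v in asdict(config).items() if k != "thresholds"},
            "thresholds": asdict(config.thresholds),
        },
        "stages": {},
    }

    stage = "load"
    try:
        screen = read_screen(config.screen_path)
        report["stages"]["screen_rows"] = len(screen)

        stage = "fitness"
        fitness = relative_fitness(screen)
        normalized = normalize_to_wildtype(fitness, config.wildtype)

        stage = "sscore"
        scores = sscore(normalized)
        scores.to_tsv(out / "sscores.tsv")
        report["stages"]["sscore_rows"] = len(scores.scores)

        stage = "classify"
        calls = classify(scores, config.thresholds)
        days = sorted(calls["day"].unique())
        if config.day not in days:
            raise InputError(f"day {config.day} not screened (days: {days})")
        if len(days) >= 2:
            calls = flag_transient_resistance(calls, min(days), max(days))
        else:
            calls = calls.assign(transient_resistant=False)
        write_calls(calls, out / "calls.tsv", color=True)
        report["stages"]["call_rows"] = len(calls)
        report["stages"]["transient_resistant_pairs"] = int(
            calls.loc[calls["transient_resistant"], ["strain", "drug"]]
            .drop_duplicates()
            .shape[0]
        )

        stage = "gene_sets"
        drugs = sorted(calls["drug"].unique())
        gene_sets = {
            d: drug_gene_set(calls, d, config.day, config.min_level,
                             config.wildtype)
            for d in drugs
        }
        universe = frozenset(set(calls["strain"]) - {config.wildtype})
        report["stages"]["gene_set_sizes"] = {
            d: len(s) for d, s in gene_sets.items()
        }

        stage = "overlap"
        overlaps = overlap_table(gene_sets, universe)
        if config.network_path is not None:
            graph = load_network(
                config.network_path, config.confidence_floor,
                config.annotations_path,
            )
            overlaps["shared_edges"] = [
                shared_edge_count(graph, gene_sets[a], gene_sets[b])
                for a, b in zip(overlaps["drug_a"], overlaps["drug_b"])
            ]
            report["stages"]["network_edges"] = graph.number_of_edges()
        write_overlap_table(overlaps, out / "overlaps.tsv")
        report["stages"]["overlap_pairs"] = len(overlaps)

        stage = "similarity"
        profiles = build_profiles(scores, config.day, drugs, config.wildtype)
        similarities = compare_drug_pairs(
            profiles, config.n_profiles, config.seed, config.method
        )
        write_similarity_table(similarities, out / "similarities.tsv")

        stage = "ranking"
        ranking = rank_partners(config.target_drug, overlaps, similarities)
        ranking.to_csv(out / "ranking.tsv", sep="\t", index=False)

        stage = "summary"
        summary = summarize_gene_counts(
            calls, config.target_drug, config.day, config.wildtype
        )
        report["stages"]["gene_count_summary"] = {
            "counts": summary.counts,
            "n_mutants": summary.n_mutants,
            "cohort_percentage": round(summary.cohort_percentage, 1),
        }
    except Exception as exc:
        exc.add_note(f"pipeline stage: {stage}")
        raise

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")

    return PipelineResult(
        sscores=scores.scores,
        folds=scores.folds,
        calls=calls,
        gene_sets=gene_sets,
        overlaps=overlaps,
        similarities=similarities,
        ranking=ranking,
        summary=report["stages"]["gene_count_summary"],
        output_dir=out,
    )
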