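"""Categorical sensitivity calls from per-concentration fold values.

The screen's convention: a strain is "10-fold sensitive" at a dose when its
WT-normalized fold is <= 0.1.  Calls per (strain, drug, day):

* ``strong``         — fold <= strong_fold (10-fold) at ALL nonzero doses;
* ``weak``           — fold <= weak_cutoff at EXACTLY ONE dose and above
                       strong_fold everywhere;
* ``not_sensitive``  — no dose at or below weak_cutoff and none at or above
                       resist_cutoff;
* ``resistant``      — positive s-score, at least one dose with fold >=
                       resist_cutoff and none at or below weak_cutoff;
* ``medium``         — everything in between (the residual category).

Boundary ties are inclusive on the sensitive side (<= for the sensitivity
cutoffs, >= for the resistance cutoff).  The five categories partition every
fold vector.

Transient resistance is the day-3-resistant / day-7-sensitive pattern: a
strain that outgrows WT at the intermediate time point but is hypersensitive
by the stationary one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError, StructuralError
from .scoring import SScoreTable, WILDTYPE

CALL_CATEGORIES = ("not_sensitive", "weak", "medium", "strong", "resistant")

#: Ordering of the sensitivity levels used by gene-set extraction and the
#: monotonicity contract (resistant sits outside this scale).
SENSITIVITY_LEVELS = {"weak": 1, "medium": 2, "strong": 3}

#: Heat-map palette for exports (strong/medium/weak/none/resistant).
CALL_COLORS = {
    "strong": "dark red",
    "medium": "red",
    "weak": "pink",
    "not_sensitive": "white",
    "resistant": "light blue",
}


@dataclass(frozen=True)
class Thresholds:
    """Fold cutoffs for the categorical classifier.

    strong_fold: the 10-fold sensitivity bound (a dose counts as strongly
    sensitive when fold <= strong_fold).  weak_cutoff: the minimal fold
    reduction that counts as "sensitive" at all (default 2-fold, the
    smallest reduction plausibly scoreable by eye on a dilution series).
    resist_cutoff: fold at or above which a dose counts as resistant
    (default symmetric with weak_cutoff).
    """

    strong_fold: float = 0.1
    weak_cutoff: float = 0.5
    resist_cutoff: float = 2.0

    def __post_init__(self) -> None:
        if not 0 < self.strong_fold < self.weak_cutoff <= 1 <= self.resist_cutoff:
            raise ConfigurationError(
                "thresholds must satisfy 0 < strong_fold < weak_cutoff <= 1 "
                f"<= resist_cutoff; got strong_fold={self.strong_fold}, "
                f"weak_cutoff={self.weak_cutoff}, "
                f"resist_cutoff={self.resist_cutoff}"
            )


def classify_folds(
    folds, s_score: float, thresholds: Thresholds = Thresholds()
) -> str:
    """Classify one (strain, drug, day) cell from its fold vector."""
    f = np.asarray(folds, dtype=float)
    if f.size == 0:
        raise StructuralError("empty fold vector")
    t = thresholds
    n_weak = int(np.sum(f <= t.weak_cutoff))
    if np.all(f <= t.strong_fold):
        return "strong"
    if n_weak == 1 and np.all(f > t.strong_fold):
        return "weak"
    if n_weak == 0:
        if np.any(f >= t.resist_cutoff):
            if s_score > 0:
                return "resistant"
            return "medium"
        return "not_sensitive"
    return "medium"


def classify(
    sscores: SScoreTable, thresholds: Thresholds = Thresholds()
) -> pd.DataFrame:
    """Call table: one categorical call per (strain, drug, day)."""
    grouped = sscores.folds.groupby(["strain", "drug", "day"])["fold"].agg(list)
    scores = sscores.scores.set_index(["strain", "drug", "day"])["s_score"]
    records = []
    for key, folds in grouped.items():
        records.append((*key, classify_folds(folds, scores.loc[key], thresholds)))
    calls = pd.DataFrame(records, columns=["strain", "drug", "day", "call"])
    return calls.sort_values(["strain", "drug", "day"], kind="mergesort").reset_index(
        drop=True
    )


def detect_transient_resistance(
    calls: pd.DataFrame, early_day: int = 3, late_day: int = 7
) -> list[tuple[str, str]]:
    """Pairs (strain, drug) resistant at the early day, sensitive at the late.

    Requires both days to be present for every (strain, drug) pair.
    """
    wide = calls.pivot_table(
        index=["strain", "drug"], columns="day", values="call", aggfunc="first"
    )
    for d in (early_day, late_day):
        if d not in wide.columns:
            raise StructuralError(f"call table has no day-{d} calls")
    incomplete = wide[[early_day, late_day]].isna().any(axis=1)
    if incomplete.any():
        strain, drug = wide.index[incomplete][0]
        raise StructuralError(
            f"({strain!r}, {drug!r}) is missing a day-{early_day} or "
            f"day-{late_day} call"
        )
    flagged = wide[
        (wide[early_day] == "resistant")
        & wide[late_day].isin(list(SENSITIVITY_LEVELS))
    ]
    return sorted(flagged.index.tolist())


def flag_transient_resistance(
    calls: pd.DataFrame, early_day: int = 3, late_day: int = 7
) -> pd.DataFrame:
    """Return calls with a boolean ``transient_resistant`` column added."""
    pairs = set(detect_transient_resistance(calls, early_day, late_day))
    out = calls.copy()
    out["transient_resistant"] = [
        (s, d) in pairs for s, d in zip(out["strain"], out["drug"])
    ]
    return out


@dataclass(frozen=True)
class GeneCountSummary:
    """How many mutants are sensitive to exactly k non-target drugs.

    ``cohort_percentage`` is the share of mutants with k <= 1 — the genes
    whose hypersensitivity is (nearly) specific to the target drug.
    """

    target_drug: str
    day: int
    counts: dict[int, int]
    n_mutants: int

    @property
    def cohort_percentage(self) -> float:
        k01 = self.counts.get(0, 0) + self.counts.get(1, 0)
        return 100.0 * k01 / self.n_mutants


def summarize_gene_counts(
    calls: pd.DataFrame,
    target_drug: str,
    day: int,
    wildtype: str = WILDTYPE,
) -> GeneCountSummary:
    """Count mutant strains by number of non-target drugs they are sensitive to.

    A strain counts as sensitive to a drug when its call is weak, medium or
    strong at the requested day.  The wild-type reference is excluded.
    """
    drugs = set(calls["drug"])
    if target_drug not in drugs:
        raise InputError(f"unknown target drug {target_drug!r}")
    sub = calls[
        (calls["day"] == day)
        & (calls["drug"] != target_drug)
        & (calls["strain"] != wildtype)
    ]
    if sub.empty:
        raise InputError(f"no day-{day} calls for non-target drugs")
    sensitive = sub["call"].isin(list(SENSITIVITY_LEVELS))
    k_per_strain = sensitive.groupby(sub["strain"]).sum().astype(int)
    counts = k_per_strain.value_counts().sort_index()
    return GeneCountSummary(
        target_drug=target_drug,
        day=day,
        counts={int(k): int(v) for k, v in counts.items()},
        n_mutants=int(k_per_strain.size),
    )


def write_calls(calls: pd.DataFrame, path, color: bool = False) -> None:
    """Export calls as TSV; optionally with the heat-map color column."""
    out = calls.copy()
    if color:
        out["color"] = out["call"].map(CALL_COLORS)
    out.to_csv(path, sep="\t", index=False)
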