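"""Growth fitness and sensitivity-score (s-score) computation.

A spot-assay screen records one growth readout per (strain, drug,
concentration, day); concentration 0 is the untreated control.  Scoring
proceeds in three stages:

1. ``relative_fitness`` — per-strain growth on drug relative to growth
   without drug, f = growth(treated) / growth(untreated), with a small
   symmetric pseudocount so zero-growth spots stay finite.
2. ``normalize_to_wildtype`` — fold relative to the wild-type reference,
   F = f(strain) / f(WT), so F = 1 means the strain responds like WT.
3. ``sscore`` — the sensitivity score, the mean over a drug's nonzero
   concentrations of log10(F).  Negative s-scores indicate drug
   hypersensitivity, positive scores resistance, and 0 a WT-like response;
   an s-score of -1 corresponds to 10-fold sensitivity.

Each observation day is scored independently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateReferenceError, InputError, StructuralError

SCREEN_COLUMNS = ("strain", "drug", "concentration", "day", "growth")

#: Pseudocount scale: epsilon = PSEUDOCOUNT_SCALE x per-(drug, day) median
#: untreated growth.
PSEUDOCOUNT_SCALE = 1e-6

WILDTYPE = "WT"


def read_screen(path) -> pd.DataFrame:
    """Read a screen growth table from TSV.

    Expected header: strain, drug, concentration, day, growth.
    """
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in SCREEN_COLUMNS if c not in table.columns]
    if missing:
        raise InputError(f"screen table is missing columns: {missing}")
    return table[list(SCREEN_COLUMNS)]


def write_screen(screen: pd.DataFrame, path) -> None:
    screen.to_csv(path, sep="\t", index=False)


def _validate_screen(screen: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SCREEN_COLUMNS if c not in screen.columns]
    if missing:
        raise InputError(f"screen table is missing columns: {missing}")
    if (screen["growth"] < 0).any():
        bad = screen.loc[screen["growth"] < 0].iloc[0]
        raise InputError(
            "negative growth for strain "
            f"{bad['strain']!r}, drug {bad['drug']!r}, "
            f"concentration {bad['concentration']}, day {bad['day']}"
        )
    return screen


def relative_fitness(
    screen: pd.DataFrame, pseudocount: float | None = None
) -> pd.DataFrame:
    """Per-cell relative fitness f = (treated + eps) / (untreated + eps).

    Parameters
    ----------
    screen
        Long-format growth table with columns strain, drug, concentration,
        day, growth.  Every (strain, drug, day) must include a
        concentration-0 (untreated) row.
    pseudocount
        Symmetric pseudocount ``eps``.  Default: ``PSEUDOCOUNT_SCALE`` times
        the median untreated growth of the same (drug, day) plate group.

    Returns
    -------
    DataFrame with columns strain, drug, concentration, day, fitness —
    one row per treated (concentration > 0) cell.
    """
    screen = _validate_screen(screen)
    untreated = screen[screen["concentration"] == 0]
    treated = screen[screen["concentration"] > 0]

    untr = untreated.rename(columns={"growth": "growth_untreated"})[
        ["strain", "drug", "day", "growth_untreated"]
    ]
    merged = treated.merge(untr, on=["strain", "drug", "day"], how="left")
    if merged["growth_untreated"].isna().any():
        bad = merged.loc[merged["growth_untreated"].isna()].iloc[0]
        raise StructuralError(
            "missing untreated (concentration 0) row for "
            f"({bad['strain']!r}, {bad['drug']!r}, day {bad['day']})"
        )

    if pseudocount is None:
        med = (
            untreated.groupby(["drug", "day"])["growth"]
            .median()
            .rename("untreated_median")
        )
        merged = merged.merge(med, on=["drug", "day"], how="left")
        eps = PSEUDOCOUNT_SCALE * merged.pop("untreated_median")
    else:
        eps = float(pseudocount)

    merged["fitness"] = (merged["growth"] + eps) / (merged["growth_untreated"] + eps)
    return merged[["strain", "drug", "concentration", "day", "fitness"]]


def normalize_to_wildtype(
    fitness: pd.DataFrame, wildtype: str = WILDTYPE
) -> pd.DataFrame:
    """Fold relative to the wild-type reference: F = f(strain) / f(WT).

    WT rows must exist for every (drug, concentration, day); WT itself
    normalizes to exactly 1.
    """
    wt = fitness[fitness["strain"] == wildtype]
    if wt.empty:
        raise StructuralError(f"no rows for wild-type strain {wildtype!r}")
    wt = wt.rename(columns={"fitness": "fitness_wt"})[
        ["drug", "concentration", "day", "fitness_wt"]
    ]
    merged = fitness.merge(wt, on=["drug", "concentration", "day"], how="left")
    if merged["fitness_wt"].isna().any():
        bad = merged.loc[merged["fitness_wt"].isna()].iloc[0]
        raise StructuralError(
            "missing wild-type fitness for "
            f"({bad['drug']!r}, concentration {bad['concentration']}, "
            f"day {bad['day']})"
        )
    if (merged["fitness_wt"] <= 0).any():
        bad = merged.loc[merged["fitness_wt"] <= 0].iloc[0]
        raise DegenerateReferenceError(
            "wild-type fitness is zero for "
            f"({bad['drug']!r}, concentration {bad['concentration']}, "
            f"day {bad['day']}); cannot normalize"
        )
    merged["fold"] = merged["fitness"] / merged["fitness_wt"]
    # force exact 1.0 on the reference itself (guards float round-off)
    merged.loc[merged["strain"] == wildtype, "fold"] = 1.0
    return merged[["strain", "drug", "concentration", "day", "fold"]]


@dataclass
class SScoreTable:
    """Sensitivity scores plus the per-concentration folds they summarize.

    Attributes
    ----------
    scores
        One row per (strain, drug, day) with column ``s_score``.
    folds
        Long-format WT-normalized folds, one row per (strain, drug,
        concentration > 0, day) with column ``fold``; retained because the
        categorical classifier operates on the per-concentration folds,
        not on the averaged score.
    """

    scores: pd.DataFrame
    folds: pd.DataFrame

    def to_tsv(self, path) -> None:
        """Export wide TSV: strain, drug, day, s_score, F1..Fk.

        F columns hold the normalized folds in ascending concentration
        order within each drug; drugs with fewer tested doses leave the
        trailing columns empty.
        """
        folds = self.folds.sort_values(
            ["strain", "drug", "day", "concentration"], kind="mergesort"
        ).copy()
        folds["rank"] = folds.groupby(["strain", "drug", "day"]).cumcount() + 1
        wide = folds.pivot_table(
            index=["strain", "drug", "day"], columns="rank", values="fold"
        )
        wide.columns = [f"F{int(r)}" for r in wide.columns]
        out = self.scores.merge(wide.reset_index(), on=["strain", "drug", "day"])
        out.to_csv(path, sep="\t", index=False)


def sscore(normalized: pd.DataFrame, day: int | None = None) -> SScoreTable:
    """Sensitivity score: mean of log10 fold over nonzero concentrations.

    Parameters
    ----------
    normalized
        WT-normalized fold table from :func:`normalize_to_wildtype`.
    day
        Restrict to one observation day; default scores every day present.
    """
    folds = normalized[normalized["concentration"] > 0].copy()
    if day is not None:
        folds = folds[folds["day"] == day]
    if folds.empty:
        raise StructuralError("no treated concentrations to score")
    if (folds["fold"] <= 0).any():
        bad = folds.loc[folds["fold"] <= 0].iloc[0]
        raise InputError(
            f"non-positive fold for ({bad['strain']!r}, {bad['drug']!r}); "
            "pseudocount handling upstream should prevent this"
        )
    scores = (
        np.log10(folds["fold"])
        .groupby([folds["strain"], folds["drug"], folds["day"]])
        .mean()
        .rename("s_score")
        .reset_index()
    )
    return SScoreTable(scores=scores, folds=folds.reset_index(drop=True))


def score_screen(
    screen: pd.DataFrame,
    day: int | None = None,
    pseudocount: float | None = None,
    wildtype: str = WILDTYPE,
) -> SScoreTable:
    """Convenience: raw growth table -> s-scores in one call."""
    return sscore(
        normalize_to_wildtype(relative_fitness(screen, pseudocount), wildtype),
        day,
    )
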