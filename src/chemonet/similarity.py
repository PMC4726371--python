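"""Drug-profile similarity against a random-profile permutation null.

A drug's profile is the vector of per-gene s-scores over the screened
mutants (fixed, shared gene order).  Similarity between two drugs x and y
is a correlation coefficient s(x, y).  Its significance is assessed against
random profiles: two sets S_x and S_y of random profiles are generated —
by default 10,000 independent permutations of each observed profile's
values over the genes, which preserves each drug's marginal s-score
distribution — and s(x, y) is compared with the correlations between a
random profile from S_x and one from S_y.  The empirical p-value uses the
plus-one correction, p = (#{null >= observed} + 1) / (n + 1), so p is never
zero and the test is exact under the null.

For short profiles the permutation-pair distribution can be enumerated in
full (all |x|! x |y|! pairs); :func:`exhaustive_null` provides that oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, permutations

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateProfileError, InputError
from .scoring import SScoreTable, WILDTYPE

import logging

logger = logging.getLogger(__name__)

#: Random-profile set size matching the screen's published simulation.
DEFAULT_N_PROFILES = 10_000


@dataclass(frozen=True)
class DrugProfile:
    """Per-gene s-score vector for one drug at one observation day."""

    drug: str
    day: int
    genes: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.values):
            raise InputError("genes and values differ in length")


@dataclass(frozen=True)
class NullDistribution:
    """Correlations between paired random profiles."""

    values: np.ndarray
    n_profiles: int
    seed: int | None


def build_profiles(
    sscores: SScoreTable,
    day: int,
    drugs=None,
    wildtype: str = WILDTYPE,
) -> dict[str, DrugProfile]:
    """Gene-aligned profiles for every (requested) drug at one day.

    The gene order is the sorted set of mutant strains; a strain with no
    score for some drug is imputed as 0 (WT-like) and logged.
    """
    scores = sscores.scores[sscores.scores["day"] == day]
    if scores.empty:
        raise InputError(f"no s-scores for day {day}")
    if drugs is None:
        drugs = sorted(scores["drug"].unique())
    genes = tuple(sorted(set(scores["strain"]) - {wildtype}))
    wide = scores.pivot_table(index="strain", columns="drug", values="s_score")
    profiles: dict[str, DrugProfile] = {}
    for drug in drugs:
        if drug not in wide.columns:
            raise InputError(f"no s-scores for drug {drug!r} at day {day}")
        col = wide[drug].reindex(list(genes))
        n_missing = int(col.isna().sum())
        if n_missing:
            logger.info(
                "drug %s day %d: imputing %d missing s-scores as 0 (WT-like)",
                drug, day, n_missing,
            )
        profiles[drug] = DrugProfile(
            drug=drug, day=day, genes=genes,
            values=col.fillna(0.0).to_numpy(dtype=float),
        )
    return profiles


def _aligned_values(x: DrugProfile, y: DrugProfile) -> tuple[np.ndarray, np.ndarray]:
    if x.genes != y.genes:
        raise InputError(
            f"profiles {x.drug!r} and {y.drug!r} have different gene orders"
        )
    xv, yv = np.asarray(x.values, float), np.asarray(y.values, float)
    for p, v in ((x, xv), (y, yv)):
        if np.std(v) == 0:
            raise DegenerateProfileError(
                f"profile {p.drug!r} has zero variance; correlation undefined"
            )
    return xv, yv


def _corr(xv: np.ndarray, yv: np.ndarray) -> float:
    xc, yc = xv - xv.mean(), yv - yv.mean()
    return float((xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc)))


def profile_correlation(
    x: DrugProfile, y: DrugProfile, method: str = "pearson"
) -> float:
    """Correlation s(x, y) between two gene-aligned drug profiles."""
    xv, yv = _aligned_values(x, y)
    if method == "spearman":
        xv, yv = rankdata(xv), rankdata(yv)
    elif method != "pearson":
        raise InputError(f"unknown correlation method {method!r}")
    return _corr(xv, yv)


def _pairwise_row_corr(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    num = np.einsum("ij,ij->i", Xc, Yc)
    den = np.sqrt(
        np.einsum("ij,ij->i", Xc, Xc) * np.einsum("ij,ij->i", Yc, Yc)
    )
    return num / den


def permutation_null(
    x: DrugProfile,
    y: DrugProfile,
    n_profiles: int = DEFAULT_N_PROFILES,
    seed: int | None = None,
    method: str = "pearson",
    resample: bool = False,
) -> NullDistribution:
    """Null distribution of correlations between paired random profiles.

    Each of the ``n_profiles`` draws takes one random profile derived from
    x and one from y and records their correlation.  With the default
    ``resample=False`` a random profile is an independent permutation of
    the observed values over genes; ``resample=True`` instead draws values
    with replacement (a parametric-flavoured alternative that does not
    preserve the exact marginal).
    """
    if n_profiles < 1:
        raise InputError("n_profiles must be >= 1")
    xv, yv = _aligned_values(x, y)
    if method == "spearman":
        xv, yv = rankdata(xv), rankdata(yv)
    elif method != "pearson":
        raise InputError(f"unknown correlation method {method!r}")
    rng = np.random.default_rng(seed)
    n = len(xv)
    if resample:
        X = rng.choice(xv, size=(n_profiles, n), replace=True)
        Y = rng.choice(yv, size=(n_profiles, n), replace=True)
        sd_zero = (X.std(axis=1) == 0) | (Y.std(axis=1) == 0)
        # resampled rows can degenerate; redraw them (finitely many tries)
        for _ in range(100):
            if not sd_zero.any():
                break
            k = int(sd_zero.sum())
            X[sd_zero] = rng.choice(xv, size=(k, n), replace=True)
            Y[sd_zero] = rng.choice(yv, size=(k, n), replace=True)
            sd_zero = (X.std(axis=1) == 0) | (Y.std(axis=1) == 0)
    else:
        X = rng.permuted(np.broadcast_to(xv, (n_profiles, n)).copy(), axis=1)
        Y = rng.permuted(np.broadcast_to(yv, (n_profiles, n)).copy(), axis=1)
    values = _pairwise_row_corr(X, Y)
    return NullDistribution(values=values, n_profiles=n_profiles, seed=seed)


def exhaustive_null(
    x: DrugProfile, y: DrugProfile, method: str = "pearson", max_len: int = 6
) -> np.ndarray:
    """Fully enumerated permutation-pair null (all |x|! x |y|! pairs).

    Only feasible for short profiles (guarded by ``max_len``); used as the
    exact oracle against which the sampled null is validated.
    """
    xv, yv = _aligned_values(x, y)
    if len(xv) > max_len:
        raise InputError(f"exhaustive enumeration limited to length <= {max_len}")
    if method == "spearman":
        xv, yv = rankdata(xv), rankdata(yv)
    elif method != "pearson":
        raise InputError(f"unknown correlation method {method!r}")
    values = [
        _corr(np.array(px), np.array(py))
        for px in permutations(xv)
        for py in permutations(yv)
    ]
    return np.array(values)


def empirical_pvalue(
    observed: float, null: NullDistribution, alternative: str = "greater"
) -> float:
    """Plus-one-corrected empirical p-value of ``observed`` under ``null``.

    greater: p = (#{null >= observed} + 1) / (n + 1); two_sided applies the
    same count to absolute values.  Ties count against the alternative
    (inclusive >=), which is conservative.
    """
    if np.isnan(observed):
        raise InputError("observed correlation is NaN")
    vals = np.asarray(null.values)
    if vals.size == 0:
        raise InputError("null distribution is empty")
    if alternative == "greater":
        count = int(np.sum(vals >= observed))
    elif alternative == "two_sided":
        count = int(np.sum(np.abs(vals) >= abs(observed)))
    else:
        raise InputError(f"unknown alternative {alternative!r}")
    return (count + 1) / (vals.size + 1)


def compare_drug_pairs(
    profiles: dict[str, DrugProfile],
    n_profiles: int = DEFAULT_N_PROFILES,
    seed: int | None = None,
    method: str = "pearson",
    alternative: str = "greater",
) -> pd.DataFrame:
    """Observed correlation + permutation p for every drug pair, with BH q.

    Each pair gets an independent child seed spawned deterministically from
    ``seed`` so results do not depend on pair evaluation order.
    """
    if len(profiles) < 2:
        raise InputError("need >= 2 profiles")
    rows = []
    ss = np.random.SeedSequence(seed)
    pairs = list(combinations(sorted(profiles), 2))
    children = ss.spawn(len(pairs))
    for (a, b), child in zip(pairs, children):
        pair_seed = int(child.generate_state(1)[0] % (2**31))
        r = profile_correlation(profiles[a], profiles[b], method)
        null = permutation_null(
            profiles[a], profiles[b], n_profiles, pair_seed, method
        )
        rows.append(
            {
                "drug_a": a,
                "drug_b": b,
                "method": method,
                "correlation": r,
                "n_profiles": n_profiles,
                "p_value": empirical_pvalue(r, null, alternative),
                "seed": pair_seed,
            }
        )
    table = pd.DataFrame(rows)
    table["q_value"] = multipletests(table["p_value"], method="fdr_bh")[1]
    return table[
        ["drug_a", "drug_b", "method", "correlation", "n_profiles",
         "p_value", "q_value", "seed"]
    ]


def fisher_z_pvalue(r: float, n: int) -> float:
    """Analytic one-sided p via the Fisher z-transform (cross-check only)."""
    from scipy.stats import norm

    if n < 4:
        raise InputError("Fisher z needs n >= 4")
    z = np.arctanh(np.clip(r, -0.999999, 0.999999)) * np.sqrt(n - 3)
    return float(norm.sf(z))


def write_similarity_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)
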