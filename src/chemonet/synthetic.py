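"""Synthetic spot-assay screens and interaction networks with known truth.

The generator emulates a deletion-library chemogenomic screen: ~90 mutant
strains plus a wild-type reference, each spotted on plates carrying a drug
at several concentrations (concentration 0 = untreated), read out at an
intermediate and a stationary day.  Growth is a nonnegative proxy for spot
intensity: growth = baseline x planted_fold x lognormal noise, where the
planted fold encodes the intended sensitivity class relative to WT.

Planted classes and their fold plans (per nonzero concentration):

* ``not_sensitive``       — 1.0 everywhere (WT-like);
* ``strong``              — 0.05 everywhere (beyond 10-fold);
* ``medium``              — 0.05 at the first dose, 1.0 elsewhere
                            (strong at some but not all doses);
* ``weak``                — 0.3 at the first dose only;
* ``resistant``           — 3.0 everywhere, both days;
* ``transient_resistant`` — 3.0 everywhere at the early day, 0.3
                            everywhere at the late day.

With ``noise_sd = 0`` the downstream classifier recovers every planted call
exactly; the default noise (0.05 on the log10 scale) leaves wide margins to
every classification threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError
from .scoring import SCREEN_COLUMNS, WILDTYPE

PLANTED_CLASSES = (
    "strong",
    "medium",
    "weak",
    "not_sensitive",
    "resistant",
    "transient_resistant",
)

# fold values realizing each planted class
STRONG_FOLD = 0.05
WEAK_FOLD = 0.3
RESISTANT_FOLD = 3.0

# edge confidence scores written by generate_network
INTRA_MODULE_SCORE = 0.9
INTER_MODULE_SCORE = 0.5


def mutant_names(n_mutants: int) -> list[str]:
    """Deterministic mutant/gene names g001..gNNN."""
    return [f"g{i:03d}" for i in range(1, n_mutants + 1)]


@dataclass
class ScreenConfig:
    """Design of a synthetic screen.

    ``drugs`` maps each drug name to its list of nonzero test
    concentrations (arbitrary units); the untreated concentration 0 is
    always generated and must not be listed.  ``planted_calls`` maps
    (strain, drug) to an intended class; unlisted pairs default to
    ``not_sensitive``.  ``noise_sd`` is the standard deviation of the
    multiplicative log-normal growth noise on the log10 scale.
    """

    drugs: Mapping[str, Sequence[float]]
    n_mutants: int = 90
    days: tuple[int, ...] = (3, 7)
    planted_calls: Mapping[tuple[str, str], str] = field(default_factory=dict)
    noise_sd: float = 0.05
    baseline_growth: float = 100.0
    seed: int = 0

    @property
    def strains(self) -> list[str]:
        return [WILDTYPE] + mutant_names(self.n_mutants)

    @property
    def early_day(self) -> int:
        return min(self.days)

    @property
    def late_day(self) -> int:
        return max(self.days)

    def validate(self) -> None:
        if self.n_mutants < 1:
            raise ConfigurationError("n_mutants must be >= 1")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.baseline_growth <= 0:
            raise ConfigurationError("baseline_growth must be > 0")
        if len(self.days) < 1:
            raise ConfigurationError("days must be nonempty")
        if not self.drugs:
            raise ConfigurationError("drugs must be nonempty")
        for drug, concs in self.drugs.items():
            if len(concs) < 1:
                raise ConfigurationError(
                    f"drugs[{drug!r}] needs >= 1 nonzero concentration"
                )
            if any(c <= 0 for c in concs):
                raise ConfigurationError(
                    f"drugs[{drug!r}] lists a non-positive concentration; "
                    "concentration 0 (untreated) is implicit"
                )
        strains = set(self.strains)
        for (strain, drug), cls in self.planted_calls.items():
            if cls not in PLANTED_CLASSES:
                raise ConfigurationError(
                    f"planted_calls[({strain!r}, {drug!r})]: unknown class {cls!r}"
                )
            if strain == WILDTYPE and cls != "not_sensitive":
                raise ConfigurationError(
                    "planted_calls: the WT reference must stay not_sensitive"
                )
            if strain not in strains:
                raise ConfigurationError(
                    f"planted_calls names unknown strain {strain!r}"
                )
            if drug not in self.drugs:
                raise ConfigurationError(
                    f"planted_calls names unknown drug {drug!r}"
                )
            if cls == "medium" and len(self.drugs[drug]) < 2:
                raise ConfigurationError(
                    f"planted_calls[({strain!r}, {drug!r})]: a medium call "
                    "needs >= 2 nonzero concentrations"
                )


@dataclass
class GroundTruth:
    """What the generator planted, for downstream recovery checks.

    ``expected_call_table`` is the per-(strain, drug, day) categorical call
    a perfect classifier should produce, derived from the fold plans (a
    transient_resistant plant reads resistant at the early day and
    medium — weak on a single-dose drug — at the late day).
    """

    planted_calls: dict[tuple[str, str], str]
    planted_drug_modules: dict[str, frozenset[str]]
    expected_call_table: pd.DataFrame

    def expected_transient(self) -> list[tuple[str, str]]:
        return sorted(
            key for key, cls in self.planted_calls.items()
            if cls == "transient_resistant"
        )


def _planted_folds(cls: str, n_conc: int, is_late_day: bool) -> np.ndarray:
    folds = np.ones(n_conc)
    if cls == "strong":
        folds[:] = STRONG_FOLD
    elif cls == "medium":
        folds[0] = STRONG_FOLD
    elif cls == "weak":
        folds[0] = WEAK_FOLD
    elif cls == "resistant":
        folds[:] = RESISTANT_FOLD
    elif cls == "transient_resistant":
        folds[:] = WEAK_FOLD if is_late_day else RESISTANT_FOLD
    return folds


def _expected_call(cls: str, n_conc: int, is_late_day: bool) -> str:
    if cls == "transient_resistant":
        if not is_late_day:
            return "resistant"
        return "weak" if n_conc == 1 else "medium"
    return cls


def generate_screen(config: ScreenConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a complete growth table plus its ground truth.

    One row per (strain, drug, concentration, day) including the untreated
    concentration-0 controls; bit-for-bit reproducible for a fixed config
    and seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    late = config.late_day

    rows: list[tuple] = []
    expected: list[tuple] = []
    for strain in config.strains:
        for drug, concs in config.drugs.items():
            cls = config.planted_calls.get((strain, drug), "not_sensitive")
            for day in config.days:
                is_late = day == late and len(config.days) > 1
                folds = _planted_folds(cls, len(concs), is_late)
                noise = 10.0 ** rng.normal(0.0, config.noise_sd, len(concs) + 1)
                untreated = config.baseline_growth * noise[0]
                rows.append((strain, drug, 0.0, day, untreated))
                for conc, fold, nz in zip(concs, folds, noise[1:]):
                    rows.append(
                        (strain, drug, float(conc),
                         day, config.baseline_growth * fold * nz)
                    )
                if strain != WILDTYPE:
                    expected.append(
                        (strain, drug, day,
                         _expected_call(cls, len(concs), is_late))
                    )

    screen = pd.DataFrame(rows, columns=list(SCREEN_COLUMNS))
    modules: dict[str, frozenset[str]] = {}
    sensitive_late = {"strong", "medium", "weak", "transient_resistant"}
    for drug in config.drugs:
        modules[drug] = frozenset(
            s for (s, d), cls in config.planted_calls.items()
            if d == drug and cls in sensitive_late
        )
    truth = GroundTruth(
        planted_calls=dict(config.planted_calls),
        planted_drug_modules=modules,
        expected_call_table=pd.DataFrame(
            expected, columns=["strain", "drug", "day", "call"]
        ),
    )
    return screen, truth


def generate_network(
    gene_names: Sequence[str],
    n_modules: int,
    intra_p: float,
    inter_p: float,
    seed: int,
) -> nx.Graph:
    """Planted-partition interaction network over ``gene_names``.

    Genes are split into ``n_modules`` contiguous blocks; within-block
    edges are drawn with probability ``intra_p``, between-block edges with
    ``inter_p``.  Edge attribute ``score`` carries a confidence value
    (higher within modules), mimicking a functional-interaction export.
    """
    if len(gene_names) == 0:
        raise InputError("gene_names is empty")
    if n_modules < 1:
        raise ConfigurationError("n_modules must be >= 1")
    if not 0 <= inter_p <= intra_p <= 1:
        raise ConfigurationError(
            f"need 0 <= inter_p <= intra_p <= 1; got intra_p={intra_p}, "
            f"inter_p={inter_p}"
        )
    rng = np.random.default_rng(seed)
    blocks = np.array_split(np.arange(len(gene_names)), n_modules)
    module_of = np.empty(len(gene_names), dtype=int)
    for m, block in enumerate(blocks):
        module_of[block] = m

    graph = nx.Graph()
    graph.add_nodes_from(gene_names)
    for i in range(len(gene_names)):
        for j in range(i + 1, len(gene_names)):
            same = module_of[i] == module_of[j]
            p = intra_p if same else inter_p
            if rng.random() < p:
                graph.add_edge(
                    gene_names[i],
                    gene_names[j],
                    score=INTRA_MODULE_SCORE if same else INTER_MODULE_SCORE,
                )
    return graph


def write_network(graph: nx.Graph, path) -> None:
    """Write the 3-column edge-list TSV (gene_a, gene_b, score)."""
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tscore\n")
        for a, b, data in sorted(graph.edges(data=True)):
            fh.write(f"{a}\t{b}\t{data.get('score', 1.0):g}\n")


def write_ground_truth(truth: GroundTruth, path) -> None:
    """Key-value sidecar: planted calls and per-drug module membership."""
    with open(path, "w") as fh:
        for (strain, drug), cls in sorted(truth.planted_calls.items()):
            fh.write(f"call\t{strain}\t{drug}\t{cls}\n")
        for drug, genes in sorted(truth.planted_drug_modules.items()):
            fh.write(f"module\t{drug}\t{','.join(sorted(genes))}\n")


def read_ground_truth(path) -> tuple[dict, dict]:
    """Read the sidecar back: (planted_calls, planted_drug_modules)."""
    calls: dict[tuple[str, str], str] = {}
    modules: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if parts[0] == "call":
                calls[(parts[1], parts[2])] = parts[3]
            elif parts[0] == "module":
                genes = parts[2].split(",") if parts[2] else []
                modules[parts[1]] = frozenset(genes)
    return calls, modules


# ---------------------------------------------------------------------------
# Default study design: 90 mutants x 6 drugs, dose grids shaped like a real
# spot-assay panel (2-5 nonzero doses per drug), with a shared
# DNA-replication-stress module (HU/CPT/MMS), a partially overlapping
# spindle-drug module (TBZ), two unique-profile drugs (cisplatin, SAHA),
# nine HU transient-resistant strains and one constitutively resistant one.
# ---------------------------------------------------------------------------

DEFAULT_DRUGS: dict[str, tuple[float, ...]] = {
    "HU": (2.0, 4.0),
    "CPT": (6.0, 8.0, 10.0, 12.0),
    "MMS": (0.001, 0.002, 0.005, 0.01, 0.02),
    "TBZ": (8.0, 10.0),
    "cisplatin": (1.2, 1.6),
    "SAHA": (10.0,),
}


def default_planted_calls(n_mutants: int = 90) -> dict[tuple[str, str], str]:
    """The default planted design over mutants g001..g090."""
    if n_mutants < 90:
        raise ConfigurationError("the default design needs >= 90 mutants")
    g = mutant_names(n_mutants)
    calls: dict[tuple[str, str], str] = {}

    def plant(indices, drug, cls):
        for i in indices:
            calls[(g[i - 1], drug)] = cls

    for drug in ("HU", "CPT", "MMS"):  # shared replication-stress module
        plant(range(1, 11), drug, "strong")
        plant(range(11, 17), drug, "medium")
        plant(range(17, 23), drug, "weak")
    plant(range(17, 25), "TBZ", "strong")  # overlaps the trio on g017-g022
    plant(range(25, 29), "TBZ", "medium")
    plant(range(35, 45), "cisplatin", "strong")
    plant(range(45, 51), "cisplatin", "weak")
    plant(range(55, 65), "SAHA", "strong")
    plant(range(65, 71), "SAHA", "weak")
    plant(range(80, 89), "HU", "transient_resistant")  # nine strains, HU only
    plant([89], "TBZ", "resistant")
    return calls


def default_screen_config(seed: int = 0, noise_sd: float = 0.05) -> ScreenConfig:
    """The package's reference study design (see module docstring)."""
    return ScreenConfig(
        drugs=dict(DEFAULT_DRUGS),
        n_mutants=90,
        days=(3, 7),
        planted_calls=default_planted_calls(),
        noise_sd=noise_sd,
        baseline_growth=100.0,
        seed=seed,
    )
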