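# Methods

## Growth readout and the s-score

Spot-assay growth is treated as a nonnegative real proxy (e.g. summed
colony signal across a dilution series); any monotone readout supports the
fold-ratio arithmetic, but the underlying quantification of a visual spot
assay is an assumption, not a measurement model. Scoring is a three-stage
ratio chain:

* relative fitness f = (growth_treated + ε) / (growth_untreated + ε), with
  a symmetric pseudocount ε = 10⁻⁶ × the median untreated growth of the
  same (drug, day) plate group, so zero-growth spots stay finite (ε is
  configurable);
* wild-type normalization F = f(strain) / f(WT), per (drug, dose, day);
  the WT strain itself is forced to exactly 1 to guard float round-off;
* s-score s = mean over the drug's nonzero doses of log10 F.

Log base 10 is chosen so that the classifier's "10-fold" threshold maps to
s = −1 exactly. "Mean of the log folds" is one reading of an ambiguous
verbal definition ("the mean of the sum" of log-transformed normalized
fitness); it is the only reading we found that satisfies every stated
qualitative property (0 for WT-like growth, negative = sensitive,
positive = resistant, −1 ⇔ uniform 10-fold), and it is isolated in a
single function (`chemonet.scoring.sscore`) for easy replacement. Days are
scored independently: the intermediate (day 3) and stationary (day 7)
readouts each get their own s-score.

Consequences asserted as properties: multiplying one strain's treated
growth by 10⁻¹ lowers its s-score by exactly 1 (up to pseudocount effects
< 10⁻⁴); rescaling an entire (drug, dose, day) plate leaves every F and s
unchanged; elementwise-smaller fold vectors never score higher.

## Categorical calls

The published thresholds define only the extremes: strong = fold ≤ 0.1 at
all doses, weak = one sub-threshold dose, medium = in between. Two cutoffs
are necessarily our own:

* `weak_cutoff = 0.5` — the minimal fold reduction that counts as
  "sensitive" at all; 2-fold is the smallest change plausibly scoreable by
  eye on a dilution series;
* `resist_cutoff = 2.0` — symmetric with the sensitivity cutoff; a dose
  counts toward "resistant" only when the s-score is also positive.

Ties are inclusive on the sensitive side (≤) and on the resistant side
(≥). The five categories provably partition every fold vector (asserted by
grid enumeration over {0.01, 0.1, 0.3, 0.5, 1, 2, 4}³), and lowering any
single fold never moves a call toward a less-sensitive category. A literal
consequence of the weak rule worth knowing: a vector like (4.0, 0.25) is
called weak — one sensitive dose — even though another dose is elevated.

Transient resistance is the pair rule day-3 call = resistant ∧ day-7 call
∈ {weak, medium, strong}; late-onset sensitivity without early resistance
is deliberately not flagged.

## Overlap and similarity statistics

Drug gene sets are taken at day 7 with `min_level = weak` by default (the
stationary-phase calls are the stable phenotype). The gene universe
defaults to the screened mutants, not all network nodes, because
sensitivity is only observable for screened genes. Overlap is reported two
ways because the underlying significance claim never names its test:

* hypergeometric upper tail P(X ≥ k) for |A∩B| = k drawn from N screened
  genes — fast, assumption-laden; BH-adjusted across the drug-pair family;
* the permutation approach below, applied to the s-score profiles.

Network edges do not enter the default statistic (node-set overlap only);
a shared-edge count across the loaded interaction network is available as
a secondary descriptor. Network ingestion accepts the STRING tab-export
dialect, including 0–1000 integer confidence scores (rescaled to [0, 1]),
with a default confidence floor of 0.4 ("medium confidence").

"Random profiles" are implemented as label permutations of the observed
per-gene s-scores — the minimal-assumption null that preserves each drug's
marginal score distribution; a resampling-with-replacement variant sits
behind a flag. Two sets of 10,000 random profiles (one per drug) are drawn
by default; each null draw pairs one profile from each set and records
their Pearson (optionally Spearman) correlation, computed vectorized with
the row means/variances of the permuted matrices. The empirical p-value
uses the plus-one correction, p = (#{null ≥ s(x,y)} + 1) / (n + 1), with
inclusive ties — conservative and never zero. For profiles of length ≤ 5
the full |x|!·|y|! enumeration is implemented and serves as the oracle;
the sampled null converges to it (KS < 0.05 at n = 10,000), and on
independent profiles the test is calibrated (≤ 7 % of 500 pairs reach
p ≤ 0.05 at n = 999). A Fisher-z analytic p is provided as a cross-check
utility only. Test runs use n = 999 for speed; the default stays 10,000.

## Combination ranking

The combination heuristic — smaller resistance-network overlap predicts
stronger cooperativity — is qualitative in origin; the composite score is
our explicit operationalization: mean of the candidate's Jaccard rank and
profile-correlation rank against the target, ascending, ties broken by
Jaccard then drug name. The tier is high when both components fall in the
bottom tercile of candidates, low when both fall in the top tercile. The
scorer is isolated so alternative composites can be plugged in. No
quantitative synergy model (Bliss/Loewe) is attempted; the output is a
screening prioritization.

The natural target of the original screen design (doxorubicin) has, by
construction, the entire mutant panel as its hypersensitive set and no
per-dose scores of its own, so `rank_partners` is generic over any
screened target drug; the reference synthetic design exercises it with HU
as target.

## The synthetic-data generator

`default_screen_config` is the package's reference study: 91 strains (WT +
90 mutants) × 6 drugs × days {3, 7}, dose grids mirroring a realistic
spot-assay panel (HU 2, CPT 4, MMS 5, TBZ 2, cisplatin 2, SAHA 1 nonzero
doses). Growth = baseline (100) × planted fold × 10^N(0, σ) with σ =
noise_sd = 0.05 on the log10 scale. Planted structure: a replication-stress
module sensitive to HU/CPT/MMS (strong g001–g010, medium g011–g016, weak
g017–g022), a TBZ module overlapping it on g017–g022, unique cisplatin
(g035–g050) and SAHA (g055–g070) modules, nine HU transient-resistant
strains (g080–g088) and one constitutively TBZ-resistant strain (g089).
Planted fold plans: strong 0.05, weak 0.3 at the first dose, medium 0.05
at the first dose only, resistant 3.0, transient 3.0 → 0.3 across days.

What it emulates: WT-relative fold structure, dose grids, two-day kinetics,
shared vs unique drug modules, multiplicative measurement noise including
the shared wild-type reference draw (an unlucky WT plate shifts every
strain on it, exactly as a single reference lane would). What it does not:
dilution-series optics, growth-curve kinetics, dose–response shapes,
batch/plate-position effects, or biologically correlated noise between
related genes. Passing recovery tests therefore demonstrates that the
statistics invert the generator's model faithfully, not that they are
robust to every artifact of real spot assays.

With noise_sd = 0 the classifier recovers 100 % of planted calls; at the
default noise it recovers ≈ 99 % over 20 seeds (occasional flips come from
boundary crossings of the weak 0.3-fold plants and from shared WT plate
draws), and the unique-profile drugs take ranks 1–2 against the HU target
in ≥ 95 % of seeded runs.

## Numerical and degenerate-input choices

Zero-variance profiles raise rather than silently returning 0 or NaN;
missing profile entries are imputed as 0 (WT-like) with a log message;
a missing untreated or WT row is a structural error naming the offending
key; WT fitness of zero is a degenerate-reference error. All RNG flows
through `numpy.random.default_rng`; per-pair permutation seeds are spawned
via `SeedSequence` so drug-pair results are independent of evaluation
order, and every pipeline output is byte-identical under a fixed config
and seed. Problem sizes in the test suite (999-profile nulls, 20-seed
recovery batches, 500-pair calibration) are chosen to keep the full suite
under a minute of compute while leaving the statistical margins wide.

## Known limitations

* The s-score formula is one disambiguation of a verbally defined
  statistic; replicate handling (summing before averaging) could differ.
* The weak/resistant cutoffs are conventions; calls near fold 0.5 or 2.0
  move with them.
* The hypergeometric test assumes exchangeable gene sets; correlated gene
  modules violate it (the permutation test is the safer of the two).
* The ranking is ordinal; it does not estimate synergy magnitude.
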