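# Methods

## Module definitions and pathwise completeness

A module definition is parsed with a strict recursive-descent grammar over
the KEGG flat-file DEFINITION conventions. Operator precedence, loosest to
tightest: space (sequential steps), comma (alternative branches), `+`/`-`
(complex subunits). Parentheses group; `--` is a reaction step with no KO;
`M#####` tokens reference other modules and are expanded in place at
evaluation time with cycle detection and a nesting-depth cap of 10.
Unbalanced parentheses and unknown tokens are rejected with the failing
character position; parsing and rendering round-trip (render(parse(x))
re-parses to an identical structure).

Completeness is *pathwise*: every combination of alternative branches is
enumerated into a route, each route is scored as the mean per-step
completeness, and the module takes the best route. Enumeration is exact with
a hard cap (100,000 routes by default); exceeding the cap raises an error
rather than silently truncating or sampling. The maximum over routes is
order-independent, and only the value is reported when several routes tie.

Two scoring choices are configurable because the upstream convention is not
fully specified:

* **Complexes** score the fraction of essential (`+`) subunits annotated;
  non-essential (`-`) components are ignored. An all-or-nothing policy flag
  is provided.
* **Gap steps** (`--`) count as always-absent steps by default, which is
  conservative: a module with one gap among *k* steps can reach at most
  (k−1)/k. A policy flag excludes gaps from route length instead.

Both defaults, and the evaluator itself, are property-tested: completeness
is monotone under KO-set growth, adding an alternative branch never lowers
it, and the evaluator agrees with an independent brute-force route
enumeration on a thousand random definitions.

## Detection and coverage summaries

Detection is breadth of coverage: the fraction of nucleotide positions
covered by ≥1 read. Mean coverage alone cannot separate low-abundance
populations from conserved-region cross-mapping, whereas breadth is bimodal
between present and absent populations; the presence call uses an inclusive
0.25 threshold. The Q2–Q3 coverage summary sorts the values and drops the
floor(n/4) lowest and highest before averaging — a deterministic, count-based
reading of "mean coverage in the 2nd and 3rd quartiles" that is exact when n
is divisible by 4. The upstream "non-outlier" coverage of single-copy core
genes is consumed as an input column when available; where it is not, the
Q2–Q3 mean over per-gene coverages is the documented proxy (the exact
MAD-based outlier rule is not reproduced).

## Colonization phenotyping

Subpopulation (strain) profiles are filtered before use: proportions below
1% of a genome's population in a sample are discarded (the rule is strict
"less than", so exactly 1% is retained), and all subpopulation evidence for
a (genome, sample) cell is discarded when single-copy core-gene coverage is
below 10X, or when no coverage information exists for the cell.

For a (genome, recipient) pair the decision tree is: not detected in the
transplant sample → `not_applicable`; detected there but in no recipient
sample taken more than 7 days post-FMT → `not_colonized`; detected
post-window with a filtered subpopulation that is present in the transplant
sample, absent from every pre-FMT sample of that recipient, and detected
post-window → `colonized`; otherwise `undetermined`. "More than 7 days" is
strict (day 8 qualifies, day 7 does not), and the same window is used for
the poor-colonizer clause — a deliberate harmonization of two near-identical
phrasings of the rule. A recipient lacking a usable pre-FMT or post-window
sample is a validation error, and pairs without subpopulation evidence are
`undetermined` rather than guessed. The full truth table over donor
detection × pre-FMT detection × post-window detection × subpopulation
evidence × discriminating-strain existence is tested exhaustively.

Good/poor classification intentionally uses raw detection only (its
definition does not reference subpopulations): good = donor-detected and
post-window detected in all recipients; poor = donor-detected but
post-window absent in at least 3 recipients; the two are mutually exclusive
by construction. When more good than poor colonizers are found, the good set
is reduced to the size of the poor set by keeping the genomes most prevalent
in the reference (healthy-cohort) samples, ties broken lexicographically.

The dose/prevalence analysis fits one joint logistic model of the binary
outcome on both standardized predictors and reports per-predictor Wald
tests; the joint model was chosen (over two marginal fits) so each
predictor's test is adjusted for the other. Perfect or quasi-perfect
separation raises an explicit error instead of returning runaway estimates.

## Enrichment

Occurrence of a module in a genome means completeness ≥ 0.75 — the same
0.75 used by the downstream "at least 75% complete" enrichment criterion,
since no separate occurrence cutoff is published; it is exposed as
configuration. With pooled occurrence p̂ across groups, the statistic

score = Σ_g n_g (p_g − p̂)² / (p̂(1−p̂))

is the Rao score test of the intercept-only binomial GLM against the
group-saturated model and coincides exactly with the Pearson chi-square of
the occurrence table (checked to 1e−9 against an independent implementation
on random tables). p-values use the chi-square upper tail with G−1 degrees
of freedom for all sample sizes — no exact-test fallback, matching the
GLM/Rao formulation; with 20 genomes per group the null rejection rate at
p < 0.05 calibrates to ≈ 0.043, slightly conservative due to binomial
discreteness. Zero-variance rows (p̂ ∈ {0,1}) return (0, 1) rather than NaN.
q-values are Benjamini–Hochberg. A module is enriched in its associated
group (argmax occurrence proportion; ties evaluated per group) when
q < 0.05 (strict), group mean completeness ≥ 0.75 and group occurrence
≥ 0.50.

## MI score

The metabolic-independence score of a genome is the sum of its completeness
over the marker-module set (the modules enriched in good colonizers), so it
lives in [0, |set|]. No numeric HMI cutoff is published; the default
threshold is 0.8 × |set| — chosen to mirror the 75–80% completeness regime
of the enrichment criteria — and is always reported next to the score so
downstream users can re-threshold. Unpaired group contrasts use the
Mann–Whitney rank-sum with continuity correction under the normal
approximation; paired contrasts report the signed-rank statistic V (sum of
positive-difference ranks, zeros dropped — the R convention). Exact
permutation versions exist for small-sample cross-checks in the tests.
Category percentages are computed against the module-set size, so modules
carrying several categories can make the percentages sum past 100%.

## Synthetic data: what it emulates and what it does not

The generators reproduce the statistical structure the analysis relies on,
at the study's scale: 443 modules of which 33 are planted as differential,
occurrence probabilities 0.95 vs 0.10 between 20 good- and 20 poor-colonizer
genomes with a 0.30 background, 3–8 KOs per module, one donor with five
recipients sampled pre-FMT (day −1) and on days 7/30/90/180 (day 7
deliberately sits outside the strict >7-day window), 20 healthy reference
samples for prevalence, and bimodal detection (presence ≈ N(0.9, 0.05),
absence ≈ N(0.02, 0.02) clipped to [0,1] — near but not exactly zero so the
0.25 threshold is genuinely exercised). Subpopulations are drawn per sample
with Dirichlet(5) proportions, 1–3 strains per genome, with sub-1% strains
planted to exercise the proportion filter. A 50-genome cohort plants 20
good, 20 poor and two of each decision-tree branch case (absent from the
transplant sample, present pre-FMT, sub-10X coverage, sub-1% discriminating
strain, and sporadic colonizers). All randomness derives from
`numpy.random.default_rng` seeded with fixed per-generator substreams of one
seed, so outputs are byte-identical across runs and platforms.

Planted (differential) modules are restricted to modules that can actually
express the planted effect: modules that participate in nesting are excluded
so KO pools stay independent across modules, and modules containing a `--`
gap step are excluded because their attainable completeness is capped below
1 under the default gap policy, which would contradict the generator's
contract that a genome carrying the full KO set of a route scores a complete
module. Both features remain exercised by the background modules.

What passing these benchmarks does **not** show about real data: KO
annotation error and incompleteness (the generator plants exact KO sets),
compositional coupling between genomes in a sample, real strain phylogenies
(subpopulations here are exchangeable labels), uneven sampling timelines,
and any relationship between genome size, taxonomy and module content.
Recovery rates on synthetic cohorts are upper bounds on what identical
settings achieve on real metagenomes.

## Problem sizes and numerics

The test suite runs the full 443-module, 20+20-genome enrichment condition
and a 10,000-replicate null calibration directly; the shared fixture for
unit tests is scaled down (80 modules, 8 genomes per group, 20 cohort
genomes), where enrichment power is naturally lower — those tests assert
plumbing and calibrated lower bounds, while the full-scale guarantees live
in the acceptance tests and `scripts/acceptance.py`. Floats are written to
TSV at 4 decimals; the synthetic generator quantizes subpopulation
proportions to survive that rendering with valid sums. Output tables carry
a `#` provenance header (version, seed, config hash) that every reader
skips.

## Known limitations

* The flat-file reader handles ENTRY/NAME/DEFINITION/CLASS records only —
  enough for definitions and categories, not a general KEGG parser.
* Complex components must be single KOs; parenthesized groups inside a
  `+`/`-` complex are rejected rather than interpreted.
* The enrichment model has no covariates; confounding between groups (e.g.,
  phylogeny) must be handled by the matched-subgroup design upstream.
* `run_supplementary_reproduction` expects long-format tables with
  documented column names (a column map handles renames); spreadsheet
  parsing is out of scope.
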