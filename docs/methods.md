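# Methods

This note documents the models, parameter choices and numerical
conventions behind each pipeline stage, what the synthetic-data
generators do and do not emulate, and the design decisions taken where
the underlying procedures were open to interpretation.

## Screen design and combinatorics

The screen design is declared, never inferred: a config lists species,
genes, gene absences per species, and a symmetric divergence-time
matrix (million years, zero diagonal). Ortholog discovery is out of
scope. Each present (gene, species) ortholog is one protein with
exactly four constructs — bait and prey, each tagged N- and
C-terminally — because terminal fusions can mask binding surfaces or
disturb folding, and testing a pair in all bait×prey tag combinations
reduces the false-negative rate. A heterotypic pair therefore has 8
configurations (2 bait tags × 2 prey tags × 2 orientations); for a
homotypic pair the orientation swap is the identity at the construct
level, so it has 4 distinct configurations. Pairs are canonically
ordered lexicographically on (gene, species) so pair identity is
independent of input order.

The default roster covers 11 piRNA-precursor-biogenesis genes (Rhi,
Del, Cuff, Kipf, Moon, TfIIA-S, Trf2, CtBP, Boot, Nxf3, UAP56) across
five *Drosophila* species, with Kipferl absent from *D. persimilis* and
*D. virilis*: 53 proteins and 1431 unique pairs (308 intra-species).
Published descriptions of this screen variously state 53 or 54
proteins; only 53 is consistent with the 308/1123/1431 pair
combinatorics, so 53 is used here. Default divergence times are
approximate literature values (Dmel–Dsim 5 My; melanogaster subgroup to
Dere 13 My; melanogaster group to Dper 30 My; anything to Dvir 40 My)
and are config inputs, not constants.

## Replication scoring

Colony sizes are discretized at thresholds (t_low, t_high): below
t_low → 0 (no growth), below t_high → 1 (background colony), at or
above t_high → 3 (fully grown spot). The upper boundary is inclusive.
The defaults (0.25, 0.6) apply to the simulator's normalized 0–1 size
scale; real-data thresholds are instrument-specific and user-supplied.
The growth score 0 is this package's explicit representation of
"no colony" (schemes that count only 1 and 3 leave absence implicit);
the ratio denominator is always all stamped positions.

Scoring proceeds: per configuration and biological replicate, ratio =
#(score 3)/#positions; a configuration passes the replication gate only
if every biological replicate in which it was tested had ratio > 0, and
then contributes its maximum per-replicate ratio; pair score = sum over
configurations (≤ 8). Decisions worth noting:

* The gate treats a configuration tested in a single biological
  replicate as vacuously passing. Both the gate rule (`all_positive` |
  `majority`) and this behavior are configurable.
* The call threshold comparison is inclusive (score ≥ 0.75 is
  positive), which is asserted explicitly in tests since calls exactly
  at the cutoff are reported in practice.
* Auto-active baits are flagged from mating-free selective plates: any
  control position at score 3 flags the bait (a minimum fraction is
  configurable). Auto-active preys are flagged when positive with more
  than half (configurable) of all non-auto-active baits, and only when
  tested against at least 8 distinct baits — stickiness is growth with
  *many independent* baits, and in a very small screen a genuine
  interaction would otherwise be indistinguishable from auto-activity.

## Trajectory classification

Per gene pair, the calls form a matrix over (species of gene A's
ortholog) × (species of gene B's ortholog); cells are positive,
negative, or untested/absent. Untested and absent cells never enter
denominators. For homotypic gene pairs the matrix is symmetrized by OR
and unordered species combinations are counted once. Distance groups
default to the exact unique divergence values; both orientations of an
inter-species test fall in the same group (they have the same
divergence). Custom bins are supported.

The labels are assigned by explicit rules, evaluated in precedence
order with defaults θ_c = 0.5, θ_f = 0.25, mono_tol = 0.1,
k_restrict = 2:

1. **not_detected** — no positive cell.
2. **conserved** — fraction ≥ θ_c in every tested distance group.
3. **coevolving** — intra-species fraction ≥ θ_c, fractions
   non-increasing with distance within tolerance, and fraction ≤ θ_f in
   the largest tested distance group.
4. **species_restricted** — positives exist and, for at least one of
   the genes, come from orthologs of at most k_restrict species.
5. **sporadic** — everything else.

The qualitative conserved/coevolving/species-restricted taxonomy is
standard for cross-species interaction data; the thresholds and
precedence are this package's formalization and are all surfaced in
`TrajectoryParams`. The monotonicity tolerance is applied as a sup-norm
band around the isotonic non-increasing fit (pool-adjacent-violators)
rather than as a bound on successive differences: adjacent distance
groups can hold very different numbers of tested cells (the 5-cell
intra group sits next to the 2-cell closest-species group), where a
single false negative moves a group fraction by 0.2 and successive-
difference checks misfire. The band accepts exactly the borderline
(0.8, 1.0) inversion at the default tolerance.

With a single-species design only distance group 0 exists, so only
not_detected and (intra-only) conserved are reachable; this degenerate
case is asserted in the tests.

## Pairwise dN/dS (NG86)

The estimator is the classic Nei–Gojobori counting method, chosen as a
methodological stand-in for DnaSP-style pairwise dN/dS (that family of
tools defaults to NG86-type counting); it is not a bit-exact clone of
any particular program.

* Site counts: at each codon position, the synonymous fraction of the
  three single-nucleotide changes is computed over non-stop changes
  only, renormalizing so s + n = 3 per codon (one of the two standard
  stop-exclusion conventions; the exhaustive oracle in the tests pins
  it down).
* Difference counts: averaged over all k! substitution pathways between
  two codons, skipping pathways through stop codons; when every pathway
  passes through a stop (possible for some 2–3-step pairs) the average
  is taken over all pathways as a documented fallback.
* Jukes–Cantor correction d = −(3/4)ln(1 − 4p/3); ω is flagged
  undefined when dS = 0 and non-finite when either proportion reaches
  saturation (p ≥ 3/4).
* Codon columns with gaps, ambiguity codes or stops in either sequence
  are dropped entirely (complete deletion).

Site-model likelihood-ratio tests of positive selection (CODEML-style
M7/M8/M8a) are out of scope; `write_phylip` exports the filtered
alignment for users who wish to run them externally.

## co-IP/MS enrichment

"Normalization across all protein groups of all samples" is
implemented as per-sample median centering of log2 intensities
(configurable to quantile normalization) — median centering is the
least-assumptive choice when the normalization method is not further
specified. A protein group enters a (group, biological replicate)
sample only when detected in **all** of its technical replicates, then
technical replicates are averaged. The t test is Welch's (unequal
variance, two-sided, unpaired by default; one-sided available) and the
adjustment is Benjamini–Hochberg. The fold-change threshold is applied
strictly on the linear scale (ratio > 1.5, i.e. |log2FC| >
log2 1.5 ≈ 0.585) together with −log10(adjusted p) > 2. Missing values
are never imputed; proteins with fewer than two replicate values on
either side are flagged untestable, not dropped. Tukey's fences use
linear-interpolation (type-7) quantiles. Preprocessing is idempotent on
already-centered log2 data to numerical tolerance.

## Synthetic-data generators

All generators are pure functions of (config, seed).

**Y2H screens.** The default configuration emulates the study
conditions: the full 53-protein roster, 60 planted true pairs, 10
auto-active bait and 2 auto-active prey constructs, baits screened in 2
or 3 biological replicates, preys stamped at 3 or 4 technical
positions (~97,000 stamped positions per screen). Colony sizes are
drawn from two beta modes on [0, 1] (negative mean 0.1, positive mean
0.8) so size discretization is meaningful. Tag interference is modeled
by making each configuration of a true pair independently detectable
with probability 0.75; detectable positions grow fully with probability
0.85, all others with a 0.01 spurious rate. Mating-free control plates
use their own spurious-growth rate (default 0): without prey-dependent
reporter activation, full growth on selective medium reflects genuine
bait auto-activity rather than mating-plate background. Precision and
recall of downstream calls are evaluated against planted pairs with at
least 4 detectable configurations surviving QC — a pair whose signal
was planted into fewer working configurations is not a fair recall
target at the 0.75 cutoff.

**Trajectory matrices.** Planted labels generate full 5×5 call
matrices: conserved plants positives everywhere; coevolving plants
positives with logistic probability in divergence (default midpoint
9 My, scale 0.75 My — inter-species signal essentially confined to the
closest species pair, matching the coevolution signature of
nearest-neighbor-only detection, and steep enough that the noiseless
limit is deterministic); species-restricted confines positives to one
gene's orthologs from 1–2 species; not_detected plants none. Noise is
signal dropout: each planted positive flips negative with probability
`flip_noise` (default 0.1). Spurious positives are controlled by a
separate rate defaulting to 0, because Y2H noise after auto-activity QC
is dominated by false negatives — and because a symmetric flip would
make the not_detected class unrecoverable by construction under the
classifier's own precedence rules.

**Codon pairs.** A deliberately simple mutation–acceptance scheme, not
a full codon substitution model: an ancestor of uniform random sense
codons evolves along two independent lineages; substitution attempts
arrive as a Poisson process (half the target divergence per lineage),
each attempt mutates one random position to a random alternative base
(optionally transition-weighted), stop-creating attempts are rejected,
and synonymous/nonsynonymous attempts are accepted with relative
probabilities 1 : ω. Its adequacy is established empirically: the NG86
estimator recovers ω = 1 within ±10% on 50 neutral simulations of 3000
codons at divergence 0.2, and estimates are monotone in planted
ω ∈ {0.2, 1, 2}. The scheme has no codon-frequency or rate-class
structure and does not emulate indels.

**co-IP tables.** Baseline log2 intensities are normal (mean 20,
sd 1.5); two bait groups and a GFP reference group each get 4
biological × 2 technical replicates; planted enrichment multiplies 15
protein groups per bait by 8-fold; biological noise is a 10% CV
(log2-sd log2(1.1)) plus small technical noise; missingness is an
intensity-dependent logistic dropout anchored so a protein at the
baseline mean drops out with the configured probability (default 0.1;
0 and 1 give the exact degenerate limits). Exact hit recovery is
checked at missingness 0 (the low-noise configuration): with dropout
enabled, low-abundance planted proteins can lose control-side
replicates and become legitimately untestable, which is the filtering
semantics working as intended, not an estimator failure.

## Problem sizes and determinism

The test suite and the acceptance script run entirely on generated
data: one full-roster screen (~97k observations), 200 trajectory
matrices per noise level, 50 + 20 codon simulations of 3000 codons, and
co-IP tables of 150–400 protein groups — a few seconds per stage on one
CPU. All randomness flows through `numpy.random.default_rng` seeds
carried in the config objects; identical configs give byte-identical
outputs.

## What passing tests do and do not show

The simulators establish that the scoring, classification and
statistical machinery recover known truth under the stated noise
models. They do not establish performance on real screens, where
colony-size distributions are instrument-specific, auto-activity can be
marginal rather than binary, detection failures correlate across
configurations of the same construct, codon evolution has
composition/rate structure the simulator lacks, and co-IP missingness
mixes abundance dependence with stochastic peptide sampling. The actual
published call counts for the motivating screen (199 interacting pairs
from 89,088 tests) are not reproducible here because the raw colony
counts are not publicly deposited; the pipeline reproduces the *rules*
that produced them.
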