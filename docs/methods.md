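# Methods

`convphy` analyses tandem gene families whose history mixes divergent and
concerted evolution — the situation exemplified by the vertebrate TLR1
family (avian TLR1A/B and TLR2A/B, mammalian TLR1/2/6/10), where
gene-conversion events between tandem paralogues have repeatedly
homogenized parts of the coding sequence while the rest diverged normally.
This note records the models, the numerical choices, and what the
synthetic benchmarks do and do not establish.

## Gene-conversion detection

**Fragment statistic.** Within a group alignment, the polymorphic columns
are listed (columns containing any gap or `N` are excluded so alignment
artifacts cannot seed fragments). For a sequence pair, a *fragment* is a
maximal run of consecutive polymorphic columns at which the pair agrees;
by default no mismatches are tolerated inside a fragment (a configurable
mismatch-free convention). A run of `L` matching sites for a pair with
match probability `q = 1 − tot_difs/n_poly` scores `−L·log q`, so the
score grows both with run length and with the pair's overall divergence.

**Significance.** Two p-values are attached to each fragment. The
*simulated* p-value permutes the order of polymorphic columns (default
10,000 pseudo-replicates; `(1+hits)/(R+1)` convention, seeded). The
*KA-type* p-value is the tail probability of the longest success run given
the pair's match/mismatch counts — the quantity Karlin–Altschul theory
approximates for maximal-segment scores — computed *exactly* by big-integer
inclusion–exclusion over arrangements, then Bonferroni-multiplied by the
number of pair comparisons in the scan and capped at 1. The exact tail
agrees with exhaustive enumeration identically and with the Poisson/KA
form in the far tail.

**Tract calling.** A conversion tract older than a few My is interrupted
by post-conversion substitutions, so mismatch-free fragments tile it
rather than span it, and the tract appears as a dense stretch of matching
polymorphic sites. Calling is seed-and-extend: a fragment with corrected
p < 0.05 seeds a call (no seed, no call — the family-level false-positive
rate is set by the corrected threshold alone), and the extent is the
maximal-scoring segment containing the seed under per-site log-likelihood
ratios of tract (match probability 0.95, or halfway to 1 when the
background is already high) versus the pair's global match probability;
overlapping calls merge. Recovery of simulated tracts ≥ 300 columns at
ages up to ~20 My achieves Jaccard ≥ 0.9 median against truth; the
residual errors are boundary erosion on the oldest tracts.

**Bootscan.** Sliding windows (default 200 columns, step 20) are
bootstrapped by column resampling (default 1,000 replicates); per
replicate an NJ tree is built from closed-form F84 maximum-likelihood
distances and the query's partner is the taxon that shares a two-leaf
split with it. Saturated bootstrap distances are replaced by 1.25× the
largest finite distance in that replicate — just above the observed range,
because a large inflation distorts the NJ Q criterion toward cross joins;
a display-profile concession; point estimates elsewhere never clamp
saturation, they flag it.

## Phylogenetics

Distances: closed-form F84 (with transition/transversion decomposition,
reused by the saturation screen) and two-sequence ML distances under HKY85
or the embedded Jones–Taylor–Thornton (1992) protein model. Neighbor
joining is implemented on numpy arrays (the bootscan calls it ~10⁵ times;
library tree objects dominate runtime at n ≤ 10) and is exact on additive
matrices; scikit-bio's NJ serves as an independent cross-check in the test
suite. Saturated distances cause the offending taxon to be dropped from NJ
with a warning rather than clamped.

Likelihoods use Felsenstein pruning over pattern-compressed alignments
with per-node rescaling, a spectral (symmetrized eigendecomposition)
transition-matrix cache, and L-BFGS-B on log/logit-transformed parameters.
Rate heterogeneity: proportion of invariable sites plus discrete gamma
with 4 equal-probability categories (category rate = within-bin mean).
The two-phase bootstrap protocol is supported by freezing rate parameters
estimated on the point alignment (`estimate=()`), then rebuilding trees on
column-resampled replicates. Tree search beyond NJ is
nearest-neighbor-interchange hill climbing — adequate for the ≤ 30-taxon
families targeted here, and a deliberate simplification relative to full
ML tree search.

Quartet likelihood mapping scores the three topologies of sampled quartets
by ML branch lengths and converts the posterior weights to simplex
regions. A quartet is *resolved* when one topology carries weight > 2/3;
pairs of competing topologies (smallest weight < 1/6) fall in edge
regions, the remainder in the center. Only the resolved proportion is used
downstream; the region geometry is a documented package choice.

## Codon site models and positive selection

The substitution process is GY94: single-nucleotide codon changes at rate
proportional to the target codon frequency, × κ for transitions, × ω for
amino-acid-changing substitutions; frequencies default to F3x4 (F61 and
equal available). Site-class mixtures M0, M1a, M2a, M7, M8 and M8a are
fitted by maximum likelihood; the beta distributions of M7/M8 use 10
equal-probability categories with within-bin means. M2a's third class is
constrained to ω₂ ≥ 1 (the usual convention for the positive-selection
class; unconstrained ω₂ is unidentifiable against the ω < 1 class).

**Branch-length protocol.** Branch lengths are estimated once under M0
(full per-branch optimization from an NJ starting tree), then each site
model re-optimizes a single shared tree-scale factor together with κ and
its class parameters. This mirrors the common fixed-relative-branch-length
protocol for site-model batteries and stabilizes the nested-model lnL
ordering; full per-model branch optimization remains available
(`branch_mode="full"`). Each fit uses two starting points with the
ω-type parameters initialized low (0.5-style) and high (2.0-style), the
second start warm-started from the first fit's nuisance parameters.
Optimizer: L-BFGS-B, finite-difference step 10⁻⁶ on transformed
parameters, relative lnL tolerance 10⁻¹⁰; in practice fitted lnL values
are reproducible to ~10⁻⁵, and LRT statistics (reported to 0.01) are
clamped at 0 when optimizer noise inverts a nesting.

LRTs: M1a⊂M2a (df 2), M7⊂M8 (df 2), M8a⊂M8 (df 1, with the ½χ²₀+½χ²₁
boundary-corrected p-value also reported). Sites under selection are
identified by naive empirical Bayes at the MLEs — posterior class
probabilities per site, P(ω>1) thresholded at 0.9 — and labelled by the
ungapped residue number of a designated reference sequence ("286Q" style).
NEB ignores parameter uncertainty; with few sequences its site lists are
less stable than Bayes-averaged alternatives, a known limitation.

## Clock dating

Dating runs in two phases: substitution nuisance parameters (κ and ω for
codon data; κ, α, p_inv for nucleotide data) are estimated without a
clock, then fixed while node ages and the rate are optimized under the
clock constraint. Node ages are parameterized as the root age plus
per-node fractions of the parent age, which enforces parent > child by
construction; fossil calibrations are boxes on node ages (point
calibrations pin them), interval interpolation keeps every iterate
feasible, and residual violations (a calibrated node squeezed by its
ancestors) incur a smooth quadratic penalty. Contradictory calibrations
are rejected up front. The local-clock variant allows exactly one extra
rate on user-flagged branches. Two optimizer restarts with perturbed
starting ages guard against the rate/age ridge.

Conversion events are dated from the pairwise divergence of the converted
region: after the transfer the two copies' tract history is a simple
two-lineage split, so `age = d/(2·rate)` with the rate taken from a clock
fit (or an orthologue calibration); rate intervals propagate to age
intervals, and zero divergence is flagged "recent or ongoing".

## Co-evolution scanning

Each variable site is summarized over unordered sequence pairs by the
BLOSUM80 transition score of the two residues divided by the pair's
divergence-time proxy (Poisson-corrected protein distance), centered and
scaled; two sites co-evolve when these vectors correlate (Pearson r).
Inter-molecular scans match rows across two alignments by taxon and use
each protein's own divergence proxies.

Sites must be *informative*: gap-free, with ≥ 3 sequences carrying
non-majority residues and ≥ 3 distinct residues. This filter exists
because weakly variable sites form large families of identical
substitution patterns whose r = 1 correlations reflect nothing but the
shared tree.

Significance is two-stage. Stage 1 screens each pair against an
*empirical* null — the correlations of 10,000 randomly sampled real site
pairs — at 5×α. Because the null is drawn from the same population as the
tested pairs, it carries the full tree-induced background correlation and
is self-calibrating: on null data the fraction passing the screen is the
screen level itself (measured ≈ 0.005 at α = 0.001, against the ≤ 10α
budget). Stage 2 applies a Westfall–Young step-down max-T correction
within the screened candidates (per permutation round, the running maximum
of candidate null statistics ordered by observed rank); the reported p is
the step-down value and significance requires p < α. A plain permutation
null over all pairs was evaluated and rejected: with a shared phylogeny it
declares ~10% of null pairs significant. Significant pairs are grouped
into connected components, labelled by compartment intervals
(extracellular / transmembrane / cytoplasmic) and exported as GraphML/SIF
networks with r as the edge attribute.

## Conversion vs. convergence diagnostic

Over alignment columns where a paralogue pair encodes the identical amino
acid, the fraction whose codons are also nucleotide-identical is computed
per region. Conversion copies silent positions, so the converted region
shows near-total concordance (96–99% in the motivating family) against a
much lower background (57–66%); convergent or conserved evolution leaves
silent positions free. The verdict is "conversion" when the candidate
region exceeds the background by ≥ 0.2 (absolute; configurable — chosen to
split the two observed bands), "convergence" when it does not exceed it at
all, otherwise inconclusive. No formal test is attached to the contrast;
the statistic is descriptive.

The saturation screen tabulates s, v and F84 d for all pairs and flags a
transition plateau when the fitted slope of s on d beyond d = 0.7 drops to
≤ 10% of the slope below (each side needs ≥ 3 finite points).

## Synthetic data

The generator evolves codon sequences by an exact event-by-event (jump
process) simulation of GY94 along a duplicated species tree, so that
events can interrupt lineages at exact times: at a conversion event the
donor lineage's tract (snapped outward to whole codons) overwrites the
acceptor lineage — naming a leaf at a time before its species split
converts the whole descendant clade, as inferred for the primate TLR1/6
pair. `mutation_rate` is the neutral substitution rate per codon site per
My; per-site ω classes scale it. Co-evolving pairs substitute
branch-synchronously: the pair's `allowed_residues` define its repertoire,
and when either site changes amino acid the partner jumps to a random
repertoire residue with the coupling probability. With no pairs (or
coupling 0) the code path and the random stream are identical to the
independent-sites simulator.

**Preset conditions.** The study-shaped preset uses 4 bird + 4 mammal
species (amniote split 315 My), duplication at 359 My, 800 codons, κ=2.5,
ω classes (0.6, 0.35, 0.05) at (0.05, 0.4, 1.0), and a neutral rate of
0.0065 subs/codon/My — chosen so that chicken/turkey-aged orthologues sit
near 93% nucleotide identity and pairs older than ~160 My approach
transition saturation (d > 0.7), matching the divergence regime of the
real family. Conversion tracts cover the C-terminal third at
species-specific times of 5–44 My.

**Benchmark conditions** (fixed before the acceptance tests were frozen):
type-I error of M1a-vs-M2a on 6 taxa × 300 codons; power/site-recovery on
12 taxa × 300 codons with 5% of sites at ω=4 and neutral rate 0.008;
tract recovery on 8 taxa × 700 codons with ≥ 300-column tracts at 8 My;
clock recovery on 6 taxa × 1000 codons (all internal nodes ≥ 40 My, so
sampling variance alone cannot breach the 15% band) with a 90-My
point-calibrated root;
co-evolution on 12 taxa × 300 codons at rate 0.025 with coupled sites at
ω=0.15 and repertoire DEKRH. Problem sizes keep the full suite within a
routine CI run.

**What the simulations do not capture.** No indels (real TLR alignments
are gapped), no alignment error, no codon-usage bias beyond the frequency
model, no rate autocorrelation along lineages, no recombination other
than interval conversion, and duplications are restricted to predate the
species root (the tandem-family case studied). Passing the recovery
suites therefore demonstrates correctness of the estimators under the
generating model, not robustness to alignment artifacts or model
misspecification on real data.

## Degenerate inputs and conventions

Coordinates are 1-based inclusive in every report and config, 0-based
half-open internally. Identity denominators exclude columns gapped in
either sequence; `N`/`X` count as mismatches and are excluded from
polymorphism calls. The standard genetic code only; terminal stop codons
are stripped with a note, internal stops are errors. Region boundaries
off codon frame are trimmed inward to whole codons with a warning.
Eigenvalue products λt are clamped at 0 (rate-matrix spectra are ≤ 0
analytically; roundoff positives otherwise overflow). All stochastic
stages take explicit seeds; the pipeline derives stage seeds from one
top-level seed and reruns are byte-identical.
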