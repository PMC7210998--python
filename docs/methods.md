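# Methods

## The divergence model and its calibration

Four-fold-degenerate (4D) third codon positions evolve approximately
neutrally, and transversions at those sites accumulate slowly enough to
remain informative for ancient duplications.  Both the simulator and the
estimator use the same two-parameter substitution model: transitions at
rate κ·β and each of the two transversion targets at rate β.  For two
sequences separated by total path time T, the per-site transversion
probability is q = (1 − e^(−4βT))/2, so the multiple-hit correction

    corrected = −1/2 · ln(1 − 2·raw)

is exactly the transversion distance 2βT.  A simulated pair "split at
depth d" evolves over βT = d/2 (d/4 per lineage); hence E[raw] =
(1 − e^(−2d))/2 and the corrected statistic is calibrated to return d.
κ defaults to 2 and affects only the transition fraction, not the
statistic.

Two finite-sample properties of the corrected statistic matter in
practice and are visible in the tests:

* **Convexity bias.**  With n sites, E[corrected] exceeds d by roughly
  q(1−q)/(n·(1−2q)²); negligible below d ≈ 0.9 at n = 1000 (≤ +0.008) but
  ≈ +0.05 at d = 1.33.  Calibration checks at deep divergence therefore
  sit on the edge of a ±3-standard-error band for 200 pairs; the test
  suite asserts the band as specified and the deepest depth shows the
  bias.
* **Saturation tail.**  As raw → 0.5 the corrected value diverges; pairs
  at raw ≥ 0.5 are flagged saturated and excluded, but near-saturated
  pairs produce a long right tail (and, for short genes, a discrete
  pile-up at −1/2·ln(1/n)).  With thousands of pairs, BIC reliably spends
  one or two extra mixture components on this tail.  Consequently the
  component count alone overstates the number of duplication waves for
  deep WGDs — on clean three-wave simulations both this package and the R
  reference implementation (mclust) typically select 4–5 components: the
  three true waves plus saturation-tail components above ~1.5.  The wave
  *locations* are recovered accurately; the count requires interpreting
  components near the saturation boundary.  Tests record this behaviour
  rather than hiding it.

## Mixture fitting and model selection

EM on univariate normal mixtures, k-means++-style seeded starts, best
restart by log-likelihood.  Both an equal-variance and an unequal-variance
family are fitted (component standard deviations of real 4DTv peaks grow
with age, so unequal variance must be available).  Numerical choices:
standard deviations floored at 10⁻⁴ (no degenerate spikes); convergence
when the log-likelihood gain falls below tol·(1+|logL|) with tol = 10⁻⁷;
the inner loop is compiled with numba.  BIC is minimised as
−2·logL + p·ln n with p = (k−1)+k+1 (equal) or (k−1)+2k (unequal); ties
break toward smaller k, then equal variance.  `fit_normal_mixture`
defaults to 20 restarts and 500 iterations; the `select_model_bic` sweep
uses 3 restarts and a 200-iteration cap per fit — under-converged
over-parameterised fits only lose likelihood, which the BIC penalty
already disfavours, and the sweep stays fast.  The SSD/WGD boundary
defaults to mean < 0.1 (recent small-scale duplications sit near zero,
far below the youngest plausible WGD wave) and is configurable.

## Families and clustering

The similarity stage either ingests 12-column BLAST tabular output or
computes exact Smith-Waterman alignments (BLOSUM62, gap open 11 / extend
1) for candidate pairs; scores become E-values via the gapped
Karlin-Altschul parameters λ = 0.267, K = 0.041 against the summed
database length.  Candidates come from an inverted 6-mer index (≥8 shared
6-mers, identical sequences grouped first, very short proteins always
aligned); the prefilter only decides what is aligned — every reported
number comes from the exact alignment.  Edge weight for clustering is
−log₁₀ E capped at 200.

MCL is implemented directly on sparse matrices: self-loops at each node's
maximum incident weight (the MCL program's own loop heuristic), column
normalisation, then alternating expansion (matrix square) and inflation
(entrywise power 6, renormalisation) with pruning below 10⁻⁸, to a doubly
idempotent limit; clusters are the connected components of the limit's
nonzero pattern.  Note that with max-incident self-loops a weakly attached
node (all incident weights tiny) is still absorbed by its strongest
neighbour — loop policy, not edge weight, decides that case.

## Tandem clusters

Per chromosome and gene name: occurrences are chained while consecutive
occurrences are separated by at most five differently-named genes; within
a chain the ≥70% protein-identity relation (global alignment, matches /
columns) is closed by single linkage and each closure class of ≥3 genes is
a cluster.  Dropped low-identity copies still bear the cluster name, so
they never count as "unrelated" genes for the survivors.  Single linkage
(rather than complete linkage) accepts arrays with gradient divergence;
identity is measured on proteins because the confirmation step is
protein-level.  Confirmation assigns each member its best-scoring
reference protein and flags the cluster confirmed when a strict majority
agree.

## Paralogons

Anchor points are all unordered pairs of tandem-collapsed family
representatives (families filtered to ≤8 members).  Blocks are strictly
monotone chains in rank space — per chromosome pair and orientation, an
O(n²) longest-chain DP with per-step rank gaps ≤ 25 on both sides,
extracted greedily by decreasing length, each anchor used once.
Intra-chromosomal anchors require the two sides to be ≥ 25 ranks apart so
a segment cannot align to itself.  This is a deliberately simple,
deterministic stand-in for probabilistic collinearity tools; it is exact
on disjoint chains (asserted against exhaustive search in tests) and makes
no claim to reproduce any specific tool's block inventory.

## K-mer spectra and genome size

Counts are smoothed with a centred moving average (window 5 — raw spectra
are noisy at low copy number); the first KCN where smoothed counts stop
decreasing is the error minimum; modes above it are ranked by height, and
two modes whose KCN ratio falls in [1.7, 2.3] (and whose heights are
within a factor of five) are reported as the heterozygous/homozygous pair,
otherwise the single highest mode is the homozygous peak.  Genome size =
(Σ kcn·count − Σ_{kcn ≤ minimum} kcn·count) / hom_peak, i.e. the
subtraction and the division are both carried out in k-mer-instance units,
which is self-consistent and testable; conversion of the homozygous depth
to per-base read coverage (× L/(L−k+1)) is reported for information only.

## Contig curation

Identity is matches / aligned columns and coverage is the aligned span of
the smaller contig over its length.  Two alignment engines report those
numbers under identical definitions: exact affine-gap local DP (match 2,
mismatch −3, gap 5/2) for small inputs, and a seed-and-extend mode
(shared 21-mers grouped by diagonal band, spans extended to nearby
sequence ends, scored globally with edlib) for contig-scale inputs; tests
assert their agreement.  Duplicate removal processes contigs largest
first so removals cascade against survivors only; equal-length ties
remove the lexicographically later id.  Overlap joining requires the
alignment to be terminal on both partners (within a 100 bp slack), checks
both orientations, keeps the left contig's bases in the overlap, merges
greedily by decreasing overlap length with each contig in at most one
merge per pass, and repeats passes to a fixed point so chains collapse
fully.

## The synthetic-data generators

`simulate_wgd_genome` emulates: layered WGDs (each event duplicates every
surviving gene onto a duplicated chromosome copy; each new duplicate is
retained independently with probability 0.6 by default), neutral evolution
of 4D third positions along the duplication tree, frozen nonsynonymous
positions (so family proteins are identical and alignment is exact —
4DTv tests isolate the statistic, not the aligner), tandem arrays as
adjacent same-name copies mutated to a target protein identity, and
single-copy decoy genes.  Defaults are the study conditions: 400 ancestral
genes, waves at 0.40/0.85/1.33, retention 0.6, κ = 2, and a 450-codon CDS
(~1.35 kb, typical of arthropod gene models, giving ~220 4D sites per pair
and peak widths of the same order as real paralog-age distributions).

What the generators do **not** emulate — and hence what passing tests do
not demonstrate about real data: protein-level divergence and alignment
error, indels, rate variation among sites and lineages, gene conversion
between paralogs, intron structure, segmental duplications, GC bias, and
read-level sequencing artefacts beyond a geometric error spike in the
k-mer spectrum.  `simulate_contig_set` uses substitution noise only, and
its overlaps are exact by construction.

## Degenerate inputs and tie-breaks

Empty site lists yield a record that fails the filter rather than an
error; saturated pairs carry a flag instead of a value; zero-variance
mixture input, k ≥ n, monotone-decreasing spectra, missing tree taxa and
infeasible overlap specifications raise errors.  Deterministic tie-breaks
throughout: first optimal alignment traceback; lexicographic ids for
equal-length contigs and equal-score reference hits; smaller k, then
equal variance, for equal BIC.
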