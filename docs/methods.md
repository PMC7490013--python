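# Methods

This note documents the models implemented in `tecsuite`, their
assumptions, the parameters that matter, what the synthetic-data
generators do and do not emulate, and the numerical choices made where the
design was genuinely open.

## TCR rearrangement simulation

**Model.** A thymocyte attempts to assemble a beta chain, then — only on
success (allelic exclusion) — an alpha chain. Per allele, the beta chain is
tried twice: the first attempt draws V and D uniformly and takes J and C
from the first cassette (TRBJ1/TRBC1); a retry takes them from the second
cassette (TRBJ2/TRBC2). Both alleles failing means no receptor. The alpha
chain gets one attempt per allele (uniform V and J, single C). At every
junction (beta: V–D and VD–J; alpha: V–J) an untemplated insert of
Poisson(λ) nucleotides, uniform over {A,C,G,T}, joins the segments.
λ defaults to 4, so a beta attempt carries 8 inserted nucleotides in
expectation and an alpha attempt 4.

**Productivity.** An attempt is productive when some ATG lying entirely
within the chosen V segment opens a reading frame that (i) ends exactly at
the final base of the constant segment (span divisible by 3, ≥ 3 nt) and
(ii) contains no stop codon strictly before that final codon. Any
qualifying ATG suffices, not only the first. No exonucleolytic trimming is
modelled — junctions only gain nucleotides.

**Second-attempt resampling.** On a cassette-2 retry, V and D are resampled
along with J/C. Resampling everything is the simplest symmetric choice; the
alternative (holding V/D fixed) changes nothing observable under uniform
segment sampling.

**Clonotypes.** The CDR3 clonotype of a productive attempt is the
amino-acid translation, in the productive frame, of the junction window:
the last `flank_nt` (default 9) nucleotides of V, the insert(s) (plus D for
beta), and the first `flank_nt` of J, snapped inward to codon boundaries of
that frame. The flank is configurable because CDR3 boundaries are not
defined for simulated germline sequences. Repertoire diversity is the
Shannon entropy of clonotype frequencies, base 2 (bits) by default and
configurable.

**Reporting denominators.** `frac_beta_valid` is computed over all
simulated thymocytes; `frac_alpha_valid` over the thymocytes that reached
alpha rearrangement, consistent with the sequential model;
`frac_alpha_valid_overall` (over all thymocytes) is also reported so either
convention is available.

**Simulation modes.** `mode="attempts"` simulates exactly n thymocytes;
`mode="productive"` runs until n productive pairs and guards against
non-termination (default cap 1000·n attempts) for loci that admit no
productive rearrangement.

## Synthetic germline loci

Segments are random sequences with configurable per-base composition.
Spurious ATG triplets are scrubbed from V segments and a single ATG is
planted at a configurable offset in a configurable fraction of V segments.
Productivity of an attempt is then governed by one frame: the planted ATG
must reach the final base (probability ≈ 1/3 over insertion lengths) and
meet no stop codon. Default segments are short (V 36–48 nt, D 10–14, J
15–21, C 21–30) with a T-poor composition (A/C/G/T = 0.30/0.25/0.30/0.15),
keeping per-attempt productivity in a realistic range — real V(D)J segments
achieve the same by being ORF-biased, which uniform random sequence is not.
A fraction of zero planted ATGs produces a sterile locus on which every
attempt fails (the degenerate control). The synthetic locus makes no
attempt at sequence-level mimicry of the murine locus; the published
validity percentages (63.1% beta, 40.2% alpha) depend on real sequence
content and are only reproducible with the real segment set, which users
can supply as a FASTA.

## QC and normalisation

Plate-mode QC removes cells with ERCC spike-in fraction > 0.40, depth
< 10⁵ read pairs, or sparsity > 97%. Droplet-mode QC removes barcodes with
< 1000 UMIs or mitochondrial fraction above the per-sample median + 2×MAD
fence. The MAD is the raw median absolute deviation (the literal
definition); the 1.4826 normal-consistency factor is exposed as
`mad_scale`. The fence is one-sided — only high mitochondrial content
indicates damage. Both filters are idempotent.

Size factors: `library_size` (per-cell total over the geometric mean of
totals) is the reference method; `deconvolution` implements a pooled-ratio
scheme — cells ordered by library size on a ring, pooled counts compared to
the average cell profile over several window sizes, per-cell factors
recovered by sparse least squares, rescaled to unit geometric mean. On
homogeneous data the two agree closely; deconvolution is more robust to
zero inflation in heterogeneous data. Expression is log₁₀(count/sf + 1),
preserving the zero pattern.

HVG selection fits a polynomial (degree 2) trend of per-gene variance on
mean log-expression and tests each gene's excess variance with
(n−1)·var/trend ~ χ²(n−1) (upper tail), BH-adjusted; the default FDR is
10⁻⁷. If the variance structure is degenerate the top-K residual-variance
genes are returned instead (flagged by warning).

## GF-ICF and clustering

G\_f = log₂(C + pseudocount): the pseudocount (default 1) is required
because log₂(0) is undefined; zeros map to zero. ICFₓ = log₁₀(N/(1+Eₓ))
with Eₓ the number of cells expressing gene x; a gene expressed everywhere
gets a small negative ICF which is retained, not clipped. The transform
up-weights rarely expressed genes — in TEC the promiscuously expressed
tissue antigens — and is monotone in C per gene.

The SNN graph joins cells that appear in each other's k-nearest-neighbour
lists (Euclidean; neighbour sets include the cell itself), weighted by the
Jaccard overlap of the two sets, pruning zero weights. Walktrap (step
length 4) produces a merge dendrogram cut at maximum modularity. The
partition depends only on the weighted graph, so it is invariant to cell
order. A practical caveat measured during development: on isotropic
Gaussian clouds the modularity cut oversplits communities unless k is
comparable to the cluster size; expression-like matrices with marker
structure do not show this at the default sizes (k = 10 plate-style, k = 31
with 20 PCs droplet-style).

Consensus robustness re-clusters over a parameter grid (with/without
GF-ICF, several k) and reports the cell×cell co-clustering frequency plus
the mean within-reference-cluster consensus. For independent random
partitions with cluster proportions p the expected off-diagonal consensus
is Σpᵢ², which the tests verify.

kNN label transfer cosine-normalises both matrices per cell, applies an
injected batch corrector (identity default; per-batch mean-centering
shipped; mutual-nearest-neighbour correction can be plugged in), and votes
among the k = 5 nearest reference cells, breaking ties by smallest mean
distance to the tied class.

## Hashtag demultiplexing

Within a sample: (1) CPM-normalise counts per barcode across the expected
HTOs; (2) k-means (k = number of expected HTOs, 10 seeded restarts) on the
CPM profiles; (3) per HTO, exclude the partition with the highest mean CPM
for that HTO and the top 0.5% of raw counts, fit a negative binomial to
the remaining raw counts and set q at its 99th quantile; (4) assign the
HTO to every barcode with raw count ≥ q; (5) barcodes with exactly one
assignment are Singlets, more than one Multiplets, none Dropouts.
Clustering operates on CPM while thresholds apply to raw counts — mixing
the two scales is easy to get wrong and deliberate here.

**Numerical choice.** The NB background is fitted by maximum likelihood
(Nelder-Mead on log-parameters) initialised from the moment estimates. The
pure moment estimator is badly non-robust to the handful of signal-level
doublet counts that survive the exclusion steps: ~1.5% contamination
inflates the moment-based q by an order of magnitude, while the likelihood
fit moves far less. Degenerate backgrounds fall back as flagged in the
output: constant counts give q equal to that constant; variance ≤ mean
gives a Poisson quantile.

**Generator conditions.** The HTO mixture generator defaults to six
hashtags per sample — the pooled design the algorithm was built for —
with NB(mean 500, size 10) signal and NB(mean 5, size 10) background.
With only two hashtags the procedure degrades structurally: every doublet
contaminates exactly one HTO's background (k-means cannot isolate a
doublet cluster), and no estimator choice recovers the threshold; the
two-HTO case is therefore covered by degeneracy tests, not recall targets.

## Tau index and tissue representation

τ = Σᵢ(1−x̂ᵢ)/(n−1) with x̂ᵢ = xᵢ/maxⱼxⱼ over n ≥ 2 tissues; τ is
scale-invariant, lies in [0,1], is 0 for uniform and 1 for single-tissue
profiles, and weakly decreases as expression spreads. All-zero genes are
excluded with a warning (τ undefined). Classes: TRA at τ ≥ 0.8,
constitutive at τ ≤ 0.4, miscellaneous between. A TRA gene is assigned the
tissue of maximal expression; exact ties go to the first panel column and
are logged. No detectability floor is applied by default (panel values are
already normalised maxima); callers can pre-filter.

Tissue representation counts, per cell and assigned tissue, the TRA genes
with log-normalised expression > 0 (i.e. any non-zero normalised count),
aggregates over cells within (age, replicate), and also reports the
percentage of each cell's expressed genes classed as TRA. Aggregated counts
equal the sum of per-cell counts by construction, feeding the NB abundance
model directly.

## Diffusion pseudotime and meta-stable states

PCA (20 components by default when the input is wider) feeds a kNN graph
(k = 21); the diffusion map is the eigendecomposition of the resulting
transition operator and DPT is the random-walk diffusion distance from a
root cell. The root defaults to the cell with the lowest DC1 — the apex of
bifurcating lineages — and can be supplied. DC signs are arbitrary;
downstream consumers orient by a known anchor when needed. A disconnected
kNN graph is an error naming the component sizes.

Two measured properties of the random-walk DPT worth knowing: (i) even on
a noiseless curve the ordering admits rare adjacent-rank swaps (Spearman
ρ ≈ 0.9996, not exactly 1); (ii) in the thin-manifold regime — many cells,
near-zero off-manifold noise — the λ/(1−λ) weighting of diffusion
components degenerates (high-order, fine-scale components get eigenvalues
≈ 1 and dominate the distance) and DPT decouples from the latent order
although DC1 remains clean. The trajectory generator therefore defaults to
a realistic embedding noise (sd 0.2 against state sds of 0.5 on the latent
axis), which is also what keeps the kNN graph connected, matching the
continuous density a real differentiation trajectory shows.

Density along pseudotime is a Gaussian KDE (Silverman bandwidth,
configurable) evaluated at ⌈0.01·n⌉ points spanning the DPT range.
Meta-stable states are a 1-D Gaussian mixture (2 or 3 components as the
branch requires) fitted by EM with 10 seeded restarts, tolerance 10⁻⁶;
cells take their max-responsibility component and states are relabelled by
ascending mean DPT so state 1 is always least differentiated.

## Abundance and trend models

`nb_abundance_test`: per group, counts ~ age (weeks; optionally + age²)
in an NB GLM with log link. The NB dispersion is estimated once per group
by method of moments on a Poisson pilot fit of the *full* model and shared
between the full and intercept-only fits, so their deviances are
comparable — estimating it per model silently destroys the test. The total
cells captured per replicate enter as prior (variance) weights, normalised
to mean 1. The age terms are tested with a quasi-likelihood F-test: the
Pearson dispersion of each group is shrunk toward the across-group mean
(prior df 10), and the denominator df is the residual df alone — crediting
the prior df makes the far tail, where BH at FDR 1% operates,
anticonservative because the dispersion is itself estimated. A
likelihood-ratio chi-square is available as `method="lrt"` and labelled in
the output. Under the stated simulation conditions (slope −0.1/week,
dispersion 0.1, 5 ages × 5 replicates, baseline 500) the test attains full
power with ~93% 2-SE slope coverage, and the empirical false-discovery
proportion over all-null simulations stays well under 2% at nominal 1% —
both recomputed by `scripts/acceptance.py`.

`poisson_state_test`: per meta-stable state, replicate cell counts ~ age in
a Poisson GLM; Bonferroni across the states of a lineage; significance at
adjusted p ≤ 0.01. `offset_selection_test`: wave counts ~ age with
log(parent population) as offset, so the coefficient is the age trend of
the selected fraction and joint rescaling of wave and parent changes
nothing; BH at FDR 1%. `age_expression_trend`: vectorised OLS of
log-normalised expression on log₂(age) plus log(size factor) as a depth
adjustment; constant genes get slope 0 and p = 1; BH across genes. The
week-scale age in the abundance models versus log₂(age) in the expression
model is deliberate — the two questions are calibrated differently.

## Synthetic single-cell counts

Cells are Poisson draws from per-cluster mean profiles (lognormal baseline,
fold-boosted disjoint marker blocks, a TRA block expressed only in one
mTEC-like cluster, constant-mean ERCC genes, flagged mitochondrial genes),
with lognormal per-cell depth, Bernoulli dropout, and multinomial cluster
composition that shifts with age. Ground truth (cluster labels, TRA tissue
map, marker identities) is returned beside — never inside — the AnnData
the pipeline consumes. What this emulates: discrete subtype structure,
composition shifts, spike-in/mito fractions, dropout. What it does not:
batch effects, ambient RNA, UMI saturation, doublet transcriptomes, or
continuous differentiation within clusters — so green tests here show the
algorithms recover the structure they assume, not that real data meets
those assumptions.

## Problem sizes

The default test and acceptance runs use 10⁵ simulated thymocytes, 500-cell
clustering matrices, 2000-barcode hashtag mixtures, 1350-cell trajectories,
and 200 power / 500 null GLM simulations — sizes at which every measured
quantity is stable to the third digit across seeds while the whole suite
runs in minutes on one CPU.

## Known limitations

* The rearrangement simulator models insertions but not exonucleolytic
  trimming, and uniform segment usage rather than locus-position biases.
* The deconvolution size-factor implementation is a compact pooled-ratio
  scheme, not a re-implementation of any published estimator's exact
  pooling design.
* Mutual-nearest-neighbour batch correction is an injection point, not an
  implementation.
* Walktrap-at-maximum-modularity has a resolution scale set by k (above).
* The HTO background model assumes doublet contamination of each HTO's
  background is small after the exclusion steps; heavily doublet-loaded
  two-hashtag designs violate this structurally.
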