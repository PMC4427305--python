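# Methods

This note documents the models, conventions and numerical choices behind
nirpipe, and what the synthetic-data tests do and do not establish about
real data.

## Read filtering and demultiplexing

MID barcodes are matched by Hamming distance on the fixed-length 5′
prefix (tolerance 1); no indel tolerance, since MIDs are short synthetic
tags designed for substitution-robust decoding. If two MIDs both fall
within tolerance the read is rejected as ambiguous rather than assigned
arbitrarily. The forward primer is matched next with IUPAC degeneracy
(tolerance 2). The length (≥ 200 bp) and homopolymer (> 8 nt) filters
apply to the *trimmed* read: barcode and primer are synthetic and carry
no sequencing noise of interest. Filter order is fixed — barcode,
primer, length, homopolymer, chimera, contaminant — and each stage's
report conserves reads (kept + rejected = input), which the pipeline
asserts on every run.

## Frameshift repair of coding reads

454 homopolymer miscalls insert or delete single bases; in a
protein-coding amplicon one such error frameshifts the rest of the read.
We align each read to a position-specific scoring profile built from a
user-supplied reference protein alignment: columns with > 50% gaps are
dropped, residue frequencies are smoothed with a pseudocount (default
0.5) and converted to log₂-odds against a background (uniform 1/20 by
default). The alignment DP has five moves: codon match (3 nt, scored by
the profile column), frameshift deletion (2 nt; repaired by appending
`N`, translated as the neutral residue X), frameshift insertion (4 nt;
the base whose removal scores best is dropped), and whole-codon
insertion/deletion relative to the profile at a linear per-codon gap
penalty (default 8 bits). Frameshift moves cost 12 bits by default —
high enough that spurious frameshifts in clean reads are never
profitable, low enough that a single real indel always pays for itself.
Alignment is semi-global (free leading/trailing profile columns; at most
2 unaligned trailing read bases kept verbatim). Equal-score paths prefer
non-frameshift moves, then the leftmost placement; inside repeated
motifs the reported frameshift position can therefore shift by a few
codons from the physical error while producing an identical (or
synonymously equivalent) repaired sequence. The DP is verified against
brute-force enumeration of all alignment paths on small instances.

A full profile HMM with trained transition probabilities would make the
same corrections at amplicon scale; the explicit matrix form was chosen
because it is directly verifiable and has two interpretable knobs. Its
bit scores are *not* HMMER bit scores, so published score thresholds
(e.g. 107 / 48 in comparable surveys) do not transfer numerically;
thresholds here are calibrated per marker, and on synthetic pools true
reads and shuffled decoys separate by a wide margin.

## Dereplication, preclustering and chimera removal

After dereplication, residual sequencing noise is absorbed by an
abundance-greedy precluster: a unique sequence merges into the most
abundant seed within 2 edit operations that is at least twice as
abundant. This is the standard stand-in for flowgram-level denoising
(which needs raw flowgrams nirpipe does not model) and bounds the
all-pairs distance stage to a few thousand sequences even at survey
scale.

Bimera detection scores each unique against candidate parents at ≥ 2×
its abundance: the score is the identity gain of the best two-parent
single-breakpoint mosaic over the best single parent (exhaustive
breakpoint search on per-position identity profiles from global
alignments). A query is flagged when the gain exceeds 0.02, both
segments span ≥ 30 bp, *and* the mosaic explains the query at ≥ 98%
identity. The third condition is essential: a genuine bimera is its
parents' mosaic up to sequencing error, whereas for a genuinely
divergent sequence a patchwork of relatives can also beat the best
single parent by > 2% — without the identity condition, rare real taxa
are systematically flagged. On synthetic nir-like pools (identity
0.70–0.90) the scorer reaches ≈ 0.89 sensitivity at zero measured false
positives; on 16S-like pools (0.80–0.95) sensitivity drops to ≈ 0.75
because many simulated joins are locally identical to one parent and
carry no detectable signal — a limitation shared by any chimera
detector.

## Distances and clustering

Pairwise distance = (mismatches + internal gap events) / (columns where
both sequences have a base), terminal gaps ignored, a contiguous gap run
counting once — the mothur "onegap" convention. The reference engine is
a Needleman-Wunsch alignment with match 1 / mismatch −1 / gap open −2 /
extend −1; above 80 unique sequences the pipeline switches to edlib
(unit-cost edit distance), whose alignments of closely related amplicons
are near-identical and ~100× faster. Clustering is agglomerative with
average linkage (nearest/furthest available), merging while the linkage
distance ≤ cutoff; average linkage is monotone, so cutting the scipy
dendrogram reproduces the merge-while-below-cutoff semantics exactly,
which a brute-force agglomeration oracle confirms. OTU representatives
are the most abundant member (ties: lexicographically smallest id);
OTUs are labelled `Otu0001…` by decreasing total abundance.

The functional cutoff calibration clusters the coding sequences at each
grid value (default 0.05–0.20, step 0.01), translates the
representatives, and computes amino-acid p-distances (pairwise-deletion
convention). The chosen cutoff is the **smallest** grid value at which
all representative pairs have AA distance > 0. Smallest-qualifying was
chosen because it retains maximal resolution while meeting the
uniqueness criterion; surveys reporting calibrated cutoffs do not state
the selection direction, and the grid and rule are both arguments.
The 16S path skips calibration and uses the conventional 0.03.

## Diversity and community statistics

Chao1 uses the bias-corrected form `S_obs + n₁(n₁−1)/(2(n₂+1))` (defined
when doubletons are absent) with the standard variance and log-normal CI
on the estimated excess. The inverse Simpson CI uses the delta method on
the concentration D (`var(D) ≈ 4/N(Σp³ − (Σp²)²)`); mothur's variance
formula differs slightly, so CIs carry a method tag. Rarefaction is the
exact hypergeometric expectation (log-gamma arithmetic), not
resampling; a Monte-Carlo oracle bounds it in tests. The abundant
partition is strict (> 1%): an OTU at exactly 1% is non-abundant.

Group-level Jaccard and Bray-Curtis are computed on replicate-pooled
counts (one value per group pair, the way survey tables print them);
per-replicate matrices feed the PERMANOVA, which uses Anderson's
partitioning of squared distances (`SS_total` from all pairs divided by
n, `SS_within` per group divided by group size) and unrestricted label
permutations, `p = (1 + #{F* ≥ F}) / (1 + n_perm)`. The non-abundant
level is the observed universe minus the union of the pooled groups'
abundant sets. Simulated exchangeable communities put the PERMANOVA
type-I error at the nominal 5% within Monte-Carlo error.

Univariate tests support summary-statistics entry (mean, SD, n) because
environmental covariates are typically published as mean ± SD; a pooled
t-test is the default with a Welch fallback gated on a Brown-Forsythe
Levene pre-test, all two-sided. Mann-Whitney U uses midranks with exact
enumeration of group splits up to a combined n of 16 and a tie-corrected
normal approximation beyond.

The undetected-diversity estimator formalises a back-of-envelope
argument: if detected functional-gene OTUs (D) all fall in lineages
holding a fraction f_det of total 16S diversity, other gene-bearing
lineages hold f_other, and the denitrifier/non-denitrifier ratio is
stable across lineages, then U = D·f_other/f_det OTUs were missed and
the detected share is D/(D+U). It is linear in D and f_other and only
as good as its three assumptions, which the package states but cannot
check.

## qPCR quantification

Standard curves are least-squares fits of Cq on log₁₀ copies over the
10¹–10⁹ dilution series; efficiency `10^(−1/slope) − 1`; detection limit
= lowest level with all replicates amplified; curves with efficiency
outside [0.6, 1.1] are flagged. The inhibition factor is the fractional
recovery of a known spike in the sample matrix, with the sample's own
(uncorrected) signal as background: factor = (recovered − background) /
spike, clamped to (0, 1]; recovery > 1.2 is a data-inconsistency error.
Corrected copies/g = mean replicate copies × dilution ×
(extract volume / template volume) / (factor × mass) — replicates are
aggregated on the copy scale, matching the mean ± SD presentation of
survey tables, and correction *divides* by the factor, so corrected
values exceed raw ones. Default volumes are 50 µl extract / 2.5 µl
template per reaction, all configurable. Under triplicate noise of
0.15 Cq and inhibition factors 0.3–0.6, simulated truth is recovered
within ±25% for ≥ 95% of samples.

## The synthetic-data generator

Marker pools radiate from a random ancestor (450 bp for 16S-like,
474 bp — divisible by 3 — for nir-like, matching 454 Titanium read
lengths). When the divergence budget allows, each taxon mutates a
disjoint position set, making pairwise distances exact; otherwise
positions are random and distances concentrate around the requested
midpoint. Coding taxa are built codon-wise (no internal stops by
construction), differ at the protein level, and carry synonymous
variants within a 9-nt radius. Communities draw lognormal (default
σ = 2) or log-series abundances — at survey-like sizes this yields a
small abundant (> 1%) fraction and a long rare tail; note that for pools
of ~200–250 taxa the abundant *fraction* is around 7–10% (the abundant
*count* being a handful), and falls below 5% only for pools of ~1000
taxa. Reads are barcode + primer + template with uniform substitutions
(default 10⁻³/nt), homopolymer indels with probability proportional to
run length above 2 (default 5·10⁻³ per unit), and two-parent chimeras
(default 2%) with breakpoints uniform in the middle 60% of the template
(end-chimeras are trivially undetectable and uninformative). Every read
has exactly one truth record; every generator is a pure function of its
seed.

What the generator does **not** model: flowgram-level error structure
and quality scores, PCR amplification bias, intra-genome 16S copy
variation, and real phylogenetic (non-star) topologies. Passing tests
therefore establish algorithmic correctness under a controlled error
model, not field performance on arbitrary 454 runs; in particular
chimera sensitivity and frameshift-repair rates on real data depend on
the true divergence structure of the community.

## Problem sizes and determinism

The test suite exercises the full pipeline at 30 000 reads/sample × 6
samples (180 000 reads, 250 taxa), which completes in a few minutes on
one CPU thanks to the precluster stage and the edlib distance engine;
unit tests use pools of 2–40 taxa where the exact Needleman engine runs.
All randomness flows from `RunConfig.seed` (or an explicit seed
argument) through numpy Generators; no global random state is touched,
and repeated runs with one seed produce byte-identical artifacts.
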