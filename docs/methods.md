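# Methods

This note records the modelling and numerical choices behind `somgrn`:
what each stage assumes, which knobs matter, what the synthetic data does
and does not emulate, and where the design was genuinely open.

## Genome partitioning and RPKM

Peaks from all chromatin experiments are flattened into covered segments
split at every peak boundary (0-based half-open BED coordinates
throughout; narrowPeak summit columns are ignored).  Segments shorter than
`min_size` (default 200 bp) are merged left-to-right into a contiguous
preceding covered segment, else a contiguous following one; an isolated
short segment is kept and symmetrically padded to `min_size`, clipped at
chromosome ends and flagged.  This merge rule is deterministic and
idempotent: re-partitioning the output reproduces it exactly.  Reads are
assigned to the partition containing their 5′ end (strand-aware), avoiding
double counting; RPKM uses the per-experiment total mapped read count, not
the in-partition sum, so partitions are comparable across experiments.

## SOM training

Classic online Kohonen training on a hexagonal lattice ("odd-r" offset
layout; lattice distance is the hexagonal cube-coordinate metric; metric in
data space is Euclidean).  Defaults: α₀ = 0.1; σ₀ = max(rows, cols)/2
(at least 1); both decay as exp(−t/λ).  λ is set so that σ reaches
`sigma_min` (default 0.2 lattice units) at the last presentation.  A final
radius *below* one lattice spacing is required for units to decouple in the
endgame — with a floor of 1, neighbouring units feel 61% of every update
forever and can never converge to separated cluster means (the 1×2-lattice
two-blob fixture demonstrates this).  Each trial trains on a seeded 50%
row split and is scored by mean quantization error on the **full** matrix;
the best of `trials` wins.  Weights are initialized by sampling data rows
with replacement.  Default preprocessing is log₂(x+1): TPM/RPKM span four
orders of magnitude and untransformed training lets a few high rows
dominate the map; identity and per-row max-normalization are selectable.

## Lattice-contiguous metaclustering and model selection

The constrained k-means grows k regions greedily from random seed units
(always attaching the unassigned frontier unit closest in weight space to
an adjacent cluster centroid, ties broken by unit index), then iterates
boundary reassignment that accepts a move only if the donor cluster stays
connected, until RSS stops improving (max 100 sweeps); best of `trials`
restarts by RSS.  On planted two-block 4×4 lattices this matches the
exhaustive optimal contiguous 2-partition exactly; on unstructured weights
it is, like any k-means, a local optimizer.

k is selected by AIC (default; BIC selectable) under the spherical-
Gaussian mixture likelihood with pooled variance σ² = RSS/(d(n−k)), the
cluster-size (mixture-weight) term Σ nᵢ ln(nᵢ/n), and parameter count
p = k(d+1).  The mixture-weight term matters: without it the criterion is
nearly flat past the true k on lattice-sized problems (each extra cluster
buys ≈2(d+1) of RSS) and selection becomes noise.  With it, planted k=3
at 5× separation is recovered in 20/20 seeded lattices.

Per-metacluster condition contrasts use the paired two-sided Wilcoxon
signed-rank on member genes (exact null for n ≤ 25, normal approximation
with continuity correction above; zero differences dropped), BH-corrected
across metaclusters.  Paired (not rank-sum) because each gene contributes
one value per condition.  Fold changes use pseudocount 1 on the TPM scale.

## Linking

A region links to the gene minimizing |region midpoint − TSS| on its
chromosome within 1 Mb; ties go to the lexicographically smaller gene id.
Midpoint (rather than edge or summit) is symmetric and deterministic; TSS
anchors regulation at promoters.  Strand never affects distance.  All
k_RNA × k_DNA LM bins are enumerated, empty bins retained, so bin counts
are a pure function of the two clusterings (16×88 → 1,408; 84×88 → 7,392).

## Motif scanning and exact p-values

PWMs are scored as Σ log₂(P_pwm(b)/P_bg(b)); the background is the genome
base composition.  The null score distribution is computed exactly by
discretizing per-position scores to 10⁻³ bits and convolving the
position-wise distributions under the background — so p(hit) = P(score ≥
observed) carries no sampling error beyond binning.  The scanner uses the
*same* discretized score matrix as the DP, so every observed score
coincides with an atom of the null support; zero-probability entries are
floored far below any achievable score and surface as p = 1.  The DP
matches brute-force enumeration of all 4^w words exactly for every tested
w ≤ 8 PWM.

**BH family.**  q-values are computed per motif within one linked
metacluster's scanned positions (both strands), mirroring a separate
scanner run per LM.  A family pooled over *all* scanned positions is not
usable for short degenerate consensi: for `AATMHACA`, P(match) ≈ 9.2×10⁻⁵
per position, so with ~10⁵ pooled positions and tens of true sites the
best attainable q is p·m/n ≫ 0.1 — no signal of this class can ever pass,
independent of data quality.  The per-LM family is self-normalizing: the
attainable q scales as p · (positions per region) / (sites per region),
independent of LM size.

**Density enrichment.**  Per (LM, motif), the fraction of the LM's regions
with ≥1 hit is tested one-tailed against the pooled global fraction with a
normal z (a region counts once however many hits it carries), BH across
all (LM, motif) pairs, retained at q < 0.05 (a p-mode flag exists because
the enrichment is sometimes thresholded on p directly).  The z test
assumes each LM is a small fraction of the pooled regions; when one LM is
a large share of the pool the test becomes conservative (the calibration
experiment uses 30 LMs of 200 regions, where the empirical type-I error is
within 3 SE of the nominal 0.05).

## Filter cascade, FPR/FDR, CRM scores

"TF ChIP signal in the 75th percentile" and "enriched Ep300 signal" are
both formalized as: metacluster mean RPKM ≥ the 75th percentile (linear
interpolation) of per-metacluster means.  One rule for both keeps the
cascade auditable; the expression filter retains RNA metaclusters whose
mean member TPM exceeds 1 in at least one selected stage.  Every stage
logs motif and unique-gene counts; the counts are monotone by
construction and asserted in tests.

The unchanging-gene test is TOST: both one-sided normal tests of
|log₂FC| < 0.5 on log₂(x+1) replicate means, p = max of the two.
Per-gene variances at 2–3 replicates are unusably noisy, so they are
moderated toward the genome-wide mean variance (empirical-Bayes weight:
prior df 10 against residual df n₁+n₂−2), with a small additive SE
stabilizer (0.05) for all-zero genes.  Power depends on replicate
variability: at log₂-SD 0.2 (a typical well-expressed gene) ≥60% of true
nulls are called unchanging at n=3; at 0.25 the TOST+BH call rate drops to
~24% — the resulting true-negative sets are smaller but remain valid for
FPR estimation (they are conservative, not biased).  FPR and FDR are plain
set ratios in percent; on the published set sizes (5,864 true negatives,
696 overlap, 6,717 predicted) they evaluate to 11.87% and 10.36%.

CRM effect scores are group means of RPKM over the CRM's partitions for
five signal groups plus their arithmetic mean; agreement with observed
perturbation effects is ranked by Spearman correlation.  Spatial regulator
labels come from the Pearson correlation between a TF's spatial profile
and its predicted targets' mean profile (activator r>0, repressor r<0),
reported only when the TF's own spatial differential test is significant.

Region-set overlap significance uses a per-chromosome circular-shift
permutation (uniform offset, wrap-around; a region split by the wrap
counts once), p = (1+#{null ≥ obs})/(n_perm+1).  The p-value is valid for
any shift-invariant null and is discretely conservative through ties;
calibration uses region densities high enough that the tie mass is small,
where the p distribution is indistinguishable from uniform by KS at 200
replicates.

## The synthetic study

One seed generates everything downstream of sequencing:

* **Genome and genes** — i.i.d. uniform sequence; 150 genes in evenly
  spaced slots (jitter bounded to a third of a slot) across 2 × 8.4 Mb
  chromosomes, so neighbouring TSSs sit ~112 kb apart; TSS at the
  strand-appropriate end of a 2 kb body.
* **Planted network** — 3 TFs × 20 disjoint targets.  TF consensi come
  from a fixed pool headed by the Fox-type `AATMHACA` and Sox-type
  `ACAAWRG` patterns; each edge's CRM (300 bp) is placed 1–50 kb from the
  target TSS, rejecting placements whose midpoint is nearer another gene's
  TSS (nearest-gene ambiguity between neighbouring genes is real biology
  but not what the planted network is meant to test).  Each CRM carries a
  homotypic cluster of 4 exact consensus realizations on random strands —
  enough sites per region that the per-LM q-value of a true site sits
  safely below 0.1 for the weakest (7-mer) pattern.
* **Hard negatives** — decoy CRMs near non-target genes carry the
  published knockout substitutions (`AATMHACA→AAGMHAAA`,
  `ACAAWRG→ATAGWRG`); accidental matches of the original pattern inside a
  decoy are scrubbed.  Decoys get full active-enhancer chromatin, so only
  the motif stage can reject them.
* **Chromatin** — regions emit peaks and Poisson-placed 50 bp reads
  according to a state signature (active enhancer per TF: own-TF ChIP +
  H3K4me1 + H3K27ac + Ep300 + ATAC; poised; primed; polycomb;
  heterochromatin with 10× lower Ep300 than active).  240 distractor
  regions draw a continuous per-region intensity (log₂-uniform ±2),
  because real chromatin signal is a spectrum and the percentile filters
  assume many populated inactive metaclusters, not a few discrete levels.
  Library depth is 2×10⁷ reads, giving per-region shot noise of a few
  percent, as in real libraries.
* **Expression** — six module mean profiles (Gaussian bumps over six
  stages, amplitude 20–60 TPM over baseline 1; TF-target modules peak
  inside the early-stage window); tissue columns multiply module means by
  planted log₂-uniform spatial factors; each TF's MO multiplies its
  targets' means by the knockdown factor 0.25 against paired control
  columns, 3 replicates each; observed TPM = mean · 2^N(0, 0.25).

What the generator does **not** emulate: read-level sequencing error,
mappability and GC bias, isoform structure, overlapping regulatory
domains, TF cooperativity, or diffuse (non-peak) chromatin signal.
Passing tests therefore show that the pipeline's logic recovers a clean
planted signal at realistic noise; they do not certify performance on the
messier ambiguities of real genomes.

## Problem sizes and runtime

Desk-scale defaults keep the full 20-seed end-to-end evaluation at about
two minutes on one CPU: RNA SOM 12×18, DNA SOM 8×12, 30 epochs, 5 trials,
k searched over 2–12 (RNA) and 6–16 (DNA) with 5 restarts.  These are the
packaged study conditions; map sizes in the hundreds of units and 100
epochs/trials behave identically, only slower.

## Known limitations

* The constrained k-means is a greedy local optimizer; global optimality
  is only guaranteed (and tested) on clearly separated block structure.
* The percentile filters operate on metacluster means; with very few
  populated metaclusters the 75th-percentile cutoff can land between
  near-tied active clusters.
* The density z-test is conservative when one LM dominates the pooled
  region set.
* TOST power falls quickly once replicate log₂-SD approaches half the
  equivalence threshold.
* Nearest-gene linking is midpoint-to-TSS only; no chromatin-loop or
  multi-gene assignment.
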