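# Methods

This note documents the models and procedures `isochrom` implements, the
defaults and why, what the synthetic-data generator does and does not
emulate, and the numerical choices that matter.

## Splice-event classification

Events are found by comparing every unordered pair of a gene's transcript
models on strand-oriented coordinates (the genome axis is negated for
minus-strand genes, so "donor" and "acceptor" always mean the transcript's
5' and 3' intron ends). The rules are local, SUPPA-style, rather than a
global splice graph:

* **SE** — an internal exon of one transcript overlaps nothing in the other,
  and the other carries the direct donor→acceptor skipping junction across
  it (2 inclusion junctions vs 1 exclusion junction).
* **MX** — one internal exon per transcript, mutually non-overlapping,
  sharing both outer flanking splice sites, with neither transcript carrying
  both exons (2 vs 2).
* **RI** — an exon of one transcript strictly contains a junction of the
  other (1 vs 0). Containment is deliberately not required to share outer
  exon boundaries, so an unspliced transcript spanning a 3-exon transcript
  yields one RI per intron.
* **A5/A3** — two junctions sharing one boundary and differing at the other,
  with the *alternative exons overlapping each other* (overlap is what
  separates an alternative splice site from an alternative first/last exon).
* **AF/AL** — non-overlapping first (last) exons whose junctions land on a
  shared acceptor (leave a shared donor).

Duplicate events from different pairs (same type + junction set) are merged
with their transcript sets accumulated. Junctions are reported in genomic
order as (upstream exon end, downstream exon start), 0-based half-open — the
identifiers a junction-count table keys on. Classification is invariant
under genome-axis reflection with strand flip; flipping strand *without*
reflecting swaps A5 and A3 (property-tested).

## PSI and differential PSI

PSI for a skipped exon averages the two inclusion junctions:
`psi = mean(incl_up, incl_down) / (mean(incl_up, incl_down) + skip)`,
undefined (flagged NaN) when all three counts are zero. This is a
deliberate simplification of full probabilistic isoform-assignment
machinery: junction reads are weighted equally and no length model is used.
It recovers planted PSI to ±0.02 at depth 2000 (tested).

ΔPSI = mean(condition 2) − mean(condition 1). Its p-value is a two-sided
permutation test on group labels: exhaustive enumeration of all C(n, n1)
assignments when that count is ≤ 10,000 (then p is the exact fraction — the
observed assignment is one of them, so p ≥ 1/C(n,n1) with no extra
smoothing), otherwise Monte-Carlo with add-one smoothing and a mandatory
seed. Consequence worth knowing: at n = 3+3 the smallest attainable
two-sided p is 2/20 = 0.1, so "significance at 0.05" is meaningless there;
the pipeline reports events at the attainable floor instead. A permutation
null was chosen over a t-test because n = 2–3 per condition supports no
distributional assumptions on PSI.

## Isoform differential expression

Counts → log2 CPM with offsets: `log2((count + 0.5)/(libsize + 1) · 1e6)`.
Isoforms with a zero in any sample are removed *before* normalisation (the
removal list is part of the output). The per-isoform test is a two-group
moderated t: the pooled two-group variance s²_r (d_r = n1+n2−2 df) is shrunk
towards a prior s0² with d0 prior df,

    s²_post = (d0·s0² + d_r·s²_r)/(d0 + d_r),
    t = (mean2 − mean1)/(s_post·sqrt(1/n1 + 1/n2)),  p from t(d0 + d_r).

(d0, s0²) are estimated by method of moments on z = log s²_r using the
scaled-F identities E[z] and Var[z] (digamma/trigamma); the trigamma
inversion is a Newton iteration. When the observed variance of z is below
the trigamma floor, d0 = ∞ (all rows share s0²; the reference becomes
normal). `d0_override=0` reproduces the ordinary pooled t exactly (asserted
to 1e−10); `d0_override=inf` gives the common-variance z-like limit. The
full precision-weight (voom-style) scheme is intentionally not
reimplemented: at the package's design point (deep bulk libraries, ≥ 3
replicates) the log-CPM + moderated-t core carries the analysis.

Thresholds default to p < 0.05 and |log2FC| > 0.5, symmetric and
configurable. No FDR correction is applied to the partition itself (the
analysis contract filters on raw p); a BH q-value column is emitted for
reference. The prioritisation step keeps genes with ≥ 1 *non-principal*
differential isoform (principal flags come from annotation tags or a
sidecar table, never recomputed); genes with no annotated principal
transcript are kept with a warning code rather than dropped.

The qPCR micro-operation `ddcq_fold_change` implements the comparative
2^−ΔΔCq formula and nothing else.

## Chromatin

TSS = strand-aware 5' end of the gene's 5'-most transcript. The promoter
window is ±2 kb (configurable; annotation conventions vary and nothing in
the pipeline is sensitive to the exact choice at the ±kb scale). A peak may
serve several genes; when several peaks serve one gene the max-mean-signal
peak represents it (deterministic and monotone). Open status: signal ≥
threshold, default the median of nonzero peak signals — a scale-free choice
that splits peaks into a more- and less-accessible half. Differential
peaks: ratio of condition means with +1 pseudo-count, strictly > 2-fold
(or < 1/2). Swapping condition labels exactly exchanges the two output sets
(tested). Per-sample grouping is the default; per-condition (majority
status, ties open) is available by flag since bulk designs sometimes warrant
condition-level calls.

## Bayesian integration

Per gene, expression is the log2 of the summed isoform CPMs (transcript
abundances add in linear space), and samples are grouped by that gene's own
promoter status. The group-difference model is a robust two-group
("BEST"-style) formulation:

    y_gj ~ Student-t(ν, μ_j, σ_j),   j ∈ {open, closed}
    μ_j ~ Normal(pooled mean, (1000 · pooled sd)²)
    σ_j ~ Uniform(pooled sd · 10⁻³, pooled sd · 10³)
    ν   ~ 1 + Exponential(1/29)        (or fixed via nu_fixed)

Sampling is random-walk Metropolis-within-Gibbs on
(μ₁, μ₂, log σ₁, log σ₂, log(ν−1)) with log-scale proposals carrying their
Jacobians. Step sizes adapt toward ~0.44 acceptance during burn-in only, so
the retained chain is Markovian. Defaults: 4000 iterations, 1000 burn-in,
2 chains; a seed is mandatory (no silent default). Convergence is
split-chain potential scale reduction on θ (flag at R̂ < 1.1). The sampler
is vectorized across genes sharing a (n_open, n_closed) signature, with each
batch's seed derived from the master seed by signature — results are
independent of batch composition and of which other genes are present.
The marginal likelihood is never computed; the chain targets the
unnormalized posterior.

θ = μ_open − μ_closed. Reported: posterior mean, HDI, P(θ > 0) as the
fraction of retained draws above zero. Genes with an empty or singleton
group are *skipped with a reason*, never fitted; zero pooled sd yields a
flagged point-mass summary.

**HDI.** Shortest contiguous window over the sorted draws containing
⌈mass·n⌉ draws; ties break to the earlier window; at least ⌈1/(1−mass)⌉
draws are required. Verified against an exhaustive window scan up to
n = 5000 and against analytic 95% intervals of N(0,1) and Exp(1).

**Coordination call.** A gene is coordinated iff P(θ > 0) strictly exceeds
0.999 (open-chromatin samples express it more highly) *and* its promoter
peak passed the fold-change rule; the class is open_up when the peak is more
open under condition 2 and closed_down when less open. Note both classes
require θ > 0: in a closed_down gene the open group is condition 1, so
falling expression tracks closing chromatin. The 0.999 comparison is
strict (">"), so a posterior probability of exactly 0.999 is null.

**Power at small n.** The 99.9% criterion is stringent by construction. At
n = 3 per group with replicate noise of ~0.3 log2 units (what an
overdispersion of 0.1 induces at the gene level) even the exact
Behrens–Fisher oracle clears 0.999 for only ~a quarter of genes carrying a
2-log2-unit effect, and the robust model — whose uniform-σ prior is more
diffuse than the oracle's implicit Jeffreys prior — clears it for fewer.
Users should read a null result at n = 3 as "insufficient evidence at an
extremely strict bar", not absence of coordination; the per-gene posterior
summaries carry the graded information. False positives are correspondingly
rare: 0 of 1000 null genes at n = 5 in the calibration run.

**Oracle agreement.** The closed-form check (`conjugate_oracle`, a
Welch-approximate t posterior under a Normal likelihood with flat priors)
is a valid reference only where the robust model reduces to it: Normal
data, ν fixed large, groups big enough that the σ-prior difference
(uniform vs Jeffreys) is immaterial. Agreement is tested at n = 15 per
group, where max |ΔP| ≤ 0.03; at n = 10 the prior difference alone
contributes ~0.03 and the comparison stops being informative about sampler
correctness.

## Motif scanning and enrichment

Scores are log2 odds against a 0-order background (default uniform;
configurable base frequencies). A pseudocount of 0.1 is added to PWM counts
before normalisation to avoid −∞ scores. P-values are exact under the
background model by dynamic programming: per-column scores are shifted
non-negative and discretized onto an integer grid (default 10,000 levels
across the total score range; < 100 rejected), and the distribution of the
integer sum is built by convolution across columns. The scanner computes
the *same* integer score for each window, so a hit's p-value is exactly the
DP survival value; the only approximation is the grid itself, with absolute
score error bounded by width/scale. Verified against full 4^w enumeration
for widths up to 8.

Both strands are scanned by scoring the reverse-complement matrix on the
forward sequence; the background is complemented too, so the RC log-odds
matrix is exactly the 180°-rotated forward matrix and one DP table serves
both strands. Windows containing N are skipped; coordinates are
forward-strand 0-based starts.

Multiple testing across reported hits uses Benjamini–Hochberg (step-up with
monotonicity enforcement, order preserved) rather than a π₀-estimating
q-value method — a recorded divergence from some scanning tools' defaults;
on the sparse-signal regimes here the two differ negligibly and BH is the
more conservative choice. TF-target overlap uses the upper-tail
hypergeometric with an explicit, caller-supplied universe (no silent
genome-wide default), BH-adjusted across TFs. Gene assignment of hits uses
the gene span (5'-most start to 3'-most end), optionally promoter-extended.

## Synthetic data generator

The generator emulates a two-condition bulk design — wildtype vs transgenic,
3 replicates each by default — with every planted signal recorded in a
ground-truth manifest sufficient to score the downstream stage.

* **Annotation**: per planted gene, the minimal transcript pair realising
  its event type, from fixed exon templates (mirrored within the gene span
  for minus-strand genes so the transcript-oriented type is preserved).
  The default event mix (AF 27%, A5 23%, SE 22%, A3 13%, RI 8%, AL 5%,
  MX 1%, remainder single-transcript genes) reflects the canonical
  proportions of a differential-alternative-transcript signature in
  neural-progenitor data; allocation is largest-remainder, so planted counts
  are deterministic. Transcript 1 of each pair is flagged principal.
* **Counts**: negative binomial with variance μ + αμ² (α = 0.1 by default, a
  standard bulk RNA-seq overdispersion; α = 0 gives the Poisson limit).
  Gene base means are log-uniform in [20, 2000], split across isoforms by a
  Dirichlet(5) draw. A configurable fraction of genes (default 10%) gets a
  2-log2-unit effect in the transgenic condition, applied to a non-principal
  isoform whenever one exists (the alternative-isoform switch genes).
* **Junctions**: per sample, junction totals are Poisson(depth) (default
  2000 — junction-level coverage consistent with a deep bulk library) and
  each junction count is a binomial thinning (inclusion at psi, skipping at
  1 − psi), so the PSI estimator is unbiased by construction. The default
  planted pair is (0.02, 0.25): near-absent exon skipping in wildtype rising
  to a quarter of transcripts in the transgenic condition.
* **Accessibility**: one promoter peak per gene (±250 bp around the TSS),
  log-normal noise (σ = 0.3). Coordinated genes (default 10%, split evenly
  open_up/closed_down) change by 4-fold and draw their baseline from the
  low (open_up) or high (closed_down) end of the signal range, so their
  samples genuinely cross the open-status threshold between conditions;
  the matching expression shift is applied by the counts generator through
  a shared, deterministically derived assignment.
* **Sequences**: i.i.d. background at configurable GC (default 0.42),
  with occurrences of a 21-bp RE1-like matrix (a constructed
  consensus-shaped PWM, *not* a database matrix) sampled from the PWM and
  inserted without overlap at recorded positions and strands.
* **TF target sets**: one planted TF covering most coordinated genes plus
  uniform decoy sets, to exercise the enrichment stage end-to-end.

Randomness: one master seed; each generator derives its stream via a stable
CRC-32 hash of its name, so adding a generator never perturbs the others,
and identical config + seed reproduce byte-identical outputs (tested).

What the generator does **not** emulate: read-level artefacts (mapping,
positional/GC bias, fragment-length effects), correlated library-size or
batch structure, distal regulatory elements (every peak is promoter-local),
dependence between splicing and accessibility beyond the planted classes,
and realistic genome composition (no repeats, no real gene structure).
Passing tests therefore demonstrate correctness of the *computational
contract* — recovery of known signals under the stated noise models — not
performance on real sequencing data.

## Problem sizes and runtime

The default verification runs use 700 genes for event recovery, 200
replicate draws for PSI recovery, ~2000 isoforms for DE calibration, 1000
genes at n = 5/group for Bayesian null calibration, 100 datasets at
n = 15/group for oracle agreement, a 200-gene end-to-end demo, and 1 Mb of
sequence for motif recovery — sizes at which every Monte-Carlo tolerance
above is comfortably resolved while the full suite and the acceptance
script each complete in about a minute on a single core, thanks to the
gene-vectorized sampler.

## Known limitations

* Event classification is pairwise-local; complex nested events that only a
  splice graph can represent are out of scope.
* PSI ignores junction-length and read-assignment effects; it is a junction
  count ratio, not a posterior isoform abundance.
* The DE stage tests isoforms marginally; no gene-level aggregation test.
* The integration model shares nothing across genes; at n = 3 its 99.9%
  criterion has very low sensitivity (see above).
* The qPCR formula assumes equal amplification efficiencies.
* BH controls FDR under independence/PRDS; scanning windows overlap, so the
  q-values on dense hit clusters are approximate.
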