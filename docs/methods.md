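# Methods

## Data model and coordinates

All computations live in transcript space: 0-based, half-open
intervals on the spliced sense strand. GFF3 (1-based inclusive) and
fixedStep wiggle (1-based) are converted at the file boundary. A
transcript carries one CDS whose length is a codon multiple, the
amino-acid sequence of that CDS, and zero or more uORFs entirely
upstream of the CDS start; a uORF's `end` excludes its stop codon, so
intervals cover exactly the translated codons. Count matrices are
integer features × samples tables for one assay (RPF or RNA) with
complete genotype/treatment/replicate metadata.

## Differential testing: the NB interaction model

For each feature the eight counts of a two-condition comparison (two
assays × two conditions × replicates) are modelled as

    y_ij ~ NB(mu_ij, alpha),   mu_ij = s_j * m_cell(i),
    Var = mu + alpha * mu^2,

with library size factors s_j as offsets and a free mean per
assay × condition cell (the model is saturated in the cells). The
quantity of interest is the interaction

    b = [log m(num, test) − log m(num, ref)]
      − [log m(den, test) − log m(den, ref)],

the log ratio-of-ratios: log ΔTE when numerator/denominator are
RPF/RNA, log ΔRRO when they are uORF/CDS footprints. Cell means are
NB maximum likelihood given the dispersion, solved per cell by damped
Newton iteration on the score equation (vectorised across features;
60 iterations max, relative tolerance 1e-10; non-convergent features
fall back to the moment estimate and are flagged). With equal size
factors within a cell the MLE equals the normalised count mean, so on
balanced designs the estimate coincides with the plug-in log
ratio-of-ratios. The Wald variance of b is the sum over cells of the
inverse Fisher information of log m, `1 / Σ_i μ_i/(1+αμ_i)`.

**Dispersion.** Per-feature method of moments on size-factor-
normalised counts pooled over cells, then stabilised against a
mean-dispersion trend (trimmed means in ≤15 quantile bins of log mean,
linearly interpolated). The working value is
`trend + 0.5 × max(featurewise − trend, 0)`: a feature is never
allowed below the trend, and only half of any excess above it is
kept. With two replicates the feature-wise estimate is extremely
noisy and frequently zero; flooring at the trend is what keeps the
test calibrated.

**Reference distribution.** The Wald statistic is referred to a t
distribution with df = 2 × Σ_cells (n_cell − 1) — the residual df
plus an equal prior df reflecting the half-weight trend shrinkage, in
the spirit of quasi-likelihood moderation. The plug-in normal
reference is visibly anticonservative at two replicates (its tails
ignore dispersion-estimation noise); with the t reference, twenty
5000-gene null simulations yield zero BH discoveries at FDR < 0.25,
matching the design goal that a two-replicate comparison at this FDR
should call nothing under the null.

**Normalisation.** `size_factors` offers total-count (library total
over the geometric mean of totals) and DESeq-style median-of-ratios.
The differential test defaults to median-of-ratios: when a handful of
genes respond strongly, library totals absorb their signal and
total-count normalisation biases every other gene's ΔTE by the same
log offset (~0.2 log2 in our 40-fold-injection simulations);
the median of per-feature ratios is robust to this. Total-count is
the natural choice for display-level normalisation (rpm wiggle
tracks) and is retained for it.

**Detection filter.** A gene is tested only if its mean raw RPF and
mean raw RNA counts over all samples of the comparison are ≥ 1
(configurable). BH-FDR is computed across tested genes only.

## Conditional-dependence classification

Given the four log₂ΔTE contrasts (double-perturbation vs single,
treatment within mutant, treatment within WT, mutation alone), a gene
is *conditional* iff the first two are ≤ −t_down and the last two are
≥ −t_tol; defaults t_down = 0.5 and t_tol = 0.25 echo the 1.41-fold
(2^0.5) convention for an "appreciable" change. Genes with a missing
contrast are unclassifiable. For display the ΔTE matrix is ordered by
average-linkage hierarchical clustering (Euclidean); rows are sorted
lexicographically first so ties break deterministically.

The rule is exact, so its error rate is set entirely by the noise of
the contrast estimates. With two replicates at dispersion 0.01 the
contrast SE is ≈ 0.2–0.25 log₂ — the same size as t_tol — and
threshold misclassification is unavoidable at the percent level.
The pipeline therefore reads the pattern within the set of genes
already significant (FDR < 0.25, downward) in the double-vs-single
contrast, as one would on real data; and the classifier-validation
simulations use deep, tight libraries (dispersion 0.002, mean counts
~1000, replicate r ≈ 0.998) so that label errors reflect the rule
rather than counting noise. Noise behaviour of the estimates
themselves is what the null-calibration and effect-recovery suites
measure.

## uORF occupancy

RRO = uORF footprints / parent-CDS footprints, per sample; the
condition value is by default the mean of per-replicate ratios (the
ratio of summed counts is available; the difference is second order).
Eligibility is inclusive at the stated boundaries: mean uORF RPF ≥ 2
AND mean CDS RPF ≥ 32 over the combined samples of the comparison —
counts *below* the cutoffs are excluded. Because both count sets come
from the same footprint libraries, library size factors cancel in the
ratio and the differential test uses unit offsets. Set-overlap
enrichment is the exact hypergeometric upper tail
P(X ≥ overlap); the universe defaults to the genes tested in the
relevant TE contrast. A Fisher-style two-sided reading is possible
but the upper tail is the question actually asked ("are functional-
uORF mRNAs over-represented?").

## Pause scores

Footprint 3′-ends are assigned to the codon containing
`position − offset` (default 18 nt), which places the assigned codon
as the *first* (E-site) codon of the tripeptide held by that
ribosome; the A-site codon — the one being decoded, and the one whose
tRNA supply sets the dwell time — is the motif's third codon. A
site's pause score is the footprint rpm at that single ribosome
position divided by the mean rpm of the surrounding CDS; using the
single position (rather than averaging the motif's three codons)
keeps the A-site signal undiluted — a ×3 dwell appears as ≈ ×3/mean-
dwell, not ×1.5 — while a flat profile still scores exactly 1.

Flanks are handled at codon resolution: ⌈window/3⌉ = 17 codons each
side for the 50 nt default, excluding the motif's own three codons.
Sites whose flank would leave the CDS, and sites over a zero-mean
flank, are excluded. Per-motif scores are means over all scored sites
in the translatome; motifs with fewer than 100 occurrences in the
transcriptome are dropped. Condition comparisons report per-motif
score pairs, the median ratio of the highlighted A-site residue group
(default Val), and a Mann-Whitney U p against all other motifs.

Note the arithmetic of the floor: a transcriptome of C total codons
spreads over 8000 tripeptides, so motifs average C/8000 occurrences —
the 100-occurrence floor needs C ≳ 10⁶. Pause analyses should be run
on transcriptomes of at least that size (the validation simulations
use ~4.6 M codons so the median motif clears 500 scored sites); on
smaller toys, lower `min_occurrence` explicitly.

## Polysome-gradient TE

For each pooled fraction f with ribosome multiplier k_f (0 for the
unbound pool, which never contributes):

    level_f   = 2^−(Ct_target − Ct_18S)                (within-fraction)
    volume_f  = (V_f / 300 µl) × (25 µl / evol_f)
    recover_f = (A260 share of f) / (18S share of f)   (within-gradient)
    G         = mean polysomal A260 over the parallel set / this gradient's

    load = Σ_f level_f · volume_f · recover_f · G · k_f
    TE   = load / (input level, 2^−ΔCt vs the reference mRNA)

`evol_f` is the volume of the 25 µl extract containing 5 µg RNA. The
"2^−Ct" of qPCR practice is implemented as 2^−ΔCt against the
within-fraction 18S (or the reference mRNA for inputs); an absolute
2^−Ct would only add a constant that cancels in every reported ratio.
Each factor is exactly 1 when its distortion is absent, and the
generator emits observables by the exact forward model, so
estimate ∘ simulate is the identity to machine precision without
noise, and unbiased to ≪ 2% under 5% measurement noise (Monte-Carlo,
1000 replicates). The cross-gradient factor G assumes every gradient
loads the same monosome+polysome content per A260 of extract;
gradients whose polysomal A260 deviates > 25% from the parallel-set
mean are flagged (`recovery_flag`) since the assumption is then
suspect. ΔTE is the per-replicate treated/untreated ratio,
summarised as mean ± SEM (sd/√n, n ≥ 2) with a Welch t-test between
genotypes; two zero-variance identical ratio sets report p = 1
(no difference).

## The synthetic generator

One integer seed drives everything through numpy's PCG64; distinct
SeedSequence streams separate transcriptome, counts, per-condition
tracks, and gradients, so outputs are byte-identical per seed and
independent of call order. `noise=False` replaces draws by
expectations (count matrices then carry exact fractional values and
every estimator must return truth exactly — the generator/estimator
consistency contract).

Defaults emulate the emulated study's conditions: 2000 genes,
CDS 100–400 codons, 5′UTRs 90–250 nt, 2×2×2 design; log-normal
baseline expression (median 150 counts, σ = 1.3 nats); NB dispersion
0.01 per assay, which puts replicate log-count correlations near the
r ≈ 0.99 of tight biological replicates; 25% of genes carry a uORF
(AUG:near-cognate 50:50; annotated/conserved/functional 50/30/20;
mostly inhibitory), with baseline RRO log-normal around 0.08.
TE effects, RRO effects and motif dwell factors are injected per
condition through explicit maps; ribosome 3′-ends are placed at
`E-codon start + offset` so track simulation and codon assignment are
exact inverses, and A-sites are restricted to codons 2..L−1 so no
reads are lost at CDS edges.

What the generator does *not* emulate: raw reads and their biases
(ligation, rRNA contamination, mappability), footprint-length
heterogeneity and length-dependent offsets, reading-frame structure
within codons, 5′UTR/uORF occupancy outside annotated uORFs,
between-gene dispersion variation, and the mechanistic reinitiation
behaviour of GCN4-class leaders. Passing tests therefore demonstrate
the correctness and calibration of the estimators under the stated
count model, not robustness to those real-data artefacts.

## Numerical and degenerate-input conventions

* Features with an all-zero cell get a 0.5 pseudocount for fitting
  and a `zero_cell` flag; all-zero libraries are errors.
* BH q-values pass NaNs through; q is monotone in p by construction.
* Hierarchical-clustering ties and report orders are made
  deterministic by lexicographic pre-sorting.
* Empty motif tables, empty eligible-uORF sets, single-replicate SEM
  requests, zero monosome areas, zero library totals with rpm
  requested, and orphan uORFs all raise typed errors naming the
  offender rather than propagating NaNs.
* The gradient occupancy profile is a truncated Poisson over 1..10
  ribosome pools rescaled so expected ribosomes per mRNA equal the
  TE exactly; TEs much above ~5 exceed the pools and are rejected.

## Validation problem sizes

The shipped suites run at desk scale, chosen to finish in minutes on
one CPU: null calibration at 20 seeds × 5000 genes; effect recovery
with 8 replicate genes per injected effect at mean counts ≥ 500
(reported as the mean estimate over the replicate genes);
pause-score validation at ~4.6 M codons; gradient Monte-Carlo at
1000 replicates. The full pytest suite completes in well under a
minute of compute plus the pause-scale fixtures (~30 s total).
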