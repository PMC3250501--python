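# Methods

This note documents the models, procedures, parameter choices and known
limitations behind the `nagnag` package.  Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Coordinates and conventions

Genomic intervals are 0-based half-open; GFF3 1-based closed coordinates
are converted on read.  Splice-site-relative numbering puts the last
intron base at −1, the first exon base at +1, and the junction itself at 0
(used for gap positions); there is no position-0 base.  Reverse-strand
extraction always returns the transcribed sequence.  Intron phase is the
number of bases of the interrupted codon carried by the upstream exon
(GFF CDS phase p converts as (3 − p) mod 3).

## Catalog construction

Annotated acceptors (introns ending in AG on the transcribed strand) are
scanned for the NAGNAG motif in two placements: a second NAG 3 nt upstream
of the annotated AG (both AGs intronic; the annotated site is distal), or
a NAG formed by the first three exonic bases (the annotated site is
proximal).  Any N in the 6-mer rejects the placement — the motif must be
literal.  When a chained NAGNAGNAG admits both placements the intronic one
is taken first; enumeration deduplicates by junction coordinates, so
chained sites reachable from different annotated acceptors are still kept
distinct.  Sites reachable from several transcripts collapse to one record
in deterministic (contig, coordinate) order.

Junction sequences carry L flanking bases on each side of the junction
(CLI default 45).  Proximal and distal sequences share the upstream-exon
arm and differ by the 3-nt NAG the proximal isoform retains.

**Uniqueness.**  Mappability is enforced by exact k-mer membership (k = 36,
the shortest read length the quantification is designed for), not by
re-running an aligner: deterministic and sufficient at this scale, though
it does not reproduce mismatch-tolerant mapping.  Two rules apply: (a) no
junction-spanning k-mer with at least the read-counting overhang (6 nt) on
each side may occur in the genome on either strand — windows overhanging
the junction by fewer bases cannot arise from counted reads, and would
collide with the genome at rate ~4^(−overhang) purely by chance, discarding
perfectly mappable sites; (b) no k-mer window at any offset may be shared
between two different sites' junction sequences, which removes both
members of a colliding pair.

## Junction quantification

A read (or its reverse complement) counts toward a junction when it is an
exact substring of the junction sequence covering the junction with ≥ 6 nt
on each side.  The matcher requires exact identity over the whole matched
window — a deliberate simplification of quality-aware mapping; it has no
mismatch model.  Reads matching both junctions are discarded (impossible
after the uniqueness filter when k does not exceed the read length).

ψ = n_prox/(n_prox + n_dist).  The 95% CI is the Wilson score interval,
chosen over Wald for its coverage at small counts and its behaviour at
ψ = 0 or 1.  Samples with fewer than 10 junction reads are excluded from
all per-site statistics, which controls for junction coverage differences
driven by expression.

Flags: *alternative* = some covered sample has minor isoform ≥ 5%;
*regulated* = alternative and chi-square homogeneity p ≤ 0.01 across
covered samples; *strongly regulated* = regulated and switch score
(max ψ − min ψ, absolute scale) ≥ 0.25.  Threshold comparisons allow a
1e-12 tolerance so that decimal psi differences (e.g. 0.35 − 0.10) are not
lost to binary float representation.

The regulation test is the chi-square test of homogeneity on the 2×T
count table without continuity correction — the T-group generalisation of
the two-sample proportion z-test.  It is unconditional and asymptotic: on
small tables it runs anti-conservative relative to a margin-conditioned
permutation null (the suite checks agreement at RNA-Seq-scale counts,
where the two approach each other), and its null rejection rate at
α = 0.01 calibrates to ~1% at 100 reads per sample.

**FDR.**  Per tissue, sites alternative in at least one of two replicates
are tested between replicates; the FDR is the flagged fraction, and the
mean FDR weights tissues by their alternative-site counts.  The
tissue-number curve averages the strongly-regulated fraction over 200
random tissue subsets per size k (seeded); the extrapolation is an
unweighted least-squares line evaluated at the target tissue count, minus
the mean FDR, floored at zero.

## Boltzmann model

Proximal and distal splice sites compete with weights exp(B·S_prox + Q)
and exp(B·S_dist); ψ is logistic in ΔS = S_prox − S_dist.  Q captures the
intrinsic proximal preference (scanning-type 3′ss recognition), B converts
score bits into effective energy units.

Fitting: per-site mean ψ over covered tissues; overlapping ΔS bins of
width 3.25 bits at 0.5-bit steps (half-open [c − w/2, c + w/2)); median ψ
per populated bin; the crossing is the first adjacent bin pair whose
medians bracket 0.5 (ties broken toward the pair with more sites); an
unweighted least-squares line through the six flanking bins (three per
side, shifted inward at the range edge); inversion by the first-order
Taylor expansion of the logistic at its midpoint: slope = B/4, so B = 4m
and Q = −B·ΔS₀ with ΔS₀ = (0.5 − intercept)/m.  The inversion formulas are
the unique first-order expansion of the stated model; the unweighted line
fit is a choice (bin weighting is not otherwise determined).  Because the
logistic curves away from its tangent over the six-bin window, the
recovered B (and hence Q) runs ~3–4% low at the default operating point —
visible in the recovery experiments and well inside their tolerance.

The measurement-error envelope is E[√(ψ(1−ψ)/n)] over the empirical
distribution of per-site read totals.

The PWM acceptor scorer covers splice-site-relative positions −20..+3,
trained by counting on constitutive acceptor windows with a +1 pseudocount
against a uniform (configurable) background; scores are summed log-odds in
bits.  It is plumbing for producing ΔS, not a replacement for richer
splice-site models — externally computed scores are accepted via TSV and
are interchangeable.

## Acceptor features

Polypyrimidine tract: first run of ≥ 5 consecutive C/T scanning upstream
from −4; the full run extent and its junction-proximal offset are
reported.  CT content: maximal tiling of the pattern T?(CT)+C? over the
tract, covered bases / tract length (the phrase being operationalised is
ambiguous; a plain dinucleotide-count variant would be a one-line change).
AG exclusion boundary: the A of the first AG at or upstream of −16.
Positional information content: 2 − H(column) bits against a uniform
background, gaps excluded with renormalisation; frequency matrices are
emitted for logo rendering elsewhere.

Conservation profiles align sites at the proximal junction, average
scores over a 2-nt sliding window, and report per-position mean ± SEM per
switch-score group (default bins [0,0.05), [0.05,0.25), [0.25,0.5),
[0.5,1]; the category boundaries are a package choice and configurable).
The −4/−3 conservation ratio uses the per-class median with a seeded
bootstrap SE.  Ortholog ψ comparison classes are defined by conservation
of the score difference between species (|ΔS₁ − ΔS₂| ≤ 0.5 bits) —
reading the comparison as between-species conservation of the difference;
Spearman ρ per class, with the Fisher z test for the ρ difference.
Percentiles use linear interpolation between order statistics.

## Exon evolution

The aligned unit is an annotation-bounded mRNA fragment per species: the
upstream exon's tail followed by the exon under study, making the acceptor
junction internal to the alignment (mirroring the concatenation of
consecutive exons).  Alignment is global with affine gaps: match +1,
mismatch −1, a gap of length k costs 4 + k (configurable); externally
supplied alignments bypass the aligner.  QC requires identity > 70%
(computed over aligned residue pairs, gap columns excluded) and total
inserted length ≤ 20% of the shortest exon.

Gaps are slid to abut exon boundaries when the slide preserves the number
of exact matches (asserted per call), nearest boundary first, ties toward
the 3′ss.  Gap positions are then assigned relative to the junction: the
inserted material's own annotation decides the side.  Junction-touching
gaps are disambiguated by the species' exon annotations — if the intact
species' exon is longer, the event is at the acceptor (3′ss position 0);
if the upstream-exon tails differ, it is donor-side — which is exactly
the information annotation-bounded extraction carries, and resolves
placements where the aligner's optimal gap pairs the inserted bases with
the opposite exon.  Terminal gaps and junction-straddling gaps the
annotations cannot resolve are flagged ambiguous and dropped (their
inclusion does not change the headline enrichment, but they are rare by
construction).  The recovery experiments show the end-to-end estimator
runs a few percent low: a small fraction of injected acceptor shifts are
rendered by the aligner as displaced or merged gaps that resist
reassignment.

The gap profile reports, per position over ±30 nt around the junction
(span configurable; an exon pair counts at most once per position), the
fraction of pairs with a gap; the background is the mean over all profiled
positions except 3′ss position 0, and the enrichment is the position-0
fraction over that background.  The permutation test reassigns each
profiled gap, within its own alignment, to a uniformly random profiled
position (preserving per-alignment gap counts) and reports
p = (1 + #{null ≥ observed})/(1 + n); the scheme is a package construction
(only the test's name is given upstream).  When every gap sits at the
target the observed enrichment is treated as +∞ and p attains its minimum
1/(n + 1).

Boundary changes with a 3-nt acceptor offset are classified against
outgroups in priority order; the first outgroup whose boundary matches
exactly one ingroup is informative, the matching ingroup is ancestral, and
the longer exon is *expanded* or the shorter *contracted* accordingly.
Residual-motif windows are anchored at the changed lineage's current 3′ss
over [−10, +6]: expansions leave the ancestral NAG at exonic +1..+3,
contractions at intronic −6..−4.

Amino-acid spectra: for a 3-nt acceptor gap with known intron phase, the
local coding windows start at the codon `phase` bases into the upstream
exon.  Phase 0 counts the inserted codon directly; phases 1 and 2 compare
the longer species' two codons against the shorter's one — if one of the
two residues equals the shorter's residue the other was inserted,
otherwise both count.  Windows containing stop codons are excluded and
logged.  The background distribution is the codon four codons downstream
of the 3′ss.  Shannon entropy is −Σ p log₂ p.

## Synthetic data generator

The generator's defaults are the study conditions used throughout the
suite: 2,000 sites; ΔS uniform on [−8, 8] bits; (Q, B) = (0.55, 0.58);
8 tissues at Poisson mean coverage 100 (negative-binomial overdispersion
deliberately omitted — sufficient for calibration); 40% of sites regulated
with per-tissue logit offsets of ±1.5 (applied on the logit scale so truth
stays in (0,1); at the model midpoint this yields a truth switch of
logistic(1.5) − logistic(−1.5) ≈ 0.635, shrinking toward the ψ extremes);
−3 base composition favouring pyrimidines (C/T 0.40 each).  Replicates
share truth, so between-replicate differences are pure sampling noise —
the null the FDR calibration needs.

Ortholog pairs: ancestral tail (60 nt) + exon (120 nt) mutated
independently into two ingroups and an outgroup at 0.05 substitutions per
site.  With probability 18.5 × 0.002 one lineage's acceptor shifts by
3 nt by moving the annotated splice point — an expansion absorbs the
ancestral intron-terminal NAG into the exon, a contraction sheds the
exon's leading NAG (the generator makes it one so the shift is
splice-legal) — which mirrors the substitution/exaptation route rather
than a genomic indel, and leaves the residual motif in the emitted
acceptor windows.  Independent 3-nt deletions hit each other profiled
position at 0.002.  NAGNAG presence in a third species is Bernoulli at a
4% baseline, ×7.5 for boundary-changed exons.  Conservation tracks draw
uniform scores with mean 0.4, add a configurable elevation over [−50, −1]
for designated groups, and clip to [0, 1].

What the generator does not emulate: read errors and quality scores,
expression-level structure beyond Poisson coverage, indel length
variation (injected events are 3 nt), alignment-degrading repeats, and
real splice-site score distributions (ΔS is uniform by design).  Passing
recovery tests therefore demonstrates correctness of the estimators under
the modelled noise, not robustness to artefacts real pipelines must face
upstream (mapping bias, misannotation, paralogy).

## Problem sizes

The recovery experiments use 2,000 sites × 8 tissues × 100 reads over 20
seeded datasets for the model fit, 5,000 ortholog pairs over 10 datasets
for the gap enrichment (with 10⁴-scale permutations), and 400 + 4,000
exons over 20 datasets for the association ratio — sizes chosen so each
experiment completes in about a minute on one CPU while leaving the
Monte-Carlo error of each median well inside the quantities' tolerances.
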