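# Methods

This note documents the models and procedures behind `isoarch`: what the
synthetic generator emulates and how, how each analysis stage works, the
parameters that matter with their defaults and rationale, and where the
design was genuinely open.

## 1. The scientific setting

Mammalian genomes are mosaics of isochores: long (≳200 kb) segments of
relatively homogeneous GC, classified into five families of increasing GC —
L1, L2 (the GC-poor, gene-poor "genome desert") and H1, H2, H3 (the GC-rich,
gene-rich "genome core").  Chromatin architecture assays describe the same
genomes as mosaics of topologically associating domains (TADs, 0.2–2 Mb,
from Hi-C contact maps) and lamina-associated domains (LADs, GC-poor,
median ~500 kb, from DamID, each carrying a contact frequency CF — the
proportion of cells in which the segment touches the nuclear lamina).  The
package's analyses quantify the correspondence between the compositional
and the architectural mosaics: boundary-level association of interval sets,
evolutionary conservation of GC across syntenic regions, and compositional
stratification of chromatin contacts.

## 2. The synthetic generator

Real analyses of this question consume external genome assemblies, Hi-C
archives, DamID maps and ortholog databases.  `isoarch` instead generates
all inputs with *planted, recorded ground truth*, chosen as the simplest
stochastic laws that reproduce the qualitative structures of the real data.
Every law is a configuration knob (`SimulationConfig`); every draw comes
from a named, seed-derived stream, so identical configurations produce
bit-identical outputs and adding one simulation product never perturbs the
others.

**Isochore mosaic.**  Families succeed one another along a chromosome as a
Markov chain (default: transition mass decays as 2^(−|Δfamily|), zero
diagonal so adjacent isochores always differ; the first family is drawn
from the chain's stationary distribution).  Lengths are lognormal per
family, truncated below at 200 kb; a terminal remainder too short to stand
alone joins the last isochore.  Default medians run from 1.2 Mb (L1) to
0.5 Mb (H3) — the ~1 Mb scale of real isochore maps, with the GC-poorest,
LAD-eligible family skewed largest.  Sequence is i.i.d. A/C/G/T with
per-100-kb-tile GC equal to the family target plus N(0, 1 GC%), clipped to
[0, 100].  Targets (35, 39, 44, 49.5, 56 GC%) sit inside the family ranges
below.  No repeats, N-runs or realistic k-mer structure are simulated; N
handling in the profiler is exercised with hand-built fixtures instead.

**Domains.**  Each concordant TAD is one true isochore with endpoints
jittered by N(0, 50 kb), clipped to the chromosome and redrawn if collapsed;
a configurable fraction of TADs is instead placed uniformly (discordant).
LADs are the true L1/L2 isochores with CF drawn from family Beta laws —
Beta(8, 2) for L1 (mean 0.8, the "stable" high-CF contacts) and Beta(4, 4)
for L2 (mean 0.5), so L1 stochastically dominates L2 and CF > 0.8 is
essentially an L1 property.

**Contacts.**  Intra-chromosomal matrices at 250 kb resolution are Poisson
draws around E[i,j] = base·|i−j|^(−γ) (γ = 1), times a 4× boost for bin
pairs in the same true isochore and a 3× boost for GC-poor × GC-poor pairs
at any separation — GC-rich pairs decay without it, which is exactly the
"GC-poor regions interact even when far away" signature.  Inter-chromosomal
matrices designate per chromosome a set of interaction-hub bins of which a
fraction p (default 0.75) are GC-rich, drawn once per chromosome from a
chromosome-keyed stream so all pairings of that chromosome see the same hub
loci; all hub×hub cross-chromosome pairs receive high Poisson intensity and
everything else low background.  The parameter p is therefore, by
construction, the planted GC-rich fraction of the distinct bins involved in
top interactions — the quantity the analysis recovers.  Matrices are
consumed as already normalized; no balancing is performed.

**Orthologs.**  Genes are laid out evenly along each chromosome (10 kb
genes, 250 per chromosome by default) and grouped into consecutive blocks
of 5.  Blocks are permuted onto the species-B chromosome, and each block's
orientation is *forced* by its successor's position — direct iff the next
A-block sits earlier in B — so every junction between A-adjacent blocks
breaks monotonicity and each planted block is detectable by the chaining
rule below.  (An unconstrained permutation with independent coin-flip
inversions lets adjacent blocks continue a monotone trend and merge; at 50
blocks that happens with probability ≈ 1.)  The orientation sequence is the
descent pattern of a uniform permutation: a near-fair, weakly dependent
coin.  Per-gene species-B GC is the species-A value plus N(0, σ); the
helper `calibrate_ortholog_noise` inverts r = sd(GC_A)/√(sd(GC_A)² + σ²) to
plant a target cross-species correlation.

**CTCF sites.**  A homogeneous Poisson process per isochore at the family's
rate; default densities 1, 3, 6, 10, 16 sites/Mb for L1…H3, a strictly
increasing gradient.

## 3. Isochore calling

GC% per window is 100·(G+C)/(A+C+G+T); bases outside ACGT count in neither
numerator nor denominator, and windows with >50% non-ACGT are masked.  A
trailing partial window is kept iff it covers at least half a window.
Segmentation requires non-overlapping windows (step = window): overlapping
windows would double-count sequence; overlapping steps remain available for
display profiles.

Family assignment is a total, monotone step function on half-open GC ranges
[low, high).  Fixed cutpoints: 37 / 41 / 46 / 53 GC%, so L1 < 37 ≤ L2 < 41 ≤
H1 < 46 ≤ H2 < 53 ≤ H3; a GC of exactly 46 — the H1 upper threshold — falls
in H2.  The *extended* preset raises the H1/H2 cutpoint to 47 to tolerate
minimal trespassings of 46 by H1 isochores.  All four cutpoints are
configuration values.

Segmentation merges equal-family window runs, then absorbs segments shorter
than `min_size` (default 200 kb, the lower edge of the domain size range)
into the flanking neighbour with nearer mean GC — smallest segment first,
left neighbour on an exact tie — re-pooling the ACGT-weighted mean GC and
reassigning the family from the pooled mean, until stable.  Segments
produced by absorption are flagged `merged`, since individual windows may
disagree with the final label.  Masked windows break segments and absorption
never crosses them.  The procedure is threshold classification plus
smoothing; no HMM or likelihood segmentation is attempted.

## 4. Interval association

The permutation test follows the standard randomization recipe: evaluate an
overlap statistic on (A, B), re-evaluate on n randomized copies of A, and
report z = (obs − null mean)/null sd and the empirical one-sided
p = (1 + #{null ≥ obs})/(n + 1), so the attainable minimum is 1/(n+1).
Two statistics are provided: *count* (A intervals overlapping the union of
B — the usual default) and *basepair* (intersection bp of the two unions).
Count saturates when B tiles the genome, which isochores do; basepair mode
is therefore the default in the pipeline.  For the same reason the
pipeline's synthetic association tests are class-restricted: A = TADs whose
source isochores are GC-poor, B = the GC-poor isochores (and LADs vs the
same B) — the synthetic analogue of testing one compositional compartment's
domains against its isochores.  Unrestricted tiling sets make any coverage
statistic degenerate regardless of the statistic chosen.

Randomization schemes: *uniform* re-places each interval on its own
chromosome without overlap (the exact gap construction — intervals in
random order laid at sorted uniform points of the free space — which is
uniform over non-overlapping configurations and never rejects; with a mask,
placements are rejection-sampled with bounded retries); *circular* shifts
all intervals of a chromosome by one uniform offset, wrapping at the ends
(an interval crossing the end is split in two: bp content exact, count +1
at most).  Both preserve the per-chromosome length multiset (up to the
wrap split).

The local z profile translates A circularly by offsets −D…+D and recomputes
z at each.  The null is drawn once at shift 0 and reused — circular
translation leaves the randomization law invariant — with a `renull` option
to redraw per shift.  Peak sharpness is |z(0)| divided by the largest |z| at
|shift| ≥ D/2; profiles with sharpness ≥ 2 are classified *sharp*
(boundary-specific), otherwise *flat* (regional).  The classification
protocol sets D = 5× the mean interval length of A: for a
boundary-concordant set the half-range then probes far beyond the boundary
scale (z collapses), while for small intervals inside large territory
blocks it stays within the territory scale (z persists).

## 5. Synteny and GC conservation

Ortholog pairs sorted by species-A position are chained greedily: a chain
extends while the next pair keeps the same B chromosome (and arm, when a
centromere table is supplied) and keeps B positions strictly monotonic in
the chain's orientation, fixed by the first non-tied comparison; tied B
positions, chromosome/arm changes, or direction reversals close the chain
and open a new one at the violating pair.  Chains with ≥ `min_genes`
members (default 3) are emitted.  Descending B order counts as conserved
(an inverted block) — inversions are ubiquitous in mammalian synteny and
excluding them would fragment blocks; `direct_only` restores the strict
reading, and an optional `max_gap` bounds the B-side gap between
consecutive members (no maximum by default).  The chain rule is strict:
a single out-of-order gene closes the chain (micro-rearrangement tolerance
is not attempted).

Isochores overlapping a block's A-span by ≥ 50% of the isochore (slivers
are not informative) are projected into species B by linear proportional
mapping within the block, mirrored for inverted blocks; the B-side GC is
the mean over the supplied B GC records overlapping the projected region.
Cross-species GC agreement is summarized by Pearson and Spearman
correlations with a Fisher-z 95% CI.

## 6. Contact stratification

Matrix bins take the isochore family of majority bp overlap (exact ties go
to the family containing the bin midpoint; bins more than half uncovered
stay unassigned), collapsed to GC-poor (L1+L2) vs GC-rich (H1+H2+H3).
Distance-stratified means count every unordered annotated intra-chromosomal
bin pair once; absent sparse entries are zeros.  Top-N inter-chromosomal
interactions (default N = 100 per chromosome pair) are the largest
cross-chromosome entries, ties broken by ascending bin index; the class
fractions of their *distinct* involved bins (a bin in many top pairs counts
once; endpoint weighting available) are the headline GC-rich/GC-poor
split.  Across chromosome pairs, distinct bins are keyed by genomic locus,
since bin ids are matrix-local.

The distance-decay exponent is the negative slope of log mean contact vs
log bin separation; the pipeline estimates it on GC-rich bin pairs beyond
the domain scale (8 bins), which carry neither same-domain enrichment nor
the GC-poor boost.  The long-range GC-poor/GC-rich ratio is estimated
beyond 5 Mb separation (the "long range" default; the real-data notion is
unquantified) with exact-distance matching — per-separation class means,
inverse-variance weighted on the log scale — so compositional differences
in the distance mixture within a stratum do not bias it; its standard error
is Poisson-delta.  Boundary concordance is the fraction of domain
boundaries within a tolerance (default 100 kb) of the nearest isochore
boundary on the same chromosome.  LAD contact frequencies are summarized
per majority-overlap family, with the fraction above a threshold defaulting
to 0.8 — the level at which lamina contacts are essentially confined to L1.

## 7. Pipeline, seeds and report

`run_pipeline` executes simulate → profile/segment → domains → association
(+ local z) → synteny → contacts → concordance/LAD-CF/CTCF, writing every
intermediate in plain-text formats (FASTA, BED, TSV, bin-table + triplet
matrices, JSON) plus a MANIFEST recording per-stage completion; a stage
failure aborts with the stage name and retains partial outputs.  Stage
seeds derive from the global seed and a CRC-32 hash of the stage name, so
streams are stable under pipeline evolution.  The final `report.json` is a
pydantic model (schema published as `src/isoarch/report.schema.json`) and
contains no timestamps: a report regenerates bit-identically from its
configuration.

## 8. Recovery studies and what they show

`isoarch.experiments` closes the loop for each mechanism (these are the
studies `scripts/acceptance.py` reports): boundary and family recovery of
the planted mosaic from sequence; floor p-values and large z for jittered
domains vs their source isochores; type-I error calibration on independent
sets; sharp-vs-flat discrimination of the local z profile; exact synteny
block recovery and agreement with a brute-force longest-valid-prefix
enumeration on fuzzed tables; recovery of a planted cross-species GC
correlation (r = 0.9, n = 300); recovery of the planted 75% GC-rich
inter-chromosomal involvement over 21 chromosome pairs; decay-exponent and
long-range-boost recovery; the boundary-concordance fraction against its
Gaussian closed form 2Φ(tol/sd) − 1 ≈ 0.954 at sd 50 kb / tol 100 kb; and
the CTCF density ordering (run on a 5-chromosome, 100 Mb structure, where
the planted densities separate the full five-family ordering reliably).

Problem sizes — 20 Mb chromosomes, 100–999 permutations, 5–100 replicate
seeds per study — are the package's study conditions, chosen to give each
tolerance adequate Monte Carlo resolution at desk scale.

Because the generator is the simplest-law emulation, passing these studies
shows that the *methods* recover what they claim under the stated laws; it
does not certify performance on real genomes, whose isochores have
autocorrelated GC, whose TAD calls depend on resolution and caller, and
whose contact matrices carry coverage and mappability structure none of
which is simulated.

## 9. Numerical and degenerate-input choices

- Coordinates are 0-based half-open throughout; BED written accordingly.
- A degenerate permutation null (sd = 0) returns the empirical p with z
  flagged undefined (NaN) rather than failing.
- A fully masked GC profile yields an empty isochore list with a warning;
  correlation on zero-variance vectors returns null with a warning.
- Boundary clipping at chromosome ends slightly inflates the concordance
  fraction relative to the Gaussian closed form (clipped boundaries match
  exactly); at the study's ~700–750 boundaries the effect sits well inside
  the binomial CI.
- The jitter redraw on collapsed TADs (≤ 0 length after jitter) logs a
  warning and retries up to 100 times before falling back to the source
  isochore unchanged.
- Hub selection warns and degrades gracefully when a chromosome lacks
  enough bins of a class.

## 10. Key defaults (config reference)

| Parameter | Default | Why |
|---|---|---|
| family GC targets | 35/39/44/49.5/56 GC% | strictly increasing, centred in the family ranges |
| family cutpoints (fixed) | 37/41/46/53 | standard family boundaries; 46 is the H1 upper threshold |
| cutpoints (extended) | 37/41/47/53 | absorb minimal trespassings of 46 |
| isochore length medians | 1.2/0.9/0.75/0.6/0.5 Mb | ~1 Mb real-map scale, L1 largest |
| min isochore / `min_size` | 200 kb | lower edge of the domain size range |
| window noise sd | 1 GC% | visible window scatter without family confusion |
| TAD jitter sd | 50 kb | boundary agreement at sub-window scale |
| LAD CF Beta | L1 (8,2), L2 (4,4) | CF > 0.8 essentially L1-only |
| contact resolution | 250 kb | the analysis resolution of the domain maps |
| decay exponent γ | 1.0 | canonical contact-decay scale |
| domain / GC-poor boost | 4× / 3× | visible blocks; recoverable long-range signal |
| interchrom preference | 0.75 | the planted GC-rich involvement fraction |
| hubs per chromosome | 12 | sparse enough that involved-bin counting is exact |
| genes per block / per chrom | 5 / 250 | 50 detectable blocks per 20 Mb chromosome |
| CTCF densities | 1/3/6/10/16 per Mb | strictly increasing with GC |
| n_perm (pipeline) | 199 | p floor 0.005 at interactive cost |
| sharpness threshold | 2.0 | separates the sharp/flat modes cleanly |
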