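# Methods

This note documents the models, conventions and numerical choices behind
`tadmeqtl`, and what the synthetic data do and do not establish about real
data.

## Coordinates and record model

All intervals are 0-based half-open (`[start, end)`, BED convention);
adjacent intervals overlap by zero bases.  meQTL tables on disk carry
1-based SNP/probe positions (the convention of public meQTL exports) and
are shifted on read.  The meQTL uniqueness key is
`(snp_id, probe_id, cancer_type)`; burden analyses count **unique SNP
positions**, so a SNP associated with many probes or cancer types counts
once per region, and its clumping p-value is the minimum over its
associations (the conservative choice for retaining signals).

## Consensus TADs

A reference-set TAD (first input cell line) is emitted iff every other
cell line contains a partner whose overlap is at least `min_frac`
(default 0.2) of **both** TAD lengths.  Matching is greedy by largest
overlap, ties broken by smaller start, and each partner is consumed at
most once; consensus coordinates are the reference TAD's.  The reciprocal
reading is the stricter and order-stable interpretation of a "20% overlap"
rule; a one-sided mode (fraction of the reference TAD only) is available
via `mode="one-sided"`.

*Known property:* under heavy endpoint jitter, greedy partner consumption
means that lowering `min_frac` can occasionally remove a consensus TAD (an
earlier reference TAD absorbs a partner a later one needed).  When jitter
is small relative to TAD length every reference TAD has a unique best
partner and the monotone behaviour holds; the test suite checks
monotonicity only in that regime and checks exact agreement with an
exhaustive matching oracle everywhere.

## Activity classification

Per TAD and per epigenome track, the composition vector is covered bp per
chromHMM state divided by annotated bp inside the TAD; tracks are averaged
with equal weight and renormalised (which epigenomes drive the published
heat maps is not recoverable, so equal weighting is the neutral choice).
K-means uses k=5, 50 restarts and a fixed seed; clusters are re-indexed
into lexicographic centroid order so numbering is initialisation-free.

Cluster labels are assigned from centroid state masses:
`active_mass` = Σ fractions over states 1–7 (TssA, TssAFlnk, TxFlnk, Tx,
TxWk, EnhG, Enh); `inactive_mass` = Σ over states 9, 13, 14, 15 (Het,
ReprPC, ReprPCWk, Quies).  A cluster is **Mixed** when
|active − inactive| < 0.1, otherwise takes the larger side; within a side,
suffixes -1, -2 are ordered by descending dominant mass.  The 0.1 margin
is a documented config default (`mixed_margin`): published analyses label
such clusters by visual inspection of the state heat map, and the margin
makes that judgment explicit and testable.  States 8 (ZNF/Rpts) and 10–12
(bivalent) count toward neither side.

## Genome partition and burden

Each TAD endpoint contributes a boundary `[e − 50 kb, e + 50 kb)` clipped
to the chromosome.  When consecutive TADs are closer than 100 kb, each
boundary keeps its inward 50 kb plus the proximal half of the gap, and the
two abutting pieces merge into one region spanning the inter-TAD window.
Boundaries flanked by a Mixed TAD are tagged `mixed-adjacent` and excluded
from transition analyses but still count as Boundary for burden; the
outermost endpoints of a chromosome are tagged `chrom-edge`.

The partition tiles every chromosome exactly with precedence
Boundary > TAD interior > Other (verified at construction).  Region burden
uses the partition (so Boundary bp are subtracted from TAD interiors),
whereas the per-TAD Active-vs-Inactive comparison uses densities over the
**full TAD span** — the two analyses answer different questions and both
behaviours are exposed.  The per-TAD comparison defaults to the Welch
unequal-variance t-test (a pooled-variance flag exists); variance equality
between activity classes is not defensible a priori.  Promoter methylation
is summarised at the TAD containing the promoter midpoint and compared
across categories with the Kruskal–Wallis test; promoters outside all
consensus TADs are dropped and counted.

## Boundary profiles and the shuffle null

The profiled span is the inter-TAD gap only (TAD end → next TAD start).
It is divided into 40 bins whose widths differ by at most 1 bp (remainder
spread from the left); spans shorter than 40 bp are skipped and logged.
Per transition category the profile is the mean over spans of per-bin
count / bin bp.  Smoothing (centred rolling mean, default window 5,
truncated at the edges) is for display only.

The null permutes the Active/Inactive/Mixed labels across all consensus
TADs — genome-wide label counts are preserved by construction — and
regroups the (label-independent) per-span profiles by the new transitions;
100 shuffles by default.  A strict mode resamples permutations until the
per-category transition counts match the observed ones exactly, but that
constraint makes the null nearly degenerate on small genomes, so the
label-permutation null is the default.

The default test statistic is the per-span half difference
Δ = mean density (bins 21–40) − mean density (bins 1–20), compared between
observed spans and the pooled shuffled spans with a Welch t-test; a
paired per-bin alternative (`mode="per_bin"`) is available.  The half
difference targets the scientific claim — a density shift across the
boundary — and is insensitive to overall level differences between
transition categories.  Because the pooled null mean is estimated from
many correlated shuffle draws, the test is slightly conservative; in
calibration runs (uniform placement, 100 shuffles) it rejects ~3–4% of
the time at α = 0.05.

## LD clumping

Greedy: repeatedly take the unassigned SNP with the smallest p ≤ p1 as
index, absorb every unassigned SNP within 250 kb (inclusive, index-to-
candidate bp) with p ≤ p2 and r² ≥ 0.5.  Ties on p break by position then
id, making output deterministic.  r² is the squared Pearson correlation of
dosage vectors (`DosageLD` precomputes standardised rows; any object with
an `r2(snp, others)` method can substitute, e.g. precomputed triplets).

## Driver enrichment

A meQTL is a driver meQTL when its probe lies in ≥1 promoter of a
role-bearing gene (half-open intervals; probes in promoters of both an
oncogene and a TSG yield one annotation per role, logged).  Oncogene and
TSG sets are analysed separately with trial sample sizes equal to their
driver counts.  Each of 1000 trials draws, per driver, one non-driver
clumped meQTL with |ΔMAF| ≤ 0.05 (absolute scale; a relative mode exists),
without replacement within the trial; the MAF constraint is asserted on
every draw.  Per-trial and observed densities go through the same
count→per-Mb helper, so no logic is duplicated.  Results report the trial
mean, SD and SE (error bars in the literature are sometimes SD, sometimes
SE, so both are kept), a z-score, and add-one empirical p-values
(`(1+k)/(n+1)`, never exactly zero; two-sided = 2·min, capped at 1).
Regions reported by default are ActiveTAD, InactiveTAD and Boundary —
mixed regions are excluded from this analysis for their biological
ambiguity — with the full label set available via `labels=`.

## Synthetic data: what it emulates

Defaults (one seed drives everything; identical configs are byte-identical
on disk):

| parameter | default | rationale |
|---|---|---|
| chromosomes | 5 × 230 Mb | ~40% of a human genome, enough TADs per chromosome |
| TADs | 220/chrom, 800 ± 200 kb, gaps 200 ± 60 kb | 1100 consensus-scale TADs; human TAD:boundary size ratio |
| cell lines | 5, endpoint jitter sd 10 kb | multi-cell-line concordance with realistic disagreement |
| archetype mixture | 0.10/0.10/0.30/0.27/0.23 | ≈20% active / 57% inactive / 23% mixed consensus TADs |
| Dirichlet concentration | 50 | within-archetype composition noise |
| meQTLs | 60 000 (+54 oncogene, +102 TSG drivers) | clumped pan-cancer meQTL scale |
| boundary gradient g | 1.5 | moderate active→inactive density ramp |
| MAF | 0.5·Beta(1.5, 4), floor 0.005 | right-skewed minor allele frequencies |
| LD | blocks of 10 SNPs, within-block r² ≈ 0.7 | exchangeable block LD, enough to exercise clumping |
| promoter β | Active 0.45, Inactive +0.15, sd 0.10, clipped to [0,1] | higher methylation in inactive domains |

meQTL placement density is piecewise-constant per region with per-category
multipliers; when g ≠ 1 the density across a gap between two non-Mixed
TADs ramps linearly (40 constant steps) from the active-flank weight 1 to
the inactive-flank weight g (so II gaps are flat at g, AA flat at 1 —
level differences carry no Δ signal).  Driver meQTLs are placed with
additional per-(role, region) multipliers and their probes sit inside
same-chromosome promoters of genes with that role; non-driver probes are
nudged out of driver promoters so annotation recovers the planted flags
exactly.  Dosages are Gaussian with block-shared factors
(`a = r²^(1/4)`, giving pairwise r² ≈ the target within a block).

**Not emulated:** recombination maps or distance-decaying LD, spatial
autocorrelation of chromatin states beyond per-TAD archetypes, probe
density heterogeneity (CpG islands), population structure in MAF, and any
genotype–methylation effect sizes (association p-values are synthetic
labels, not regression outputs).  Passing tests therefore demonstrate that
the estimators recover what they claim under the stated generative model —
not that real meQTL catalogues will show these effects.

## Problem sizes in the checks

The acceptance checks run, per invocation: 50 five-cell-line genomes of
~200 TADs for the consensus oracle; 1100 TADs for classification recovery;
100 random layouts × 100 point lookups for the partition oracle; 200
uniform datasets × 100 shuffles for profile calibration; 100 seeds at
~300 usable boundaries × 10⁵ meQTLs for profile power; 100 block-LD
instances of 200 SNPs for the clumping oracle; and 50 + 100 seeds at 100
drivers / 5000 non-drivers × 1000 trials for enrichment calibration and
power.  `scripts/acceptance.py` reports the same quantities at moderately
reduced replicate counts plus one default-scale pipeline run.

## Known limitations

* Consensus monotonicity in `min_frac` is not guaranteed under heavy
  jitter (see above).
* The strict transition-count-preserving shuffle can fail to find a
  permutation on large genomes within the retry budget; it is intended for
  small diagnostic runs.
* The half-difference profile test is mildly conservative by construction.
* With aggressive clumping few planted driver meQTLs survive as index
  SNPs, so the default pipeline's enrichment z-scores are sign-correct but
  modest; enrichment power claims are established on unclumped driver sets.
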