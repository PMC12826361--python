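# tadmeqtl

Analysis of how cancer **meQTLs** (methylation quantitative trait loci —
SNPs whose genotype shifts DNA methylation at a CpG site) distribute with
respect to 3D genome architecture: **topologically associating domains
(TADs)**, their transcriptional activity, and their boundaries.

The package is aimed at regulatory-genomics researchers who have per-cell-
line TAD calls, chromHMM segmentations and a cis-meQTL catalogue, and want
to ask: do meQTLs concentrate in active or inactive chromatin domains, how
does their density change across TAD boundaries, and are meQTLs that hit
cancer-driver-gene promoters placed unusually relative to MAF-matched
controls?  Because the real inputs of such studies (TCGA genotypes,
pan-cancer meQTL exports, Hi-C TAD calls) are controlled-access or bulky,
the package ships a synthetic-data generator that emulates their
statistical structure with a planted-truth record, so the whole pipeline
is testable end to end.

## What it computes

1. **Consensus TADs** — a TAD is kept when every other cell line has a
   reciprocal ≥20% overlap partner (greedy largest-overlap matching).
2. **TAD activity** — per-TAD chromHMM 15-state composition vectors
   f ∈ Δ¹⁴, k-means with k=5, clusters labelled Active-1/2, Inactive-1/2
   or Mixed from the balance of active-state mass (TssA…Enh) vs
   inactive-state mass (Het, ReprPC, ReprPCWk, Quies); collapsed to
   Active/Inactive/Mixed.
3. **Genome partition & burden** — boundaries are ±50 kb around TAD
   endpoints (proximal-half rule for gaps <100 kb); the genome is tiled
   into ActiveTAD / InactiveTAD / MixedTAD / Boundary / Other with
   Boundary precedence; burden = unique SNPs per region / region length
   (per Mb).  Per-TAD densities are compared Active vs Inactive by Welch
   t-test; promoter methylation β values by Kruskal–Wallis.
4. **Boundary profiles** — each inter-TAD span is cut into 40 equal bins;
   per-bin density (count / bin bp) is averaged within transition category
   (AA, AI, IA, II; Mixed-flanked spans excluded) and compared with a null
   from 100 random permutations of the TAD activity labels.  The test
   statistic is the per-span half difference Δ = mean(bins 21–40) −
   mean(bins 1–20), Welch-tested against the pooled shuffled Δs.
5. **LD clumping** — greedy PLINK-style reduction to index SNPs
   (p1=10⁻⁴, p2=0.01, r²≥0.5, 250 kb window), per-SNP p = min over probe
   associations.
6. **Driver enrichment** — clumped meQTLs whose CpG probe falls in an
   oncogene/TSG promoter are compared, per region and per role, with 1000
   random draws of non-driver meQTLs matched on MAF (|ΔMAF| ≤ 0.05),
   reporting observed vs expected density per Mb, z, SE/SD and an add-one
   empirical p.

## Worked example

```python
from tadmeqtl import run_pipeline
summary = run_pipeline({"seed": 1}, outdir="demo_run")
```

This simulates the default synthetic study — 5 cell lines, 5×230 Mb
chromosomes, 1100 true TADs, 60 000 non-driver meQTLs plus 54
oncogene-promoter and 102 TSG-promoter driver meQTLs with a planted
boundary density gradient g=1.5 — then runs every stage.  With seed 1 it
prints/writes (see `demo_run/summary.json`):

```
consensus TADs:      1100
activity classes:    {'Active': 235, 'Inactive': 616, 'Mixed': 249}
burden per Mb:       ActiveTAD 50.5  InactiveTAD 50.4  Boundary 56.1  Other 56.5
promoter KW:         H = 106.6, p = 7.0e-24
boundary profiles:   AA p = 0.936   AI p = 0.018   IA p = 0.0005   II p = 0.081
clumping:            6239 index SNPs from 60156
```

Reading: all 1100 planted TADs are recovered and classified (roughly 20%
active / 57% inactive / 23% mixed, mirroring the planted mixture);
promoter methylation separates activity classes; the density ramp planted
across boundaries makes the active→inactive (AI) and inactive→active (IA)
profiles deviate from the label-shuffle null while AA and II do not; the
boundary-region excess (≈56 vs ≈50 meQTLs/Mb) reflects the same gradient.
The driver-enrichment table (`driver_enrichment.tsv`) reports, per role ×
region, observed and expected density with z-scores whose signs follow the
planted multipliers (oncogene meQTLs depleted in active TADs, TSG meQTLs
enriched at active TADs and boundaries).

The same stages are exposed on the command line:

```bash
tadmeqtl simulate --seed 1 -o inputs/
tadmeqtl consensus --tads inputs/tads_cell1.bed --tads inputs/tads_cell2.bed ... -o consensus.bed
tadmeqtl run --config pipeline.yml -o run/
```

## Layout

```
src/tadmeqtl/
  core.py        domain types, 0-based half-open coordinate convention
  io.py          BED / meQTL-TSV / gene-role / dosage readers and writers
  simulate.py    synthetic datasets with planted truth
  consensus.py   cross-cell-line consensus TADs
  classify.py    15-state compositions, k-means, activity labels
  partition.py   boundaries, genome tiling, burden, per-TAD tests
  profiles.py    40-bin boundary profiles and the shuffle null
  clumping.py    greedy LD clumping
  enrichment.py  driver annotation and MAF-matched randomisation
  pipeline.py    config-driven orchestration
  cli.py         click CLI (`tadmeqtl`)
```

See `docs/methods.md` for the modelling choices and their rationale.
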