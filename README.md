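# nucarch

Quantification of 3D nuclear architecture in single-cell fluorescence
microscopy, with the chromosomal-enrichment statistics that connect imaging
phenotypes to genomic interval data.

Aging of hematopoietic stem cells (HSCs) comes with a characteristic set of
nuclear phenotypes: the histone mark H4K16ac loses its polarized
("epipolar") distribution, chromosome-11 homologs drift apart, nuclei grow
and lose their pocket-like invaginations, and differentially bound H4K16ac
peaks cluster non-randomly on specific chromosomes. `nucarch` implements
those measurements as a tested, reusable library:

- **segmentation** — nuclear masks from a DAPI channel (smooth → Otsu →
  watershed → morphological cleanup) and chromosome-territory objects from
  paint channels (threshold within the nucleus, 26-connected components).
- **morphometry** — voxel-coverage volume; the nuclear shape factor
  NSF = π^⅓·(6V)^⅔ / A (sphericity: 1 for a perfect sphere), with the
  surface area A from an iso-surface mesh in physical coordinates;
  solidity V/V_hull with an invagination cutoff; thresholded channel volume
  (e.g. LaminA/C); and a peripherality index for boundary-proximal signal.
- **territories** — homolog centroid-to-centroid distances (centroid =
  unweighted mean of voxel centres, in µm), proximity classification
  (merged object or distance ≤ d_prox), and mark–territory co-localization
  volume.
- **polarity** — a reproducible epipolarity score: the largest fraction of
  within-nucleus mark intensity on one side of a plane through the mask
  centroid, maximised over a deterministic spherical direction lattice;
  score ∈ [0.5, 1], polar ⇔ score ≥ τ.
- **chromenrich** — observed vs expected per-chromosome peak counts under
  size- or gene-density-proportional nulls, enrichment scores, Pearson X²
  goodness of fit with an exact multinomial Monte-Carlo option,
  differential-peak overlap with same-direction logic, and midpoint-based
  genomic annotation (TSS / promoter / gene body / intergenic).
- **synthetic** — a scene generator with known ground truth: parametric
  nuclei (ellipsoid + roughness + spherical invagination pockets), a mark
  channel with von Mises–Fisher polarity concentration κ, homolog blob
  pairs at tunable separation, PSF blur, Poisson + read noise, 16-bit
  output; plus multinomial peak-table sampling with per-chromosome folds.
- **pipeline** — per-cell quantification with error containment, group
  statistics in the reporting style of the source experiments (mean + 1 SEM
  with the biological repeat as the unit of replication; paired t /
  one-way ANOVA; Bonferroni post-tests only when the overall p < 0.05),
  and a deterministic cohort runner.

A thin CLI (`nucarch simulate|quantify|enrich|report`) wraps the library
for shell use; the primary interface is the Python API plus the scripts in
`examples/`.

## Worked example

`examples/peak_enrichment.py` samples 118 peaks on mouse chromosome sizes
with a 5-fold excess on chromosome 11 and tests for non-random placement:

```
       observed  expected  enrichment_score
chr11        25      5.29              4.73
chr4         10      6.78              1.48
chr2         11      7.88              1.40
chrX          9      7.40              1.22
chr7         7       6.30              1.11

X2 = 89.93 (df = 20), p = 0.0001 (monte-carlo)
top chromosome: chr11
```

Chromosome 11 carries 25 peaks where ~5.3 were expected from its size
(enrichment score 4.7), and the Monte-Carlo goodness of fit rejects random
placement (p = 1e-4) — the enriched chromosome is identified from peak
counts alone.

`examples/aging_cohort.py` runs the full imaging pipeline on a simulated
young-vs-aged cohort (8 cells × 3 repeats per group):

```
             metric     test  statistic  p_value  mean_aged  mean_young
         volume_um3 paired-t    14.2462   0.0049   168.5191     88.7552
                nsf paired-t    -5.3525   0.0332     0.9796      1.0101
           solidity paired-t    19.1528   0.0027     1.0000      0.9868
polarity_score_mark paired-t   -27.3351   0.0013     0.6325      0.9955
```

Aged nuclei come out larger, less spherical, and apolar; young homolog
pairs are merged (proximal) while aged pairs resolve at ~4 µm — the
directions of the generating parameters are recovered with p < 0.05.

The other examples (`nuclear_morphometry.py`, `polarity_scoring.py`,
`homolog_distances.py`) each exercise one capability on a small generated
input and print what the numbers mean.

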