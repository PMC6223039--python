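# Methods

This note documents the models, measurement definitions, defaults and
numerical choices behind `nucarch`, and what the synthetic-data tests do
and do not establish about real microscopy data.

## Coordinate conventions

Stacks are (z, y, x) voxel arrays with physical spacing (dz, dy, dx) in
micrometres; anisotropy (dz ≥ dx, e.g. 0.5 µm z-steps against 0.25 µm
pixels) is the normal case and every physical quantity — volumes, surface
areas, distances, distance-transform shells — is computed in physical
coordinates, never in voxel counts along mixed axes. Voxel (k, j, i) is
identified with its centre ((k+0.5)dz, (j+0.5)dy, (i+0.5)dx); centroids
are unweighted means of voxel centres.

## Nuclear segmentation

Gaussian smoothing (default σ = 0.3 µm) → global Otsu threshold →
watershed split of touching components, seeded at maxima of the smoothed
Euclidean distance transform with a 0.5 µm minimum seed separation →
morphological closing, hole filling, largest 26-connected component. One
nucleus per field is assumed (sorted single cells on coverslips);
multi-nucleus fields resolve to the largest object, with size ties broken
by the lowest (z, y, x) centroid. Objects below 20 µm³ are rejected as
debris. The mask is invariant under positive rescaling of the intensities
(Otsu is scale-equivariant) and equivariant under whole-voxel
translations.

On noiseless rendered scenes the mask overlaps the generating mask with
Jaccard ≥ 0.95; with the default noise model, Otsu thresholding of the
PSF-blurred boundary inflates volume by ≈ 2%, which is small against the
between-cell volume scatter of any realistic cohort.

## Morphometry

- **Volume** is voxel coverage: foreground count × dz·dy·dx.
- **Nuclear shape factor (NSF)** is sphericity ψ = π^⅓(6V)^⅔ / A with V
  the voxel-coverage volume and A the area of a marching-cubes iso-surface
  extracted at level 0.5 from the lightly smoothed (σ = 1 voxel) binary
  mask, with physical spacing. Counting exposed voxel faces instead would
  overestimate A by ~1.5× for a sphere and destroy the sphere ⇒ 1 anchor.
  The mask is padded by 4 voxels (beyond the smoothing support) so the
  estimate is exactly translation-equivariant. A digital sphere (r = 3 µm,
  0.125 µm isotropic) scores 1.001; the stated mesh tolerance is ±0.02, and
  a prolate 2:1 spheroid matches its closed-form sphericity within 3%.
  Masks under 100 voxels are rejected — the surface estimate is unreliable
  below that. Equivalence with any proprietary shape-factor implementation
  is not claimed; only the sphere anchor and ordering (more irregular ⇒
  lower NSF) are.
- **Solidity** is V / V_hull with the convex hull rasterised over voxel
  centres (`offset_coordinates=False`; the half-voxel-offset variant
  inflates the hull of a digital sphere and pushes its solidity to ~0.97).
  Convexity is affine-invariant, so the index-space hull is correct under
  anisotropic spacing. A nucleus is classified invaginated when solidity
  < 0.92 — a free default chosen to sit clearly below convex digital
  shapes (≥ 0.98) while single 1–1.5 µm pockets land near 0.95; the raw
  solidity is always reported alongside the call.
- **Channel volume** (e.g. LaminA/C) Otsu-thresholds the channel within
  the nuclear mask and reports the supra-threshold voxel volume; an
  all-zero channel gives 0, not an error.
- **Peripherality index** is the fraction of within-mask channel intensity
  within a shell depth (default 0.5 µm) of the boundary, using the
  physical-units Euclidean distance transform. It is an imaging proxy for
  peripheral (lamina-associated) heterochromatin. Shell fraction and core
  fraction sum to 1 exactly for uniform intensity.

## Territories, distances, proximity, co-localization

Paint channels are Otsu-thresholded on within-nucleus intensities only,
labelled with 26-connectivity, filtered at 0.5 µm³, and truncated to the
two largest objects (homolog pairs). Distances are centroid-to-centroid in
µm. A cell is *proximal* when one merged object is detected or two objects
lie within d_prox = 2.0 µm (boundary inclusive); zero objects leave the
call undefined and the cell is excluded from percentages. d_prox is a
configurable default at the territory-radius scale that separates the
adjacent-homolog regime (merged objects) from the separated regime
(~3–4 µm).

With threshold-plus-components detection the resolution scale is set by
the territory width convolved with the PSF, not by the PSF alone: two
Gaussian blobs merge once the intensity saddle between them rises above
the threshold, which for σ_blob = 0.4 µm and psf ≈ 0.2 µm happens below
≈ 2.5 µm separation. Merging of adjacent homologs is therefore expected
behaviour, mirrored in real paint data, and is exactly why the proximity
call accepts a single merged object as proximal. No watershed splitting is
applied to territories.

Co-localization volume is the voxel overlap between a territory and the
mark channel thresholded (Otsu) within the nucleus, reported with the
fraction of the territory covered.

## Epipolarity score

Over a deterministic set of unit directions, the score is the largest
fraction of total within-mask mark intensity on one side of the plane
through the *geometric* mask centroid (matching a visual call made "across
the middle of the nucleus"; the intensity centroid would chase the
asymmetry being measured). Voxels exactly on the plane contribute half to
each side, so a symmetric mark scores exactly 0.5 and the score is in
[0.5, 1] by construction. The direction set is a Fibonacci spiral
symmetrised over the 24 octahedral rotations plus the coordinate axes
(~220 directions at the default n = 200), which makes the score seed-free,
exactly invariant under 90° axis rotations on laterally isotropic grids,
exactly 1 for axis-aligned half-space marks, and within 0.02 of a
5000-direction search on smooth marks. The score is invariant under
positive rescaling of the intensities; additive offsets (unsubtracted
background) compress it toward 0.5 — no background subtraction is applied
by default.

A cell is *polar* when score ≥ τ = 0.7. Under the isotropic null the score
sits near 0.5 (rising with noise and shrinking voxel counts), so τ = 0.7
cleanly separates null from concentrated marks at realistic cell sizes;
τ is a config knob and the raw score is always reported. Percent-polar is
summarised per biological repeat and reported as mean + 1 SEM across
repeats; a single repeat reports SEM 0 with a warning.

## Chromosomal enrichment

Expected counts are total × wᵢ/Σw with weights either chromosome sizes or
per-chromosome gene counts (gene counts rather than genes/Mb, so the two
weightings are commensurate totals; the alternative is a one-line config
change). The fit is Pearson's X² = Σ(obs−exp)²/exp. `method="auto"` uses
the asymptotic chi-square distribution (df = k−1) when all expected
counts are ≥ 5 and otherwise an exact multinomial Monte-Carlo null with
p = (1 + #{X²_sim ≥ X²_obs}) / (1 + n_sim) — with ~100 peaks over 21
mouse chromosomes, expected counts fall below 5 and the asymptotic test is
unsafe. The Monte-Carlo test is calibrated: its type-I error at α = 0.05
is 0.05 ± 0.01 over 2000 null datasets (n_sim = 2000), and it tracks the
chi-square p within Monte-Carlo error when expected counts are large.
Enrichment scores are observed/expected. Note that sampling peaks with a
fold f on one chromosome yields a measured score of f/(1+(f−1)p) (p the
chromosome's weight share), because the fold renormalises the remaining
chromosomes' probabilities.

Differential-peak overlap counts each A peak once, paired with its first
overlapping same-chromosome B interval (≥ 1 bp by default) in coordinate
order; same-direction requires matching gain/loss labels, with direction
taken from a label column or the sign of the score. Genomic annotation
assigns each peak by its midpoint with precedence TSS (± 100 bp of the
strand-aware TSS) > promoter (1 kb upstream) > gene body > intergenic;
counts always sum to the table size.

## Synthetic-data generator

The generator is first-class, tested code; its defaults define the study
conditions for every recovery test.

- **Nucleus**: ellipsoid (radius × per-axis ratios), optional smooth
  radial roughness (a low-frequency Gaussian random field, unit-s.d.,
  scaled by the roughness amplitude), and spherical pockets carved at
  random boundary points, each penetrating `invagination_depth` below the
  local surface — a formalisation of the pocket-like invaginations of
  young HSC nuclei, which were shown but never parameterised. Largest
  component + hole filling guarantee a single connected mask. Shapes that
  do not fit the grid with a 2-voxel margin raise an error naming the axis.
- **Mark**: intensity ∝ exp(κ·cosθ) about a random unit direction (a von
  Mises–Fisher angular profile; κ = 0 is isotropic), normalised to unit
  mean inside the nucleus so the total mark amount is independent of κ —
  polarisation redistributes the mark, it does not change how much there
  is. (Peak normalisation instead couples κ to total intensity and lets
  the camera-noise pedestal dilute concentrated marks more than diffuse
  ones, inverting the score ordering at high κ.)
- **Homologs**: two Gaussian blobs (σ default 0.4 µm) at ± separation/2
  along a random direction whose endpoints fall inside the nucleus.
- **Optics and camera**: per-axis Gaussian PSF (default 0.35/0.2/0.2 µm),
  Poisson photon noise with gain, additive Gaussian read noise, clipped
  and quantised to uint16 (matching 16-bit acquisition exports). All
  randomness flows from explicit seeds; identical (config, seed) gives
  bit-identical stacks.
- **Peak tables**: chromosome drawn from a multinomial ∝ size × fold,
  start uniform in [0, size − width), fixed 500 bp width, sorted output.

The default aging cohort (`aging_cohort()`) encodes the study conditions:
young = radius 2.8 µm, two 1.2 µm pockets, κ = 8, separation 1 µm; aged =
radius 3.4 µm, no pockets but elongated (axis ratios 1.25/1.0/0.8) and
rough-boundaried (roughness 0.1) — hence less spherical — κ = 0.5,
separation 4 µm; per-cell scatter on radius, κ and separation; 3
biological repeats. The aged group's irregularity parameters are the one
place the group definitions go beyond radius/pockets/κ/separation; they
encode the reported aged phenotype (larger *and* less spherical nuclei)
and were fixed as part of the cohort design.

What the generator does **not** emulate: realistic optics (no OTF/SIM
model, no depth-dependent aberration), chromatin texture inside the
nucleus, autofluorescence gradients, multi-cell fields, or
polymer-physics territory shapes. Passing recovery tests therefore shows
the estimators are correct and unbiased under a faithful geometric model
of the measurement — not that segmentation or scoring is robust to every
real-world artefact.

## Group statistics

The biological repeat is the unit of replication: metrics are averaged per
(group, repeat) before testing, matching mean + 1 SEM reporting (a
per-cell pooled mode exists for distance/volume-style plots). Two groups
with matched repeat structure use a paired t test; otherwise Welch's t;
three or more groups use one-way ANOVA. Pairwise Bonferroni-adjusted
t tests (p_adj = min(1, m·p_raw)) are computed only when the overall p is
below 0.05, and the pairwise table is empty otherwise. For binary
per-cell outcomes whose per-repeat proportions can be degenerate (all
cells polar in every young repeat), the recovery tests fall back to
Fisher's exact test on pooled counts.

## Problem sizes and determinism

Recovery suites run on 40×72×72 stacks at (0.5, 0.25, 0.25) µm — large
enough to hold a 3.5 µm-radius nucleus with margin — with 30 cells per
group for cohort recovery, 20 cells per κ level for the monotonicity
sweep, 2000×2000 simulations for null calibration and 1000 seeds for the
enrichment-power study; these sizes give stable statistics while keeping
the full suite fast. Cohort CSVs are byte-identical across reruns with the
same configuration and seed; all seeds derive from one root seed via
spawned seed sequences.

## Known limitations

- Absolute NSF and solidity values depend on mesh and hull conventions;
  only anchors and orderings are comparable across implementations.
- The epipolarity score saturates near 1 for κ ≳ 10; concentration
  differences beyond that are not resolvable from the score.
- Territory detection cannot separate homologs below the blob + PSF
  merging scale (by design; such cells are classified proximal, and their
  distances are undefined rather than imputed).
- The Monte-Carlo goodness-of-fit p has resolution 1/(1+n_sim); n_sim
  must be raised for very small target p-values.
- Peak annotation is midpoint-based; peaks spanning category boundaries
  are assigned a single category, and no attempt is made to reproduce any
  specific annotation tool's precedence rules beyond the documented one.
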