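# Methods

This note records what each stage computes, the default parameter values,
and why those defaults were chosen.  Everything here is testable against
the synthetic generator's ground truth; the test suite does exactly that.

## Data model

A nucleus is observed over one or more hybridization rounds.  Each round is
a `VoxelStack`: a `(z, y, x)` float volume per fluorochrome plus the
fluorochrome → chromosome map and the physical voxel spacing in µm, stored
on disk as a multi-page TIFF with a JSON sidecar.  Masks are boolean volumes
on the same grid.  All coordinates are `(z, y, x)`; the grid is anisotropic
(the z step is coarser than the in-plane pixel size) and spacing only enters
when voxel counts are converted to physical volumes.

## Synthetic generator

`ctfish.synthetic` produces nuclei with voxel-exact ground truth:

1. the nucleus is an ellipsoid on the voxel grid;
2. each painted chromosome receives one territory per copy, grown by seeded
   random aggregation on the 6-neighbourhood.  `shape_irregularity` blends
   breadth-first (compact) and random-frontier (rough) growth;
3. the two homologs are *paired* with the per-chromosome probability of the
   chosen stage preset.  A paired second copy grows from a face-neighbour of
   the first, so the merged signal is one connected component under both 6-
   and 26-connectivity; an unpaired second copy grows outside a
   `min_gap_voxels`-wide Chebyshev margin, so the copies are non-adjacent
   under either rule;
4. territories of one round are mutually exclusive domains.  With per-pair
   probability `association_probability`, a chromosome is instead seeded
   *inside* a same-round partner territory, so that two chromosomes share
   voxels if and only if association was drawn for the pair;
5. each channel renders nucleoplasm + signal intensities, is blurred by a
   Gaussian PSF and degraded with Gaussian noise, then clipped at zero.

All randomness flows from one `numpy` `Generator`; populations draw
per-nucleus seeds from `SeedSequence.spawn`, so any nucleus can be
regenerated independently and runs are reproducible bit-for-bit.

### Generator defaults and rationale

| parameter | default | rationale |
| --- | --- | --- |
| voxel spacing (z, y, x) | (0.17, 0.1, 0.1) µm | instrument z-step between optical sections; in-plane pixel size of a 63× objective at the used zoom.  Population runs use 0.12 µm in-plane to keep whole-karyotype simulations cheap |
| nucleus semiaxes | (2.0, 3.0, 3.0) µm | flattened-spheroid nucleus of a germ-line cell preparation |
| `territory_voxels` | 500 (240 in population runs) | places one territory copy at ≈1.1% of the nucleus volume, the observed single-signal NVP average; the per-round sum of copies must fit the nucleus |
| `paired_volume_factor` | 1.6 | paired (merged) signals are ~60% larger than single signals in the modeled data |
| `shape_irregularity` | 0.5 | territories are irregular, not spherical; 0.5 keeps rough surfaces while remaining recoverable at the default PSF |
| `association_probability` | 0.4 | a mid-range association rate; fully configurable per pair |
| `signal_amplitude` / `nucleoplasm_intensity` | 200 / 40 | ≈5:1 paint-to-counterstain contrast; non-zero nucleoplasm makes the nucleus segmentable from the summed channels |
| `blur_sigma_um` | 0.075 | diffraction-limited lateral PSF sigma of a 1.4-NA oil objective at ~500 nm emission (≈0.21·λ/NA).  Modeled isotropic; real axial PSFs are wider, which would mainly thicken the top/bottom faces |
| `noise_sd` | 8 | detector noise at ~5% of signal amplitude (high-SNR confocal regime) |
| `min_gap_voxels` | 3 | unpaired copies separated by ≥3 background voxels, safely beyond 26-adjacency |

Stage presets convert the packaged per-stage pairing counts into
per-chromosome pairing probabilities; the two late stages are fully paired.
A `lymphocyte` preset applies one uniform baseline probability (default
0.1947) to model somatic proximity-by-chance.

### Known simplifications

Territories are single blobs (no substructure), the PSF is isotropic and
Gaussian, noise is additive Gaussian rather than Poisson-dominated, rounds
are perfectly co-registered, and photobleaching/stripping residuals between
rounds are not modeled.  Adjacent (non-associated) territories may still
*touch* after thresholding, so segmentation-level association rates run
slightly above the generator's ground-truth rate; the summary statistics
flag pairs relative to the population mean, which absorbs this shared bias.

## Segmentation

The nucleus mask is the largest connected component of the summed channels
after Gaussian pre-smoothing (sigma 1 in-plane voxel, scaled to be
physically isotropic in z), Otsu thresholding and hole filling.  Summing
channels (and, when available, rounds) uses all photons; the nucleoplasm
background separates the nucleus from the outside.

Territory masks are Otsu-thresholded **within the nucleus** — the threshold
is computed from in-nucleus voxels only, making the mask invariant to
uniform intensity scaling — then speckle-filtered (`min_size`, default 5
voxels) and hole-filled.  Territory channels are **not pre-smoothed by
default**: painting signals are only a few voxels across, and measured
against ground truth, pre-smoothing both drags the Otsu threshold into the
blur shell (systematically dilating the mask) and erases genuine boundary
detail.  On whole-karyotype synthetic populations at default noise, voxel
Jaccard recovery is ≈0.95 without smoothing versus ≈0.73–0.89 with sigma
0.5–1, with identical pairing-call accuracy; a `sigma` parameter remains
available for low-SNR data.

## Pairing, association, NVP

* **Connected components** use 26-connectivity by default (a diagonal touch
  is continuous), configurable to 18 or 6.  The published rule — paired =
  "a unique and continuous group of voxels" — does not state a connectivity;
  26 is the most permissive reading, and the choice is exposed everywhere.
* **Pairing call**: components below `min_size` are ignored; one retained
  component ⇒ paired, two or more ⇒ unpaired, none ⇒ uncallable (excluded
  from rate denominators).  The single-copy Y is never classified.
* **Association**: two same-round chromosomes are associated when their
  masks share ≥1 voxel; overlap percentages are normalized per territory.
* **NVP**: signal voxels / nucleus voxels × 100.  A paired signal yields one
  two-chromosome record; an unpaired signal yields one one-chromosome record
  per retained component; Y yields one-chromosome records.

## Population statistics

* Per-chromosome pairing tables count one-signal (paired) vs two-signal
  (unpaired) nuclei.  Stage mean/SD are **unweighted** across the 20
  classifiable chromosomes (autosomes plus X) with the sample (n−1) SD,
  matching the published convention.
* Pearson correlations of paired percentage against chromosome size, GC
  content and gene count use the two-sided t-based p-value (df = n−2) and
  are defined only for the two early stages (later stages have zero
  variance).
* The NOR-bearing vs non-NOR comparison is a pooled-variance two-sample
  Student t-test (6 vs 14 chromosomes), Welch available as an option.  The
  published analysis predates the now-common Welch default and reproduces
  only under the pooled test.
* Association rates get Wald 95% CIs, switching to the Wilson score interval
  whenever k = 0 (the Wald interval degenerates to zero width there).  A
  pair is flagged `above_mean`/`below_mean` when its whole interval lies
  above/below the overall weighted mean Σk/Σn, again following the published
  convention; no multiple-testing correction is applied by default (a
  Bonferroni option exists as an extension).
* NVP column averages are unweighted means over the 21 chromosome rows per
  stage and signal kind.

## Published correlations

The stage means/SDs, NVP column averages, and NOR t-test p-values all
reproduce exactly (at printed precision) from the packaged per-chromosome
tables.  The printed Pearson coefficients do not: recomputing from the
printed counts gives r = −0.370 (p = 0.109) for size at the first stage and
r = −0.327 (p = 0.159) at the second, where −0.36 (p = 0.117) and −0.41
(p = 0.070) are printed; the GC and gene-density pairs deviate similarly.
The recomputed r and p values are mutually consistent at n = 20 (each p
follows from its r via the t transform), while the printed pairs are as
well — so the printed correlations were evidently computed from per-cell
source data (or a table revision) that the printed per-chromosome counts do
not reproduce.  Every plausible variant was checked: n = 19/20/21 (with and
without X or the late-stage chromosomes), gene count vs gene density per Mb,
Spearman and Kendall instead of Pearson — none yields the printed values.
The package computes the correlations faithfully from the packaged tables
and reports the mismatch (`ctfish reproduce-paper`); the corresponding
acceptance test asserts the printed values and therefore fails, which is
the intended, documented outcome.
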