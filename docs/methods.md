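# Methods

This note documents the models, parameter choices and numerical conventions
behind `gelquant`, and what the synthetic-data validation does and does not
demonstrate.

## Stain model and deconvolution

Bright-field colour is modelled with the Beer–Lambert law. Per-pixel optical
density is OD = −log10((I + 1)/256) per RGB channel; a pixel's OD vector is
assumed to be a non-negative combination of two unit stain vectors
(hematoxylin with eosin, or hematoxylin with DAB; Ruifrok–Johnston-style
values, normalised). Unmixing is per-pixel least squares against the chosen
pair with negative concentrations clipped to zero. The synthetic renderer
uses the same forward model, so deconvolution is a genuine inverse problem:
the render → unmix round trip is accurate to ≲0.02 OD (quantisation), and
the tests require ≤0.05 mean absolute error.

## Solid/hollow segmentation

Hollow (unstained) regions transmit nearly all light (total OD ≈ 0); solid
gel and cells are stained. The split is Otsu's threshold on the total-OD
histogram, with one refinement: the histogram of a cellular section is
trimodal (hollow ≈ 0, gel ≈ 0.2–0.35, nuclei ≳ 1), and Otsu can land in the
gel/nucleus valley or in a stain-rim tail. The threshold is therefore
re-applied below itself (up to four times) until the lower class is
genuinely near-white (mean total OD ≤ 0.12); if no such class emerges the
section is reported as all solid. Hollow components smaller than
`min_hole_um2` (default 30 µm²) are absorbed into solid. A stain-free image
yields an all-hollow mask with an `EmptySectionWarning`.

## Nucleus segmentation

Nuclear signal is hematoxylin OD, plus DAB OD for H-DAB stains (DAB-positive
nuclei can be nearly hematoxylin-free); eosin is excluded. Candidate pixels
exceed `od_threshold` (default 0.15). Touching nuclei are split by a
watershed on the distance transform, smoothed with σ = 0.6 px — heavier
smoothing erases the distance peaks of small karyorrhectic fragments
attached to a nucleus. Peaks closer than one typical nucleus radius
(√(14/π) µm) are merged; any connected component left without a marker is
seeded at its distance maximum so that no object can silently vanish.
Components below `min_nucleus_um2` (default 5 µm²) are discarded for
morphometry; phase analysis re-uses the same labels down to 0.5 µm² so that
fragments survive.

Per-nucleus staining intensity is estimated as the median DAB OD over the
"core" pixels — the upper half of the object's pixels ranked by nuclear OD.
The core excludes the blurred rim (which dilutes a plain mean) and the
median resists slivers of a touching neighbour mis-assigned by the
watershed; a plain or upper-half mean produced single-bin misclassification
in both directions.

## Cluster labelling and morphometry

Clusters are connected components of the morphological closing of the
nucleus union (disk radius = one typical nucleus diameter, 4.2 µm),
intersected with solid gel. Any component containing a full nucleus is a
cluster — so an isolated single cell counts, consistent with treating every
nucleated solid component as a cluster; `min_cluster_um2` (default 20 µm²)
gates only components whose nuclear material is all sub-nuclear fragments.
Components touching the image border are kept and flagged. Size classes are
half-open and lower-inclusive: area < 400 µm² small, 400–2000 µm² medium,
≥ 2000 µm² large; classes are assigned by area alone. Density is
count/solid-area (mm²), occupancy is 100·Σarea/solid-area, both reported per
class and total. Connectivity is 8-connected throughout; areas are pixel
counts × (µm/px)²; quantiles use linear interpolation.

Nucleus perimeter uses the Crofton formula (4 directions), which is nearly
unbiased on smooth rasterised boundaries; the diagonal-corrected
boundary-step length overestimates them by ~5%, which is enough to pull the
circularity of a radius-20 px disk to 0.91. The shape factor is circularity
4πA/P² clipped to 1; an elongation alternative (minor/major axis ratio) is
available behind `shape_metric="elongation"` because the convention used by
vendor pathology software is not published — note that reported shape-factor
trends in the literature sometimes run opposite to the circularity
convention, so no claim is made that either switch matches a specific
instrument.

## IHC scoring and phases

Intensity bins on mean DAB OD are lower-inclusive at (0.15, 0.40, 0.70) for
weak/moderate/strong; the H-score uses the standard 1/2/3 weights (bin count
and weights are configurable). The categorical scale is − (<1%), + (1–20%),
++ (20–50%, 50 inclusive), +++ (>50%).

Phase calls are explicit artifact definitions standing in for pathologist
judgment: karyorrhexis = a halo of ≥3 small nuclear fragments (components
below 40% of the median nucleus area, grouped by centroid distance ≤ 5.5 µm);
mitosis = solidity ≥ 0.9, aspect ratio ≥ 1.8 and above-median nuclear OD;
otherwise interphase. Because the halos of adjacent dying cells chain into
one connected fragment group, a group of *m* fragments is counted as
round(m/4.5) karyorrhectic cells (4.5 ≈ the expected fragments per cell).
Karyorrhectic cells are intensity-scored from the median of per-fragment
core estimates, not pooled pixels, so a chained group spanning different
intensity classes is not blurred into an intermediate value.

MKI thresholds follow the Shimada convention with the 2–4% band closed:
low < 2%, intermediate 2–4% inclusive, high > 4%. MKI is computed
whole-section (no 5000-cell field-sampling emulation beyond an optional
subsample in the CLI).

## Mechanics

`to_stress_strain` drops samples before the first force ≥ preload (default
0.1 mN), re-zeroes displacement there, and uses engineering quantities
(stress = F/A₀ in mN/mm² = kPa, strain = Δh/h₀); samples beyond 50%
compression are discarded, matching the protocol ceiling. The modulus is the
OLS slope (intercept free) over strain ∈ [0.05, 0.15] by default — above the
toe region, well below the compression limit; `best_window` slides a
0.10-strain window one sample at a time and keeps the highest r², ties
toward lower strain. r² of a residual-free fit to constant data is defined
as 1. Only the slope-of-linear-region modulus is implemented (no tangent vs
secant distinction, no viscoelastic models). Group comparison is a
two-sided t-test, Welch by default since equal variances between
formulations are not guaranteed; a pooled variant exists. Degenerate
zero-variance groups: equal means give p = 1, unequal means a vanishing p.

## Statistics and reporting

Pearson chi-square on 2×2 positive/negative tables, df = 1, no continuity
correction by default (counts are large in this setting); Yates available.
Stars: *** p<0.001, ** p<0.01, * p<0.05, ns otherwise, all strict. No
multiple-testing correction by default, matching common practice in this
literature; aggregation reports mean with sample SD or SEM (SD for moduli,
SEM for morphometry, per the respective figure conventions; both derivable
from the stored values). Display rounding is one decimal for percentages and
two for moduli; CSVs keep full precision.

## Synthetic generator: what it emulates

Sections default to 512×512 px at 0.5 µm/px (a 20× scan scale). Clusters are
unions of 3–6 overlapping disks (irregular outlines), placed with ≥8 µm
mutual clearance — enough, together with the nucleus-free interior margins,
that the segmentation closing cannot bridge neighbours. Hollow blobs are
placed after the clusters to reach the target porosity within ±0.2 points.
Nuclei are ellipses (area ~N(14, 2.5²) µm², clipped to 8–20) on a jittered
hexagonal grid at 25 nuclei per 1000 µm² of cluster (≈40 µm² of cluster per
cell, which makes the size-class areas and their nominal cell counts
mutually consistent; grid spacing is exposed as `nucleus_spacing_um`).
Mitotic nuclei render elongated (axis ratio 2.4–3.0, so the measured ratio
stays above the 1.8 cutoff after blur) with elevated hematoxylin;
karyorrhectic nuclei render as 3–5 fragments in a compact halo kept inside
the cluster and ≥2 px clear of siblings, with a 1.25× OD boost (condensed
chromatin) that compensates the blur loss of small objects. Rendered DAB
densities (0.30/0.57/0.92 for weak/moderate/strong) sit at the centres of
the default calling bins; the gel counterstain in IHC mode (0.10 OD) is kept
several noise standard deviations below the nuclear threshold. Rendering
adds σ = 0.6 px Gaussian blur and 0.012 OD Gaussian noise.

Curves sample σ = E·ε + c·ε³ + N(0, sd) on an even grid of 300 points to 50%
strain (a 20%/min ramp lasts 150 s; a few samples per second). The default
noise is 1% of nominal peak stress. Pore masks place non-overlapping disks
with exact lognormal areas, largest first.

All generators are pure functions of their parameter record including the
seed; identical parameters give bit-identical output.

### Condition presets

`CONDITION_PRESETS` carries the six stiffness × time conditions (0/1/2%
AlgMA at 2 and 4 weeks) with published condition means — porosity, Ki67
positive fraction and H-score, MKI phase rates, acellular and cellular
moduli — used purely as generator inputs of realistic magnitude. The
intensity mix for a target H-score uses the binomial parametrisation
((1−t)², 2t(1−t), t²) with t = (μ−1)/2, whose mean weight is exactly μ.

### What passing tests show — and don't

Recovery tests show the pipeline inverts its own forward model: porosity to
±1 point, cluster counts to ±10%, percent positive to ±2 points and H-score
to ±10 across seeds, modulus to ≤2% median error at 1% noise. They do not
show robustness to real histology — folds, tears, stain batch variation,
out-of-focus regions, touching clusters, or scanner colour profiles are not
modelled, and phase classification is validated only against the generator's
own phenotype encoding. Known quantitative limitations: karyorrhexis
detection is conservative (roughly half of generated events are recovered at
the default density, because fragments fuse with neighbouring nuclei under
blur), so measured MKI percentages underestimate high karyorrhexis rates;
measured nucleus areas run ~20% above truth because the OD threshold sits on
the blurred rim; and cluster areas are closing-of-nuclei areas, not painted
gel areas, so occupancy is an estimate of cellular footprint rather than a
pixel-exact recovery.
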