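# Methods

This note documents the models, parameter choices and numerical decisions
behind `cloneburden`, and what the synthetic-data validation does and does
not demonstrate about real midgut images.

## Measurement pipeline

**Calibration.** All areas are physical: pixels × (pixel size)². Images
without a pixel size in their TIFF metadata are rejected unless one is
passed explicitly; percentages are exact pixel-count ratios.

**Z handling.** The default analysis path max-projects the z-series before
segmentation; screening acquisitions use a few z-planes rather than full
stacks, and few-plane versus deep-stack analyses of the same organ give
closely matching coverage (encoded as a <15 % relative-difference test).
A `per_plane` mode is kept for audit.

**Gut mask.** The organ is the largest 8-connected component of the red
(phalloidin) channel above Otsu's threshold, with holes filled. Failure to
find any red object raises an explicit "no gut detected" error rather than
returning zeros.

**Clone segmentation.** Foreground is green intensity *strictly greater
than* the threshold. `auto` mode computes Otsu's threshold on the green
histogram restricted to the gut mask; `fixed` mode exposes the user-set
"variable threshold" that accommodates images from different microscopes.
Components are labelled with 8-connectivity (ImageJ particle-analysis
behaviour) and components below 10 µm² (configurable) are discarded as
single-pixel noise; survivors are relabelled contiguously. Raising the
threshold can therefore never increase labelled area (a tested invariant).

**Anterior region.** The bench workflow selects the anterior portion
manually; here it is the first 40 % (configurable) of the gut mask's axial
extent, assuming the organ's long axis runs along image columns, as it does
in stitched tile scans. This makes the anterior-coverage metric
reproducible at the cost of ignoring organ curvature in the axial
coordinate.

**Tumour-like classification.** `area > 7,800 µm²`, strict inequality
("over" the threshold). The rule is a pure function of (area, threshold);
monotonicity in the threshold and permutation invariance are property-
tested.

**Nuclear morphometry.** The DAPI channel is thresholded (Otsu), and each
connected component is split by marker-based watershed on its Euclidean
distance transform. Markers are the connected blobs where the distance
map exceeds 0.85 of its component maximum: superlevel sets of a distance
transform over a convex region are connected, so a single convex nucleus
always yields one marker, while two fused nuclei pinched at a waist yield
two. Nuclei below 20 µm² are discarded; each nucleus is assigned to the
clone containing its centroid, and extra-clonal nuclei are excluded.
Nuclear areas are cross-sections on the analysis plane, not volumes.

**Pooled luciferase model.** A pool of k flies reads out the *mean* of its
members' activities. This is a modelling convention (the bench protocol
fixes the lysis volume rather than normalising arithmetically); it matches
the observation that pooling leaves the average readout unchanged while
shrinking its variance as 1/k. Pools are formed in input order for
reproducibility (a seeded shuffle is available); when the fly count is not
divisible by k the remainder forms a final, flagged, smaller pool.

**Statistics.** Kruskal–Wallis (tie-corrected, via `scipy.stats.kruskal`)
for skewed readings and count data, one-way ANOVA as the parametric
alternative; pairwise post-hoc Mann–Whitney tests carry Holm correction.
All-identical data returns statistic 0 / p 1 instead of an undefined tie
ratio. Survival curves are plain per-day percent-alive counts (censoring
only at the end of the observation window, where they coincide with
Kaplan–Meier — verified against `lifelines` in a test).

## Synthetic-data generator

The generator is the package's test bed: every rendered structure carries
ground truth (true masks, areas, owning clone), so the pipeline is
validated by parameter recovery rather than by eye.

**Geometry.** An idealised midgut: a tapered band 5,000 µm long (hard cap
6,000 µm) and 280 µm wide, gently curved, with a low-frequency width
bulge; per-gut jitter of ±5 % length and ±7 % width supplies biological
variation. The anterior region is the first 40 % of the axial length.

**Clone populations.** Clone areas are truncated lognormals — clone-size
distributions are strongly right-skewed — with per-condition hard maxima:

| preset | clones/gut | area law (median, σ, truncation) | anterior only |
|---|---|---|---|
| control | Poisson(15) | 700 µm², 0.8, ≤ 6,000 µm² | no |
| snail | Poisson(25) | 1,100 µm², 0.8, ≤ 6,500 µm² | no |
| apcras (base) | Poisson(45) | 800 µm², 0.6, ≤ 7,000 µm² | yes |
| apcras (merged) | Binomial(8, 0.75) | 9,500 µm², 0.12, 8,000–13,000 µm² | yes |
| apcras_treated | Poisson(rate solved, see below) | apcras base law | yes |

The tumour arm's supra-threshold clones are a separate "merged" component
(large masses formed by the fusion of a few surviving clones). Its count
law is sub-Poisson (binomial, mean 6/gut) deliberately: a handful of
merging events per organ is the biology being emulated, and it keeps the
per-gut total-burden coefficient of variation near the realistic ~15 %
rather than the >25 % a Poisson count on 10⁴-µm² masses would impose —
important because drug-effect comparisons run with 10 guts per arm. The
treated arm drops the merged component entirely (supra-threshold clones
essentially vanish under treatment) and its Poisson rate is solved from
the analytic truncated-lognormal means so that expected total clone area
is *exactly* half the untreated arm's at the parameter level.

**Nuclei.** Cross-section areas are truncated lognormals with the
condition maxima 420 µm² (control, snail), 980 µm² (apcras) and 680 µm²
(apcras_treated); the apcras/treated laws are broader (σ = 1.0,
median 120 µm²) to produce the "huge range of nuclei sizes" of tumour
clones. Nominal densities are 2.2 (control), 2.6 (snail) and 3.0
(apcras/treated) nuclei per 1,000 µm² of clone area. Nuclei are ellipses
(aspect ≤ 1.6) placed by random sequential adsorption with a 2-px
clearance; in densely packed tumour clones placement saturates and the
realized density falls below nominal — the skipped nuclei are simply not
rendered, so ground truth stays exact. Sparse small background nuclei
(30–90 µm²) outside clones exercise the pipeline's extra-clonal exclusion.

**Rendering.** 1.0 µm/px, 3 z-planes, 16-bit. Structures are crisp
(no point-spread blur): clones at ~12,000 counts over a 600-count
intra-gut background, gut at 8,000 over 500, nuclei at 9,000 over 300.
Noise is one Gaussian draw per pixel with variance
`read_noise² + signal/gain` — a Gaussian approximation of Poisson shot
noise, accurate at these signal levels — plus a small per-plane intensity
jitter. The default SNR is far above 3 by design: the tests probe
segmentation and measurement correctness, not denoising.

**Determinism.** Every entry point is seeded; structure (geometry, clone
and nucleus placement) and noise are drawn from two independent streams,
so re-rendering the same gut with a different z-plane count changes only
the noise. Batch runs derive per-gut seeds from the batch seed, making
gut *i* of a batch bit-identical to a direct single-gut call.

**Placement failure.** A clone that cannot be placed inside the organ
(with full containment and 2-px clearance) after 200 retries raises an
explicit `PlacementError` — reachable when clone areas are incompatible
with the supplied geometry, e.g. tumour-scale clones in a very short or
narrow gut whose anterior region cannot hold them.

## Study sizes

Recovery studies run at the sizes a bench screen would use: 20 guts per
condition for classification and nuclear-morphometry recovery, 10 guts
per arm for the drug-effect coverage comparison, 3 pools of 10 flies for
the luciferase screen, 10,000 replicates for the pooling variance profile,
21-day survival windows. With ~30–300 in-clone nuclei per gut, the batch
maximum of the truncated nuclear law sits within a few percent of the
truncation point, which is what makes "maximal nuclear area" a recoverable
condition signature.

## What passing tests do and do not show

The generator validates the *measurement machinery*: exact area
arithmetic, threshold behaviour, batch/single equivalence, recovery of
designed population parameters through rendering plus segmentation. It
does not emulate confocal optics (no PSF, no depth attenuation), tile-
stitching artefacts, staining variability, clone loss over time, or
out-of-focus light — so passing recovery tests does not guarantee the
same accuracy on low-SNR or poorly stained real images; the fixed and
auto threshold modes exist precisely because real acquisitions vary.
Two further known gaps: whole-gut coverage differs between control and
tumour arms in the generator (~1 % vs ~8 %), whereas in real data that
comparison can be non-significant (clone loss and between-fly variability
are not modelled); and multilayering/orthogonal-view morphology is out of
scope (a qualitative, not screening, readout).

## Degenerate inputs and tie-breaks

Blank green channel: empty label map with a warning (not an error), so
clone-free guts flow through batches. Blank red channel: explicit
"no gut detected" error. All-tied statistics: statistic 0, p 1. Clones
straddling the gut boundary: only the intersection with the gut mask
counts toward coverage. Zero-dispersion laws: exact point masses, used as
sanity oracles. Remainder pools: kept and flagged, never dropped.
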