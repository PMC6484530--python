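# Methods

`ecprof` implements a high-content phenotyping workflow for confluent
endothelial-cell (EC) monolayers imaged in three fluorescence channels —
a nuclear stain, a membrane junction marker (VE-cadherin–like), and an
activated-NOTCH spot stain — together with a ground-truthed simulator that
makes every stage testable without microscope data.

## The synthetic monolayer model

A confluent monolayer is modeled as a Voronoi tessellation of blue-noise
(Poisson-disc) seeds, clipped to the frame. Anisotropy ("cell stretching",
the canonical VEGF response) is produced by scaling one coordinate axis by
the `elongation` factor before seed placement and tessellation and mapping
the polygons back; cells therefore elongate uniformly without overlaps, and
the mean width/length ratio of the tessellation decreases monotonically in
`elongation` (verified over {1, 1.5, 2}). Boundaries are optionally warped
by a smooth random displacement field (`jaggedness`, px). Because the field
is global, shared borders stay shared and the ground-truth adjacency
(polygon border sharing) is preserved.

Each cell receives one nucleus ellipse (area ≈ `nucleus_area_fraction` ×
cell area, default 0.15, long axis aligned with the cell, shrunk until it
lies strictly inside the polygon) and a NOTCH activation category drawn
from `category_probs` = (π_neg, π_cyt, π_nuc). Spot counts per required
compartment are `1 + Poisson(rate − 1)` so the category constraints hold by
construction: cytoplasm-only cells get ≥ 1 cytoplasmic and no nuclear
spots; nuclear-active cells get ≥ 1 nuclear spot plus optional cytoplasmic
ones; negative cells get none. Nuclear spots are placed well inside the
ellipse and cytoplasmic spots at ≥ 3 px from both the nucleus and the cell
border, so that compartment assignment is unambiguous at the rendered
resolution.

### Rendering

Channels (order fixed: nuclear, junction, spots) are drawn at 16-bit range:
filled nucleus ellipses; cell-border polylines with a Gaussian cross
profile (`junction_width`/2 as σ); and isotropic Gaussian spots
(`spot_sigma`). All channels get a PSF blur (`psf_sigma`), a constant
background offset, and additive Gaussian noise. Rendering is deterministic
for fixed (scene, params, seed).

**Junction fragmentation.** Borders are cut into `segment_length` chunks
(default 16 px); each chunk is independently *interrupted* with probability
`junction_fragmentation` (p_frag) by carving a gap of 45 % of its length
out of its middle. The expected number of discontinuities per border is
then proportional to p_frag over the whole [0, 1] range, which makes the
measured J_n statistic a monotone readout of the knob (deleting whole
segments instead would make the number of surviving fragments peak at
p_frag = 0.5 and fall off beyond it, destroying the monotone
discontinuity↔J_n relationship the assay is built on). The 16 px segment
length keeps both gaps (~7 px) and surviving pieces (~9 px) comfortably
above the detection scale of the ridge filter.

### Default study conditions

The packaged acquisition design mirrors the assay layout: 2 cell models ×
2 treatments × 2 replicates × 5 areas = 40 areas, each a 3×3 grid of
192×192 px tiles with 0.05 % (fraction 0.0005) overlap — read literally
from the printed instrument setting; 5 % is available via config. The
baseline scene is 576×576 px at 0.5 µm/px with 120 cells per area
(~690 µm² per cell), noise σ 25 on a background of 200 with signal
amplitudes 3000–4000.

Phenotype presets encode only the *orderings* the assay is meant to
resolve, since no generative parameter values exist to fit:

| preset       | elongation | p_frag | (π_neg, π_cyt, π_nuc) | density factor |
|--------------|-----------:|-------:|-----------------------|---------------:|
| huvec_basal  | 1.15       | 0.15   | (0.10, 0.25, 0.65)    | 1.0 |
| huvec_vegf   | 1.60       | 0.18   | (0.10, 0.25, 0.65)    | 1.0 |
| ipsc_basal   | 1.35       | 0.45   | (0.30, 0.50, 0.20)    | 0.7 |
| ipsc_vegf    | 1.55       | 0.55   | (0.25, 0.30, 0.45)    | 0.7 |

VEGF raises elongation within each model; the progenitor (iPSC-derived)
model has more fragmented junctions, a lower nuclear-active fraction at
baseline with a VEGF-induced rise, and a sparser monolayer of larger cells
(density factor 0.7). The reference model's category mix (> 60 % N⁺/⁺,
~25 % N⁺/⁻) reflects its high constitutive activation and is VEGF-inert.

What the simulator does *not* emulate: optical vignetting and chromatic
aberration, illumination gradients, staining variability between cells,
debris/mitotic figures, non-convex or migrating cell shapes, and 3D
structure. Passing the recovery suites therefore shows the measurement
chain is correct on idealized confluent monolayers, not that it is robust
to every real-world artifact.

## Measurement chain

**Segmentation.** Nuclei: Gaussian smooth (σ 2 px) → Otsu threshold →
fill holes → distance-transform watershed split (peak separation 12 px) →
area gate 30–400 µm². Cells: seeded watershed on the smoothed junction
channel, nuclei as seeds — the junction stain forms ridges along borders,
which are exactly the watershed lines. The monolayer is assumed confluent
(foreground = full frame), so cell labels partition the image and
cell id = nucleus id. Cells touching the frame edge are excluded from
per-cell statistics but keep their pixels for adjacency.

**Junction objects and J_n.** The junction channel is enhanced with a
Hessian ridge filter (σ 1.5 px, reflective boundaries): per pixel, the
magnitude of the most negative Hessian eigenvalue clipped at zero — high
on thin bright lines, zero on flat regions, invariant to intensity
offsets. The ridge map is thresholded (Otsu over positive ridge values by
default, so doubling all intensities leaves counts unchanged) and
intersected with each retained cell's boundary ring (pixels within
`ring_width` = 4 px of its border); 8-connected components of ≥ 4 px² are
that cell's junction objects. An unbroken shared border counts once for
each neighbor — a consistent convention for a statistic used
comparatively. J_n = total objects over retained cells / retained nuclei.

**NOTCH classification.** Spots: difference-of-Gaussians band-pass
(σ 1.5 px, ratio 1.6), local maxima ≥ 4 px apart, kept above 8 robust
standard deviations (1.4826·MAD) of the response. Each spot belongs to the
cell containing its center; it is nuclear iff the center lies in that
cell's nucleus. Cell rule: no spots → N⁻/⁻; cytoplasmic only → N⁺/⁻; any
nuclear spot → N⁺/⁺ (nucleus-only cells are grouped into N⁺/⁺). Contact
clusters are connected components of N⁺/⁺ cells on the adjacency graph
(cells adjacent iff ≥ 3 4-connected pixel pairs straddle their labels,
suppressing corner-touch artifacts); the four cluster features are the
number of clusters, mean and maximum cluster size, and the fraction of
N⁺/⁺ cells in clusters of size ≥ 2.

**Morphometry and STAR.** Shape features per binary object: area,
Crofton perimeter (4 directions), roundness = min(1, 4πA/P²), and the
4√λ ellipse-equivalent length/width from population pixel moments (a disk
of radius R gives exactly 2R). STAR intensity-distribution features per
cell and channel: symmetry (1 − Σ|I − I_mirror|/(ΣI + ΣI_mirror), mirrored
across the *mask's* principal axis through the intensity centroid, so
off-axis intensity lowers symmetry instead of re-orienting the axis);
threshold compactness at fractions 0.3/0.4/0.5/0.6 of the in-mask mean,
normalized so a uniform disk scores 1; intensity-weighted axial ratio and
small-axis length; and the intensity-weighted mean and standard deviation
of the normalized distance-to-border. Zero-intensity cells get all-zero
STAR values (logged).

**The 47-feature registry.** 6 cell-shape + 6 nucleus-shape + 1
nucleus/cell area ratio + 9 STAR (junction channel) + 9 STAR (spot
channel) + 4 mean intensities + 4 junction statistics (J_n, mean object
area, ring area fraction, object mean intensity) + 3 NOTCH category
percentages + 4 cluster features + 1 cell count. The registry is ordered,
serializable, and drives area aggregation: per-cell features by mean,
area-level statistics from their definitions.

**Profiling.** Area rows are z-scored per feature (ddof = 1;
zero-variance features set to 0 and logged). PCA is the SVD of the
centered matrix with explained-variance ratios s²/Σs² and a deterministic
sign convention (largest-magnitude loading positive). Hierarchical
clustering uses average linkage (UPGMA) on Euclidean row distances; leaf
order follows the "ordered by average value" convention — at each merge
the subtree with the lower mean feature value comes first. "Weight ordered
by average value" was ambiguous between leaf ordering and feature
weighting; it is implemented as leaf ordering.

## Numerical and design choices

- 0-based row-major pixel coordinates; labels 1-based; label images
  relabeled contiguously, ordered row-major by centroid for determinism.
- A single master seed fans out to per-area seeds through a counter-based
  `SeedSequence` derivation (parallel-safe, < 2³¹).
- Stitching trusts nominal stage offsets (step = round(dim·(1−overlap)))
  and blends overlaps by linear feathering; no registration. It is the
  left inverse of the simulator's tiling up to blending rounding.
- Degenerate inputs: empty nuclei mask → "no seeds" error; zero retained
  nuclei → J_n undefined (error); < 4 px objects excluded and logged;
  constant images → zero nuclei / zero ridge / zero spots.
- Problem sizes in the validation suites (384²-px scenes with ~55 cells,
  40-area default experiment at 576² px / 120 cells) were chosen as the
  smallest sizes at which per-area statistics are stable (≥ ~30 retained
  cells per area).

## Known limitations

- The ridge filter is a generic line enhancer standing in for the
  instrument vendor's proprietary edge-texture operator; J_n values are
  comparable within this pipeline, not across software.
- STAR definitions are this package's own bounded, disk-normalized
  instantiation of the feature family; the vendor's exact formulas are
  unpublished.
- Junction-object double counting across shared borders inflates J_n by a
  roughly constant factor; comparative conclusions are unaffected.
- Segmentation assumes confluence; sparse cultures need the optional
  foreground threshold and are untested here.
- The classifier decides spot compartments by center membership; spots
  straddling the nuclear envelope resolve to whichever side the peak
  falls on.
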