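# Methods

## Coordinate and angle conventions

Pixel coordinates are 0-based `(x, y) = (column, row)`, pixel-center
referenced; physical coordinates are in micrometres. All angles use one
convention everywhere: `angle = atan2(−Δrow, Δcol)` mapped onto [0°, 360°),
so 0° points toward increasing column ("east") and 90° points up as the
image is displayed. This fixes the ambiguity in "angle with respect to a
horizontal axis, transformed to positive angles" once, for the simulator,
the measurements and the statistics alike.

## Synthetic epithelial sheet

The generator produces multichannel fields (default 50 µm × 50 µm at
0.1 µm/px) of a multiciliated epithelium with fully known ground truth.

**Geometry.** Cell outlines are the Voronoi tessellation of uniformly
scattered seeds after two Lloyd relaxation iterations — convex-ish,
moderately regular polygons resembling ependymal apical surfaces, without
modelling tissue mechanics. Default 25 cells per field (~100 µm² mean
apical area). Segments of the tessellation clipped by the field border
carry no membrane signal, so border cells are open and excluded downstream,
as they would be in real fields.

**Translational polarity.** Each cell's BB-patch centre is displaced from
the cell centroid by a magnitude drawn around `displacement_um` (15%
relative jitter, clipped at 0) along a direction drawn from a von Mises
distribution (`displacement_coordination_kappa`) about a global tissue
direction. The patch centre is clipped to the region where the whole patch
still fits inside the cell — displacements larger than the cell geometry
allows saturate at the membrane, as real BB patches do. The recorded
ground-truth displacement is the vector from the cell centroid to the
**realised patch centroid** (the mean of the sampled BB positions), i.e.
exactly the quantity the pipeline estimates, recorded before rendering and
noise.

**Basal bodies.** `bb_per_cell` (default 12–22) dots are placed on a
randomly rotated, jittered hexagonal lattice inside a disc
(`bb_patch_radius_um`, default 2.0 µm) intersected with the cell interior.
The lattice pitch guarantees a minimum spacing (`bb_min_spacing_um`,
default 0.65 µm) even after jitter. The spacing default deliberately
exceeds twice the FOP offset (0.3 µm) so each FOP dot is unambiguously
closest to its own γ-tubulin dot; with tighter packing the FOP→γ-tubulin
correspondence becomes genuinely ill-posed for any pairing algorithm (a
neighbouring BB's γ-tubulin dot can sit closer than the dot's own
partner). The patch is recentred on its target so the patch centroid
tracks the intended displacement; the shift is scaled back whenever it
would push a BB outside the cell.

**Rotational polarity.** Each cell draws a mean rotational angle from von
Mises(global direction, `rotation_coordination_kappa` = 5); each BB draws
its angle from von Mises(cell mean, `rotation_kappa`). The FOP dot is
placed `fop_offset_um` behind the γ-tubulin dot so the FOP→γ-tubulin
direction equals the drawn angle.

**Markers.** The membrane-enriched marker (Vangl2/Fzd3 role) renders the
membrane ribbon at `membrane_to_cytoplasm_ratio` (default 4) times the
cytoplasm level; a uniform marker is the non-enriched control. Punctate
membrane dots (p-MLC role) are placed on deduplicated junctional segments
as a Poisson process with linear density `dot_density_per_um`
(default 0.5/µm).

**Optics and noise.** Intensities are on a 16-bit scale: background 100,
spot/membrane peak amplitude 1000, cytoplasm level 250. Spots and ribbons
are convolved with a Gaussian PSF (`psf_sigma_um`, default 0.1 µm lateral;
0.4 µm axial for z-stacks); Poisson shot noise and Gaussian read noise
(default SD 100, hence amplitude-to-noise ≈ 10) are applied last. With a
fixed config and seed the images and tables are byte-identical across
runs.

**z-stacks.** For docking experiments the membrane and diffuse markers sit
at a flat apical surface (`apical_z_um`); each cell is docked with
probability `docked_fraction`. Docked cells place BBs at the apical z with
0.15 µm jitter; scattered cells draw BB depths uniformly from 0.8 µm to
`scatter_depth_um` below the surface. Channels are modulated by a Gaussian
axial profile per plane.

**What the simulator does not emulate:** cell-cell mechanical signalling,
cilia beating, realistic (Airy/astigmatic) PSFs, uneven illumination,
chromatic shifts between channels, or nested animal-level variance (cells
are exchangeable within an arm). Passing recovery tests therefore
demonstrates the correctness and calibration of the measurement chain on
well-posed images, not robustness to every real-microscopy artefact.

## Membrane selection and segmentation

The membrane mask follows the classic desktop recipe: Gaussian blur with
σ = 10 **pixels** (the convention of the source tool; exposed in config),
automatic threshold (Otsu default, IsoData selectable — the recipe names
no method and both are standard "automatic" choices), morphological
skeletonisation to a 1-px midline, then binary dilation of the midline for
15 iterations with a 3×3 structuring element (square default, cross
selectable) to form the "plasma membrane selection". Cells are 4-connected
components of the skeleton complement, with border-touching components and
components outside 10–2000 µm² removed. A cell's membrane band is its
boundary dilated the same number of iterations, intersected with the
global selection.

## Spot detection, pairing, assignment

Spots are multiscale Laplacian-of-Gaussian maxima (scale-normalised,
σ = 1–2 px default) above a threshold that is the larger of
`threshold_rel` × max response and `threshold_snr` × a robust (MAD-based)
noise level of the response. The second term makes blank fields yield
(essentially) no detections, which a purely relative threshold cannot do.
Sub-pixel positions come from a 1D quadratic fit per axis around the
response peak, clamped to ±0.5 px. FOP and γ-tubulin dots are paired by
mutual nearest neighbours under a 0.8 µm cap (≈ twice the FOP offset);
mutual-NN is deterministic, symmetric in input order, and agrees with the
min-cost bipartite assignment at realistic BB densities. Spots on the
membrane/background label take the nearest cell within 1 µm, else remain
unassigned.

## Polarity measurements

- **tPCP**: cell centre = area centroid of the segmented mask (robust to
  boundary pixelation); target = unweighted centroid of the cell's BB
  spots. Zero-magnitude vectors carry angle 0 and a degeneracy flag and are
  excluded from angular summaries, as are vectors below a noise floor
  (default 0.2 µm) when summarising tissue-level coordination.
- **rPCP**: per-BB angle of the FOP→γ-tubulin vector; per-cell circular
  mean and CSD over cells with ≥ `min_bb` (default 5) pairs. CSD is fixed
  to √(−2 ln R̄) (the circular-statistics desktop convention); the
  "angular deviation" √(2(1 − R̄)) is selectable. R̄ = 0 (e.g. antipodal
  pairs) is an explicit error, not a number.
- **Watson U²** is computed tie-aware from cumulative-fraction differences
  over the pooled circular order statistics and tested by label
  permutation, `p = (1 + #{U²_perm ≥ U²_obs}) / (B + 1)` with a fixed
  seed; the permutation route gives an exact achievable p without critical-
  value interpolation (the asymptotic 10/5/1% critical values are exported
  for cross-checks). Whether the genotype comparison should use per-cell
  mean angles or all pooled BB angles is not standardised; per-cell means
  are the default, pooling is a one-liner on the per-cell table.

## Membrane quantification and docking

MFI is the arithmetic mean of the marker over the membrane selection, raw
by default (background subtraction — median of non-selection pixels — is
recorded when enabled). Dot statistics restrict spot detection to a cell's
membrane band; dot intensity is the peak value at the sub-pixel fit.
Docking uses the peak (parabolically refined) of the membrane z-profile
over the cell's membrane band as the apical reference and the per-spot
γ-tubulin z-profile peak as the BB depth; a cell is docked when ≥ 80% of
its BBs lie within δz = 1.0 µm of the reference (≥ 10 BBs required). These
thresholds operationalise a visual criterion and are all exposed in
config and logged. Genotype proportions are compared with two-sided
Fisher's exact tests.

## Statistical decision tree

Two groups: D'Agostino–Pearson on each group (n ≥ 8 per group; below that
the gate is skipped and the rank test used, with a note); if either
normality p < α the comparison is Mann–Whitney (exact for small untied
samples, normal approximation with tie correction otherwise), else the
unpaired two-tailed t-test. Significance at p < 0.05. More than two
groups: Kruskal–Wallis omnibus with Dunn's z comparisons on pooled
mid-ranks (tie-corrected); the adjustment is Bonferroni over tested pairs
by default (no method is standardised for this workflow; selectable and
recorded). Relative expression is 2^ΔCt with ΔCt = Ct(reference) −
Ct(gene); reporter activity is firefly/Renilla normalised to a control
ratio.

## Problem sizes and numerical choices

The benchmark experiments (`pcpquant.experiments`, exercised by the test
suite and `scripts/acceptance.py`) use the study conditions of the
headline analyses: 24 cells/genotype for displacement recovery (2.0 vs
0.3 µm arms), 105 cells/genotype for rotational recovery (κ = 8 vs 0.5),
n = 125/140 for the docking contingency, 500 null + 100 alternative
replicates for Watson U² calibration, and n = 500 angles per κ for CSD
recovery. Bessel ratios I₁/I₀ use exponentially scaled evaluations for
stability at large κ; permutation comparisons use a 10⁻¹² slack against
float-equality artefacts; parabolic sub-pixel/sub-plane refinements are
clamped to half a sample.

## Known limitations

Segmentation assumes a closed junctional network; heavily fragmented
membranes produce merged cells (counted, not repaired). Docking estimates
BB depth from the axial intensity profile at the 2D spot position and will
mislocalise overlapping BBs at different depths. No mixed-effects
modelling of animal-level nesting is provided — cells are pooled within
genotype, matching the target workflow. The Watson U² permutation test
treats cells as exchangeable; clustered sampling would inflate its
nominal size.
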