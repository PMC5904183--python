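# Methods

## Stepwise transcriptome filter

The filter is a deterministic fold-change procedure on probe-level log2
expression (RMA-normalized input is assumed; normalization is outside
this package's scope). For a contrast A → B:

1. **Expression floor.** A probe set is kept iff its mean expression
   over the samples of the contrast being analysed is ≥ `floor`
   (default 5, log2 units). The inequality is strict for removal — a
   probe averaging exactly the floor is retained. The floor is applied
   per contrast, not to the whole file: each analysis decides
   expressed-ness on its own samples, so a probe can enter one contrast
   and not another.
2. **Per-probe log2 fold change.** Replicate means are taken per
   condition first and then differenced (Δ = mean_B − mean_A); for
   balanced designs this equals the mean of paired differences. Values
   are already log2, so Δ > 0.5 is a ≈1.4-fold increase.
3. **Gene calling.** A probe is regulated up iff Δ > `threshold` and
   down iff Δ < −`threshold` (strict, default 0.5). A gene is called up
   (down) iff ≥ `min_probes` (default 3) of its probes are regulated in
   that direction; its effect size is the mean Δ over exactly those
   regulated probes. A gene meeting the `min_probes` rule in *both*
   directions is flagged bidirectional — a candidate splice-variant
   switch — and excluded from the final up/down lists; the fraction of
   regulated genes that are bidirectional is reported. We require
   ≥ `min_probes` in each direction for bidirectionality (the laxer
   "any probes in both directions" variant is not used; at the default
   parameters the choice moves only genes that are already borderline).
4. **Knockdown dependence.** For each up/down gene, the knockdown
   contrast's Δ is averaged over exactly the probe IDs that drove the
   original call; the gene is dependent iff |mean Δ| > `threshold`.
   Dependence is direction-agnostic (an effect can be abolished or
   over-reversed); the stricter reading — the knockdown shift must
   oppose the stiffness direction — is preserved as the
   `concordant_reversal` flag without being enforced. Genes whose
   probes are absent from the knockdown data are reported unassessable,
   never dropped.
5. **Flat (gene-level) filter.** Processed gene-level matrices (e.g. a
   static-vs-shear comparison set) use floor + per-row Δ threshold with
   no min-probe rule. Cross-stimulus overlap is exact, case-sensitive
   set intersection of gene identifiers; an optional two-column mapping
   file translates identifiers between platforms (no mapping is
   bundled, and none is guessed).

There is no variance moderation or hypothesis testing anywhere in the
filter: it is fold-change-only by construction, and its outputs are
pure functions of the input matrix and parameters.

## Hertz indentation model

Units are chosen so that kPa·µm² = nN exactly; no conversion constants
enter the model. The four-sided pyramidal indenter contact force is

    F(δ) = (tan θ / √2) · E/(1 − ν²) · δ²

with θ the **face-to-axis** half-angle by default (25°). Pyramid "edge
angle" is ambiguous between the face-to-axis and edge-to-axis
conventions; both are supported (`angle_convention`, related by
tan θ_edge = √2·tan θ_face) and the choice is reported rather than
guessed. ν defaults to 0.5 (incompressible soft tissue) and is
exposed. A cantilever-tilt correction (multiplying force by
1/cos²(10°), ≈ +3%) is implemented but **off** by default, since the
correction form used by instrument software is not standardized.

**Preprocessing.** The linear pre-contact baseline (offset + slope) is
first estimated on the leading 60% of the approach and subtracted, the
non-contact region is refined by a 5σ force-excursion threshold, and
the baseline is then re-estimated *jointly* with the contact term by a
four-parameter least squares (offset, slope, amplitude, contact
point). The joint step matters: any threshold-chosen baseline window
necessarily swallows the sub-threshold tail of the quadratic contact
force, tilting the baseline by a small but systematic amount —
noiseless self-consistency then plateaus near 1e-4 relative error,
whereas the joint fit recovers simulated moduli to machine precision.
Deflection (force / spring constant) is subtracted from piezo
extension to give the tip-position axis when a spring constant is
available; curves already expressed as force-vs-separation pass
through unchanged.

**Fitting.** E and the contact point are fitted jointly by bounded
least squares (`scipy.optimize.least_squares`), initialized from a
threshold-based contact estimate and the terminal force point. Fits
that fail to converge, return E ≤ 0, or have fewer than
`min_post_contact_points` (default 8) indentation points are flagged
non-converged; they are counted and reported by the aggregation step
but never contribute to region means. `max_indentation_fraction`
optionally restricts the fit to shallow indentation where the
half-space assumption is most defensible. Moduli are *effective*
Young's moduli throughout: the model assumes a homogeneous, elastic,
quasistatically indented half-space, so values are comparative rather
than absolute — exactly the regime in which the regional fold ratio is
the meaningful statistic.

**Calibration.** Deflection sensitivity (nm/V) is the inverse slope of
the photodiode signal vs piezo extension in the contact region of a
rigid-substrate ramp (terminal 30% by default); a linear fit with
R² < 0.98, or a flat curve, is a calibration error.

## Image measurements

- **CTCF** = Σ(intensity in cell) − area(cell) × mean(background
  intensity). Exactly zero on any uniform field, invariant under
  adding a constant to the whole image, and linear in intensity
  scaling; these identities are tested. The background mask is
  user-supplied (or generator truth) — there is no automatic
  background detection.
- **Circularity** = 4π·area/perimeter², an undefined-in-source shape
  descriptor for which we use the standard definition. The perimeter
  is the length of the traced contour polygon (marching squares at the
  0.5 level) smoothed by a circular moving average over 5% of the
  contour length. The smoothing is essential: the raw marching-squares
  staircase inflates perimeters by ≈5% and biases circularity ≈10% low;
  after smoothing, rasterized discs and ellipses at the ~100 px scale
  agree with analytic polygon values to ≤ ~1%. Single-pixel objects
  report 1.0 with a degeneracy flag. `circularity_from_polygon` exposes
  the exact-polygon route (a square gives π/4 identically).
- **Nuclear/cytoplasmic split**: nuclear mean over (nuclear ∩
  coverage); cytoplasmic mean over (coverage − nuclear). The two
  regions partition the coverage mask exactly. An empty cytoplasmic
  remainder is an error, not a silent zero. The source workflow's 3D
  surface masking is reduced here to 2D label-mask extraction on
  projections — a documented simplification.
- **Object counting**: strict threshold, 8-connected labeling,
  `min_area` size filter (an object of min_area − 1 pixels is
  discarded). The audit label image is returned with the count.

## Synthetic data

The generators define the study conditions; they are not tuned per
test.

**Arrays.** Genes carry 4–10 probes; expressed probes draw baselines
from N(8, 1.2²) log2 units and unexpressed probes (15%) from
N(3, 0.8²), so the floor filter has real work. Planted effects are
per-probe N(1.0, 0.15²) log2 shifts (10% of genes up, 10% down) applied
in the soft/OSS arm; replicate noise is additive Gaussian on the log2
scale (default 0.1; recovery checks use 0.05). The default layout is
the emulated experiment: 6+6 control stiff/soft and 2+2 knockdown
replicates. 30% of planted genes are knockdown-dependent — between the
affected fractions observed for the up and down lists in the emulated
study — with the effect fully abolished in the knockdown soft arm by
default (`dependence_attenuation` < 1 gives partial dependence).
Regulated genes are only planted on genes with ≥ 3 expressed probes,
the detection unit of the min-probe rule: planting an effect the rule
cannot see is not part of the emulated design. What the generator does
*not* emulate: probe-level sequence effects, correlated (batch) noise,
heavy-tailed intensity distributions, cross-hybridization. Recovery
results on this generator therefore bound what the filter can do under
clean additive noise, not on real arrays.

**Force curves.** z runs 0 → `z_range` (default 10 µm, inside the
1–14 µm working envelope) with contact at 6.5 µm; pre-contact force is
a linear baseline, post-contact adds the pyramidal Hertz term; the
ramp truncates at the 5 nN setpoint; force noise is Gaussian (default
0.05 nN; ensemble checks use 0.25 nN = 5% of setpoint). For soft-region
ensembles (0.27 kPa) the scan range is 14 µm with contact at 4 µm so
the setpoint is actually reached — mirroring range-to-force adaptation
in practice. `raw_mode` emits photodiode volts with a known spring
constant and sensitivity to exercise the calibration/conversion path.
Not emulated: viscoelastic drag, adhesion on retract, piezo creep.

**Images.** Elliptical cells (semi-axes 40×28 px) with concentric
elliptical nuclei (16×12 px), placed without overlap under a bounded
retry budget; `boundary_roughness` adds low-order Fourier radial
perturbations to both boundaries; intensities are flat per compartment
plus optional Gaussian noise; masks are exact integer label images
(0 = background) and per-object truth (areas, noiseless integrated
densities) is recorded. Not emulated: shading, point-spread blur,
touching cells, out-of-focus light.

All generators are bit-reproducible for a fixed seed.

## Problem sizes

The test suite and `scripts/acceptance.py` use deliberately compact
ensembles chosen to make the checked statistics stable: 150–400 genes
× 10 seeds for recovery and null controls (binomial s.e. < 1.5% at the
0.95 criteria), 50 ramps per region for the fold ratio (relative
s.e. ≈ 0.8%), 600-point ramps, 256-px images. The whole suite runs in
well under a minute on one core.

## Known limitations

- The filter's counts on deposited datasets depend on the probe→gene
  annotation used; annotation retrieval is out of scope and mappings
  are user-supplied.
- Dependence assessment with 2 replicates per arm has no variance
  control by design; the threshold is the only guard against noise.
- Hertz moduli are effective values under elastic-half-space
  assumptions; deep indentation or layered samples violate them.
- Circularity on objects smaller than ~10 px across is
  digitization-limited even with contour smoothing (the degeneracy
  flag marks the extreme case only).
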