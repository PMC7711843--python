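# Methods

`dockquant` quantifies SUV–GUV docking sites in cryo-electron tomograms of
reconstituted SNARE-mediated fusion systems: small unilamellar vesicles
(SUVs) carrying v-SNARE/Syt1 docked onto a giant unilamellar vesicle (GUV)
that mimics the plasma membrane. The package has two halves that validate
each other: a synthetic scene generator/renderer that produces tomogram-like
volumes with known ground truth, and a blind measurement pipeline that
recovers docking-site geometry and protein-density arrangements from such
volumes (or from real maps).

## The morphology model

Each docking site (junction) is described by:

* **membrane separation** — Euclidean distance from the SUV outer leaflet at
  the point of closest approach to the GUV outer leaflet (nm);
* **protein densities** — point landmarks at the centres of discrete
  densities on the SUV membrane, the GUV membrane, or in the inter-membrane
  space;
* **morphology class** on the conventional 0 / 0.5 / 1 scale: *clustered*
  (0) — all densities inside an exclusion cylinder of radius `r_ex` about
  the docking axis; *ring-like* (1) — no density inside the cylinder and at
  least `min_ring_points` (default 3) arranged outside it; *intermediate*
  (0.5) — otherwise. The cylinder rule is the package's operational
  replacement for a visual call; `r_ex` defaults to 10 nm (half the typical
  ring contact-diameter scale) and is reported with results;
* **GUV protrusion flag** — 1 when the target membrane bulges locally
  toward the vesicle by more than `protrusion_min_height` (default 3 nm)
  relative to a baseline plane fitted outside a 25 nm window;
* **contact diameter** — for membranes in direct contact, the diameter of
  the flattened facet.

Class-conditional separations in the default population are uniform over
5–26 nm (clustered), 3–8 nm (intermediate) and 0–7 nm (ring-like), with
2–34 densities per site, SUV diameters normal(80, 25) nm clipped to
20–150 nm, and protrusion probabilities (0.8, 0.3, 0.0) per class. These
defaults give the population its characteristic statistical structure —
a strongly negative class/separation correlation, a positive
protrusion/separation correlation and a negative protrusion/class
correlation.

## Synthetic scenes and rendering

The generator builds scenes in a canonical frame: a flat GUV membrane patch
(the plasma-membrane mimic; spherical/tubulated surfaces are supported
downstream via user-supplied surfaces only), SUVs docked along +z at their
drawn separations, and per-junction density points placed to satisfy the
class definition with a deliberate radial margin (inside points at ≤ 0.7
`r_ex`, outside points ≥ `r_ex` + 1.5 nm) so that sub-voxel measurement
jitter cannot flip the in/out assignment that defines the label.

Density placement encodes two physical constraints. First, points repel
each other at 3.5 nm (dart throwing): protein complexes are solid bodies,
so densities pile up side by side rather than coinciding — this also keeps
the rendered local density within a realistic range. Second, each density
is membrane-anchored: its centre sits 2.8–4.8 nm off one of the leaflet
surfaces (SNAREs and Syt1 are membrane proteins). Radially displaced (ring)
densities are placed only where the inter-membrane gap fits a ~5 nm
complex, which on a large vesicle in direct contact pushes the ring onto
the shoulder outside the contact rim — the steric-exclusion picture that
motivates the three-class scheme in the first place. About 40% of
ring-like junctions are drawn in direct contact, with a flattened facet
whose diameter is normal(16, 8) nm clipped to 4–30 nm; because of the
contact mixture, the uniformity of ring-like separations holds for the
continuous (non-contact) part of the distribution.

Rendering: membranes are two Gaussian leaflet shells 4 nm apart (leaflet
σ 1.5 nm), density points are isotropic Gaussian blobs (σ 2 nm), both at
unit amplitude; a 1 nm Gaussian low-pass stands in for the reconstruction
point-spread; the ±60° missing wedge is applied as a hard Fourier mask and
white Gaussian noise is added last (default σ 0.2 of the membrane
amplitude — the high-contrast regime of Volta-phase-plate data at ~4×
binning, default voxel 2.0 nm ≈ a 5 Å pixel binned 4×). The wedge uses
tilt axis y and beam axis x, so the default flat patch (normal z) stays
outside the missing wedge, as a membrane imaged edge-on does in a real
tomogram; the convention is recorded in the volume metadata.

The renderer is linear before noise (rendering a union of scenes equals
summing their renderings), deterministic given seeds, and warns when the
voxel size exceeds twice the leaflet/blob widths.

## The measurement pipeline

1. **SUV detection** — spherical-shell matched filter over a radius grid
   (10–75 nm, 5 nm steps) on the thresholded, smoothed map. The automatic
   binarisation threshold is half the 98th-percentile intensity: a quantile
   matched to the typical membrane volume fraction, so bright compact
   densities cannot drag it above the membrane level. Candidates must
   exceed 0.5 shell occupancy, have a hollow interior (vesicle lumen), and
   survive non-maximum suppression; the outer-leaflet radius is refined
   from the density-weighted radial centroid of the far hemisphere.
2. **GUV surface** — per-column bilayer-template tracking about the
   dominant plane, median-filtered.
3. **Docking rule** — a site is emitted iff the outer-leaflet gap is
   ≤ 50 nm *and* the density detector finds protein density at the
   junction. Vesicle pairs with radii within 20% of each other are
   excluded (no assignable SUV–GUV polarity).
4. **Oriented extraction** — 150 nm boxes centred on the inter-membrane
   midpoint, rotated (minimal rotation, trilinear resampling) so the
   docking axis lies on +z; the rotation, source bounds and an
   inside-fraction are recorded.
5. **Separation** — from the disk-averaged axial profile using half-maximum
   edge crossings on the two *clean* sides: scanning up from the empty
   region below the GUV and down from the empty vesicle lumen. Template
   correlation fails here in two characteristic ways that drove this
   design: at separations comparable to the bilayer thickness the four
   leaflets form an evenly spaced comb that a single bilayer template pairs
   incorrectly, and bright density clusters out-correlate membranes
   entirely. The edge-based estimator sees neither, because everything
   confounding lies between the membranes, not beyond them. A
   rolling-minimum baseline removes the broad negative bowl that the
   missing wedge casts around bright junctions. Merged leaflet ridges read
   as separation 0.
6. **Densities** — a membrane-only model (tracked GUV heightfield + fitted
   SUV sphere, separate least-squares amplitudes for sheet and shell
   because the wedge attenuates them differently, both wedge-filtered, fit
   restricted to columns away from the junction and inside the source
   volume) is subtracted; landmarks are local maxima of the smoothed
   residual above `background mean + 3 SD`, where the background includes
   membrane-proximal voxels outside the junction so the threshold reflects
   the artifact floor of the subtraction rather than the pure noise floor.
   Maxima closer than `merge_radius` (5 nm) merge into the strongest — an
   unresolved group of proteins yields one landmark, which is the expected
   behaviour of filtered cryo-ET data. Geometric eligibility mirrors the
   generator's physics: landmarks sit off the leaflet midlines, attach to
   a membrane (or sit on the axis), and belong to the membrane apposition
   zone. Two rescue passes recover structures that produce no discrete
   maxima: a slab-averaged central test for density squeezed between close
   membranes, and an azimuthal-sector test (≥ 3 occupied sectors with a
   radial crest required) for continuous rings.
7. **Classification** — the cylinder rule on the landmark set, plus ring
   completeness as the fraction of 12 angular sectors occupied by outside
   points.
8. **Protrusion** — elevation of the axial membrane position above a
   baseline plane fitted on the 25–40 nm annulus.
9. **Contact diameter** — per-column leaflet-gap map from edge crossings
   with per-column amplitude normalisation (a merged contact doubles the
   mid-layer amplitude; the normalisation is capped so the threshold never
   exceeds the single outer leaflets); the facet is the connected plateau
   where the gap stays within 0.5 nm of its central floor.
10. **Statistics** — plain Pearson correlations over (class code,
    separation, protrusion flag, density count), exactly as the quantities
    are coded; two-sided p-values from the t statistic; strength labels
    with left-closed boundaries at 0.1/0.3/0.5; unadjusted p-values
    headline, a Bonferroni column for transparency.
11. **Class averaging** — members aligned by pure translation of the SUV
    base landmark to a common origin (no angular search; azimuthal
    heterogeneity averages out by design), voxelwise mean, density
    landmarks pooled into an overlay cloud; cylindrical radial profiles at
    the inter-membrane level summarise the radial redistribution of
    density between classes.

## Desk-scale validation conditions

The validation suite renders one junction per 104³-voxel scene at 2.2 nm
voxels (a ~229 nm box, large enough for the biggest 150 nm vesicles) and
runs the full blind pipeline on 300 such scenes. Detection recall is ~0.9
at the default noise; separation is recovered with a mean absolute error of
~0.3 voxel and the protrusion flag with ~99% agreement; the pooled
correlation matrix reproduces the expected sign structure (class–separation
strongly negative, protrusion–separation positive, protrusion–class
negative).

## Known limitations

* **Landmark coalescence bounds class recovery.** With 2–34 densities per
  site, blob width ~2 nm and 5 nm merging, dense clusters and
  closely-spaced rings merge into smooth structures whose discrete maxima
  undercount the truth; densities squeezed into gaps of 3–5 nm overlap
  both membranes and can vanish entirely. Classification survives most of
  this (it needs only the in/out pattern, not counts), but intermediate
  junctions — which need *both* an inside and an outside detection — are
  the hardest, and end-to-end class agreement plateaus near 75–80% at
  these conditions. Rendering at 1.8 nm voxels does not help, confirming
  the limit is the physical blob overlap, not sampling. Landmark-level
  classification (points given, no rendering) exceeds 95%.
* Contact facets smaller than ~2√R nm are overestimated: within
  measurement precision the spherical shoulder of an R-nm vesicle is
  indistinguishable from a small flat patch.
* Density counts are systematically below the generated counts whenever
  spacing is below the merge radius — by design, mirroring the resolution
  caveat of filtered tomograms; count *correlations* remain informative.
* The wedge-artifact handling (model subtraction, satellite suppression,
  streak-aware filters) assumes the subtomogram axes are aligned with the
  lab frame; oblique-axis sites fall back to geometry-only filtering.
* The generator places densities membrane-anchored and sterically; it does
  not emulate continuous filamentous tethers, partial occupancy of the
  wedge by gold fiducials, CTF/phase-plate contrast, or dose effects, so
  passing tests demonstrate geometric and statistical fidelity of the
  method, not photorealism.
* Protrusion detection assumes the bump is centred on the docking axis
  (true of the generator; approximately true of real junctions).

## Numerical choices

* Canonical units: nm everywhere in memory; MRC headers in Å.
* Coordinates 0-based with voxel centres on integer lattice points.
* Trilinear interpolation for all resampling; rotation matrices
  orthonormal to 1e-9 and recorded in metadata.
* Half-maximum crossing offsets are computed from the leaflet model
  (σ_eff = 1.8 nm, thickness 4 nm), not fitted per site.
* Sub-voxel positions by parabolic refinement; ties in azimuthal binning
  broken upward with a 1e-9 epsilon.
* Degenerate inputs (blank volumes, empty tables, zero-variance columns,
  zero density points) return empty results or explicit NaN/errors, never
  silently fabricated values.
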