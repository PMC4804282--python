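# Methods

This note documents the models, conventions and numerical choices behind
`cortmorph`, and what the phantom-based validation does and does not
demonstrate about real data.

## Coordinate and connectivity conventions

Volumes are arrays indexed `(z, y, x)` with z the bone axis; physical
coordinates are `(x, y, z)` in micrometres, `position = index *
voxel_size_um` with the origin at voxel `(0, 0, 0)`.  Voxels are
isotropic (default 10.5 um).  Bone components are 26-connected,
background components 6-connected — the standard complementary pair that
prevents both sets from percolating through each other.  A rigid
transform maps reference coordinates into moving coordinates
(`resample(moving, T)(x) = moving(T(x))`, the ITK convention), is
parameterised by extrinsic x-y-z Euler angles (degrees), a translation
(um) and a rotation centre (um), and is serialised as plain text.

## Registration

1. **Bone isolation.** A provisional threshold plus largest-26-component
   selection suppresses the fibula and loose debris; grey values outside
   the dilated main component are replaced by the background median, so
   only the tibia drives the alignment.
2. **Pre-alignment** superimposes the intensity-weighted centres of
   gravity (weights: grey above the volume median, which sits in the
   background).  Principal axes of the second-moment tensor are aligned
   only when the eigenvalues are well separated (relative gap >= 10%);
   for a near-tubular bone the two transverse moments are close, so the
   pre-alignment typically contributes the translation and leaves the
   rotation to the metric refinement.  The sign ambiguity of eigenvectors
   is resolved by choosing, among the four proper sign combinations, the
   rotation of smallest angle.
3. **NMI refinement.** The criterion is the Studholme normalised mutual
   information, `(H(A)+H(B))/H(AB)` on a 64-bin joint histogram.  Three
   numerical choices matter, each visible as a failure mode when absent:
   - both volumes are pre-smoothed (sigma 1 voxel) for the metric only:
     unfiltered, scan-independent noise creates the classic interpolation
     ripple (spurious NMI extrema at integer voxel offsets) that traps
     the optimiser at ~1 voxel error;
   - the joint histogram is evaluated on a dilated bone mask of the
     reference; over the full, background-dominated grid the NMI peak is
     an order of magnitude flatter;
   - six slices at each axial end are excluded from the metric: an
     axially shifted scan is truncated at the end faces, and including
     the truncated slabs biases the axial estimate toward zero (observed
     as a pure-z error proportional to the applied z-shift).
   Optimisation is Powell over the six rigid parameters (degrees /
   voxels) on a 3-level pyramid (decimation 4/2/1 after matched Gaussian
   smoothing), with evaluation budgets of 600/400/400 and the metric
   resampled only within the mask bounding box.  The refined transform is
   guaranteed no worse (in full-resolution NMI) than its initialisation.
4. **Resampling** of the registered scan onto the reference grid uses a
   Lanczos windowed-sinc kernel (a = 3, via SimpleITK); out-of-domain
   voxels are filled with the moving volume's median (background) grey.
5. **ROI.** One axial slab of `round(fraction x tibia_length / voxel)`
   slices (default 5% of tibia length) is defined on the reference —
   centred at the axial midpoint unless configured otherwise — and the
   identical slice range is applied to every time point.

Recovery on phantoms (misalignments up to ~4 voxels and 3 degrees, noise
SD 20/1000): translation within 0.25 voxel and rotation within 0.25
degree.  In-plane rotation is only identifiable because the phantom
cross-section is non-circular (10% ellipticity, matching the distinctly
non-circular tibial mid-shaft); on a perfectly circular tube the rotation
about the bone axis is unobservable for any intensity-based method.

## Segmentation

Grey volumes are Gaussian-filtered (default sigma 0.8 voxel, the
conventional preprocessing for this instrument family) and thresholded
at 423 on the 0-1000 grey scale.  Debris in the medullary canal is
removed by keeping the largest 26-connected component; a spicule touching
the endocortical wall is, by that rule, cortex.

The endocortical/periosteal split closes the cortical shell (ball,
default radius 2 voxels, sized to seal vessel channels), flood-fills the
enclosed canal to obtain the solid bone+canal body, and contracts the
solid body inward from its outer boundary by `shrink_thickness_um` using
a Euclidean distance-transform threshold (metrically accurate and
rotation invariant, unlike iterated erosion).  Cortex inside the
contracted body is endocortical; the stripped outer band is periosteal;
the two regions partition the cortex exactly.  The shrink distance is by
convention three times the periosteal surface movement expected over the
observation window (default expected movement 40 um, i.e. shrink 120 um,
tunable; phantom studies use 42 um = 4 voxels for their 84 um wall).
The exterior background is identified by contact with the four *lateral*
volume faces only: the diaphyseal ROI is an open-ended tube, so the canal
legitimately reaches the two z end faces and must not be flooded from
there.  If the closing fails to seal the shell the split aborts with a
diagnostic rather than silently mislabelling.

Surfaces are region/background interfaces.  One voxel is peeled from all
surfaces to suppress partial-volume overestimation; surface voxels of the
peeled cortex then carry a compensating 1.5-voxel effective thickness in
area bookkeeping.  All inter-time-point comparisons operate on the
peeled masks, so event bands sit directly against the surfaces used by
the morphometry.

## Remodeling classification

Between registered, segmented, peeled masks: quiescent = bone at both
times, formed = bone only later, resorbed = bone only earlier —
exact set differences, so `|bone(t1)| = |bone(t0)| + |formed| -
|resorbed|` holds identically.  Event voxels inherit the region of the
nearest day-0 labelled voxel (Euclidean distance; ties resolved to
endocortical), which is deterministic and total.  Formed/resorbed voxels
group into 26-connected packages.

The pipeline's standard configuration removes packages smaller than 3
voxels before quantification.  Rationale: under the characterised noise
(SD 20 after 0.8-voxel smoothing) isolated surface voxels flip state with
probability ~1% per surface column, producing 1-2-voxel speckle
"events"; unfiltered they dominate MS/BS through the 26-neighbour surface
marking, while scripted (and biological) packages are two to three orders
of magnitude larger.  The `label_packages` operation itself defaults to
keeping everything (`min_size=1`); the filter is a pipeline-level choice,
exposed in `RunConfig`.

## Morphometry

- **Ct.BV** = bone voxel count x voxel volume; **Ct.Ar** = Ct.BV /
  (number of slices x slice thickness); **Ct.Th** = mean local thickness
  over bone voxels, where local thickness is the largest-inscribed-sphere
  diameter computed by sphere-fitting on the Euclidean distance
  transform.  Packages additionally evaluate the transform on a
  2x-refined grid, which resolves the half-voxel offset between voxel
  centres and the true boundary (a single voxel then measures 1 voxel, a
  two-voxel slab 2 voxels).  Radii are quantised to at most 48 classes to
  bound the number of distance-transform passes; each package keeps a
  one-voxel background apron so the transform does not treat crop faces
  as bone continuation.
- **MV/BV, EV/BV** use one shared denominator — the whole day-0 cortical
  bone volume — so the two surfaces are directly comparable.
- **MS/BS, ES/BS**: a day-0 surface voxel is mineralising (eroding) if
  any of its 26 neighbours is a formed (resorbed) voxel of that region;
  with all surface voxels carrying the same 1.5-voxel area weight the
  weights cancel in the ratio.  BS is the day-0 surface.
- **MTh, ED** are volume-weighted means of per-package mean local
  thickness; empty package sets report 0 with an explicit flag.
- **Rates** are definitional divisions by the interval, so
  `MAR x interval = MTh` and `BFR x interval = MV/BV` to machine
  precision.
- Surface-sensitive parameters (MS/BS, ES/BS, MTh, ED) are computed only
  for the final (longest) interval by default, where the accumulated
  signal is largest relative to the resolution; configurable.
- All intervals are anchored at day 0, never chained scan-to-scan, and
  the net-change curve per surface is `MV/BV - EV/BV` at each scan day.

## The phantom and what the validation shows

The phantom is a tubular shell (outer/inner radii 210/126 um), bowed
(31.5 um at mid-length) and 10% elliptical, with radially drilled vessel
channels (8 um — real mouse cortical canals are below ~15 um diameter),
loose spicules in the canal, and stripe-shaped events defined in
cylindrical coordinates around the bowed centreline so they appear as
axis-parallel stripes.  Events are applied instantaneously at interval
boundaries; truth masks live on the reference grid, pre-blur and
pre-noise; the per-time-point misalignment affects only the rendered
volumes, so registration error is measurable against the stored
corrective transforms.

Acquisition defaults: PSF sigma 5.25 um (reading the instrument class's
quoted ~12 um resolution as a PSF full width at half maximum), additive
Gaussian noise SD 20 on the 0-1000 grey scale, bone/background grey
700/150 (placing the 423 threshold essentially at the blurred-edge
midpoint, as a calibrated density threshold behaves).  Both the PSF and
the noise magnitude are free parameters of the emulation, not measured
properties of any particular scanner.

Ground-truth morphometry applies the *same definitions* as the
measurement pipeline (peel, day-0 normalisation, 26-neighbour marking,
inscribed-sphere thickness) to the exact masks, so recovery error
isolates what acquisition corruption plus analysis does to a known
signal.  On corruption-free renderings the pipeline reproduces the truth
exactly (to the voxel); with blur and noise the remaining bias is a
genuine partial-volume effect: the blur tail of a formation patch lifts
the measured surface in an apron one to two voxels wide around the
footprint, overestimating formed volume by roughly 5% of the event volume
(proportional to footprint perimeter).  Consequently the absolute MV/BV
recovery band of +/-0.2 percentage points is comfortably met for
event sets up to ~3% MV/BV and approached at ~4% and beyond.  Scripted
stripe footprints span 35-55 degrees by 150-300 um: wide enough (>= ~7
voxel arc) to be resolvable at the stated PSF — narrower stripes are
largely removed by the surface peel — and sized so per-region MV/BV
stays in the sub-3% regime the in-vivo protocol reports for control and
moderately loaded limbs.

What the phantom does **not** emulate: beam hardening and ring
artefacts, motion within one scan, spatially varying mineral density
(greys are two-valued), gradual mineralisation ramps, woven bone, or
trabecular structure beyond loose spicules.  Passing recovery tests
therefore demonstrates the correctness of the analysis chain under
controlled corruption, not the accuracy of the method on any particular
scanner's output.

## Strain summaries

`percent_difference` is `100 x (peri - endo) / endo` on the per-surface
mean absolute-maximum principal strains, reported rounded
half-away-from-zero to integer percent with the raw value retained; it is
invariant under common rescaling of both means and antisymmetric only up
to the denominator convention.  `summarize_strains` consumes a two-column
table (strain in microstrain, surface tag), computes per-surface mean,
SD (n-1) and maximum, the fraction of periosteal points strictly above
the endocortical maximum (invariant under any strictly monotone
transform of all samples), and shared-bin relative-frequency histograms.
Finite-element model construction is out of scope; printed per-surface
summary statistics are valid inputs.

## Problem sizes

Phantom studies run on 96 x 96 x 64 grids at 10.5 um voxels (a ~1 x 1 x
0.67 mm section) with 10 phantoms per study — sizes chosen so the full
validation battery completes in minutes on one CPU while every length
scale of the method (wall ~8 voxels, events 1-3 voxels, PSF ~0.5 voxel)
matches the real protocol.

## Known limitations

- MV/BV recovery carries the +~5%-relative formation apron bias
  discussed above; EV/BV is correspondingly biased slightly low at
  cavity edges.
- Sub-voxel events (< 1 voxel apposition) are below the detection
  floor by construction of the binary classification.
- The medullary debris rule is purely connectivity-based; mineralised
  tissue bridging to the cortex is kept as cortex.
- In-plane rotation recovery degrades as the cross-section approaches
  circularity (an identifiability limit, not an implementation one).
- The NMI refinement assumes the pre-alignment lands within its capture
  range (a few voxels / degrees), which centre-of-gravity matching
  provides for this geometry.
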