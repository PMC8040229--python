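# Methods

`toothct` automates the morphological description of single-rooted teeth
from reconstructed micro-CT slice stacks.  This note documents the model
behind each stage, the tunable parameters, the synthetic phantom used for
validation, and the numerical choices made where the design was open.

## Input model

A tooth arrives as a directory of axial 8-bit gray-scale slices (PNG or
TIFF) with an isometric voxel size, nominally 10 µm, the axial index
running from crown to apex.  Gray values reflect X-ray attenuation:
enamel ≫ dentin ≫ canal lumen ≈ air.  An optional scanner log
(INI-style `Key=Value` lines) supplies acquisition metadata; keys are
matched case-insensitively against a maintained synonym list
(`Source Voltage (kV)`, `Image Pixel Size (um)`, …) because scanner
vendors do not share a schema.  16-bit input is linearly rescaled to 8-bit
with a warning: every pixel- and gray-value threshold below assumes the
8-bit dialect.  Volumes persist as zarr stores, chunked one axial slice
per chunk by default to match the per-slice access pattern of canal
extraction.

## Cropping

Tooth and background are split by one fixed gray threshold applied to all
datasets.  The threshold (default 25 of 255) is data dependent — it must
sit above air-plus-noise and below dentin — and is therefore exposed in
the configuration; the default suits 8-bit reconstructions with the noise
levels emulated by the phantom.  26-connected components below 1000 voxels
are discarded as speckle (strict: a 999-voxel component goes, 1000 stays),
and the bounding box of the largest surviving component defines the crop.
Ties between equal-size components break toward the smaller axial start
for determinism.  Metal-filling streaks that reach the volume border are
not special-cased; the box may then equal the full volume, which costs
disk space but nothing else.

## Canal extraction

Per axial slice: Otsu's threshold separates tooth from background; the
slice is inverted to select everything that is not tooth; every inverted
region 8-connected to the image border (the surrounding air) is deleted;
remaining components with area < 64 px are removed; enclosed background
regions (4-connected) with area < 100 px are filled.  Both area rules are
strict at the boundary.  Otsu runs independently on every slice, so the
threshold varies along the axis — intentional, as crown and root slices
have very different histograms.  Constant slices (pure air after cropping)
yield empty canal masks rather than errors.  Hole filling acts on the
canal mask, not the tooth mask, and is implemented directly on labeled
background components because the strict "smaller than 100 px" rule must
keep a hole of exactly 100 px open.

At the apex, a slice where the lumen connects in-plane to outside air is
removed by border clearing; the canal volume therefore ends at its lowest
*closed* cross-section, and all apical measurements anchor there.

## Axial landmarks and configuration code

The mean gray value per axial slice forms a brightness profile.  It is
smoothed with LOWESS (window fraction 0.05 of the axis length — wide
enough to suppress slice noise, narrow enough not to blur the edge at the
~2700-slice scale; configurable).  LOWESS runs without robustness
iterations: the iterative reweighting would treat the slices beyond the
enamel–dentin step as outliers and displace the derivative peak by
several slices.  The enamel–dentin border (EDB) is the index of maximal
absolute first difference of the smoothed profile; the absolute value
also covers upside-down stacks, and ties break toward the smaller index.
The smoothed curve is clipped to the raw range so local linear fits
cannot overshoot at the profile ends.

For teeth whose metal fillings dominate the profile (the gradient then
sits at the bottom of the filling, not the EDB) the border can be set
manually (`edb_slice`, given in original-stack indices); the report
records whether the border was automatic or manual.

Four classification slices are planned: the EDB `e`, the bottom `b`
(largest axial index with tooth foreground, taken from the despeckled
tooth mask), and two slices equidistant between, at
`e + round((b−e)/3)` and `e + round(2(b−e)/3)` with half-up rounding.
The planned gaps differ by at most one slice.  Around each slice a
minimum-gray projection over a 400 µm window (total width, ±200 µm,
clipped at the volume ends) is rendered: minima make fine accessory
canals visible at the cost of noise, and these windows are a visual aid
only.  Canal components (8-connected) are counted at the exact planned
slice.  The code "a-b-c/d" takes its three counts from the EDB and the
two intermediate slices; the fourth digit is the number of physiological
foramina from the apical analysis.  Which of the four extracted slices
feed the three digits is a convention of this package (the bottom slice
count is reported separately in the per-tooth JSON).  The automatic code
is advisory — it aids, not replaces, a trained observer, particularly for
configurations with lateral canals or apical deltas that component
counting cannot resolve.

## Apical foramen geometry

The apical 3.5 mm of the tooth (350 slices at 10 µm, clipped for shorter
volumes) is extracted, ending at the bottom landmark.  The exact 3-D
Euclidean distance transform labels every canal voxel with its distance
to the canal wall in µm, so twice the maximal distance across a
cross-section is the largest inscribed-sphere diameter.  For visual
reading, reconstruction and distance map are merged: non-canal voxels
keep their gray value (compressed below 200), canal voxels show
`200 + r` with `r` the inscribed-sphere radius in whole voxels, and the
volume is written as sagittal slices so the radius can be read off in any
viewer.

Foramina are detected per apical *opening*: for each 26-connected canal
component whose lowest slice lies in the window, every 8-connected
in-plane region of that lowest cross-section is one opening (a bifurcated
canal is a single 3-D component but exits through two foramina).  The
opening diameter is twice the maximal **in-plane** (2-D) distance
transform of the region.  The in-plane convention is deliberate: at a
closed canal end the 3-D transform is dominated by the axial end cap
(about one voxel) and would misclassify every foramen; the in-plane value
measures the opening itself.  Openings with diameter ≥ 0.20 mm
(inclusive) are physiological (main) foramina, smaller ones accessory.
The counts depend only on the binary canal mask, never on reconstruction
gray values, and physiological + accessory always equals the number of
openings.  The distance between physiological and anatomical foramina is
not computed; the overlay supports reading it manually.

## Synthetic phantom

The phantom emulates what the pipeline actually consumes: a surface of
revolution with a dome-shaped crown (cross-section area growing linearly
to the full radius), a cylindrical root, a tapered apex, an enamel cap
above the EDB slice, canal tubes of specified radii with branch/merge
topology, and additive Gaussian noise truncated to the 8-bit range
(NumPy PCG64, fixed seed, bit-reproducible).  Gray levels default to
air 5, canal 10, dentin 120, enamel 220 — the attenuation ordering with
headroom for noise.  Ground truth (canal mask, EDB slice, configuration
code, per-exit foramen diameters) is derived from the tube geometry,
never by segmenting the rendered image, so tests against it are not
circular.

Scale: real scans run ~2700 slices at 10 µm.  The default suite keeps
the voxel size, the gray-level ordering and every pixel/voxel threshold,
but uses 420 × 141 × 141 volumes (a 4.1 mm tooth) so the full 12-phantom
suite — six configuration codes {1-1-1/1, 1-2-1/1, 1-2-2/2, 2-2-2/2,
2-1-1/1, 1-1-2/2}, each at noise σ ∈ {0, 10} — generates and processes
in about fifteen seconds on one CPU.  Branch and merge transitions sit at
least 30 slices from every planned counting slice, so the recovered code
is stable against the EDB tolerance.  Canal tubes run through to the
tooth's bottom slice, modeling the open apical foramen.  Two rasterization
choices make nominal and measured diameters coincide exactly: disks use a
strict inequality (center distance < radius) and the in-plane dimensions
are odd so tube centers sit on the voxel lattice; the maximal distance
transform of a cross-section then equals the integer tube radius.

What the phantom does **not** emulate: beam hardening, ring artifacts,
metal fillings, cone-beam geometry, partial-volume blur at the
enamel–dentin interface, curved or oval canals, apical deltas.  Passing
the suite therefore demonstrates the correctness of the processing chain
under the stated noise model, not segmentation performance on clinical
scans; on real data the fixed crop threshold and the LOWESS fraction are
the parameters most likely to need adjustment.

## Batch semantics

`batch` discovers tooth directories (any subdirectory containing slice
images, excluding its own output tree), processes each through every
stage, and records per-tooth failures as rows instead of raising.  Each
report JSON carries a hash of the configuration; a directory whose report
matches the current hash is served from cache, so re-running after new
scans arrive computes only the new teeth, and any configuration change
invalidates every cache.  Whole-tooth length is reported as
`(bottom − first tooth slice + 1) × voxel size`, from the cropped
volume's own extent.

## Numerical notes and limitations

- All connectivity conventions are pinned: 26 (3-D) and 8 (2-D) for
  objects, 4 for holes; tests check them against explicit flood fills.
- `plan_slices` uses half-up rounding; Python's banker's rounding would
  make the plan depend on parity.
- On noisy data the bottom landmark may sit a slice or two below the last
  true tooth slice when noise voxels touch the root; all apical anchors
  are component-local, so foramen measurements are unaffected.
- A constant brightness profile (no enamel, e.g. a root fragment) has no
  detectable EDB; the pipeline reports the tooth as failed at the
  classification stage unless a manual border is given.
- The foramen diameter is an in-plane measure at the exit slice; for
  canals exiting very obliquely it overestimates the true (oblique)
  opening diameter.
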