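# toothct

Automated segmentation and description of the internal morphology of
single-rooted teeth from micro-CT slice stacks.

Endodontic treatment planning needs two things from an extracted-tooth
scan: the **root canal configuration** — how many canals run at each level
of the root and how many main openings they exit through — and the
**geometry of the apical foramen**, the canal's opening at the root tip.
Modern desktop micro-CT scanners image whole cohorts of teeth in batches,
producing thousands of reconstructed slices per tooth; describing them by
scrolling through stacks by hand does not scale and is operator dependent.
`toothct` is a batch pipeline that derives both descriptions automatically
and reproducibly from the reconstructed axial slices, for researchers in
dental morphology and endodontics.

## Method

For each tooth directory the pipeline runs:

1. **Read / store** — stack the axial 8-bit slices (lexicographic file
   order), parse the scanner log, persist as a chunked compressed zarr
   store.
2. **Crop** — segment tooth vs background with one fixed gray threshold,
   drop 3-D speckles < 1000 voxels, crop to the bounding box of the
   largest object.
3. **Overview** — middle slices and maximum-intensity projections per
   anatomical plane, plus a cohort montage.
4. **Canal extraction** — per slice: Otsu threshold → invert → clear
   border-connected regions (air) → remove components < 64 px → fill
   enclosed holes < 100 px.  What remains is the canal lumen, stored as a
   binarized volume.
5. **Classification** — the mean gray value per slice forms a brightness
   profile along the long axis; after LOWESS smoothing, the maximal
   |first difference| marks the enamel–dentin border (EDB).  Four slices —
   EDB, bottom, and two equidistant between — are extracted with 400 µm
   minimum-gray windows; canal components are counted per slice and the
   4-digit configuration code `a-b-c/d` is assembled (counts at three
   levels / number of main foramina).
6. **Foramen geometry** — the apical 3.5 mm is extracted; the exact
   Euclidean distance transform (EDT) labels every canal voxel with its
   distance to the canal wall, so 2 × max EDT across a cross-section is
   the inscribed-sphere diameter.  Each apical opening is measured at its
   exit cross-section and classified by the 0.20 mm rule: diameter
   ≥ 0.20 mm → physiological (main) foramen, else accessory.  An
   EDT/reconstruction overlay is written as sagittal slices for visual
   reading.

A synthetic **tooth phantom** generator (bright enamel cap, dentin body,
canal tubes with branch/merge topology, additive noise) provides exact
analytic ground truth, so every stage is testable without scan data.

## Worked example

Generate a noisy phantom with a known 1-2-2/2 configuration and process
it:

```
$ toothct phantom --code 1-2-2/2 --noise 10 --seed 7 --out teeth/p1
wrote phantom 1-2-2/2 to teeth/p1

$ toothct process teeth/p1 --out analysis/p1
```

The printed report (excerpt):

```json
{
  "tooth_id": "p1",
  "status": "complete",
  "edb_index": 129,
  "edb_source": "automatic",
  "bottom_index": 418,
  "slice_indices": [129, 225, 322, 418],
  "canal_counts": [1, 2, 2],
  "code": "1-2-2/2",
  "length_mm": 4.16,
  "foramina": [
    {"exit_slice": 415, "exit_centroid": [57.0, 43.0],
     "diameter_um": 240.0, "kind": "physiological"},
    {"exit_slice": 415, "exit_centroid": [57.0, 71.0],
     "diameter_um": 200.0, "kind": "physiological"}
  ]
}
```

Reading it: the enamel–dentin border was found automatically at slice 129
and the bottom of the tooth at slice 418, so the four classification
slices are 129/225/322/418.  The canal count per level is 1, 2, 2 and two
apical openings of 240 µm and 200 µm were measured — both at or above the
0.20 mm physiological threshold — giving the code **1-2-2/2**, which
matches the phantom's ground truth (the generated lumen was a single
canal bifurcating below the EDB into two branches of 120 µm and 100 µm
radius).  The tooth length 4.16 mm is the phantom's crown-to-apex extent.
Alongside the JSON, the output directory holds the cropped and binarized
zarr stores, overview PNGs, the per-tooth report figure (profile with
landmarks + the four minimum-gray windows) and the sagittal EDT overlay
stack.

For a whole cohort: `toothct batch ROOT --config cfg.toml` — one report
row per tooth directory, cached so that re-runs only compute newly added
scans.

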