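# iovkit — interobserver variability of radiotherapy delineations

When several radiation oncologists contour the same target volumes and
organs at risk (OARs) on the same planning CT, the resulting structures can
differ substantially — in a head-and-neck case, planning target volumes can
vary almost two-fold between observers.  `iovkit` quantifies that
interobserver variability (IOV) from multi-observer contour sets:

* **Geometry** — planar contours (DICOM-RT STRUCT or a portable JSON
  dialect) or NIfTI binary masks are rasterized onto a common voxel lattice
  (centre-in-polygon, even–odd rule; a contoured slice fills the full slice
  thickness).
* **Volume dispersion** — per structure: observer count N, mean, sample SD,
  range, and the coefficient of variation CoV = SD/mean.
* **Spatial agreement** — pairwise Dice similarity coefficient
  DSC = 2|A∩B|/(|A|+|B|), Jaccard index, mean absolute surface distance
  (MASD, mm), and the pairwise conformity index

      CIpairs = Σ_{i<j} |Vᵢ ∩ Vⱼ| / Σ_{i<j} |Vᵢ ∪ Vⱼ|,

  which, unlike an average DSC, is robust to the number of observers.
* **Nodal-level coverage** — a lymph-node level counts as included in an
  observer's PTV when the overlap exceeds 70 % of the level's volume
  (strictly greater; the threshold is configurable).
* **Landmark analysis** — cranial/caudal border positions of a structure as
  signed offsets to named landmarks (e.g. the sphenoid-sinus floor and the
  sternoclavicular joints), axial width on a reference slice, and the
  cohort spread of each.
* **Synthetic cohorts** — a generator that emulates a multi-observer study
  with known ground truth: per-observer systematic margins, smooth boundary
  noise, caudal truncation of the elective target volume, and structure
  omissions.  It stands in for clinical structure sets, which are rarely
  shareable.

Observers who omitted a structure are excluded from that structure's
statistics — never imputed as empty.

## Worked example

The analysis drivers run the whole pipeline on the built-in synthetic
ten-observer cohort (1×1×4 mm grid, 512×512×80 voxels, 18 structures):

```sh
python analysis/01_simulate_cohort.py    # writes scratch/*.json
python analysis/02_volume_agreement.py   # results/volume_agreement.csv
python analysis/03_level_inclusion.py    # results/level_inclusion.csv
python analysis/04_landmark_borders.py   # results/landmark_borders.csv
```

`02_volume_agreement.py` prints one row per structure, most variable first
(volumes in cm³, MASD in mm; excerpt):

```
structure   n  mean_cc  sd_cc   cov  min_cc  max_cc  ci_pairs  dsc_mean  masd_mean_mm
eye lens L  10   0.868  0.454  0.52   0.288    1.54      0.39      0.55          1.52
pituitary    7   1.570  0.531  0.34   0.844    2.40      0.50      0.67          0.88
...
PTV1        10 803.000 67.500  0.08 706.000  878.00      0.82      0.90          3.85
PTV2        10 440.000 26.500  0.06 395.000  476.00      0.90      0.95          1.13
```

Small organs (eye lenses, pituitary, inner ears) show the highest relative
volume dispersion even though every observer applies the same margin habits
— the same pattern clinical contouring studies report.  The pituitary row
has N = 7 because three simulated observers omitted it.
`04_landmark_borders.py` reports a caudal PTV1 border spread of 20.0 mm
(the generator's truncation offsets recovered exactly), a mean caudal
border 10.4 mm above the sternoclavicular joint, and a mean supraclavicular
width of 16.25 cm; `03_level_inclusion.py` shows bilateral levels II/III
covered by all ten observers while the medial supraclavicular levels IVb
left/right pass the 70 % rule for only 3 and 4 observers.

The same reports are available from the CLI on any cohort file:

```sh
iov simulate --seed 42 --out simulated/
iov metrics   --config config.yaml
iov levels    --config config.yaml --threshold 0.70
iov landmarks --config config.yaml
```

where `config.yaml` names the cohort/levels/landmarks files, the PTV
structure and the output directory.

## Layout

```
src/iovkit/       grid, contours (I/O + rasterization), agreement metrics,
                  level inclusion, landmark analysis, synthetic cohorts,
                  report tables, CLI
analysis/         numbered drivers reproducing the full analysis
tests/            pytest suite (unit, property and acceptance tests)
docs/methods.md   models, conventions and design choices
```
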