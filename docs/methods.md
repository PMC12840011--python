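# Methods

## Geometry and rasterization

All geometry lives in physical millimetres in the DICOM patient convention
(x to the patient's left, y posterior, z cranial).  An `ImageGrid` is a
regular lattice defined by the centre of voxel (0,0,0), per-axis spacing
and voxel counts; its extent is half-open per axis.  The default grid is
1×1 mm in plane with 4 mm slices — typical of a head-and-neck planning CT
without dedicated thin-slice reconstruction.

Contours are closed planar polygons tagged as outer boundaries or holes.  A
voxel is set iff its **centre** lies inside the even–odd combination of all
rings on its slice (outer rings minus holes), matching common
treatment-planning-system behaviour and admitting a clean brute-force
oracle (ray casting over every voxel centre, which the test suite runs
independently of the shapely-based implementation).  Points exactly on a
polygon edge have no defined owner; test fixtures keep edges off voxel
centres.  A contour is assigned to the slice whose centre is nearest
(|z − z_k| ≤ dz/2, exact ties to the lower slice), and a contoured slice
occupies the full slice thickness dz — the slab model.  Volumes are
therefore (set-voxel count)·dx·dy·dz/1000 cm³.  Interpolating between
slices would be the main alternative; the slab model was chosen because it
is what slice-wise planning systems report and because it makes
z-quantization effects (±dz/2 per border) explicit rather than hidden.
No resampling between heterogeneous grids is attempted; mismatched grids
are an error.

## Agreement statistics

* **Volume dispersion**: mean, sample SD (n−1 denominator; defined 0 for a
  single observer) and CoV = SD/mean.  The sample SD is the
  clinical-reporting default; with ≤ 10 observers the population/sample
  choice shifts CoV by ~5 %, so reported CoV values cannot discriminate
  between the two — the convention is fixed here and documented.
* **DSC / Jaccard** on voxel counts; both undefined when both masks are
  empty (an error, not 0 or 1).  DSC = 2J/(1+J) is verified as a property.
* **CIpairs** = Σ over unordered observer pairs of pairwise intersection
  volumes divided by the same sum of pairwise unions.  It collapses to the
  Jaccard index for two observers, is invariant under observer reordering,
  and equals 1 iff all masks are identical.  For structures contoured by a
  subset of observers it is computed over exactly that subset.
* **MASD**: surface voxels are set voxels with at least one face-adjacent
  unset (or out-of-grid) neighbour; the distance from each surface-voxel
  centre to the nearest surface-voxel centre of the other mask is averaged
  over both surfaces together (sums divided by the total number of surface
  voxels).  A sub-voxel mesh distance would be smoother but is not
  reproducible across mesh extractors; the voxel-centre convention is exact,
  grid-anchored and oracle-checkable.

Reporting rounding follows clinical tables: volumes to 3 significant
figures, CoV and the conformity indices to 2 decimals, ties away from zero.
Statistics undefined for a single observer are left blank in reports, never
printed as 0, to avoid implying perfect agreement.

## Nodal-level inclusion

A level counts as included in an observer's PTV when
|level ∩ PTV| / |level| exceeds the threshold **strictly** ("more than
70 %"), computed on voxel counts of the shared grid to avoid double
rounding.  The threshold defaults to 0.70 and is configurable for
sensitivity analyses.  Lateralized levels are independent entries keyed by
name.  Observers lacking the PTV are excluded with a logged warning; an
observer who split the PTV into two same-named structures is handled at
read time by merging duplicates by union (also logged).

## Landmark analysis

Borders are the z centres of the most caudal/cranial occupied slices, so on
4 mm slices all border offsets are multiples of 4 mm — deliberately mirroring
how clinicians pick border slices.  Offsets are signed so that "4 mm below
the cranial landmark" and "12 mm above the caudal landmark" are positive in
the stated sense.  Axial width on a reference slice is the occupied extent
along one in-plane axis plus one voxel (outer-edge convention: a single
voxel is dx wide, not 0).  Width is measured left–right (x) by default and
is configurable to y; maximal in-plane diameter is out of scope.  Landmarks
are user-declared z positions; no image-based landmark detection is
attempted.

## Synthetic cohort generator

The generator is the stand-in for clinical multi-observer structure sets
and defines the study conditions all end-to-end tests run under.  Observer
error is decomposed into the three effects that dominate real contouring
variation:

1. **Systematic margin** δᵢ ~ Normal(μ_δ, σ_δ) mm per observer, applied as
   isotropic dilation (clamped at −min radius/2), modelling different
   safety-margin habits.
2. **Smooth boundary noise**: contour radii are perturbed by a low-order
   angular Fourier series (harmonics 2–5, coefficients fixed per observer
   and structure, scaled to a configurable angular SD in mm), modelling
   boundary ambiguity.  The perturbation is fully correlated along z,
   keeping surfaces smooth.
3. **Caudal truncation**: a per-observer cut plane for the elective target
   volume, offsets in multiples of dz, modelling differing caudal-border
   slice choices.

Omissions are per-structure — either explicit observer indices (for a
deterministic observer count) or an omission probability.  Random draws
occur in a fixed order independent of parameter values, so the same seed
yields bit-identical cohorts.

The default `study_cohort_spec` uses 10 observers on a 512×512×80 grid at
1×1×4 mm.  Base shapes (an elliptic tube for PTV1, ellipsoids/spheres/tubes
for PTV2 and 16 OARs) were sized so their closed-form volumes match the
reported per-structure means (e.g. PTV1 ≈ 845 cm³, brainstem ≈ 25.8 cm³,
pituitary ≈ 0.70 cm³), with omissions fixed to the observed counts
(pituitary 7/10, optic chiasm 9/10, TMJs 8/10).  Observer-model defaults —
margin 2 ± 1 mm, boundary noise 1.5 mm, truncation offsets
(0, −4, −4, −8, −8, −8, −12, −16, −16, −20) mm — are at the scale of the
reported findings: margins of a few mm (up to ~6 mm on small OARs), a
caudal border spread of 20 mm, a mean caudal border ~10 mm above the
sternoclavicular joint, and a supraclavicular PTV1 width around 16 cm.
Nodal levels are axis-aligned boxes placed against the PTV1 tube so that
bilateral II/III are always covered, VIa never, and the caudal IVb/Ia/V
boxes pass the 70 % rule only for observers with caudal-enough truncation
(yielding inclusion counts of 3–7).  Because truncation is quantized to
4 mm slices, only certain inclusion counts are reachable; the level set
reproduces a representative subset of a clinical coverage table, not every
row.

What the generator does **not** emulate: real head-and-neck anatomy, HU
textures or window settings, inter-structure anatomical coupling (e.g.
brainstem/spinal-canal border trade-offs), registration effects, or
non-star-shaped contour errors.  Passing tests therefore demonstrate that
the metrics, rules and reports are computed correctly on realistic
geometry and magnitudes — not that any particular clinical cohort would
produce these values.

## Numerical choices and degenerate inputs

* Grid comparisons use a 10⁻⁶ mm tolerance; NIfTI affines must match the
  declared grid within 10⁻³.
* Polygons with fewer than 3 vertices or zero area are parse errors;
  contours outside the grid extent are coordinate errors naming the ROI.
* CoV with zero mean and non-zero SD, DSC/CIpairs/MASD on all-empty masks,
  and overlap fractions of empty levels are undefined-metric errors.
* Inclusion thresholds must lie strictly inside (0, 1).
* Table rows are sorted by rounded CoV descending, ties alphabetically, so
  re-runs are byte-identical.

## Problem sizes

The analysis drivers and the acceptance script run the full study-scale
cohort (10 observers × 18 structures on 512×512×80 voxels ≈ 21 M voxels per
mask); a complete metrics/levels/landmarks pass takes well under a minute
on one CPU.  Property tests use small grids (≤ 70³ voxels) and 20-cohort
ensembles for margin recovery, which keeps the whole suite around half a
minute.
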