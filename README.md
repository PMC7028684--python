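# ficd — fiber connectivity density mapping

Cerebral small-vessel disease (CSVD) damages white matter diffusely: white
matter hyperintensities and lacunar infarcts sever association fibers long
before dementia is diagnosable. **Fiber connectivity density (FiCD)
mapping** quantifies, for every small patch of cortex, how much fiber
connectivity still reaches it — a vertex-resolution alternative to
atlas-scale connectome graphs, aimed at localising where connectivity is
lost in patients with and without mild cognitive impairment (MCI).

This package implements the full pipeline as a tested library plus a set of
analysis drivers, exercised end-to-end on synthetic phantoms and cohorts:

1. **Parcellation** — the GM–WM interface mesh is split into K = 2000
   cluster units (CUs) by k-medoids on graph geodesics
   (`ficd.parcellation`).
2. **Tractography** — whole-volume deterministic (FACT-like) streamline
   tracking on a diffusion-tensor field, terminated at FA < 0.14, turning
   angle > 45°, and constrained to lengths of 30–300 mm
   (`ficd.tractography`).
3. **FiCD statistic** — for a CU with association fibers f₁…f_N (streamlines
   with an endpoint in the CU's voxel mask),

   FiCD = ( MA(f₁) + … + MA(f_N) ) / V_CU

   where MA is a streamline's mean anisotropy (mean interpolated FA along
   its points) and V_CU the CU volume in mm³ (`ficd.mapping`).
4. **Smoothing and inference** — per-CU values are projected to the surface,
   smoothed with a 10-mm-FWHM kernel (calibrated discrete heat diffusion),
   and compared across groups vertex-wise with an OLS general linear model
   and Monte Carlo cluster-extent correction (`ficd.stats`).
5. **Lesion quantification** — WMH/lacune volumes, relative brain volume,
   and cross-subject lesion possibility maps (`ficd.lesions`).

`ficd.synthetic` generates every input with known ground truth: tensor
phantoms with embedded fiber bundles, sphere meshes standing in for the
cortical surface, three-group patient cohorts with regional FiCD
reductions, and lesion masks of controlled volume. `ficd.experiments`
bundles the canonical phantoms and the calibration simulations.

## Worked example

`analysis/03_subject_ficd_map.py` builds a complete single-subject map: a
radius-18-mm spherical cortex enclosing two orthogonal bundles whose ends
terminate at the surface, 64 CUs, whole-volume tracking, FiCD per CU:

```
400 retained streamlines; 10/64 CUs with nonzero FiCD
global FiCD (CU mean): 0.0044
nonzero CUs sit at the bundle ends (|medoid - pole| small):
  cu   4  ficd   0.0613  distance to nearest bundle pole   5.3 mm
  cu  44  ficd   0.0584  distance to nearest bundle pole   2.5 mm
  cu  38  ficd   0.0453  distance to nearest bundle pole   3.9 mm
  cu  20  ficd   0.0428  distance to nearest bundle pole   2.0 mm
```

Only units pierced by a bundle end carry signal, and their FiCD equals the
summed mean-FA of their fibers divided by the unit volume. The other
drivers follow the same pattern: `01` checks the tracker's termination
contract on four phantoms, `02` runs the study-scale 2000-CU parcellation,
`04` compares three synthetic groups vertex-wise (graded 15%/30% regional
reduction), `05` measures false-positive calibration and effect recovery
(`FWER 0.070 ... binomial interval [0.007, 0.093]`, `median Dice 0.76`),
and `06` runs the lesion volumetrics and imaging–cognition statistics.

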