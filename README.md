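# imfseg

Fully-automated segmentation of muscle and inter-/intra-muscular fat (IMF)
from axial T1-weighted MRI of calves and thighs.

Fatty infiltration of skeletal muscle tracks metabolic disease, dystrophy,
aging and fracture risk, and responds to exercise and pharmacologic
intervention — but measuring *change* requires a segmentation whose
test-retest error is smaller than the expected annual change. On
T1-weighted images the muscle/fat intensity threshold drifts between
scanners, scans and slices, which ruins fixed-threshold methods. `imfseg`
implements an iterative threshold-seeking algorithm (ITSA) with a fully
automated region of interest and corrections for the two dominant error
sources, targeted at researchers running longitudinal muscle-quality
studies (1 T pMRI calf protocols, 3 T TSE thigh protocols) and at method
developers who need a reproducible IMF baseline.

## The method

Per slice, starting from an Otsu seed on the fascia-bounded, bone-free ROI,
the threshold is iterated to a fixed point of

```
ST_R = (1 + (SF_i − SM_i) / SF_i) · SM_i
```

where `SM_i`, `SF_i` are the mean intensities of the currently segmented
muscle and fat. A second round on the ROI minus round-1 fat captures
partial-volumed fat. Candidate fat islands are then verified in 3-D
(islands ≥ 16 mm² are definite; smaller ones survive only with fat on an
adjacent slice), fat within 2 SD of the muscle mean is returned to muscle
(lean-muscle safeguard), and each remaining sub-threshold voxel gets a fat
fraction from the linear-mixture inversion

```
C = (SV_x − SM_x) / (SF_max − SM_x)
```

with `SF_max` the mean top-quartile round-1 fat intensity and `SM_x` the
mean muscle signal after IMF removal. Final metrics:
`IMF_V = (NF + NV·C̄)·Vv`, `M_V = (NM + NV·(1−C̄))·Vv`,
`IMF% = IMF_V/(IMF_V+M_V)·100`. The ROI itself is automated: multi-Otsu
tissue pre-mask, cortex/marrow bone segmentation (marrow found by z-summing
the fat class), and a convex hull refined by a three-round active contour
onto the fascia. Test-retest precision is summarised with RMSCV / RMSSD /
LSC = 1.96·√2·RMSSD and ICC(2,1); method agreement with Bland-Altman and
univariable regression. A synthetic leg-phantom generator with exact
ground truth (supersampled rendering → analytic partial-volume fractions)
drives validation end to end; no patient data are required or included.

See `docs/methods.md` for the full model description and design choices.

## Worked example

```python
from imfseg import PipelineConfig, calf_1T, generate_phantom, segment_case

result = generate_phantom(calf_1T(true_imf_fraction=8.0, seed=42))
case = segment_case(result.volume, PipelineConfig(slice_preset="calf_1T"))
m = case.metrics
print(f"estimated IMF%: {m.IMF_pct:.2f}   (truth: {result.truth['IMF_pct']:.2f})")
print(f"IMF volume: {m.IMF_V_cm3:.2f} cm^3, muscle volume: {m.M_V_cm3:.2f} cm^3")
print(f"voxel classes: NF={m.NF} full fat, NV={m.NV} partial (mean C={m.C_mean:.2f}), NM={m.NM} muscle")
```

prints (exact values from this seed):

```
estimated IMF%: 8.54   (truth: 8.21)
IMF volume: 8.82 cm^3, muscle volume: 94.44 cm^3
voxel classes: NF=5255 full fat, NV=44949 partial (mean C=0.89), NM=480154 muscle
```

i.e. on a synthetic calf with 8.21% true fat the pipeline reads 8.54% —
most captured fat voxels sit below the pure-fat reference and contribute
their fractional fat content (mean C = 0.89) rather than a full voxel.
More examples: `examples/01_generate_phantom.py` (ground truth),
`02_segment_volume.py` (pipeline), `03_test_retest_precision.py`
(RMSCV/LSC/ICC), `04_qc_correction_roundtrip.py` (manual-correction
workflow).

A thin CLI wraps the same functions:

```bash
imfseg phantom --preset calf_1T --imf 8 --seed 42 --out out/
imfseg segment out/phantom.nii.gz --out results/
imfseg precision batch.csv --metrics IMF_pct
imfseg qc export labels.nii.gz volume.nii.gz tags.nii.gz
```

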