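# promisequant

Automated analysis of PSMA PET/CT downstream of organ segmentation:
reference-organ SUV quantification, lesion detection by multi-scale blob
detection with physiological-uptake suppression, fast-marching lesion
pre-segmentation, and SUV quantification — plus the agreement statistics
used to evaluate such pipelines and a synthetic phantom generator with
ground truth.

**Who it is for.** Researchers building or evaluating automated whole-body
PET lesion workflows who already have organ label maps (from any CT
segmenter) co-registered to a PET volume in SUV units, and who need a
reproducible, configurable reference implementation of the analysis stages
plus a phantom test bed.

## The method in brief

Given a PET volume `I` (SUV) and an organ label map:

- **Blood-pool reference**: mean of the SUVs within the interquartile range
  of the eroded thoracic-aorta mask.
- **Liver reference**: the liver SUVs are fitted with a two-component 1D
  Gaussian mixture; the reference is the mean of the dominant high-uptake
  component, so breathing-attenuation regions of artifactually low uptake
  do not bias it.
- **Detection**: per compartment (bone regions on raw PET; lymph and
  prostate on PET minus a fitted model of normal liver/kidney/bladder
  uptake), candidates are local maxima of the scale-normalized Laplacian-
  of-Gaussian response −σ²∇²(G_σ ∗ I) over physical blob diameters
  d = 2σ√3 ∈ {9, …, 25} mm.
- **Pre-segmentation**: from each seed, the Eikonal equation |∇T(x)| = 1/F(x)
  is solved by fast marching with speed
  F = clip((I − floor)/(I_seed − floor), ε, 1)², floor = 0.4 × blood pool;
  the lesion is {T ≤ 18} within 40 mm.
- **Quantification**: SUVmax, SUVmean, uptake volume (mL), and SUVpeak
  (best 1 mL-sphere mean inside the mask).
- **Evaluation**: Dice 2|A∩B|/(|A|+|B|), one-to-one lesion matching,
  sensitivity with Wilson CI, Pearson r with Fisher-z CI, per-method SD,
  and ICC(2,1).

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

```python
import promisequant as pq
from promisequant.pipeline import reproducibility_spec, analyze_grids

# a trunk phantom with 7 lesions (3 bone, 3 lymph, 1 prostate)
suv, labels, truth = pq.make_phantom(reproducibility_spec(seed=42))

result = analyze_grids(suv, labels)
print(f"blood pool {result.references.blood_pool:.2f}, "
      f"liver {result.references.liver:.2f}")
for r in result.lesions:
    print(f"{r.compartment:9s} SUVmax {r.suv_max:5.2f}  SUVpeak {r.suv_peak:5.2f}"
          f"  SUVmean {r.suv_mean:5.2f}  {r.volume_ml:5.2f} mL")

m = pq.match_lesions(truth, result.lesions)
pct, ci = pq.sensitivity(m)
print(f"sensitivity {pct:.1f}% ({ci[0]:.1f}-{ci[1]:.1f}), "
      f"FP {len(m.false_positives)}")
```

prints

```
blood pool 1.75, liver 5.95
bone      SUVmax  6.47  SUVpeak  4.95  SUVmean  4.57   1.19 mL
bone      SUVmax  5.37  SUVpeak  3.83  SUVmean  3.83   0.49 mL
bone      SUVmax  4.82  SUVpeak  3.45  SUVmean  3.45   0.81 mL
lymph     SUVmax  5.05  SUVpeak  4.20  SUVmean  3.63   1.97 mL
lymph     SUVmax  6.02  SUVpeak  4.34  SUVmean  4.02   1.19 mL
lymph     SUVmax  3.69  SUVpeak  2.76  SUVmean  2.76   0.89 mL
prostate  SUVmax  6.03  SUVpeak  4.25  SUVmean  4.25   0.73 mL
sensitivity 100.0% (64.6-100.0), FP 0
```

The blood-pool estimate sits just below the generative mean of 1.8 (partial
volume in a 12 mm vessel), and the liver mixture mode recovers the clean
6.0 uptake to within 0.05 despite 30% of the liver carrying a half-uptake
artifact — a plain mean would read ≈5.1. All seven planted lesions are
detected, segmented and quantified; sub-mL lesions report SUVpeak =
SUVmean by design.

The same pipeline is scriptable from the shell:

```sh
promisequant phantom --seed 42 --out-dir work/
promisequant analyze --pet work/pet.nii.gz --labels work/labels.nii.gz --out-dir work/out
promisequant experiment detection_sensitivity --n 20 --seed 11
```

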