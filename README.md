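# findlv

Automatic contrast-phase detection for 4D cardiac CT.

A dynamic (4D) cardiac CT perfusion study acquires one 3D volume per
RR-interval while a contrast bolus transits the heart: the agent enhances
the right ventricle (RV) first, passes through the lungs, and then peaks in
the left ventricle (LV). Downstream steps such as automatic heart-axis
alignment need one specific phase — high contrast in the LV, low contrast
in the RV — which is otherwise picked by hand during the examination.
`findlv` selects that phase automatically from the time-dependent contrast
distribution, for radiologists and imaging-pipeline developers working with
4D cardiac CT.

## Algorithm

Let $I_p(v)$ be the attenuation (HU) of voxel $v$ in phase
$p \in \{1,\dots,P\}$ after mean-pooling every phase by one integer shrink
factor $f = \max(1, \lfloor n_x / \text{matrix size} \rfloor)$ (each output
voxel is the mean of its $f^3$ block). A voxel casts a vote iff

1. **eligibility** — its first-phase value lies in the unenhanced-blood
   window: $30 \le I_1(v) \le 150$ HU, and
2. **increase** — its temporal maximum $M(v) = \max_p I_p(v)$ shows the
   required rise over the first phase: $M(v) \ge I_1(v)\,(1 + c)$
   (relative mode, default $c = 1$) or $M(v) \ge I_1(v) + c$ (absolute
   mode, $c$ in HU).

The vote goes to the bin $\operatorname{argmax}_p I_p(v)$ of a per-phase
histogram (earliest phase on ties); the fullest bin is the detected phase.
Because acquisition starts with contrast already high in the RV, RV voxels
exceed the window in phase 1 and never vote. If no voxel votes, the result
is an explicit no-detection, not an error. The recommended matrix size is
16: far smaller loses too much spatial information (at 2×2 detection fails
outright), and larger sizes only cost time.

The package also provides a seedable synthetic first-pass phantom (two
ellipsoidal blood pools with gamma-variate bolus curves, myocardial shell,
lung and soft-tissue background, Gaussian noise) with recorded ground
truth, and the evaluation statistics used to assess agreement with human
readers: exact Clopper–Pearson binomial intervals built from inverse
cumulative-beta quantiles, normal-approximation timing intervals, and
Bonferroni correction for pairwise matrix-size comparisons.

## Worked example

```python
from findlv import DetectionParams, detect_phase, generate_phantom
from findlv.phantom import PhantomParams

dataset, truth = generate_phantom(PhantomParams(seed=1))   # 64x64x48, 20 phases
result = detect_phase(dataset, DetectionParams(matrix_size=16))
print("ground-truth LV peak:", truth.lv_peak_phase)
print("detected phase:", result.detected_phase)
print("votes:", result.eligible_voxels, "shrink factor:", result.shrink_factor)
```

prints

```
ground-truth LV peak: 10
detected phase: 10
votes: 143 shrink factor: 4
```

The phantom's LV bolus peaks at the 10th of 20 phases; the detector shrinks
the 64-voxel axis by factor 4 to reach matrix size 16, and the 143 voxels
passing both conditions all place the winning vote mass at phase 10.

The same pipeline is available from a shell:

```sh
findlv phantom --seed 1 --out phantom.nii
findlv detect --input phantom.nii --matrix-size 16 --out result.json
findlv evaluate --manifest cases.json --matrix-sizes 2,4,8,16,32,64,128 --out eval.json
```

`detect` accepts a 4D NIfTI file, a directory, or a glob of ordered 3D
NIfTI/MetaImage volumes, and writes a JSON report with the detected phase
(null for no-detection), the full phase histogram, vote count and
parameters. Exit code 0 covers legitimate no-detection.

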