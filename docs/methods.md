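# Methods

## The detection model

`findlv` treats phase selection in 4D cardiac CT as a voting problem over
first-pass contrast dynamics. Contrast agent reaches the right ventricle
(RV) first and the left ventricle (LV) only after lung transit, so the
phase with the strongest attenuation *increase relative to the first
phase* is, under the clinical acquisition protocol, the phase with high LV
and low RV contrast. Two assumptions are load-bearing:

1. **Acquisition starts with the RV already enhanced.** RV voxels then
   exceed the HU eligibility window in phase 1 and never vote. If a scan
   started before bolus arrival, RV voxels would be eligible and could
   out-vote the LV; the phantom's `rv_arrival_delay` parameter reproduces
   exactly this failure mode, and the algorithm deliberately does not
   verify that the RV is dark at the detected phase.
2. **Phases are co-registered on one grid and supplied in acquisition
   order.** The algorithm trusts the ordering and never re-sorts by time
   stamp; mismatched grids are rejected rather than resampled.

## Pipeline and numerical choices

Four steps: integer-factor mean pooling of every phase; a per-voxel
temporal maximum and argmax; the two-condition vote into a per-phase
histogram; selection of the fullest bin.

* **Shrink (bin) filter.** The factor is
  `max(1, floor(nx / matrix_size))`, identical for all three axes, so
  anisotropic z-extents simply yield `ceil(nz/f)` output voxels; the
  filter never up-samples. Each output voxel is the arithmetic mean of
  its block, accumulated in float64 (narrow integer accumulation would
  overflow at clinical volume sizes). Partial boundary blocks average
  over the voxels actually present — not zero-padded, not truncated —
  which keeps the global mean as close to invariant as possible.
  Non-finite voxels are excluded from block means; a block that is
  entirely non-finite yields NaN, which downstream comparisons treat as
  ineligible. The operation is purely functional: results do not depend
  on any execution partitioning.
* **Inclusive comparisons.** Both the eligibility window
  `[hu_lower, hu_upper]` (default `[30, 150]` HU, the range of
  unenhanced blood) and the increase rule use `>=`/`<=`; "at least" and
  "between" are read inclusively.
* **Increase rule.** Exposed in two modes because the required magnitude
  is a clinical tuning choice: relative (`max >= first * (1 + c)`,
  default `c = 1.0`, i.e. at least a doubling — first-pass LV
  enhancement typically multiplies baseline blood attenuation
  severalfold) and absolute (`max >= first + c` HU). The default is
  visible in every serialized report, never silently applied.
* **Tie-breaking.** Both the temporal argmax and the histogram argmax
  resolve ties toward the earliest phase. One-voxel histogram margins do
  occur at small matrix sizes, so the tie rule is pinned and tested.
* **No-detection** (all bins zero) is a first-class result serialized as
  `null`, with exit code 0 from the CLI; it is how the algorithm reports
  that the data contain no voxel consistent with unenhanced blood that
  later enhances.
* **Phase numbering** is 1-based at every external interface (reports,
  histograms, ground truth), 0-based internally.

## Parameters that matter

| parameter | unit | default | why |
|---|---|---|---|
| `hu_lower`, `hu_upper` | HU | 30, 150 | unenhanced-blood window applied to phase 1 |
| `increase_mode`, `increase_value` | – / HU | relative, 1.0 | required temporal rise; doubling separates enhancing blood from static tissue |
| `matrix_size` | voxels | 16 | best accuracy/speed trade-off; 8 works but decisions get one-voxel tight, 2 destroys the signal |

## The synthetic phantom

The phantom emulates the dynamic acquisition protocol: one volume per
RR-interval (default 0.8 s) during a dynamic window, plus late single
acquisitions 10, 20 and 35 s after it — 20 phases by default (17 dynamic
+ 3 late), within the clinically typical 14–26 range. Geometry is two
non-overlapping ellipsoidal blood pools (LV and RV) in a 64×64×48 grid, a
static myocardial shell around the LV, lung slabs at both x-edges and
soft-tissue background. Tissue constants: background and myocardium 50 HU,
blood baseline 40 HU, lung −800 HU — chosen so the baseline blood sits
inside the eligibility window and the phantom genuinely exercises the
filter. A 128×128 grid option mirrors pre-shrunk clinical inputs.

Chamber enhancement follows a normalized gamma-variate bolus curve, the
standard first-pass model: zero before arrival `t0`, peak `amplitude` at
`t0 + alpha*beta`. Defaults: RV `t0 = −2 s` (already enhanced at scan
start, consistent with the dose-sparing clinical protocol), peak +400 HU
and washed out by mid-scan; LV `t0 = 2 s`, peak +300 HU timed so the
sampled maximum lands at phase 10 of the default protocol. Gaussian noise
(default σ = 10 HU) comes from `numpy.random.default_rng(seed)`; identical
parameters give byte-identical datasets.

What the phantom does *not* model: anatomy beyond ellipsoids, cardiac or
respiratory motion, ECG-gating artifacts, beam hardening, reconstruction
noise texture, or inter-patient variability of bolus timing. Passing the
phantom-recovery tests therefore demonstrates that the pipeline correctly
implements its own contract under idealized first-pass dynamics — not
that it attains any particular accuracy on patient data, where reader
agreement must be measured with the evaluation module.

The lung slabs are what makes the extreme-shrink regime informative: at
matrix size 2 every pooled block mixes lung (−800 HU) into the mean,
drags the first-phase value below the eligibility window, and detection
collapses — reproducing qualitatively the observed 2×2 failure on
clinical data.

## Evaluation statistics

A case counts as a success iff the detected phase lies in that case's
reference set (the intersection of the phases two readers accepted; it may
contain several phases). A no-detection is a failure, and every case
stays in the denominator. Agreement ratios get exact Clopper–Pearson
intervals assembled from inverse cumulative-beta quantiles
(`lower = Beta⁻¹(α/2; x, n−x+1)`, `upper = Beta⁻¹(1−α/2; x+1, n−x)`,
with the x = 0 / x = n boundaries pinned to 0 and 1); the construction is
asymmetric near the boundaries and conservative in coverage. Detection
durations get symmetric normal-approximation intervals
(`mean ± z·sd/√n`, sample sd). Pairwise duration comparisons across k
matrix sizes use two-sided paired t tests at the Bonferroni-corrected
level `α / C(k,2)` (0.05/21 for the canonical seven sizes); the paired t
choice is this package's documented assumption, as the original test
statistic for durations was not specified. Display rounding is whole
percent, half away from zero; raw ratios are always retained in
serialized output.

## Known limitations

* Exactly one phase is returned; protocols needing an RV-only or
  both-ventricles-dark phase would require a different vote target.
* MRI signal-intensity data are out of scope (the HU window is
  CT-specific).
* The first phase is the comparison baseline by construction; scans
  started before RV bolus arrival can be misdetected (see above), and the
  possible "first local maximum as baseline" adaptation is deliberately
  not implemented.
* Timing numbers are hardware-dependent; the evaluation module reports
  and compares them but no test asserts absolute durations.
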