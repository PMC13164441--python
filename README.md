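# nccthist

Time-histogram Hounsfield-unit metrics for acute ischemic stroke on
non-contrast CT (NCCT).

In the first hours after a middle-cerebral-artery occlusion, ischemic edema
lowers brain attenuation so subtly that hyperacute lesions are often
invisible on NCCT. What changes earlier than the mean HU is the *shape* of
the HU distribution inside the lesion. `nccthist` is a small analysis
pipeline for radiology researchers that quantifies this: per ROI and scan
time it computes four first-order histogram metrics —

* **SD** — within-ROI dispersion (tissue heterogeneity), n−1 denominator,
* **skewness** — adjusted Fisher–Pearson G1,
* **excess kurtosis** — bias-corrected G2 (Gaussian → 0),
* **entropy** — H = −Σ pᵢ log₂ pᵢ of the HU histogram (100 bins of 1 HU
  over the −40..60 brain window), in bits —

and compares lesion ROIs against contralateral mirrored controls, tracks
per-subject metric trajectories over minutes post-onset (detecting the
lesion-over-control mean-HU *crossover* interpreted as penumbral salvage,
and searching for the *peak diagnostic window* where cortical and
basal-ganglia lesions separate most strongly), and runs the standard
two-group battery (ANOVA, pooled t with Bonferroni correction, Cohen's d,
bootstrap CIs, repeated-measures ANOVA).

Because patient-level data for this kind of study are rarely shareable, the
package includes a first-class synthetic cohort generator: pixel
distributions are Gaussian mixtures *calibrated by nested root finds* so
every ROI hits its target SD and entropy exactly, subjects carry realistic
between-subject spread, a third of cortical cases carry a planted ~94-min
crossover, and scans cluster around a jittered anchor grid peaking at
76–87 min. Every pipeline stage is therefore testable end to end against
known ground truth.

## Worked example

```python
import numpy as np
from nccthist import (CohortConfig, HistogramSpec, calibrate_joint_pmf,
                      make_cohort, metric_set, sample_roi,
                      cohort_to_trajectories, trajectories_to_frame,
                      baseline_lesion_frame, crossover_fraction, window_scan)

# a single calibrated cortical-lesion ROI: 1e5 pixels whose SD and entropy
# are solved to the group targets (5.16 HU, 4.34 bits)
pmf = calibrate_joint_pmf(target_sd=5.16, target_entropy=4.34, mean_hu=26.71)
roi = sample_roi(pmf, n_px=100_000, seed=7)
m = metric_set(roi, HistogramSpec())
print(f"one ROI  : mean {m.mean_hu:.2f} HU, SD {m.sd:.2f}, skew {m.skewness:+.3f}, "
      f"kurt {m.kurtosis:+.3f}, entropy {m.entropy:.3f} bits")

# the default 45-subject cohort, metric pipeline, temporal analysis
cohort = make_cohort(CohortConfig(seed=1))
trajs = cohort_to_trajectories(cohort)
base = baseline_lesion_frame(trajectories_to_frame(trajs))
for reg in ("cortical", "bg"):
    g = base[base.region == reg]
    print(f"{reg:9s}: n={len(g)}  SD {g['sd'].mean():.2f} ± {g['sd'].std():.2f}  "
          f"entropy {g['entropy_bits'].mean():.2f} ± {g['entropy_bits'].std():.2f}")
print(f"crossover: cortical {crossover_fraction(trajs, 'cortical')}%, "
      f"bg {crossover_fraction(trajs, 'bg')}%")
peak = window_scan(trajs)[0]
print(f"peak window [{peak.start_min:.0f}, {peak.end_min:.0f}) min, "
      f"p_sd={peak.stats['sd']['p']:.2g}, p_entropy={peak.stats['entropy']['p']:.2g}")
```

prints

```
one ROI  : mean 26.72 HU, SD 5.16, skew -0.003, kurt -0.901, entropy 4.336 bits
cortical : n=27  SD 5.17 ± 1.17  entropy 4.33 ± 0.33
bg       : n=18  SD 3.95 ± 0.46  entropy 3.99 ± 0.16
crossover: cortical 33.3%, bg 0.0%
peak window [73, 85) min, p_sd=1.3e-05, p_entropy=1.4e-05
```

Reading this: the single calibrated ROI reproduces its SD/entropy targets
to the second decimal (the ~−0.9 kurtosis is the location-mixture shape
that realizes "high SD at sub-Gaussian entropy"). At cohort level the
baseline group means and between-subject SDs match the cortical and
basal-ganglia targets; exactly 9/27 = 33.3% of cortical subjects show a
lesion-over-control crossover and no basal-ganglia subject does; and the
sliding-window scan localizes the strongest cortical-vs-BG separation to a
12-minute window overlapping the planted 76–87-min peak, with both SD and
entropy separating at p ≈ 1e-5.

## Command line

```bash
nccthist simulate --seed 1 --out results            # cohort → metrics.csv + manifest.json
nccthist metrics img.nii.gz mask.nii.gz --time-min 80   # one image+ROI → metric rows
nccthist temporal results/metrics.csv               # crossovers + peak window
nccthist compare results/metrics.csv --seed 1       # baseline comparison table
nccthist run --seed 1 --out results                 # everything end to end
```

All design knobs (bin range, clip policy, t flavor, Bonferroni family,
window width/step, anchor tolerance, pixel counts) are exposed through a
JSON `--config`; see `docs/methods.md` for what each one means and why the
defaults are what they are.

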