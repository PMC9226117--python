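# seqrsa

Representational similarity analysis of learned temporal structure.

`seqrsa` is for researchers who study how event sequences are encoded in
multi-voxel activity patterns: it models the **change** in pattern
similarity between a pre-learning and a post-learning scan as a function
of the temporal relations between events, and ships the full statistical
machinery such an analysis needs — two-level permutation inference,
linear mixed-model comparisons, representational geometry, and a
searchlight engine with small-volume TFCE correction — together with a
synthetic-data generator so every stage can be validated end to end
without any imaging data.

## The analysis in brief

Participants learn four sequences ("virtual days") of five events each.
Every event has a time on a hidden virtual clock whose speed differs
between sequences, partially dissociating three temporal metrics for each
of the 190 event pairs: virtual-time distance, order distance, and
real-time distance in seconds.

For events *i*, *j* and scan phase *φ*, pattern similarity is the mean
Fisher-z Pearson correlation across all ordered pairs of different
mini-blocks,

    S_ij(φ) = mean_{a≠b} atanh( r(x_i^a, x_j^b) ),   ΔS_ij = S_ij(post) − S_ij(pre),

and ΔS is regressed on the z-scored time metrics per subject. Each focal
t is converted to Z = Φ⁻¹(1 − p_r) with p_r from shuffling ΔS (10,000
times), and the per-subject Z-values are tested against zero with a
sign-flip permutation t-test (Cohen's d with Hedges correction and
noncentral-t CIs attached). The same hypotheses are testable as
likelihood-ratio tests between nested maximum-likelihood mixed models
with random slopes for the focal effect. Behavioral counterparts (timeline
construction, sorting/swap errors, the structural generalization bias)
use the identical two-level scheme.

## Worked example

```python
import numpy as np
from seqrsa import (SimulationConfig, simulate_dataset, build_pair_table,
                    RoiAnalysisSpec, run_roi_model, sequence_interaction_test)
from seqrsa.rsa import similarity_change_from_datasets

cfg = SimulationConfig(n_subjects=12)        # planted: +0.04 within, -0.04 across
design, subjects = simulate_dataset(cfg, seed=5)
pairs = build_pair_table(design)
changes = np.stack([
    similarity_change_from_datasets(s.patterns_pre, s.patterns_post)
    for s in subjects
])

res = run_roi_model(changes, pairs, RoiAnalysisSpec(
    subset="same", predictors=("virtual",), focal="virtual",
    n_perm=500, n_flips=1000, seed=1))
print(res.summary())

inter = sequence_interaction_test(changes, pairs, n_perm=500, seed=3, n_flips=1000)
print(inter.summary())
```

prints

```
ROI similarity-change model [roi]
  subset=same, predictors=['virtual'], focal=virtual
  n=12 subjects, mean Z=1.765
  group signflip-t: stat=11.976, p=0.000999 (two-sided, 1000 resamples), d=3.216 [1.782, 4.632]
sequence-membership x virtual-time interaction
  paired sign-flip: paired-signflip-t: stat=24.859, p=0.001998 (two-sided, 1000 resamples), d=6.925 [4.021, 9.823]
  mixed model: LRT vt_mem: chi2(1) = 34.71, p = 3.823e-09
```

Reading the output: same-sequence pairs show a positive relation between
virtual temporal distance and similarity change (mean permutation
Z = 1.77 across the 12 simulated subjects; the sign-flip test rejects the
null at its resolution, p = 1/1001); the relation differs between same-
and different-sequence pairs both by the paired summary test and by the
mixed-model likelihood-ratio test (χ²(1) = 34.7) — exactly the planted
structure (+0.04/−0.04 in correlation units, attenuated by pattern
noise).

A `seqrsa` command-line interface wraps the batch pipeline
(`seqrsa simulate | behavior | rsa | interaction | mds | searchlight | all`),
each subcommand taking `--config`, `--seed` and `--out`.

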