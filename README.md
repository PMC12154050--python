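# cohgram

Coherence time-graph imaging of multichannel EEG (**Connectogram-COH**) with
subject-wise cross-validated CNN/ResNet classification.

Dynamic functional connectivity treats the brain as a graph whose nodes are
electrodes and whose edge weights are pairwise signal synchrony. `cohgram`
turns a multichannel EEG recording into a grayscale image of that graph's
evolution: each short sliding window becomes one pixel column encoding the
full connectivity pattern at that moment, and the columns tiled over time form
an image that standard convolutional classifiers can consume. The package is
aimed at researchers studying EEG biomarkers of neurological conditions (e.g.
dementia), where coherence differences between groups are an established
signal, and at anyone who wants a leakage-safe reference pipeline for
segment-level EEG classification.

## The transform

For a recording with `c` channels sampled at `f_s` Hz:

1. **Segment** the recording into fixed-length, non-overlapping segments
   (10/20/30 s); each segment is an independent classification sample that
   inherits its subject's label.
2. **Slide** a 0.4 s window in 0.2 s steps (50 % overlap) across the segment.
3. For every window and every channel pair (x, y), estimate the
   **magnitude-squared coherence**

   ```
   Coh_xy(f) = |P_xy(f)|^2 / (P_xx(f) P_yy(f))  ∈ [0, 1]
   ```

   by Welch's method (Hann-tapered, 50 %-overlapping sub-segments; at the
   defaults, M = 3 sub-segments per 0.4 s window), and average it over the
   0.5–45 Hz band. This yields a symmetric `c × c` adjacency matrix with unit
   diagonal per window.
4. **Flatten** the strictly-upper triangle (row-major pair order) into a
   `c(c−1)/2`-long vector — 171 values for the 19-electrode 10–20 montage —
   and tile these columns horizontally in window order.

The result is a `c(c−1)/2 × n_windows` image in [0, 1]: 171 × 149 for a 30 s
segment, 171 × 99 for 20 s, 171 × 49 for 10 s. Float NPZ is the canonical
form; 8-bit grayscale PNG export is provided for inspection.

Two classifiers are included, implemented on the package's compact NumPy
neural-network engine (`cohgram.nn`, plain layers with manual backprop and
Adam): a 2-D **custom CNN** (three valid 3×3 conv + 2×2 max-pool stages at
32/64/128 filters, Dense 128, softmax) and a 1-D **shallow ResNet** that
treats the pair axis as the sequence dimension (strided Conv1D(64) + BN +
ReLU + max-pool, three basic residual blocks at 64/128/256 with projection
shortcuts, global average pooling, softmax). Evaluation uses **subject-wise
k-fold cross-validation**: folds are assigned at the subject level *before*
segmentation, and a hard assertion re-checks on every fold that no subject
contributes segments to both train and test.

## Worked example

```python
import numpy as np
from cohgram import (default_cohort_spec, generate_cohort, assign_folds,
                     segment_recording, build_connectogram,
                     ModelSpec, TrainConfig, subject_wise_cv)

# two-class synthetic cohort: a posterior coupled block, the "dem" class
# with noisier (weaker) coupling — 6 subjects/class, 60 s at 500 Hz
recs = generate_cohort(default_cohort_spec(n_subjects=6, seed=42))

imgs, labels, subjects = [], [], []
for rec in recs:                       # 10 s segments -> 171 x 49 images
    for seg in segment_recording(rec, 10.0):
        imgs.append(build_connectogram(seg).pixels)
        labels.append(seg.label)
        subjects.append(seg.subject_id)

plan = assign_folds(sorted({(r.subject_id, r.label) for r in recs}), k=5, seed=42)
reports, agg = subject_wise_cv(
    np.stack(imgs), labels, subjects, plan,
    ModelSpec("shallow_resnet", (171, 49), 2),
    TrainConfig(epochs=30, batch_size=8, seed=42))
print(agg)
```

prints

```
{'mean_accuracy': 1.0, 'sd_accuracy': 0.0}
```

— the mean and standard deviation of test accuracy over the five
subject-wise folds (72 segment images total). The planted coherence contrast
between the classes is strong, so the residual network separates held-out
subjects perfectly; on real clinical EEG accuracies are of course lower and
depend on the cohort.

The same pipeline is available from the shell:

```bash
cohgram run-all --outdir run1 --seed 42        # simulate → split → transform → train
cohgram transform --outdir run2 --manifest my_edfs.csv   # your own recordings
```

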