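# p300grid

Single-trial P300 detection from grid-shaped EEG tensors, evaluated on
simulated auditory-oddball recordings.

In an auditory oddball brain–computer interface, a listener attends to one
of six virtual sound directions; a stimulus from the attended direction
elicits a P300, a positive EEG deflection 250–700 ms after onset. Detecting
that deflection in a *single* trial is the core classification problem for
auditory BCIs. This package is for researchers who want a complete,
reproducible desk-scale testbed for that problem: an event-level oddball
simulator, the standard ERP preprocessing chain, a spatially faithful input
encoding, a family of small convolutional classifiers, and the statistics
used to compare them.

## The method

Each 1100 ms trial epoch (64 channels × 28 time samples after 0.1–8 Hz
bandpass and decimation to 25.6 Hz) is scattered onto a 10 × 11 scalp grid,
giving a (10, 11, 28) tensor whose 46 electrode-free cells are zero — the
spatial arrangement of the cap is preserved instead of flattened away. A
two-digit *patch code* selects a convolution patch (digit 1 of 0–5:
[3×3], [2×2], [3×2], [2×3], [2×4], [1×4]) and a pooling patch (digit 2 of
0–4: [2×2], [3×3], [1×2], [1×3], [2×3]); the pooling stride is either the
patch itself ("default") or a fixed [1×1]…[2×3], smaller strides forcing
window overlap. Each network is: shared spatial kernel convolved with every
time slice (28 feature maps, one per time sample) → tanh → max-pool →
hidden tanh layer → 2-class softmax, trained by mini-batch SGD (learning
rate 0.008, batch 100).

Because targets are 1 trial in 6, performance is the product of per-class
recalls

    accuracy = (TP / P) × (TN / N)

which is 0 whenever either class is written off. Model families are
compared with one-way ANOVA over the subject-averaged 30 × 6 accuracy
table: across the 30 patch codes (df 29, 150; critical F ≈ 1.54) and
across the 6 strides (df 5, 174; critical F ≈ 2.26).

## Worked example

```python
import p300grid as pg

# one simulated subject: 12 sessions x 180 trials, 500 ms trials, 10 uV P300
specs = pg.subject_session_specs(trial_length_ms=500.0, seed=0)
rec = pg.synthesize_recording(specs, p300=pg.P300Params(amplitude=10.0), seed=0)
print(len(rec.events), int(rec.events.is_target.sum()))   # 2160 360

epochs = pg.epoch_trials(rec)                   # 2160 epochs of shape (64, 28)
train, test = pg.split_train_test(epochs, seed=0)

acc, counts = pg.evaluate_cell(train, test, patch_code="22", stride="1x2")
print(round(acc, 3), counts)
# 0.874 EvalCounts(TP=159, TN=890, P=180, N=900)
```

The run above trains the patch-code-22 network (conv [3×2], pool [1×2])
with an overlapping [1×2] stride on 1080 trials and scores it on the held
out 1080: target recall 159/180 ≈ 0.88, nontarget recall 890/900 ≈ 0.99,
multiplicative balanced accuracy ≈ 0.87.

The same pipeline is scriptable from the shell:

```sh
p300grid simulate --trial-length 500 --amplitude 10 --seed 0 --out runs/rec
p300grid preprocess --in runs/rec --out runs/eps.npz
p300grid train --epochs-file runs/eps.npz --patch-code 22 --stride 1x2
p300grid evaluate --grid quick --master-seed 0 --out runs/quick
p300grid anova --results runs/full/results.tsv --by strides   # full grid only
```

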