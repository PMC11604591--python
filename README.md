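# saccade

Hard-attention recurrent classification of images and EEG-like multichannel
signals, implemented in pure NumPy.

A multi-scale *glimpse sensor* extracts a stack of foveated patches (native
resolution at the center, progressively wider mean-pooled windows outward)
around a focal location. A small glimpse network embeds each stack, a GRU core
integrates the sequence, and three heads act on the recurrent state:

* a **location head** — the mean of a fixed-variance Gaussian policy over the
  next focal location, trained with the REINFORCE score-function estimator
  against a learned state-value baseline (hard attention: no gradients flow
  through sampled coordinates);
* an **action head** — softmax classification at the final step, trained by
  backpropagated cross-entropy through the core and glimpse network;
* a **baseline head** — a scalar return estimate, trained by MSE, used only to
  reduce policy-gradient variance.

Episodes earn a terminal 0/1 reward for a correct classification.

Everything is exercisable offline via seeded synthetic generators: translated
glyph canvases, multichannel noise epochs carrying class-discriminative
oscillatory bursts, and a competition-shaped scaffold
(9 subjects × 2 sessions × 6 runs × 48 trials = 5,184 epochs, 22 channels,
1000 timepoints at 250 Hz).

## CLI

All commands take a YAML config (strictly validated; unknown keys rejected)
and an output directory, and write a provenance block (config hash, seed,
version) beside their outputs.

```bash
saccade generate -c config.yaml -o run/          # HDF5 dataset + CSV manifest
saccade train    -c config.yaml -o run/          # checkpoint.npz + train_log.tsv
saccade train    -c config.yaml -o run/ --resume # continue epoch numbering
saccade evaluate -c config.yaml -o run/          # JSON report + confusion CSVs
saccade glimpse-debug -c config.yaml -o run/ --index 0 --row 0 --col 0
```

Minimal config:

```yaml
task: burst_eeg            # glyphs | burst_eeg | bci2a_shaped | external_eeg
seed: 0
eval_mode: pooled          # pooled | subject_dependent | loso
data:    {n: 500, channels: 22, timepoints: 1000, num_classes: 4}
glimpse: {k: 3, base_rows: 2, base_cols: 7}
train:   {T: 6, epochs: 10, batch_size: 32, lr: 0.001, sigma: 0.17}
```

Evaluation runs the deterministic policy (start at the center, follow the
location mean, argmax action); training samples locations stochastically.

## Library

```python
import numpy as np
from saccade import (GlimpseConfig, TrainSettings, gen_burst_eeg,
                     two_class_burst_specs, train, predict, score)

rng = np.random.default_rng(0)
data = gen_burst_eeg(500, channels=10, timepoints=120,
                     specs=two_class_burst_specs(10, 120), rng=rng)
params, log = train(data, TrainSettings(T=6, epochs=30, batch_size=25, seed=0,
                                        glimpse=GlimpseConfig(k=3, base_rows=2,
                                                              base_cols=7)))
preds = predict(data, params, T=6, config=GlimpseConfig(k=3, base_rows=2, base_cols=7))
print(score(preds, [ep.label for ep in data], 2).accuracy)
```

## Layout

```
src/saccade/
  glimpse.py          multi-scale foveated patch extraction, coordinates
  model.py            glimpse net, GRU core, heads, init, checkpoints
  policy_training.py  rollouts, REINFORCE + baseline, hybrid updates, training
  synthetic_data.py   glyph / burst / competition-shaped generators
  evaluation.py       accuracy, Cohen's kappa, confusion, split protocols
  cli_io.py           YAML config schema, CLI, HDF5/CSV/EDF I/O
  _edf.py             minimal EDF record reader/writer
```
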