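# spikemyo

Spiking-neural-network gesture recognition for surface electromyography
(sEMG), built for the question a myoelectric-control designer actually
faces: can a spiking classifier match conventional networks while training
from a single gesture repetition, tolerating electrode re-wearing, and
running at a fraction of the arithmetic energy?

The package implements the full scheme end to end:

* **Adaptive temporal-contrast encoding** — a window `s(t)` becomes spikes
  via `diff(t) = s(t+1) − s(t)`, firing where `|diff(t)| ≥ V_thr1` with
  `V_thr1 = mean(|diff|) + θ·std(|diff|)` recomputed from each sample
  (θ = 0.6), which makes the spike code invariant to amplitude scaling —
  the disturbance electrode shifts and subject differences produce.
* **Voltage–current LIF network** — neurons with coupled leaky states
  `I(t) = μI(t−1) + Ws(t) + b`, `U(t) = τU(t−1) + RI(t)` (τ_syn = 5,
  τ_mem = 10), firing at `U ≥ V_thr2` with multiplicative penalty reset
  `U ← U(1−p)`, p = 1.5; two hidden layers, softmax readout of the second
  layer's time-averaged membrane voltage; surrogate-gradient BPTT with
  plain SGD (lr 0.1, batches of 1/8 of the training set).
* **Comparators** — LDA on MAV/VAR/WL/ZC features, an LSTM and a compact
  CNN (NumPy implementations with verified gradients).
* **AC/MAC energy model** — inference power counted as 0.1 per accumulate
  and 3.1 per multiply-accumulate; spiking layers scale with the measured
  spike release rate SRR = n/(T·N).
* **Synthetic HD/LD sEMG generator** — 128-channel (two 8×6 + two 4×4
  arrays) and 8-channel montages, 9 gesture classes with subject-specific
  spatial activation maps, burst-modulated band-limited noise, and
  re-wearing effects (electrode shift, gain and impedance changes), fully
  seeded. Every experiment in the repository runs on this generator; no
  download is needed.

`docs/methods.md` describes the models, the numerical choices and the
generator's scope in detail.

## Worked example

```python
import numpy as np
from spikemyo import encode, experiments, power, preprocess, snn, synth

# one subject, one session: 9 gestures x 8 repetitions, 128 channels
cfg = synth.SynthConfig(n_subjects=1, n_trials=1, n_gestures=9,
                        n_repetitions=8, seed=3)
X, labels = preprocess.build_dataset(synth.iter_dataset(cfg))
print(X.shape)                       # (2808, 128, 100): 9*8*39 windows

spikes = encode.encode_batch(X, encode.EncoderConfig(theta=0.6))
y = labels["gesture"].to_numpy()
train, test = experiments.split_by_ratio(labels, 1)   # 1 repetition trains

net = snn.SnnNetwork.init(128, 100, 9, T=100, seed=0)
net, _ = snn.train(net, spikes[train], y[train], snn.TrainConfig(seed=0))

acc = snn.evaluate(net, spikes[test], y[test])
srr1 = float(spikes[test].mean())
srr2 = snn.hidden_layer_srr(net, spikes[test])
total = power.snn_total_power(100, 128, 128, 100, 9, srr1, srr2).total
print(f"accuracy {acc:.3f}  SRR1 {srr1:.3f}  SRR2 {srr2:.3f}")
print(f"inference power {total/1e4:.2f}e4 vs LSTM "
      f"{power.lstm_power(100,128,100,9).total/1e4:.1f}e4")
```

Output:

```
(2808, 128, 100)
accuracy 0.992  SRR1 0.210  SRR2 0.105
inference power 13.84e4 vs LSTM 2855.1e4
```

Reading: trained on one repetition per gesture (351 windows), the spiking
network recognises the other seven repetitions at 99% on this synthetic
subject; roughly one in five encoder time steps carries a spike (SRR1), one
in ten hidden-neuron steps fires (SRR2), and the event-driven energy total
sits two orders of magnitude below the equivalent LSTM's.

The same pipeline is scriptable from the shell:

```bash
spikemyo synth --subjects 1 --trials 1 --gestures 9 --reps 8 --seed 3 --out raw/
spikemyo preprocess --in raw/ --out real/
spikemyo encode --in real/ --out spikes/ --mode adaptive --theta 0.6
spikemyo train-snn --in spikes/ --hidden 100 --out model.npz
spikemyo eval-snn --model model.npz --in spikes/
spikemyo power --arch snn --srr1 0.21 --srr2 0.10
```

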