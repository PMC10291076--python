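# Methods

This note documents the models implemented in `spikemyo`, the choices made
where the design was genuinely open, and what the synthetic data generator
does and does not emulate.

## The recognition scheme

A gesture sample is a 100 ms window of multichannel surface EMG (sEMG),
sampled at 1 kHz: a `channels x 100` matrix in [0, 1]. The pipeline is

1. **Conditioning** — broken channels are replaced by the mean of their
   grid neighbours; the activity burst is segmented at 10% of the envelope
   peak; the segment is resampled to 5,000 points, band-pass filtered
   (20–500 Hz, 51-tap FIR) and Min-Max normalised per channel; 39 windows
   (100 ms length, 50 ms increment) are cut from the 2 s steady phase.
2. **Spike encoding** — temporal contrast: `diff(t) = s(t+1) − s(t)`, and a
   spike is emitted wherever `|diff(t)| ≥ V_thr1`. In adaptive mode
   `V_thr1 = mean(|diff|) + θ·std(|diff|)` is recomputed from each sample's
   own differences (θ = 0.6 by default); in fixed mode `V_thr1 = 0.18`.
3. **Spiking network** — input → hidden LIF layer (100 neurons for 128
   channels, 20 for 8) → second LIF layer with one neuron per gesture.
   Class scores are the softmax of the second layer's time-averaged
   membrane voltage.
4. **Energy accounting** — inference power is counted in relative units per
   arithmetic operation: 0.1 per accumulate (AC), 3.1 per multiply-accumulate
   (MAC). Spiking layers pay ACs proportional to the spike release rate
   SRR = n/(T·N) plus 2 MACs per neuron per step for the state updates;
   dense LSTM/CNN layers pay a MAC per weight per evaluation.

## Neuron model

The voltage–current LIF neuron keeps two leaky states per neuron,

    I(t) = μ·I(t−1) + Σ_j w_ij s_j(t) + b_i        μ = e^(−1/τ_syn)
    U(t) = τ·U(t−1) + R·I(t)                        τ = e^(−1/τ_mem)

with τ_syn = 5, τ_mem = 10 steps and R = 1. The neuron fires when
`U ≥ V_thr2` (equality fires) and is then reset multiplicatively,
`U ← U(1 − p)` with p = 1.5, leaving a *negative* voltage that suppresses
immediate re-firing without an explicit refractory clamp. A hard refractory
period is available but off by default. The voltage-only ablation variant
(`variant="lif-v"`) drops the current memory (μ = 0) and uses V_thr2 = 0.5.
Both layers spike and reset during readout; the readout averages the stored
(post-reset) voltages. States start at zero for every sample, so per-sample
classification is order-independent.

Useful closed forms used as test oracles: with no input and no spiking,
`U(t) = τ^t U(0)`; under constant drive `c` the states converge to
`I → c/(1−μ)` and `U → c/((1−μ)(1−τ))`.

## Training

Mini-batch SGD (learning rate 0.1, batch = 1/8 of the training set) on the
cross-entropy of the softmax readout, backpropagated through time. The
non-differentiable spike indicator gets a normalised fast-sigmoid
pseudo-derivative

    g(v) = (β/4) / (1 + β|v|/2)²,   v = (U − V_thr2) / |V_thr2|,

with β = 10 (even, peak β/4 at v = 0, unit area). Two numerical choices
matter and are deliberate:

* **Threshold-normalised surrogate argument.** With a raw voltage distance
  the pseudo-derivative's width is fixed in volts, so it is ~20× narrower
  relative to the V_thr2 = 10 dynamics than to the V_thr2 = 0.5 variant,
  and the voltage–current model systematically under-trains. Normalising
  by |V_thr2| gives both variants the same effective surrogate width.
* **Gradient clipping.** The readout integrates voltage over T = 100 leaky
  steps, which amplifies readout-path gradients by roughly
  1/((1−μ)(1−τ)) ≈ 58; plain SGD at lr 0.1 then oscillates. Updates are
  rescaled to a global gradient norm of at most 1.0 (configurable).

The reset term is detached during backprop (`dU_post/dU_pre = 1 − p·S` with
S treated as a constant), the common convention in surrogate-gradient
implementations. Weights start zero-mean uniform; the first layer is scaled
by `V_thr2/(2√fan_in)` so its membrane voltages fluctuate near threshold
from the start — with plain `1/√fan_in` scaling the layer is silent at
V_thr2 = 10, the surrogate sees only its vanishing tail, and no learning
occurs. Training stops early on a loss plateau (patience 10, default budget
100 epochs); fixed seeds make trajectories bit-reproducible.

## Encoder threshold granularity

The adaptive threshold pools the difference statistics over all channels of
a sample (one threshold per sample, from its own distribution). The
alternative — an independent threshold per channel — is strictly more
invariant (it also absorbs channel-wise gain changes) but cuts a fixed
quantile of every channel's difference distribution: for stationary Gaussian
channels `|diff|` is half-normal, so every channel then spikes at the same
rate and the cross-channel rate pattern, which carries the spatial class
signature, is erased. Pooled thresholding keeps whole-sample scale
invariance (`encode(a·s) = encode(s)` for a > 0) while preserving that
pattern; `per_channel=True` remains available.

## Comparators

* **LDA** on the per-channel time-domain features (MAV, VAR, WL, ZC; MAV
  and ZC on the mean-centred window, since a [0, 1]-normalised signal never
  crosses zero). Pooled within-class covariance with diagonal shrinkage
  `1e-4 · trace(Σ)/d` — unavoidable with 4 × channels features and a
  one-repetition training set.
* **LSTM**: one recurrent layer (hidden size matched to the SNN) and a
  fully-connected readout of the final hidden state; Adam, lr 0.01.
* **CNN**: windows reshaped to 100-plane images on the electrode grid
  (16×8 or 4×2); two blocks of 2×2 stride-2 convolutions (32 then 16
  filters, same padding) with batch norm and 2×2 max pooling (skipped on
  axes of size 1), then a fully-connected softmax layer; Adam, lr 0.01.

All three are self-contained NumPy implementations with hand-written
backprop; gradients are verified against central differences in the tests.
Baseline training runs its full epoch budget (no early stop) because Adam
loss curves on small sets oscillate through plateaus. Note the power model's
CNN FC term uses the printed idealisation `H·W·C2·o` rather than the
realised post-pooling flatten size — the energy model is an operation-count
convention, kept verbatim.

## Synthetic data generator

No public dataset accompanies the recording protocol this package targets,
so `spikemyo.synth` generates labelled recordings with the statistical
structure the pipeline relies on:

* **Geometry** — two 8×6 forearm arrays (14 mm pitch) and two 4×4 upper-arm
  arrays (18 mm), 128 channels; the 8-channel low-density montage is the
  centre electrode of each 3×3 block of a centred 6×6 sub-grid on the two
  forearm arrays (a channel subset, exactly as selected from the
  high-density montage).
* **Signal model** — per channel: `gain · envelope(t) · m(t) · carrier(t) +
  floor · noise(t)`, where the carrier and floor noise are band-limited
  (20–500 Hz) Gaussian noise, the envelope is a 2 s raised-cosine onset,
  2 s plateau, 1 s offset, and `m(t) = exp(depth · z(t))` is a lognormal
  amplitude modulation driven by a slow (8–25 Hz) common-drive process
  shared across channels, with per-channel depth proportional to the
  activation map. The burst modulation is essential, not decorative: for
  stationary Gaussian noise the adaptive encoder cuts a fixed quantile of
  the difference distribution regardless of amplitude or spectrum, so
  *burstiness is the only channel property that survives scale-invariant
  encoding* — as it does in real sEMG, where the interference pattern at
  sub-maximal effort is amplitude-modulated by common motor-unit drive.
* **Class structure** — each gesture has a spatial activation map built
  from per-array Gaussian bumps at gesture-specific centres, jittered and
  gain-perturbed per subject.
* **Wearing effects** — each trial after the first applies (i) an integer
  electrode shift (activation maps translated on each grid with edge
  replication, no rotation), (ii) a global gain factor (lognormal), and
  (iii) per-channel impedance jitter realised as a one-pole low-pass of
  random strength. The impedance term matters for encoder comparisons:
  Min-Max segment normalisation already cancels pure gain, so a
  low-pass-induced change in the difference-to-amplitude ratio is the
  disturbance a per-sample adaptive threshold absorbs and a fixed
  threshold does not.
* **Reproducibility** — a seed hierarchy (master → subject → trial →
  repetition) makes any sub-collection independently reproducible;
  identical seeds give bit-identical datasets.

What the generator does **not** emulate: motor-unit action potentials and
recruitment, force levels, electrode rotation, power-line or motion
artefacts, cross-channel noise correlation from volume conduction, and the
non-stationarities of fatigue. Accuracies on this generator therefore say
nothing quantitative about human data; passing tests demonstrate that the
pipeline's mechanisms work (scale invariance, monotone rate control,
trainability, the qualitative benefit of adaptive encoding under wearing
changes), not that any published accuracy is reproduced.

## Channel repair rule

A channel is flagged when its RMS exceeds 100× the median channel RMS
(configurable, as is the whole rule). The default targets saturation and
disconnect faults; it must not fire on genuine hotspot channels, which on a
sparse 8-channel montage can legitimately reach tens of times the median of
the mostly-inactive channels. At most 5% of channels (at least one) may be
repaired per recording.

## Problem sizes in the shipped experiments

The tests and the reproduction script run scaled-down study conditions,
chosen once: 1 subject × 1 trial × 9 gestures × 8 repetitions (128
channels) for the single-repetition training protocol, 1 subject × 2 trials
× 9 gestures × 4 repetitions (8 channels) for the shift/ablation
comparison over 10 seeds, and 1 subject × 5 trials × 9 gestures × 8
repetitions (8 channels) for per-participant sample counting. The generator
defaults keep the full 8 × 5 × 9 × 8 protocol.

## Known limitations

* The surrogate family, its β, the weight-init scale and the clipping norm
  are defensible defaults, not tuned optima.
* The protocol runner trains only the spiking network; comparator training
  at protocol scale is left to the user (the classes are provided).
* The vthr2 sweep varies the release threshold on fixed trained weights —
  the monotone SRR guarantee is a fixed-weight property; retraining at each
  grid point would not be monotone in general.
* The ANOVA utility is a plain one-way F test without post-hoc corrections.
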