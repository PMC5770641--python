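# Methods

## Neuron model and rate coding

The simulator advances a stack of non-leaky integrate-and-fire layers in
discrete steps of size `Δt` (default 1, so the maximum rate is
`r_max = 1/Δt = 1` spike per step). A neuron spikes when
`V(t-1) + z(t) ≥ V_thr`; the tie at exactly `V_thr` fires. Two reset rules
are implemented: reset to zero (residual charge above threshold is
discarded) and reset by subtraction (`V ← V − V_thr`, charge-conserving).
Under reset by subtraction with constant nonnegative input the exact
bookkeeping `V(t) = t·z − N(t)·V_thr` holds at every step and is asserted
in the tests; the cumulative rate therefore equals the target activation up
to the `V(t)/(t·V_thr)` transient. Under reset to zero the steady-state
rate is reduced by the factor `V_thr/(V_thr+ε)` with
`ε = n·z − V_thr ≥ 0`, `n = ⌈V_thr/z⌉`; the closed forms in
`snnconv.theory` take the ANN activation directly and convert internally
via `z = V_thr·a`. The analysis assumes `z ≤ V_thr` (at most one threshold
crossing per step); for larger inputs the neuron still emits a single spike
per step and carries the surplus forward, a regime the closed forms do not
model.

Inputs larger than the threshold, inhibitory input, and negative membrane
potentials are all allowed; there is no lower clamp by default (an optional
floor at 0 exists as a flag). At most one spike per neuron per step is
emitted in all modes. With signed spikes a mirror threshold at `−V_thr`
emits events of size −1, for networks whose activations live in {−1, +1}.

## Conversion pipeline

1. **Batch-norm folding.** `BN(y) = γ(y−μ)/σ + β` is absorbed into the
   preceding conv/dense layer as `W̃ = (γ/σ)W`, `b̃ = (γ/σ)(b−μ) + β`.
   This is exact; the test suite checks forward equivalence to 1e-6 in the
   ∞-norm on random models.
2. **Parameter normalization.** Per parameterized layer a scale `λ^l` is
   taken from calibration activations (post-ReLU where a ReLU follows, the
   raw output for the final logits layer) and applied jointly:
   `W → W·λ^{l-1}/λ^l`, `b → b/λ^l`, with `λ^0 = 1` because inputs are in
   [0, 1]. By positive homogeneity of ReLU this only rescales activations
   per layer, preserving classification decisions. `mode="max"` guarantees
   calibration activations ≤ 1; `mode="percentile"` (default p = 99.9) is
   robust to singular outlier samples at the cost of saturating a small
   fraction of units. The percentile is computed by linear interpolation
   between order statistics (numpy's default); the population includes
   zero activations, with an option to restrict to non-zero values. A layer
   whose calibration activations are all zero keeps `λ = 1` and emits a
   warning rather than dividing by zero. Normalization is per layer, not
   per channel.

## Simulation semantics

Layers update synchronously within a step in network order, each consuming
the spikes its predecessor emitted in the same step (pipeline latency 0).
Conv, dense and average-pool layers become IF layers (average pooling is a
fixed-weight linear layer); max-pool layers become gates that pass only the
current spike of the window input with the highest running rate estimate —
full-history `N(t)/t` by default, or a configurable moving-average window —
with ties broken to the lowest index. ReLU and flatten dissolve into the
surrounding stages; a trailing softmax accumulates potentials and either
spikes (external Poisson clock with one expected tick per step by default,
or per-neuron Bernoulli draws on `softmax(V)`) or is read out directly from
the potentials. The readout at each step is the class with the highest
cumulative output count (softmax of potentials under direct readout); ties
resolve to the lowest class index, and steps before any output evidence
report class 0 with a `no_evidence` flag so the per-step error rate is
defined everywhere.

Input encoding is constant-current by default (the analog image multiplied
into the first layer's kernels as a fixed per-step charge, which removes
input sampling noise); Poisson encoding (pixel spikes with per-step
probability `x·r_max·Δt`) is provided as the baseline. With clamping
enabled, spiking layer `l` (1-based over IF layers) is held at `V = 0` and
silent for the first `d·l` steps; gates are not clamped. Images in a batch
are simulated independently, with all stochastic draws for image `i` taken
from a generator seeded `seed + i`.

## Operation accounting

ANN cost per frame is `Σ_l (2·f_in,l + 1)·n_l` over conv/dense layers
(multiply + add per connection, one add for the bias); pooling and the
softmax evaluation are not counted. By default the conv fan-in is the
nominal kernel volume (kernel area × input channels) for every neuron —
this is the convention under which the headline GOps figure for the
BinaryNet CIFAR-10 architecture (1.23 GOps) is obtained; `border_aware=True`
instead counts only real connections of 'same'-padded kernels (1.11 GOps on
the same architecture).

SNN cost is `Σ_t Σ_l f_out,l·s_l(t)`: each spike triggers one postsynaptic
update per outgoing connection. Fan-out here is always border- and
stride-aware, computed from explicit coverage counts; a spike into a
max-pool gate costs one update, a spike into the softmax accumulators one
update per neuron, and bias- or constant-current-driven additions are not
counted, nor are input-pixel Poisson spikes (the sum runs over network
layers only). The count is validated against a brute-force counter that
replays recorded rasters through loop-built connection matrices, with exact
integer equality.

## Synthetic fixtures

`make_images` draws class-conditional Gaussian blobs (amplitude 0.9, width
σ = 1.6 px, ±1 px jitter, additive noise σ = 0.08, clipped to [0, 1]) at
class centers spaced on a circle of radius 0.28·min(H, W); labels are
balanced. `make_network` generates random-weight CNNs and rescales each
layer on a probe batch so the 99th percentile of its activations is 0.8,
i.e. calibration activations are mostly in [0, 1] as they would be for a
trained, well-normalized network. `make_classifier_fixture` builds a
prototype-matching network (matched Gaussian filters in the convolution,
position templates in the dense layer) analytically from the class
templates — no gradient training, yet ≥ 90% accuracy on its own batch.

Heavy-tailed activation distributions — the regime that motivates robust
percentile normalization — are emulated by *rare structured samples*: a
small fraction of images carries a saturated 3×3 checkerboard patch, and
the network carries a high-gain checkerboard kernel (in the classifier
fixture a decoy channel with zero downstream weights, so decisions are
unchanged). Smooth blobs barely excite that kernel, so only the rare
patch samples produce activations several times above the 99.9th
percentile, reproducing a maximum-to-percentile ratio well above 1 while
leaving high percentiles stable. This captures the mechanism (singular
outlier samples inflating the maximum) but not the full diversity of real
image statistics; passing the ordering tests shows the *relative* merits of
max-norm versus percentile normalization under such tails, not absolute
error rates on natural images.

## Problem sizes and numerical choices

End-to-end experiments use 60-sample batches on 12×12 single-channel
images with a conv(5×5)–maxpool–dense classifier, presented for T = 150–200
steps — small enough for the whole suite to run in seconds while leaving
all rate transients clearly resolved. Theory–simulator equivalence is
checked on a dyadic activation grid (k/64), for which double-precision
membrane dynamics are exact, making "equal at spike times" a true equality
test rather than a tolerance; elsewhere rate checks use the analytic 1/t
and 2/t transient bounds. Exact-representation latencies are computed with
rational arithmetic (`fractions.Fraction`): the earliest step at which
`N(t)/t` equals `a = p/q` is `q`, cross-checked against a simulated neuron.
Floats passed to these functions are taken at their exact binary value, so
decimal grids should be given as fractions or strings.

## Known limitations

* No leak, refractory period, or synaptic delays; time-stepped execution
  only (no event-driven simulation or hardware export).
* The closed-form rate theory covers constant-current input and reset by
  subtraction in higher layers; Poisson input has no closed form here.
* Normalization scales are per layer; per-channel scales are not
  implemented.
* Physical units are left to the user: rates are per time step, with no
  fixed `Δt` ↔ seconds mapping.
* Training is out of scope; networks come from the analytic generators or
  from model files.
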