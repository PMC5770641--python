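# snnconv

Convert trained continuous-valued feed-forward CNNs into rate-coded spiking
neural networks (SNNs) and simulate them step by step, for researchers who
want event-driven inference with near-ANN accuracy and an explicit
accuracy-versus-operations trade-off.

## The model

Each analog unit with ReLU activation `a_i = max(0, Σ_j W_ij a_j + b_i)` is
replaced by a non-leaky integrate-and-fire neuron whose membrane potential
integrates the input current

```
z_i(t) = V_thr (Σ_j W_ij Θ_j(t) + b_i)
```

each time step (`Θ_j(t) ∈ {0,1}` the presynaptic spikes, the bias a constant
current) and fires when `V_i(t-1) + z_i(t) ≥ V_thr`. With **reset by
subtraction** (`V ← V − V_thr` on a spike) the cumulative firing rate
`r_i(t) = N_i(t)/t` of a first-layer neuron under constant input satisfies

```
r_i(t) = a_i r_max − V_i(t) / (t V_thr),        r_max = 1/Δt,
```

so the rate converges to the activation with a transient that decays as 1/t;
with reset to zero the residual charge above threshold is discarded and the
rate persistently undershoots. In deeper layers the rate is the weighted sum
of presynaptic rates minus the accumulated residual terms, which is why
deeper networks need longer presentation times.

Supporting machinery covers the full conversion pipeline:

* **Batch-norm folding** into the preceding layer's weights and biases.
* **Data-based parameter normalization**: weights/biases rescaled by
  per-layer activation scales λ (the maximum, or a robust high percentile
  that ignores singular outlier samples) so firing rates stay below `r_max`.
* **Analog constant-current input** (or Poisson spike trains as a baseline).
* **Spiking softmax** (external Poisson clock, per-neuron Bernoulli on
  softmax of the membrane potentials, or direct potential readout).
* **Gated spiking max-pooling** that forwards only the spikes of the window's
  maximally firing input.
* **Signed spikes** with a second threshold at −V_thr, and a membrane-clamp
  schedule (`N(l) = d·l`) that suppresses transients in deep networks.
* **Operation accounting**: ANN cost `Σ_l (2 f_in + 1) n_l` per frame versus
  cumulative SNN synaptic operations `Σ_t Σ_l f_out s_l(t)`.

Everything runs on synthetic fixtures (blob-image classification tasks and
analytically constructed prototype-matching CNNs), so no dataset downloads
are required.

## Worked example

```python
import snnconv as sc
from snnconv import fixtures, conversion, simulation
from snnconv.spiking_core import SimConfig

model, images, labels = fixtures.make_classifier_fixture(seed=0, n=60)
ann_pred = sc.ann_argmax(model, images)
print("ANN accuracy:", (ann_pred == labels).mean())

stats = conversion.collect_activation_stats(model, images)
snn_model = conversion.normalize_parameters(model, stats, mode="percentile", p=99.9)
result = simulation.run(snn_model, images, SimConfig(T=200, seed=0), labels=labels)
agree = sc.agreement_curve(result, ann_pred)
print("SNN/ANN agreement at t=10, 50, 200:", agree[[9, 49, 199]])
ops, err = sc.tradeoff_curve(result)
print(f"error rate {err[-1]:.3f} after {ops[-1]:.0f} synaptic ops/frame")
print(f"ANN cost (fixed): {sc.count_ann_ops(model)} ops/frame")
```

prints

```
ANN accuracy: 1.0
SNN/ANN agreement at t=10, 50, 200: [1. 1. 1.]
error rate 0.000 after 15799 synaptic ops/frame
ANN cost (fixed): 15268 ops/frame
```

The converted network reproduces every ANN decision already after a few time
steps; the trade-off curve shows how the error falls as more synaptic
operations are invested, whereas the ANN always spends its fixed 15268 ops.

The same pipeline is available from the shell:

```
snnconv fixtures generate --kind classifier --seed 0 --out model.json
snnconv convert  --model model.json --calib model_batch.h5 --norm percentile:99.9 --out snn.json
snnconv simulate --model snn.json --data model_batch.h5 --T 200 --seed 1 --out result.h5
snnconv profile  --result result.h5 --out curve.csv
```

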