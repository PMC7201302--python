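# Methods

## Model

`synsample` simulates supervised learning in a spike-based
winner-take-all (WTA) circuit whose synaptic parameters evolve by a
sampling-type stochastic differential equation.  A stimulus is encoded
by Gaussian-tuned input neurons into 200-ms Poisson spike trains; each
train is filtered by a peak-normalized double-exponential EPSP kernel to
give the input trace x_i(t).  K output neurons carry membrane potentials
u_k(t) = Σ_i w_ki x_i(t) and fire with rates ρ_k(t) = R_total ·
softmax(u(t))_k, at most one output spike per 1-ms bin (lateral
inhibition as exact divisive normalization over a shared rate budget).
The predicted label is the neuron with the most spikes in the window.

Weights are an exponential function of the underlying parameters,
w = e^(θ − θ0), so weights are always positive and plasticity acts
multiplicatively.  After each 200-ms presentation the parameters move by
one Euler step of

    dθ = b·[ (μ − θ)/σ²  +  N · w (x̄ − α e^w)(Θ{h} − S̄)  +  ξ ] dt

with x̄ the time-averaged input trace, S̄ the normalized output spike
counts, Θ{h} the one-hot label, and ξ ~ Normal(0, N·α·e^w) drawn
independently per synapse, the second parameter being the **standard
deviation**.  The likelihood factor w(x̄ − α e^w) is a simplified STDP
window: potentiation while the input exceeds the weight-dependent
threshold α e^w, depression beyond it; its fixed point α e^w = x̄ is a
log-template of the input (w* = ln(x̄/α)), i.e. the converged network is
a matched filter for its class.  The noise scale grows exponentially
with the weight — the analogue of larger dendritic spines fluctuating
more — and with the noise off the rule is the exact deterministic
gradient scheme used as the baseline arm.

A per-bin STDP mode (`stdp_mode="per_bin"`) replaces the aggregated
factor with Σ_t w(x_i(t) − α e^w)(Θ{h_k}·ρ_tgt·dt − s_k(t)), reading the
input trace at the actual output spike times.  Its bin-summed drift
carries the window's spike mass (ρ_tgt·T ≈ 20), so the noise term is
scaled by the same mass to preserve the noise-to-drift ratio of the
aggregated form.  The aggregated mode is the default; the per-bin mode
converges to a smaller-weight fixed point at which the noise-sensitive
regime (below) is never entered.

## Parameters

| parameter | default | meaning |
|---|---|---|
| N | 1000 | sample-count constant scaling likelihood and noise |
| α | e⁻⁶ | rate scale of the implicit Poisson input model |
| b | 10⁻⁴ | learning rate (the larger of the two standard choices; the reduced-scale run presents ~5× fewer samples than the full-scale one) |
| μ, σ | 0, 1 | Gaussian prior on θ |
| θ0 | 3 | weight offset; initial weights ≈ e^(θ−3) |
| dt_update | 1 | effective step length per presentation |
| R_total | 100 Hz | output WTA rate budget (~20 spikes per window) |
| T, dt | 200 ms, 1 ms | presentation window and simulation bin |
| r_max, r_bg | 80, 5 Hz | tuning-curve peak and background rates |
| σ_tc | 0.2 | tuning width (feature units) |
| θ clip | [−10, +5.75] | see "Runaway direction" below |

## Numerical integration

The likelihood drift is exponentially stiff in θ near its equilibrium
(local relaxation rate ~ b·N·w²·x̄), so each presentation's update is
integrated in Euler sub-steps of at most 0.5 with the drift recomputed
per sub-step, and every sub-step increment is clipped elementwise to
±0.25 (a trust region; the capped events are overshoots of the
mean-reverting STDP factor).  The noise is drawn once per presentation
at the entering weight scale and spread uniformly over sub-steps, so its
total contribution per presentation is exactly b·dt·ξ (or b·√dt·ξ under
the optional Wiener scaling).  Exponent arguments are capped at 60 so
that even a parameter pinned at the clip bound yields finite drift.

## Runaway direction and the role of noise

The supervision factor (Θ{h} − S̄) makes the STDP fixed point one-sided:
on the label row (error ≥ 0) the equilibrium α e^w = x̄ is stable, but on
a row that fires *wrongly* (error < 0) the same point is unstable from
above — a synapse whose weight exceeds ln(x̄/α) for the current stimulus
receives a positive-feedback kick.  Since trained template weights reach
ln(x̄_max/α) ≈ 6.3 while the background-input flip point is ≈ 3.3, any
well-trained row that misfires pushes its own template weights upward.
The θ ceiling of +5.75 caps weights slightly above the strongest-input
equilibrium: runaway rows pin at the ceiling instead of diverging, and
they form stable misclassification basins ("trapped" configurations with
positive Hessian-trace certificate).  A pinned row that is currently
silent receives no likelihood drift at all; without noise only the weak
prior pull (~b·θ/σ² per step) can move it, which takes thousands of
presentations.  The weight-dependent noise, whose standard deviation
N·α·e^w is large precisely at such weights, diffuses pinned rows back
below the flip point within tens of presentations.  This trap-and-rescue
asymmetry is the mechanism behind the with-noise > without-noise
accuracy ordering that the comparison experiments measure, and it is the
same configuration class the strict-saddle certificate counts.

## Synthetic sensory environment

Ten classes are Gaussian clusters of 3-D points: cluster means drawn per
coordinate from a normal with mean 0.5 and **variance** 0.2 (std ≈
0.45), covariances 0.04·I + 0.01·ξ with ξ i.i.d. standard normal,
symmetrized and eigenvalue-clipped to the nearest PSD matrix.  The
variance reading is deliberate: under it an ideal observer (quadratic
discriminant with the true parameters) reaches accuracy in the low 80s —
the regime in which the well-trained network operates — whereas reading
0.2 as a standard deviation produces clusters so overlapped that the
Bayes limit itself falls below 50%, beneath the accuracies the
comparison is supposed to resolve.  A `scale_is_std` flag restores the
other reading.  Datasets are balanced (class counts differ by ≤ 1) and
shuffled.

Input neurons each watch one random coordinate with preferred values ~
Uniform(−0.5, 1.5), covering ±2 standard deviations of the feature
distribution; narrower coverage (e.g. the unit interval) leaves tail
stimuli encoded only by background firing and caps even an ideal decoder
of the rate code near 50%.

What the generator does *not* emulate: temporal structure within a
presentation (rate coding only), input correlations, refractoriness,
heterogeneous tuning widths, or any real-sensor noise; passing
comparisons here show the learning rule and noise mechanism behave as
described on well-specified Gaussian category tasks, not that they reach
any particular accuracy on natural data.  Loaders for MNIST/CIFAR-10
raw formats are provided as untested conveniences, out of the core
scope.

## Three-layer network

The hidden layer is a second WTA group (J neurons, own budget).  The
output layer applies the same sampling rule with hidden EPSP traces as
inputs; its applied increment dθ^L is transported to the hidden layer as
dθ_ji = (β/α)·x̄_i·(dθ^L_kj + dθ^L_mj), with k the neuron that fired
most and m the desired neuron.  Three choices here were genuinely open
and are set as follows:

- **Hidden offset θ0 = 2** (vs 3 for the output layer): with the
  standard offset the untrained hidden WTA fires near-uniformly and
  transmits almost no stimulus information; the smaller offset gives
  dispersed potentials and a sparse, selective random-feature code.
- **R_hidden = 1000 Hz**, the saturation of the one-spike-per-bin
  scheme: hidden winners then fire at rates comparable to tuned input
  neurons, so the output layer sees traces on the scale its rule is
  calibrated for.
- **β = 0.01·α**: the outer-product hidden update has a strong
  rich-get-richer mode (responding units get their active inputs
  potentiated and respond more); gains near β = α let a few hidden units
  capture the code within a few thousand presentations and collapse
  accuracy to chance.  The small default keeps hidden plasticity a
  gentle refinement of the random feature map.  A `center_hidden_update`
  option subtracts the hidden-mean of the credit vector; it mitigates
  but does not remove the capture mode.

At reduced scale (J = 100) the hidden bottleneck costs roughly a dozen
points of linearly decodable information relative to the raw encoding,
so the three-layer network does not reach two-layer accuracy at equal
presentation counts; the with-noise > without-noise ordering still
holds through the output layer's trap-and-rescue dynamics.

## Strict-saddle diagnostics

For a parameter configuration θ and one input, the Hessian trace of the
objective decomposes as A + B + C with A = −K·I/σ², B = Σ(θ−μ)/σ², and
C = Σ_k Σ_i w·α·e^w·(S_k − Θ{h_k}); A+B+C > 0 certifies a strict saddle
(some eigenvalue must be positive).  C is the product of
misclassification mass and the weight-exponential factor, so certified
configurations are exactly confident misclassifications by heavy rows —
the trapped basins described above.  The pipeline counts certified
(snapshot, input) pairs using convergence-stage snapshots (evenly spaced
tail iterations) from each arm of a comparison, with S_k realized as the
normalized per-window spike count (a per-bin mode exists; the window
statistic is consistent with the aggregated drift).  The reduction rate
(S2 − S1)/S2 summarizes how many certified configurations the noise
removed.

## Experiment profiles and problem sizes

`ExperimentConfig.full_synthesis()`: I = 1,000 input neurons, 14,400
training / 1,000 test samples, 10 matched-seed run pairs.
`ExperimentConfig.reduced_synthesis()` — the profile used by the test
suite and `scripts/acceptance.py` — scales this to I = 200, 3,000
training samples and 3 run pairs, which one laptop core completes in a
few minutes.  Each run pair shares data, tuning bank, initialization and
forward randomness between its noise-on and noise-off arms through
separately spawned RNG streams, so the arms differ only in the noise
term; the noise-off arm is bitwise reproducible.

## Known limitations

- The trap-and-rescue gap between arms has run-to-run variance of
  several accuracy points at the reduced scale; three run pairs resolve
  its direction reliably, not its full-scale magnitude.
- The three-layer transport rule is the weakest part of the model: it
  provides no per-hidden-unit error signal, so hidden learning is either
  negligible or destructive outside a narrow β range.
- Evaluation samples output spikes (~20 per window), costing 2–4
  accuracy points relative to an argmax-of-potential readout; this is
  intentional, as prediction is defined by spike counts.
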