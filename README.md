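# schurnet

Tools for studying **non-normal transient amplification** in recurrent
rate networks, for computational neuroscientists who want direct,
independent control over the two ingredients that shape a network's
transient dynamics: its **eigenspectrum** and its **hidden feedforward
structure**.

## The model

The network state `x(t)` (one entry per neuron) follows

```
tau dx/dt = -x + W f(x),        r = f(x)
```

with `tau = 200 ms` and `f` either the identity (linear analysis) or a
saturating tanh bounded in `(-r_min, r_max) = (-1, 4)` Hz. Rather than
sampling `W` directly, the package works in the real Schur picture

```
W~ = Lambda + T
```

where `Lambda` is block diagonal (each complex pair `alpha ± i beta` is a
2×2 block) and `T` is strictly upper triangular. `||Lambda||_F` (the
*spectrum norm*) and `||T||_F` (the *feedforward norm*) can be set
independently, which lets you dial the network through weak, short- and
long-transient amplification regimes and relate them to eigenvector
geometry (pairwise angles, effective rank `erank(V) = exp H(p)` of the
normalised singular values).

Amplification is quantified through the evoked energy
`E(a) = 2 tau ∫ ||x(t)||² dt`, a quadratic form `aᵀQa` whose operator `Q`
solves `AᵀQ + QA = -2 tau I` with `A = (W - I)/tau`; its iteratively
deflated eigenbasis is the ordered orthogonal set of maximally amplifying
unit inputs.

On the biological side, the package builds sparse Dalean
(excitatory/inhibitory) matrices with base weight
`w0 = R_outer / sqrt(p(1-p)[1+(I/E)²]/2)`, predicts the inhibitory
outlier `gamma ≈ (p w0 sqrt(N)/2)(1 - I/E)` and the inner/outer spectral
radii, and stabilises them into stability-optimised circuits (SOCs) by
gradient descent on a smoothed spectral abscissa that modifies inhibitory
weights only.

## A worked example

`examples/04_inhibition_switch.py` stabilises an inhibition-dominated
circuit (100 neurons, I/E = 40) and then weakens all inhibitory synapses
by 1/40:

```
stabilised in 188 iterations, spectral abscissa = 0.501
I/E = 40:  38.0% of conditions amplified, largest max norm = 7.47
I/E =  1:   0.0% of conditions amplified, largest max norm = 1.00
```

With strong global inhibition, 38% of the orthogonal optimal initial
conditions are transiently amplified (their response norm exceeds 1.5
despite unit input and a stable spectrum); after scaling inhibition down
the response never exceeds its initial norm — global inhibition acts as
a switch for amplification, and *weakening* inhibition *removes* it.

The other examples build an upper-triangular amplifier and count its
amplified directions (`01`), walk through the weak/long transient
regimes of the nonlinear network (`02`), compare a Dalean spectrum
against its closed-form outlier and radii (`03`), and show how the
imaginary diameter controls eigenvector alignment and dimensionality
(`05`). Figure-level parameter sweeps are available as presets:

```python
from schurnet import preset_config, run_sweep
rows, summary = run_sweep(preset_config("fig3A", realisations=5, seed=1))
```

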