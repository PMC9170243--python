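# v4popcode

Attention improves visual perception, and one of its most reliable
neurophysiological correlates is a *decrease in mean correlated
variability* (spike-count correlations, r_SC) in visual area V4.  That
observation is puzzling for standard population-coding theory: an optimal
*specific* decoder — a linear readout tuned to one fine discrimination —
can largely ignore shared fluctuations, so why should behavior track them?
One resolution is that observers instead use a *general* decoding strategy:
a single, fixed readout good for the whole range of stimuli, whose weights
necessarily depend on the same tuning-similarity structure that shapes
correlated variability.

`v4popcode` implements the computational machinery of this hypothesis for
orientation coding in the V1→V4 hierarchy, end to end and at desk scale:

* a **spiking circuit model** of attention — an orientation-mapped
  Gabor/Poisson V1 layer-4 front end driven by noisy Gabor images
  (Ornstein–Uhlenbeck pixel noise), feeding recurrent exponential
  integrate-and-fire (EIF) excitatory/inhibitory layers for V1 L2/3 and V4;
  attention scales the V1→V4 feedforward gain γ from 20 to 23 mV and
  depolarizes V4 inhibitory cells by μ_i up to 0.5 mV/ms;
* a fast **ring surrogate**: orientation-tuned populations with a rank-1
  multiplicative ("radial") shared fluctuation that attention shrinks;
* the **decoders**: the optimal specific (local linear) decoder with
  bias-corrected linear Fisher information

  Î = (Δf̂/dθ)ᵀ Σ̂⁻¹ (Δf̂/dθ) · (2Ntr−N−3)/(2Ntr−2) − 2N/(Ntr dθ²),

  and the optimal general (complex linear) decoder
  ẑ = wᵀ r with w = ⟨Σ(θ)+ffᵀ⟩θ⁻¹⟨f e^{i2πθ}⟩θ and information
  Îᵍ = [1/Var(arg ẑ/2π − θ)]·(Ntr−N−2)/(Ntr−1);
* **shared-variability statistics**: pairwise noise/signal correlations and
  maximum-likelihood factor analysis x ~ N(μ, LLᵀ+Ψ) with the eigenvalues
  of LLᵀ summarizing low-dimensional co-fluctuations;
* a **session pipeline** reproducing the monkey-style analyses on synthetic
  cued change-detection days: unit inclusion (rate > 10 Hz and Wilcoxon
  p < 1e−10 vs. baseline), 60–260 ms rate and 60–130 ms decoder windows,
  stimulus-trained *specific* and choice-trained *subject's* decoders
  scored by leave-one-out cross-validation against stimulus identity, the
  generality ladder over subsets of change amounts, decoder-performance
  versus r_SC correlations with Tukey outlier exclusion, and Williams'
  procedure for comparing dependent correlations.

No external data are required: every analysis runs on the synthetic
generators, which plant known structure (a readout axis, a shared-noise
amplitude, tuning curves) so that recovery can be verified exactly.
See `docs/methods.md` for models, assumptions, and limitations.

## Worked example

Specific- and general-decoder information on the ring surrogate, for the
unattended (level 0) and attended (level 1) states:

```python
import numpy as np
from v4popcode.synthetic import RingModelParams
from v4popcode.workflows import ring_information_sweep, information_ratios

ring = RingModelParams(n_units=200, radial_noise_sd=0.25)
sweep = ring_information_sweep(ring, attention_levels=(0.0, 1.0),
                               pop_sizes=(50, 100, 200), seed=0)
print(information_ratios(sweep).to_string(index=False))
```

```
 n_units  ratio_specific  ratio_general
      50        1.066733       1.324920
     100        1.015488       1.464498
     200        1.167230       1.770341
```

Each row is one population size; the columns are the attended/unattended
information ratios.  The specific decoder barely benefits from attention
(ratios near 1): the shared "radial" fluctuation is orthogonal to the local
discrimination direction, so shrinking it adds little fine-discrimination
information.  The general decoder benefits strongly (ratios ≈ 1.3–1.8):
low-gain trials corrupt the decoded angle everywhere on the ring, so
quenching the shared gain pays off for a fixed global readout — the core
asymmetry the general-decoder hypothesis builds on.

The same quantities are available from the command line
(`v4popcode sweep`, `v4popcode decode`, `v4popcode session`,
`v4popcode simulate`, `v4popcode stats`), all seeded and configurable
through a JSON config.

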