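# ecdcm — effective connectivity for resting-state BOLD

`ecdcm` estimates **effective connectivity** — the directed coupling one
brain region exerts over another — from resting-state fMRI, and carries
those estimates through a full group analysis. It is aimed at
neuroimaging researchers studying how network coupling degrades across
clinical stages (the built-in synthetic cohort emulates a CN → EMCI →
LMCI → AD progression over seven default-mode / salience / executive
nodes), and at methodologists who want an end-to-end, fully seeded
spectral-DCM-style pipeline they can validate against oracles.

## The model

Node activity follows a linear stochastic differential equation

    dx/dt = A x + v,        v ~ power-law spectrum α f^(−β)

where `A[i, j]` (Hz) is the influence of node *j* on node *i*
(columns → rows) — the estimand. Activity drives a Balloon hemodynamic
model per node (vasodilatory signal, inflow, venous volume v,
deoxyhemoglobin q) with BOLD readout

    y = V0 [ k1 (1 − q) + k2 (1 − q/v) + k3 (1 − v) ].

Subject-level estimation fits the model-implied cross-spectral density
S_y(f) = |h(f)|² H(f) G_v(f) H(f)ᴴ + G_e(f) I to the Welch-estimated CSD
of the data by **variational Laplace** (Gaussian posterior, free-energy
ascent). Group-level **parametric empirical Bayes** pools the subject
posteriors under a random-effects model, and **Bayesian model
reduction** scores the on/off pattern of every connection analytically,
yielding posterior connection probabilities thresholded at
{0, 0.5, 0.75, 0.95, 0.99}. Downstream, per-connection one-way ANOVA
with Bonferroni pairwise contrasts and forward stepwise regression of
cognitive scores (MMSE/CDR-like) on connection strengths complete the
analysis. `docs/methods.md` has the details.

## Worked example

Simulate one subject from the default 7-node ground truth, invert it,
and look at the posterior:

```python
import numpy as np
from ecdcm import (BASE_A, CouplingModel, HemodynamicParams,
                   NeuronalNoiseSpec, SpectralDCM, bold_timeseries)

model = CouplingModel(A=BASE_A)           # 7 nodes, L-PCC ... mPFC
noise = NeuronalNoiseSpec(amplitude_alpha=1e-3, observation_alpha=1e-8)
y = bold_timeseries(model, noise, HemodynamicParams(),
                    n_volumes=400, tr=3.0, dt=0.05, seed=7)

res = SpectralDCM.from_timeseries(y, tr=3.0).fit()
print(f"converged={res.converged} after {res.n_iterations} iterations, "
      f"F={res.free_energy:.1f}")
print("L-PCC -> R-PCC coupling:",
      f"{res.A_mean[1, 0]:.3f} +/- {res.A_sd[1, 0]:.3f} Hz "
      f"(truth {BASE_A[1, 0]:.3f})")
```

prints

```
converged=True after 34 iterations, F=466.4
L-PCC -> R-PCC coupling: 0.061 +/- 0.045 Hz (truth 0.070)
```

— the fit converged with a rising free energy (the evidence bound), and
the posterior for the left-to-right posterior-cingulate coupling covers
the generating value well within one standard deviation.

The full pipeline — synthetic cohort, per-subject inversion, per-group
PEB with thresholded networks, ANOVA and stepwise regression — runs from
a config:

```sh
ecdcm all --config run.yaml --out results/ --seed 7
```

writing the cohort manifest, per-subject posteriors, group matrices in
From/To/M/Var layout with connection probabilities, a threshold-grid
table (no-threshold + 4 levels per group), the ANOVA pairwise table and
stepwise summaries, plus a JSON provenance record; the same config and
seed reproduce every file byte-for-byte. Stage subcommands
(`simulate`, `extract`, `invert`, `peb`, `stats`, `report`) operate on
the same run-directory layout.

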