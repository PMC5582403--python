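# burstfit

Bayesian inference of stochastic transcription kinetics from time-resolved
population snapshots of single-molecule RNA FISH (smFISH).

smFISH gives, for each fixed cell, the number of mRNA molecules and the
number of active transcription sites (TS) — but only as static snapshots of
a population sampled before and after a stimulus. `burstfit` turns those
snapshots into posterior distributions over the kinetics of transcriptional
bursting: promoter activation (k1) and deactivation (k0) rates, basal and
active synthesis rates (mu0, mu1), with mRNA decay (delta) fixed to an
independently measured value. It is aimed at labs quantifying
stimulus-induced genes (e.g., neuronal immediate-early genes) in
post-mitotic diploid cells.

## Model and method

The default model is the two-state (telegraph) promoter with two
independent alleles. The cell state x = [rho1, m] (active alleles, mRNA
count) evolves by four reactions with propensities k1(2−rho1), k0·rho1,
mu0(2−rho1)+mu1·rho1, and delta·m. The chemical master equation
dP/dt = A(θ)P is solved exactly on the state space truncated at m ≤ M:

* pre-stimulus cells sit at the stationary law P* of A(θᵁ) (null-vector
  solve);
* post-stimulus distributions are P(τ) = exp(A(θˢ)τ) P*, where θˢ differs
  from θᵁ only in the parameters the stimulus is hypothesized to change;
* the data likelihood is a product of multinomials, one per sampled time
  point, scoring the observed per-cell states against the model
  distributions;
* the posterior P(θ|Y) ∝ L(Y|θ)P(θ) (flat prior with hard physiological
  bounds) is sampled by random-walk Metropolis; competing
  parameter–stimulus hypotheses are ranked by BIC, AICc, and DIC.

A synthetic-data module generates technical replicates by multinomial
sampling from the model's own distributions, and an independent Gillespie
SSA oracle validates the master-equation solvers. See `docs/methods.md`
for the numerics (banded stationary solve, uniformization, proposal
calibration) and assumptions.

## Worked example

Simulate a ground-truth experiment and re-infer its parameters:

```bash
burstfit simulate --preset k1_stim --n 1000 -M 200 --seed 1 --out snap.tsv
burstfit fit snap.tsv --stimulus-params k1 --delta 0.05 -T 10000 -M 200 \
    --seed 2 --replicas 1 --out-dir run_k1
burstfit summarize run_k1/chain_rep0
```

The `k1_stim` preset is a promoter whose activation rate jumps from
k1 = 0.01 to 1 min⁻¹ at the stimulus (k0 = 0.1 min⁻¹, mu1 = 2,
mu0 = 0.01 mRNA·min⁻¹, delta = 0.05 min⁻¹), sampled at t = 0, 5, 15,
25 min with 1000 cells per time point. The same experiment through the
library API (this is what `scripts/acceptance.py` runs) prints:

```
t2 (k1_U): mean=0.00991 sd=0.000506 95% CI=(0.008934, 0.0109)
t3 (k1_S): mean=0.9432  sd=0.037    95% CI=(0.874, 1.016)
t4 (k0):   mean=0.09812 sd=0.00432  95% CI=(0.08968, 0.1071)
t5 (mu1):  mean=2.007   sd=0.0118   95% CI=(1.985, 2.03)
```

Every posterior mean lands within a few percent of the generating truth
and every truth value lies inside its central 95% interval: the snapshots
alone constrain all four free kinetic parameters, including the 100-fold
activation jump. `burstfit compare run_a run_b ...` then ranks alternative
stimulus hypotheses (which parameters the stimulus touches) by all three
information criteria.

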