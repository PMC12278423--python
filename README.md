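# cardiograph

Typed temporal-graph modeling of multimodal cardiovascular time series.

Clinical cardiovascular records mix three kinds of information on one
timeline: continuous physiological state samples (heart rate, HRV, blood
pressure, autonomic proxies), discrete clinical events (arrhythmia alerts,
hypotension episodes), and intervention actions (drug doses). `cardiograph`
is a library + CLI for researchers who want to model such records jointly:
it builds a typed graph over each patient's trajectory, encodes it with
time-weighted graph attention and bidirectional recurrent fusion, and
trains the latent trajectories under a family of alignment and
regularization objectives, including a counterfactual simulation operator
for intervention effects. Everything runs on seeded synthetic cohorts with
known ground truth — no external dataset is required.

## Model

For patient *p*, states `x_t ∈ R^d` at times `T_p`, events `(τ_k, z_k)`
and actions `(ρ_j, u_j)` become nodes of a graph `G_p` with a temporal
backbone, window co-occurrence edges, and directed causal-prior edges
weighted `exp(−Δt/max_lag)`. The encoder computes

* typed init: `h_v⁰ = φ_x(x_t) | φ_e(z_k) | φ_a(u_j)` (one MLP per kind),
* attention propagation:
  `h_v^{l+1} = σ(Σ_{u∈N(v)} α_{uv} W^{(l)} h_u^{l})` with
  `α_{uv} = softmax_u(−λ·|t_v−t_u|·ψᵀ[h_u‖h_v])`,
* layer aggregation `h_v^agg = (1/L) Σ_l h_v^{(l)}` and gated context
  fusion `h̃_t = h_{x_t}^agg + Σ_{v≺t} γ_{v,t} h_v^agg`,
* the simulation operator
  `S(h,u,Δt) = h + η·e^{−λ_sim Δt}·tanh(W_s[h‖u]+b_s)`,
* attention pooling + forward/backward GRUs:
  `s_t = h̃_t + W_f[r_t‖b_t] + b_f`.

Training combines a forecast loss with cross-patient alignment
`Σ_t‖s_t^{(p)}−s_t^{(q)}‖²`, clinical-prior projection, arc-length
smoothness `∫‖γ'(τ)‖²dτ`, stage separation `Σ_{i<j} e^{−‖μ_i−μ_j‖²}`,
soft temporal alignment, intervention-orientation against an expected
response field `G(u,Δt)`, event attractors with anchor separation
`Σ 1/(‖c_i−c_j‖²+ε)`, graph-Laplacian smoothness `Tr(HᵀLH)`, and a hinge
relaxation of the latent-geometry constraint
`|d_lat(t₁,t₂) − Δ_obs(t₁,t₂)| ≤ ε`. See `docs/methods.md` for every
definition, default, and design decision.

## Worked example

```python
import numpy as np
from cardiograph import SyntheticCohortSpec, generate_cohort, build_graph
from cardiograph.synthetic import make_prior_table
from cardiograph.training import RunConfig, train, evaluate, lvcf_baseline

spec = SyntheticCohortSpec(n_patients=10, steps=40, seed=3)
cohort, gt = generate_cohort(spec)
priors = make_prior_table(spec)
g = build_graph(cohort[0], priors, window=10.0)
print("patient", cohort[0].patient_id, "nodes:", g.kind_counts(),
      "edges:", len(g.edges))

cfg = RunConfig(seed=3, D=12, L=2, epochs=8, batch_size=5,
                curriculum=[(0, {})])
model, history = train(cohort, cfg, ground_truth=gt, priors_table=priors)
print("epoch 1 total: %.4f   epoch 8 total: %.4f"
      % (history[0].total, history[-1].total))
metrics = evaluate(model, cohort, cfg, ground_truth=gt, priors_table=priors)
print("forecast MSE: %.5f   persistence baseline: %.5f"
      % (metrics["rmse"] ** 2, lvcf_baseline(cohort)))
```

prints

```
patient p0000 nodes: {'state': 40, 'event': 3, 'action': 0} edges: 184
epoch 1 total: 0.5636   epoch 8 total: 0.4507
forecast MSE: 0.00388   persistence baseline: 0.00400
```

The first line shows the typed graph built for one patient (40 state
samples, 3 events, backbone + co-occurrence + causal edges). The total
weighted objective falls over training, and the learned 1-step forecast
already beats last-value-carried-forward persistence on this small
8-epoch run — the model has captured part of the oscillatory
heart-rate/blood-pressure coupling the generator embeds.

## CLI

```bash
cardiograph simulate --seed 1 --out data/            # cohort + ground truth + priors
cardiograph train    --config config.yaml --out run/ # checkpoint + loss history
cardiograph predict  --config config.yaml --checkpoint run/checkpoint.json --out pred/
cardiograph evaluate --config config.yaml --checkpoint run/checkpoint.json --out eval/
```

Configs are YAML mirroring `RunConfig` (unknown keys are rejected; `seed`
is mandatory). Cohorts travel as JSONL (one patient per line, byte-stable
round trips) or a states/events/actions CSV trio.

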