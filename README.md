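# smfret

Single-molecule FRET analysis of riboswitch conformational dynamics: from
donor/acceptor intensity traces to state populations, folding free energies,
dwell-time kinetics and ligand dose–response — with a ground-truth-preserving
trajectory simulator so every stage is testable without experimental data.

The package was built around the smFRET dissection of a guanidinium-responsive
transcriptional riboswitch, whose aptamer hops among three conformations
(unfolded / pre-folded / kissing-loop-folded, proximity ratios E ≈ 0.2 / 0.5 /
0.8 at 0.1 s frames), but every component is generic K-state machinery.

## What it computes

- **Proximity ratio** per frame, `E = I_A / (I_A + I_D)`, with photobleach
  detection and rule-based trace QC (`smfret.traces`).
- **Idealization**: a Gaussian-emission hidden Markov model fitted jointly to
  all traces of a condition by maximum-likelihood Baum–Welch, state count by
  BIC, per-trace Viterbi paths (`smfret.hmm`). Forward and Viterbi recursions
  are verified against exhaustive path enumeration in the test suite.
- **Kinetics**: dwell-time extraction with censoring flags, exponential
  lifetime MLE `τ̂ = mean(uncensored dwells)` with exact χ² confidence
  intervals (binned least-squares fit available), rate constants `k = 1/τ`,
  transition density plots (`smfret.kinetics`).
- **Thermodynamics**: occupancy and Gaussian-mixture state populations with
  bootstrap-over-molecules uncertainties, and relative free energies
  `ΔΔG_ab = −RT ln(P_b / P_a)` (R = 1.9872×10⁻³ kcal mol⁻¹ K⁻¹,
  T = 293.15 K default) (`smfret.thermo`).
- **Dose–response**: Hill and one-site (K_d) fits of titration tables by
  multi-start nonlinear least squares, and the co-transcriptional window
  summary of folded-fraction response vs nascent-RNA length
  (`smfret.dose_response`).
- **Simulation**: exact (Gillespie) continuous-time Markov trajectories,
  frame-clock emission with per-channel Gaussian noise and single-step
  photobleaching, ligand-coupled titration ensembles and read-through assay
  tables, all with stored ground truth (`smfret.simulate`).

Model objects follow the statsmodels convention: construct a model from data,
`fit()` returns a results object with estimates, uncertainties and a
`summary()`.

## Worked example

Simulate a three-state aptamer ensemble at its 2 mM Mg²⁺ kinetics
(τ = 0.69 / 0.11 / 0.40 s), idealize it, and read off populations, ΔΔG and
lifetimes:

```python
import smfret

model = smfret.three_state_model()            # unfolded <-> pre-folded <-> folded
ens = smfret.simulate_ensemble(model, n_traces=80, trace_length=400, seed=2024)
efret = [smfret.compute_efret(t) for t in ens.traces]

res = smfret.fit_hmm(efret, K=3, seed=0)
print(res.summary())

paths = res.decode(efret)
pops = smfret.state_populations(paths, res)
ddg = smfret.delta_delta_g(pops.fractions[0], pops.fractions[2])
print(f"P = {pops.fractions.round(3)}  ddG(folded vs unfolded) = "
      f"{ddg.delta_delta_g:+.3f} kcal/mol")

dwells = smfret.extract_dwells(paths, frame_interval=0.1)
print(smfret.fit_dwell_exponential(dwells, state=2).summary())
```

Output:

```
Gaussian-emission HMM (joint fit)
  states: 3   frames: 31926   logL: 25483.010   BIC: -50820.823
  converged: True in 23 iterations
  state    mean E    sd E    self-transition
      0    0.1989   0.0642   0.8968
      1    0.4999   0.0597   0.4438
      2    0.8015   0.0645   0.8103
P = [0.558 0.16  0.282]  ddG(folded vs unfolded) = +0.397 kcal/mol
state 2: tau = 0.5173 s [0.4933, 0.5431], k = 1.9332 1/s (1666 dwells, mle/exclude)
```

The recovered means sit on the generator's 0.2/0.5/0.8; the folded state is
less populated than the unfolded one at these kinetics, so its ΔΔG is
positive (+0.4 kcal/mol). The folded lifetime reads 0.52 s rather than the
generator's 0.40 s — the documented upward bias of frame-quantized dwells
when a neighbouring state's lifetime (0.11 s) is close to the 0.1 s frame
interval; see `docs/methods.md`.

Fitting a titration table is one call:

```python
law = smfret.TitrationLaw(midpoint=68.7, hill_n=1.0, floor=0.15, ceiling=0.85)
table = smfret.simulate_readthrough_assay(law, [1, 5, 20, 70, 300, 2000, 10000],
                                          n_replicates=3, noise_sd=0.02, seed=7)
fit = smfret.fit_hill(smfret.dose_response.TitrationTable(table))
print(fit.summary())
```

A thin CLI mirrors the pipeline stages (`smfret simulate / efret / idealize /
kinetics / populations / ddg / fit-hill / fit-binding`); run
`smfret --help`.

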