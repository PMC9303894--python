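# panelnet

Two-wave symptom network analysis for ordinal questionnaire panels.

Psychopathology research increasingly models a disorder not as the
downstream effect of one latent cause but as a network of symptoms that
activate each other. `panelnet` implements the full analysis pipeline for a
two-wave panel of this kind — e.g. the 22-item Impact of Event Scale–Revised
(IES-R, 0–4 Likert responses) administered to the same participants at
baseline and one year later:

- **Cross-sectional networks per wave.** A Gaussian graphical model (GGM)
  whose edges are regularized partial correlations: the graphical lasso is
  solved over a descending penalty path and the model minimizing the
  extended Bayesian information criterion,
  `EBIC(λ) = −2ℓ + E·log n + 4γ·E·log p` (E = nonzero edges, default
  γ = 0.5), is selected. Edge weights are
  `w_ij = −ω_ij / √(ω_ii·ω_jj)` from the estimated precision matrix Ω.
- **Expected influence centrality.** `EI(i) = Σ_j w_ij`, the signed one-step
  sum of a node's edge weights, with z-standardized reporting.
- **Network comparison test (NCT).** A permutation test of equal overall
  connectivity `S = |Σ|w_a| − Σ|w_b||`, re-estimating both networks for
  every permutation of the pooled participants.
- **Cross-lagged panel network (CLPN).** One lasso regression per wave-2
  symptom on all wave-1 symptoms, penalty selected by 10-fold
  cross-validation; the diagonal of the coefficient matrix holds the
  autoregressive paths. Cross-lagged in/out expected influence (IEI/OEI) are
  the column/row sums excluding the diagonal.
- **Stability analytics.** Nonparametric bootstrap CIs per edge (1,000
  replicates), edge/centrality difference tests, and the case-drop
  correlation-stability coefficient (CS ≥ 0.50 = strong stability).
- **Data handling.** Wide-CSV panel I/O with validation, joint two-wave
  complete-case filtering, and single imputation by predictive mean matching
  (chained equations, 5 donors).
- **Synthetic data with known truth.** A generator that draws a sparse,
  subscale-clustered precision matrix, a sparse cross-lag matrix,
  discretizes through per-item thresholds anchored to realistic item means,
  and injects missingness at random driven by the wave-1 latent total — so
  every estimator has a parameter-recovery test surface.

## Worked example

```python
import panelnet as pn

# simulate a study-like panel: 22 items, two waves, n = 698
spec = pn.study_like_spec(seed=1)
data, latent = pn.simulate_panel(spec, n=698, seed=2)

net1 = pn.fit_ggm(data, "baseline")
net2 = pn.fit_ggm(data, "followup")
print(net1.nonzero_edges, net2.nonzero_edges)
# 98 97

ei1 = pn.expected_influence(net1)
print(pn.rank_centrality(ei1)[:3])
# ['Nb1', 'In4', 'Av3']

edge_r, ei_r = pn.cross_wave_similarity(net1, net2, ei1, pn.expected_influence(net2))
print(round(edge_r, 2), round(ei_r, 2))
# 0.93 0.96

eff = pn.paired_t_hedges(data)
print(eff.degrees_of_freedom, round(eff.t_statistic, 1), round(eff.hedges_g, 3))
# 697 -23.9 -0.928
```

The two waves share one generating network, so their estimated edge lists
correlate strongly (0.93) and the expected-influence profiles even more so
(0.96); the built-in latent decline at follow-up shows up as a negative
paired effect on the total score (Hedges' g ≈ −0.93 here). With ~100 of the
231 possible edges surviving regularization at n = 698, the fitted networks
sit in the sparsity regime typical of published symptom networks.

The same pipeline runs from the shell:

```sh
panelnet simulate --n 698 --seed 1 --missing-rate 0.05 --out panel.csv --truth-out truth.json
panelnet run panel.csv --out report.json
panelnet fit-ggm panel.csv --wave baseline --out baseline_net
panelnet compare panel.csv --permutations 1000 --out nct.json
```

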