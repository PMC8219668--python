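# kinscale

Kinetic scaling relations for interfacial enzymes.

Cellulases hydrolyze insoluble cellulose, so their kinetics are
heterogeneous: substrate is specified by mass load S₀ (g/L) and the
apparent Michaelis constant K_M shares that unit. Across structurally
diverse cellulases, ln k_cat scales linearly with ln K_M — enzymes that
bind the substrate more tightly turn it over more slowly. `kinscale`
implements that analysis as a tested pipeline for enzyme kineticists
and protein engineers:

1. **Michaelis–Menten fitting** — per-enzyme (k_cat, K_M) from
   quasi-steady-state rates v_ss = E₀·k_cat·S₀/(S₀+K_M), with
   heteroscedasticity-robust uncertainties.
2. **Free-energy mapping** — relative binding and activation energies
   against a reference enzyme:
   ΔΔG°_B = RT·ln(K_M/K_M,ref), ΔΔG‡ = −RT·ln(k_cat/k_cat,ref).
3. **LFER estimation** — the scaling line of ln k_cat on ln K_M with
   iterated ±2.5σ studentized-residual outlier rejection, 95%
   confidence/prediction bands, Φ = −slope, and classification of the
   energetic regime (uniform binding Φ=0, ground-state stabilization
   Φ=−1, transition-state stabilization |Φ|→∞).
4. **Volcano analysis** — the LFER turned into a rate model
   v_ss(K_M) = E₀·A·K_M^a·S₀/(S₀+K_M) with a = −Φ, whose interior
   maximum K_M,opt = S₀·a/(1−a) embodies the Sabatier principle:
   intermediate binding strength is optimal.
5. **Binding-energy calibration** — a linear map from externally
   computed binding energies to the experimental scale, and prediction
   of (K_M, k_cat) for uncharacterized enzymes from computed energies
   alone.
6. **Synthetic data** — generators for scaling-line ensembles, noisy
   triplicate rate tables, and a mechanistic three-step
   (association/hydrolysis/dissociation) simulator whose
   transition-state coupling c yields Φ = c − 1 exactly.

See `docs/methods.md` for the model, numerical choices, and what the
synthetic generators do and do not emulate.

## Worked example

Generate a synthetic 83-enzyme study and analyze it end to end:

```bash
cat > config.yaml <<'YAML'
ensemble:
  n_enzymes: 83
  seed: 11
measurement:
  seed: 12
analysis:
  reference_enzyme_id: SYN01
YAML

kinscale synth --config config.yaml --out synth
kinscale pipeline synth/rates.csv --config config.yaml --out run
```

```
[synth] 83 enzymes, 83 rate tables -> synth
[pipeline] fitting Michaelis-Menten parameters
[pipeline] slope=0.7577 phi=-0.7577 (intermediate) -> run
```

`run/scaling.csv` holds the fitted line:

```
slope_a,intercept_lnA,phi,se_slope,se_intercept,r_squared,n_used,n_outliers,outlier_ids
0.75768093447471,-0.023130394100416986,-0.75768093447471,0.023457864068574173,...
```

The generating slope was 0.74; the fit recovers 0.758 ± 0.023 from the
noisy rate data, flags 5 planted sub-line outliers, and reports
Φ = −0.758 — an `intermediate` regime annotated `gs_dominated`:
kinetic differences between these enzymes are mostly differences in
ground-state (binding) stabilization, with the transition-state energy
nearly common. `run/volcano_curves.csv` contains the predicted
rate-vs-K_M curves at five loads with the analytic optima marked; at
a = 0.74 the optimum sits at K_M,opt ≈ 2.8·S₀, i.e. the fastest enzyme
at a given load binds about threefold weaker than the load.

The same steps are available as library calls (`fit_all`,
`run_pipeline`, `fit_scaling`, `optimal_km`, …):

```python
import kinscale as ks

ens = ks.generate_lfer_ensemble(ks.EnsembleSpec(seed=11))
rates = ks.generate_rate_tables(ens, ks.MeasurementSpec(seed=12))
params = ks.fit_all(rates)
fit = ks.fit_scaling(params)
print(fit.slope_a, fit.phi, fit.outlier_ids)
print(ks.optimal_km(10.0, -fit.phi))   # optimal K_M at 10 g/L load
```

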