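# enantiosep

Analytics for chiral-HPLC enantioseparation screens of proton pump
inhibitors (omeprazole, rabeprazole, lansoprazole) on polysaccharide
chiral stationary phases (CSPs) in polar organic mode — and, more
generally, for any screening campaign that records retention factors,
resolutions, and enantiomer elution orders across CSP × eluent
conditions.

The package covers five connected analyses:

1. **Screening metrics.** Retention factor `k = (tR − t0)/t0`,
   selectivity `α = k2/k1`, resolution `Rs = 2(t2 − t1)/(w1 + w2)`, and
   the *directed* resolution (Rs signed negative when the S enantiomer
   elutes first). Aggregation yields success rates, baseline-separation
   counts (`Rs > 1.5`), sum-Rs rankings, and an exhaustive taxonomy of
   enantiomer-elution-order (EEO) reversals along the backbone,
   substituent, and mobile-phase axes.
2. **Van 't Hoff thermodynamics.** Regression of `ln k` (and `ln α`) on
   `1/T` gives transfer enthalpies/entropies and the enantioselective
   differences Δ(ΔH°), Δ(ΔS°), from which follow
   `Δ(ΔG°)(T) = Δ(ΔH°) − T·Δ(ΔS°)`, the isoenantioselective temperature
   `T_iso = Δ(ΔH°)/Δ(ΔS°)` (where the EEO reverses), and the
   enthalpy/entropy-control index `Q = Δ(ΔH°)/(T_ref·Δ(ΔS°))`.
3. **Retention hysteresis.** For composition sweeps of mixed eluents,
   the hystereticity `υ = k_forward/k_reverse` per enantiomer and the
   ratio `υ_R/υ_S`, whose position relative to 1 determines — per the
   separated (case A) or co-eluting (case B) forward branch — what the
   reverse branch can have done to the separation (selectivity change,
   coelution, or EEO reversal).
4. **Multivariate system comparison.** A systems × (directed Rs, Q,
   Δ(ΔG°) per analyte) feature matrix feeds pairwise-complete Pearson
   correlation, hierarchical clustering on standardized features, PCA
   with per-variable cos², and a deterministic medoid-based selection of
   a minimal representative CSP panel.
5. **Resolution prediction.** Repeated (3-fold × 5) cross-validated
   regression of directed resolution from system encodings,
   thermodynamic features, and RDKit molecular descriptors, with a
   random forest and an L2-regularized feedforward network.

A synthetic-data generator produces screening tables, temperature
series, and hysteresis loops with exactly known ground truth, so every
stage is validated by parameter recovery.

## Worked example

```python
import enantiosep as es

table = es.load_table1()          # packaged 7 CSP x 4 eluent x 3 PPI screen
s = es.screening_summary(table)
print(f"measurements: {s.n_total}   separated: {s.n_separated}   "
      f"success rate: {s.success_rate:.1f}%   baseline (Rs > 1.5): {s.n_baseline}")
for analyte, (rs, csp, eluent) in s.max_rs_by_analyte.items():
    print(f"best {analyte:12s} Rs = {rs:.2f}  on {csp}/{eluent}")

series, truth = es.gen_vant_hoff_series(es.SynthConfig(seed=1, sigma_lnk=0.01))
th = es.enantio_thermo(series)
print(f"ddH = {th.ddH:.0f} J/mol (true {truth['ddH']:.0f})   "
      f"ddS = {th.ddS:.2f} J/(mol K) (true {truth['ddS']:.2f})")
print(f"T_iso = {th.T_iso:.1f} K   Q = {th.Q:.2f}   control: {th.control}")
```

prints

```
measurements: 84   separated: 59   success rate: 70.2%   baseline (Rs > 1.5): 38
best omeprazole   Rs = 9.91  on AD/MeOH
best rabeprazole  Rs = 6.16  on Cell4/MeOH
best lansoprazole Rs = 3.26  on Cell4/MeOH
ddH = 14556 J/mol (true 14486)   ddS = 46.56 J/(mol K) (true 46.38)
T_iso = 312.6 K   Q = 1.05   control: mixed
```

Of the 84 screening measurements, 59 achieve enantiorecognition (70%),
38 reach baseline separation, and the best single conditions per analyte
are read directly off the table. The van 't Hoff block fits a noisy
synthetic enantiomer pair and recovers the generating Δ(ΔH°)/Δ(ΔS°)
within ~0.5%; the fitted `Q ≈ 1` flags a mixed enthalpy/entropy-controlled
separation whose predicted EEO reversal temperature (312.6 K) falls just
inside a 10–40 °C operating window.

## Command line

```sh
enantiosep screen-summary                      # packaged screening table
enantiosep simulate hysteresis --seed 4 --out loops/
enantiosep hysteresis --input loops/hysteresis_loop.csv --threshold 0.05
enantiosep multivariate --k 5 --linkage complete
enantiosep run --config config.json --out results/
```

`enantiosep run` executes all configured stages and writes a manifest
(config hash, seeds, input digests, per-stage status) for reproducibility.

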