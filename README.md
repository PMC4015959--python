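# flavochar

Quantitative characterization of flavoprotein redox enzymes, built for the
standard biophysical work-up of an FMN-dependent NAD(P)H:acceptor
oxidoreductase (a flavodoxin-fold quinone/flavin reductase of the
NADPH-dependent FMN reductase family). Given plain-text instrument outputs
— fluorescence titration tables, two-wavelength equilibration time series,
initial-rate tables, stopped-flow traces, SEC marker tables and SAXS
curves — it extracts:

- **Flavin-binding thermodynamics** — K_d from the exact single-site
  (tight-binding) quadratic isotherm
  `C = ((P+L+K_d) − √((P+L+K_d)² − 4PL))/2`, then
  ΔG_b = RT ln(K_d/1 M), mutant ΔΔG_b, moiety contributions and fold
  changes.
- **Midpoint potentials** — deconvolution of dye-coupled reductive
  equilibrations and the Nernst plot of log([red]/[ox])ₑₙᵤ vs
  log([red]/[ox])_dye, slope n_F/n_D, with
  E_enz = E_dye + (ν/n_F)·intercept (ν = 59 mV/decade).
- **Steady-state kinetics** — Michaelis–Menten and global ping-pong bi-bi
  fits (`v = kcat·E·A·B/(K_a·B + K_b·A + A·B)`), specificity constants
  kcat/K_m, KIE and activity ratios, specific-activity → kcat conversion.
- **Transient kinetics** — single-exponential stopped-flow fits and the
  hyperbolic k_obs = k_max·S/(K_half + S) saturation analysis.
- **Oligomeric state** — SEC calibration → subunit count, and non-negative
  mixture-fraction fitting of a SAXS curve over supplied form factors.

A seeded synthetic-data module generates every input class with known
ground truth, so the whole pipeline is testable by parameter recovery.

## Worked example

Generate a synthetic dataset tree (ground truth recorded in
`manifest.json`), then run the analyses:

```
$ flavochar simulate --seed 5 --out fx
$ flavochar titrate fx/titration.csv --out res
Kd = 26.76 ± 0.53 nM (ok=True)

$ flavochar potentiometry fx/equilibration.csv --flavin-total-um 65 \
    --dye-total-um 40 --out res
slope = 0.997, E_m = -138.0 mV

$ flavochar pingpong fx/rates_pingpong.csv --enzyme-total-um 0.061 --out res
kcat = 47.51 s^-1, Ka = 30.7 µM, Kb = 104 µM (parallelism CV = 0.045)

$ flavochar stopflow fx/stopflow_manifest.json --out res
k_max = 146.2 s^-1, K_half = 6.33 µM

$ flavochar saxs-mix fx/saxs_mixture.dat fx/form_factors.dat --out res
dimer 9.0%, tetramer 91.0% (chi^2 = 0.95)
```

The fixtures were generated with 1–2% noise from ground truths of
K_d = 27 nM, E_m = −138 mV vs indigo carmine (−125 mV), ping-pong
(kcat, K_a, K_b) = (50 s⁻¹, 33 µM, 111 µM), stopped-flow
(k_max, K_half) = (147 s⁻¹, 6.4 µM) and a 9:91 dimer:tetramer sphere
mixture — each fit recovers its truth within the noise. The equilibration
slope near 1 is the diagnostic that both the enzyme flavin and the dye are
two-electron couples at true redox equilibrium.

`flavochar paper-checks` re-derives the worked reference numbers of the
study this pipeline reproduces (−138 mV from the −0.45 intercept,
−43.2 kJ mol⁻¹ from 27 nM, the 13.6 kJ mol⁻¹ phosphate contribution, the
244-fold riboflavin K_d change, 397 s⁻¹ from 1111 µmol min⁻¹ mg⁻¹ at
21 412 Da, and the 11 727 / 4 900 mM⁻¹ s⁻¹ specificity cells) and exits
nonzero if any check fails.

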