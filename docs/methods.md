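# Methods

`flavochar` implements the quantitative analyses of the standard biophysical
work-up of an FMN-dependent NAD(P)H:acceptor oxidoreductase. This note
records the models, the defaults and why, the numerical choices, and what
the synthetic-data generator does and does not emulate.

## Flavin-binding thermodynamics

Binding of free flavin to apoenzyme quenches flavin fluorescence, so a
titration of apoprotein into a fixed flavin solution traces the binding
isotherm. Because the fixed flavin (100 nM by default) is of the same order
as the dissociation constant of a tight complex (tens of nM), the usual
free≈total approximation is invalid; the emission is fitted with the exact
single-site mass balance,

    C = ((P + L + K_d) − sqrt((P + L + K_d)² − 4 P L)) / 2
    F = f_free (L − C) + f_bound C,

by nonlinear least squares over (K_d, f_free, f_bound). The quadratic model
was chosen over the hyperbolic excess-titrant approximation precisely
because ligand depletion is severe in this regime; in the hyperbolic limit
(K_d ≫ L) the two coincide, so nothing is lost for weak binders such as
riboflavin. Degenerate curves with no quenching signal are reported as
failures, never as a finite K_d; a K_d estimate that collapses onto the
zero bound is flagged as an upper limit. Dilution during titrant addition
is not corrected by default; a per-point dilution-factor column is applied
when supplied.

Gibbs energies use ΔG_b = R T ln(K_d/1 M) with R = 8.314 J mol⁻¹ K⁻¹ and
T = 298.15 K unless overridden (1 M standard state). ΔΔG_b is
mutant-minus-wild-type, positive for weakened binding; the additivity check
Σ(parts) − whole quantifies cooperativity among residue contributions, with
sign retained.

## Redox potentiometry

The midpoint potential of the enzyme-bound flavin is obtained by the
slow-equilibration method: a constant influx of reducing equivalents (the
xanthine/xanthine-oxidase system) reduces enzyme and reference dye together
while a mediator maintains a common solution potential. Per time point, the
two-wavelength absorbances are solved linearly for the oxidized
concentration of each couple under the closure constraint [ox]+[red]=total;
reduced flavin hydroquinone and leuco-dyes are taken as non-absorbing at
the analysis wavelengths by default (full 4×2 extinction matrices are
accepted). Singularity of the ox-minus-red submatrix is rejected with the
condition number reported. Fractions are clipped to [0, 1] and clipping
flagged.

The equilibration plot uses log₁₀([red]/[ox]) of the enzyme (ordinate)
against that of the dye (abscissa). With this orientation the Nernst
equation gives exactly

    slope = n_F / n_D,   intercept = n_F (E_enz − E_dye) / ν,

so the midpoint follows as E_enz = E_dye + (ν/n_F)·intercept. Plotting
log([ox]/[red]) instead flips the intercept's sign and would require the
subtraction form of the formula; the [red]/[ox] orientation was adopted
because it makes the widely used addition formula exact and round-trips the
generator's ground truth to numerical precision. The Nernst slope constant
defaults to ν = 59 mV/decade (the field's conventional rounded value at
25 °C) and is configurable; using 59.16 changes a typical intercept-derived
midpoint by well under 1 mV.

Regression points are restricted to oxidized fractions in (0.1, 0.9) for
both couples, because the variance of the log ratio explodes at the ends;
the window is configurable. Two n=2 couples only co-occupy this window when
their midpoints are within ~56 mV, which is why reference dyes are chosen
close to the expected enzyme potential. A fitted slope deviating more than
25% from n_F/n_D raises an equilibrium warning. Bundled dye references
(pH 7): indigo carmine −125 mV, phenosafranin −252 mV,
anthraquinone-2-sulfonate −225 mV, all treated as two-electron couples
(the anthraquinone n is not standardized in the sources used here; 2 is the
default and overridable).

## Steady-state kinetics

Initial velocities from A340 slopes: v (µM s⁻¹) = |slope|/(6.22·path)·1000/60.
Michaelis–Menten and ping-pong bi-bi fits are unweighted nonlinear least
squares (an optional 1/v² weighting flag exists for strongly
heteroscedastic data). Double-reciprocal plots are produced as diagnostics
only; parameters always come from the nonlinear fit. The ping-pong
parallelism statistic is the coefficient of variation of per-B-level
double-reciprocal slopes: identically zero under the ping-pong law (slopes
= Ka/Vmax regardless of B), and large for sequential ternary-complex data,
which the generator can also produce as a negative control. Specificity
constants are reported in mM⁻¹ s⁻¹ (Km in µM), and ratio quantities (KIE,
activity ratios) carry first-order (delta-method) standard errors when
input errors are supplied. Specific activity converts to kcat as
SA·M/60000 (µmol min⁻¹ mg⁻¹ × Da → s⁻¹).

## Transient kinetics

Stopped-flow traces are fitted to A(t) = offset + amplitude·e^(−k_obs t)
with initial guesses from a log-linear transform of the baseline-subtracted
signal. Traces are assumed trimmed past the instrument dead time; an
optional dead-time shift is applied before fitting. Flags: flat traces
(amplitude within noise → k_obs unidentifiable), under-sampling
(k_obs·t_max < 1), and residual-sign structure suggesting a second phase —
only a warning, since the model is deliberately single-exponential. The
k_obs–concentration dependence is fitted to k_obs = k_max·S/(K_half + S);
when every concentration is far above K_half the half-saturation constant
is flagged unidentifiable. The limiting k_max is the quantity comparable
(with temperature caveats) to the steady-state kcat when the reductive
half-reaction limits turnover; the package reports both and asserts nothing
about their ratio.

## Oligomeric state

SEC: ordinary least squares of log₁₀(mass) on elution volume over marker
proteins; apparent masses queried outside the marker range are flagged as
extrapolations; subunit count = apparent/monomer mass, two decimals. Two
markers define an exact line but bypass any quality control, so fewer than
three draws a warning.

SAXS: the measured curve of an oligomer mixture is modelled as
I(q) = c·Σ wᵢ Iᵢ(q) over supplied component form factors, with wᵢ ≥ 0 and
Σwᵢ = 1. The fit is a σ-weighted non-negative least squares on bᵢ = c·wᵢ
followed by normalization — equivalent to the constrained problem because
the model is homogeneous in (c, w). Goodness of fit is the reduced
χ² = Σ[(I−fit)/σ]²/(N−K) with K the number of components (one scale plus
K−1 independent weights). Weight uncertainties come from the linearized
covariance at the solution via the delta method and blow up, as they
should, when component profiles are nearly colinear (also warned via the
condition number). Form factors are inputs; computing scattering from
atomic coordinates is out of scope. The built-in analytic component is the
homogeneous sphere, [3(sin qR − qR cos qR)/(qR)³]²·R⁶ — the R⁶ keeps
forward scattering proportional to squared particle volume — with a series
branch below qR = 10⁻² where the closed form cancels catastrophically.

## Synthetic-data generator

Every consumed input class can be generated with known ground truth:
titrations (exact quadratic isotherm), reductive equilibrations, MM and
ping-pong rate grids, single-exponential traces, and sphere-mixture SAXS
curves with per-point σ. Noise is multiplicative Gaussian on the signal
(instrument-like relative error) with an optional absolute floor; the
default relative level is 2% where a level matters. Same seed ⇒
bit-identical output.

The equilibration generator assumes a constant electron influx with
instantaneous inter-couple equilibrium — the regime the analysis method
itself requires — and partitions the delivered charge Q(t) = min(influx·t,
capacity) by solving the common-potential balance with bisection
(`brentq`, xtol 10⁻¹⁰ mV). The mediator is not modelled explicitly; it is
what justifies the equilibrium assumption. Semiquinone intermediates,
photoreduction artifacts and enzyme inactivation are deliberately absent,
so passing recovery tests demonstrates estimator correctness under the
stated model, not robustness to those real-data pathologies. Likewise the
sphere form factors stand in for real oligomer profiles: they reproduce
the mixture-decomposition arithmetic, not protein shape detail.

Default design grids mirror the study conditions this package was built
around: 100 nM flavin with 0–1 µM apoprotein in 12 points; 65 µM enzyme
flavin vs 40 µM indigo-carmine-like dye with ~5 µM equivalents min⁻¹
influx over 40 min; bisubstrate grids with fixed co-substrate levels
10/20/50/100 µM and eight NADH levels log-spaced 5–640 µM (the NADH grid
is not prescribed anywhere, so a log-spaced span bracketing Ka was chosen
once); stopped-flow amplitudes of 0.1 absorbance over a 0.05 baseline
sampled 250 points to five time constants; SAXS on q ∈ [0.008, 0.2] Å⁻¹
(200 points) with sphere radii 24 and 30 Å approximating dimer and
tetramer volumes of a ~21 kDa-subunit protein.

## Problem sizes and numerical choices

Recovery studies use 100 seeded replicates (binding, exponential) or 20
(SAXS bias), sizes at which the medians they test are stable; grid oracles
in the test suite profile the single nonlinear parameter on a dense grid
and solve the conditionally linear parameters exactly, so they share no
code with the Levenberg–Marquardt path they check. All fits use lmfit's
Levenberg–Marquardt with asymptotic standard errors. Display rounding for
comparisons against published table cells rounds half away from zero
(396.5 → 397), not half-to-even.

## Known limitations

Single-site binding only (no cooperativity, no inner-filter corrections);
two-state redox couples only (no semiquinone/three-state unmixing);
single-exponential transients (second phases are flagged, not fitted); no
Guinier/P(r) or shape reconstruction on the SAXS side; SEC calibration
assumes the linear log-mass regime of the column.
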