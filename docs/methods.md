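# Methods

## The model

`raassim` implements a quantitative-systems-pharmacology (QSP) model of the
canine renin–angiotensin–aldosterone system (RAAS) under oral benazepril, and
a virtual-clinical-trial engine built on top of it. The dynamical core is a
24-state ODE system for one dog; all states are molar amounts (pmol), volumes
litres, time hours.

**Drug (benazeprilat) pharmacokinetics.** Oral benazepril is dosed as
benazepril HCl and converted to a molar amount with MW 460.96 g/mol; all
bioavailable drug is treated as the active metabolite benazeprilat.
Absorption is a continuous analogue of sequential zero-/first-order uptake:
a fraction `F0abs` (0.695) of each dose enters a two-stage chain at rate
`ka` (1.5 h⁻¹) — the "zero-order analogue" — and the remainder is absorbed
directly at the much slower `ka1` (0.0148 h⁻¹), which supplies the long
shallow tail of drug input between doses. Bioavailability `Fbio` scales both
paths. Disposition is a two-compartment mammillary model (free circulation
`fr`, volume `Vfr = Vpl + Vrn`; tissue `ts`) with an additional
non-specific plasma-protein binding pool (`ns`) inside the central
compartment and linear clearance `ClI` from free circulation.
Intercompartmental flows `Q` are converted to first-order rates by dividing
by the source-compartment volume.

**ACE inhibition.** Free-circulation and tissue ACE pools (split by
`FACEfr = 0.035`, total `ACEtotal`) follow the differential Michaelis–Menten
scheme for a competitive inhibitor: ACE binds angiotensin I (the substrate
`S`) reversibly (association `k_m1`, dissociation `k1`), catalysis of the
complex at `k2` produces angiotensin II one-to-one, and benazeprilat binds
the free enzyme reversibly (association `k_m3`, dissociation `k3`) without
being consumed. Enzyme totals are conserved exactly in each compartment
(`E + ES + EI = const`), a property the test suite verifies to < 10⁻⁶
relative along dosed trajectories.

**Angiotensin cascade.** AngI is produced at rate
`r_S · (1 + f(t))`, where `f(t) = δ₂₄ · cos((t − PRA)·2π/24)` is the
circadian modulation with peak clock time `PRA` (8.4 h, i.e. ~08:24) and
relative amplitude `δ₂₄` (0.292). AngI and AngII each occupy free and
tissue pools; AngII converts to Ang(1‑7) (rate `kII17`, the ACE2 /
alternative pathway), AngI converts directly to Ang(1‑7) at `kI17`, and
AngII converts to AngIII inside the renal sub-volume (`kII_III`, scaled by
`Vrn/Vfr` — aminopeptidase A is renally bound), with AngIII → AngIV at
`kIII_IV`. AngIII and AngIV live on a renal/plasma/tissue sub-circuit and
are cleared from plasma. Observed plasma concentrations divide
free-circulation amounts by `Vfr`; the benazeprilat observation sums free,
non-specifically bound and ACE-bound drug, and AngIII/AngIV observations sum
plasma and renal pools. A proportional residual-error model
(`C·(1+ε), ε ~ N(0, b²)`) is available for generating synthetic
observations; all trial summaries use noise-free predictions.

## Unit conventions and the two derived constants

The published parameter table mixes scales: concentrations are printed in
pmol/L, but the estimation was carried out with all concentrations in
µmol/L, so the enzyme total (`ACEtotal` = 0.0002), the AngI production rate
(`r_S` = 0.0117 h⁻¹-scale) and the bimolecular association constants live on
a micromolar amount scale. `derive_rates` converts everything to one
consistent system (pmol, L, h) via `amount_scale = 10⁶` and converts the
"scaled" per-second enzyme rate constants (`k1s`, `k2s`, `k3s`) to per-hour
via `rate_scale = 3600`.

Two quantities are not published and must be derived; both are fixed by
internal-consistency ("baseline-referencing") arguments, not by fitting:

1. **Bimolecular association `k_m1` (and `k_m3 = k_m1`).** The placebo
   response of the original engine is the baseline chronobiology function —
   the printed time-zero concentrations are a drug-free fixed point. We
   therefore require the printed AngII baseline to be stationary: with
   tissue transfers cancelling at equal concentrations, catalysis must
   balance AngII losses, `k2·ES₀ = P₀·Vfr·(ClP/Vfr + kII17 + kII_III·Vrn/Vfr)`,
   which pins the baseline ES occupancy (≈ 12.6 % of free-circulation ACE)
   and hence `k_m1` (0.620 pmol⁻¹h⁻¹ for the typical dog). The published
   association/catalysis ratio `kd` gives an independent estimate
   (`kd·k2/10⁶` = 0.410 pmol⁻¹h⁻¹, available as
   `association_mode="kd-ratio"`); the two agree to within 50 %, which we
   take as corroboration of the convention.
2. **Effective AngI production `r_S,eff`.** The default
   (`steady-state-constrained`) mode chooses the production rate that makes
   free-circulation AngI stationary at the baseline-anchored drug-free state
   with the circadian term at its zero crossing. For the typical dog this
   gives 11 491 pmol/h = 0.0115 µmol/h, within 2 % of the printed relative
   rate (0.0117 µmol/h) — a second, independent consistency check. The
   printed value is available as `mode="table-value"`.

## Population model

Individual dogs are realized from the typical values through diagonal
log-normal random effects (`φ = μ·e^η`, `η ~ N(0, ω²)`) for positive
parameters and logit-normal effects for the two bounded fractions
(`F0abs`, `Fbio`); ω values are the published IIV SDs, including the entries
pinned to the small exploratory value 0.030. `PRA` is drawn log-normally and
wrapped modulo 24 h so it remains a clock time. There are no covariate
effects (none were retained in the source analysis) and no random-effect
correlations. η = 0 reproduces the typical dog exactly; the suite checks
that sample medians of log-linked parameters recover their typical values to
2 % at n = 10⁴.

## Trial engine

A trial design holds one to four regimens (dose in mg/kg benazepril HCl,
interval, first-dose clock time, optional dose cap of 2 mg/kg q6h as in the
original application) plus an implicit placebo arm. One population is
sampled per design seed and **all arms share it** (matched individuals), so
between-arm contrasts are paired; the drug-free burn-in (default 10 days,
enough to reach the circadian limit cycle — verified to 10⁻³ relative
periodicity) is computed once per individual and reused across arms, which
is exact because arms differ only in dosing. Integration is piecewise
between dose events with LSODA and an analytic Jacobian; dose events add
mass to the absorption depots only. Trial runs default to
rtol 10⁻⁶ / atol 10⁻⁸ pmol, which reproduces the rtol 10⁻⁸ / atol 10⁻¹⁰
solution's day-20 AUEC to six significant figures while keeping a 2 000-
simulation protocol within minutes; model-level utilities default to the
tighter pair. Solver correctness is checked against a fixed-step explicit
RK4 oracle whose step size is set from the system's own spectral radius
(the stiffest mode, enzyme binding at high drug, is ~10⁵–10⁶ h⁻¹).

Two audit accumulators (cleared drug; depot mass lost to incomplete
bioavailability) are integrated alongside the 24 model states so drug mass
can be audited to 0.1 %.

## Effect analysis

The comparison statistic is the area under the effect curve (AUEC):
trapezoidal integration of an analyte's noise-free plasma concentration over
a window, with linear interpolation at window edges (default: day 20,
hours 480–504, by which dosing is at periodic steady state — day-19 vs
day-20 drug AUC agree within 1 %). Following the source convention, the
headline statistic is the percent difference between the **median** treated
AUEC and the **median** matched-placebo AUEC; the flanking 5th/95th
percentile columns summarize per-individual paired percent differences
(quantiles by linear interpolation of order statistics), and the paired
median is reported alongside so both conventions are visible. Prediction
bands are nested central intervals (5–95 % in 10 % steps) across
individuals. `relative_improvement(a, b) = 100·(|a|/|b| − 1)` compares two
placebo-referenced effect magnitudes.

## What the simulations do and do not show

The virtual population reproduces the *study conditions* of the source
analysis: nine-beagle-derived population parameters, 10-kg bodyweight,
continuous (un-rounded) doses, noise-free pharmacodynamic readouts. It does
not emulate assay error (available but off by default), co-medication,
disease states, age/breed effects, or the tablet-increment rounding of the
animal study (available via `round_to_mg`). Percent-difference endpoints are
robust to the absolute calibration of the linear downstream pools because
baseline factors cancel in treated/placebo ratios; they remain sensitive to
the enzyme-node conventions discussed above, which is the main structural
uncertainty of this reimplementation — the tissue-compartment micro-rates
(no dedicated tissue flow is published for the renal/plasma/tissue
sub-circuit) are reused from the free↔tissue flow, and with 96.5 % of ACE in
tissue the tissue AngI pool equilibrates well below its anchored baseline.
In practice the AngII suppression of the q12h arms and the dose-to-dose
improvement statistic reproduce the published medians closely, the
schedule rank-ordering and all effect signs reproduce exactly, while the
q24h classical-pathway medians come out ~5–10 points weaker than published
(the simulated trough inhibition decays somewhat faster than the original
engine's) and the AngI / Ang(1‑7) increases run ~10–20 % high at the
strongest schedule (AngI accumulates slightly more under deep inhibition
than in the original engine, and Ang(1‑7) inherits that excess through its
AngI-derived production).

## Numerical choices

- LSODA (automatic stiff/non-stiff switching) with the analytic 26×26
  Jacobian; hard restarts at dose events.
- Baseline-anchored initialization: angiotensin pools at printed
  concentrations × compartment volumes (AngIII/IV split renal:plasma at
  equal concentration); ES at its algebraic binding equilibrium; EI = 0;
  drug-free. Burn-in integrates this state for 10 virtual days.
- Negative solver excursions within the tolerance band are clipped to zero
  for observation.
- Output grid: uniform, 500 points over 25 days (~1.2 h spacing) by
  default; AUEC windows interpolate at edges.
- Degenerate inputs (zero placebo AUEC, >4 regimens, out-of-range doses,
  inadmissible equilibrium roots) raise typed configuration errors.

## Problem sizes used in the shipped checks

The packaged test suite runs the four-schedule comparison at 50 matched
dogs (with a Monte-Carlo allowance of twice the standard error of the
median added to the published-value tolerance) and dose-monotonicity at 12
dogs; `scripts/acceptance.py` runs the full 500-dog protocol, matching the
published simulation size.
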