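# Methods

## Scientific setting

In *Saccharomyces cerevisiae*, ammonium is normally taken up as the
NH4+ ion by the Mep permeases (Amt family), using the negative membrane
potential as driving force; each imported charge must be re-exported as
a proton by the plasma-membrane H+-ATPase, at ATP cost.  A strain with
all three Mep genes deleted can still grow on ammonium, which raises
the question this package's analysis addresses quantitatively: is
passive diffusion of the uncharged NH3 species sufficient to explain
the Delta-mep strain's physiology, and what membrane permeability does
that imply?

The analysis rests on four small models, each implemented as a
separately testable module.

## Acid-base speciation (`speciation`)

Total ammonium NH_X = NH3 + NH4+ partitions by the
Henderson-Hasselbalch relation; the NH3 mole fraction is
`f(pH) = 1/(1 + 10^(pKa-pH))`.  Defaults: pKa 9.25, temperature
303.15 K.  The pKa is used uncorrected at 30 degC: the
room-temperature literature value reproduces every tabulated quantity
in the reference dataset, so no temperature correction is applied
implicitly (an override exists on `AcidBaseParams`).  Activity
coefficients are ignored (ideal solution), consistent with the
reference arithmetic.  Between pH 3 and 7 the pool is >99.4% NH4+, and
the shortcut `NH3 = total * 10^(pH-pKa)` is accurate to ~1% whenever
pKa - pH >= 2.

Concentrations are carried in mmol/L throughout the package
(numerically identical to mol/m^3), with umol/L appearing only at the
presentation layer.  This makes the flux equation free of hidden unit
factors except one explicit mol-to-mmol factor of 1000 in
`transport.diffusion_flux`.

## Compartment model (`compartments`)

Whole-cell metabolomic measurements average over compartments of very
different pH.  Three compartments are modelled - cytosol (70% of cell
volume, pH 6.5), vacuole (14%, pH 4.5), mitochondria (1%, pH 7.5) -
with free NH3 equilibrated across all internal membranes by passive
diffusion (no intracellular NH_X transporters are described in the
literature).  The whole-cell pool per litre of cell then factorizes as
`NHX_IC = NH3_free * R` with the retention factor
`R = sum_i V_i (1 + 10^(pKa - pH_i))` (about 8.3e3 for the default
model, vacuole-dominated).  Choices behind the defaults:

* cytosolic pH 6.5 is the midpoint of the 6-7 sensitivity range and is
  the value under which deconvolution of the tabulated whole-cell
  pools reproduces the tabulated cytosolic NH3 estimates (1.31 and
  0.90 umol/L at pH 6 and 7);
* mitochondrial pH 7.5 is not critical - the mitochondrion contributes
  <0.01% of R, and any value in 7-8 changes nothing at the reported
  precision; it is configurable;
* the ~15% of cell volume outside the three compartments (largely dry
  matter) is treated as NH_X-free; including it at cytosolic pH would
  shift the deconvolved cytosolic NH3 by ~1%;
* the `+1` dissociation terms are kept exact rather than approximated
  by `10^(pKa-pH)`.

### Mechanism-specific equilibrium ratios

* **Diffusion**: at equilibrium NH3_cyt = NH3_EC, so
  `IC/EC = R / (1 + 10^(pKa - pH_EC))`, independent of the
  concentration level and of the membrane potential.
* **Uniport**: NH4+ equilibrates with the electrical gradient,
  `[NH4+]_cyt/[NH4+]_EC = 10^(-dPsi/Z)` with Nernst slope
  `Z = ln(10) R T / F` (60.15 mV at 30 degC) and
  `dPsi = pmf + Z (pH_cyt - pH_EC)`.  The cytosolic pH cancels except
  through R, and the ratio rises tenfold per unit of extracellular pH.

The proton motive force is not printed anywhere in the reference
dataset.  The default pmf = -200 mV was reverse-engineered: it
reproduces both tabulated pH-5 uniport corner bounds (5.44e3 and 108)
within 1% and is physiologically reasonable for yeast at acidic
external pH.  It is flagged as a model choice in the constants registry
and configurable in the YAML model file.

### Sensitivity bounds

The tabulated ratio ranges are extrema over vacuolar volume fraction
(0.14-0.25), cytosolic pH (6.0-7.0) and vacuolar pH (4.0-5.5).  Both
ratio formulas are monotone in each coordinate, so the extrema lie on
the 8 corners of the box; `ratio_bounds` scans corners (verified in the
test suite against exhaustive 21^3 grids on random boxes) in
lexicographic (V_vac, pH_cyt, pH_vac) order, keeping the first corner
on ties.  A caveat on the tenfold-per-pH rule for diffusion: the
quotient `ratio(pH+1)/ratio(pH)` lies in [9.9, 10.0] only while
pKa - (pH+1) >= 2, i.e. up to pH_EC ~ 6.25; by pH_EC 7 it has fallen
to ~9.5.

## Transport and permeability (`transport`)

The flux law `-q_N = P a_m ([NH3]_EC - [NH3]_cyt)` uses a
biomass-specific membrane area a_m = 3.22 m^2/g_CDW.  The growth law
divides the N-flux by the biomass N-content chi_N = 5.60e-3 mol
N/g_CDW; the product form `mu = chi_N^-1 * (-q_N)` is the only
dimensionally coherent reading of the growth relation and is the one
implemented.

`solve_steady_state` computes, per chemostat observation: NH3_EC by
speciation, NH3_cyt by deconvolution, then P by inversion of the flux
law.  When the default model yields a non-positive gradient
(physically: the equilibrium model over-predicts cytosolic NH3), the
solver searches the sensitivity box for the smallest assumption change
that restores inward diffusion - vacuolar volume raised on a 0.01
lattice first, then vacuolar pH lowered on a 0.1 lattice at maximal
volume.  On the reference pH-5 condition this path terminates exactly
at vacuole 25% / pH 4.2, the adjustment documented in the reference
table's footnote.  If nothing in the box helps, the solution is
returned with `feasible=False` and a diagnostic rather than raising:
infeasibility is a result about the model, not a programming error.

A reproduction caveat: the pH-5 permeability recomputed from the
*printed* (3-significant-figure) inputs is 2.47 m/h versus the
tabulated 2.73 m/h.  This quantity is a quotient by the small
difference of two similar concentrations (0.393 - 0.369 umol/L); a
0.5% rounding of either input moves P by ~10%, and rounding both
intermediate concentrations to their printed two decimals gives
2.95 m/h.  The package always reports the full-precision value; the
tabulated 2.73 evidently derives from unrounded measurements that are
not available.  The pH-6 and pH-7 estimates (0.38 and 0.025 m/h vs
tabulated 0.37 and 0.03) are insensitive to this because their
gradients are not small differences.

### Batch fit

`fit_permeability_from_growth` regresses growth rate on extracellular
NH3 through the origin and converts the slope via
`P = slope * chi_N / a_m`.  The linear region is not defined in the
reference figure (its R^2 of 0.73 suggests generous inclusion); the
default rule keeps points below the concentration at which the fitted
line predicts 0.5 mu_max, iterated to a fixed point (converges in a
handful of iterations; 50-iteration cap).  Alternatives - an explicit
concentration window, a mu < 0.8 mu_max cap, or a user callable - are
selectable.  R^2 is the uncentered (through-origin) definition.

## Physiology (`physiology`)

ATP production is counted as 1.9 mol ATP/mol O2 (respiration, P/O
taken as given) plus 1 mol ATP/mol ethanol (fermentation), appropriate
for the respirofermentative regime of these N-limited cultures.
Yield uses a glucose molar mass of 180.16 g/mol.  The C/N consumption
ratio uses glucose carbon only (6 q_S / q_N); this reproduces all
tabulated C/N values, so carbon from the co-consumed feed ethanol was
evidently excluded in the source arithmetic.  Because the feed contains
ethanol, net ethanol flux is ambiguous from the tabulated data alone
and no full carbon/electron balance is attempted.  Rates are stored as
non-negative magnitudes with direction fixed by field semantics, since
the source tables print consumption rates as positive numbers.

`validate_observation` is report-only: it flags rows violating the
nitrogen balance `q_N = mu * n_content` and tabulated derived cells
that disagree with recomputation.  On the reference dataset 22 of 24
derived cells agree within 2%; the two flagged cells are the
Mep-deleted pH-5 yield (0.081 tabulated vs 0.075 recomputed, cause
unknown) and the reference-strain pH-7 C/N, where the tabulated 104.1
equals `6 q_EtOH / q_N` to the printed precision - a demonstrable
column transposition in the source table.  Similarly, the source
table's "estimated Cyt/EC ratio" column is inconsistent with its own
neighbouring columns; the package reports the quotient of its own NH3
estimates instead.

## Synthetic data (`synthetic`)

The generator defines the study conditions under which the pipeline is
validated; it emulates the reference design, not an idealization of it.

**Chemostat**: dilution rate 0.05 1/h, pH setpoints 5/6/7, triplicate
measurements; baseline q-rates, N-content, biomass and cell volume per
condition equal the reference strain-matched values.  `q_N = D *
n_content`; for the diffusion mechanism the flux law fixes the NH3
gradient given the true permeability, and the *level* is set by a drawn
cytosol/EC NH3 ratio, uniform in [0.25, 0.95] - the range spanned by
the steady-state estimates on the reference data.  (Physically this
missing degree of freedom is the assimilation kinetics, which the
equilibrium analysis does not model.)  For the uniport mechanism the
residual extracellular NH_X is the near-zero reference level (8-13 uM)
and the whole-cell pool follows the electrochemical equilibrium ratio.
Noise is multiplicative log-normal per measured quantity, independent
across quantities (deviations in the reference tables scale roughly
with magnitude), default CV 5%.

**Micro-titer**: duplicate wells over a two-fold (NH4)2SO4 dose ladder
(1.19-76 mM NH_X) at initial pH 5/6/7, initial OD 0.1, readings every
0.25 h for 16 h, growth capped at mu_max = 0.21 1/h.  The noise acts
multiplicatively on each well's realized growth rate - modelling the
replicate-to-replicate spread that dominates rate determinations -
with optional additional per-reading OD jitter (off by default; at the
default 8-point window a per-reading CV above ~1% makes the R^2 >= 0.98
floor unreachable for slow wells, which is the correct behaviour of the
window rule on genuinely noisy optics, not a target condition for the
recovery analyses).  What the generator deliberately does not emulate:
plate-reader optics (path length, OD nonlinearity), lag phases,
acidification drift during growth, and Monod-type saturation (the
ceiling is hard, matching the linear-then-flat reference behaviour).
Passing recovery tests therefore demonstrate identifiability of the
transport parameters under the stated noise structure, not robustness
to optical artefacts or kinetic model error.

`growth_rate_from_od` fits ln(OD) against time over every sliding
window (default width 8 points) and returns the largest slope among
windows with R^2 >= 0.98; slope maximization automatically skips lag
phases, and a perfectly flat window counts as R^2 = 1 with slope 0.
The width and floor are exposed because the reference protocol does not
state its windowing.

## Numerical and degenerate-input choices

* Errors are typed: `DomainError` for out-of-range physics,
  `ConfigurationError` for inconsistent models, `EstimationError`
  (carrying the best candidate) for failed fits,
  `InfeasibleGradientError` to route callers to the adjustment path,
  `ParseError` listing every offending CSV cell with line numbers.
* All randomness flows from a single integer seed through
  `numpy.random.default_rng`; derived seeds stay below 2^31.  Identical
  configurations give byte-identical CSV output.
* Zero total NH_X, zero free NH3 and zero-dose wells are exact zeros
  through the whole chain, not small numbers.
* The pipeline writes no timestamps, so reruns are hash-stable.

## Problem sizes

The Monte-Carlo recovery analysis uses 200 observations (median
recovery error ~6% at 5% noise, seconds of runtime); the grid oracle
validates corner search on 50 random boxes at 21^3 resolution; the
synthetic plate has 42 wells (3 pH x 7 doses x 2 replicates).  These
sizes give stable medians and exhaustive-enough oracles while keeping
the full suite interactive.

## Known limitations

* Equilibrium-only compartments: no kinetic vacuolar sequestration, no
  Mep saturation (K_M) kinetics - the reference strain's measured
  ratios at pH 6-7 in fact sit below the uniport equilibrium
  prediction, consistent with kinetic (affinity) control that this
  package deliberately does not model.
* The pmf schedule behind the uniport bounds is a single constant; a
  pH-dependent pmf would change the spread of the uniport bounds
  across culture pH.
* The batch fit is validated against synthetic data only, since the
  underlying rate measurements exist only as a figure.
* No ionic-strength or temperature correction of pKa; no multi-protic
  buffers; no CO2/carbonate chemistry.
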