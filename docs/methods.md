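# Methods

This note documents the models implemented in `pfaspartition`, the
assumptions behind them, the synthetic-data generator that serves as the
package's test harness, and the numerical and design choices that were
genuinely open.

## Membrane–water partitioning (SSLM depletion assay)

The solid-supported lipid membrane (SSLM) assay measures the
phospholipid membrane–water partition coefficient

    K_MW = (C_membrane) / (C_water),   C in ng per mL of each phase,

by depletion: six vials carry increasing phospholipid volumes
(0.067–2.166 μL on the default geometric ladder) and an identical PFAS
spike; whatever is missing from the water at equilibrium is in the
membrane. Per measurement the membrane mass is

    M_mem = m_spike − C_aq·V_water                      (mass balance)
    M_mem = m_spike − C_aq·V_water − m_rinse            (rinse corrected)

and K_MW is the slope of the zero-intercept least-squares regression of
`M_mem` on `C_aq·V_lipid`, pooled over vials and replicates. A zero
intercept is forced because zero aqueous concentration implies zero
membrane load; with this choice K_MW *is* the slope of the depletion
data. The standard error of log10 K_MW comes from the regression slope
standard error by the delta method. Measurements whose implied membrane
mass is non-positive (possible under noise for weak partitioning) are
dropped, not truncated to zero — truncation would bias low-K_MW
estimates upward — and counted in the output. If no measurement
survives, the compound is reported as below quantifiable partitioning
rather than given a number.

The rinse-corrected variant subtracts the PFAS mass recovered by a
methanol rinse of the vial wall; it exists because highly hydrophobic
compounds (flagged in the registry) sorb appreciably to container
surfaces, and without the correction that loss masquerades as membrane
binding, biasing K_MW upward.

**Assay-design defaults.** The kit fixes the lipid ladder endpoints, but
the aqueous volume per vial and spike level are free design parameters
of the simulated assay. They were set by a power analysis of the
depletion estimator *before* any recovery experiment was run: with
aqueous volume `V_w` the depleted fraction in the largest vial is
`K·V_lip/(V_w + K·V_lip)`, and for the weakest homolog the default
trend scenario produces (log10 K_MW ≈ 0.1, K ≈ 1.2) a 5% multiplicative
measurement error requires `V_w` ≈ 0.05 mL for the depletion signal to
clear the noise floor. The defaults are therefore `V_w = 0.05 mL` and a
10 ng spike (initial concentration 200 ng/mL, comfortable for LC-MS/MS
quantification). With larger aqueous volumes the short-chain end of a
homolog series becomes unquantifiable — which is also the realistic
failure mode of the laboratory assay.

**Chain-length trends.** Within a homologous series, log10 K_MW is
regressed on the fluorinated-carbon count FC_n by ordinary least
squares; the slope is the per-CF2 increment (≈0.36 log units for the
carboxylates, ≈0.37 for the sulfonates in the generator presets). The
pH comparison pairs per-compound estimates at two pH values and
propagates standard errors in quadrature; the sign convention (a − b)
is carried in the output metadata rather than assumed.

## HSA binding (equilibrium dialysis, Langmuir isotherm)

A 1.0 mL PFAS sample dialyses against a 0.1 mL cup containing 1.0 μM
human serum albumin across a 10 kDa membrane; at equilibrium the free
concentration C is uniform over the combined 1.1 mL and the bound
amount per mole of HSA follows the single-site Langmuir isotherm

    B = B_max · C / (K_D + C).

The no-HSA control fixes the total recoverable PFAS per dose
(`n_tot = C_control · V_tot`), which simultaneously compensates
nonspecific losses to the apparatus, since control and sample share the
same surfaces. Bound-vs-free points are then

    B = (n_tot − C_free · V_tot) / n_HSA,

with negative B retained (clipping them would bias B_max) but flagged.

`fit_single_site` minimises the unweighted sum of squared residuals of
B against C by `scipy.optimize.least_squares` over (log10 K_D,
log10 B_max) — the log parameterisation enforces positivity — restarted
from five log-spaced K_D initials spanning one decade below to two
decades above the observed C range; the lowest-SSE solution wins.
Standard errors come from the Jacobian at the optimum, delta-method
transformed to the natural scale. A failed optimisation returns
`converged=False` with a diagnostic message instead of raising.
Affinities are reported as `log10 K_A = −log10(K_D / mol L⁻¹)`, and
docking free energies interconvert with affinities via
`ΔG = −RT ln K_A` with R = 1.98720425×10⁻³ kcal/(mol·K) and a default
temperature of 298.15 K (the assays are room-temperature equilibria and
no other temperature is defined for them).

**Identifiability limitation.** Under this dialysis design the free
concentration never exceeds ~1.8×10⁻⁷ M (the 2:1 dose over 1.1 mL), so
K_D is well identified only when it lies at or below the dosed range.
Validation experiments in the test suite show median K_D recovery
within a few percent at K_D = 10⁻⁷ M, a material downward bias
(~30–50%) at 10⁻⁶ M, and essentially no identifiability at 10⁻⁵ M,
where less than 2% of the ligand binds and the isotherm is sampled only
in its linear regime. The bias at 10⁻⁶ M is intrinsic to unweighted
bound-vs-free fitting with dialysis data, not an optimiser artifact
(fits always match or beat a 200×200 exhaustive grid on SSE): because B
is computed from the same measured free concentration that serves as
the regressor, each point's error displaces it along its dose's
mass-balance line, whose slope (−V_tot/n_HSA ≈ −1.1×10⁷ L/mol) is
comparable to the isotherm's initial slope B_max/K_D — a structured
errors-in-variables geometry that attenuates the fitted curvature.
Consumers should treat fitted K_D values near or above 10⁻⁶ M from this
design as lower-resolution estimates; weak binders would need higher
doses or more protein for sharp constants.

## HSA/water distribution versus membrane partitioning

K_MW is a ratio of equilibrium concentrations and does not depend on
the aqueous PFAS level; protein binding saturates, so the HSA/water
distribution coefficient falls with concentration. Extrapolating the
single-site fit to a mass-concentration ratio between an HSA phase and
water gives

    D_HSA/W(C_aq) = B_max · ρ_HSA / ( MW_HSA · (K_D + C_aq / MW_PFAS) ),

with ρ_HSA the density of the HSA phase (g/L), MW_HSA = 66,400 g/mol,
MW_PFAS the compound's molar mass and C_aq in g/L. D is pseudounitless
(bound mass per HSA mass over aqueous mass concentration), finite at
C_aq = 0 (plateau `B_max·ρ_HSA/(MW_HSA·K_D)`) and strictly decreasing
with log-log slope → −1 in saturation. The crossover with the flat
membrane line has the closed form

    C* = MW_PFAS · ( B_max·ρ_HSA / (MW_HSA·K_MW) − K_D ),

and does not exist when K_MW already exceeds the plateau.

Two conventions here were genuinely open and are stated rather than
hidden:

* **Basis of D.** The symbol set (densities and molecular weights)
  fixes units but not the basis; this implementation uses the
  mass-concentration ratio. A mol/mol convention would shift every
  profile by a compound-specific constant without changing shapes or
  orderings.
* **ρ_HSA.** No measured density of an HSA-rich phase is defined by the
  assays; the default is 1360 g/L, a typical packed-protein density. It
  is an explicit parameter, echoed in every pipeline log, because D
  scales linearly with it.

Profiles are tabulated on a log-spaced grid whose default bounds,
0.1–10,000 ng/mL, span mean PFAS serum concentrations reported across
occupational and background populations. (A narrower 1–10,000 ng/mL
variant of the same range also circulates; the wider bound is the
default and both are reachable through `grid_min`.)

## Synthetic-assay generator

The generator is the package's ground-truth harness. It emulates:

* the six-vial SSLM ladder (geometric between the published endpoints
  0.067 and 2.166 μL — the intermediate kit volumes are not published,
  and any increasing ladder with those endpoints is a valid stand-in),
  triplicate measurements, pH label, optional container-surface loss;
* the dialysis ladder (1.0 mL sample, 0.1 mL cup of 1.0 μM HSA, molar
  dose ratios 1:16–2:1, duplicates, 48 h equilibration as an
  informational field).

Noise is multiplicative lognormal on measured concentrations —
concentrations are positive and LC-MS/MS error is roughly proportional
— parameterised so the **median** (not the mean) of the measured value
equals the noiseless value, which keeps log-scale estimators unbiased
and makes round-trip tests exact at σ = 0. Controls in the dialysis
simulation are stored noiseless (`n_tot/V_tot`). Surface loss is
modelled as a fraction of the *unbound* (aqueous) mass sorbing to the
wall, recorded as the rinse mass; in the pipeline it is applied only to
hydrophobic-flagged compounds by default. All simulators are
deterministic under a fixed seed (`numpy.random.default_rng`).

A consequence of the loss model worth knowing: the wall competes with
the membrane for the same aqueous pool, so for very strongly
partitioning compounds the absolute wall loss is tiny and the
mass-balance and rinse-corrected estimators coincide to within noise.
The correction-efficacy validation therefore runs at log10 K_MW = 2,
where wall sorption is a material mass pathway; at a realistic
hydrophobic-compound value (log10 K_MW ≈ 4.4) the correction is
harmless but undetectable under this model.

What the generator does **not** emulate — and hence what passing tests
do not establish about real data: kinetic approach to equilibrium
(long-chain PFAS may not equilibrate in 4 h), bead-surface nonspecific
binding beyond the wall-loss proxy, LC-MS calibration error structure
beyond proportionality, volume shifts across the dialysis membrane,
inter-day/batch effects, and real inter-compound variation around the
planted linear chain-length trends.

**Whole-registry scenario.** The study prints per-compound values only
for a few compounds (log K_MW 4.1 and 4.4 for the 6:2 and 8:2
phosphate diesters). Full-registry pipeline runs therefore use a
documented synthetic truth scenario: log K_MW linear in FC_n with the
published per-CF2 slopes and headgroup-dependent intercepts (sulfonates
as strong acids highest, betaines/zwitterions lowest), and binding
affinities ordered by structural group following the observed ranking
(sulfonates ≈ ether sulfonates strongest, sulfonamide ethanols
weakest) with a mild chain-length increment saturating at FC8 and
B_max = 1. These numbers define a self-consistent simulation scenario,
not measured values.

## Compound registry

Sixty compounds in eleven structural groups plus "Other", with
acronyms, fluorinated-carbon counts, element-count formulas and molar
masses from IUPAC standard atomic weights (additive to <0.01 g/mol).
Strong acids (carboxylic, sulfonic, phosphoric, sulfonamidoacetic) are
stored as their anions — the aqueous speciation at assay pH — with the
neutral form available on request; weak-acid sulfonamides and the
sulfonamidoethanols are stored neutral, and betaines as net-neutral
zwitterions. The hydrophobic flag marks the fifteen compounds whose
K_MW measurement requires the rinse correction. CAS registry numbers
are optional strings, included only where well established, and never
validated against an external service. Formulas for the betaine-type
compounds are reconstructed from their structural names. One
literature-facing caveat: published tables occasionally misplace the
PFOA/PFNA parenthetical; the registry uses the standard assignments
(PFOA = perfluorooctanoic acid, FC7; PFNA = perfluorononanoic acid,
FC8).

## Validation sizes and numerics

Recovery experiments in the test suite use: 200 simulated assays per
condition for estimator-consistency and correction-efficacy checks, 100
seeds per (K_D, B_max) combination for Langmuir recovery, 50 seeded
assays for the hydrophobic-compound median, and triplicate six-vial
series for trend recovery — sizes at which the Monte-Carlo error of the
checked statistic is well below the asserted tolerance. Root-finding
oracles (scipy `brentq`) and exhaustive grid searches provide
independent cross-checks of the closed-form crossover and of the
Langmuir optimiser. Tolerances: exact identities at 1e−9–1e−12
relative; simulation-based recoveries at the tolerance the relevant
statistic supports (e.g. mean log K_MW within 0.02 over 200 assays).
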