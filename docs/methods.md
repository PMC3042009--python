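# Methods

## Model

The package simulates a deterministic compartmental model of IFNγ-driven
STAT1 signaling with two compartments (cytoplasm, nucleus) of equal effective
area. State variables, all in arbitrary concentration units (a.u.), time in
minutes:

| symbol | meaning |
|---|---|
| `IIr` | active receptor complex (Janus kinases lumped in) |
| `SUc`, `SUn` | unphosphorylated STAT1, cytoplasmic / nuclear (monomer units) |
| `SDc`, `SDn`, `SDnd` | phosphorylated STAT1 dimers: cytoplasmic, free nuclear, DNA-bound (dimer units) |
| `mSOCS1`, `mSTAT1` | SOCS1 and STAT1 mRNA |
| `chain_*` | auxiliary delay-chain stages (three blocks) |

Modeling assumptions:

* **No receptor deactivation or ligand degradation.** Activation
  `d IIr/dt = k_act·u·(I_total − IIr)` is monotone; the inactive receptor is
  implicit (`Ir = I_total − IIr`), so receptor mass is conserved exactly.
* **Rapid, high-affinity dimerization.** Phosphorylation consumes monomers at
  flux `v = k_phos·IIr·SUc/(1 + k_inh·z_fb)` and feeds the dimer pool at
  `v/2` (two monomers per dimer). Dissociation after nuclear
  dephosphorylation returns two monomers to `SUn`.
* **Free-diffusion shuttling.** Only unphosphorylated STAT1 shuttles, as a
  symmetric first-order exchange `k_shut·(SUn − SUc)`; with equal
  compartment areas the resting state has `SUc = SUn`.
* **Reversible DNA binding; only free nuclear dimers dephosphorylate.**
* **SOCS1 negative feedback** acts multiplicatively on the phosphorylation
  flux through `1/(1 + k_inh·z_fb)` — the simplest saturating inhibition.
  SOCS1 protein is not an explicit species; the feedback is driven by
  delayed SOCS1 mRNA, the delay absorbing translation.
* **Distributed delays.** Transcription of SOCS1 and STAT1 (driven by the
  DNA-bound dimer) and the feedback signal (driven by SOCS1 mRNA) pass
  through linear chains of `n_chain` first-order stages at per-stage rate
  `n_chain/τ̄` — the standard "linear chain" realization of a gamma-kernel
  delay with mean `τ̄` and variance `τ̄²/n_chain`. Only mean delays are
  biologically constrained, so the chain order is a configuration knob;
  the default is `n_chain = 3`.
* **STAT1 synthesis** is an explicit mRNA pool translated into `SUc` with no
  basal protein turnover, which matches the observed monotone late rise of
  total STAT1 over 12 h. First-order mRNA degradation (`k_degS`, `k_degT`)
  keeps transcript dynamics bounded; setting these rates to zero is allowed.

Internal phospho pools are stored in dimer units; every observable converts
to monomer (band-intensity) equivalents with a factor of 2, so total STAT1
monomer equivalents `SUc + SUn + 2(SDc + SDn + SDnd)` are conserved exactly
whenever translation is switched off (receptor, binding, dephosphorylation
and shuttling all conserve STAT1 mass by construction).

Conventions: the initial experimental total STAT1 is normalized to 1, and the
total receptor concentration defaults to one tenth of it (`I_total = 0.1`).
Initial `IIr`, `SDn`, `SDnd`, mRNAs and chain stages are structurally zero;
`SUc`, `SUn`, `SDc` are free initial conditions.

## Observation model

Immunoblot intensities have arbitrary gain, so each blot series maps to a
species combination through a positive scaling factor: total and
fraction-resolved phospho-STAT1 (`WB_STAT1D`, `WB_STAT1Dc`, `WB_STAT1Dn`)
and total STAT1 (`WB_STAT1`, `WB_STAT1c`, `WB_STAT1n`). mRNA series carry no
scaling factor: data and model series are both normalized to their time
averages, which makes an mRNA gain redundant. The confocal
nuclear:cytoplasmic ratio `RSNC = (SUn + 2(SDn+SDnd))/(SUc + 2SDc)` is
scale-free under the equal-area assumption and is compared directly; its
value is identical whether dimers are weighted as molecules or as band
intensity, because both numerator and denominator use monomer equivalents.

The fitting convention is: *experimental* series are time-average normalized
(per replicate, then averaged); *model* blot series are `WB·combination`
with the gain fitted, **not** renormalized — this is what makes a fixed
`WB_STAT1Dn` informative in the sweep. Model mRNA series are normalized to
their own average over the series' time points.

The headline quantity, the nuclear phospho-STAT1 fraction
`2·SDn / (SUc + SUn + 2(SDc + SDn + SDnd))`, uses free nuclear dimers by
default (the DNA-bound pool can be included with a flag; both variants are
reported by the sweep CLI) and divides by total STAT1 *at the same time
point* (dividing by the t = 0 total is the documented alternative; with the
late protein rise it would give slightly larger fractions).

## Assay preprocessing

Immunoblots: per time point, target band over loading-control band
(ERK 1/2 for total lysate, GAPDH cytosolic, lamin A/C nuclear); each
replicate series divided by its time average; mean ± SEM over replicates
(SEM uses the n−1 standard deviation over √n). qPCR: technical replicates
are averaged in Ct domain by default (linear-domain averaging is available),
then `2^−ΔCt` against HPRT, then the same time-average normalization.
Confocal: per cell, mean pixel intensity (sum/area) nuclear over
cytoplasmic; mean ± SEM over 30–40 cells. Tumor volumes use the ellipsoid
approximation width² × length × 0.52, with width taken as the smaller
caliper reading (swapped with a warning if given the other way around).

## Fitting

Cost: `χ²(θ) = Σ_k Σ_l ((y_exp − y_mod)/σ_exp)²` over observables and time
points, summed over doses. Kinetic parameters are global (shared across
doses — the dose enters the receptor equation explicitly); blot gains are
local per dose, because each dose's series was normalized to its own time
average, making the effective gain dose-specific. Scopes are fully
user-configurable.

Free blot gains are *profiled analytically* at every cost evaluation: for
fixed kinetics the optimal gain of a series is the weighted least-squares
closed form `Σ(w·y·c)/Σ(w·c²)` (clipped to its bounds), where `c` is the
model combination and `w = 1/σ²`. This removes 6–8 conditionally linear
dimensions from the search. A gain that is fixed (the sweep) or supplied
explicitly bypasses profiling.

The optimizer is a hybrid: seeded simulated-annealing restarts (Metropolis
acceptance, geometric cooling, Gaussian proposals on a small random subset
of coordinates, log₁₀ transform for rate constants and delays, reflection
at the bounds), followed by bounded trust-region least squares
(`scipy.optimize.least_squares`, TRF) from the best point. Defaults:
5 restarts × 2000 SA iterations, initial temperature 50, cooling 0.97, step
scale 0.15 of the (transformed) box width, 40 trust-region iterations.
Everything is reproducible from the settings seed.

Numerical choices: integration uses LSODA with rtol 1e-9 / atol 1e-12
(1e-8 / 1e-11 inside the fit); integrator undershoots below zero smaller
than 1e-9 are clipped with a warning, larger ones are errors. A hard cap of
50 000 derivative evaluations per simulation converts runaway-stiff
parameter draws (possible during stochastic search) into fast failures;
failed simulations inside the search return a large finite penalty (1e12)
so annealing can continue. Zero SEMs in input data are rejected rather than
floored — noise floors must be stated explicitly upstream.

## Plateau sweep

The nuclear phospho-STAT1 blot determines only the product
`WB_STAT1Dn · 2(SDn + SDnd)`, so the absolute nuclear pool is not
practically identifiable. The sweep fixes `WB_STAT1Dn` at each value of an
ascending grid (default log-spaced 10 … 10000) and re-optimizes everything
else. Below the data-implied scale the forced pool distorts the other
observables and χ² rises; above it the pool is dynamically negligible and
χ² is flat. The plateau is declared at the smallest grid value from which
every successive relative change |Δχ²|/χ² stays within `rel_tol`
(default 1%, a CLI flag; the tolerance defines how flat "flat" is — the
choice is a convention, since only the existence of a plateau is
biologically meaningful). The fit at the plateau start carries the largest
nuclear phospho fraction consistent with the data, reported per requested
time and as the overall maximum — an upper bound on the true fraction.

Because each grid point is an independent stochastic fit, optimizer noise of
a few percent would blur a genuinely flat profile. The sweep therefore adds
*continuation*: each point is also refined locally from its neighbors'
optima with `k_imp` scaled down and `k_deph` scaled up by √(gain ratio)
(preserving the product `WB·SDn` to first order while leaving the
cytoplasmic dimer dynamics intact), in alternating forward/backward polish
passes until no point improves. The minimum over candidates is taken, which
can only lower χ² toward the true profile value.

## Synthetic data

The generator emulates the study design: doses 10 and 100 ng/ml; sampling
grid {0, 15, 30, 60, 120, 180, 360, 540, 720} min (the end points and span
follow the experiments; the interior spacing is a synthetic choice resolving
both response phases); 4 replicates (design range 4–6); full observable
panel (subcellular fractions, SOCS1 qPCR, 35-cell confocal RSNC) at the high
dose and total-lysate blots at the low dose, mirroring which measurements
were made at which dose.

Noise model (the raw tables are pushed through the same preprocessing as
real data): band intensities carry mean-one multiplicative lognormal noise
(default CV 0.20; band intensities are positive and right-skewed), loading
controls likewise (CV 0.10); Ct values carry additive Gaussian noise
(SD 0.15 cycles) on each of 2 technical replicates; per-cell RSNC scatters
lognormally (CV 0.15) around the model ratio on top of lognormal cell
brightness. A configurable SEM floor (default 0.05 in normalized units)
keeps noiseless demonstrations fittable. qPCR rows are only emitted where
the true expression is strictly positive — a finite Ct cannot encode zero
transcript — which drops the pre-induction t = 0 point of the SOCS1 series,
as a real detection limit would.

What the generator does *not* emulate: gel/lane artifacts and saturation,
correlated (batch) replicate errors, cell-cycle heterogeneity, segmentation
errors in imaging, and day effects. Passing recovery tests on these data
therefore shows that the estimation machinery is correct and well
calibrated under the stated noise model, not that the model is identifiable
from any particular laboratory's data.

The packaged demo truth (`demo_truth`) was chosen once so that simulation
reproduces the qualitative response features: a biphasic phospho-STAT1 rise
at 100 ng/ml (receptor-limited fast phase, then a slow further increase fed
by newly translated STAT1), a strictly slower rise at 10 ng/ml, a late rise
of total STAT1, an almost unchanged nuclear:cytoplasmic ratio (<5% relative
change over 12 h), and a maximal nuclear phospho fraction of ≈1/500
(0.00201 at 100 ng/ml). The demo search space brackets each rate constant
and delay with generous log-scale bounds; `I_total`, the chain order and the
initial dimer pool are fixed by convention.

## Problem sizes used in the packaged checks

The end-to-end checks run at deliberately modest sizes chosen as realistic
desk-scale analyses: the ground-truth recovery fit uses the default hybrid
budget (5 × 2000 SA iterations + local refinement) on a 2-dose, 89-point
dataset; the sweep uses a reduced budget (2 × 300 SA iterations + 60
trust-region iterations per grid point, plus the continuation polish) over
the 7-point default grid. The integrator cross-check compares LSODA at the
default tolerances with an independent fixed-step classical Runge–Kutta
reference (h = 0.05 min) over the full 0–720 min span at both doses.

## Known limitations

* Deterministic ODEs only; no molecule-count stochasticity or spatial
  resolution, and no explicit JAK kinetics.
* The feedback form (multiplicative saturating inhibition by delayed SOCS1
  mRNA) is one of several structures consistent with "SOCS1 inhibits STAT1
  phosphorylation"; the data used here cannot discriminate alternatives.
* The plateau criterion declares a plateau from relative χ² changes on a
  finite grid; a grid that ends before the cost flattens yields "no
  plateau" by design, and the bound inherits the grid resolution (the bound
  is reported at the plateau *grid point*, not at the exact transition).
* Profile-likelihood machinery is implemented only for `WB_STAT1Dn`; other
  parameters get point estimates without confidence intervals.
* With shuttling-equilibrated initial pools the unstimulated state is a
  fixed point; starting `SUc ≠ SUn` relaxes first (by design of the
  free-diffusion assumption).
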