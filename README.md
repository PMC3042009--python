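# stat1kin

Kinetic modeling of IFNγ-driven STAT1 signaling in pancreatic cancer cells:
a distributed-delay ODE model of the JAK/STAT pathway, the observation model
for immunoblot / qPCR / confocal read-outs, multi-dose χ² fitting with a
hybrid simulated-annealing + trust-region optimizer, and the scaling-factor
sweep that converts a practically non-identifiable blot gain into an upper
bound on the nuclear phospho-STAT1 fraction.

## Who this is for

Systems biologists analyzing cytokine-receptor → transcription-factor time
courses measured by quantitative western blot, RT-qPCR and confocal imaging,
who need to (i) fit a compartmental ODE model jointly across stimulus doses,
and (ii) reason about quantities the data determine only up to an arbitrary
gain — here, the absolute size of the nuclear phospho-STAT1 pool.

## The model

IFNγ at dose *u* converts inactive receptor into the active complex *IIr*
(no deactivation, so receptor activation is monotone and
*Ir* + *IIr* = *I* is conserved):

    d IIr/dt = k_act · u · (I − IIr)

Active receptor phosphorylates cytoplasmic STAT1 (*SUc*), inhibited by a
delayed SOCS1 feedback signal z_fb; phosphorylated monomers dimerize rapidly
(two monomers per dimer):

    v       = k_phos · IIr · SUc / (1 + k_inh · z_fb)
    d SUc/dt = −v + k_shut (SUn − SUc) + k_transl · mSTAT1
    d SDc/dt = v/2 − k_imp · SDc

Dimers import into the nucleus (*SDn*), bind DNA reversibly (*SDnd*), and
only free nuclear dimers are dephosphorylated, releasing two unphosphorylated
nuclear monomers (*SUn*) that shuttle back by free diffusion. DNA-bound
dimers drive SOCS1 and STAT1 transcription through distributed delays with
mean delay times τ̄ᵢ, realized as linear chains of n first-order stages
(gamma kernels with mean τ̄ and variance τ̄²/n).

Measured blot series are related to species combinations through positive
scaling factors (WB_·) because band intensities have arbitrary units; each
experimental series is normalized to its time average. The confocal
nuclear:cytoplasmic ratio (RSNC) and the mRNA series carry no gain.

The cost is the SEM-weighted sum of squares over observables and time points,

    χ²(θ) = Σ_k Σ_l ((y_exp − y_mod) / σ_exp)²,

minimized jointly over doses with shared (global) kinetic parameters and
per-dose (local) blot gains.

## Worked example

```python
import numpy as np
from stat1kin import (demo_truth, demo_parameter_space, generate_dataset,
                      NoiseSpec, OptimizerSettings, fit, sweep,
                      concentration_bound, nuclear_phospho_fraction, simulate)

params, sf = demo_truth()

# truth: the nuclear phospho-STAT1 pool peaks at ~1/500 of total STAT1
traj = simulate(params, 100.0, np.linspace(0, 720, 721))
print(nuclear_phospho_fraction(traj)[1])          # 0.00201

# synthetic study: doses 10 & 100 ng/ml, 4 replicates, 20% blot noise
data = generate_dataset(params, sf, noise=NoiseSpec(seed=7))

# joint two-dose fit (5 SA restarts x 2000 iterations + local refinement)
result = fit(data.dataset, demo_parameter_space(), OptimizerSettings(seed=11))
print(result.chi2, result.chi2 / result.n_data)   # 70.03  0.787

# sweep the nuclear blot gain to bound the fraction from the data alone
sw = sweep(data.dataset, demo_parameter_space(),
           settings=OptimizerSettings(n_restarts=2, sa_iterations=300,
                                      local_max_iterations=60, seed=11))
print(sw.chi2.round(2))   # [83.37 68.75 67.02 66.11 66.13 66.18 66.73]
print(sw.plateau_value)   # 300.0
print(concentration_bound(sw)["max"])             # 0.0053
```

The sweep output reads: forcing the nuclear blot gain WB_STAT1Dn below the
data-implied scale visibly degrades the fit (χ² 83 at gain 10), while from
gain 300 on the cost is flat — the data cannot distinguish smaller nuclear
pools. The fit at the plateau start carries the largest nuclear phospho
fraction still consistent with the data, here 0.0053, an upper bound that
indeed covers the generating truth of 0.002.

The same pipeline is scriptable from the shell:

```bash
stat1kin synth --seed 7 --out-dir run/
stat1kin fit run/dataset.csv --out-dir run/
stat1kin sweep run/dataset.csv --grid 10,30,100,300,1000,3000,10000 --out-dir run/
stat1kin preprocess --blots run/blots.csv --qpcr run/qpcr.csv --cells run/cells.csv \
    --sem-floor 0.05 --out run/dataset2.csv
```

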