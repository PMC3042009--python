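"""Synthetic assay data with the statistical structure of the real pipeline.

The generator simulates ground-truth trajectories, renders them as raw assay
tables — immunoblot band/loading intensities with multiplicative lognormal
noise, qPCR cycle thresholds with additive Gaussian noise, per-cell confocal
intensities scattering around the model nuclear:cytoplasmic ratio — and then
pushes those tables through the same preprocessing (:mod:`stat1kin.assay`)
as real measurements, yielding a fit-ready :class:`~stat1kin.fitting.Dataset`.

Default conditions mirror the study design: doses of 10 and 100 ng/ml IFNγ,
nine sampling times from 0 to 720 min, four replicates per series, the full
observable panel (subcellular fractions, SOCS1 qPCR, confocal RSNC) at the
high dose and total-lysate immunoblots at the low dose.

qPCR rows are emitted only where the truth expression is strictly positive
(a finite cycle threshold cannot encode zero transcript; in the model SOCS1
mRNA is exactly zero before stimulation), which mimics the detection limit
of the assay.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from . import assay
from .fitting import Dataset, ParamSpec, ParameterSpace
from .model import KineticParameters, ModelDomainError, simulate
from .observables import BLOT_SCALING, ScalingFactors, species_combination

__all__ = [
    "NoiseSpec",
    "SyntheticData",
    "generate_dataset",
    "demo_truth",
    "demo_parameter_space",
    "DEFAULT_TIMES",
    "DEFAULT_DOSES",
]

#: Default sampling grid (min); endpoints from the study design, interior
#: points chosen to resolve both the fast and the slow response phase.
DEFAULT_TIMES = (0.0, 15.0, 30.0, 60.0, 120.0, 180.0, 360.0, 540.0, 720.0)
DEFAULT_DOSES = (10.0, 100.0)

#: Observables measured at every dose vs only at full-panel doses.
TOTAL_LYSATE_PANEL = ("STAT1P_total", "STAT1_total")
FRACTION_PANEL = ("STAT1P_cyt", "STAT1_cyt", "STAT1P_nuc", "STAT1_nuc")

_HPRT_CT = 20.0  # housekeeping cycle threshold used by the generator


@dataclass(frozen=True)
class NoiseSpec:
    """Noise model and design sizes for synthetic assay data."""

    blot_cv: float = 0.2        # lognormal CV per band intensity
    loading_cv: float = 0.1     # lognormal CV of loading-control bands
    ct_sd: float = 0.15         # additive sd on each Ct value (cycles)
    cell_ratio_cv: float = 0.15  # lognormal CV of per-cell RSNC
    n_replicates: int = 4       # independent experiments per series
    n_cells: int = 35           # cells per confocal time point
    n_technical: int = 2        # technical qPCR replicates
    sem_floor: float = 0.05     # lower bound on SEM in normalized units
    seed: int = 0

    def __post_init__(self):
        for name in ("blot_cv", "loading_cv", "ct_sd", "cell_ratio_cv"):
            if getattr(self, name) < 0:
                raise ModelDomainError(f"{name} must be >= 0")
        if self.n_replicates < 2 or self.n_cells < 2 or self.n_technical < 1:
            raise ModelDomainError("replicate/cell counts too small")
        if self.sem_floor < 0:
            raise ModelDomainError("sem_floor must be >= 0")


@dataclass
class SyntheticData:
    dataset: Dataset
    blots: pd.DataFrame
    qpcr: pd.DataFrame
    cells: pd.DataFrame
    manifest: dict


def _lognormal_factor(rng, cv, size):
    """Multiplicative lognormal noise with mean exactly 1."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


def _floor_sem(sem: np.ndarray, floor: float) -> np.ndarray:
    if floor > 0:
        return np.maximum(sem, floor)
    if np.any(sem <= 0):
        raise ModelDomainError(
            "zero-variance SEM with no floor configured; set NoiseSpec.sem_floor"
        )
    return sem


def generate_dataset(
    params: KineticParameters,
    sf: ScalingFactors | None = None,
    doses=DEFAULT_DOSES,
    times=DEFAULT_TIMES,
    noise: NoiseSpec | None = None,
    full_panel_doses=None,
) -> SyntheticData:
    """Simulate truth and emit raw assay tables plus the preprocessed Dataset.

    ``full_panel_doses`` (default: the highest dose) get subcellular-fraction
    blots, SOCS1 qPCR and confocal RSNC in addition to the total-lysate blots
    generated for every dose.
    """
    if sf is None:
        sf = ScalingFactors()
    if noise is None:
        noise = NoiseSpec()
    times = np.asarray(times, dtype=float)
    if times.size < 2:
        raise ModelDomainError("need at least 2 time points")
    if full_panel_doses is None:
        full_panel_doses = (max(doses),)
    rng = np.random.default_rng(noise.seed)

    blot_rows = []
    qpcr_rows = []
    cell_rows = []
    data_rows = []
    implied_gains: dict[str, float] = {}

    for dose in sorted(doses):
        traj = simulate(params, dose, times)
        full = dose in full_panel_doses
        panel = TOTAL_LYSATE_PANEL + (FRACTION_PANEL if full else ())

        # ---- immunoblots -------------------------------------------------
        for name in panel:
            combo = species_combination(name, traj)
            band = getattr(sf, BLOT_SCALING[name]) * combo
            reps = []
            for rep in range(1, noise.n_replicates + 1):
                target = band * _lognormal_factor(rng, noise.blot_cv, times.size)
                loading = _lognormal_factor(rng, noise.loading_cv, times.size)
                reps.append(
                    pd.DataFrame(
                        {
                            "observable": name,
                            "dose_ng_ml": dose,
                            "replicate": rep,
                            "time_min": times,
                            "target_signal": target,
                            "loading_signal": loading,
                        }
                    )
                )
            raw = pd.concat(reps, ignore_index=True)
            blot_rows.append(raw)
            normalized = assay.blot_normalize(raw)
            summary = assay.summarize_replicates(normalized)
            summary["sem"] = _floor_sem(summary["sem"].to_numpy(), noise.sem_floor)
            data_rows.append(
                pd.DataFrame(
                    {
                        "observable": name,
                        "dose_ng_ml": dose,
                        "time_min": summary["time_min"],
                        "mean": summary["mean"],
                        "sem": summary["sem"],
                    }
                )
            )
            mean_combo = float(combo.mean())
            if mean_combo > 0:
                implied_gains[f"{BLOT_SCALING[name]}@{dose:g}"] = 1.0 / mean_combo

        if not full:
            continue

        # ---- SOCS1 qPCR ---------------------------------------------------
        rel = species_combination("SOCS1_mRNA", traj)
        detectable = rel > 0
        t_det = times[detectable]
        rel_det = rel[detectable]
        for rep in range(1, noise.n_replicates + 1):
            for tech in range(1, noise.n_technical + 1):
                ct_t = (
                    _HPRT_CT
                    - np.log2(rel_det)
                    + rng.normal(0.0, noise.ct_sd, t_det.size)
                )
                ct_h = _HPRT_CT + rng.normal(0.0, noise.ct_sd, t_det.size)
                qpcr_rows.append(
                    pd.DataFrame(
                        {
                            "dose_ng_ml": dose,
                            "replicate": rep,
                            "technical": tech,
                            "time_min": t_det,
                            "gene": "SOCS1",
                            "ct_target": ct_t,
                            "ct_hprt": ct_h,
                        }
                    )
                )
        qpcr_dose = pd.concat(qpcr_rows[-noise.n_replicates * noise.n_technical:],
                              ignore_index=True)
        # qpcr_series averages technical replicates (Ct domain) internally
        socs = assay.qpcr_series(qpcr_dose)
        socs["sem"] = _floor_sem(socs["sem"].to_numpy(), noise.sem_floor)
        data_rows.append(
            pd.DataFrame(
                {
                    "observable": "SOCS1_mRNA",
                    "dose_ng_ml": dose,
                    "time_min": socs["time_min"],
                    "mean": socs["mean"],
                    "sem": socs["sem"],
                }
            )
        )

        # ---- confocal RSNC -------------------------------------------------
        rsnc = species_combination("RSNC", traj)
        nuc_area, cyt_area = 100.0, 150.0
        means = []
        sems = []
        for t, r_true in zip(times, rsnc):
            brightness = 100.0 * _lognormal_factor(rng, noise.cell_ratio_cv,
                                                   noise.n_cells)
            ratio_noise = _lognormal_factor(rng, noise.cell_ratio_cv, noise.n_cells)
            cyt_conc = brightness
            nuc_conc = r_true * brightness * ratio_noise
            cell_rows.append(
                pd.DataFrame(
                    {
                        "dose_ng_ml": dose,
                        "time_min": t,
                        "image": 1 + (np.arange(noise.n_cells) % 4),
                        "cell": np.arange(1, noise.n_cells + 1),
                        "nuc_sum": nuc_conc * nuc_area,
                        "nuc_area": nuc_area,
                        "cyt_sum": cyt_conc * cyt_area,
                        "cyt_area": cyt_area,
                    }
                )
            )
            m, s, _ = assay.rsnc_from_cells(cell_rows[-1])
            means.append(m)
            sems.append(s)
        data_rows.append(
            pd.DataFrame(
                {
                    "observable": "RSNC",
                    "dose_ng_ml": dose,
                    "time_min": times,
                    "mean": means,
                    "sem": _floor_sem(np.asarray(sems), noise.sem_floor),
                }
            )
        )

    dataset = Dataset(
        pd.concat(data_rows, ignore_index=True),
        provenance="synthetic",
        seed=noise.seed,
    )
    manifest = {
        "theta_star": params.to_dict(),
        "scaling_factors": sf.to_dict(),
        "implied_gains": implied_gains,
        "noise": asdict(noise),
        "doses": [float(d) for d in doses],
        "full_panel_doses": [float(d) for d in full_panel_doses],
        "times": times.tolist(),
        "seed": noise.seed,
    }
    return SyntheticData(
        dataset=dataset,
        blots=pd.concat(blot_rows, ignore_index=True),
        qpcr=(
            pd.concat(qpcr_rows, ignore_index=True)
            if qpcr_rows
            else pd.DataFrame()
        ),
        cells=pd.concat(cell_rows, ignore_index=True) if cell_rows else pd.DataFrame(),
        manifest=manifest,
    )


def demo_truth() -> tuple[KineticParameters, ScalingFactors]:
    """Packaged ground-truth parameter set.

    Chosen so that the simulated pathway reproduces the qualitative behavior
    of IFNγ-stimulated pancreatic cancer cells: a biphasic phospho-STAT1 rise
    at 100 ng/ml (fast receptor-limited phase, then a slow further increase
    fed by new STAT1 protein), a clearly slower rise at 10 ng/ml, a late rise
    of total STAT1, a nuclear:cytoplasmic STAT1 ratio that stays within a few
    percent of its resting value, and a maximal nuclear phospho-STAT1
    fraction of about 1/500 of total STAT1.
    """
    params = KineticParameters(
        k_act=5e-4,     # receptor activation ~ (k_act*dose)^-1 = 20 min at 100 ng/ml
        k_phos=2e-3,    # keeps the phosphorylated pool small (<1% of STAT1)
        k_inh=60.0,     # late, moderate SOCS1 feedback
        k_imp=0.05,     # nuclear import of dimers, ~20 min residence in cytosol
        k_bind=0.1,
        k_unbind=0.05,
        k_deph=0.045,
        k_shut=0.1,     # fast shuttling keeps SUn ~ SUc (RSNC ~ 1)
        k_txS=0.02,
        k_degS=0.02,    # SOCS1 mRNA half-life ~ 35 min
        k_txT=0.5,
        k_degT=0.01,
        k_transl=0.01,
        tau_socs=40.0,
        tau_stat1=120.0,
        tau_fb=90.0,
        n_chain=3,
        I_total=0.1,
        init_SUc=0.5,
        init_SUn=0.5,
        init_SDc=0.0,
    )
    return params, ScalingFactors()


def demo_parameter_space() -> ParameterSpace:
    """Default search space for fitting the demo model.

    Rate constants and delays are searched on a log scale over plausible
    ranges for minute-scale signaling; the receptor total and chain order are
    fixed by convention, the initial cytoplasmic dimer pool is fixed at zero.
    All kinetic parameters are global (the dose enters the equations
    explicitly); the blot gains are local per dose because each dose's series
    was normalized to its own time average.
    """
    params, _ = demo_truth()
    specs = [
        ParamSpec("k_act", 1e-5, 1e-2),
        ParamSpec("k_phos", 1e-4, 1e-1),
        ParamSpec("k_inh", 1.0, 1e4),
        ParamSpec("k_imp", 1e-3, 1.0),
        ParamSpec("k_bind", 1e-3, 1.0),
        ParamSpec("k_unbind", 1e-3, 1.0),
        ParamSpec("k_deph", 1e-3, 1.0),
        ParamSpec("k_shut", 1e-2, 1.0),
        ParamSpec("k_txS", 1e-4, 1.0),
        ParamSpec("k_degS", 1e-3, 0.1),
        ParamSpec("k_txT", 1e-2, 10.0),
        ParamSpec("k_degT", 1e-3, 0.1),
        ParamSpec("k_transl", 1e-4, 0.1),
        ParamSpec("tau_socs", 5.0, 300.0),
        ParamSpec("tau_stat1", 5.0, 300.0),
        ParamSpec("tau_fb", 5.0, 300.0),
        ParamSpec("init_SUc", 0.1, 1.0),
        ParamSpec("init_SUn", 0.1, 1.0),
        ParamSpec("init_SDc", fixed=True, value=0.0),
        ParamSpec("I_total", fixed=True, value=0.1),
        ParamSpec("n_chain", fixed=True, value=3),
        # blot gains: profiled analytically, local per dose
        ParamSpec("WB_STAT1", 1e-3, 1e6, scope="local"),
        ParamSpec("WB_STAT1c", 1e-3, 1e6, scope="local"),
        ParamSpec("WB_STAT1n", 1e-3, 1e6, scope="local"),
        ParamSpec("WB_STAT1D", 1e-3, 1e6, scope="local"),
        ParamSpec("WB_STAT1Dc", 1e-3, 1e6, scope="local"),
        ParamSpec("WB_STAT1Dn", 1e-3, 1e6, scope="local"),
    ]
    return ParameterSpace(specs, base=params)
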