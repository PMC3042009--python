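"""Mapping from model trajectories to measured quantities.

Immunoblot band intensities have arbitrary gain, so each blot series is
related to a combination of model species through a positive scaling factor
(``WB_*``).  mRNA series carry no scaling factor: because both data and model
series are normalized to their time averages, an mRNA gain would be redundant.
The confocal nuclear:cytoplasmic ratio (RSNC) is scale-free by the equal-area
assumption, so it is compared without any factor.

Phospho pools are carried in dimer units internally; observables convert to
monomer (band-intensity) equivalents with a factor of 2.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace

import numpy as np

from .model import ModelDomainError, Trajectory

__all__ = [
    "ScalingFactors",
    "ObservableSeries",
    "OBSERVABLE_NAMES",
    "BLOT_SCALING",
    "species_combination",
    "observe",
    "time_average_normalize",
    "nuclear_phospho_fraction",
]


@dataclass(frozen=True)
class ScalingFactors:
    """Positive multipliers relating species combinations to blot intensities."""

    WB_STAT1: float = 1.0     # total STAT1, total lysate
    WB_STAT1c: float = 1.0    # total STAT1, cytosolic fraction
    WB_STAT1n: float = 1.0    # total STAT1, nuclear fraction
    WB_STAT1D: float = 1.0    # phospho-STAT1, total lysate
    WB_STAT1Dc: float = 1.0   # phospho-STAT1, cytosolic fraction
    WB_STAT1Dn: float = 1.0   # phospho-STAT1, nuclear fraction

    def __post_init__(self):
        for f in fields(self):
            if getattr(self, f.name) <= 0:
                raise ModelDomainError(f"scaling factor {f.name} must be > 0")

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def replace(self, **kw) -> "ScalingFactors":
        return replace(self, **kw)


@dataclass
class ObservableSeries:
    name: str
    times: np.ndarray
    values: np.ndarray
    dose: float

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ModelDomainError("times and values must have the same shape")


#: Observable name -> scaling-factor field (None = scale-free).
BLOT_SCALING = {
    "STAT1P_total": "WB_STAT1D",
    "STAT1_total": "WB_STAT1",
    "STAT1P_cyt": "WB_STAT1Dc",
    "STAT1P_nuc": "WB_STAT1Dn",
    "STAT1_cyt": "WB_STAT1c",
    "STAT1_nuc": "WB_STAT1n",
}

OBSERVABLE_NAMES = tuple(BLOT_SCALING) + ("SOCS1_mRNA", "STAT1_mRNA", "RSNC")


def species_combination(name: str, traj: Trajectory) -> np.ndarray:
    """Unscaled algebraic map from model species to one observable.

    Combinations are in monomer equivalents (one dimer contributes two
    monomers to a band).
    """
    SUc = traj.species("SUc")
    SDc = traj.species("SDc")
    SDn = traj.species("SDn")
    SDnd = traj.species("SDnd")
    SUn = traj.species("SUn")
    if name == "STAT1P_total":
        return 2.0 * (SDc + SDn + SDnd)
    if name == "STAT1_total":
        return SUc + SUn + 2.0 * (SDc + SDn + SDnd)
    if name == "STAT1P_cyt":
        return 2.0 * SDc
    if name == "STAT1P_nuc":
        return 2.0 * (SDn + SDnd)
    if name == "STAT1_cyt":
        return SUc + 2.0 * SDc
    if name == "STAT1_nuc":
        return SUn + 2.0 * (SDn + SDnd)
    if name == "SOCS1_mRNA":
        return traj.species("mSOCS1").copy()
    if name == "STAT1_mRNA":
        return traj.species("mSTAT1").copy()
    if name == "RSNC":
        cyt = SUc + 2.0 * SDc
        if np.any(cyt <= 0):
            t_bad = traj.times[int(np.argmin(cyt))]
            raise ModelDomainError(
                f"RSNC undefined: cytoplasmic STAT1 is zero at t = {t_bad:g} min"
            )
        return (SUn + 2.0 * (SDn + SDnd)) / cyt
    raise KeyError(f"unknown observable {name!r}")


def observe(traj: Trajectory, sf: ScalingFactors) -> dict[str, ObservableSeries]:
    """All observable series for a trajectory under the given scaling factors."""
    out: dict[str, ObservableSeries] = {}
    for name in OBSERVABLE_NAMES:
        values = species_combination(name, traj)
        factor = BLOT_SCALING.get(name)
        if factor is not None:
            values = getattr(sf, factor) * values
        out[name] = ObservableSeries(name, traj.times, values, traj.dose)
    return out


def time_average_normalize(series: ObservableSeries) -> ObservableSeries:
    """Divide a series by its arithmetic time average (output mean = 1)."""
    if series.values.size == 0:
        raise ModelDomainError("cannot normalize an empty series")
    mean = float(series.values.mean())
    if mean <= 0:
        raise ModelDomainError(
            f"series {series.name!r} has non-positive time average {mean}"
        )
    return ObservableSeries(series.name, series.times, series.values / mean, series.dose)


def nuclear_phospho_fraction(
    traj: Trajectory, include_dna_bound: bool = False
) -> tuple[np.ndarray, float]:
    """Fraction of total STAT1 present as phosphorylated nuclear STAT1.

    Computed per time point in monomer equivalents,
    ``2·SDn / (SUc + SUn + 2·(SDc + SDn + SDnd))``; with ``include_dna_bound``
    the numerator also counts DNA-bound dimers.  Returns the per-time series
    and its maximum over the trajectory.
    """
    if traj.times.size == 0:
        raise ModelDomainError("empty trajectory")
    total = species_combination("STAT1_total", traj)
    if np.any(total <= 0):
        raise ModelDomainError("total STAT1 must be > 0 at every time point")
    numer = 2.0 * traj.species("SDn")
    if include_dna_bound:
        numer = numer + 2.0 * traj.species("SDnd")
    frac = numer / total
    return frac, float(frac.max())
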