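"""Distributed-delay ODE model of IFNγ-driven STAT1 signaling.

The model describes a minimal JAK/STAT reaction network in a cell with a
cytoplasmic and a nuclear compartment of equal effective area:

* IFNγ converts inactive receptor ``Ir`` into the active receptor complex
  ``IIr`` (Janus kinases are lumped into the complex); receptor deactivation
  and ligand degradation are neglected, so ``Ir + IIr = I_total`` is conserved
  and ``IIr`` rises monotonically towards ``I_total`` under stimulation.
* ``IIr`` phosphorylates unphosphorylated cytoplasmic STAT1 (``SUc``).
  Phosphorylated monomers dimerize rapidly, so phosphorylation flux feeds the
  cytoplasmic dimer pool ``SDc`` at half the monomer rate.
* Dimers are imported into the nucleus (``SDn``), bind DNA reversibly
  (``SDnd``), and only free nuclear dimers are dephosphorylated, dissociating
  into two unphosphorylated nuclear monomers (``SUn``).
* Unphosphorylated STAT1 shuttles between the compartments by free diffusion,
  modeled as symmetric first-order exchange.
* DNA-bound dimers drive transcription of SOCS1 and STAT1 mRNA through
  distributed delays; SOCS1 (via a further delayed signal standing in for
  translation) feeds back multiplicatively on the phosphorylation flux;
  STAT1 mRNA is translated into new ``SUc``.

Each distributed delay is realized as a linear chain of ``n_chain``
first-order stages with per-stage rate ``n_chain / tau``, which convolves the
driving signal with a gamma kernel of shape ``n_chain`` and mean ``tau``
(the "linear chain trick").

All concentrations are in arbitrary units; time is in minutes.  The initial
experimental total STAT1 is normalized to 1 by convention, hence the default
total receptor concentration of 0.1 (one tenth of total STAT1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields, replace
from typing import Sequence

import numpy as np
import yaml
from scipy.integrate import solve_ivp
from scipy.stats import gamma as _gamma_dist

__all__ = [
    "SPECIES",
    "KineticParameters",
    "Trajectory",
    "ModelDomainError",
    "IntegrationError",
    "derivatives",
    "simulate",
    "delay_chain_response",
    "load_parameters",
    "save_parameters",
]

#: Named (non-chain) state variables, in state-vector order.
SPECIES = ("IIr", "SUc", "SDc", "SDn", "SDnd", "SUn", "mSOCS1", "mSTAT1")

_N_NAMED = len(SPECIES)

#: Trajectory values more negative than this abort the integration; smaller
#: integrator undershoots are clipped to zero with a warning.
NEGATIVITY_TOLERANCE = 1e-9

#: Default integration tolerances (relative tolerance well below the 1e-8
#: contract so that fixed-step cross-checks agree to ~1e-6 relative).
DEFAULT_RTOL = 1e-9
DEFAULT_ATOL = 1e-12

#: Hard cap on right-hand-side evaluations per simulation.  Well-posed
#: parameter sets need a few thousand; runaway-stiff draws proposed during
#: stochastic search would otherwise stall the integrator indefinitely.
MAX_RHS_EVALS = 50_000


class ModelDomainError(ValueError):
    """Raised when a state, parameter or argument is outside the model domain."""


class IntegrationError(RuntimeError):
    """Raised when the ODE integrator fails; carries the failing time."""

    def __init__(self, message: str, time: float | None = None):
        super().__init__(message)
        self.time = time


class _EvaluationBudgetExceeded(Exception):
    def __init__(self, time: float):
        self.time = time


# Parameters whose natural scale is logarithmic (rate constants and delays).
RATE_PARAMETERS = (
    "k_act", "k_phos", "k_inh", "k_imp", "k_bind", "k_unbind", "k_deph",
    "k_shut", "k_txS", "k_degS", "k_txT", "k_degT", "k_transl",
)
DELAY_PARAMETERS = ("tau_socs", "tau_stat1", "tau_fb")
INITIAL_CONDITION_PARAMETERS = ("init_SUc", "init_SUn", "init_SDc")


@dataclass(frozen=True)
class KineticParameters:
    """Kinetic constants, mean delay times and free initial conditions.

    Scope (global vs per-dose) is a property of the fitting setup, not of the
    parameter values themselves; see :mod:`stat1kin.fitting`.
    """

    k_act: float      # receptor activation, per (a.u.·min); multiplies dose
    k_phos: float     # STAT1 phosphorylation by IIr, per (a.u.·min)
    k_inh: float      # SOCS1 feedback strength, per a.u.
    k_imp: float      # dimer nuclear import, per min
    k_bind: float     # dimer DNA binding, per min
    k_unbind: float   # dimer DNA unbinding, per min
    k_deph: float     # nuclear dephosphorylation/dissociation, per min
    k_shut: float     # unphosphorylated STAT1 shuttling exchange, per min
    k_txS: float      # SOCS1 mRNA production, per min
    k_degS: float     # SOCS1 mRNA degradation, per min
    k_txT: float      # STAT1 mRNA production, per min
    k_degT: float     # STAT1 mRNA degradation, per min
    k_transl: float   # STAT1 translation, per min
    tau_socs: float   # mean delay, SOCS1 transcription (min)
    tau_stat1: float  # mean delay, STAT1 transcription (min)
    tau_fb: float     # mean delay, SOCS1 negative feedback (min)
    n_chain: int = 3
    I_total: float = 0.1      # total receptor; 1/10 of initial total STAT1
    init_SUc: float = 0.5
    init_SUn: float = 0.5
    init_SDc: float = 0.0

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name == "n_chain":
                if int(v) != v or v < 1:
                    raise ModelDomainError("n_chain must be an integer >= 1")
                object.__setattr__(self, "n_chain", int(v))
            elif not np.isfinite(v) or v < 0:
                raise ModelDomainError(
                    f"parameter {f.name} must be finite and >= 0, got {v!r}"
                )
        for name in DELAY_PARAMETERS:
            if getattr(self, name) <= 0:
                raise ModelDomainError(f"{name} must be > 0")

    @property
    def n_state(self) -> int:
        return _N_NAMED + 3 * self.n_chain

    def initial_state(self) -> np.ndarray:
        """Initial state: IIr, SDn, SDnd, mRNAs and chain stages fixed at zero."""
        y0 = np.zeros(self.n_state)
        y0[1] = self.init_SUc
        y0[2] = self.init_SDc
        y0[5] = self.init_SUn
        return y0

    def replace(self, **kwargs) -> "KineticParameters":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "KineticParameters":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ModelDomainError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class Trajectory:
    """Time-resolved model state at a given IFNγ dose.

    ``states`` has one row per time point; the first eight columns are the
    named species in :data:`SPECIES` order, followed by the three delay-chain
    blocks (SOCS1 transcription, STAT1 transcription, feedback).
    """

    times: np.ndarray
    states: np.ndarray
    dose: float
    n_chain: int

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.states.shape[0] != self.times.shape[0]:
            raise ModelDomainError("times and states must have the same length")
        if self.times.size == 0:
            raise ModelDomainError("empty trajectory")

    def species(self, name: str) -> np.ndarray:
        """Column of a named species over time."""
        try:
            return self.states[:, SPECIES.index(name)]
        except ValueError:
            raise KeyError(f"unknown species {name!r}") from None

    def to_frame(self):
        """Tidy table with columns time_min, species, value, dose_ng_ml."""
        import pandas as pd

        rows = []
        names = list(SPECIES) + [
            f"chain_{block}_{i + 1}"
            for block in ("socs", "stat1", "fb")
            for i in range(self.n_chain)
        ]
        for j, name in enumerate(names):
            rows.append(
                pd.DataFrame(
                    {
                        "time_min": self.times,
                        "species": name,
                        "value": self.states[:, j],
                        "dose_ng_ml": self.dose,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def _make_rhs(params: KineticParameters, dose: float):
    """Build a fast RHS closure with parameters bound as local floats."""
    k_act = params.k_act
    k_phos = params.k_phos
    k_inh = params.k_inh
    k_imp = params.k_imp
    k_bind = params.k_bind
    k_unbind = params.k_unbind
    k_deph = params.k_deph
    k_shut = params.k_shut
    k_txS = params.k_txS
    k_degS = params.k_degS
    k_txT = params.k_txT
    k_degT = params.k_degT
    k_transl = params.k_transl
    I_total = params.I_total
    n = params.n_chain
    r_socs = n / params.tau_socs
    r_stat1 = n / params.tau_stat1
    r_fb = n / params.tau_fb
    i0, i1, i2 = _N_NAMED, _N_NAMED + n, _N_NAMED + 2 * n
    i3 = _N_NAMED + 3 * n

    def rhs(t, y, out=None):
        if out is None:
            out = np.empty(i3)
        IIr = y[0]
        SUc = y[1]
        SDc = y[2]
        SDn = y[3]
        SDnd = y[4]
        SUn = y[5]
        mS = y[6]
        mT = y[7]
        c_socs = y[i0:i1]
        c_stat1 = y[i1:i2]
        c_fb = y[i2:i3]
        z_socs = c_socs[-1]
        z_stat1 = c_stat1[-1]
        z_fb = c_fb[-1]

        v = k_phos * IIr * SUc / (1.0 + k_inh * z_fb)  # phosphorylation flux
        shuttle = k_shut * (SUn - SUc)

        out[0] = k_act * dose * (I_total - IIr)
        out[1] = -v + shuttle + k_transl * mT
        out[2] = 0.5 * v - k_imp * SDc
        out[3] = k_imp * SDc - k_bind * SDn + k_unbind * SDnd - k_deph * SDn
        out[4] = k_bind * SDn - k_unbind * SDnd
        out[5] = 2.0 * k_deph * SDn - shuttle
        out[6] = k_txS * z_socs - k_degS * mS
        out[7] = k_txT * z_stat1 - k_degT * mT
        # linear chains: stage 1 driven by the source, later stages in cascade
        out[i0] = r_socs * (SDnd - c_socs[0])
        out[i0 + 1:i1] = r_socs * (c_socs[:-1] - c_socs[1:])
        out[i1] = r_stat1 * (SDnd - c_stat1[0])
        out[i1 + 1:i2] = r_stat1 * (c_stat1[:-1] - c_stat1[1:])
        out[i2] = r_fb * (mS - c_fb[0])
        out[i2 + 1:i3] = r_fb * (c_fb[:-1] - c_fb[1:])
        return out

    return rhs


def derivatives(
    state: np.ndarray,
    t: float,
    params: KineticParameters,
    dose: float,
) -> np.ndarray:
    """Right-hand side of the ODE system at one state.

    Validating entry point; integration uses the same arithmetic through an
    internal closure.
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (params.n_state,):
        raise ModelDomainError(
            f"state must have length {params.n_state}, got shape {state.shape}"
        )
    if np.any(state < 0):
        bad = int(np.argmin(state))
        name = SPECIES[bad] if bad < _N_NAMED else f"chain[{bad - _N_NAMED}]"
        raise ModelDomainError(f"negative state component {name} = {state[bad]}")
    if dose < 0:
        raise ModelDomainError(f"negative dose {dose}")
    return _make_rhs(params, dose)(t, state)


def simulate(
    params: KineticParameters,
    dose: float,
    times: Sequence[float],
    *,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the model from its configured initial state.

    ``times`` must start at 0 and be strictly increasing; the returned
    trajectory holds the state at exactly those times.  Small integrator
    undershoots below zero (within ``NEGATIVITY_TOLERANCE``) are clipped.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 1:
        raise ModelDomainError("times must be a non-empty 1-D sequence")
    if times[0] != 0:
        raise ModelDomainError("times must start at 0")
    if times.size > 1 and np.any(np.diff(times) <= 0):
        raise ModelDomainError("times must be strictly increasing")
    if dose < 0:
        raise ModelDomainError(f"negative dose {dose}")

    y0 = params.initial_state()
    if times.size == 1:
        return Trajectory(times, y0[None, :], dose, params.n_chain)

    rhs = _make_rhs(params, dose)
    evals = [0]
    last_t = [times[0]]

    def budgeted_rhs(t, y):
        evals[0] += 1
        if evals[0] > MAX_RHS_EVALS:
            raise _EvaluationBudgetExceeded(t)
        last_t[0] = t
        return rhs(t, y)

    try:
        sol = solve_ivp(
            budgeted_rhs,
            (times[0], times[-1]),
            y0,
            method=method,
            t_eval=times,
            rtol=rtol,
            atol=atol,
        )
    except _EvaluationBudgetExceeded as exc:
        raise IntegrationError(
            f"integration stalled near t = {exc.time:g} min "
            f"(> {MAX_RHS_EVALS} derivative evaluations)",
            time=exc.time,
        ) from None
    if not sol.success:
        t_fail = float(sol.t[-1]) if sol.t.size else float(times[0])
        raise IntegrationError(
            f"integration failed at t = {t_fail:g} min: {sol.message}", time=t_fail
        )
    states = sol.y.T
    minval = states.min()
    if minval < 0:
        if minval < -NEGATIVITY_TOLERANCE:
            raise IntegrationError(
                f"trajectory went negative ({minval:.3e}) beyond tolerance"
            )
        warnings.warn(
            f"clipped small negative trajectory values (min {minval:.2e})",
            RuntimeWarning,
            stacklevel=2,
        )
        states = np.clip(states, 0.0, None)
    return Trajectory(times, states, dose, params.n_chain)


def delay_chain_response(
    tau: float, n_chain: int, times: Sequence[float]
) -> np.ndarray:
    """Normalized impulse response of the delay chain.

    A cascade of ``n_chain`` first-order stages with per-stage rate
    ``n_chain/tau`` has a gamma impulse response with shape ``n_chain``,
    mean ``tau`` and variance ``tau**2 / n_chain``.
    """
    if tau <= 0:
        raise ModelDomainError(f"tau must be > 0, got {tau}")
    if int(n_chain) != n_chain or n_chain < 1:
        raise ModelDomainError(f"n_chain must be an integer >= 1, got {n_chain}")
    times = np.asarray(times, dtype=float)
    return _gamma_dist.pdf(times, a=int(n_chain), scale=tau / n_chain)


# ---------------------------------------------------------------------------
# Parameter file round-tripping (flat key/value YAML with sections)
# ---------------------------------------------------------------------------

_SECTION_OF = {}
for _name in RATE_PARAMETERS + ("I_total", "n_chain"):
    _SECTION_OF[_name] = "kinetics"
for _name in DELAY_PARAMETERS:
    _SECTION_OF[_name] = "delays"
for _name in INITIAL_CONDITION_PARAMETERS:
    _SECTION_OF[_name] = "initial_conditions"


def save_parameters(params: KineticParameters, path, scopes: dict | None = None):
    """Write a sectioned YAML parameter file (kinetics/delays/initial_conditions)."""
    doc: dict = {"kinetics": {}, "delays": {}, "initial_conditions": {}}
    for name, value in params.to_dict().items():
        doc[_SECTION_OF[name]][name] = value
    if scopes is not None:
        doc["scopes"] = dict(scopes)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def load_parameters(path) -> tuple[KineticParameters, dict]:
    """Read a sectioned YAML parameter file; returns (parameters, scopes)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ModelDomainError("parameter file must be a mapping")
    scopes = doc.pop("scopes", {}) or {}
    flat: dict = {}
    for section, content in doc.items():
        if section not in ("kinetics", "delays", "initial_conditions"):
            raise ModelDomainError(f"unknown parameter-file section {section!r}")
        flat.update(content or {})
    return KineticParameters.from_dict(flat), scopes
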