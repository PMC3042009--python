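"""Independent oracles used by the test suite.

Everything here is hand-coded against the reaction network itself, not
against the package implementation: the right-hand side is assembled by
enumerating the individual reaction arrows with their stoichiometries, and
the reference integrator is a plain fixed-step classical Runge-Kutta loop.
"""

from __future__ import annotations

import numpy as np

N_NAMED = 8  # IIr, SUc, SDc, SDn, SDnd, SUn, mSOCS1, mSTAT1


def flux_enumeration_rhs(y, params, dose):
    """Sum of per-reaction stoichiometric contributions.

    Each arrow of the network is listed separately as
    (rate, {state index: stoichiometric coefficient}).
    """
    n = params.n_chain
    IIr, SUc, SDc, SDn, SDnd, SUn, mS, mT = y[:N_NAMED]
    chain_socs = y[N_NAMED:N_NAMED + n]
    chain_stat1 = y[N_NAMED + n:N_NAMED + 2 * n]
    chain_fb = y[N_NAMED + 2 * n:N_NAMED + 3 * n]

    reactions = []
    # receptor activation (no deactivation; Ir implicit as I_total - IIr)
    reactions.append((params.k_act * dose * (params.I_total - IIr), {0: +1}))
    # phosphorylation (one monomer per event) + rapid dimerization (half flux
    # into the dimer pool), inhibited by the delayed SOCS1 signal
    v = params.k_phos * IIr * SUc / (1.0 + params.k_inh * chain_fb[-1])
    reactions.append((v, {1: -1, 2: +0.5}))
    # nuclear import of cytoplasmic dimers
    reactions.append((params.k_imp * SDc, {2: -1, 3: +1}))
    # reversible DNA binding of nuclear dimers
    reactions.append((params.k_bind * SDn, {3: -1, 4: +1}))
    reactions.append((params.k_unbind * SDnd, {4: -1, 3: +1}))
    # dephosphorylation of free nuclear dimers -> two nuclear monomers
    reactions.append((params.k_deph * SDn, {3: -1, 5: +2}))
    # bidirectional shuttling of unphosphorylated STAT1
    reactions.append((params.k_shut * SUn, {5: -1, 1: +1}))
    reactions.append((params.k_shut * SUc, {1: -1, 5: +1}))
    # transcription driven by delayed DNA-bound dimer signals; degradation
    reactions.append((params.k_txS * chain_socs[-1], {6: +1}))
    reactions.append((params.k_degS * mS, {6: -1}))
    reactions.append((params.k_txT * chain_stat1[-1], {7: +1}))
    reactions.append((params.k_degT * mT, {7: -1}))
    # translation of STAT1 mRNA into cytoplasmic protein
    reactions.append((params.k_transl * mT, {1: +1}))
    # delay chains: first-order stages at rate n/tau
    for base, rate, source, block in (
        (N_NAMED, n / params.tau_socs, SDnd, chain_socs),
        (N_NAMED + n, n / params.tau_stat1, SDnd, chain_stat1),
        (N_NAMED + 2 * n, n / params.tau_fb, mS, chain_fb),
    ):
        prev = source
        for j in range(n):
            reactions.append((rate * (prev - block[j]), {base + j: +1}))
            prev = block[j]

    dy = np.zeros_like(np.asarray(y, dtype=float))
    for rate, stoich in reactions:
        for idx, coef in stoich.items():
            dy[idx] += coef * rate
    return dy


def rk4_simulate(params, dose, times, h=0.01):
    """Classical fixed-step RK4 over the flux-enumeration right-hand side."""
    times = np.asarray(times, dtype=float)
    y = np.zeros(N_NAMED + 3 * params.n_chain)
    y[1] = params.init_SUc
    y[2] = params.init_SDc
    y[5] = params.init_SUn

    def f(yv):
        return flux_enumeration_rhs(yv, params, dose)

    out = np.empty((times.size, y.size))
    t = times[0]
    out[0] = y
    for i in range(1, times.size):
        target = times[i]
        while t < target - 1e-12:
            step = min(h, target - t)
            k1 = f(y)
            k2 = f(y + 0.5 * step * k1)
            k3 = f(y + 0.5 * step * k2)
            k4 = f(y + step * k3)
            y = y + (step / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
            t += step
        out[i] = y
        t = target
    return out


def two_pass_mean_sem(values):
    """Textbook two-pass mean and SEM (n-1 standard deviation over sqrt(n))."""
    values = np.asarray(values, dtype=float)
    n = values.size
    mean = values.sum() / n
    var = ((values - mean) ** 2).sum() / (n - 1)
    return mean, np.sqrt(var / n) if n > 1 else float("nan")


def suffix_scan_plateau(grid, chi2, rel_tol):
    """Brute-force plateau: smallest grid value whose suffix is entirely flat."""
    for i in range(len(grid) - 1):
        flat = True
        for j in range(i, len(grid) - 1):
            if abs(chi2[j + 1] - chi2[j]) / chi2[j] > rel_tol:
                flat = False
                break
        if flat:
            return grid[i]
    return None
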