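"""Measurement arithmetic downstream of quantified assay signals.

Covers the normalization chain for immunoblot densitometry (loading-control
ratio, then per-replicate time-average normalization, then replicate
mean ± SEM), qPCR relative expression (2^−ΔCt against a housekeeping gene),
the confocal nuclear:cytoplasmic concentration ratio, and the ellipsoid
approximation for caliper tumor volumes.

Tabular inputs are plain pandas DataFrames with the column contracts stated
in each function.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .model import ModelDomainError
from .observables import ObservableSeries, time_average_normalize

__all__ = [
    "blot_normalize",
    "summarize_replicates",
    "qpcr_relative_expression",
    "average_technical_replicates",
    "qpcr_series",
    "rsnc_from_cells",
    "tumor_volume",
]

#: Ellipsoid shape constant for caliper tumor volumes (width² × length × 0.52).
TUMOR_VOLUME_CONSTANT = 0.52


def _require_columns(df: pd.DataFrame, cols: tuple[str, ...], what: str):
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ModelDomainError(f"{what} table is missing columns {missing}")


def blot_normalize(blots: pd.DataFrame) -> pd.DataFrame:
    """Loading-control and time-average normalization of blot intensities.

    Input columns: ``replicate``, ``time_min``, ``target_signal``,
    ``loading_signal`` (extra grouping columns are preserved).  Per time
    point the value is ``target_signal / loading_signal``; each replicate's
    series is then divided by its time average.  Returns a frame with
    ``replicate``, ``time_min``, ``value``.
    """
    _require_columns(
        blots, ("replicate", "time_min", "target_signal", "loading_signal"), "blot"
    )
    if (blots["target_signal"] < 0).any():
        raise ModelDomainError("negative target_signal in blot table")
    zero_loading = blots["loading_signal"] <= 0
    if zero_loading.any():
        t_bad = blots.loc[zero_loading, "time_min"].iloc[0]
        raise ModelDomainError(
            f"non-positive loading_signal at time {t_bad:g} min"
        )
    out = blots.copy()
    out["value"] = out["target_signal"] / out["loading_signal"]
    pieces = []
    for rep, grp in out.groupby("replicate", sort=False):
        if grp["time_min"].size < 2:
            raise ModelDomainError(
                f"replicate {rep!r} has fewer than 2 time points"
            )
        series = ObservableSeries(
            str(rep), grp["time_min"].to_numpy(), grp["value"].to_numpy(), np.nan
        )
        normalized = time_average_normalize(series)
        piece = grp.drop(columns=["target_signal", "loading_signal"]).copy()
        piece["value"] = normalized.values
        pieces.append(piece)
    return pd.concat(pieces, ignore_index=True)


def summarize_replicates(values: pd.DataFrame) -> pd.DataFrame:
    """Mean ± SEM over replicates per time point.

    Input columns: ``replicate``, ``time_min``, ``value``.  SEM is the
    n−1 sample standard deviation divided by √n; every time point needs at
    least two replicates for the SEM to be defined.
    """
    _require_columns(values, ("replicate", "time_min", "value"), "replicate-series")
    grouped = values.groupby("time_min", sort=True)["value"]
    counts = grouped.count()
    if (counts < 2).any():
        t_bad = counts.index[counts < 2][0]
        raise ModelDomainError(
            f"time point {t_bad:g} min has fewer than 2 replicates; SEM undefined"
        )
    summary = pd.DataFrame(
        {
            "time_min": counts.index.to_numpy(dtype=float),
            "mean": grouped.mean().to_numpy(),
            "sem": (grouped.std(ddof=1) / np.sqrt(counts)).to_numpy(),
        }
    )
    return summary.reset_index(drop=True)


def qpcr_relative_expression(ct_target, ct_hprt):
    """Relative mRNA amount ``2 ** -(Ct_target - Ct_HPRT)``."""
    ct_target = np.asarray(ct_target, dtype=float)
    ct_hprt = np.asarray(ct_hprt, dtype=float)
    if not (np.all(np.isfinite(ct_target)) and np.all(np.isfinite(ct_hprt))):
        raise ModelDomainError("Ct values must be finite")
    out = np.exp2(-(ct_target - ct_hprt))
    return float(out) if out.ndim == 0 else out


def average_technical_replicates(
    qpcr: pd.DataFrame, domain: str = "ct"
) -> pd.DataFrame:
    """Collapse technical qPCR replicates per (replicate, time, gene).

    ``domain='ct'`` (default) averages Ct values before exponentiation;
    ``domain='linear'`` averages the 2^−ΔCt values instead.  Returns one row
    per biological replicate and time with a ``rel_expr`` column.
    """
    _require_columns(
        qpcr, ("replicate", "time_min", "gene", "ct_target", "ct_hprt"), "qPCR"
    )
    if domain not in ("ct", "linear"):
        raise ModelDomainError(f"unknown averaging domain {domain!r}")
    keys = ["gene", "replicate", "time_min"]
    if domain == "ct":
        agg = qpcr.groupby(keys, sort=False)[["ct_target", "ct_hprt"]].mean()
        agg = agg.reset_index()
        agg["rel_expr"] = qpcr_relative_expression(agg["ct_target"], agg["ct_hprt"])
        return agg.drop(columns=["ct_target", "ct_hprt"])
    tmp = qpcr.copy()
    tmp["rel_expr"] = qpcr_relative_expression(tmp["ct_target"], tmp["ct_hprt"])
    return tmp.groupby(keys, sort=False)["rel_expr"].mean().reset_index()


def qpcr_series(qpcr: pd.DataFrame, domain: str = "ct") -> pd.DataFrame:
    """Full qPCR chain: technical averaging, per-replicate time normalization,
    replicate summary.  Returns columns ``gene``, ``time_min``, ``mean``, ``sem``."""
    rel = average_technical_replicates(qpcr, domain=domain)
    out = []
    for gene, gene_grp in rel.groupby("gene", sort=False):
        pieces = []
        for rep, grp in gene_grp.groupby("replicate", sort=False):
            series = ObservableSeries(
                str(rep), grp["time_min"].to_numpy(), grp["rel_expr"].to_numpy(), np.nan
            )
            normalized = time_average_normalize(series)
            pieces.append(
                pd.DataFrame(
                    {
                        "replicate": rep,
                        "time_min": grp["time_min"].to_numpy(),
                        "value": normalized.values,
                    }
                )
            )
        summary = summarize_replicates(pd.concat(pieces, ignore_index=True))
        summary.insert(0, "gene", gene)
        out.append(summary)
    return pd.concat(out, ignore_index=True)


def rsnc_from_cells(cells: pd.DataFrame) -> tuple[float, float, np.ndarray]:
    """Nuclear:cytoplasmic STAT1 concentration ratio from per-cell intensities.

    Input columns: ``nuc_sum``, ``nuc_area``, ``cyt_sum``, ``cyt_area``.
    Per cell the ratio of mean pixel intensities (sum / area) is computed;
    returns (mean, SEM, per-cell ratios).  With a single cell the SEM is NaN.
    """
    _require_columns(cells, ("nuc_sum", "nuc_area", "cyt_sum", "cyt_area"), "cell")
    if len(cells) < 1:
        raise ModelDomainError("need at least one cell")
    if (cells["nuc_area"] <= 0).any() or (cells["cyt_area"] <= 0).any():
        raise ModelDomainError("cell areas must be > 0")
    zero_cyt = cells["cyt_sum"] <= 0
    if zero_cyt.any():
        idx = cells.index[zero_cyt][0]
        raise ModelDomainError(f"cell {idx} has zero cytoplasmic signal")
    ratios = (cells["nuc_sum"] / cells["nuc_area"]) / (
        cells["cyt_sum"] / cells["cyt_area"]
    )
    ratios = ratios.to_numpy(dtype=float)
    n = ratios.size
    mean = float(ratios.mean())
    sem = float(ratios.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
    return mean, sem, ratios


def tumor_volume(width: float, length: float) -> float:
    """Caliper tumor volume, width² × length × 0.52 (ellipsoid approximation).

    Width is taken as the smaller caliper reading; swapped readings are
    reordered with a warning.
    """
    if width <= 0 or length <= 0:
        raise ModelDomainError("tumor dimensions must be > 0")
    if width > length:
        warnings.warn(
            "width > length; swapping so that width is the smaller dimension",
            UserWarning,
            stacklevel=2,
        )
        width, length = length, width
    return width**2 * length * TUMOR_VOLUME_CONSTANT
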