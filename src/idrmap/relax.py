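"""15N relaxation analysis and exchange-free R2 decomposition.

The transverse cross-correlated relaxation rate eta_xy (1H-15N dipolar /
15N-CSA cross-correlation) is exchange-free by construction, so it anchors
an exchange-free estimate of R2:

    sigma  = (NOE - 1) * R1 * gammaN/gammaH      (cross-relaxation term)
    R2_0   = kappa * eta_xy + 1.3 * sigma        (exchange-free R2)
    Rex    = R2(CPMG) - R2_0                     (conformational exchange)

kappa is an empirical, field-dependent scaling (default 1.45). gammaN/gammaH
is the *signed* gyromagnetic ratio (gammaN < 0), so sigma > 0 whenever
NOE < 1, keeping R2_0 a positive rate for disordered chains.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit, least_squares

from .errors import InvalidInputError
from .synth import GAMMA_RATIO_15N_1H

KAPPA_DEFAULT = 1.45

#: delay grids from the acquisition scheme (seconds); duplicates are used
#: for error estimation
R1_DELAYS = (0.01, 0.01, 0.02, 0.04, 0.08, 0.12, 0.16, 0.32, 0.64, 1.28)
R2_DELAYS = (0.00848, 0.00848, 0.01696, 0.03392, 0.05088, 0.06784, 0.10176,
             0.13568, 0.1696, 0.20352, 0.23744, 0.27136)
ETA_XY_DELAYS = (0.060, 0.100)


# ---------------------------------------------------------------------------
# rate fitting

def fit_decay(series: pd.DataFrame) -> pd.DataFrame:
    """Fit mono-exponential decays I(t) = I0 * exp(-R t) per residue.

    Expects columns (residue, delay, intensity). Returns rate, its SD from
    the fit covariance, and the RMS of residuals. Non-convergent residues
    are flagged (``converged = False``) rather than fatal; non-positive
    intensities raise an error since a decay series cannot contain them.
    """
    for col in ("residue", "delay", "intensity"):
        if col not in series.columns:
            raise InvalidInputError(f"intensity series missing column {col!r}")
    if (series.intensity <= 0).any():
        raise InvalidInputError("decay series intensities must be positive")

    rows = []
    for residue, grp in series.groupby("residue", sort=True):
        t = grp.delay.to_numpy(float)
        y = grp.intensity.to_numpy(float)
        if len(np.unique(t)) < 4:
            raise InvalidInputError(
                f"residue {residue}: need >= 4 distinct delays, "
                f"got {len(np.unique(t))}")
        # log-linear start; slope clipped at 0 so constant series fit cleanly
        slope, intercept = np.polyfit(t, np.log(y), 1)
        p0 = (float(np.exp(intercept)), max(0.0, -slope))
        try:
            popt, pcov = curve_fit(lambda tt, i0, r: i0 * np.exp(-r * tt),
                                   t, y, p0=p0, maxfev=5000)
            resid = y - popt[0] * np.exp(-popt[1] * t)
            sd = float(np.sqrt(pcov[1, 1])) if np.isfinite(pcov[1, 1]) else np.nan
            rows.append(dict(residue=residue, rate=float(popt[1]), rate_sd=sd,
                             rms_residual=float(np.sqrt(np.mean(resid**2))),
                             converged=True))
        except RuntimeError:
            rows.append(dict(residue=residue, rate=np.nan, rate_sd=np.nan,
                             rms_residual=np.nan, converged=False))
    return pd.DataFrame(rows)


def het_noe(sat: pd.DataFrame, ref: pd.DataFrame) -> pd.DataFrame:
    """Steady-state {1H}-15N NOE per residue: I_sat / I_ref.

    ``sat`` and ``ref`` carry (residue, intensity, replicate); the NOE SD is
    estimated from the spread across repeats. Residues with non-positive
    reference intensity are flagged instead of fatal.
    """
    merged = sat.merge(ref, on=["residue", "replicate"],
                       suffixes=("_sat", "_ref"))
    rows = []
    for residue, grp in merged.groupby("residue", sort=True):
        if (grp.intensity_ref <= 0).any():
            rows.append(dict(residue=residue, noe=np.nan, noe_sd=np.nan,
                             flagged=True))
            continue
        ratios = (grp.intensity_sat / grp.intensity_ref).to_numpy()
        rows.append(dict(residue=residue, noe=float(ratios.mean()),
                         noe_sd=float(ratios.std(ddof=1)) if len(ratios) > 1
                         else 0.0,
                         flagged=False))
    return pd.DataFrame(rows)


def eta_xy(i_a: float | np.ndarray, i_b: float | np.ndarray,
           two_delta: float) -> float | np.ndarray:
    """Invert I_A/I_B = tanh(2*Delta*eta_xy) at a single relaxation delay."""
    if two_delta <= 0:
        raise InvalidInputError("two_delta must be > 0")
    ratio = np.asarray(i_a, dtype=float) / np.asarray(i_b, dtype=float)
    if np.any(np.abs(ratio) >= 1):
        raise InvalidInputError(
            "|I_A/I_B| >= 1 cannot be inverted (exchange or noise artifact); "
            "use eta_xy_fit which flags such residues")
    out = np.arctanh(ratio) / two_delta
    return float(out) if out.ndim == 0 else out


def eta_xy_fit(series: pd.DataFrame,
               delays: Sequence[float] = ETA_XY_DELAYS) -> pd.DataFrame:
    """Per-residue eta_xy from scheme-A/B intensities at one or more delays.

    Expects columns (residue, delay, scheme, intensity) with scheme in
    {A, B}. Residues with any |I_A/I_B| >= 1 are flagged, not fatal. With
    several delays the estimate is a joint least-squares fit of
    tanh(2*Delta*eta); per-delay inversions are also reported.
    """
    rows = []
    for residue, grp in series.groupby("residue", sort=True):
        ratios, used = [], []
        for delay in delays:
            sub = grp[np.isclose(grp.delay, delay)]
            if sub.empty:
                continue
            ia = sub[sub.scheme == "A"].intensity.mean()
            ib = sub[sub.scheme == "B"].intensity.mean()
            ratios.append(ia / ib)
            used.append(delay)
        if not ratios or any(abs(r) >= 1 for r in ratios):
            rows.append(dict(residue=residue, eta_xy=np.nan, flagged=True,
                             per_delay=()))
            continue
        per_delay = tuple(float(np.arctanh(r) / d) for r, d in zip(ratios, used))
        if len(ratios) == 1:
            joint = per_delay[0]
        else:
            res = least_squares(
                lambda e: np.array(ratios) - np.tanh(np.array(used) * e),
                x0=float(np.mean(per_delay)))
            joint = float(res.x[0])
        rows.append(dict(residue=residue, eta_xy=joint, flagged=False,
                         per_delay=per_delay))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# exchange-free decomposition

def exchange_decomposition(obs: pd.DataFrame, kappa: float = KAPPA_DEFAULT,
                           gamma_ratio: float = GAMMA_RATIO_15N_1H) -> pd.DataFrame:
    """Fill sigma, r2_zero and rex columns from R1, R2, noe and eta_xy.

    Residues missing any input are skipped with a reason column. When sd
    columns (R1_sd, R2_sd, noe_sd, eta_xy_sd) are present, first-order
    (delta-method) propagation fills rex_sd.
    """
    needed = ("R1", "R2", "noe", "eta_xy")
    missing = [c for c in needed if c not in obs.columns]
    if missing:
        raise InvalidInputError(f"observables missing columns {missing}")
    out = obs.copy()
    ok = out[list(needed)].notna().all(axis=1)
    out["sigma"] = np.where(ok, (out.noe - 1.0) * out.R1 * gamma_ratio, np.nan)
    out["r2_zero"] = np.where(ok, kappa * out.eta_xy + 1.3 * out.sigma, np.nan)
    out["rex"] = np.where(ok, out.R2 - out.r2_zero, np.nan)
    out["skip_reason"] = np.where(ok, "", "missing input")
    if all(f"{c}_sd" in out.columns for c in needed):
        var_sigma = (gamma_ratio**2 * ((out.noe - 1.0)**2 * out.R1_sd**2
                                       + out.R1**2 * out.noe_sd**2))
        var_r2z = kappa**2 * out.eta_xy_sd**2 + 1.3**2 * var_sigma
        out["rex_sd"] = np.sqrt(out.R2_sd**2 + var_r2z)
    return out


# ---------------------------------------------------------------------------
# binding perturbation

@dataclass(frozen=True)
class PerturbedInterval:
    start: int
    end: int

    def residues(self) -> range:
        return range(self.start, self.end + 1)


def binding_perturbation(apo: pd.DataFrame, bound: pd.DataFrame,
                         sd_mult: float = 1.0,
                         trim_fraction: float = 0.0) -> pd.DataFrame:
    """Per-residue Delta-R2 between +ligand and apo states with 1-SD flags.

    Delta-R2 = R2(bound) - R2(apo); the significance threshold is sd_mult
    times the SD of Delta-R2 over all matched residues (optionally a
    symmetrically trimmed subset via ``trim_fraction``). Contiguous flagged
    runs are summarised as perturbed intervals in ``result.attrs``.
    """
    merged = apo[["residue", "R2"]].merge(bound[["residue", "R2"]],
                                          on="residue",
                                          suffixes=("_apo", "_bound"))
    if merged.empty:
        raise InvalidInputError("no matched residues between states")
    merged["delta_r2"] = merged.R2_bound - merged.R2_apo
    values = merged.delta_r2.to_numpy()
    if trim_fraction > 0:
        k = int(len(values) * trim_fraction)
        trimmed = np.sort(values)[k: len(values) - k] if k else values
        sd = float(np.std(trimmed, ddof=1))
    else:
        sd = float(np.std(values, ddof=1))
    merged["flagged"] = merged.delta_r2 > sd * sd_mult
    merged.attrs["sd"] = sd
    intervals: list[PerturbedInterval] = []
    run: list[int] = []
    for residue, flag in zip(merged.residue, merged.flagged):
        if flag and (not run or residue == run[-1] + 1):
            run.append(int(residue))
        else:
            if run:
                intervals.append(PerturbedInterval(run[0], run[-1]))
            run = [int(residue)] if flag else []
    if run:
        intervals.append(PerturbedInterval(run[0], run[-1]))
    merged.attrs["intervals"] = tuple(intervals)
    return merged
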