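"""Ligand-depletion anisotropy binding fit.

With labelled receptor at a concentration comparable to the dissociation
constant, the free-ligand approximation (hyperbolic isotherm) fails; the
bound fraction must come from the exact quadratic solution of the 1:1
equilibrium. All concentrations are *final* (post-mix): a 1:1 mixing step
halves the nominal dilution-series values, and the titration reader applies
a declared mixing factor so the convention is explicit.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import DegenerateFitError, InsufficientDesignError, InvalidInputError
from .io import read_header_meta

logger = logging.getLogger("idrmap")


def fraction_bound(kd: float, lt: float, rt: float) -> float:
    """Fraction of receptor bound under ligand depletion (1:1 binding).

    Quadratic solution: fb = (kd + lt + rt - sqrt((kd + lt + rt)^2 - 4 lt rt))
    / (2 rt). Valid inputs cannot make the discriminant negative; a numerical
    guard clips tiny negative values from cancellation.
    """
    if kd < 0 or lt < 0:
        raise InvalidInputError("kd and ligand concentration must be >= 0")
    if rt <= 0:
        raise InvalidInputError("receptor concentration must be > 0")
    s = kd + lt + rt
    disc = max(0.0, s * s - 4.0 * lt * rt)
    # stable root: avoids cancellation when 4*lt*rt << s**2
    return 2.0 * lt / (s + np.sqrt(disc))


def _model(lt: np.ndarray, kd: float, r_free: float, r_bound: float,
           rt: float) -> np.ndarray:
    s = kd + lt + rt
    disc = np.maximum(0.0, s * s - 4.0 * lt * rt)
    fb = 2.0 * lt / (s + np.sqrt(disc))
    return r_free + (r_bound - r_free) * fb


@dataclass
class BindingFit:
    """Result of a ligand-depletion anisotropy fit."""

    kd: float                      # nM, pooled fit
    kd_se: float                   # asymptotic SE of the pooled fit
    kd_sem: float | None           # SEM of per-replicate kd estimates
    r_free: float
    r_free_se: float
    r_bound: float
    r_bound_se: float
    receptor_total: float          # nM, fixed
    residuals: np.ndarray = field(repr=False, default=None)
    replicate_kds: tuple[float, ...] = ()
    n_points: int = 0
    converged: bool = True

    def summary(self) -> str:
        sem = f"{self.kd_sem:.3g}" if self.kd_sem is not None else "n/a"
        return (f"Kd = {self.kd:.3g} nM (pooled SE {self.kd_se:.3g}, "
                f"replicate SEM {sem}); r_free = {self.r_free:.4f}, "
                f"r_bound = {self.r_bound:.4f}; receptor {self.receptor_total} nM; "
                f"{self.n_points} points, "
                f"{len(self.replicate_kds)} replicates")


def _fit_once(lt: np.ndarray, r: np.ndarray, rt: float) -> tuple[np.ndarray, np.ndarray]:
    if np.ptp(r) < 1e-12:
        raise DegenerateFitError(
            "anisotropy is constant across the titration (r_bound == r_free)")
    p0 = (float(np.median(lt)), float(r[np.argmin(lt)]), float(r[np.argmax(lt)]))
    popt, pcov = curve_fit(lambda x, kd, rf, rb: _model(x, kd, rf, rb, rt),
                           lt, r, p0=p0,
                           bounds=([1e-9, -np.inf, -np.inf],
                                   [np.inf, np.inf, np.inf]),
                           maxfev=10000)
    return popt, pcov


def fit_titration(points: pd.DataFrame, receptor_total: float) -> BindingFit:
    """Fit r(L_t) = r_free + (r_bound - r_free) * fb(Kd, L_t, R_t).

    Nonlinear least squares on all points pooled, plus independent fits per
    replicate; the replicate-wise Kd values give the SEM matching the
    convention of reporting Kd +/- SEM over technical replicates. Warns when
    fewer than 6 distinct concentrations bracket the fitted Kd.
    """
    if receptor_total <= 0:
        raise InvalidInputError("receptor_total must be > 0")
    for col in ("ligand_total", "anisotropy"):
        if col not in points.columns:
            raise InvalidInputError(f"titration table missing column {col!r}")
    if (points.ligand_total < 0).any():
        raise InvalidInputError("ligand concentrations must be >= 0")
    distinct = points.ligand_total.nunique()
    if distinct < 4:
        raise InsufficientDesignError(
            f"only {distinct} distinct ligand concentrations; need >= 4")

    lt = points.ligand_total.to_numpy(float)
    r = points.anisotropy.to_numpy(float)
    popt, pcov = _fit_once(lt, r, receptor_total)
    perr = np.sqrt(np.diag(pcov))
    kd = float(popt[0])

    if distinct < 6:
        warnings.warn("fewer than 6 distinct ligand concentrations; "
                      "the Kd may be poorly constrained", stacklevel=2)
    if not (lt.min() < kd < lt.max()):
        warnings.warn(f"fitted Kd {kd:.3g} nM lies outside the titrated range "
                      f"[{lt.min():.3g}, {lt.max():.3g}] nM", stacklevel=2)

    rep_kds: list[float] = []
    if "replicate" in points.columns and points.replicate.nunique() > 1:
        for _, grp in points.groupby("replicate"):
            try:
                p_rep, _ = _fit_once(grp.ligand_total.to_numpy(float),
                                     grp.anisotropy.to_numpy(float),
                                     receptor_total)
                rep_kds.append(float(p_rep[0]))
            except (DegenerateFitError, RuntimeError):
                logger.warning("replicate fit failed; excluded from SEM")
    kd_sem = (float(np.std(rep_kds, ddof=1) / np.sqrt(len(rep_kds)))
              if len(rep_kds) > 1 else None)

    residuals = r - _model(lt, *popt, receptor_total)
    return BindingFit(kd=kd, kd_se=float(perr[0]), kd_sem=kd_sem,
                      r_free=float(popt[1]), r_free_se=float(perr[1]),
                      r_bound=float(popt[2]), r_bound_se=float(perr[2]),
                      receptor_total=receptor_total, residuals=residuals,
                      replicate_kds=tuple(rep_kds), n_points=len(points))


def read_titration(path: str | Path) -> tuple[pd.DataFrame, float]:
    """Read a titration TSV with header metadata.

    Header comments declare ``receptor_total`` (nM, final) and optionally
    ``mix_factor``: when ``scale: nominal`` is declared, all concentrations
    (including receptor_total) are divided by the mixing factor to obtain
    final, post-mix values. Returns (points, receptor_total).
    """
    meta = read_header_meta(path)
    if "receptor_total" not in meta:
        raise InvalidInputError(f"{path}: header must declare receptor_total (nM)")
    receptor_total = float(meta["receptor_total"])
    df = pd.read_csv(path, sep="\t", comment="#")
    if meta.get("scale", "final") == "nominal":
        factor = float(meta.get("mix_factor", 2.0))
        logger.info("read_titration: nominal scale declared; dividing "
                    "concentrations by mix_factor %.3g", factor)
        df["ligand_total"] = df.ligand_total / factor
        receptor_total /= factor
    return df, receptor_total
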