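"""Differential HDX-MS analysis: fraction exchanged, Woods-plot statistics,
and protected/deprotected region calling.

State-order convention: differences are computed as ``state B - state A``.
With A = free protein and B = protein + partner, *reduced* uptake in the
bound state gives negative differences, so protection corresponds to
``delta_fx < -threshold`` (``protected_sign = -1``, the default). The CLI
documents and logs this convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (DegeneratePeptideError, InvalidInputError,
                     MissingControlError, ParseError)
from .io import DEUTERIUM_MASS_SHIFT, SequenceRecord, count_exchangeable

logger = logging.getLogger("idrmap")

PEPTIDE_KEY = ["protein", "start", "end", "sequence"]


# ---------------------------------------------------------------------------
# fraction exchanged

def fraction_exchanged(records: pd.DataFrame,
                       normalization: str = "theoretical") -> pd.DataFrame:
    """Normalise peptide masses to fraction exchanged.

    ``fx = (m_t - m_0) / (m_max - m_0)`` with ``m_0`` from the non-deuterated
    control. ``m_max`` comes from the 24 h maximally-labelled control
    (``normalization='max-labelled'``) or from ``m_0`` plus the theoretical
    exchangeable-amide count times the deuterium mass shift
    (``normalization='theoretical'``; appropriate when uptake is not
    corrected for back-exchange). Charge states of the same peptide are
    pooled. Returns replicate mean, SD and count per peptide/state/time.
    """
    if normalization not in {"theoretical", "max-labelled"}:
        raise InvalidInputError(f"unknown normalization {normalization!r}")
    required = set(PEPTIDE_KEY + ["state", "time", "replicate", "mass_centroid",
                                  "exposure_control"])
    missing = required - set(records.columns)
    if missing:
        raise InvalidInputError(f"uptake table missing columns {sorted(missing)}")

    out_rows = []
    for key, grp in records.groupby(PEPTIDE_KEY + ["state"], sort=False):
        protein, start, end, seq_str, state = key
        nd = grp[grp.exposure_control == "non-deuterated"]
        if nd.empty:
            raise MissingControlError(
                f"no non-deuterated control for peptide {start}-{end} ({state})")
        m0 = nd.mass_centroid.mean()
        if normalization == "max-labelled":
            mx = grp[grp.exposure_control == "max-labelled"]
            if mx.empty:
                raise MissingControlError(
                    f"no maximally-labelled control for peptide {start}-{end} "
                    f"({state}); required by max-labelled normalization")
            m_max = mx.mass_centroid.mean()
        else:
            n_ex, _ = count_exchangeable(seq_str)
            m_max = m0 + n_ex * DEUTERIUM_MASS_SHIFT
        if m_max <= m0:
            raise DegeneratePeptideError(
                f"peptide {start}-{end}: m_max <= m_0 (no exchangeable amides?)")
        span = m_max - m0
        pts = grp[grp.exposure_control == "timepoint"]
        for time, tgrp in pts.groupby("time", sort=True):
            fx = (tgrp.mass_centroid - m0) / span
            out_rows.append(dict(protein=protein, start=start, end=end,
                                 sequence=seq_str, state=state, time=time,
                                 mean_fx=float(fx.mean()),
                                 sd_fx=float(fx.std(ddof=1)) if len(fx) > 1 else 0.0,
                                 n=int(len(fx))))
    return pd.DataFrame(out_rows)


# ---------------------------------------------------------------------------
# differential uptake

def _welch_df(sa: float, na: int, sb: float, nb: int) -> float:
    va, vb = sa**2 / na, sb**2 / nb
    if va + vb == 0:
        return float(na + nb - 2)
    denom = 0.0
    if na > 1:
        denom += va**2 / (na - 1)
    if nb > 1:
        denom += vb**2 / (nb - 1)
    return (va + vb) ** 2 / denom if denom > 0 else float(na + nb - 2)


def differential_uptake(fx_a: pd.DataFrame, fx_b: pd.DataFrame,
                        levels: Sequence[float] = (0.98, 0.99)) -> pd.DataFrame:
    """Per-peptide, per-time difference in fraction exchanged (B - A).

    The combined uncertainty is ``u_c = sqrt(sd_A^2/n_A + sd_B^2/n_B)`` and
    the confidence half-widths come from two-tailed t quantiles at the given
    levels with Welch-Satterthwaite degrees of freedom. Peptide/time pairs
    present in only one state are skipped; a completeness summary is stored
    in ``result.attrs`` and logged.
    """
    key = PEPTIDE_KEY + ["time"]
    merged = fx_a.merge(fx_b, on=key, suffixes=("_a", "_b"), how="outer",
                        indicator=True)
    unmatched = merged[merged._merge != "both"]
    if len(unmatched):
        logger.warning("differential_uptake: skipped %d unmatched peptide/time pairs",
                       len(unmatched))
    both = merged[merged._merge == "both"].copy()
    both["delta_fx"] = both.mean_fx_b - both.mean_fx_a
    both["u_c"] = np.sqrt(both.sd_fx_a**2 / both.n_a + both.sd_fx_b**2 / both.n_b)
    dfs = [_welch_df(sa, na, sb, nb) for sa, na, sb, nb in
           zip(both.sd_fx_a, both.n_a, both.sd_fx_b, both.n_b)]
    for level in levels:
        q = [stats.t.ppf(1 - (1 - level) / 2, df) if uc > 0 else 0.0
             for df, uc in zip(dfs, both.u_c)]
        both[f"ci{int(round(level * 100))}"] = np.asarray(q) * both.u_c.to_numpy()
    out = both[key + ["delta_fx", "u_c"]
               + [f"ci{int(round(l * 100))}" for l in levels]
               + ["n_a", "n_b"]].reset_index(drop=True)
    out.attrs["matched"] = int(len(both))
    out.attrs["unmatched"] = int(len(unmatched))
    return out


# ---------------------------------------------------------------------------
# region calling

@dataclass(frozen=True)
class RegionCall:
    """A contiguous residue interval flagged as protected or deprotected."""

    protein: str
    start: int
    end: int
    direction: str                      # "protected" | "deprotected"
    rule_branch: str                    # "multi-timepoint" | "multi-peptide" | both
    peptides: tuple[tuple[int, int], ...]
    times: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise InvalidInputError("region start > end")

    def residues(self) -> range:
        return range(self.start, self.end + 1)


def _amide_positions(start: int, sequence: str) -> set[int]:
    """Residue numbers within a peptide that carry observable amide signal."""
    return {start + i for i, aa in enumerate(sequence)
            if i > 0 and aa != "P"}


def call_regions(diffs: pd.DataFrame, threshold: float = 0.05,
                 min_timepoints: int = 2, min_peptides: int = 3,
                 protected_sign: int = -1, branch2: bool = True,
                 trim: str = "subtractive") -> list[RegionCall]:
    """Call protected/deprotected regions from differential uptake.

    Two rule branches, evaluated per direction with strict inequality
    (``|delta_fx| > threshold``):

    * multi-timepoint — a peptide exceeding the threshold (same sign) at
      >= ``min_timepoints`` observed time points flags its footprint;
    * multi-peptide — >= ``min_peptides`` mutually overlapping peptides
      exceeding the threshold at a single time point flag their union
      (in one dimension, pairwise overlap is equivalent to sharing a
      residue, so groups are found via coverage counts).

    Flagged footprints are merged into maximal contiguous intervals per
    direction. With ``trim='subtractive'`` (default), residues whose amide
    signal is covered by a *quiescent* peptide — one never exceeding the
    threshold at any time point — are removed, sub-localising the call the
    way overlapping peptic peptides are used in practice; ``trim='none'``
    keeps the raw peptide-footprint union.
    """
    if trim not in {"subtractive", "none"}:
        raise InvalidInputError(f"unknown trim mode {trim!r}")
    if protected_sign not in (-1, 1):
        raise InvalidInputError("protected_sign must be -1 or +1")
    if diffs.empty:
        return []

    calls: list[RegionCall] = []
    for protein, dgrp in diffs.groupby("protein", sort=False):
        peptides = dgrp[["start", "end", "sequence"]].drop_duplicates()
        lo, hi = int(peptides.start.min()), int(peptides.end.max())
        n_res = hi - lo + 1

        # quiescent peptides: never exceed the threshold at any time point
        quiet_veto = np.zeros(n_res, dtype=bool)
        if trim == "subtractive":
            max_abs = dgrp.groupby(PEPTIDE_KEY).delta_fx.agg(
                lambda s: float(np.max(np.abs(s))))
            for (_, start, end, seq_str), m in max_abs.items():
                if m <= threshold:
                    for pos in _amide_positions(int(start), seq_str):
                        quiet_veto[pos - lo] = True

        for direction, sign in (("protected", protected_sign),
                                ("deprotected", -protected_sign)):
            signed = dgrp.assign(excess=dgrp.delta_fx * sign)
            exceed = signed[signed.excess > threshold]

            footprints: list[tuple[int, int, str, tuple[int, int],
                                   tuple[float, ...]]] = []
            # branch 1: same peptide, >= min_timepoints observed time points
            for (prot, start, end, seq_str), pgrp in exceed.groupby(PEPTIDE_KEY):
                times = tuple(sorted(set(pgrp.time)))
                if len(times) >= min_timepoints:
                    footprints.append((int(start), int(end), "multi-timepoint",
                                       (int(start), int(end)), times))
            # branch 2: >= min_peptides mutually overlapping peptides, one time
            if branch2:
                for time, tgrp in exceed.groupby("time"):
                    peps = tgrp[["start", "end"]].drop_duplicates()
                    if len(peps) < min_peptides:
                        continue
                    cov = np.zeros(n_res, dtype=int)
                    for s, e in zip(peps.start, peps.end):
                        cov[s - lo : e - lo + 1] += 1
                    core = cov >= min_peptides
                    if not core.any():
                        continue
                    for run_start, run_end in _runs(core, lo):
                        members = peps[(peps.start <= run_end) &
                                       (peps.end >= run_start)]
                        for s, e in zip(members.start, members.end):
                            footprints.append((int(s), int(e), "multi-peptide",
                                               (int(s), int(e)), (float(time),)))

            if not footprints:
                continue
            mask = np.zeros(n_res, dtype=bool)
            for s, e, *_ in footprints:
                mask[s - lo : e - lo + 1] = True
            if trim == "subtractive":
                mask &= ~quiet_veto
            for run_start, run_end in _runs(mask, lo):
                support = sorted({fp[3] for fp in footprints
                                  if fp[0] <= run_end and fp[1] >= run_start})
                branches = sorted({fp[2] for fp in footprints
                                   if fp[0] <= run_end and fp[1] >= run_start})
                times = sorted({t for fp in footprints
                                if fp[0] <= run_end and fp[1] >= run_start
                                for t in fp[4]})
                calls.append(RegionCall(protein=protein, start=run_start,
                                        end=run_end, direction=direction,
                                        rule_branch="+".join(branches),
                                        peptides=tuple(support),
                                        times=tuple(times)))
    return calls


def _runs(mask: np.ndarray, offset: int) -> list[tuple[int, int]]:
    """Maximal runs of True in a boolean array, as inclusive residue intervals."""
    runs = []
    in_run = False
    for i, val in enumerate(mask):
        if val and not in_run:
            start = i
            in_run = True
        elif not val and in_run:
            runs.append((offset + start, offset + i - 1))
            in_run = False
    if in_run:
        runs.append((offset + start, offset + len(mask) - 1))
    return runs


def residue_map(calls: Sequence[RegionCall],
                sequence: SequenceRecord) -> pd.DataFrame:
    """Per-residue annotation from region calls.

    Labels are protected / deprotected / none; residues carrying calls in
    both directions are labelled ambiguous (and counted in ``attrs``).
    """
    labels = {r: "none" for r in range(sequence.first_residue,
                                       sequence.last_residue + 1)}
    for call in calls:
        if call.start < sequence.first_residue or call.end > sequence.last_residue:
            raise InvalidInputError(
                f"call {call.start}-{call.end} outside sequence "
                f"{sequence.first_residue}-{sequence.last_residue}")
        for r in call.residues():
            if labels[r] == "none":
                labels[r] = call.direction
            elif labels[r] not in (call.direction, "ambiguous"):
                labels[r] = "ambiguous"
    df = pd.DataFrame({"residue": list(labels), "label": list(labels.values())})
    df.attrs["ambiguous"] = int((df.label == "ambiguous").sum())
    return df


# ---------------------------------------------------------------------------
# I/O

#: Canonical uptake-table column schema shared with the synthetic generator.
UPTAKE_COLUMNS = ["protein", "start", "end", "sequence", "charge", "state",
                  "time", "replicate", "mass_centroid", "exposure_control"]

_DYNAMX_MAP = {"protein": "protein", "start": "start", "end": "end",
               "sequence": "sequence", "z": "charge", "charge": "charge",
               "state": "state", "exposure": "time", "replicate": "replicate",
               "centroid mass": "mass_centroid", "center": "mass_centroid"}


def read_uptake_table(path: str | Path, dialect: str = "native",
                      max_label_time: float | None = 86400.0) -> pd.DataFrame:
    """Read a peptide uptake table (native TSV or a DynamX-style cluster export).

    The DynamX dialect uses columns (protein, start, end, sequence, charge/z,
    state, exposure, replicate, centroid mass); exposure 0 becomes the
    non-deuterated control and exposures >= ``max_label_time`` the
    maximally-labelled control.
    """
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, comment="#")
    if dialect == "dynamx":
        df.columns = [c.strip().lower() for c in df.columns]
        unmapped = [c for c in df.columns if c not in _DYNAMX_MAP]
        if unmapped:
            logger.info("read_uptake_table: ignoring columns %s", unmapped)
        df = df.rename(columns=_DYNAMX_MAP)[[c for c in UPTAKE_COLUMNS
                                             if c in df.rename(
                                                 columns=_DYNAMX_MAP).columns]]
    elif dialect != "native":
        raise InvalidInputError(f"unknown dialect {dialect!r}")
    missing = set(UPTAKE_COLUMNS) - {"exposure_control"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    if "exposure_control" not in df.columns:
        control = np.where(df.time == 0, "non-deuterated", "timepoint")
        if max_label_time is not None:
            control = np.where(df.time >= max_label_time, "max-labelled", control)
        df["exposure_control"] = control
    return df


def write_woods(diffs: pd.DataFrame, path: str | Path,
                threshold: float = 0.05) -> None:
    """Write a Woods-plot TSV (peptide, time, delta_fx, u_c, CIs, flagged)."""
    out = diffs.copy()
    out["flagged"] = np.abs(out.delta_fx) > threshold
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, sep="\t", index=False)


def plot_woods(diffs: pd.DataFrame, path: str | Path,
               threshold: float = 0.05) -> None:
    """Render Woods plots (one panel per time point) to an image file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    times = sorted(diffs.time.unique())
    fig, axes = plt.subplots(len(times), 1, figsize=(8, 2.2 * len(times)),
                             squeeze=False, sharex=True)
    for ax, time in zip(axes.ravel(), times):
        sub = diffs[diffs.time == time]
        for _, row in sub.iterrows():
            flagged = abs(row.delta_fx) > threshold
            color = ("tab:blue" if row.delta_fx < 0 else "tab:red") if flagged \
                else "0.6"
            ax.plot([row.start, row.end], [row.delta_fx] * 2, color=color, lw=2)
        ax.axhline(threshold, ls="--", color="0.3", lw=0.8)
        ax.axhline(-threshold, ls="--", color="0.3", lw=0.8)
        ax.set_ylabel(f"{time:g} s")
    axes.ravel()[-1].set_xlabel("residue")
    fig.suptitle("Differential uptake (state B - state A)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
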