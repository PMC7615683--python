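"""Secondary Calpha chemical shifts and helical/extended stretch calling.

Secondary chemical shift: Delta-SCS = observed Calpha - random-coil Calpha.
Consecutive positive runs above the profile SD indicate helical propensity,
negative runs extended conformation. The random-coil reference is an input
(a replaceable packaged table), not a constant.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConsistencyError, InvalidInputError
from .io import SequenceRecord

MAD_TO_SD = 1.4826  # consistency factor for a normal distribution


@dataclass(frozen=True)
class RandomCoilReference:
    """Per-residue-type random-coil Calpha values (ppm) with optional
    pre-proline corrections and conditions metadata."""

    values: dict[str, float]
    pre_proline: dict[str, float] = field(default_factory=dict)
    conditions: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set("ACDEFGHIKLMNPQRSTVWY") - set(self.values)
        if missing:
            raise InvalidInputError(
                f"random-coil table missing residue types {sorted(missing)}")

    def value(self, residue_type: str, pre_pro: bool = False) -> float:
        base = self.values[residue_type]
        if pre_pro:
            base += self.pre_proline.get(residue_type, 0.0)
        return base

    def shifted(self, delta: float) -> "RandomCoilReference":
        """Reference with a constant added to every value (referencing offset)."""
        return RandomCoilReference(
            values={k: v + delta for k, v in self.values.items()},
            pre_proline=dict(self.pre_proline), conditions=dict(self.conditions))


def load_random_coil(path: str | Path | None = None) -> RandomCoilReference:
    """Load the packaged (or a user-supplied) random-coil Calpha table."""
    if path is None:
        ref = importlib.resources.files("idrmap") / "data" / "random_coil_ca.tsv"
        df = pd.read_csv(str(ref), sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    return RandomCoilReference(
        values=dict(zip(df.residue, df.ca)),
        pre_proline=dict(zip(df.residue, df.get("pre_pro", 0.0))))


def delta_scs(shifts: pd.DataFrame, rc: RandomCoilReference,
              sequence: SequenceRecord | None = None) -> pd.DataFrame:
    """Secondary chemical shifts: observed minus random-coil Calpha.

    Only CA rows are used; unassigned residues are simply absent (counted in
    ``attrs`` when a sequence is given, along with excluded prolines). If a
    sequence is supplied, residue types in the table are checked against it.
    """
    ca = shifts[shifts.atom.str.upper() == "CA"] if "atom" in shifts.columns else shifts
    if ca.empty:
        raise InvalidInputError("no CA rows in shift table")
    rows = []
    for _, row in ca.iterrows():
        if sequence is not None:
            expected = sequence.residue_type(int(row["residue"]))
            if expected != row["type"]:
                raise ConsistencyError(
                    f"residue {int(row['residue'])}: shift table says "
                    f"{row['type']}, sequence says {expected}")
        rc_val = rc.value(row["type"])
        rows.append(dict(residue=int(row["residue"]), type=row["type"],
                         observed=float(row["shift"]), random_coil=rc_val,
                         delta_scs=float(row["shift"]) - rc_val))
    profile = pd.DataFrame(rows).sort_values("residue").reset_index(drop=True)
    if sequence is not None:
        assignable = sum(1 for aa in sequence.residues if aa != "P")
        profile.attrs["assigned"] = len(profile)
        profile.attrs["unassigned"] = assignable - len(profile)
        profile.attrs["prolines_excluded"] = sequence.residues.count("P")
    return profile


@dataclass(frozen=True)
class Stretch:
    start: int
    end: int
    kind: str  # "helical" | "extended"

    def residues(self) -> range:
        return range(self.start, self.end + 1)


def profile_sd(delta: np.ndarray, estimator: str = "mad") -> float:
    """Spread of the Delta-SCS profile.

    Default is the median absolute deviation scaled to SD, which is robust
    against the structured stretches themselves inflating the threshold;
    ``estimator='sd'`` gives the plain standard deviation.
    """
    if estimator == "mad":
        return float(MAD_TO_SD * np.median(np.abs(delta - np.median(delta))))
    if estimator == "sd":
        return float(np.std(delta, ddof=1))
    raise InvalidInputError(f"unknown SD estimator {estimator!r}")


def call_stretches(profile: pd.DataFrame, sd_mult: float = 1.0,
                   min_len: int = 3, estimator: str = "mad") -> list[Stretch]:
    """Call maximal consecutive runs of Delta-SCS beyond +/- SD * sd_mult.

    Runs shorter than ``min_len`` are discarded; gaps from unassigned
    residues break runs (consecutive residue numbering is required).
    """
    if len(profile) < 10:
        raise InvalidInputError("need >= 10 assigned residues to estimate the SD")
    delta = profile.delta_scs.to_numpy()
    residues = profile.residue.to_numpy()
    sd = profile_sd(delta, estimator)
    thr = sd * sd_mult

    stretches: list[Stretch] = []
    for kind, cond in (("helical", delta > thr), ("extended", delta < -thr)):
        run: list[int] = []
        for i, flag in enumerate(cond):
            contiguous = bool(run) and residues[i] == run[-1] + 1
            if flag and (not run or contiguous):
                run.append(int(residues[i]))
            else:
                if len(run) >= min_len:
                    stretches.append(Stretch(run[0], run[-1], kind))
                run = [int(residues[i])] if flag else []
        if len(run) >= min_len:
            stretches.append(Stretch(run[0], run[-1], kind))
    return sorted(stretches, key=lambda s: s.start)
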