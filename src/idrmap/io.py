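"""Readers, writers, sequence bookkeeping and run configuration.

Coordinate convention: residue positions are 1-based and inclusive throughout.
A :class:`SequenceRecord` carries a numbering ``offset`` so that position 1 of
the stored string can correspond to, e.g., residue 414 of the full-length
protein construct.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml
from Bio import SeqIO

from .errors import ConfigError, InvalidInputError, ParseError

logger = logging.getLogger("idrmap")

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")

#: Mass difference between deuterium and protium (Da) used for theoretical
#: maximum-uptake normalisation.
DEUTERIUM_MASS_SHIFT = 1.00628


@dataclass(frozen=True)
class SequenceRecord:
    """A protein sequence with construct numbering.

    ``offset`` shifts the numbering: residue number of string position ``i``
    (1-based) is ``offset + i``.
    """

    id: str
    residues: str
    description: str = ""
    offset: int = 0

    def __post_init__(self) -> None:
        if not self.residues:
            raise InvalidInputError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - AA_ALPHABET
        if bad:
            raise InvalidInputError(
                f"sequence {self.id!r} contains illegal characters: {sorted(bad)}"
            )
        if self.offset < 0:
            raise InvalidInputError("numbering offset must be >= 0")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def first_residue(self) -> int:
        return self.offset + 1

    @property
    def last_residue(self) -> int:
        return self.offset + len(self.residues)

    def residue_type(self, number: int) -> str:
        """One-letter type of the residue with construct number ``number``."""
        if not self.first_residue <= number <= self.last_residue:
            raise IndexError(
                f"residue {number} outside {self.id!r} "
                f"({self.first_residue}-{self.last_residue})"
            )
        return self.residues[number - self.offset - 1]

    def slice(self, start: int, end: int) -> str:
        """Subsequence spanning construct numbers ``start``..``end`` inclusive."""
        if start > end:
            raise InvalidInputError(f"start {start} > end {end}")
        if start < self.first_residue or end > self.last_residue:
            raise IndexError(
                f"range {start}-{end} outside {self.id!r} "
                f"({self.first_residue}-{self.last_residue})"
            )
        return self.residues[start - self.offset - 1 : end - self.offset]


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read FASTA records; an ``offset=N`` token in the description sets numbering.

    Lowercase residues are uppercased (and logged); illegal characters raise
    :class:`~idrmap.errors.ParseError` naming the record.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if seq != seq.upper():
            logger.info("read_fasta: uppercased lowercase residues in %r", rec.id)
            seq = seq.upper()
        offset = 0
        for token in rec.description.split():
            if token.startswith("offset="):
                try:
                    offset = int(token.split("=", 1)[1])
                except ValueError as exc:
                    raise ParseError(f"bad offset token in {rec.id!r}: {token}") from exc
        try:
            records.append(
                SequenceRecord(id=rec.id, residues=seq, description=rec.description,
                               offset=offset)
            )
        except InvalidInputError as exc:
            raise ParseError(f"record {rec.id!r}: {exc}") from exc
    if not records:
        raise ParseError(f"no FASTA records found in {path}")
    return records


def count_exchangeable(seq: SequenceRecord | str, start: int | None = None,
                       end: int | None = None) -> tuple[int, int]:
    """Amide bookkeeping for a peptide or construct range.

    Returns ``(exchangeable, non_proline)``. ``exchangeable`` counts the
    non-proline residues from position 2 onward: the N-terminal amide
    back-exchanges too fast to observe and prolines have no amide proton.
    This equals the common ``length - prolines - 1`` bookkeeping except for
    peptides whose first residue is a proline, which that formula would
    subtract twice. ``non_proline`` is the plain non-proline residue count
    used for NMR assignment bookkeeping.
    """
    if isinstance(seq, SequenceRecord):
        if start is None:
            start, end = seq.first_residue, seq.last_residue
        sub = seq.slice(start, end)
    else:
        sub = seq
        if start is not None and end is not None and end - start + 1 != len(sub):
            raise InvalidInputError("start/end inconsistent with sequence length")
    n = len(sub)
    exchangeable = sum(1 for aa in sub[1:] if aa != "P")
    return exchangeable, n - sub.count("P")


# ---------------------------------------------------------------------------
# run configuration

_CONFIG_DEFAULTS: dict[str, object] = {
    "threshold": 0.05,        # HDX |delta fx| call threshold (fraction)
    "levels": [0.98, 0.99],   # two-tailed t confidence levels
    "kappa": 1.45,            # empirical eta_xy -> R2 scaling
    "gamma_ratio": -0.10136,  # signed gyromagnetic ratio gammaN/gammaH
    "sd_mult": 1.0,           # SD multiplier for stretch / perturbation calls
    "min_timepoints": 2,
    "min_peptides": 3,
    "min_len": 3,
    "consensus_score": 2,
    "bridge_gap": 2,
    "seed": 0,
}

_NUMERIC_KEYS = {"threshold", "kappa", "gamma_ratio", "sd_mult", "seed",
                 "min_timepoints", "min_peptides", "min_len",
                 "consensus_score", "bridge_gap"}


def load_config(path: str | Path | None = None) -> dict[str, object]:
    """Load a YAML key-value config, filling documented defaults.

    Unknown keys raise :class:`~idrmap.errors.ConfigError` listing the valid
    ones; malformed numerics raise a typed error naming the key.
    """
    params = dict(_CONFIG_DEFAULTS)
    if path is None:
        return params
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, Mapping):
        raise ConfigError(f"config {path} is not a key-value mapping")
    unknown = set(raw) - set(_CONFIG_DEFAULTS)
    if unknown:
        raise ConfigError(
            f"unknown config keys {sorted(unknown)}; "
            f"valid keys: {sorted(_CONFIG_DEFAULTS)}"
        )
    for key, value in raw.items():
        if key in _NUMERIC_KEYS:
            try:
                value = type(_CONFIG_DEFAULTS[key])(value)
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"malformed numeric value for {key!r}: {value!r}") from exc
        elif key == "levels":
            try:
                value = [float(v) for v in value]
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"malformed levels: {value!r}") from exc
        params[key] = value
        logger.info("config: %s = %r (overrides default)", key, value)
    return params


# ---------------------------------------------------------------------------
# tabular I/O

def read_table(path: str | Path, required: Iterable[str] = (),
               expected_rows: int | None = None) -> pd.DataFrame:
    """Read a TSV/CSV table, checking required columns and optional row count.

    The row-count check guards against silently truncated exports when the
    caller knows how many rows (replicates x time points x peptides) to expect.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, comment="#")
    missing = set(required) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    if expected_rows is not None and len(df) != expected_rows:
        raise ParseError(
            f"{path}: expected {expected_rows} rows, found {len(df)} "
            "(truncated or padded file?)"
        )
    return df


def write_table(df: pd.DataFrame, path: str | Path, header_meta: Mapping | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, value in (header_meta or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_header_meta(path: str | Path) -> dict[str, str]:
    """Parse ``# key: value`` comment lines at the top of a table file."""
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if ":" in body:
                key, value = body.split(":", 1)
                meta[key.strip()] = value.strip()
    return meta


# ---------------------------------------------------------------------------
# NMR-STAR chemical-shift loop (read-only, minimal dialect)

def read_nmrstar_shifts(path: str | Path) -> pd.DataFrame:
    """Read an ``Atom_chem_shift`` loop from an NMR-STAR file.

    Minimal reader covering BMRB-style depositions: finds the first ``loop_``
    whose tags include ``_Atom_chem_shift.Seq_ID``, ``Comp_ID``, ``Atom_ID``
    and ``Val`` and returns columns (residue, type, atom, shift). Residue
    types are converted from three- to one-letter codes.
    """
    three_to_one = {
        "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
        "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
        "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
        "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    }
    lines = Path(path).read_text().splitlines()
    i = 0
    n = len(lines)
    while i < n:
        if lines[i].strip() == "loop_":
            tags: list[str] = []
            j = i + 1
            while j < n and lines[j].strip().startswith("_"):
                tags.append(lines[j].strip())
                j += 1
            wanted = ["_Atom_chem_shift.Seq_ID", "_Atom_chem_shift.Comp_ID",
                      "_Atom_chem_shift.Atom_ID", "_Atom_chem_shift.Val"]
            if all(any(t == w for t in tags) for w in wanted):
                idx = {w: tags.index(w) for w in wanted}
                rows = []
                while j < n and lines[j].strip() not in {"stop_", ""} or (
                        j < n and lines[j].strip() == ""):
                    stripped = lines[j].strip()
                    if stripped == "stop_":
                        break
                    if stripped and not stripped.startswith("#"):
                        fields = stripped.split()
                        if len(fields) >= len(tags):
                            try:
                                rows.append({
                                    "residue": int(fields[idx[wanted[0]]]),
                                    "type": three_to_one.get(
                                        fields[idx[wanted[1]]].upper(),
                                        fields[idx[wanted[1]]]),
                                    "atom": fields[idx[wanted[2]]],
                                    "shift": float(fields[idx[wanted[3]]]),
                                })
                            except ValueError as exc:
                                raise ParseError(
                                    f"{path}: bad shift row at line {j + 1}") from exc
                    j += 1
                if not rows:
                    raise ParseError(f"{path}: empty chemical-shift loop")
                return pd.DataFrame(rows)
            i = j
        else:
            i += 1
    raise ParseError(f"{path}: no Atom_chem_shift loop found")


# ---------------------------------------------------------------------------
# ChimeraX defattr

def write_defattr(mapping: Mapping[int, float], attribute: str,
                  path: str | Path, chain: str = "") -> None:
    """Write per-residue numeric attributes in ChimeraX defattr format."""
    if not mapping:
        raise InvalidInputError("cannot write defattr from an empty table")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"attribute: {attribute}\n")
        fh.write("match mode: 1-to-1\n")
        fh.write("recipient: residues\n")
        for residue in sorted(mapping):
            fh.write(f"\t{chain}:{residue}\t{mapping[residue]}\n")


def read_defattr(path: str | Path) -> tuple[str, dict[int, float]]:
    """Parse a defattr file back into (attribute name, residue -> value)."""
    attribute = ""
    mapping: dict[int, float] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if line.startswith("attribute:"):
            attribute = line.split(":", 1)[1].strip()
        elif line.startswith("\t"):
            try:
                spec, value = line.strip().split("\t")
                residue = int(spec.rsplit(":", 1)[1])
                mapping[residue] = float(value)
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path}: bad defattr line {lineno}") from exc
    if not attribute:
        raise ParseError(f"{path}: missing attribute header")
    return attribute, mapping


def file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]
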