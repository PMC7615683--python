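"""Residue-level consensus of HDX protection, secondary-shift stretches and
relaxation perturbation, plus exports for structure visualisation.

The consensus formalises convergence between independent experiments: a
residue supported by >= 2 evidence classes belongs to a consensus binding
element. Short gaps (default <= 2 residues) inside an element are bridged,
mirroring how a disordered linker between two binding helices is treated as
contributory.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .errors import ConsistencyError, InvalidInputError
from .hdx import RegionCall
from .io import SequenceRecord, write_defattr
from .relax import PerturbedInterval
from .shifts import Stretch


@dataclass(frozen=True)
class ConsensusElement:
    start: int
    end: int
    min_score: int

    def residues(self) -> range:
        return range(self.start, self.end + 1)


def build_consensus(hdx_calls: Sequence[RegionCall],
                    stretches: Sequence[Stretch],
                    perturbed: Sequence[PerturbedInterval],
                    sequence: SequenceRecord,
                    score_threshold: int = 2,
                    bridge_gap: int = 2,
                    hdx_direction: str = "protected") -> pd.DataFrame:
    """Merge per-residue evidence into a consensus table.

    Columns: residue, hdx_call, scs_call, rex_call, score (count of non-null
    evidence classes, 0-3). Maximal intervals with score >= score_threshold
    (gaps <= bridge_gap bridged) are reported as consensus elements in
    ``result.attrs['elements']``.
    """
    lo, hi = sequence.first_residue, sequence.last_residue
    table = pd.DataFrame({"residue": range(lo, hi + 1)})
    table["hdx_call"] = ""
    table["scs_call"] = ""
    table["rex_call"] = ""

    def check(start: int, end: int, what: str) -> None:
        if start < lo or end > hi:
            raise ConsistencyError(
                f"{what} interval {start}-{end} outside sequence numbering "
                f"{lo}-{hi}")

    for call in hdx_calls:
        check(call.start, call.end, "HDX")
        if call.direction == hdx_direction:
            sel = table.residue.between(call.start, call.end)
            table.loc[sel, "hdx_call"] = call.direction
    for st in stretches:
        check(st.start, st.end, "SCS")
        sel = table.residue.between(st.start, st.end)
        table.loc[sel, "scs_call"] = st.kind
    for iv in perturbed:
        check(iv.start, iv.end, "relaxation")
        sel = table.residue.between(iv.start, iv.end)
        table.loc[sel, "rex_call"] = "perturbed"

    table["score"] = ((table.hdx_call != "").astype(int)
                      + (table.scs_call != "").astype(int)
                      + (table.rex_call != "").astype(int))

    # consensus elements: score >= threshold, bridging short gaps
    elements: list[ConsensusElement] = []
    qualifying = table.residue[table.score >= score_threshold].tolist()
    if qualifying:
        start = prev = qualifying[0]
        for r in qualifying[1:]:
            if r - prev <= bridge_gap + 1:
                prev = r
            else:
                elements.append(_element(table, start, prev))
                start = prev = r
        elements.append(_element(table, start, prev))
    table.attrs["elements"] = tuple(elements)
    table.attrs["score_threshold"] = score_threshold
    return table


def _element(table: pd.DataFrame, start: int, end: int) -> ConsensusElement:
    scores = table.score[table.residue.between(start, end)]
    return ConsensusElement(start, end, int(scores.min()))


def export_attributes(table: pd.DataFrame, attribute: str,
                      path: str | Path, column: str = "score") -> None:
    """Write a per-residue numeric attribute in ChimeraX defattr format."""
    if table.empty:
        raise InvalidInputError("cannot export attributes from an empty table")
    if column not in table.columns:
        raise InvalidInputError(f"no column {column!r} in evidence table")
    mapping = dict(zip(table.residue.astype(int), table[column].astype(float)))
    write_defattr(mapping, attribute, path)


def run_report(table: pd.DataFrame, parameters: Mapping[str, object],
               path: str | Path) -> None:
    """One-page plain-text report of inputs, parameters and consensus calls."""
    lines = ["integrative binding-element consensus report",
             "=" * 46, "", "parameters:"]
    lines += [f"  {k}: {v}" for k, v in parameters.items()]
    lines += ["", f"residues analysed: {len(table)}",
              f"score threshold: {table.attrs.get('score_threshold', '?')}",
              "", "consensus elements (score >= threshold, gaps bridged):"]
    elements = table.attrs.get("elements", ())
    if elements:
        lines += [f"  {el.start}-{el.end} (min score {el.min_score})"
                  for el in elements]
    else:
        lines.append("  none")
    counts = table.score.value_counts().sort_index()
    lines += ["", "per-residue evidence-score counts:"]
    lines += [f"  score {score}: {count} residues"
              for score, count in counts.items()]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text("\n".join(lines) + "\n")
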