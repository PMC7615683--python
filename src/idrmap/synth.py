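"""Synthetic-data generators for every pipeline input.

The generators encode the statistical structure of the real experiments the
pipeline analyses — peptic peptide pools with overlap and redundancy, uptake
curves governed by intrinsic exchange rates and protection factors, chemical
shift tables with implanted helical/extended offsets, relaxation profiles
with implanted rigidity and exchange hotspots, and ligand-depletion
anisotropy titrations — so that every downstream stage can be tested without
any deposited data. Implanted features are the ground truth against which
region callers and fits are scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.SeqUtils import molecular_weight

from .errors import InsufficientDesignError, InvalidInputError
from .io import DEUTERIUM_MASS_SHIFT, SequenceRecord, count_exchangeable

GAMMA_RATIO_15N_1H = -0.10136  # signed gyromagnetic ratio gammaN/gammaH


@dataclass(frozen=True)
class Interval:
    """A 1-based inclusive residue interval carrying a feature value.

    ``value`` is the protection-factor multiplier (>1) for protected
    intervals, the secondary-shift offset in ppm for helical (>0) /
    extended (<0) intervals, or the Rex increment in 1/s for exchange
    hotspots. ``weight`` scales helical offsets by a propensity in [0, 1].
    """

    start: int
    end: int
    value: float
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise InvalidInputError(f"interval start {self.start} > end {self.end}")
        if not 0.0 <= self.weight <= 1.0:
            raise InvalidInputError("interval weight must lie in [0, 1]")

    def __contains__(self, residue: int) -> bool:
        return self.start <= residue <= self.end

    def residues(self) -> range:
        return range(self.start, self.end + 1)


@dataclass(frozen=True)
class GroundTruth:
    """The stated world a synthetic dataset is generated from."""

    sequence: SequenceRecord
    protected_intervals: tuple[Interval, ...] = ()
    helical_intervals: tuple[Interval, ...] = ()
    extended_intervals: tuple[Interval, ...] = ()
    exchange_hotspots: tuple[Interval, ...] = ()
    true_kd: float = 5.8  # nM
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.sequence.first_residue, self.sequence.last_residue
        for group, sign in (("protected_intervals", None), ("helical_intervals", +1),
                            ("extended_intervals", -1), ("exchange_hotspots", None)):
            for iv in getattr(self, group):
                if iv.start < lo or iv.end > hi:
                    raise InvalidInputError(
                        f"{group} interval {iv.start}-{iv.end} outside "
                        f"sequence range {lo}-{hi}")
                if group == "protected_intervals" and iv.value <= 1:
                    raise InvalidInputError("protection multipliers must be > 1")
                if sign is not None and iv.value * sign <= 0:
                    raise InvalidInputError(
                        f"{group} offsets must have sign {sign:+d}")
        if self.true_kd <= 0:
            raise InvalidInputError("true_kd must be > 0")


def default_truth(seed: int = 0) -> GroundTruth:
    """A synthetic 200-residue disordered construct (numbering 414-613).

    The sequence is randomly generated with a disorder-biased composition —
    it is a synthetic stand-in, not any real protein — and carries three
    protected/helical binding elements plus one extended stretch, mirroring
    the layout of a two-helix clamp with a weaker third element.
    """
    rng = np.random.default_rng([seed, 7])
    # disorder-promoting composition (P, E, S, K, G enriched)
    aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    weights = np.array([6, 1, 6, 10, 2, 7, 2, 2, 8, 7, 2, 4, 7, 5, 6, 10, 5, 4, 1, 2],
                       dtype=float)
    drawn = list(rng.choice(aas, size=200, p=weights / weights.sum()))
    # secondary-structure elements are proline-free (prolines break helices
    # and would fragment implanted stretches in amide-detected assignments)
    for start, end in ((428, 430), (474, 477), (548, 560), (446, 449)):
        for pos in range(start - 414, end - 413):
            if drawn[pos] == "P":
                drawn[pos] = "A"
    residues = "".join(drawn)
    seq = SequenceRecord(id="synthetic_idr", residues=residues,
                         description="synthetic disordered construct offset=413",
                         offset=413)
    return GroundTruth(
        sequence=seq,
        protected_intervals=(Interval(426, 439, 100.0), Interval(471, 495, 100.0),
                             Interval(556, 571, 50.0)),
        helical_intervals=(Interval(428, 430, 2.0), Interval(474, 477, 1.8),
                           Interval(548, 560, 1.5)),
        extended_intervals=(Interval(446, 449, -1.2),),
        exchange_hotspots=(Interval(421, 431, 4.0), Interval(474, 480, 3.0),
                           Interval(558, 560, 2.0)),
        true_kd=5.8,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# peptide pools

@dataclass(frozen=True)
class Peptide:
    start: int
    end: int
    sequence: str
    charge: int


@dataclass
class PeptidePool:
    """Overlapping peptic peptides covering a parent sequence."""

    parent: SequenceRecord
    peptides: list[Peptide]

    @property
    def coverage(self) -> float:
        covered = set()
        for p in self.peptides:
            covered.update(range(p.start, p.end + 1))
        return len(covered) / len(self.parent)

    @property
    def redundancy(self) -> float:
        counts = np.zeros(len(self.parent))
        off = self.parent.offset
        for p in self.peptides:
            counts[p.start - off - 1 : p.end - off] += 1
        return float(counts.mean())


def generate_peptide_pool(sequence: SequenceRecord, mean_length: int = 9,
                          target_redundancy: float = 8.0,
                          seed: int = 0) -> PeptidePool:
    """Emulate a pepsin peptide map: staggered, overlapping peptides.

    Guarantees full coverage (a tiling pass with ~3-residue overlaps), then
    adds random peptides until the mean per-residue redundancy reaches the
    target. Deterministic for a fixed seed.
    """
    if len(sequence.residues) == 0:
        raise InvalidInputError("empty sequence")
    if mean_length < 5:
        raise InvalidInputError("mean_length must be >= 5")
    if target_redundancy < 1:
        raise InvalidInputError("target_redundancy must be >= 1")
    rng = np.random.default_rng([seed, 11])
    lo, hi = sequence.first_residue, sequence.last_residue
    length = len(sequence.residues)

    def draw_len() -> int:
        return int(np.clip(round(rng.normal(mean_length, 2.0)), 5, mean_length + 6))

    peptides: list[Peptide] = []

    def add(start: int, plen: int) -> None:
        end = min(start + plen - 1, hi)
        start = max(lo, min(start, end))
        peptides.append(Peptide(start, end, sequence.slice(start, end),
                                int(rng.integers(1, 4))))

    if length <= mean_length:
        add(lo, length)
        return PeptidePool(sequence, peptides)

    pos = lo
    while pos <= hi:
        plen = draw_len()
        add(pos, plen)
        pos = peptides[-1].end - 2  # ~3-residue overlap keeps coverage contiguous
        if pos <= peptides[-1].start:  # guarantee progress on tiny peptides
            pos = peptides[-1].start + 1
        if peptides[-1].end == hi:
            break

    target_count = max(len(peptides),
                       int(round(target_redundancy * length / mean_length)))
    while len(peptides) < target_count:
        plen = draw_len()
        start = int(rng.integers(lo, hi - min(plen, length) + 2))
        add(start, plen)
    return PeptidePool(sequence, peptides)


# ---------------------------------------------------------------------------
# intrinsic exchange-rate models

class UniformRateModel:
    """Simplified base-catalysed intrinsic exchange: k = k_ref * 10**(pD - pD_ref).

    The analysis downstream only needs relative protection, so a uniform
    reference rate suffices; pD 6.0 emulates the slowed-exchange campaign
    used to open the HDX time window for a fast-exchanging IDP.
    """

    def __init__(self, k_ref: float = 1.0, pD: float = 6.0, pD_ref: float = 7.4):
        if k_ref <= 0:
            raise InvalidInputError("k_ref must be > 0")
        self.k_ref = k_ref
        self.pD = pD
        self.pD_ref = pD_ref

    def rates(self, sequence: SequenceRecord) -> np.ndarray:
        k = self.k_ref * 10.0 ** (self.pD - self.pD_ref)
        return np.full(len(sequence.residues), k)


class TabulatedRateModel(UniformRateModel):
    """Hook for sequence-dependent intrinsic rates (Bai/Englander-style).

    ``factors`` maps one-letter residue types to multiplicative corrections
    applied on top of the uniform base-catalysed rate.
    """

    def __init__(self, factors: Mapping[str, float], **kwargs):
        super().__init__(**kwargs)
        self.factors = dict(factors)

    def rates(self, sequence: SequenceRecord) -> np.ndarray:
        base = super().rates(sequence)
        mult = np.array([self.factors.get(aa, 1.0) for aa in sequence.residues])
        return base * mult


# ---------------------------------------------------------------------------
# HDX uptake simulation

MAX_LABEL_TIME = 86400.0  # 24 h maximally-labelled control


def simulate_uptake(pool: PeptidePool, truth: GroundTruth,
                    times: Sequence[float], state: str = "apo",
                    replicates: int = 3, noise_sd: float = 0.05,
                    *, bound: bool | None = None,
                    rate_model: UniformRateModel | None = None,
                    back_exchange: float = 0.0,
                    include_controls: bool = True,
                    include_max_control: bool = False,
                    seed: int | None = None) -> pd.DataFrame:
    """Simulate peptide-level deuterium uptake records.

    Per-amide deuteration follows the single-amide kinetic scheme
    ``D_i(t) = 1 - exp(-(k_int,i / P_i) * t)``; in the bound state the
    protection factor ``P_i`` is multiplied by the ground-truth multiplier
    inside protected intervals. Prolines and each peptide's first residue
    contribute no exchangeable amide. The record mass is the monoisotopic
    peptide mass plus the summed per-amide deuteration (Da) plus Gaussian
    centroid noise.
    """
    if any(t <= 0 for t in times):
        raise InvalidInputError("labelling times must be > 0")
    if replicates < 1:
        raise InvalidInputError("replicates must be >= 1")
    if not 0.0 <= back_exchange < 1.0:
        raise InvalidInputError("back_exchange must lie in [0, 1)")
    if bound is None:
        bound = state != "apo"
    rate_model = rate_model or UniformRateModel()
    seq = pool.parent
    seed = truth.seed if seed is None else seed
    rng = np.random.default_rng([seed, abs(hash(state)) % (2**31), 13])

    k_int = rate_model.rates(seq)  # indexed by string position
    protection = np.ones(len(seq.residues))
    if bound:
        for iv in truth.protected_intervals:
            protection[iv.start - seq.offset - 1 : iv.end - seq.offset] *= iv.value

    rows: list[dict] = []
    label = 1.0 - back_exchange
    for pep in pool.peptides:
        m0 = molecular_weight(pep.sequence, seq_type="protein", monoisotopic=True)
        # exchangeable amide mask: positions 2..n of the peptide, non-proline
        idx = np.arange(pep.start - seq.offset - 1, pep.end - seq.offset)
        amide = np.array([seq.residues[i] != "P" for i in idx])
        amide[0] = False  # N-terminal amide back-exchanges too fast
        k_eff = k_int[idx][amide] / protection[idx][amide]
        n_ex = int(amide.sum())
        for t in times:
            uptake = label * float(np.sum(1.0 - np.exp(-k_eff * t)))
            for rep in range(1, replicates + 1):
                rows.append(dict(protein=seq.id, start=pep.start, end=pep.end,
                                 sequence=pep.sequence, charge=pep.charge,
                                 state=state, time=float(t), replicate=rep,
                                 mass_centroid=m0 + DEUTERIUM_MASS_SHIFT * uptake
                                 + rng.normal(0.0, noise_sd),
                                 exposure_control="timepoint"))
        if include_controls:
            for rep in range(1, replicates + 1):
                rows.append(dict(protein=seq.id, start=pep.start, end=pep.end,
                                 sequence=pep.sequence, charge=pep.charge,
                                 state=state, time=0.0, replicate=rep,
                                 mass_centroid=m0 + rng.normal(0.0, noise_sd),
                                 exposure_control="non-deuterated"))
        if include_max_control:
            for rep in range(1, replicates + 1):
                rows.append(dict(protein=seq.id, start=pep.start, end=pep.end,
                                 sequence=pep.sequence, charge=pep.charge,
                                 state=state, time=MAX_LABEL_TIME, replicate=rep,
                                 mass_centroid=m0 + DEUTERIUM_MASS_SHIFT * label * n_ex
                                 + rng.normal(0.0, noise_sd),
                                 exposure_control="max-labelled"))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# chemical shifts

def simulate_shifts(truth: GroundTruth, rc=None, noise_sd: float = 0.1,
                    seed: int | None = None,
                    assigned_fraction: float = 1.0) -> pd.DataFrame:
    """Simulate an assigned Calpha shift table with implanted secondary structure.

    Observed shift = random-coil value + interval offset (scaled by the
    interval propensity weight) + Gaussian noise. Prolines are emitted as
    unassigned (absent), as in amide-detected assignment experiments.
    """
    from .shifts import load_random_coil  # local import avoids a cycle

    rc = rc or load_random_coil()
    seq = truth.sequence
    seed = truth.seed if seed is None else seed
    rng = np.random.default_rng([seed, 17])
    offsets = np.zeros(len(seq.residues))
    for iv in truth.helical_intervals + truth.extended_intervals:
        offsets[iv.start - seq.offset - 1 : iv.end - seq.offset] += iv.value * iv.weight
    rows = []
    for i, aa in enumerate(seq.residues):
        if aa == "P":
            continue
        if assigned_fraction < 1.0 and rng.random() > assigned_fraction:
            continue
        rows.append(dict(residue=seq.offset + i + 1, type=aa, atom="CA",
                         shift=rc.value(aa) + offsets[i] + rng.normal(0.0, noise_sd)))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# relaxation

def default_base_rates(truth: GroundTruth, kappa: float = 1.45,
                       gamma_ratio: float = GAMMA_RATIO_15N_1H) -> pd.DataFrame:
    """Exchange-free baseline rates for a disordered chain with rigid elements.

    Disordered baseline (R1 1.3 1/s, hetNOE 0.35, eta_xy 1.5 1/s) with
    elevated rigidity inside helical intervals (hetNOE 0.65, eta_xy 4.0 1/s).
    R2 is constructed exchange-free, R2 = kappa*eta_xy + 1.3*sigma, so the
    apo decomposition recovers Rex = 0 identically.
    """
    seq = truth.sequence
    n = len(seq.residues)
    r1 = np.full(n, 1.3)
    noe = np.full(n, 0.35)
    eta = np.full(n, 1.5)
    for iv in truth.helical_intervals:
        sl = slice(iv.start - seq.offset - 1, iv.end - seq.offset)
        r1[sl] = 1.35
        noe[sl] = 0.65
        eta[sl] = 4.0
    sigma = (noe - 1.0) * r1 * gamma_ratio
    r2 = kappa * eta + 1.3 * sigma
    return pd.DataFrame(dict(residue=np.arange(seq.first_residue,
                                               seq.last_residue + 1),
                             R1=r1, R2=r2, noe=noe, eta_xy=eta))


def simulate_relaxation(truth: GroundTruth, base_rates: pd.DataFrame | None = None,
                        bound_fraction: float = 0.1,
                        noise: Mapping[str, float] | None = None,
                        r1_increment: float = 0.05,
                        seed: int | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate apo and +ligand per-residue relaxation observables.

    The +ligand set equals the apo set plus Rex increments confined to the
    ground-truth exchange hotspots, scaled by ``bound_fraction``, plus a
    small uniform R1 increase from slower average tumbling; hetNOE and
    eta_xy are left unchanged (they are exchange-free observables).
    """
    if not 0.0 <= bound_fraction <= 1.0:
        raise InvalidInputError("bound_fraction must lie in [0, 1]")
    base = base_rates if base_rates is not None else default_base_rates(truth)
    for col in ("R1", "R2", "noe", "eta_xy"):
        if col not in base.columns:
            raise InvalidInputError(f"base_rates missing column {col!r}")
    if (base[["R1", "R2", "eta_xy"]] < 0).any().any():
        raise InvalidInputError("base rates must be non-negative")
    seq = truth.sequence
    seed = truth.seed if seed is None else seed
    rng = np.random.default_rng([seed, 19])
    noise = dict(noise or {})

    def noisy(df: pd.DataFrame) -> pd.DataFrame:
        out = df.copy()
        for col in ("R1", "R2", "noe", "eta_xy"):
            sd = float(noise.get(col, 0.0))
            out[col] = out[col] + (rng.normal(0.0, sd, len(out)) if sd > 0 else 0.0)
            out[f"{col}_sd"] = sd
        return out

    apo = base.copy()
    bound = base.copy()
    rex = np.zeros(len(base))
    residues = base["residue"].to_numpy()
    for iv in truth.exchange_hotspots:
        rex[(residues >= iv.start) & (residues <= iv.end)] += iv.value
    bound["R2"] = bound["R2"] + rex * bound_fraction
    bound["R1"] = bound["R1"] + (r1_increment * bound_fraction if bound_fraction > 0
                                 else 0.0)
    apo, bound = noisy(apo), noisy(bound)
    apo["state"], bound["state"] = "apo", "+ligand"
    return apo, bound


def simulate_decay_series(rates: Mapping[int, float], delays: Sequence[float],
                          i0: float = 100.0, noise_frac: float = 0.0,
                          experiment: str = "R2", seed: int = 0) -> pd.DataFrame:
    """Mono-exponential peak-intensity series for decay-fit tests."""
    rng = np.random.default_rng([seed, 23])
    rows = []
    for residue, rate in rates.items():
        for d in delays:
            intensity = i0 * np.exp(-rate * d)
            if noise_frac > 0:
                intensity *= 1.0 + rng.normal(0.0, noise_frac)
            rows.append(dict(residue=residue, experiment=experiment,
                             delay=float(d), intensity=float(intensity),
                             replicate=1))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# anisotropy titration

def simulate_titration(true_kd: float, receptor_total: float = 10.0,
                       top_ligand: float = 125.0, n_points: int = 16,
                       dilution: float = 2.0, replicates: int = 3,
                       r_free: float = 0.10, r_bound: float = 0.25,
                       noise_sd: float = 0.002, seed: int = 0) -> pd.DataFrame:
    """Simulate a two-fold-dilution anisotropy titration (post-mix concentrations).

    Anisotropy follows r = r_free + (r_bound - r_free) * fb with fb from the
    quadratic ligand-depletion model. Concentrations are final (after the
    1:1 mix of ligand dilution series with labelled receptor), so the
    experiment's nominal 250 nM top / 20 nM receptor corresponds to
    defaults of 125 nM / 10 nM here.
    """
    from .binding import fraction_bound  # local import avoids a cycle

    if min(true_kd, receptor_total, top_ligand) <= 0:
        raise InvalidInputError("concentrations and Kd must be > 0")
    if dilution <= 1:
        raise InvalidInputError("dilution factor must be > 1")
    if n_points < 4:
        raise InsufficientDesignError("need at least 4 titration points")
    rng = np.random.default_rng([seed, 29])
    ligand = top_ligand / dilution ** np.arange(n_points)
    rows = []
    for rep in range(1, replicates + 1):
        fb = np.array([fraction_bound(true_kd, lt, receptor_total) for lt in ligand])
        r = r_free + (r_bound - r_free) * fb
        if noise_sd > 0:
            r = r + rng.normal(0.0, noise_sd, n_points)
        for lt, ri in zip(ligand, r):
            rows.append(dict(ligand_total=float(lt), anisotropy=float(ri),
                             replicate=rep))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ground-truth sidecar (plain-text key-value format for test oracles)

def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    def fmt(ivs: tuple[Interval, ...]) -> str:
        return ";".join(f"{iv.start}-{iv.end}:{iv.value}:{iv.weight}" for iv in ivs)

    lines = [
        f"sequence_id\t{truth.sequence.id}",
        f"residues\t{truth.sequence.residues}",
        f"offset\t{truth.sequence.offset}",
        f"protected\t{fmt(truth.protected_intervals)}",
        f"helical\t{fmt(truth.helical_intervals)}",
        f"extended\t{fmt(truth.extended_intervals)}",
        f"hotspots\t{fmt(truth.exchange_hotspots)}",
        f"true_kd\t{truth.true_kd}",
        f"seed\t{truth.seed}",
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_ground_truth(path: str | Path) -> GroundTruth:
    kv = dict(line.split("\t", 1) for line in
              Path(path).read_text().splitlines() if line)

    def parse(spec: str) -> tuple[Interval, ...]:
        out = []
        for item in filter(None, spec.split(";")):
            span, value, weight = item.split(":")
            start, end = span.split("-")
            out.append(Interval(int(start), int(end), float(value), float(weight)))
        return tuple(out)

    seq = SequenceRecord(id=kv["sequence_id"], residues=kv["residues"],
                         offset=int(kv["offset"]))
    return GroundTruth(sequence=seq, protected_intervals=parse(kv["protected"]),
                       helical_intervals=parse(kv["helical"]),
                       extended_intervals=parse(kv["extended"]),
                       exchange_hotspots=parse(kv["hotspots"]),
                       true_kd=float(kv["true_kd"]), seed=int(kv["seed"]))
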