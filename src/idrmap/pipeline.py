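"""End-to-end synthetic round trip: generate every input from one ground
truth, run all three analysis arms, and build the residue-level consensus.

This is the integration surface the CLI ``report`` command and the test
oracles share: implanted features in, recovered features out.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import hdx, relax, report, shifts, synth

#: default experiment design of the slowed-exchange HDX campaign (seconds)
HDX_TIMES = (3.0, 30.0, 60.0, 300.0)

#: centroid-mass noise (Da) giving ~<=0.5% fraction-exchanged noise on a
#: typical 8-10 residue peptic peptide
HDX_NOISE_SD = 0.03


@dataclass
class PipelineResult:
    truth: synth.GroundTruth
    hdx_calls: list[hdx.RegionCall]
    stretches: list[shifts.Stretch]
    perturbed: tuple[relax.PerturbedInterval, ...]
    consensus: pd.DataFrame


def run_hdx_arm(truth: synth.GroundTruth, noise: bool = True,
                times=HDX_TIMES, replicates: int = 3,
                trim: str = "subtractive") -> list[hdx.RegionCall]:
    """Simulate apo/bound uptake and call protected regions."""
    noise_sd = HDX_NOISE_SD if noise else 0.0
    pool = synth.generate_peptide_pool(truth.sequence, seed=truth.seed)
    apo = synth.simulate_uptake(pool, truth, times, state="apo",
                                replicates=replicates, noise_sd=noise_sd)
    bound = synth.simulate_uptake(pool, truth, times, state="+partner",
                                  replicates=replicates, noise_sd=noise_sd)
    fx_apo = hdx.fraction_exchanged(apo)
    fx_bound = hdx.fraction_exchanged(bound)
    diffs = hdx.differential_uptake(fx_apo, fx_bound)
    return hdx.call_regions(diffs, trim=trim)


def run_scs_arm(truth: synth.GroundTruth, noise: bool = True) -> list[shifts.Stretch]:
    """Simulate a shift table and call secondary-structure stretches."""
    table = synth.simulate_shifts(truth, noise_sd=0.1 if noise else 0.0)
    profile = shifts.delta_scs(table, shifts.load_random_coil(), truth.sequence)
    return shifts.call_stretches(profile)


def run_relax_arm(truth: synth.GroundTruth, noise: bool = True,
                  bound_fraction: float = 0.1):
    """Simulate apo/+ligand relaxation and find perturbed intervals."""
    noise_map = {"R2": 0.05} if noise else None
    apo, bound = synth.simulate_relaxation(truth, bound_fraction=bound_fraction,
                                           noise=noise_map)
    profile = relax.binding_perturbation(apo, bound)
    return profile.attrs["intervals"]


def run_synthetic_pipeline(seed: int = 0, noise: bool = True) -> PipelineResult:
    """Full three-arm synthetic analysis at one seed."""
    truth = synth.default_truth(seed)
    calls = run_hdx_arm(truth, noise=noise)
    stretch_list = run_scs_arm(truth, noise=noise)
    perturbed = run_relax_arm(truth, noise=noise)
    consensus = report.build_consensus(calls, stretch_list, perturbed,
                                       truth.sequence)
    return PipelineResult(truth=truth, hdx_calls=calls, stretches=stretch_list,
                          perturbed=perturbed, consensus=consensus)
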