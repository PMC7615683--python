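import pandas as pd
import pytest

from idrmap import synth
from idrmap.io import SequenceRecord


@pytest.fixture(scope="session")
def truth():
    return synth.default_truth(seed=0)


@pytest.fixture(scope="session")
def pool(truth):
    return synth.generate_peptide_pool(truth.sequence, seed=0)


@pytest.fixture
def tiny_seq():
    return SequenceRecord(id="tiny", residues="MKAGPLLDEKAFSTQR")


def make_uptake_records(start, end, sequence, masses_by_time, m0, m_max=None,
                        state="apo", protein="prot", charge=2):
    """Hand-build an uptake table for one peptide.

    ``masses_by_time`` maps time (s) -> list of replicate centroid masses.
    """
    rows = []
    for rep, _ in enumerate(masses_by_time.get(0.0, [m0]), 1):
        rows.append(dict(protein=protein, start=start, end=end,
                         sequence=sequence, charge=charge, state=state,
                         time=0.0, replicate=rep, mass_centroid=m0,
                         exposure_control="non-deuterated"))
    for time, masses in masses_by_time.items():
        if time == 0.0:
            continue
        for rep, mass in enumerate(masses, 1):
            rows.append(dict(protein=protein, start=start, end=end,
                             sequence=sequence, charge=charge, state=state,
                             time=float(time), replicate=rep,
                             mass_centroid=float(mass),
                             exposure_control="timepoint"))
    if m_max is not None:
        rows.append(dict(protein=protein, start=start, end=end,
                         sequence=sequence, charge=charge, state=state,
                         time=86400.0, replicate=1, mass_centroid=float(m_max),
                         exposure_control="max-labelled"))
    return pd.DataFrame(rows)
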