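import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from idrmap import synth
from idrmap.errors import InsufficientDesignError, InvalidInputError
from idrmap.io import DEUTERIUM_MASS_SHIFT, SequenceRecord, count_exchangeable
from idrmap.synth import (GroundTruth, Interval, UniformRateModel,
                          generate_peptide_pool, simulate_relaxation,
                          simulate_titration, simulate_uptake)


def simple_truth(residues="A" * 50, offset=0, **kwargs):
    seq = SequenceRecord(id="t", residues=residues, offset=offset)
    return GroundTruth(sequence=seq, **kwargs)


class TestGroundTruth:
    def test_interval_outside_sequence_rejected(self):
        with pytest.raises(InvalidInputError):
            simple_truth(protected_intervals=(Interval(45, 55, 10.0),))

    def test_multiplier_must_exceed_one(self):
        with pytest.raises(InvalidInputError):
            simple_truth(protected_intervals=(Interval(5, 10, 0.5),))

    def test_sidecar_round_trip(self, tmp_path):
        truth = synth.default_truth(3)
        path = tmp_path / "truth.txt"
        synth.write_ground_truth(truth, path)
        back = synth.read_ground_truth(path)
        assert back.sequence.residues == truth.sequence.residues
        assert back.sequence.offset == truth.sequence.offset
        assert back.protected_intervals == truth.protected_intervals
        assert back.helical_intervals == truth.helical_intervals
        assert back.extended_intervals == truth.extended_intervals
        assert back.exchange_hotspots == truth.exchange_hotspots
        assert back.true_kd == truth.true_kd


class TestPeptidePool:
    def test_coverage_and_redundancy(self):
        """200 residues, mean length 12, target redundancy 4: full coverage
        and redundancy within +/-1 of the target, measured from the pool."""
        seq = SequenceRecord(id="x", residues="A" * 200)
        pool = generate_peptide_pool(seq, mean_length=12, target_redundancy=4,
                                     seed=1)
        assert pool.coverage == 1.0
        assert abs(pool.redundancy - 4) <= 1.0

    def test_degenerate_short_sequence(self):
        seq = SequenceRecord(id="x", residues="AKLGV")
        pool = generate_peptide_pool(seq, mean_length=5)
        assert len(pool.peptides) == 1
        assert (pool.peptides[0].start, pool.peptides[0].end) == (1, 5)

    def test_deterministic(self):
        seq = SequenceRecord(id="x", residues="AKLGV" * 30)
        a = generate_peptide_pool(seq, seed=7)
        b = generate_peptide_pool(seq, seed=7)
        assert a.peptides == b.peptides

    def test_peptide_sequences_match_parent(self, truth, pool):
        for pep in pool.peptides:
            assert pep.sequence == truth.sequence.slice(pep.start, pep.end)

    def test_empty_sequence_rejected(self):
        with pytest.raises(InvalidInputError):
            SequenceRecord(id="x", residues="")


class TestSimulateUptake:
    def kinetics_world(self, multiplier=10.0):
        # peptide "AA": one exchangeable amide (position 2)
        truth = simple_truth(residues="AA",
                             protected_intervals=(Interval(1, 2, multiplier),))
        pool = generate_peptide_pool(truth.sequence, mean_length=5)
        return truth, pool

    def test_single_amide_hand_kinetics(self):
        """k_int = 1/s, P = 10, t = 3 s: deuteration 1 - exp(-0.3) = 0.25918."""
        truth, pool = self.kinetics_world(multiplier=10.0)
        model = UniformRateModel(k_ref=1.0, pD=7.4, pD_ref=7.4)
        rec = simulate_uptake(pool, truth, [3.0], state="bound", bound=True,
                              replicates=1, noise_sd=0.0, rate_model=model)
        uptake = rec[rec.exposure_control == "timepoint"].mass_centroid.iloc[0] \
            - rec[rec.exposure_control == "non-deuterated"].mass_centroid.iloc[0]
        assert uptake / DEUTERIUM_MASS_SHIFT == pytest.approx(1 - np.exp(-0.3),
                                                              abs=1e-12)

    def test_infinite_protection_blocks_uptake(self):
        truth, pool = self.kinetics_world(multiplier=1e15)
        model = UniformRateModel(k_ref=1.0, pD=7.4, pD_ref=7.4)
        rec = simulate_uptake(pool, truth, [3.0, 3000.0], state="bound",
                              bound=True, replicates=1, noise_sd=0.0,
                              rate_model=model)
        pts = rec[rec.exposure_control == "timepoint"]
        nd = rec[rec.exposure_control == "non-deuterated"].mass_centroid.iloc[0]
        assert np.allclose(pts.mass_centroid, nd, atol=1e-9)

    def test_saturation_equals_amide_count(self, truth, pool):
        """At t -> infinity every peptide reaches its exchangeable-amide count."""
        rec = simulate_uptake(pool, truth, [1e9], replicates=1, noise_sd=0.0)
        pts = rec[rec.exposure_control == "timepoint"]
        nd = rec[rec.exposure_control == "non-deuterated"]
        merged = pts.merge(nd, on=["start", "end"], suffixes=("", "_nd"))
        for _, row in merged.iterrows():
            n_ex, _ = count_exchangeable(row.sequence)
            uptake = (row.mass_centroid - row.mass_centroid_nd) / DEUTERIUM_MASS_SHIFT
            assert uptake == pytest.approx(n_ex, abs=1e-6)

    def test_uptake_monotone_in_time_and_protection(self, truth, pool):
        times = [3.0, 30.0, 300.0]
        free = simulate_uptake(pool, truth, times, replicates=1, noise_sd=0.0)
        bound = simulate_uptake(pool, truth, times, state="b", bound=True,
                                replicates=1, noise_sd=0.0)
        for df in (free, bound):
            pts = df[df.exposure_control == "timepoint"]
            for _, grp in pts.groupby(["start", "end"]):
                masses = grp.sort_values("time").mass_centroid.to_numpy()
                assert np.all(np.diff(masses) >= -1e-12)
        # protection never increases uptake
        key = ["start", "end", "time"]
        m = free[free.exposure_control == "timepoint"].merge(
            bound[bound.exposure_control == "timepoint"], on=key,
            suffixes=("_f", "_b"))
        assert (m.mass_centroid_b <= m.mass_centroid_f + 1e-12).all()

    def test_deterministic_under_seed(self, truth, pool):
        a = simulate_uptake(pool, truth, [3.0, 30.0], noise_sd=0.05, seed=5)
        b = simulate_uptake(pool, truth, [3.0, 30.0], noise_sd=0.05, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_bad_times_rejected(self, truth, pool):
        with pytest.raises(InvalidInputError):
            simulate_uptake(pool, truth, [0.0])


class TestSimulateRelaxation:
    def test_zero_bound_fraction_identity(self, truth):
        apo, bound = simulate_relaxation(truth, bound_fraction=0.0)
        pd.testing.assert_frame_equal(apo.drop(columns="state"),
                                      bound.drop(columns="state"))

    def test_hotspot_increment_exact(self):
        truth = simple_truth(residues="A" * 100,
                             exchange_hotspots=(Interval(21, 31, 4.0),))
        apo, bound = simulate_relaxation(truth, bound_fraction=1.0)
        delta = bound.R2.to_numpy() - apo.R2.to_numpy()
        inside = (apo.residue >= 21) & (apo.residue <= 31)
        assert np.allclose(delta[inside], 4.0)
        assert np.allclose(delta[~inside], 0.0)

    def test_negative_rates_rejected(self, truth):
        base = synth.default_base_rates(truth)
        base.loc[0, "R1"] = -1.0
        with pytest.raises(InvalidInputError):
            simulate_relaxation(truth, base_rates=base)

    def test_apo_is_exchange_free_by_construction(self, truth):
        from idrmap.relax import exchange_decomposition
        apo, _ = simulate_relaxation(truth, bound_fraction=0.0)
        dec = exchange_decomposition(apo)
        assert np.allclose(dec.rex, 0.0, atol=1e-12)


class TestSimulateTitration:
    def test_insufficient_points_rejected(self):
        with pytest.raises(InsufficientDesignError):
            simulate_titration(5.8, n_points=3)

    def test_saturation_limit(self):
        pts = simulate_titration(1e-9, receptor_total=10, top_ligand=125,
                                 noise_sd=0.0, replicates=1,
                                 r_free=0.1, r_bound=0.25)
        top = pts.loc[pts.ligand_total.idxmax(), "anisotropy"]
        assert top == pytest.approx(0.25, abs=1e-6)

    def test_deterministic(self):
        a = simulate_titration(5.8, seed=3)
        b = simulate_titration(5.8, seed=3)
        pd.testing.assert_frame_equal(a, b)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(t1=st.floats(0.1, 1e4), t2=st.floats(0.1, 1e4),
       p=st.floats(1.001, 1e6))
def test_kinetic_scheme_monotone(t1, t2, p):
    """D(t) = 1 - exp(-(k/P) t) increases with t and decreases with P."""
    k = 0.04
    d = lambda t, prot: 1 - np.exp(-(k / prot) * t)
    lo, hi = sorted((t1, t2))
    assert d(hi, p) >= d(lo, p)
    assert d(t1, p) <= d(t1, 1.0)
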