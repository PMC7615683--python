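import numpy as np
import pandas as pd
import pytest

from conftest import make_uptake_records
from idrmap import hdx, synth
from idrmap.errors import (DegeneratePeptideError, InvalidInputError,
                           MissingControlError)
from idrmap.hdx import (call_regions, differential_uptake, fraction_exchanged,
                        read_uptake_table, residue_map, write_woods)
from idrmap.io import SequenceRecord


class TestFractionExchanged:
    def test_hand_arithmetic_max_labelled(self):
        """m0=1000, mt=1004, m_max=1008 gives fx = 0.5."""
        rec = make_uptake_records(1, 9, "AAAAAAAAA", {0.0: [1000.0],
                                                      30.0: [1004.0]},
                                  m0=1000.0, m_max=1008.0)
        fx = fraction_exchanged(rec, normalization="max-labelled")
        assert fx.mean_fx.iloc[0] == pytest.approx(0.5, abs=1e-12)

    def test_undeuterated_and_saturated_limits(self):
        # theoretical: 9 residues, 8 exchangeable amides
        m0 = 1000.0
        m_sat = m0 + 8 * 1.00628
        rec = make_uptake_records(1, 9, "AAAAAAAAA",
                                  {0.0: [m0], 3.0: [m0], 300.0: [m_sat]}, m0=m0)
        fx = fraction_exchanged(rec, normalization="theoretical")
        by_time = fx.set_index("time").mean_fx
        assert by_time[3.0] == pytest.approx(0.0, abs=1e-12)
        assert by_time[300.0] == pytest.approx(1.0, abs=1e-12)

    def test_missing_control_raises(self):
        rec = make_uptake_records(1, 9, "AAAAAAAAA", {30.0: [1004.0]}, m0=1000.0)
        rec = rec[rec.exposure_control != "non-deuterated"]
        with pytest.raises(MissingControlError):
            fraction_exchanged(rec)

    def test_max_labelled_requires_control(self):
        rec = make_uptake_records(1, 9, "AAAAAAAAA", {0.0: [1000.0],
                                                      30.0: [1004.0]}, m0=1000.0)
        with pytest.raises(MissingControlError):
            fraction_exchanged(rec, normalization="max-labelled")

    def test_degenerate_peptide(self):
        # "AP": zero exchangeable amides -> m_max == m0 in theoretical mode
        rec = make_uptake_records(1, 2, "AP", {0.0: [200.0], 30.0: [200.0]},
                                  m0=200.0)
        with pytest.raises(DegeneratePeptideError):
            fraction_exchanged(rec)

    def test_charge_states_pooled(self):
        a = make_uptake_records(1, 9, "AAAAAAAAA", {0.0: [1000.0],
                                                    30.0: [1004.0]},
                                m0=1000.0, charge=2)
        b = make_uptake_records(1, 9, "AAAAAAAAA", {0.0: [1000.0],
                                                    30.0: [1004.2]},
                                m0=1000.0, charge=3)
        fx = fraction_exchanged(pd.concat([a, b]))
        assert len(fx) == 1
        assert fx.n.iloc[0] == 2


class TestDifferentialUptake:
    def fx_table(self, mean, sd=0.01, n=3, time=30.0):
        return pd.DataFrame([dict(protein="p", start=1, end=9,
                                  sequence="AAAAAAAAA", state="s", time=time,
                                  mean_fx=mean, sd_fx=sd, n=n)])

    def test_self_comparison_zero(self):
        fx = self.fx_table(0.4)
        d = differential_uptake(fx, fx)
        assert d.delta_fx.iloc[0] == 0.0

    def test_combined_uncertainty_hand_value(self):
        """sd_A=0.01, sd_B=0.02, n=3 each: u_c = sqrt(0.0005/3) = 0.012910."""
        d = differential_uptake(self.fx_table(0.3, sd=0.01),
                                self.fx_table(0.4, sd=0.02))
        assert d.u_c.iloc[0] == pytest.approx(np.sqrt(5e-4 / 3), rel=1e-9)
        assert d.u_c.iloc[0] == pytest.approx(0.012910, abs=5e-7)

    def test_ci99_wider_than_ci98(self):
        d = differential_uptake(self.fx_table(0.3, sd=0.01),
                                self.fx_table(0.4, sd=0.02))
        assert (d.ci99 > d.ci98).all()

    def test_antisymmetry(self):
        a, b = self.fx_table(0.3, sd=0.013), self.fx_table(0.45, sd=0.02)
        ab, ba = differential_uptake(a, b), differential_uptake(b, a)
        assert ab.delta_fx.iloc[0] == pytest.approx(-ba.delta_fx.iloc[0], rel=1e-12)
        assert ab.u_c.iloc[0] == pytest.approx(ba.u_c.iloc[0], rel=1e-12)

    def test_unmatched_skipped_and_counted(self):
        d = differential_uptake(self.fx_table(0.3, time=30.0),
                                self.fx_table(0.4, time=60.0))
        assert len(d) == 0
        assert d.attrs["unmatched"] == 2


def diff_rows(peptides, deltas_by_time, protein="p"):
    """Build a differential-uptake table; peptides is [(start, end, seq)]."""
    rows = []
    for (start, end, seq), by_time in zip(peptides, deltas_by_time):
        for time, delta in by_time.items():
            rows.append(dict(protein=protein, start=start, end=end,
                             sequence=seq, time=time, delta_fx=delta,
                             u_c=0.005, ci98=0.01, ci99=0.015, n_a=3, n_b=3))
    return pd.DataFrame(rows)


class TestCallRegions:
    def test_branch1_two_timepoints(self):
        """One peptide above 5% at 30 s and 300 s flags via the
        multi-timepoint branch."""
        diffs = diff_rows([(10, 18, "AAAAAAAAA")],
                          [{3.0: 0.01, 30.0: 0.06, 300.0: 0.06}])
        calls = call_regions(diffs, protected_sign=1)
        assert len(calls) == 1
        assert calls[0].direction == "protected"
        assert calls[0].rule_branch == "multi-timepoint"
        assert (calls[0].start, calls[0].end) == (10, 18)

    def test_single_timepoint_insufficient(self):
        diffs = diff_rows([(10, 18, "AAAAAAAAA")], [{30.0: 0.06, 300.0: 0.01}])
        assert call_regions(diffs, protected_sign=1) == []

    def test_all_zero_no_regions(self):
        diffs = diff_rows([(10, 18, "AAAAAAAAA")], [{30.0: 0.0, 300.0: 0.0}])
        assert call_regions(diffs) == []

    def test_branch2_three_overlapping_peptides(self):
        """Three mutually overlapping peptides above 5% at one time point
        flag their union 10-30."""
        peptides = [(10, 22, "A" * 13), (14, 26, "A" * 13), (18, 30, "A" * 13)]
        diffs = diff_rows(peptides, [{30.0: 0.06}] * 3)
        calls = call_regions(diffs, protected_sign=1, trim="none")
        assert len(calls) == 1
        assert (calls[0].start, calls[0].end) == (10, 30)
        assert calls[0].rule_branch == "multi-peptide"

    def test_branch2_disabled_never_creates_calls(self):
        peptides = [(10, 22, "A" * 13), (14, 26, "A" * 13), (18, 30, "A" * 13)]
        diffs = diff_rows(peptides, [{30.0: 0.06}] * 3)
        assert call_regions(diffs, protected_sign=1, branch2=False) == []

    def test_threshold_is_strict(self):
        """|delta| == threshold exactly never flags; threshold + eps does."""
        at = diff_rows([(10, 18, "AAAAAAAAA")], [{30.0: 0.05, 300.0: 0.05}])
        above = diff_rows([(10, 18, "AAAAAAAAA")],
                          [{30.0: 0.05 + 1e-9, 300.0: 0.05 + 1e-9}])
        assert call_regions(at, protected_sign=1) == []
        assert len(call_regions(above, protected_sign=1)) == 1

    def test_direction_follows_sign_convention(self):
        diffs = diff_rows([(10, 18, "AAAAAAAAA")], [{30.0: -0.08, 300.0: -0.08}])
        calls = call_regions(diffs, protected_sign=-1)
        assert calls[0].direction == "protected"

    def test_subtractive_trim_removes_quiet_residues(self):
        # flagged 10-18 overlapped by a quiescent peptide 14-22: residues
        # 15-18 carry quiet amide evidence and are trimmed (14 is the quiet
        # peptide's N-terminal residue, which carries no amide information)
        diffs = diff_rows([(10, 18, "A" * 9), (14, 22, "A" * 9)],
                          [{30.0: 0.08, 300.0: 0.08}, {30.0: 0.0, 300.0: 0.0}])
        calls = call_regions(diffs, protected_sign=1, trim="subtractive")
        assert len(calls) == 1
        assert (calls[0].start, calls[0].end) == (10, 14)


class TestResidueMap:
    def test_single_call(self):
        seq = SequenceRecord(id="p", residues="A" * 300)
        calls = [hdx.RegionCall("p", 255, 269, "protected", "multi-timepoint",
                                ((255, 269),), (30.0,))]
        rmap = residue_map(calls, seq)
        labelled = rmap[rmap.label == "protected"].residue
        assert labelled.min() == 255 and labelled.max() == 269
        assert (rmap.label != "none").sum() == 15

    def test_no_calls_all_none(self):
        seq = SequenceRecord(id="p", residues="A" * 20)
        rmap = residue_map([], seq)
        assert (rmap.label == "none").all()

    def test_conflicting_directions_ambiguous(self):
        seq = SequenceRecord(id="p", residues="A" * 30)
        calls = [hdx.RegionCall("p", 5, 15, "protected", "multi-timepoint",
                                ((5, 15),), (30.0,)),
                 hdx.RegionCall("p", 12, 20, "deprotected", "multi-timepoint",
                                ((12, 20),), (30.0,))]
        rmap = residue_map(calls, seq)
        assert set(rmap[rmap.residue.between(12, 15)].label) == {"ambiguous"}
        assert rmap.attrs["ambiguous"] == 4


class TestOracleRecovery:
    @pytest.mark.parametrize("noise", [False, True])
    def test_implanted_intervals_recovered(self, noise):
        """Synthetic protected intervals: high recall, low false-positive
        rate at <=0.5% fx noise (full 20-seed sweep in acceptance tests)."""
        recalls, fps = [], []
        for seed in range(4):
            truth = synth.default_truth(seed)
            pool = synth.generate_peptide_pool(truth.sequence, seed=seed)
            kw = dict(times=(3.0, 30.0, 60.0, 300.0), replicates=3,
                      noise_sd=0.03 if noise else 0.0)
            apo = synth.simulate_uptake(pool, truth, state="apo", **kw)
            bnd = synth.simulate_uptake(pool, truth, state="+partner", **kw)
            diffs = differential_uptake(fraction_exchanged(apo),
                                        fraction_exchanged(bnd))
            calls = call_regions(diffs)
            called = set()
            for c in calls:
                if c.direction == "protected":
                    called.update(c.residues())
            implanted = set()
            for iv in truth.protected_intervals:
                implanted.update(iv.residues())
            recalls.append(len(called & implanted) / len(implanted))
            fps.append(len(called - implanted) / (200 - len(implanted)))
        assert np.mean(recalls) >= 0.95
        assert np.mean(fps) <= 0.05


class TestIO:
    def test_dynamx_dialect(self, tmp_path):
        df = pd.DataFrame([dict(protein="p", start=1, end=9,
                                sequence="AAAAAAAAA", z=2, state="apo",
                                exposure=0.0, replicate=1,
                                **{"centroid mass": 1000.0}),
                           dict(protein="p", start=1, end=9,
                                sequence="AAAAAAAAA", z=2, state="apo",
                                exposure=30.0, replicate=1,
                                **{"centroid mass": 1004.0})])
        path = tmp_path / "dynamx.csv"
        df.to_csv(path, index=False)
        table = read_uptake_table(path, dialect="dynamx")
        assert set(hdx.UPTAKE_COLUMNS) <= set(table.columns)
        assert list(table.exposure_control) == ["non-deuterated", "timepoint"]

    def test_woods_tsv_flags(self, tmp_path):
        diffs = diff_rows([(10, 18, "A" * 9)], [{30.0: 0.08, 300.0: 0.02}])
        path = tmp_path / "woods.tsv"
        write_woods(diffs, path)
        back = pd.read_csv(path, sep="\t")
        assert back.flagged.tolist() == [True, False]
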