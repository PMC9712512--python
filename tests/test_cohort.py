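"""Composite scores, longitudinal change, binning and the wave matrix."""

import numpy as np
import pandas as pd
import pytest

from fatfront.cohort import (
    LongitudinalRecord,
    MuscleRecord,
    baseline_bin,
    change_by_baseline_bin,
    composite_ff,
    left_right_average,
    longitudinal_change,
    mercuri_class,
    segment_change_matrix,
)
from fatfront.dixon import StructuralError, ValidationError
from fatfront.front import FrontParams, eval_front
from conftest import make_profile


def rec(ff, vol, muscle="m", side="L", patient="P1", timepoint="baseline"):
    return MuscleRecord(muscle=muscle, side=side, patient=patient,
                        timepoint=timepoint, ff_whole=ff, volume_ml=vol, n_slices=10)


class TestCompositeFF:
    def test_volume_weighted(self):
        out = composite_ff([rec(30.0, 200.0), rec(60.0, 100.0, muscle="n")])
        assert out.ff == pytest.approx(40.0)

    def test_single_muscle_identity(self):
        assert composite_ff([rec(42.0, 150.0)]).ff == pytest.approx(42.0)

    def test_bounded_by_members_and_order_invariant(self):
        rng = np.random.default_rng(3)
        records = [rec(float(rng.uniform(0, 100)), float(rng.uniform(10, 500)),
                       muscle=f"m{i}") for i in range(12)]
        out = composite_ff(records)
        ffs = [r.ff_whole for r in records]
        assert min(ffs) <= out.ff <= max(ffs)
        shuffled = list(records)
        rng.shuffle(shuffled)
        assert composite_ff(shuffled).ff == pytest.approx(out.ff)

    def test_voxel_level_oracle(self):
        """With per-muscle FFs that are voxel means on a shared grid, the
        composite equals the pooled voxel mean."""
        rng = np.random.default_rng(5)
        voxels = [rng.uniform(0, 100, int(rng.integers(50, 400))) for _ in range(6)]
        vox_ml = 0.00925
        records = [
            rec(float(v.mean()), len(v) * vox_ml, muscle=f"m{i}")
            for i, v in enumerate(voxels)
        ]
        pooled = np.concatenate(voxels).mean()
        assert composite_ff(records).ff == pytest.approx(pooled, rel=1e-12)

    def test_empty_scope_rejected(self):
        with pytest.raises(ValidationError):
            composite_ff([], scope="upper leg")


class TestLeftRightAverage:
    def test_equal_volumes(self):
        df = left_right_average([rec(30.0, 100.0, side="L"), rec(50.0, 100.0, side="R")])
        assert df.loc[0, "ff_whole"] == pytest.approx(40.0)
        assert df.loc[0, "n_sides"] == 2

    def test_single_side_passthrough(self):
        df = left_right_average([rec(30.0, 100.0, side="L")])
        assert df.loc[0, "ff_whole"] == pytest.approx(30.0)
        assert df.loc[0, "n_sides"] == 1

    def test_unequal_volumes_weighted(self):
        df = left_right_average([rec(30.0, 300.0, side="L"), rec(50.0, 100.0, side="R")])
        assert df.loc[0, "ff_whole"] == pytest.approx((30 * 300 + 50 * 100) / 400)


class TestBins:
    @pytest.mark.parametrize("ff,expected", [
        (0.0, "0-10"), (9.99, "0-10"), (10.0, "10-20"), (30.0, "30-40"),
        (89.9, "80-90"), (95.0, "80-90"),
    ])
    def test_baseline_bin_half_open(self, ff, expected):
        assert baseline_bin(ff) == expected

    @pytest.mark.parametrize("ff,expected", [
        (5.0, "<10"), (10.0, "10-30"), (29.9, "10-30"), (30.0, "30-60"),
        (60.0, ">60"), (90.0, ">60"),
    ])
    def test_mercuri_half_open(self, ff, expected):
        assert mercuri_class(ff) == expected


class TestLongitudinalChange:
    def test_change_and_rate(self):
        out = longitudinal_change(rec(20.0, 100.0), rec(30.0, 90.0, timepoint="followup"), 2.5)
        assert out.change == pytest.approx(10.0)
        assert out.change_per_year == pytest.approx(4.0)
        assert out.bin == "20-30"

    def test_no_change(self):
        out = longitudinal_change(rec(20.0, 100.0), rec(20.0, 100.0, timepoint="fu"), 3.0)
        assert out.change == 0.0 and out.change_per_year == 0.0

    def test_rate_times_interval_recovers_change(self):
        out = longitudinal_change(rec(12.0, 80.0), rec(19.3, 75.0, timepoint="fu"), 3.67)
        assert out.change_per_year * out.interval_years == pytest.approx(out.change)

    def test_identity_mismatch_rejected(self):
        with pytest.raises(StructuralError):
            longitudinal_change(rec(20.0, 100.0), rec(30.0, 90.0, muscle="other"), 1.0)

    def test_nonpositive_interval_rejected(self):
        with pytest.raises(ValidationError):
            longitudinal_change(rec(20.0, 100.0), rec(30.0, 90.0, timepoint="fu"), 0.0)


class TestChangeByBin:
    def test_single_bin_stats(self):
        records = [
            LongitudinalRecord("m", "L", f"P{i}", ff_baseline=15.0,
                               ff_followup=15.0 + r, interval_years=1.0)
            for i, r in enumerate([1.0, 2.0, 3.0])
        ]
        df = change_by_baseline_bin(records)
        row = df[df["bin"] == "10-20"].iloc[0]
        assert row["mean"] == pytest.approx(2.0)
        assert row["sd"] == pytest.approx(1.0)
        assert row["n"] == 3

    def test_empty_bins_flagged(self):
        records = [LongitudinalRecord("m", "L", "P1", 15.0, 16.0, 1.0)]
        df = change_by_baseline_bin(records)
        assert df[df["bin"] == "50-60"].iloc[0]["empty"]
        assert not df[df["bin"] == "10-20"].iloc[0]["empty"]

    def test_bell_rate_law_argmax_recovered(self):
        """Cohort simulated with a bell-shaped rate peaking at 35% baseline
        FF: the per-bin mean rate must peak in the 30-40 bin."""
        rng = np.random.default_rng(11)
        records = []
        for i in range(400):
            ff0 = float(rng.uniform(0, 85))
            rate = 4.9 * np.exp(-(((ff0 - 35) / 20) ** 2)) + rng.normal(0, 0.3)
            records.append(LongitudinalRecord(
                f"m{i}", "L", f"P{i % 9}", ff0, ff0 + rate * 3.67, 3.67
            ))
        df = change_by_baseline_bin(records)
        assert df.loc[df["mean"].idxmax(), "bin"] == "30-40"


def front_profile(params, n=40, timepoint="baseline", muscle="m"):
    x = np.arange(n) / (n - 1)
    return make_profile(eval_front(params, x), muscle=muscle, timepoint=timepoint)


class TestSegmentChangeMatrix:
    def test_identical_timepoints_zero(self):
        p = FrontParams(70, 5, 0.5, 0.08)
        base = [front_profile(p)]
        fu = [front_profile(p, timepoint="followup")]
        m = segment_change_matrix(base, fu, 3.67)
        filled = m[~m["empty"]]
        np.testing.assert_allclose(filled["mean"], 0.0, atol=1e-12)

    def test_front_advance_concentrates_change_distally(self):
        """Noiseless front moving from x0=0.2 to 0.4: per-segment change,
        evaluated analytically from the model, is largest in segments 1-2."""
        base = [front_profile(FrontParams(80, 5, 0.2, 0.05))]
        fu = [front_profile(FrontParams(80, 5, 0.4, 0.05), timepoint="followup")]
        m = segment_change_matrix(base, fu, 1.0)
        filled = m[~m["empty"]].set_index("segment")
        assert filled.loc[2, "mean"] > filled.loc[4, "mean"]
        assert filled["mean"].idxmax() in (1, 2)
        assert filled.loc[[1, 2], "mean"].sum() > 0.8 * filled["mean"].sum()

    def test_fully_infiltrated_static(self):
        p = FrontParams(85, 80, 1.4, 0.05)
        m = segment_change_matrix(
            [front_profile(p)], [front_profile(p, timepoint="fu")], 2.0
        )
        filled = m[~m["empty"]]
        np.testing.assert_allclose(filled["mean"], 0.0, atol=1e-9)

    def test_unpaired_skipped(self, caplog):
        base = [front_profile(FrontParams(70, 5, 0.5, 0.08)),
                front_profile(FrontParams(70, 5, 0.5, 0.08), muscle="lonely")]
        fu = [front_profile(FrontParams(70, 5, 0.6, 0.08), timepoint="fu")]
        m = segment_change_matrix(base, fu, 1.0)
        assert m[~m["empty"]]["n"].max() == 1
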