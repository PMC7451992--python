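"""Timescale-split orchestration: determinism, stability, snapshots."""

import copy

import numpy as np
import pandas as pd
import pytest

import cardiorenal as cr
from cardiorenal.interventions import Intervention
from cardiorenal.scheduler import (Protocol, advance, pv_loop_snapshot,
                                   run_protocol)
from cardiorenal.virtual_patient import baseline_state, build_patient, get_preset


class TestProtocolValidation:
    def test_duration_positive(self):
        with pytest.raises(ValueError):
            Protocol(duration_days=0.0)

    def test_slow_step_bounded_by_one_day(self):
        with pytest.raises(ValueError):
            Protocol(slow_step_days=2.0)
        with pytest.raises(ValueError):
            Protocol(slow_step_days=0.0)


class TestRunProtocol:
    def test_healthy_stays_flat(self, healthy_baseline):
        slow, fast, _ = healthy_baseline
        proto = Protocol(patient="healthy", duration_days=20.0)
        res = run_protocol(proto, initial=(copy.deepcopy(slow),
                                           copy.deepcopy(fast)))
        f = res.frame
        for col in ("bv_l", "ifv_l", "map_mmhg", "edv_ml", "gfr_ml_min"):
            drift = abs(f[col].iloc[-1] / f[col].iloc[0] - 1.0)
            assert drift < 1e-4, col

    def test_bitwise_determinism(self, healthy_baseline):
        slow, fast, _ = healthy_baseline
        proto = Protocol(patient="healthy", duration_days=3.0)
        a = run_protocol(proto, initial=(copy.deepcopy(slow),
                                         copy.deepcopy(fast))).frame
        b = run_protocol(proto, initial=(copy.deepcopy(slow),
                                         copy.deepcopy(fast))).frame
        pd.testing.assert_frame_equal(a, b, check_exact=True)

    def test_intervention_applied_on_schedule(self, healthy_baseline):
        slow, fast, _ = healthy_baseline
        proto = Protocol(patient="healthy", duration_days=4.0,
                         intervention=Intervention(kind="sglt2i",
                                                   start_day=2.0))
        res = run_protocol(proto, initial=(copy.deepcopy(slow),
                                           copy.deepcopy(fast)))
        f = res.frame
        assert f.loc[f.day <= 1.5, "uge_mmol_day"].max() < 1.0
        assert f.loc[f.day >= 3.0, "uge_mmol_day"].min() > 50.0


class TestStepSizeRobustness:
    def test_halving_slow_step_changes_endpoint_little(self, healthy_baseline):
        # probe during a genuine transient: hypertensive parameters applied
        # to the healthy state
        slow, fast, _ = healthy_baseline
        params = build_patient(get_preset("hypertensive"))
        ends = []
        for step in (1.0, 0.5):
            s, f = copy.deepcopy(slow), copy.deepcopy(fast)
            s2, f2, bs = advance(s, f, params, days=8.0, step_days=step)
            ends.append((s2.bv, s2.ifv, bs.map, bs.edv))
        for a, b in zip(*ends):
            assert abs(a / b - 1.0) < 0.005


class TestPVLoopSnapshot:
    def test_snapshot_range_matches_summary(self, healthy_baseline):
        slow, fast, _ = healthy_baseline
        proto = Protocol(patient="healthy", duration_days=2.0)
        res = run_protocol(proto, initial=(copy.deepcopy(slow),
                                           copy.deepcopy(fast)))
        trace = pv_loop_snapshot(res, day=2.0)
        row = res.at_day(2.0)
        assert trace[:, 1].max() == pytest.approx(row["edv_ml"], rel=1e-3)
        assert trace[:, 1].min() == pytest.approx(row["esv_ml"], rel=1e-2)

    def test_day_out_of_range(self, healthy_baseline):
        slow, fast, _ = healthy_baseline
        proto = Protocol(patient="healthy", duration_days=2.0)
        res = run_protocol(proto, initial=(copy.deepcopy(slow),
                                           copy.deepcopy(fast)))
        with pytest.raises(ValueError, match="outside"):
            pv_loop_snapshot(res, day=10.0)
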