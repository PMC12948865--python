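"""Tracer partitioning (%CdfR, qCdfR), allocation coefficients and summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rhizotrace.errors import MissingGroupError, UndefinedPartitionError
from rhizotrace.rhizo import (
    allocation_coefficients,
    carbon_ratios,
    percent_cdfr,
    q_cdfr,
    relative_rhizodeposition,
    treatment_summary,
)


class TestPercentCdfr:
    @pytest.mark.parametrize(
        "soil,root,expected",
        [(0.2, 0.2, 50.0), (0.0, 0.1, 0.0), (0.3, 0.1, 75.0)],
    )
    def test_partition_arithmetic(self, soil, root, expected):
        assert percent_cdfr(soil, root) == pytest.approx(expected)

    def test_zero_total_excess_undefined(self):
        with pytest.raises(UndefinedPartitionError):
            percent_cdfr(0.0, 0.0)


class TestQCdfr:
    def test_symmetric_partition_doubles_root_c(self):
        assert q_cdfr(50.0, 100.0) == pytest.approx(100.0)
        assert q_cdfr(0.0, 100.0) == 0.0

    def test_singular_percent_rejected(self):
        with pytest.raises(UndefinedPartitionError):
            q_cdfr(100.0, 50.0)

    @given(st.floats(0.0, 99.9), st.floats(1e-6, 1e4))
    @settings(deadline=None, max_examples=300)
    def test_partition_identity(self, pct, rc):
        """qCdfR/(qCdfR + RC) = %CdfR/100 exactly (algebraic identity)."""
        q = q_cdfr(pct, rc)
        if q + rc > 0:
            assert q / (q + rc) == pytest.approx(pct / 100.0, abs=1e-12)


class TestRelativeRhizodeposition:
    def test_rainfed_profile_means(self):
        """237 g m-2 rhizodeposition C over 99 g m-2 root C -> ~71 %."""
        rel = relative_rhizodeposition(237.0, 99.0)
        assert rel == pytest.approx(0.7053571428571429, rel=1e-12)
        assert round(rel * 100) == 71

    def test_limits(self):
        assert relative_rhizodeposition(0.0, 5.0) == 0.0
        assert relative_rhizodeposition(7.0, 7.0) == 0.5


class TestAllocationCoefficients:
    def test_proportions(self):
        assert allocation_coefficients(300, 300, 100, 300) == pytest.approx(
            (0.3, 0.3, 0.1, 0.3)
        )

    def test_single_component(self):
        assert allocation_coefficients(0, 10, 0, 0) == pytest.approx((0, 1, 0, 0))

    def test_permutation_consistency(self):
        a = allocation_coefficients(1, 2, 3, 4)
        b = allocation_coefficients(4, 3, 2, 1)
        assert a == pytest.approx(b[::-1])

    @given(st.tuples(*[st.floats(0.0, 1e4)] * 4).filter(lambda t: sum(t) > 1e-6))
    @settings(deadline=None)
    def test_sum_to_one(self, pools):
        assert sum(allocation_coefficients(*pools)) == pytest.approx(1.0, abs=1e-9)

    def test_zero_total_undefined(self):
        with pytest.raises(UndefinedPartitionError):
            allocation_coefficients(0, 0, 0, 0)


class TestCarbonRatios:
    def test_reference_case(self):
        rs, ba = carbon_ratios(300, 300, 100, 300)
        assert rs == pytest.approx(1 / 3)
        assert ba == pytest.approx(2 / 3)

    def test_no_belowground(self):
        _, ba = carbon_ratios(300, 300, 0, 0)
        assert ba == 0.0

    @given(st.floats(1.0, 100.0))
    @settings(deadline=None)
    def test_scale_invariance(self, k):
        a = carbon_ratios(300, 300, 100, 300)
        b = carbon_ratios(300 * k, 300 * k, 100 * k, 300 * k)
        assert a == pytest.approx(b, rel=1e-12)

    def test_zero_straw_rejected(self):
        with pytest.raises(UndefinedPartitionError):
            carbon_ratios(300, 0, 100, 300)


def _plots():
    rows = []
    for system in ("A", "B"):
        for regime, val in (("control", 100.0), ("drought", 150.0)):
            for p in range(3):
                rows.append({"system": system, "regime": regime,
                             "plot_id": f"{system}-{regime}-{p}",
                             "root_c_g_m2": val + p})
    return pd.DataFrame(rows)


class TestTreatmentSummary:
    def test_means_se_and_percent_change(self):
        out = treatment_summary(_plots(), ["root_c_g_m2"])
        pooled_d = out[(out.system == "all") & (out.regime == "drought")].iloc[0]
        pooled_c = out[(out.system == "all") & (out.regime == "control")].iloc[0]
        assert pooled_c["mean"] == pytest.approx(101.0)
        assert pooled_d["mean"] == pytest.approx(151.0)
        # SE = sd/sqrt(n) over plot replicates
        assert pooled_c["se"] == pytest.approx(np.std([100, 101, 102] * 2, ddof=1) / np.sqrt(6))
        assert pooled_d["pct_change_vs_control"] == pytest.approx(
            (151.0 - 101.0) / 101.0 * 100
        )
        assert np.isnan(pooled_c["pct_change_vs_control"])

    def test_identical_groups_zero_change(self):
        df = _plots()
        df["root_c_g_m2"] = 5.0
        out = treatment_summary(df, ["root_c_g_m2"])
        drought = out[out.regime == "drought"]
        assert np.allclose(drought["pct_change_vs_control"], 0.0)

    def test_single_plot_group_se_missing(self, caplog):
        df = _plots().groupby(["system", "regime"]).head(1)
        with caplog.at_level("WARNING"):
            out = treatment_summary(df, ["root_c_g_m2"])
        per_system = out[out.system != "all"]
        assert per_system["se"].isna().all()
        assert "single-plot" in caplog.text

    def test_empty_input_raises(self):
        with pytest.raises(MissingGroupError):
            treatment_summary(pd.DataFrame(columns=["system", "regime", "x"]), ["x"])
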