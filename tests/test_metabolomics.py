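"""Metabolite ratio and adenylate energy-state statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from fluxshift.metabolomics import (
    MetaboliteTable,
    adenylate_indices,
    bh_adjust,
    fold_changes,
    intra_sample_ratio,
    pi_value_rank,
    ratio_panel,
)
from oracles import brute_force_bh


def two_group_table(rows, n_per_group=3):
    cols = [f"P{i}" for i in range(n_per_group)] + [
        f"W{i}" for i in range(n_per_group)
    ]
    abundances = pd.DataFrame(rows, index=cols).T
    groups = pd.Series(["P"] * n_per_group + ["W"] * n_per_group, index=cols)
    return MetaboliteTable(abundances=abundances, groups=groups)


@pytest.fixture
def simple_table():
    return two_group_table(
        {
            "succinate": [10, 12, 11, 2, 2.2, 1.9],
            "fumarate": [2, 2, 2, 2, 2, 2],
            "AMP": [900, 850, 950, 300, 310, 290],
            "ADP": [1200, 1150, 1250, 1000, 990, 1010],
            "ATP": [1200, 1250, 1150, 3000, 3050, 2950],
        }
    )


class TestIntraSampleRatio:
    def test_group_mean_of_per_sample_ratios(self, simple_table):
        stat = intra_sample_ratio(simple_table, "succinate", "fumarate")
        assert stat.group_means["P"] == pytest.approx(5.5)
        assert stat.per_sample["P0"] == pytest.approx(5.0)

    def test_identical_metabolites_ratio_one(self, simple_table):
        stat = intra_sample_ratio(simple_table, "fumarate", "fumarate")
        assert (stat.per_sample == 1).all()
        assert stat.group_sds["P"] == 0

    def test_zero_denominator_names_sample(self, simple_table):
        broken = simple_table
        broken.abundances.loc["fumarate", "W1"] = 0.0
        with pytest.raises(ValueError, match="W1"):
            intra_sample_ratio(broken, "succinate", "fumarate")

    def test_missing_metabolite_rejected(self, simple_table):
        with pytest.raises(KeyError):
            intra_sample_ratio(simple_table, "nothing", "fumarate")

    def test_scale_invariance_per_sample(self, simple_table):
        """Multiplying one sample's whole column cancels in the ratio."""
        baseline = intra_sample_ratio(simple_table, "succinate", "fumarate")
        scaled = simple_table.abundances.copy()
        scaled["P0"] *= 17.0
        table = MetaboliteTable(abundances=scaled, groups=simple_table.groups)
        rescaled = intra_sample_ratio(table, "succinate", "fumarate")
        assert rescaled.per_sample.equals(baseline.per_sample)
        assert rescaled.p_value == baseline.p_value

    def test_panel_gets_bh_family(self, simple_table):
        stats = ratio_panel(
            simple_table,
            [("succinate", "fumarate"), ("AMP", "ATP"), ("ADP", "ATP")],
        )
        ps = [s.p_value for s in stats]
        qs = [s.q_value for s in stats]
        assert np.allclose(qs, bh_adjust(ps))
        assert all(q >= p for p, q in zip(ps, qs))


class TestAdenylateIndices:
    @pytest.mark.parametrize(
        "amp, adp, atp, charge, amp_frac, atp_adp",
        [
            (1, 1, 1, 0.5, 1 / 3, 1.0),  # equal pools
            (0, 0, 5, 1.0, 0.0, np.nan),  # pure ATP limit
            (1, 2, 4, 5 / 7, 1 / 7, 2.0),  # mixed pool
        ],
    )
    def test_index_formulas(self, amp, adp, atp, charge, amp_frac, atp_adp):
        table = two_group_table(
            {
                "AMP": [amp] * 6,
                "ADP": [adp] * 6,
                "ATP": [atp] * 6,
            }
        )
        energy = adenylate_indices(table)
        row = energy.per_sample.iloc[0]
        assert row["energy_charge"] == pytest.approx(charge)
        assert row["amp_fraction"] == pytest.approx(amp_frac)
        if np.isnan(atp_adp):
            assert np.isnan(row["atp_adp"])
        else:
            assert row["atp_adp"] == pytest.approx(atp_adp)

    def test_group_difference_detected(self, simple_table):
        energy = adenylate_indices(simple_table)
        charge = energy.summary.query("index == 'energy_charge'")
        mean_p = charge.query("group == 'P'")["mean"].iloc[0]
        mean_w = charge.query("group == 'W'")["mean"].iloc[0]
        assert mean_p < mean_w  # planted lower energy state in P
        tests = energy.tests.set_index("index")
        assert tests.loc["energy_charge", "p"] < 0.001
        assert (tests["q"] >= tests["p"]).all()

    def test_zero_pool_rejected(self):
        table = two_group_table(
            {"AMP": [0] * 6, "ADP": [0] * 6, "ATP": [0] * 6}
        )
        with pytest.raises(ValueError, match="pool"):
            adenylate_indices(table)

    @given(
        st.lists(
            st.tuples(
                st.floats(0, 1e6),
                st.floats(0, 1e6),
                st.floats(0, 1e6),
            ),
            min_size=6,
            max_size=6,
        )
    )
    @settings(max_examples=200, deadline=None)
    def test_energy_charge_bounded(self, pools):
        """Energy charge lies in [0,1] for any non-negative pool, and
        equals 1 exactly when ADP = AMP = 0."""
        amp, adp, atp = zip(*pools)
        if all(a + d + t == 0 for a, d, t in pools):
            return
        table = two_group_table(
            {"AMP": list(amp), "ADP": list(adp), "ATP": list(atp)}
        )
        try:
            energy = adenylate_indices(table)
        except ValueError:
            return  # some sample had an all-zero pool: contract error
        charge = energy.per_sample["energy_charge"]
        assert ((charge >= 0) & (charge <= 1)).all()
        for (a, d, t), value in zip(pools, charge):
            if d == 0 and a == 0:
                assert value == pytest.approx(1.0)
            elif a > 0 or d > 0:
                assert value < 1.0 + 1e-12


class TestFoldChanges:
    def test_ratio_of_group_means(self, simple_table):
        fc = fold_changes(simple_table, "P", "W")
        assert fc.loc["fumarate", "fold_change"] == pytest.approx(1.0)
        assert fc.loc["ATP", "fold_change"] == pytest.approx(
            simple_table.abundances.loc["ATP", ["P0", "P1", "P2"]].mean()
            / simple_table.abundances.loc["ATP", ["W0", "W1", "W2"]].mean()
        )

    def test_identical_groups_give_one(self):
        table = two_group_table({"m": [2, 2, 2, 2, 2, 2]})
        fc = fold_changes(table)
        assert fc["fold_change"].iloc[0] == pytest.approx(1.0)

    def test_zero_denominator_flagged_not_dropped(self):
        table = two_group_table({"m": [2, 2, 2, 0, 0, 0]})
        fc = fold_changes(table, "P", "W")
        assert fc.loc["m", "undefined"]
        assert np.isnan(fc.loc["m", "fold_change"])

    def test_single_group_rejected(self):
        cols = ["a", "b", "c"]
        table_df = pd.DataFrame({"m": [1, 2, 3]}, index=cols).T
        groups = pd.Series(["G", "G", "G"], index=cols)
        with pytest.raises(ValueError, match="two groups"):
            fold_changes(MetaboliteTable(abundances=table_df, groups=groups))


class TestBHAdjust:
    def test_hand_computed_step_up(self):
        q = bh_adjust([0.01, 0.02, 0.03])
        assert np.allclose(q, [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_all_ones(self):
        assert np.allclose(bh_adjust([1.0, 1.0]), [1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 30))
            assert np.allclose(bh_adjust(p), brute_force_bh(p), atol=1e-12)

    def test_q_at_least_p(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(size=40)
        assert (bh_adjust(p) >= p - 1e-15).all()


class TestPiValue:
    @pytest.mark.parametrize(
        "lfc, p, expected",
        [
            (2.0, 0.01, 4.0),
            (1.5, 1.0, 0.0),  # p = 1 kills the score
            (-1.0, 0.1, -1.0),  # sign follows the fold change
        ],
    )
    def test_examples(self, lfc, p, expected):
        assert pi_value_rank(lfc, p) == pytest.approx(expected)

    def test_zero_p_rejected(self):
        with pytest.raises(ValueError, match="floor"):
            pi_value_rank(2.0, 0.0)

    def test_monotone_in_significance(self):
        scores = pi_value_rank(
            np.full(4, 2.0), np.array([0.5, 0.1, 0.01, 0.001])
        )
        assert (np.diff(scores) > 0).all()
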