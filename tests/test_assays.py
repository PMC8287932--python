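"""Foci thresholds, nuclear-area comparison, ddCt and deamination
quantification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import tcwsig as t
from tcwsig.assays import DEAMINATION_SUBSTRATE


def cell_table(rows):
    return pd.DataFrame(rows, columns=["cell_id", "condition", "53BP1", "RPA",
                                       "nuclear_area"])


class TestClassifyCells:
    def test_53bp1_boundary_strict(self):
        cells = cell_table([("c1", "x", 6, 0, 1.0), ("c2", "x", 5, 0, 1.0)])
        with pytest.warns(UserWarning):  # < 150 cells
            pos, _ = t.classify_cells(cells, "53BP1")
        assert pos.tolist() == [True, False]

    def test_rpa_boundary_strict(self):
        cells = cell_table([("c1", "x", 0, 7, 1.0), ("c2", "x", 0, 6, 1.0)])
        with pytest.warns(UserWarning):
            pos, _ = t.classify_cells(cells, "RPA")
        assert pos.tolist() == [True, False]

    def test_percentage_with_denominator(self):
        cells = cell_table(
            [("c%d" % i, "x", v, 0, 1.0) for i, v in enumerate([10, 9, 1, 0])]
        )
        with pytest.warns(UserWarning):
            _, summary = t.classify_cells(cells, "53BP1")
        assert summary.loc[0, "n_cells"] == 4
        assert summary.loc[0, "pct_positive"] == pytest.approx(50.0)

    def test_unknown_channel_errors(self):
        with pytest.raises(KeyError, match="EdU"):
            t.classify_cells(cell_table([]), "EdU")

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        counts=st.lists(st.integers(0, 20), min_size=160, max_size=160),
        thr=st.integers(0, 10),
    )
    def test_raising_threshold_never_increases_positives(self, counts, thr):
        cells = cell_table(
            [("c%d" % i, "x", v, 0, 1.0) for i, v in enumerate(counts)]
        )
        _, lo = t.classify_cells(cells, "53BP1", threshold=thr)
        _, hi = t.classify_cells(cells, "53BP1", threshold=thr + 1)
        assert hi.loc[0, "pct_positive"] <= lo.loc[0, "pct_positive"]


class TestReplicationCatastrophe:
    def test_double_positive_requires_both(self):
        cells = cell_table(
            [
                ("c1", "x", 10, 10, 1.0),  # both above
                ("c2", "x", 10, 6, 1.0),   # RPA at boundary -> negative
                ("c3", "x", 5, 10, 1.0),   # 53BP1 at boundary -> negative
            ]
        )
        rc = t.replication_catastrophe_fraction(cells)
        assert rc.loc[0, "n_double_positive"] == 1

    def test_missing_channel_errors(self):
        cells = pd.DataFrame({"condition": ["x"], "53BP1": [1]})
        with pytest.raises(KeyError, match="RPA"):
            t.replication_catastrophe_fraction(cells)

    def test_double_positive_bounded_by_single_channels(self, rng):
        cells, _ = t.simulate_cell_assay(
            {"hu": t.CellConditionSpec(foci_means={"53BP1": 6.0, "RPA": 7.0})},
            seed=3,
        )
        rc = t.replication_catastrophe_fraction(cells)
        _, s1 = t.classify_cells(cells, "53BP1")
        _, s2 = t.classify_cells(cells, "RPA")
        assert rc.loc[0, "pct_double_positive"] <= min(
            s1.loc[0, "pct_positive"], s2.loc[0, "pct_positive"]
        )


class TestCompareNuclearArea:
    def test_identical_groups_no_difference(self):
        cells = cell_table(
            [("a%d" % i, "x", 10, 10, 5.0) for i in range(5)]
            + [("b%d" % i, "x", 0, 0, 5.0) for i in range(5)]
        )
        res = t.compare_nuclear_area(cells)
        means = res.groups.set_index("group")["mean"]
        assert means["double_positive"] == means["negative"]

    def test_large_shift_gives_small_p(self, rng):
        areas_a = rng.normal(100, 5, 50)
        rows = [("a%d" % i, "x", 10, 10, a) for i, a in enumerate(areas_a)]
        rows += [("b%d" % i, "x", 0, 0, a + 50) for i, a in enumerate(areas_a)]
        res = t.compare_nuclear_area(cell_table(rows))
        assert res.p_value < 1e-10
        assert res.test.startswith("Welch")

    def test_small_group_errors(self):
        cells = cell_table([("a", "x", 10, 10, 1.0), ("b", "x", 0, 0, 1.0)])
        with pytest.raises(ValueError, match="fewer than 2"):
            t.compare_nuclear_area(cells)

    def test_three_groups_use_anova(self, rng):
        cells = cell_table(
            [("c%d" % i, "x", 0, 0, v) for i, v in enumerate(rng.normal(size=30))]
        )
        cells["phase"] = ["G1", "S", "G2"] * 10
        res = t.compare_nuclear_area(cells, group_col="phase")
        assert res.test == "one-way ANOVA"

    def test_simulated_multiplier_recovered(self):
        """A 1.5x generator-set area ratio is recovered within 10%."""
        cells, _ = t.simulate_cell_assay(
            {
                "cyclic": t.CellConditionSpec(
                    foci_means={"53BP1": 8.0, "RPA": 9.0},
                    area_multiplier=1.5,
                    n_cells=2000,
                )
            },
            seed=9,
        )
        res = t.compare_nuclear_area(cells)
        means = res.groups.set_index("group")
        assert (means.loc["double_positive", "n"] >= 300
                and means.loc["negative", "n"] >= 300)
        ratio = means.loc["double_positive", "mean"] / means.loc["negative", "mean"]
        assert ratio == pytest.approx(1.5, rel=0.10)


class TestDdct:
    @staticmethod
    def table(rows):
        return pd.DataFrame(rows, columns=["gene", "condition", "replicate", "Ct"])

    def test_reference_fold_is_one(self):
        ct = self.table(
            [
                ("18S", "normoxia", 1, 10.0),
                ("A3B", "normoxia", 1, 20.0),
                ("18S", "hypoxia", 1, 10.0),
                ("A3B", "hypoxia", 1, 20.0),
            ]
        )
        out = t.ddct_fold_change(ct, "A3B").set_index("condition")
        assert out.loc["normoxia", "fold_mean"] == pytest.approx(1.0)
        assert out.loc["hypoxia", "fold_mean"] == pytest.approx(1.0)

    def test_hand_computed_fold(self):
        # treatment dCt = 20-10 = 10; reference dCt = 22-10 = 12;
        # ddCt = -2 -> fold = 4
        ct = self.table(
            [
                ("18S", "normoxia", 1, 10.0),
                ("A3B", "normoxia", 1, 22.0),
                ("18S", "cyclic", 1, 10.0),
                ("A3B", "cyclic", 1, 20.0),
            ]
        )
        out = t.ddct_fold_change(ct, "A3B").set_index("condition")
        assert out.loc["cyclic", "fold_mean"] == pytest.approx(4.0)

    def test_block_shift_invariance(self, rng):
        """Adding a constant to every Ct of a (condition, replicate) block
        cancels in the control subtraction."""
        rows = []
        for rep in (1, 2, 3):
            for cond in ("normoxia", "cyclic"):
                base = float(rng.normal(0, 1))
                rows.append(("18S", cond, rep, 10.0 + base))
                rows.append(("A3B", cond, rep, 20.0 + base - (1.0 if cond == "cyclic" else 0.0)))
        out = t.ddct_fold_change(self.table(rows), "A3B").set_index("condition")
        assert out.loc["cyclic", "fold_mean"] == pytest.approx(2.0)
        assert out.loc["cyclic", "fold_sem"] == pytest.approx(0.0, abs=1e-12)

    def test_missing_control_named(self):
        ct = self.table([("A3B", "normoxia", 1, 20.0)])
        with pytest.raises(ValueError, match="condition='normoxia', replicate=1"):
            t.ddct_fold_change(ct, "A3B")

    def test_simulated_folds_recovered(self):
        ct = t.simulate_ct_table("A3B", {"cyclic": 4.0, "hypoxia": 0.5}, seed=2)
        out = t.ddct_fold_change(ct, "A3B").set_index("condition")
        assert out.loc["cyclic", "fold_mean"] == pytest.approx(4.0, rel=0.2)
        assert out.loc["hypoxia", "fold_mean"] == pytest.approx(0.5, rel=0.2)


class TestDeamination:
    @staticmethod
    def lanes(rows):
        return pd.DataFrame(rows, columns=["condition", "replicate", "S", "P"])

    def test_reference_relative_product_is_one(self):
        lanes = self.lanes(
            [("normoxia", r, 80.0, 20.0) for r in (1, 2, 3)]
            + [("cyclic", r, 40.0, 60.0) for r in (1, 2, 3)]
        )
        out = t.deamination_quant(lanes).set_index("condition")
        assert out.loc["normoxia", "relative_product"] == pytest.approx(1.0)
        assert out.loc["cyclic", "relative_product"] == pytest.approx(3.0)

    def test_mean_ratio_arithmetic(self):
        lanes = self.lanes(
            [("normoxia", 1, 10.0, 3.0)]
            + [("cyclic", r, 10.0, p) for r, p in enumerate((2.0, 3.0, 4.0), 1)]
        )
        out = t.deamination_quant(lanes).set_index("condition")
        assert out.loc["cyclic", "relative_product"] == pytest.approx(1.0)

    def test_complete_conversion_product_fraction(self):
        lanes = self.lanes([("normoxia", 1, 0.0, 5.0)])
        out = t.deamination_quant(lanes).set_index("condition")
        assert out.loc["normoxia", "product_fraction"] == pytest.approx(1.0)

    def test_zero_reference_product_errors(self):
        lanes = self.lanes([("normoxia", 1, 5.0, 0.0)])
        with pytest.raises(ValueError, match="reference product"):
            t.deamination_quant(lanes)


class TestScanTcwSites:
    def test_minimal_motifs(self):
        assert t.scan_tcw_sites("GGGG") == []
        sites = t.scan_tcw_sites("TCA")
        assert len(sites) == 1 and sites[0].pos == 0

    def test_substrate_oligo_single_plus_strand_site(self):
        """The printed deamination substrate carries exactly one plus-strand
        TCW site, the TCA immediately after the internal N."""
        sites = t.scan_tcw_sites(DEAMINATION_SUBSTRATE)
        assert len(sites) == 1
        site = sites[0]
        n_index = DEAMINATION_SUBSTRATE.index("N")
        assert site.pos == n_index + 1
        assert site.context == "TCA"

    def test_mutating_the_c_abolishes_the_site(self):
        n_index = DEAMINATION_SUBSTRATE.index("N")
        c_index = n_index + 2
        assert DEAMINATION_SUBSTRATE[c_index] == "C"
        mutated = (
            DEAMINATION_SUBSTRATE[:c_index] + "T" + DEAMINATION_SUBSTRATE[c_index + 1:]
        )
        assert t.scan_tcw_sites(mutated) == []

    def test_both_strands_mode(self):
        # TGA on the plus strand is TCA on the minus strand
        sites = t.scan_tcw_sites("TGA", both_strands=True)
        assert [(s.strand, s.context) for s in sites] == [("-", "TCA")]
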