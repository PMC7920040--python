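import numpy as np
import pandas as pd
import pytest

import poolscan as ps
from poolscan.phenotype import (
    CELL_TYPES,
    individual_indices,
    pool_replicates,
    read_cell_counts,
    records_from_table,
    thc_table,
)


class TestHemocyteConcentration:
    def test_reference_protocol(self):
        # 700 cells over 10 squares at 1:20 dilution -> 14,000 cells/µl
        c = ps.HemocytometerCount(cells_counted=700, n_squares=10, dilution_fraction=1 / 20)
        assert ps.hemocyte_concentration(c) == pytest.approx(14_000.0)

    def test_zero_cells(self):
        c = ps.HemocytometerCount(0, 10, 1 / 20)
        assert ps.hemocyte_concentration(c) == 0.0

    def test_stronger_dilution_scales_up(self):
        base = ps.hemocyte_concentration(ps.HemocytometerCount(700, 10, 1 / 20))
        doubled = ps.hemocyte_concentration(ps.HemocytometerCount(700, 10, 1 / 40))
        assert doubled == pytest.approx(2 * base)

    def test_linear_in_counts_inverse_in_squares(self):
        a = ps.hemocyte_concentration(ps.HemocytometerCount(350, 10, 1 / 20))
        b = ps.hemocyte_concentration(ps.HemocytometerCount(700, 20, 1 / 20))
        assert a == pytest.approx(b)

    def test_invalid_dilution_rejected(self):
        with pytest.raises(ValueError):
            ps.hemocyte_concentration(ps.HemocytometerCount(1, 1, 0.0))
        with pytest.raises(ValueError):
            ps.hemocyte_concentration(ps.HemocytometerCount(1, 1, 1.5))


def record(totals, phagocytic, **kw):
    return ps.CellCountRecord(
        individual_id=kw.get("individual_id", "L1"),
        population=kw.get("population", "north"),
        sex=kw.get("sex", "F"),
        totals=totals,
        phagocytic=phagocytic,
    )


class TestPhagocyticIndex:
    def test_worked_example(self):
        rec = record({"granulocyte": 8, "plasmatocyte": 2}, {"granulocyte": 6, "plasmatocyte": 2})
        index, comp = ps.phagocytic_index(rec)
        assert index == pytest.approx(0.8)
        assert comp["granulocyte"] == pytest.approx(0.75)
        assert comp["plasmatocyte"] == pytest.approx(0.25)

    def test_all_phagocytic(self):
        rec = record({"granulocyte": 5}, {"granulocyte": 5})
        index, _ = ps.phagocytic_index(rec)
        assert index == 1.0

    def test_no_hemocytes_is_undefined(self):
        index, comp = ps.phagocytic_index(record({}, {}))
        assert np.isnan(index) and comp == {}

    def test_composition_sums_to_one(self):
        rec = record(
            {"granulocyte": 30, "plasmatocyte": 10, "oenocytoid": 5},
            {"granulocyte": 20, "plasmatocyte": 4, "oenocytoid": 1},
        )
        _, comp = ps.phagocytic_index(rec)
        assert sum(comp.values()) == pytest.approx(1.0)

    def test_phagocytic_exceeding_total_rejected(self):
        with pytest.raises(ValueError):
            record({"granulocyte": 3}, {"granulocyte": 4})


class TestSpecificIndex:
    def test_worked_example(self):
        rec = record({"granulocyte": 10}, {"granulocyte": 7})
        assert ps.specific_phagocytic_index(rec, "granulocyte") == pytest.approx(0.7)

    def test_absent_type_is_undefined(self):
        rec = record({"granulocyte": 10}, {"granulocyte": 7})
        assert np.isnan(ps.specific_phagocytic_index(rec, "oenocytoid"))

    def test_specific_indices_weight_average_to_overall(self):
        rec = record(
            {"granulocyte": 40, "plasmatocyte": 12, "oenocytoid": 3, "other": 5},
            {"granulocyte": 31, "plasmatocyte": 8, "oenocytoid": 1, "other": 0},
        )
        overall, _ = ps.phagocytic_index(rec)
        weighted = sum(
            rec.totals[t] * ps.specific_phagocytic_index(rec, t) for t in rec.totals
        ) / sum(rec.totals.values())
        assert weighted == pytest.approx(overall, abs=1e-12)


class TestTables:
    def _long_df(self):
        rows = []
        for rep, (g_tot, g_ph) in zip(("s1", "s2"), ((40, 30), (10, 2))):
            rows.append(dict(individual_id="L1", population="north", sex="F",
                             replicate_id=rep, cell_type="granulocyte",
                             total=g_tot, phagocytic=g_ph))
        return pd.DataFrame(rows)

    def test_pooled_index_differs_from_mean_of_replicates(self):
        # pooled: 32/50 = 0.64; mean of per-slide indices: (0.75+0.2)/2 = 0.475
        df = self._long_df()
        idx = individual_indices(df)
        assert idx.loc[0, "phagocytic_index"] == pytest.approx(32 / 50)
        per_rep = df["phagocytic"] / df["total"]
        assert idx.loc[0, "phagocytic_index"] != pytest.approx(per_rep.mean())

    def test_replicate_pooling_sums_counts(self):
        pooled = pool_replicates(self._long_df())
        assert pooled.loc[0, "total"] == 50 and pooled.loc[0, "phagocytic"] == 32

    def test_wide_and_long_input_agree(self, tmp_path):
        long_df = self._long_df()
        long_path = tmp_path / "long.csv"
        long_df.to_csv(long_path, index=False)
        wide = pd.DataFrame(
            [
                {"individual_id": "L1", "population": "north", "sex": "F",
                 "replicate_id": rep, "total_granulocyte": t, "phagocytic_granulocyte": p}
                for rep, t, p in (("s1", 40, 30), ("s2", 10, 2))
            ]
        )
        wide_path = tmp_path / "wide.csv"
        wide.to_csv(wide_path, index=False)
        a = individual_indices(read_cell_counts(long_path))
        b = individual_indices(read_cell_counts(wide_path))
        assert a.loc[0, "phagocytic_index"] == b.loc[0, "phagocytic_index"]

    def test_single_record_group_mean_is_its_index(self):
        df = self._long_df()
        summary = ps.assay_summary(df)
        row = summary[(summary["index"] == "phagocytic_index")].iloc[0]
        assert row["n"] == 1 and row["mean"] == pytest.approx(32 / 50)

    def test_summary_row_count(self, cohort_tables):
        _, cells, _, _ = cohort_tables
        summary = ps.assay_summary(cells)
        n_groups = cells.groupby(["population", "sex"]).ngroups
        n_indices = 1 + 2 * len(CELL_TYPES)  # overall + composition & specific per type
        assert len(summary) == n_groups * n_indices

    def test_absent_cell_types_excluded_not_erroring(self):
        rows = [
            dict(individual_id="L1", population="north", sex="F", replicate_id="s1",
                 cell_type="granulocyte", total=20, phagocytic=10),
            dict(individual_id="L2", population="north", sex="F", replicate_id="s1",
                 cell_type="granulocyte", total=15, phagocytic=5),
            dict(individual_id="L2", population="north", sex="F", replicate_id="s1",
                 cell_type="oenocytoid", total=4, phagocytic=2),
        ]
        summary = ps.assay_summary(pd.DataFrame(rows))
        oeno = summary[summary["index"] == "specific_index_oenocytoid"].iloc[0]
        assert oeno["n"] == 1  # L1 has no oenocytoids and is excluded

    def test_cohort_group_means_recover_planted_ordering(self, cohort_tables):
        cfg, cells, _, truth = cohort_tables
        summary = ps.assay_summary(cells)
        overall = summary[summary["index"] == "phagocytic_index"]
        north = overall[overall["population"] == "north"]["mean"].mean()
        south = overall[overall["population"] == "south"]["mean"].mean()
        assert north > south  # planted higher propensity in the north

    def test_thc_table_attaches_concentration(self, cohort_tables):
        _, _, thc, _ = cohort_tables
        out = thc_table(thc)
        first = out.iloc[0]
        assert first["cells_per_ul"] == pytest.approx(
            first["cells_counted"] * 10 / (first["n_squares"] * first["dilution_fraction"])
        )

    def test_records_round_trip_through_table(self):
        df = self._long_df()
        (rec,) = records_from_table(df)
        assert rec.totals == {"granulocyte": 50}
        assert rec.phagocytic == {"granulocyte": 32}
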