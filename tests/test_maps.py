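import numpy as np
import pandas as pd
import pytest

from sdscan.maps import (
    LinkageMap,
    clean_map,
    genome_coverage,
    locate_markers,
    merge_sex_maps,
    read_map,
    summarize_map,
    write_map,
)
from sdscan.simulate import SimConfig, simulate_sexed_cohort


def lmap(rows, sex="averaged"):
    return LinkageMap(
        sex_label=sex,
        table=pd.DataFrame(rows, columns=["lg", "marker_id", "radtag_id", "pos_cM"]),
    )


class TestLinkageMap:
    def test_sorted_and_validated(self):
        m = lmap([("LG1", "b", "t2", 5.0), ("LG1", "a", "t1", 1.0)])
        assert m.table.marker_id.tolist() == ["a", "b"]
        with pytest.raises(ValueError):
            lmap([("LG1", "a", "t1", -1.0)])
        with pytest.raises(ValueError):
            lmap([("LG1", "a", "t1", 1.0), ("LG1", "a", "t1", 2.0)])

    def test_round_trip(self, tmp_path):
        m = lmap([("LG1", "a", "t1", 0.0), ("LG2", "b", "t2", 3.5)])
        write_map(m, tmp_path / "m.tsv")
        back = read_map(tmp_path / "m.tsv")
        pd.testing.assert_frame_equal(back.table, m.table)


class TestCleanMap:
    def test_multi_lg_radtag_removed(self):
        m = lmap([
            ("LG1", "a", "tx", 0.0), ("LG1", "b", "t1", 1.0),
            ("LG2", "c", "tx", 0.0), ("LG2", "d", "t2", 1.0),
        ])
        out, removals = clean_map(m)
        assert "tx" not in set(out.table.radtag_id)
        assert {r["reason"] for r in removals} >= {"multi_lg"}

    def test_terminal_gap_removed_and_reanchored(self):
        m = lmap([
            ("LG1", "a", "t1", 0.0), ("LG1", "b", "t2", 5.0),
            ("LG1", "c", "t3", 10.0), ("LG1", "d", "t9", 25.0),
        ])
        out, removals = clean_map(m, gap_threshold_cM=10.0)
        assert "t9" not in set(out.table.radtag_id)
        assert out.table.pos_cM.max() == 10.0
        assert any(r["reason"].startswith("terminal_gap") for r in removals)

    def test_leading_gap_removed(self):
        m = lmap([
            ("LG1", "a", "t9", 0.0), ("LG1", "b", "t1", 20.0),
            ("LG1", "c", "t2", 30.0), ("LG1", "d", "t3", 40.0),
        ])
        out, _ = clean_map(m, gap_threshold_cM=10.0)
        assert "t9" not in set(out.table.radtag_id)
        assert out.table.pos_cM.min() == 0.0  # re-anchored
        assert out.table.pos_cM.max() == 20.0

    def test_gap_at_threshold_kept(self):
        m = lmap([
            ("LG1", "a", "t1", 0.0), ("LG1", "b", "t2", 10.0),
            ("LG1", "c", "t3", 20.0),
        ])
        out, removals = clean_map(m, gap_threshold_cM=10.0)
        assert len(out.table) == 3 and not removals

    def test_idempotent_and_never_longer(self):
        m = lmap([
            ("LG1", "a", "t1", 0.0), ("LG1", "b", "t2", 8.0),
            ("LG1", "c", "t3", 30.0), ("LG2", "d", "t4", 0.0),
            ("LG2", "e", "t4", 2.0),
        ])
        once, _ = clean_map(m)
        twice, removals = clean_map(once)
        pd.testing.assert_frame_equal(once.table, twice.table)
        assert not removals
        for lg in once.table.lg.unique():
            before = m.table[m.table.lg == lg].pos_cM.max()
            after = once.table[once.table.lg == lg].pos_cM.max()
            assert after <= before


class TestMerge:
    def test_shared_marker_mean(self):
        male = lmap([("LG1", "a", "t1", 0.0), ("LG1", "x", "t2", 10.0)], "male")
        female = lmap([("LG1", "a", "t1", 0.0), ("LG1", "x", "t2", 20.0)], "female")
        avg = merge_sex_maps(male, female)
        pos = avg.table.set_index("marker_id").pos_cM
        assert pos["x"] == 15.0

    def test_single_map_marker_interpolated(self):
        male = lmap(
            [("LG1", "a", "t1", 0.0), ("LG1", "m", "t2", 5.0), ("LG1", "b", "t3", 10.0)],
            "male",
        )
        female = lmap([("LG1", "a", "t1", 0.0), ("LG1", "b", "t3", 10.0)], "female")
        avg = merge_sex_maps(male, female)
        pos = avg.table.set_index("marker_id").pos_cM
        assert pos["m"] == 5.0  # anchors unchanged -> position preserved

    def test_double_length_female(self):
        rows_m = [("LG1", f"k{i}", f"t{i}", float(i)) for i in range(10)]
        rows_f = [("LG1", f"k{i}", f"t{i}", 2.0 * i) for i in range(10)]
        avg = merge_sex_maps(lmap(rows_m, "male"), lmap(rows_f, "female"))
        pos = avg.table.set_index("marker_id").pos_cM
        for i in range(10):
            assert pos[f"k{i}"] == pytest.approx(1.5 * i)

    def test_anchor_symmetry(self):
        male = lmap([("LG1", "a", "t1", 0.0), ("LG1", "b", "t2", 12.0)], "male")
        female = lmap([("LG1", "a", "t1", 4.0), ("LG1", "b", "t2", 6.0)], "female")
        avg1 = merge_sex_maps(male, female)
        avg2 = merge_sex_maps(
            LinkageMap("male", female.table), LinkageMap("female", male.table)
        )
        pd.testing.assert_frame_equal(avg1.table, avg2.table)

    def test_degenerate_lg_passes_through_female(self, caplog):
        male = lmap([("LG1", "a", "t1", 0.0)], "male")
        female = lmap([("LG1", "a", "t1", 0.0), ("LG1", "c", "t2", 7.0)], "female")
        avg = merge_sex_maps(male, female)
        pos = avg.table.set_index("marker_id").pos_cM
        assert pos["c"] == 7.0


class TestSummarize:
    def test_simple_lg_metrics(self):
        m = lmap([("LG1", "a", "t1", 0.0), ("LG1", "b", "t2", 5.0),
                  ("LG1", "c", "t3", 10.0)])
        s = summarize_map(averaged=m)
        row = s.loc["LG1"]
        assert row["averaged_length_cM"] == 10.0
        assert row["averaged_n_unique_positions"] == 3
        assert row["averaged_nonzero_interval_cM"] == 5.0

    def test_totals_are_sums(self):
        m = lmap([("LG1", "a", "t1", 0.0), ("LG1", "b", "t2", 4.0),
                  ("LG2", "c", "t3", 0.0), ("LG2", "d", "t4", 6.0)])
        s = summarize_map(averaged=m)
        assert s.loc["Total", "averaged_n_snps"] == 4
        assert s.loc["Total", "averaged_length_cM"] == 10.0

    def test_fm_ratio_variants(self):
        male = lmap([("LG1", "a1", "t", 0.0), ("LG1", "a2", "t", 100.0),
                     ("LG2", "a3", "u", 0.0), ("LG2", "a4", "u", 100.0)], "male")
        female = lmap([("LG1", "b1", "t", 0.0), ("LG1", "b2", "t", 200.0),
                       ("LG2", "b3", "u", 0.0), ("LG2", "b4", "u", 100.0)], "female")
        s = summarize_map(male=male, female=female)
        assert s.loc["LG1", "fm_ratio"] == 2.0
        assert s.loc["LG2", "fm_ratio"] == 1.0
        assert s.attrs["fm_ratio_mean"] == 1.5
        assert s.attrs["fm_ratio_total"] == 1.5

    def test_random_map_brute_force_recount(self, rng):
        rows = []
        for lg in ("LG1", "LG2"):
            pos = np.sort(rng.random(30) * 80)
            pos[0] = 0.0
            for i, p in enumerate(pos):
                rows.append((lg, f"{lg}m{i}", f"{lg}t{i}", float(p)))
        m = lmap(rows)
        s = summarize_map(averaged=m)
        for lg in ("LG1", "LG2"):
            pos = np.array([r[3] for r in rows if r[0] == lg])
            uniq = np.unique(pos)
            assert s.loc[lg, "averaged_n_snps"] == len(pos)
            assert s.loc[lg, "averaged_n_unique_positions"] == len(uniq)
            assert s.loc[lg, "averaged_length_cM"] == pytest.approx(uniq.max() - uniq.min())
            assert s.loc[lg, "averaged_nonzero_interval_cM"] == pytest.approx(
                np.diff(uniq).mean()
            )


class TestCoverage:
    def test_zero_markers(self):
        assert genome_coverage(0.5, 0, 100.0) == 0.0

    def test_closed_form_value(self):
        c = genome_coverage(0.49, 8662, 1796.90)
        assert c == pytest.approx(1 - np.exp(-2 * 0.49 * 8662 / 1796.90))
        assert round(c, 3) == 0.991

    def test_monotone_in_n(self):
        values = [genome_coverage(0.5, n, 500.0) for n in range(0, 3000, 100)]
        assert all(b > a for a, b in zip(values, values[1:]))
        assert all(0 <= v < 1 for v in values)

    def test_dn_equals_L(self):
        assert genome_coverage(2.0, 50, 100.0) == pytest.approx(1 - np.exp(-2))

    def test_bad_length(self):
        with pytest.raises(ValueError):
            genome_coverage(1.0, 10, 0.0)


class TestLocate:
    def test_absent_marker_unplaced(self):
        m = lmap([("LG1", "a", "t1", 0.0)])
        table, _ = locate_markers(m, ["a", "zz"])
        assert table.set_index("marker_id").placed.tolist() == [True, False]

    def test_span_on_one_lg(self):
        m = lmap([("LG1", "a", "t1", 2.0), ("LG1", "b", "t2", 9.0),
                  ("LG1", "c", "t3", 4.0)])
        _, summary = locate_markers(m, ["a", "b", "c"])
        assert summary.loc[0, "span_cM"] == 7.0

    def test_sd_locus_in_hit_span(self):
        cfg = SimConfig(
            n_lgs=3, markers_per_lg=80, sd_lg=2, sd_region_markers=8,
            linkage_decay_per_cM=0.0, sd_position_cM=40.0, seed=33,
        )
        m, t = simulate_sexed_cohort(cfg)
        from sdscan.sexlink import scan_sex_linkage

        calls, _ = scan_sex_linkage(m)
        ids = [c.marker_id for c in calls if c.system == "XY" and c.marker_id]
        fmap = t.linkage_map("female")
        table, summary = locate_markers(fmap, ids)
        lg2 = summary[summary.lg == "LG2"].iloc[0]
        assert lg2.span_min <= 40.0 <= lg2.span_max
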