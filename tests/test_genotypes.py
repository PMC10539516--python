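import numpy as np
import pandas as pd
import pytest

from sdscan.genotypes import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    dedupe_replicates,
    filter_markers,
    filter_samples,
    read_genotypes,
    replicate_mismatch_rate,
    write_genotypes,
    write_sample_metadata,
)
from sdscan.simulate import SimConfig, simulate_f1_family

from conftest import build_matrix


def _write_vcf(tmp_path, body_lines, samples=("s1", "s2")):
    header = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=RT,Number=1,Type=String,Description="x">',
        '##INFO=<ID=SO,Number=1,Type=Integer,Description="x">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="x">',
        "##contig=<ID=LG1>",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    vcf = tmp_path / "in.vcf"
    vcf.write_text("\n".join(header + body_lines) + "\n")
    meta = tmp_path / "meta.tsv"
    rows = [{"sample_id": s, "role": "adult", "sex": "unknown"} for s in samples]
    pd.DataFrame(rows).to_csv(meta, sep="\t", index=False)
    return vcf, meta


class TestReadWrite:
    def test_all_het(self, tmp_path):
        body = [
            f"LG1\t{i}\tmk{i}\tA\tC\t.\t.\tRT=t{i};SO=0\tGT\t0/1\t0/1"
            for i in (1, 2, 3)
        ]
        vcf, meta = _write_vcf(tmp_path, body)
        m = read_genotypes(vcf, meta)
        assert m.n_markers == 3 and m.n_samples == 2
        assert (m.genotypes == HET).all()

    def test_missing_call_and_tag_presence(self, tmp_path):
        body = ["LG1\t1\tmk1\tA\tC\t.\t.\tRT=t1;SO=0\tGT\t./.\t0/0"]
        vcf, meta = _write_vcf(tmp_path, body)
        m = read_genotypes(vcf, meta)
        assert m.genotypes[0, 0] == MISSING
        _, pres = m.tag_presence()
        assert pres[0].tolist() == [False, True]

    def test_unknown_sample_is_fatal(self, tmp_path):
        body = ["LG1\t1\tmk1\tA\tC\t.\t.\tRT=t1;SO=0\tGT\t0/0\t0/0"]
        vcf, meta = _write_vcf(tmp_path, body)
        bad = tmp_path / "bad_meta.tsv"
        pd.DataFrame(
            [{"sample_id": "s1", "role": "adult", "sex": "unknown"}]
        ).to_csv(bad, sep="\t", index=False)
        with pytest.raises(ValueError, match="s2"):
            read_genotypes(vcf, bad)

    def test_multiallelic_modes(self, tmp_path):
        body = ["LG1\t1\tmk1\tA\tC,G\t.\t.\tRT=t1;SO=0\tGT\t0/1\t0/2"]
        vcf, meta = _write_vcf(tmp_path, body)
        with pytest.raises(ValueError, match="multi-allelic"):
            read_genotypes(vcf, meta)
        assert read_genotypes(vcf, meta, on_multiallelic="drop").n_markers == 0
        m = read_genotypes(vcf, meta, on_multiallelic="split")
        assert m.n_markers == 2
        assert m.genotypes[0].tolist() == [HET, MISSING]
        assert m.genotypes[1].tolist() == [MISSING, HET]

    def test_empty_matrix_header_only(self, tmp_path):
        m = build_matrix(np.zeros((0, 2), dtype=np.int8))
        out = tmp_path / "empty.vcf"
        write_genotypes(m, out, tmp_path / "meta.tsv")
        text = out.read_text()
        assert text.startswith("##fileformat=VCFv4.2")
        assert len([x for x in text.splitlines() if not x.startswith("#")]) == 0

    def test_monomorphic_written_with_dot_alt(self, tmp_path):
        m = build_matrix([[0, MISSING]], monomorphic=[True])
        out = tmp_path / "mono.vcf"
        write_genotypes(m, out, tmp_path / "meta.tsv")
        record = [x for x in out.read_text().splitlines() if not x.startswith("#")][0]
        assert record.split("\t")[4] == "."

    def test_round_trip_identity(self, tmp_path):
        cfg = SimConfig(
            n_lgs=2, markers_per_lg=25, n_offspring=8, seed=7, sd_lg=1,
            genotype_error_rate=0.05, missing_rate=0.1, depth_mean=15.0,
        )
        m, _ = simulate_f1_family(cfg)
        vcf, meta = tmp_path / "rt.vcf", tmp_path / "rt_meta.tsv"
        write_genotypes(m, vcf, meta)
        back = read_genotypes(vcf, meta)
        assert back.marker_ids == m.marker_ids
        assert back.sample_ids == m.sample_ids
        np.testing.assert_array_equal(back.genotypes, m.genotypes)
        np.testing.assert_array_equal(back.depth, m.depth)
        assert [mk.radtag_id for mk in back.markers] == [mk.radtag_id for mk in m.markers]
        assert [mk.alt_allele for mk in back.markers] == [mk.alt_allele for mk in m.markers]


class TestFilterMarkers:
    def test_call_rate_removal(self):
        g = [[0] * 5 + [MISSING] * 5, [0, 1] * 5]
        m = build_matrix(g)
        out, report = filter_markers(m, min_call_rate=0.6, min_maf=0.0)
        assert out.marker_ids == ["m0001"]
        assert report["removed_call_rate"] == 1

    def test_maf_threshold_inclusive(self):
        g = [[HET] + [HOM_REF] * 24]  # maf = 1/50 = 0.02
        m = build_matrix(g)
        out, _ = filter_markers(m, min_call_rate=0.0, min_maf=0.02)
        assert out.n_markers == 1
        out, _ = filter_markers(m, min_call_rate=0.0, min_maf=0.021)
        assert out.n_markers == 0

    def test_depth_masking_precedes_call_rate(self):
        g = [[0] * 10]
        depth = [[3] * 5 + [10] * 5]  # 5 calls below depth 5 get masked
        m = build_matrix(g, depth=depth)
        out, report = filter_markers(m, min_call_rate=0.6, min_maf=0.0)
        assert out.n_markers == 0
        assert report["depth_masked_calls"] == 5

    def test_monomorphic_handling(self):
        g = [[0, 0, 0, 0], [0, 1, 1, 0]]
        m = build_matrix(g, monomorphic=[True, False])
        out, rep = filter_markers(m, min_call_rate=0.5, min_maf=0.02, keep_monomorphic=False)
        assert out.marker_ids == ["m0001"]
        assert rep["removed_not_biallelic"] == 1
        out, _ = filter_markers(m, min_call_rate=0.5, min_maf=0.02, keep_monomorphic=True)
        assert out.n_markers == 2

    def test_report_matches_brute_force_recount(self, rng):
        g = rng.integers(-1, 3, size=(100, 30))
        depth = rng.integers(0, 60, size=(100, 30))
        depth[g == MISSING] = 0
        m = build_matrix(g, depth=depth)
        out, report = filter_markers(m, 0.6, 0.05, 5, 50, keep_monomorphic=False)
        # independent sequential recount
        gg = g.copy()
        gg[(gg != MISSING) & ((depth < 5) | (depth > 50))] = MISSING
        removed_cr = removed_maf = kept = 0
        keep_rows = []
        for i in range(gg.shape[0]):
            row = gg[i]
            called = row != MISSING
            if called.mean() < 0.6:
                removed_cr += 1
                continue
            alt = row[called].sum()
            f = alt / (2 * called.sum())
            if min(f, 1 - f) < 0.05:
                removed_maf += 1
                continue
            kept += 1
            keep_rows.append(i)
        assert report["removed_call_rate"] == removed_cr
        assert report["removed_maf"] == removed_maf
        assert report["retained"] == kept == out.n_markers
        np.testing.assert_array_equal(out.genotypes, gg[keep_rows])

    def test_idempotent(self, rng):
        g = rng.integers(-1, 3, size=(60, 20))
        m = build_matrix(g)
        once, _ = filter_markers(m, 0.6, 0.05)
        twice, rep = filter_markers(once, 0.6, 0.05)
        np.testing.assert_array_equal(once.genotypes, twice.genotypes)
        assert rep["retained"] == once.n_markers


class TestFilterSamples:
    def test_boundary_strict(self):
        g = np.zeros((100, 3), dtype=np.int8)
        g[:41, 0] = MISSING  # 41%
        g[:40, 1] = MISSING  # exactly 40%
        m = build_matrix(g)
        out = filter_samples(m, max_missing=0.40)
        assert out.sample_ids == ["s001", "s002"]

    def test_parent_never_dropped(self, caplog):
        g = np.full((10, 2), MISSING, dtype=np.int8)
        g[:, 1] = 0
        m = build_matrix(g, roles=["mother", "offspring"])
        out = filter_samples(m, 0.4)
        assert out.sample_ids == ["s000", "s001"]

    def test_injected_missingness_truth(self, rng):
        g = np.zeros((200, 10), dtype=np.int8)
        injected = {}
        for j in range(10):
            k = rng.integers(0, 150)
            rows = rng.choice(200, size=k, replace=False)
            g[rows, j] = MISSING
            injected[f"s{j:03d}"] = k
        m = build_matrix(g)
        out = filter_samples(m, 0.4)
        expected = [s for s, k in injected.items() if k / 200 <= 0.4]
        assert out.sample_ids == expected


class TestReplicates:
    def test_pair_keeps_least_missing(self):
        g = np.zeros((20, 2), dtype=np.int8)
        g[:2, 0] = MISSING  # 10%
        g[:1, 1] = MISSING  # 5%
        m = build_matrix(g, replicate_groups=["r1", "r1"])
        out = dedupe_replicates(m)
        assert out.sample_ids == ["s001"]

    def test_singleton_and_threeway(self):
        g = np.zeros((20, 4), dtype=np.int8)
        g[:5, 1] = MISSING
        g[:3, 2] = MISSING
        g[:1, 3] = MISSING  # global minimum within r1
        m = build_matrix(g, replicate_groups=[None, "r1", "r1", "r1"])
        out = dedupe_replicates(m)
        assert out.sample_ids == ["s000", "s003"]
        assert len({s.replicate_group for s in out.samples if s.replicate_group}) == 1

    def test_tie_broken_lexicographically(self):
        g = np.zeros((10, 2), dtype=np.int8)
        m = build_matrix(g, replicate_groups=["r1", "r1"])
        assert dedupe_replicates(m).sample_ids == ["s000"]

    def test_identical_replicates_zero_mismatch(self):
        g = np.tile(np.array([[0], [1], [2], [1]], dtype=np.int8), (1, 2))
        m = build_matrix(g, replicate_groups=["r1", "r1"])
        t = replicate_mismatch_rate(m)
        assert (t["mismatch_rate"] == 0).all()

    def test_single_disagreement_rate(self):
        a = np.array([0, 0, 0, 0, 0, 1, 1, 1, 2, 2], dtype=np.int8)
        b = a.copy()
        b[0] = 2
        m = build_matrix(np.column_stack([a, b]), replicate_groups=["r1", "r1"])
        t = replicate_mismatch_rate(m)
        overall = t[t.genotype_class == "all"]
        assert overall.n_mismatch.sum() / overall.n_comparisons.sum() == pytest.approx(0.1)

    def test_no_pairs_empty(self):
        m = build_matrix(np.zeros((5, 2), dtype=np.int8))
        assert replicate_mismatch_rate(m).empty

    def test_injected_error_rates_recovered(self, rng):
        # two replicates of the same genotype vector, 10% disagreement injected
        n = 4000
        a = rng.integers(0, 3, size=n).astype(np.int8)
        b = a.copy()
        flip = rng.random(n) < 0.1
        b[flip] = (b[flip] + rng.integers(1, 3, size=int(flip.sum()))) % 3
        m = build_matrix(np.column_stack([a, b]), replicate_groups=["r1", "r1"])
        t = replicate_mismatch_rate(m)
        rate = t[t.genotype_class == "all"].pipe(
            lambda d: d.n_mismatch.sum() / d.n_comparisons.sum()
        )
        se = np.sqrt(0.1 * 0.9 / n)
        assert abs(rate - 0.1) < 4 * se


@pytest.mark.parametrize("seed", range(8))
def test_write_read_round_trip_property(seed, tmp_path):
    rng = np.random.default_rng(seed)
    g = rng.integers(-1, 3, size=(12, 5))
    m = build_matrix(g)
    write_genotypes(m, tmp_path / "x.vcf", tmp_path / "x.tsv")
    back = read_genotypes(tmp_path / "x.vcf", tmp_path / "x.tsv")
    np.testing.assert_array_equal(back.genotypes, m.genotypes)
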