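"""Projection of bedGraph counts and nanopore calls onto the probe space."""

import numpy as np
import pytest

from methylomap.harmonize import (
    BedGraphRecord,
    SiteCall,
    bedgraph_to_betas,
    nanopore_calls_to_betas,
    read_beta_table,
)
from methylomap.io import write_beta_table
from methylomap.probe_store import FILL_VALUE, build_probeset, load_betas, save_betas
from methylomap.synthetic import gen_bedgraph, synthetic_probeset


@pytest.fixture()
def ps4():
    return build_probeset(
        [("a", "chr1", 100), ("b", "chr1", 200), ("c", "chr2", 50), ("d", "chr2", 60)]
    )


def rec(chrom, pos, m, u):
    """Record covering the 1-based probe position ``pos``."""
    return BedGraphRecord(chrom, pos - 1, pos, round(100 * m / max(m + u, 1)), m, u)


class TestBedgraph:
    def test_fraction_is_recomputed_from_counts(self, ps4):
        vec = bedgraph_to_betas([rec("chr1", 100, 3, 1)], ps4)
        assert vec.values[0] == 0.75
        assert not vec.fill_mask[0]

    def test_uncovered_probes_get_neutral_fill(self, ps4):
        vec = bedgraph_to_betas([rec("chr1", 100, 3, 1)], ps4)
        assert vec.values[1] == FILL_VALUE and vec.fill_mask[1]
        assert vec.values[3] == FILL_VALUE and vec.fill_mask[3]

    def test_zero_total_count_stays_filled(self, ps4):
        vec = bedgraph_to_betas([rec("chr1", 100, 0, 0)], ps4)
        assert vec.values[0] == FILL_VALUE and vec.fill_mask[0]

    def test_covered_plus_filled_equals_probeset_size(self):
        ps = synthetic_probeset(1000, seed=2)
        betas = np.random.default_rng(3).random(1000)
        from methylomap.probe_store import BetaVector

        records = gen_bedgraph(BetaVector("s", betas), ps, coverage_fraction=0.6, seed=4)
        vec, report = bedgraph_to_betas(records, ps, return_report=True)
        assert report.n_covered_probes + report.n_filled_probes == len(ps)
        assert report.n_filled_probes == 400

    def test_output_invariant_under_record_permutation(self, ps4):
        records = [rec("chr1", 100, 3, 1), rec("chr2", 50, 1, 4), rec("chr1", 200, 2, 2)]
        a = bedgraph_to_betas(records, ps4)
        b = bedgraph_to_betas(records[::-1], ps4)
        assert np.array_equal(a.values, b.values)

    def test_strand_split_records_summed_by_default(self, ps4):
        records = [rec("chr1", 100, 3, 1), rec("chr1", 100, 1, 3)]
        vec = bedgraph_to_betas(records, ps4)
        assert vec.values[0] == 0.5  # (3+1)/(4+4)
        first = bedgraph_to_betas(records, ps4, strand_merge="first")
        assert first.values[0] == 0.75

    def test_unmatched_records_counted_not_fatal(self, ps4):
        records = [rec("chr1", 100, 1, 1), rec("chr22", 999, 5, 5)]
        vec, report = bedgraph_to_betas(records, ps4, return_report=True)
        assert report.n_unmatched == 1
        assert vec.values[0] == 0.5

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            BedGraphRecord("chr1", 0, 1, 0.0, -1, 2)

    def test_fractions_match_brute_force_recomputation(self):
        """Synthetic 60%-coverage panel against an independent per-record oracle."""
        ps = synthetic_probeset(1000, seed=5)
        rng = np.random.default_rng(6)
        from methylomap.probe_store import BetaVector

        records = gen_bedgraph(
            BetaVector("s", rng.random(1000)), ps, coverage_fraction=0.6, seed=7
        )
        vec = bedgraph_to_betas(records, ps)
        expected = {}
        for r in records:  # oracle: dict-based recomputation
            idx = ps.index_at(r.chrom, r.start + 1)
            m, u = expected.get(idx, (0, 0))
            expected[idx] = (m + r.m_count, u + r.u_count)
        for idx, (m, u) in expected.items():
            assert vec.values[idx] == m / (m + u)


class TestNanoporeCalls:
    def test_fraction_of_confident_methylated_calls(self, ps4):
        calls = [SiteCall("chr1", 100, llr) for llr in (5, 5, -5, 5)]
        sparse = nanopore_calls_to_betas(calls, ps4, llr_threshold=2.5)
        assert sparse.entries[0] == 0.75

    def test_probe_absent_when_all_calls_weak(self, ps4):
        calls = [SiteCall("chr1", 100, 1.0), SiteCall("chr1", 200, 5.0)]
        sparse = nanopore_calls_to_betas(calls, ps4, llr_threshold=2.5)
        assert 0 not in sparse.entries and 1 in sparse.entries

    def test_no_fill_values_ever_emitted(self, ps4):
        calls = [SiteCall("chr1", 100, 4.0), SiteCall("chr2", 50, -4.0)]
        sparse = nanopore_calls_to_betas(calls, ps4)
        assert set(sparse.entries) == {0, 2}

    def test_zero_matches_signals_coordinate_mismatch(self, ps4):
        with pytest.raises(ValueError, match="build or coordinate|coordinate"):
            nanopore_calls_to_betas([SiteCall("chr9", 1, 5.0)], ps4)

    def test_aggregation_matches_group_by_oracle(self):
        ps = synthetic_probeset(2000, seed=8)
        rng = np.random.default_rng(9)
        idx = rng.integers(0, 2000, size=10_000)
        llr = rng.normal(0, 5, size=10_000)
        calls = [
            SiteCall(ps.chroms[i], ps.positions[i], float(l)) for i, l in zip(idx, llr)
        ]
        sparse = nanopore_calls_to_betas(calls, ps, llr_threshold=2.5)
        groups: dict = {}
        for i, l in zip(idx, llr):  # oracle: plain group-by counting
            if abs(l) >= 2.5:
                m, n = groups.get(int(i), (0, 0))
                groups[int(i)] = (m + (l > 0), n + 1)
        expected = {i: m / n for i, (m, n) in groups.items()}
        assert sparse.entries == expected


class TestBetaTable:
    def test_columns_realigned_to_probeset_order(self, ps4, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("sample\td\ta\n" "s1\t0.9\t0.1\n" "s2\t0.8\t0.2\n")
        mat = read_beta_table(path, ps4)
        assert mat.matrix[0, 0] == 0.1 and mat.matrix[0, 3] == 0.9
        assert mat.matrix[1, 1] == FILL_VALUE  # probe b absent from table

    def test_missing_cell_gets_fill(self, ps4, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("sample\ta\tb\ns1\t0.1\t\n")
        mat = read_beta_table(path, ps4)
        assert mat.matrix[0, 1] == FILL_VALUE and mat.fill_mask[0, 1]

    def test_no_overlap_is_an_error(self, ps4, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("sample\tzz\ns1\t0.1\n")
        with pytest.raises(ValueError, match="overlap"):
            read_beta_table(path, ps4)

    def test_non_numeric_cell_names_row_and_column(self, ps4, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("sample\ta\ns1\toops\n")
        with pytest.raises(ValueError, match="'s1'.*'a'"):
            read_beta_table(path, ps4)

    def test_table_roundtrips_through_binary_storage(self, tmp_path):
        ps = synthetic_probeset(500, seed=10)
        rng = np.random.default_rng(11)
        from methylomap.probe_store import BetaMatrix

        mat = BetaMatrix(
            [f"s{i:02d}" for i in range(50)], rng.random((50, 500)), ps
        )
        write_beta_table(mat, tmp_path / "t.tsv")
        back = read_beta_table(tmp_path / "t.tsv", ps)
        assert np.allclose(back.matrix, mat.matrix, atol=1e-6)
        # and each row survives binary save/load at float32 precision
        vec = back.row("s07")
        save_betas(vec, tmp_path / "s07.bin", ps)
        reloaded = load_betas(tmp_path / "s07.bin", ps)
        assert np.allclose(reloaded.values, vec.values, atol=1e-6)
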