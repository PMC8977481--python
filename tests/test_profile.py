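"""Tests for per-motif abundance aggregation and the 19-statistic table."""

import io
import math

import pytest

from telomotif.profile import (
    STAT_FIELDS,
    merge_profiles,
    motif_statistics,
    profile_reads,
    read_stats_tsv,
    write_stats_tsv,
)

RANDOM_15 = "GATTACAGATCCGTA"  # no qualifying runs


def _stats_by_canonical(stats):
    return {s.canonical: s for s in stats}


class TestProfileReads:
    def test_forced_arithmetic_with_genome_size(self):
        reads = [(f"t{i}", "AACCT" * 3) for i in range(3)] + [("bg", RANDOM_15)]
        prof = profile_reads(reads, genome_size=60)
        assert prof.effective_coverage == 1.0
        row = _stats_by_canonical(motif_statistics(prof))["AACCT"]
        assert row.n_reads_with_repeat == 3
        assert row.total_repeat_length_bp == 45
        assert row.total_repeat_length_per_1x == 45.0
        assert row.pct_repeat_of_read_bases == 75.0
        assert row.n_pure_reads == 3  # each read is 100% covered

    def test_normalization_scales_only_the_per_1x_field(self):
        reads = [(f"t{i}", "AACCT" * 3) for i in range(3)] + [("bg", RANDOM_15)]
        a = _stats_by_canonical(motif_statistics(profile_reads(reads, genome_size=60)))["AACCT"]
        b = _stats_by_canonical(motif_statistics(profile_reads(reads, genome_size=120)))["AACCT"]
        assert b.total_repeat_length_per_1x == 90.0
        for f in STAT_FIELDS:
            if f != "total_repeat_length_per_1x":
                assert getattr(a, f) == getattr(b, f), f

    def test_no_normalization_gives_nan_per_1x(self):
        prof = profile_reads([("t", "AACCT" * 3)])
        (row,) = motif_statistics(prof)
        assert math.isnan(row.total_repeat_length_per_1x)

    def test_empty_per_motif_map_when_no_runs(self):
        prof = profile_reads([("a", RANDOM_15), ("b", "ACGTACG")])
        assert prof.per_motif == {}
        assert motif_statistics(prof) == []

    def test_errors(self):
        with pytest.raises(ValueError):
            profile_reads([("a", ""), ("b", "")])
        with pytest.raises(ValueError):
            profile_reads([("a", "ACGT")], genome_size=-5)
        with pytest.raises(ValueError):
            profile_reads([("a", "ACGT")], genome_size=10, coverage=2.0)


class TestMotifStatistics:
    def test_every_row_has_exactly_19_statistics(self, rng, make_dna):
        reads = [("tel", "TTAGG" * 20), ("tel2", "TTATTGGG" * 12), ("bg", make_dna(100))]
        stats = motif_statistics(profile_reads(reads, genome_size=500))
        assert len(STAT_FIELDS) == 19
        for row in stats:
            assert [getattr(row, f) is not None for f in STAT_FIELDS] == [True] * 19

    def test_single_motif_gets_rank_one_share_one_and_sentinel(self):
        (row,) = motif_statistics(profile_reads([("t", "AACCT" * 3)], coverage=1.0))
        assert row.rank_by_total_repeat_length == 1
        assert row.share_of_total_repeat_bp == 1.0
        assert math.isinf(row.fold_ratio_to_next)

    def test_fold_ratio_between_ranks(self):
        reads = [(f"a{i}", "TTAGG" * 6) for i in range(3)] + [("b", "AT" * 15), ("pad", "A" * 30)]
        stats = motif_statistics(profile_reads(reads, coverage=1.0))
        assert [s.rank_by_total_repeat_length for s in stats] == [1, 2]
        assert stats[0].total_repeat_length_bp == 90
        assert stats[1].total_repeat_length_bp == 30
        assert stats[0].fold_ratio_to_next == 3.0
        assert math.isclose(stats[0].share_of_total_repeat_bp + stats[1].share_of_total_repeat_bp, 1.0)

    def test_normalization_roundtrip(self, make_dna):
        reads = [("tel", "TTAGG" * 20), ("bg", make_dna(150))]
        prof = profile_reads(reads, coverage=2.5)
        for row in motif_statistics(prof):
            back = row.total_repeat_length_per_1x * 2.5
            assert math.isclose(back, row.total_repeat_length_bp, rel_tol=1e-9)

    def test_conservation_of_repeat_bases(self, rng, make_dna):
        """Sum of per-motif repeat bp equals per-read covered bases, counted per motif."""
        from telomotif.repeat_core import canonical_key, find_tandem_runs

        reads = [(f"r{i}", make_dna(int(rng.integers(30, 150)))) for i in range(150)]
        reads += [("tel", "TTAGG" * 25), ("mix", "AT" * 10 + "TTAGG" * 10)]
        prof = profile_reads(reads)
        expected: dict[str, int] = {}
        for _, seq in reads:
            per_motif: dict[str, set] = {}
            for r in find_tandem_runs(seq):
                canon = canonical_key(r.unit).canonical
                per_motif.setdefault(canon, set()).update(range(r.start, r.end))
            for canon, pos in per_motif.items():
                expected[canon] = expected.get(canon, 0) + len(pos)
        got = {s.canonical: s.total_repeat_length_bp for s in motif_statistics(prof)}
        assert got == expected
        assert sum(got.values()) <= prof.total_read_bases

    def test_appending_a_read_never_decreases_count_statistics(self, make_dna):
        base = [("tel", "TTAGG" * 20), ("bg", make_dna(120))]
        before = _stats_by_canonical(motif_statistics(profile_reads(base)))["AACCT"]
        after = _stats_by_canonical(
            motif_statistics(profile_reads(base + [("extra", "TTAGG" * 8)]))
        )["AACCT"]
        for f in ("n_reads_with_repeat", "n_runs", "total_copies",
                  "total_repeat_length_bp", "n_pure_reads", "max_copies_per_run",
                  "max_run_length_bp"):
            assert getattr(after, f) >= getattr(before, f), f


class TestMergeProfiles:
    def _reads(self, rng, make_dna, n=200):
        reads = []
        for i in range(n):
            if i % 5 == 0:
                reads.append((f"t{i}", "TTATTGGG" * 12 + make_dna(4)))
            else:
                reads.append((f"r{i}", make_dna(100)))
        return reads

    def test_identity_and_commutativity(self, rng, make_dna):
        reads = self._reads(rng, make_dna, 40)
        from telomotif.profile import DatasetProfile

        p = profile_reads(reads, coverage=1.0)
        empty = DatasetProfile(params=p.params, coverage=1.0)
        assert motif_statistics(merge_profiles(p, empty)) == motif_statistics(p)
        a = profile_reads(reads[:20], coverage=1.0)
        b = profile_reads(reads[20:], coverage=1.0)
        assert motif_statistics(merge_profiles(a, b)) == motif_statistics(merge_profiles(b, a))

    def test_chunked_merge_equals_single_pass(self, rng, make_dna):
        reads = self._reads(rng, make_dna, 200)
        whole = profile_reads(reads, coverage=1.0)
        chunks = [profile_reads(reads[i::4], coverage=1.0) for i in range(4)]
        merged = chunks[0]
        for c in chunks[1:]:
            merged = merge_profiles(merged, c)
        assert merged.total_reads == whole.total_reads
        assert merged.total_read_bases == whole.total_read_bases
        assert motif_statistics(merged) == motif_statistics(whole)

    def test_chunk_boundary_independence_within_one_pass(self, rng, make_dna):
        reads = self._reads(rng, make_dna, 120)
        a = profile_reads(reads, coverage=1.0, chunk_bases=1_000)
        b = profile_reads(reads, coverage=1.0, chunk_bases=10_000_000)
        assert motif_statistics(a) == motif_statistics(b)

    def test_parameter_mismatch_rejected(self, make_dna):
        a = profile_reads([("r", "TTAGG" * 5)], min_copies=3)
        b = profile_reads([("r", "TTAGG" * 5)], min_copies=4)
        with pytest.raises(ValueError):
            merge_profiles(a, b)


class TestStatsTsv:
    def test_roundtrip(self, make_dna):
        reads = [("tel", "TTAGG" * 20), ("tel2", "TTATTGGG" * 12), ("bg", make_dna(100))]
        stats = motif_statistics(profile_reads(reads, genome_size=500))
        buf = io.StringIO()
        write_stats_tsv(stats, buf)
        buf.seek(0)
        again = read_stats_tsv(buf)
        assert [s.canonical for s in again] == [s.canonical for s in stats]
        for s1, s2 in zip(stats, again):
            for f in STAT_FIELDS:
                v1, v2 = getattr(s1, f), getattr(s2, f)
                assert v1 == pytest.approx(v2, rel=1e-5), f

    def test_header_is_fixed(self):
        buf = io.StringIO()
        write_stats_tsv([], buf)
        header = buf.getvalue().strip().split("\t")
        assert header[:2] == ["canonical", "display"]
        assert len(header) == 21
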