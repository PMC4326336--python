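"""Index construction: scanning, bit packing, Table A/B layout, serialization."""

from collections import Counter

import numpy as np
import pytest

import offtarget as ot
from offtarget.encoding import Genome, KmerCode, reverse_complement
from offtarget.index import (
    MAGIC,
    CapacityError,
    IndexFormatError,
    PackingError,
    SiteRecord,
    build_index,
    load_index,
    pack_record,
    save_index,
    scan_pam_sites,
    sites_per_chromosome,
    unpack_record,
)
from offtarget.pam import builtin_pams, pam_match, parse_pam


def naive_prefix_counts(genome, pams):
    """Independent per-prefix site counter: plain string scan, no index code."""
    counts = Counter()
    for _, seq in genome.chromosomes:
        for strand_seq in (seq, reverse_complement(seq)):
            for pam in pams:
                w = 20 + pam.length
                for i in range(len(strand_seq) - w + 1):
                    window = strand_seq[i : i + w]
                    if "N" in window:
                        continue
                    if pam_match(window[20:], pam) is not None:
                        counts[window[:16]] += 1
    return counts


class TestPackRecord:
    def test_all_zero_fields_give_word_zero(self):
        r = SiteRecord(KmerCode(0, 4), 0, "A", 0, 0, 0)
        assert pack_record(r) == 0  # base A encodes as 0 bits

    def test_stated_bit_layout(self):
        """Independently evaluate the documented field layout."""
        r = SiteRecord(
            tail_code=KmerCode(255, 4), pam_id=0, pam_bases="T",
            chrom=1, strand=1, position=100,
        )
        assert pack_record(r) == 100 + (1 << 28) + (1 << 29) + (3 << 37) + (255 << 45)

    def test_roundtrip_random_records(self):
        rng = np.random.default_rng(99)
        pams = builtin_pams()
        for _ in range(10_000):
            pattern = pams[rng.integers(4)]
            bases = "".join(
                "AG"[rng.integers(2)] if pattern.text[p] == "R"
                else "ACGT"[rng.integers(4)]
                for p in pattern.unspecified_positions
            )
            r = SiteRecord(
                tail_code=KmerCode(int(rng.integers(256)), 4),
                pam_id=pattern.pam_id,
                pam_bases=bases,
                chrom=int(rng.integers(32)),
                strand=int(rng.integers(2)),
                position=int(rng.integers(1 << 28)),
            )
            assert unpack_record(pack_record(r), pams) == r

    @pytest.mark.parametrize(
        "kwargs,field",
        [
            (dict(position=1 << 28), "position"),
            (dict(chrom=32), "chrom"),
            (dict(strand=2), "strand"),
            (dict(pam_id=8), "pam_id"),
            (dict(pam_bases="ACGTA"), "pam_bases"),
        ],
    )
    def test_overflow_names_the_field(self, kwargs, field):
        base = dict(
            tail_code=KmerCode(0, 4), pam_id=0, pam_bases="A",
            chrom=0, strand=0, position=0,
        )
        base.update(kwargs)
        with pytest.raises(PackingError, match=field):
            pack_record(SiteRecord(**base))


class TestScan:
    def test_minimal_forward_site(self, ngg):
        g = Genome(chromosomes=[("c1", "A" * 21 + "GG")])
        sites = list(scan_pam_sites(g, [ngg]))
        assert len(sites) == 1
        s = sites[0]
        assert (s.prefix_code, s.tail_code, s.chrom, s.strand, s.position) == (
            0, 0, 0, 0, 0,
        )
        assert s.capture.bases == "A"

    def test_minimal_reverse_site_agrees_with_oracle(self, ngg):
        # "CC" + 21 T: the reverse complement of the forward example genome.
        g = Genome(chromosomes=[("c1", "CC" + "T" * 21)])
        sites = list(scan_pam_sites(g, [ngg]))
        assert len(sites) == 1
        s = sites[0]
        assert (s.strand, s.position) == (1, 3)
        # the oracle fixes the full reconstruction
        oracle_hits = ot.brute_force_offtargets(g, "A" * 20, ngg, 0)
        assert len(oracle_hits) == 1
        assert oracle_hits[0].position == s.position
        assert oracle_hits[0].strand == "-"
        assert oracle_hits[0].pam_instance == "AGG"

    def test_n_inside_window_skipped(self, ngg):
        g = Genome(chromosomes=[("c1", "AAAAANAAAAAAAAAAAAAAAGG")])
        assert list(scan_pam_sites(g, [ngg])) == []

    def test_site_matching_two_patterns_emits_two_tuples(self):
        ngg, nag = parse_pam("NGG", 0), parse_pam("NAG", 1)
        # NAG site only
        g = Genome(chromosomes=[("c1", "A" * 20 + "TAG")])
        sites = list(scan_pam_sites(g, [ngg, nag]))
        assert [s.capture.pam_id for s in sites] == [1]
        # NRG-ambiguous site is impossible, but a window can match NGG and a
        # custom NNG at once:
        nng = parse_pam("NNG", 4)
        g2 = Genome(chromosomes=[("c1", "A" * 20 + "TGG")])
        sites2 = list(scan_pam_sites(g2, [ngg, nng]))
        assert sorted(s.capture.pam_id for s in sites2) == [0, 4]

    def test_capacity_errors(self, ngg):
        many = Genome(chromosomes=[(f"c{i}", "A" * 40) for i in range(33)])
        with pytest.raises(CapacityError, match="32"):
            list(scan_pam_sites(many, [ngg]))


class TestBuild:
    def test_empty_genome_gives_empty_tables(self, ngg):
        g = Genome(chromosomes=[("c1", "ACGTACGTACGTACGT")])
        idx = build_index(g, [ngg])
        assert idx.table_b.size == 0 and len(idx.table_a) == 0

    def test_single_site_group(self, ngg):
        g = Genome(chromosomes=[("c1", "A" * 21 + "GG")])
        idx = build_index(g, [ngg])
        assert idx.group_range(0) == (0, 1)
        assert idx.table_b.size == 1

    def test_total_count_matches_independent_scan(self, small_genome, small_index):
        naive = naive_prefix_counts(small_genome, small_index.pam_table)
        assert small_index.table_b.size == sum(naive.values())

    def test_group_sizes_match_independent_counts(self, small_genome, small_index):
        """Table A offset differences equal per-prefix counts (the pointer-
        difference identity of the two-table layout)."""
        naive = naive_prefix_counts(small_genome, small_index.pam_table)
        assert len(small_index.table_a) == len(naive)
        for prefix, count in naive.items():
            s, e = small_index.group_range(ot.kmer_to_code(prefix).value)
            assert e - s == count

    def test_every_record_reconstructs_its_genomic_site(self, small_genome, small_index):
        """Prefix + decoded tail must equal the genome at (chrom, strand, pos),
        followed there by the dereferenced PAM."""
        from offtarget.index import reconstruct_sequence, unpack_record
        from offtarget.pam import PamCapture, dereference_pam

        by_id = {p.pam_id: p for p in small_index.pam_table}
        for prefix_code in small_index.occupied_prefixes:
            s, e = small_index.group_range(int(prefix_code))
            for word in small_index.table_b[s:e]:
                word = int(word)
                rec = unpack_record(word, small_index.pam_table)
                seq20 = reconstruct_sequence(int(prefix_code), word)
                name, chrom_seq = small_genome.chromosomes[rec.chrom]
                pattern = by_id[rec.pam_id]
                window = chrom_seq[rec.position : rec.position + 20]
                if rec.strand == 0:
                    pam_window = chrom_seq[rec.position + 20 : rec.position + 20 + pattern.length]
                else:
                    window = reverse_complement(window)
                    pam_window = reverse_complement(
                        chrom_seq[rec.position - pattern.length : rec.position]
                    )
                assert window == seq20
                assert pam_window == dereference_pam(
                    PamCapture(rec.pam_id, rec.pam_bases), pattern
                )

    def test_determinism(self, small_genome, builtin_pams):
        a = build_index(small_genome, builtin_pams)
        b = build_index(small_genome, builtin_pams)
        assert np.array_equal(a.table_b, b.table_b)
        assert a == b

    def test_per_chromosome_counts_sum_to_total(self, small_index):
        counts = sites_per_chromosome(small_index)
        assert sum(counts.values()) == small_index.table_b.size


class TestSerialization:
    def test_roundtrip_single_site(self, tmp_path, ngg):
        g = Genome(chromosomes=[("c1", "A" * 21 + "GG")])
        idx = build_index(g, [ngg])
        path = tmp_path / "one.idx"
        save_index(idx, path)
        assert load_index(path) == idx

    def test_roundtrip_random_genome(self, tmp_path, small_index):
        path = tmp_path / "small.idx"
        save_index(small_index, path)
        loaded = load_index(path)
        assert loaded == small_index
        assert loaded.genome_meta == small_index.genome_meta
        assert loaded.pam_table == small_index.pam_table

    def test_truncated_file_rejected(self, tmp_path, small_index):
        path = tmp_path / "trunc.idx"
        save_index(small_index, path)
        data = path.read_bytes()
        path.write_bytes(data[: len(data) // 2])
        with pytest.raises(IndexFormatError, match="truncated"):
            load_index(path)

    def test_bad_magic_rejected(self, tmp_path):
        path = tmp_path / "bad.idx"
        path.write_bytes(b"NOTANIDX" + b"\0" * 64)
        with pytest.raises(IndexFormatError, match="magic"):
            load_index(path)

    def test_version_mismatch_rejected(self, tmp_path):
        path = tmp_path / "vers.idx"
        path.write_bytes(MAGIC + (99).to_bytes(4, "little") + b"\0" * 64)
        with pytest.raises(IndexFormatError, match="version"):
            load_index(path)
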