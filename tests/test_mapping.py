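"""Circular k-mer mapping, pair reconstruction, dedup, SAM interop."""

import shutil
import subprocess

import numpy as np
import pytest

from domyseq.library_sim import Fragment, ShearModel, shear_plasmid
from domyseq.mapping import (
    AlignmentParams,
    KmerIndex,
    MappedFragment,
    ReadAlignment,
    dedup,
    export_sam,
    import_sam,
    map_pairs,
    map_read,
    pair_to_fragment,
)
from domyseq.reads import ErrorModel, simulate_reads, write_fastq
from domyseq.reference import PlasmidMap, revcomp
from conftest import build_toy_plasmid


@pytest.fixture(scope="module")
def plasmid():
    return build_toy_plasmid(orf_aa=200, length=2100, cds_start=300, seed=6)


@pytest.fixture(scope="module")
def index(plasmid):
    return KmerIndex(plasmid, k=21)


PARAMS = AlignmentParams(k=21, max_mismatches=3, min_insert=20, max_insert=900)


class TestIndex:
    def test_every_reference_kmer_self_lookup(self, plasmid, index):
        doubled = plasmid.sequence * 2
        for pos in range(0, plasmid.length, 97):
            assert pos in index.lookup(doubled[pos : pos + 21])

    def test_origin_spanning_kmer_found(self):
        # brute-force oracle: every rotation of a toy circle must expose the
        # origin-crossing k-mers at their modular positions
        toy = build_toy_plasmid(orf_aa=12, length=60, cds_start=9, seed=1)
        idx = KmerIndex(toy, k=11)
        doubled = toy.sequence * 2
        for pos in range(toy.length - 10, toy.length):
            kmer = doubled[pos : pos + 11]
            brute = [
                p for p in range(toy.length) if doubled[p : p + 11] == kmer
            ]
            assert sorted(idx.lookup(kmer)) == sorted(brute)

    def test_absent_kmer_empty(self, index):
        assert index.lookup("X" * 21) == []

    def test_k_larger_than_plasmid_rejected(self):
        toy = build_toy_plasmid(orf_aa=12, length=60, cds_start=9, seed=1)
        with pytest.raises(ValueError):
            KmerIndex(toy, k=61)


class TestMapRead:
    def test_error_free_read_maps_exactly(self, plasmid, index):
        for pos in (0, 777, plasmid.length - 80):  # includes origin-wrapping
            seq = plasmid.fetch(pos, 150)
            aln = map_read(seq, index, PARAMS)
            assert (aln.pos, aln.strand, aln.mismatches) == (pos, "+", 0)

    def test_reverse_strand_read(self, plasmid, index):
        seq = revcomp(plasmid.fetch(500, 150))
        aln = map_read(seq, index, PARAMS)
        assert (aln.pos, aln.strand) == (500, "-")

    def test_mismatch_threshold(self, plasmid, index):
        seq = list(plasmid.fetch(700, 150))
        for i in (40, 60, 80, 100):  # 4 > max_mismatches, away from seeds
            seq[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[seq[i]]
        assert map_read("".join(seq), index, PARAMS) is None
        seq2 = list(plasmid.fetch(700, 150))
        for i in (40, 60, 80):
            seq2[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[seq2[i]]
        aln = map_read("".join(seq2), index, PARAMS)
        assert aln is not None and aln.mismatches == 3

    def test_ambiguous_repeat_unmapped(self):
        # two exact copies of the same 80-mer: reads from it are dropped
        core = build_toy_plasmid(orf_aa=30, length=400, cds_start=30, seed=8)
        unit = core.sequence[200:280]
        seq = core.sequence[:120] + unit + core.sequence[120:200] + unit + core.sequence[280:]
        dup = PlasmidMap("pDUP", seq, cds_start=30, cds_aa_length=30)
        idx = KmerIndex(dup, k=21)
        assert map_read(unit, idx, PARAMS) is None


class TestPairToFragment:
    def test_round_trip_interval(self, plasmid, index):
        frag = Fragment("f", 1000, 350, "+")
        pairs = simulate_reads([frag], plasmid, 150, ErrorModel(0.0), seed=0)
        [pa] = map_pairs(pairs, plasmid, PARAMS, index)
        assert pa.fragment.status == "proper_pair"
        assert (pa.fragment.start, pa.fragment.end, pa.fragment.strand) == (1000, 1350, "+")

    def test_same_strand_pair_is_singleton(self):
        a1 = ReadAlignment(100, "+", 0, 150)
        a2 = ReadAlignment(400, "+", 0, 150)
        frag = pair_to_fragment("r", a1, a2, PARAMS, 2100)
        assert frag.status == "singleton"

    def test_one_mate_unmapped_is_singleton(self):
        frag = pair_to_fragment("r", ReadAlignment(100, "+", 0, 150), None, PARAMS, 2100)
        assert frag.status == "singleton"

    def test_both_unmapped(self):
        assert pair_to_fragment("r", None, None, PARAMS, 2100).status == "unmapped"

    def test_origin_wrapping_pair_uses_modular_distance(self, plasmid, index):
        L = plasmid.length
        frag = Fragment("f", L - 100, 300, "+")  # wraps the origin
        pairs = simulate_reads([frag], plasmid, 150, ErrorModel(0.0), seed=0)
        [pa] = map_pairs(pairs, plasmid, PARAMS, index)
        assert pa.fragment.status == "proper_pair"
        assert (pa.fragment.start % L, pa.fragment.length) == (L - 100, 300)

    def test_excessive_insert_is_singleton(self):
        a1 = ReadAlignment(0, "+", 0, 150)
        a2 = ReadAlignment(1800, "-", 0, 150)  # insert 1950 > max 900
        assert pair_to_fragment("r", a1, a2, PARAMS, 2100).status == "singleton"


class TestDedup:
    def _frag(self, start, end, strand="+", status="proper_pair", rid="r"):
        return MappedFragment(read_id=rid, start=start, end=end, strand=strand, status=status)

    def test_identical_coordinates_collapse(self):
        frags = [self._frag(10, 60, rid=f"r{i}") for i in range(3)]
        unique = dedup(frags, 2100)
        assert len(unique) == 1 and unique[0].read_id == "r0"
        assert [f.duplicate for f in frags] == [False, True, True]

    def test_one_nt_difference_kept(self):
        frags = [self._frag(10, 60), self._frag(10, 61)]
        assert len(dedup(frags, 2100)) == 2

    def test_singletons_excluded(self):
        frags = [self._frag(10, 60), self._frag(5, 0, status="singleton")]
        assert len(dedup(frags, 2100)) == 1

    def test_idempotent_and_counts_distinct_keys(self):
        rng = np.random.default_rng(3)
        frags = [
            self._frag(int(s), int(s) + int(l), "+" if b else "-", rid=f"r{i}")
            for i, (s, l, b) in enumerate(
                zip(rng.integers(0, 50, 300), rng.integers(20, 40, 300), rng.integers(0, 2, 300))
            )
        ]
        unique = dedup(frags, 2100)
        keys = {(f.start % 2100, (f.start % 2100) + f.length, f.strand) for f in frags}
        assert len(unique) == len(keys)
        assert dedup(list(unique), 2100) == unique
        assert len(unique) <= len(frags)


@pytest.fixture(scope="module")
def mapped_run(plasmid, index):
    frags = shear_plasmid(
        plasmid, ShearModel(mean_len=350, sd_len=60, min_len=120, n_fragments=120, seed=9)
    )
    pairs = simulate_reads(frags, plasmid, 150, ErrorModel(0.0), seed=1)
    return frags, pairs, map_pairs(pairs, plasmid, PARAMS, index)


class TestSamInterop:

    def test_export_import_round_trip(self, mapped_run, plasmid, tmp_path):
        _, _, alignments = mapped_run
        path = tmp_path / "aln.sam"
        export_sam(alignments, plasmid, path)
        back = import_sam(path, plasmid, PARAMS)
        ours = [
            (pa.fragment.start % plasmid.length, pa.fragment.length, pa.fragment.strand,
             pa.fragment.status)
            for pa in alignments
        ]
        theirs = [
            (f.start % plasmid.length, f.length, f.strand, f.status) for f in back
        ]
        assert ours == theirs

    def test_unknown_reference_rejected(self, mapped_run, plasmid, tmp_path):
        _, _, alignments = mapped_run
        path = tmp_path / "aln.sam"
        export_sam(alignments, plasmid, path)
        other = build_toy_plasmid(orf_aa=30, length=400, cds_start=30, name="pOTHER", seed=2)
        with pytest.raises(ValueError, match="reference"):
            import_sam(path, other)

    def test_bwa_concordance_on_error_free_reads(self, plasmid, index, tmp_path):
        # independent cross-tool oracle: bwa mem must reconstruct the same
        # proper-pair intervals as the internal mapper (error-free,
        # non-origin-crossing fragments)
        if shutil.which("bwa") is None or shutil.which("samtools") is None:
            pytest.fail("bwa/samtools expected on PATH for the concordance check")
        rng = np.random.default_rng(12)
        frags = [
            Fragment(f"f{i}", int(s), int(l), "+" if i % 2 else "-")
            for i, (s, l) in enumerate(
                zip(rng.integers(0, plasmid.length - 500, 60), rng.integers(250, 450, 60))
            )
        ]
        pairs = simulate_reads(frags, plasmid, 150, ErrorModel(0.0), seed=2)
        fasta = tmp_path / "ref.fasta"
        from domyseq.reference import write_fasta

        write_fasta(plasmid, fasta)
        r1, r2 = tmp_path / "R1.fastq", tmp_path / "R2.fastq"
        write_fastq(pairs, r1, r2)
        subprocess.run(["bwa", "index", str(fasta)], check=True, capture_output=True)
        sam = tmp_path / "bwa.sam"
        with open(sam, "w") as fh:
            subprocess.run(
                ["bwa", "mem", str(fasta), str(r1), str(r2)],
                check=True, stdout=fh, stderr=subprocess.DEVNULL,
            )
        external = {
            f.read_id: (f.start, f.end, f.strand)
            for f in import_sam(sam, plasmid, PARAMS)
            if f.status == "proper_pair"
        }
        internal = {
            pa.fragment.read_id: (pa.fragment.start, pa.fragment.end, pa.fragment.strand)
            for pa in map_pairs(pairs, plasmid, PARAMS, index)
            if pa.fragment.status == "proper_pair"
        }
        assert len(internal) == len(frags)
        shared = set(external) & set(internal)
        assert len(shared) >= 0.95 * len(frags)
        for rid in shared:
            assert external[rid] == internal[rid]


class TestRecoveryInvariants:
    def test_error_free_recovery_is_exact(self, plasmid, index):
        frags = shear_plasmid(
            plasmid, ShearModel(mean_len=300, sd_len=50, min_len=120, n_fragments=300, seed=5)
        )
        pairs = simulate_reads(frags, plasmid, 150, ErrorModel(0.0), seed=3)
        alignments = map_pairs(pairs, plasmid, PARAMS, index)
        L = plasmid.length
        ok = sum(
            pa.fragment.status == "proper_pair"
            and (pa.fragment.start % L, pa.fragment.length) == (f.start % L, f.length)
            for f, pa in zip(frags, alignments)
        )
        assert ok == len(frags)

    def test_rotation_invariance(self):
        base = build_toy_plasmid(orf_aa=60, length=900, cds_start=90, seed=13)
        rot = 250
        rotated = PlasmidMap(
            "pROT", base.sequence[rot:] + base.sequence[:rot],
            cds_start=(base.cds_start - rot) % base.length, cds_aa_length=60,
        )
        params = AlignmentParams(k=21, max_mismatches=1, min_insert=20, max_insert=600)
        idx_a, idx_b = KmerIndex(base, 21), KmerIndex(rotated, 21)
        for pos in (0, 100, 870):
            seq = base.fetch(pos, 80)
            a = map_read(seq, idx_a, params)
            b = map_read(seq, idx_b, params)
            assert a is not None and b is not None
            assert b.pos == (a.pos - rot) % base.length
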