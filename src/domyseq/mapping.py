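"""Circular-plasmid read mapping and paired-end fragment reconstruction.

The internal mapper is deliberately simple: exact k-mer seeding on the
doubled reference (so alignments crossing the origin need no special
handling) followed by full-length mismatch verification on both strands.
Plasmid references are a few kb, so gapped alignment buys nothing here;
reads produced by an external aligner can be imported from SAM instead.

From each properly oriented pair the originating fragment interval — the
"PE fragment" — is reconstructed as the span from the leftmost read start
to the rightmost read end, circular-aware.  Duplicate fragments (identical
start, end and strand) are flagged so that downstream coverage can be
restricted to the unique-pair (UniquePE) set; singletons never enter it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam

from .reads import ReadPair
from .reference import PlasmidMap, revcomp


@dataclass(frozen=True)
class AlignmentParams:
    k: int = 21
    max_mismatches: int = 3
    min_insert: int = 20
    max_insert: int = 2000

    def __post_init__(self) -> None:
        if self.k < 11:
            raise ValueError("seed k-mer length must be >= 11")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")
        if self.min_insert > self.max_insert:
            raise ValueError("min_insert must be <= max_insert")


@dataclass
class ReadAlignment:
    """A single-end alignment: 0-based ``pos`` of the read's leftmost base
    on the forward reference strand, mapped ``strand``, and mismatch count."""

    pos: int
    strand: str
    mismatches: int
    length: int

    @property
    def end(self) -> int:
        return self.pos + self.length


@dataclass
class MappedFragment:
    """Reconstructed fragment interval from one read pair.

    ``start``/``end`` are 0-based half-open on the plasmid; ``end`` may
    exceed the plasmid length for origin-wrapping fragments (normalize with
    ``start % L``/``end - start``).  ``strand`` is the cloned orientation
    (the strand R1 mapped to).
    """

    read_id: str
    start: int = 0
    end: int = 0
    strand: str = "+"
    status: str = "unmapped"  # proper_pair | singleton | unmapped
    n_mismatches_r1: int = -1
    n_mismatches_r2: int = -1
    duplicate: bool = False
    frame_label: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start

    def key(self, L: int) -> tuple[int, int, str]:
        return (self.start % L, (self.start % L) + self.length, self.strand)


class KmerIndex:
    """Exact k-mer positions over the doubled circular reference, mod length."""

    def __init__(self, plasmid: PlasmidMap, k: int = 21):
        if k >= plasmid.length:
            raise ValueError(f"k={k} not smaller than plasmid length {plasmid.length}")
        self.plasmid = plasmid
        self.k = k
        self.L = plasmid.length
        doubled = plasmid.sequence + plasmid.sequence
        self._fwd = np.frombuffer(doubled.encode(), dtype="S1")
        index: dict[str, list[int]] = {}
        for i in range(self.L):
            index.setdefault(doubled[i : i + k], []).append(i)
        self.index = index

    def lookup(self, kmer: str) -> list[int]:
        return self.index.get(kmer, [])

    def count_mismatches(self, seq: str, pos: int) -> int:
        """Mismatches of ``seq`` aligned at circular position ``pos`` (forward strand)."""
        pos %= self.L
        arr = np.frombuffer(seq.encode(), dtype="S1")
        return int(np.count_nonzero(self._fwd[pos : pos + len(arr)] != arr))


def map_read(seq: str, index: KmerIndex, params: AlignmentParams) -> ReadAlignment | None:
    """Seed-and-verify mapping of one read; ambiguous best hits are dropped."""
    if len(seq) < params.k:
        return None
    k = params.k
    candidates: dict[tuple[int, str], int] = {}
    for strand in ("+", "-"):
        oriented = seq if strand == "+" else revcomp(seq)
        offsets = list(range(0, len(oriented) - k + 1, k))[:4]
        seen: set[int] = set()
        for off in offsets:
            for hit in index.lookup(oriented[off : off + k]):
                pos = (hit - off) % index.L
                if pos in seen:
                    continue
                seen.add(pos)
                mm = index.count_mismatches(oriented, pos)
                if mm <= params.max_mismatches:
                    candidates[(pos, strand)] = mm
    if not candidates:
        return None
    best = min(candidates.values())
    winners = [loc for loc, mm in candidates.items() if mm == best]
    if len(winners) > 1:
        return None  # ambiguous: deterministic outputs beat random placement
    pos, strand = winners[0]
    return ReadAlignment(pos=pos, strand=strand, mismatches=best, length=len(seq))


def pair_to_fragment(
    read_id: str,
    a1: ReadAlignment | None,
    a2: ReadAlignment | None,
    params: AlignmentParams,
    L: int,
) -> MappedFragment:
    """Reconstruct the fragment interval from the two mate alignments.

    R1 carries the cloned 5' end, so the fragment strand is R1's strand.
    The insert is measured on the shorter arc via modular distance; pairs
    on the same strand or outside the insert bounds become singletons.
    """
    frag = MappedFragment(read_id=read_id)
    if a1 is None and a2 is None:
        return frag
    if a1 is None or a2 is None:
        frag.status = "singleton"
        return frag
    frag.n_mismatches_r1 = a1.mismatches
    frag.n_mismatches_r2 = a2.mismatches
    if a1.strand == a2.strand:
        frag.status = "singleton"  # two singletons in the All stratum
        return frag
    fwd, rev = (a1, a2) if a1.strand == "+" else (a2, a1)
    insert = (rev.end - fwd.pos) % L
    if insert == 0:
        insert = L
    if not params.min_insert <= insert <= params.max_insert:
        frag.status = "singleton"
        return frag
    frag.start = fwd.pos
    frag.end = fwd.pos + insert
    frag.strand = a1.strand
    frag.status = "proper_pair"
    return frag


@dataclass
class PairAlignment:
    """Bookkeeping for one pair: both mate alignments plus the fragment."""

    pair: ReadPair
    a1: ReadAlignment | None
    a2: ReadAlignment | None
    fragment: MappedFragment


def map_pairs(
    pairs: list[ReadPair],
    plasmid: PlasmidMap,
    params: AlignmentParams | None = None,
    index: KmerIndex | None = None,
) -> list[PairAlignment]:
    params = params or AlignmentParams()
    if index is None:
        index = KmerIndex(plasmid, params.k)
    out = []
    for p in pairs:
        a1 = map_read(p.r1_seq, index, params)
        a2 = map_read(p.r2_seq, index, params)
        frag = pair_to_fragment(p.id, a1, a2, params, plasmid.length)
        out.append(PairAlignment(pair=p, a1=a1, a2=a2, fragment=frag))
    return out


def dedup(fragments: list[MappedFragment], L: int) -> list[MappedFragment]:
    """Flag duplicate proper pairs; returns the UniquePE subset, order-stable.

    One representative per (start, end, strand) keeps ``duplicate=False``;
    singletons and unmapped pairs are excluded from the result.
    """
    seen: set[tuple[int, int, str]] = set()
    unique = []
    for f in fragments:
        if f.status != "proper_pair":
            continue
        key = f.key(L)
        if key in seen:
            f.duplicate = True
        else:
            f.duplicate = False
            seen.add(key)
            unique.append(f)
    return unique


# -- SAM import/export -----------------------------------------------------

_F_PAIRED, _F_PROPER, _F_UNMAP, _F_MUNMAP = 0x1, 0x2, 0x4, 0x8
_F_REV, _F_MREV, _F_READ1, _F_READ2 = 0x10, 0x20, 0x40, 0x80


def _sam_record(
    qname: str,
    flag: int,
    plasmid: PlasmidMap,
    aln: ReadAlignment | None,
    seq: str,
    qual: str,
) -> str:
    if aln is None:
        return f"{qname}\t{flag | _F_UNMAP}\t*\t0\t0\t*\t*\t0\t0\t{seq}\t{qual}\n"
    # SAM POS is 1-based; this is the single point of 0->1 based conversion.
    pos1 = aln.pos % plasmid.length + 1
    if aln.strand == "-":
        flag |= _F_REV
        seq, qual = revcomp(seq), qual[::-1]
    return (
        f"{qname}\t{flag}\t{plasmid.name}\t{pos1}\t60\t{aln.length}M\t*\t0\t0\t"
        f"{seq}\t{qual}\tNM:i:{aln.mismatches}\n"
    )


def export_sam(alignments: list[PairAlignment], plasmid: PlasmidMap, path: str | Path) -> None:
    """Minimal text SAM of all read pairs (mapped and unmapped)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        fh.write(f"@SQ\tSN:{plasmid.name}\tLN:{plasmid.length}\n")
        for pa in alignments:
            proper = _F_PROPER if pa.fragment.status == "proper_pair" else 0
            f1 = _F_PAIRED | _F_READ1 | proper
            f2 = _F_PAIRED | _F_READ2 | proper
            if pa.a2 is None:
                f1 |= _F_MUNMAP
            elif pa.a2.strand == "-":
                f1 |= _F_MREV
            if pa.a1 is None:
                f2 |= _F_MUNMAP
            elif pa.a1.strand == "-":
                f2 |= _F_MREV
            fh.write(_sam_record(pa.pair.id, f1, plasmid, pa.a1, pa.pair.r1_seq, pa.pair.r1_qual))
            fh.write(_sam_record(pa.pair.id, f2, plasmid, pa.a2, pa.pair.r2_seq, pa.pair.r2_qual))


def import_sam(
    path: str | Path, plasmid: PlasmidMap, params: AlignmentParams | None = None
) -> list[MappedFragment]:
    """Rebuild MappedFragments from a SAM file (internal or external aligner).

    The reference name in the header must match the plasmid; fragment
    intervals are re-derived from the mate alignments with the same rule
    as the internal mapper.
    """
    params = params or AlignmentParams()
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        refs = list(sam.references)
        if plasmid.name not in refs:
            raise ValueError(f"SAM references {refs} do not include plasmid {plasmid.name!r}")
        by_name: dict[str, dict[int, ReadAlignment | None]] = {}
        order: list[str] = []
        for rec in sam.fetch(until_eof=True):
            mate = 2 if rec.is_read2 else 1
            if rec.qname not in by_name:
                by_name[rec.qname] = {}
                order.append(rec.qname)
            if rec.is_unmapped:
                by_name[rec.qname][mate] = None
            else:
                if rec.reference_name != plasmid.name:
                    raise ValueError(f"read {rec.qname} mapped to unknown reference")
                nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
                by_name[rec.qname][mate] = ReadAlignment(
                    pos=rec.reference_start,
                    strand="-" if rec.is_reverse else "+",
                    mismatches=int(nm),
                    length=rec.query_length or rec.infer_read_length() or 0,
                )
    return [
        pair_to_fragment(name, by_name[name].get(1), by_name[name].get(2), params, plasmid.length)
        for name in order
    ]
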