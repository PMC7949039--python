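"""Circular plasmid data model, coordinate conventions, and translation utilities.

Everything downstream of this module reasons about a single circular prey
plasmid: a vector backbone carrying an N-terminal fusion tag (activation or
DNA-binding domain) followed by the prey ORF.  Nucleotide coordinates are
0-based half-open internally; user-facing residue intervals are 1-based
inclusive ("aa 58 to 128" style).  Circularity is handled by normalizing
coordinates mod plasmid length and extracting substrings from the doubled
sequence, so the origin needs no special-casing.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_ACGT = frozenset("ACGT")

#: The six reading-frame class labels.  Sense fragments get positive labels,
#: antisense fragments negative ones ("negative frame means reverse strand").
FRAME_LABELS = ("-3", "-2", "-1", "+1", "+2", "+3")

#: Offset of a fragment's leftmost base relative to the ORF codon grid,
#: mapped to its frame-class label.  Offset 0 places the insert in the prey's
#: native frame; by convention that class is labelled "+2" (the in-frame,
#: coding class), and the remaining labels follow cyclically.
DEFAULT_LABEL_MAP = {
    ("+", 0): "+2", ("+", 1): "+3", ("+", 2): "+1",
    ("-", 0): "-2", ("-", 1): "-3", ("-", 2): "-1",
}

#: Frame label carried by in-frame (coding) fragments under the default map.
CODING_LABEL = DEFAULT_LABEL_MAP[("+", 0)]

#: 5' TruSeq read-1 primer-binding sequence used as the cloning adaptor.
#: Translated in frame 0 it reads HSFPTRRSSD, and the trailing CT overhang
#: plus the first base of the insert always encodes leucine, giving the
#: linker peptide HSFPTRRSSDL regardless of insert sequence.
TRUSEQ_ADAPTOR_5P = "CACTCTTTCCCTACACGACGCTCTTCCGATCT"
LINKER_PEPTIDE = "HSFPTRRSSDL"


class AlphabetError(ValueError):
    """A sequence contains characters outside the expected alphabet."""


class ConstructSpecError(ValueError):
    """A fusion-construct specification violates its frame invariants."""


def _check_dna(dna: str) -> str:
    dna = dna.upper()
    bad = set(dna) - _ACGT
    if bad:
        raise AlphabetError(f"non-ACGT characters in sequence: {sorted(bad)}")
    return dna


def revcomp(dna: str) -> str:
    return str(Seq(dna).reverse_complement())


def translate(dna: str, offset: int = 0) -> str:
    """Translate ``dna`` starting at ``offset`` with the standard code.

    One residue per complete codon; the incomplete trailing codon is
    dropped; stop codons render as ``*``.
    """
    if not dna:
        raise AlphabetError("empty sequence")
    if offset not in (0, 1, 2):
        raise ValueError(f"offset must be 0, 1 or 2, got {offset}")
    dna = _check_dna(dna)
    trimmed = dna[offset:]
    trimmed = trimmed[: len(trimmed) - len(trimmed) % 3]
    if not trimmed:
        return ""
    return str(Seq(trimmed).translate())


@dataclass(frozen=True, order=True)
class AaInterval:
    """1-based inclusive residue interval on an ORF."""

    start_res: int
    end_res: int

    def __post_init__(self) -> None:
        if not (1 <= self.start_res <= self.end_res):
            raise ValueError(
                f"invalid residue interval ({self.start_res}, {self.end_res})"
            )

    @property
    def width(self) -> int:
        return self.end_res - self.start_res + 1

    def contains(self, other: "AaInterval") -> bool:
        return self.start_res <= other.start_res and other.end_res <= self.end_res

    def overlaps(self, other: "AaInterval") -> bool:
        return self.start_res <= other.end_res and other.start_res <= self.end_res

    def intersect(self, other: "AaInterval") -> "AaInterval | None":
        lo = max(self.start_res, other.start_res)
        hi = min(self.end_res, other.end_res)
        return AaInterval(lo, hi) if lo <= hi else None

    def __str__(self) -> str:  # mirrors the reporting convention "aa X to Y (W aa)"
        return f"aa {self.start_res} to {self.end_res} ({self.width} aa)"


@dataclass
class PlasmidMap:
    """Circular reference plasmid with an annotated prey fusion CDS.

    ``cds_start`` is the 0-based offset of the first base of the prey ORF's
    ATG; ``cds_aa_length`` counts residues excluding the stop codon.
    ``vector_features`` are (label, start, end) backbone annotations with
    0-based half-open nt intervals.
    """

    name: str
    sequence: str
    cds_start: int
    cds_aa_length: int
    cds_strand: str = "+"
    vector_features: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = _check_dna(self.sequence)
        if not self.sequence:
            raise ValueError("empty plasmid sequence")
        L = len(self.sequence)
        if self.cds_strand not in ("+", "-"):
            raise ValueError(f"cds_strand must be '+' or '-', got {self.cds_strand!r}")
        self.cds_start %= L
        if self.cds_aa_length < 1:
            raise ValueError("cds_aa_length must be >= 1")
        if 3 * (self.cds_aa_length + 1) > L:
            raise ValueError("CDS longer than plasmid")
        if self.start_codon() != "ATG":
            raise ValueError(
                f"codon at cds_start is {self.start_codon()!r}, expected ATG"
            )
        self.vector_features = [
            (lab, s % L, e % L if e % L else e) for (lab, s, e) in self.vector_features
        ]

    @property
    def length(self) -> int:
        return len(self.sequence)

    # -- circular sequence access ------------------------------------------

    def fetch(self, start: int, length: int) -> str:
        """Circular substring of ``length`` nt starting at ``start``."""
        if length < 0 or length > self.length:
            raise ValueError(f"fetch length {length} out of range")
        start %= self.length
        doubled = self.sequence + self.sequence
        return doubled[start : start + length]

    def start_codon(self) -> str:
        if self.cds_strand == "+":
            return self.fetch(self.cds_start, 3)
        return revcomp(self.fetch((self.cds_start - 2) % self.length, 3))

    def cds_sequence(self) -> str:
        """Coding sequence of the prey ORF, 5'->3', excluding the stop codon."""
        n = 3 * self.cds_aa_length
        if self.cds_strand == "+":
            return self.fetch(self.cds_start, n)
        return revcomp(self.fetch((self.cds_start - n + 1) % self.length, n))

    def orf_peptide(self) -> str:
        return translate(self.cds_sequence())

    def codon_nt_start(self, residue: int) -> int:
        """0-based nt offset of the first base of 1-based ``residue`` (plus-view)."""
        if not 1 <= residue <= self.cds_aa_length:
            raise ValueError(f"residue {residue} outside ORF")
        return (self.cds_start + 3 * (residue - 1)) % self.length

    def plus_view(self) -> "PlasmidMap":
        """Equivalent plasmid with the CDS on the plus strand.

        Fragments on a minus-strand CDS are analysed by reflecting all
        coordinates through ``reflect_interval``; for a plus-strand CDS this
        is the identity.
        """
        if self.cds_strand == "+":
            return self
        L = self.length
        return PlasmidMap(
            name=self.name,
            sequence=revcomp(self.sequence),
            cds_start=L - 1 - self.cds_start,
            cds_aa_length=self.cds_aa_length,
            cds_strand="+",
            vector_features=[
                (lab, (L - e) % L, L - s if s else L) for (lab, s, e) in self.vector_features
            ],
        )

    def reflect_interval(self, start: int, length: int, strand: str) -> tuple[int, int, str]:
        """Map an interval into the plus-view coordinate system."""
        if self.cds_strand == "+":
            return start % self.length, length, strand
        L = self.length
        new_start = (L - (start % L) - length) % L
        return new_start, length, ("-" if strand == "+" else "+")

    def config_hash(self) -> str:
        h = hashlib.sha256()
        h.update(self.sequence.encode())
        h.update(f"{self.name}:{self.cds_start}:{self.cds_strand}:{self.cds_aa_length}".encode())
        return h.hexdigest()[:12]


def residue_span(plasmid: PlasmidMap, start: int, length: int) -> AaInterval | None:
    """Residues of the prey ORF whose *full* codon lies inside a fragment.

    ``start``/``length`` describe a circular nt interval on the plasmid.
    Partial codons encode no residue and are excluded.  Returns ``None``
    when no complete codon is covered.
    """
    if length <= 0:
        return None
    pl = plasmid.plus_view()
    start, length, _ = plasmid.reflect_interval(start, length, "+")
    L = pl.length
    naa = pl.cds_aa_length
    # CDS-local coordinates: nt position p maps to (p - cds_start) mod L.
    rel = (start - pl.cds_start) % L
    pieces = [(rel, min(rel + length, L))]
    if rel + length > L:
        pieces.append((0, rel + length - L))
    spans: list[tuple[int, int]] = []
    for a, b in pieces:
        b = min(b, 3 * naa)
        if b <= a:
            continue
        first = -(-a // 3)          # ceil(a/3): first fully covered codon (0-based)
        last = b // 3               # exclusive
        if last > first:
            spans.append((first + 1, last))  # 1-based inclusive
    if not spans:
        return None
    if len(spans) == 2:
        # Two pieces can only both touch the CDS when a fragment wraps the
        # origin back into the CDS; merge if contiguous, else keep the longer.
        spans.sort()
        if spans[0][1] + 1 >= spans[1][0]:
            spans = [(spans[0][0], max(spans[0][1], spans[1][1]))]
        else:
            spans.sort(key=lambda s: s[1] - s[0])
            spans = spans[-1:]
    return AaInterval(*spans[0])


def frame_offset(
    plasmid: PlasmidMap, start: int, strand: str, length: int = 1
) -> tuple[int, str]:
    """(codon-grid offset, plus-view strand) of a fragment's leftmost base.

    The offset is ``(start - cds_start) mod 3`` in the plus view; the
    leftmost base is the one the cloning junction fused to the adaptor for
    sense inserts, so offset 0 means the insert reads in the prey's native
    frame.  ``length`` matters only for minus-strand-CDS plasmids, where
    the whole interval is reflected into the plus view first.
    """
    pl = plasmid.plus_view()
    start, _, strand = plasmid.reflect_interval(start, length, strand)
    return (start - pl.cds_start) % 3, strand


def frame_label(
    plasmid: PlasmidMap,
    start: int,
    strand: str,
    label_map: dict[tuple[str, int], str] | None = None,
    length: int = 1,
) -> str:
    """Reading-frame class label for a fragment interval.

    Shared by the library simulator (truth assignment) and the coverage
    analysis (frame decision on mapped fragments) so both use one rule.
    """
    label_map = label_map or DEFAULT_LABEL_MAP
    off, s = frame_offset(plasmid, start, strand, length)
    return label_map[(s, off)]


# -- fusion construct ------------------------------------------------------


@dataclass(frozen=True)
class FusionConstructSpec:
    """N-terminal fusion construct: tag, then adaptor linker, then insert.

    The 5' adaptor frame is chosen so that a CT overhang remains; together
    with the first base of any insert the overhang always encodes leucine,
    so the translated linker is invariant to the insert.
    """

    adaptor_5p: str = TRUSEQ_ADAPTOR_5P
    adaptor_frame_offset: int = 0
    linker_peptide_expected: str = LINKER_PEPTIDE

    def __post_init__(self) -> None:
        _check_dna(self.adaptor_5p)
        if self.adaptor_frame_offset not in (0, 1, 2):
            raise ConstructSpecError("adaptor_frame_offset must be 0, 1 or 2")
        tail = (len(self.adaptor_5p) - self.adaptor_frame_offset) % 3
        if self.linker_peptide_expected.endswith("L"):
            if tail != 2 or not self.adaptor_5p.upper().endswith("CT"):
                raise ConstructSpecError(
                    "linker peptide ends in L but the adaptor does not leave a "
                    "CT overhang in the chosen frame"
                )


def linker_peptide(spec: FusionConstructSpec, first_insert_base: str) -> str:
    """Translated linker for a given first insert base.

    For a valid construct the result equals ``spec.linker_peptide_expected``
    for every choice of ``first_insert_base`` (CTN all encode leucine).
    """
    first_insert_base = _check_dna(first_insert_base)
    if len(first_insert_base) != 1:
        raise ValueError("first_insert_base must be a single nucleotide")
    return translate(spec.adaptor_5p + first_insert_base, spec.adaptor_frame_offset)


# -- FASTA + sidecar config I/O -------------------------------------------


def write_fasta(plasmid: PlasmidMap, path: str | Path) -> None:
    rec = SeqRecord(Seq(plasmid.sequence), id=plasmid.name, description="")
    SeqIO.write([rec], str(path), "fasta")


def read_fasta(path: str | Path, strict: bool = False) -> tuple[str, str]:
    """Read a (name, sequence) pair from a FASTA file.

    Multi-record files take the first record (or raise when ``strict``);
    sequences are uppercased on load.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    names = [r.id for r in records]
    if len(records) > 1:
        if strict or len(set(names)) < len(names):
            raise ValueError(f"multiple records in {path}: {names}")
        import warnings

        warnings.warn(f"{path}: {len(records)} records, using first ({names[0]})")
    return records[0].id, _check_dna(str(records[0].seq))


def write_plasmid(plasmid: PlasmidMap, fasta_path: str | Path, config_path: str | Path) -> None:
    """Write the plasmid FASTA plus its structured annotation sidecar."""
    write_fasta(plasmid, fasta_path)
    cfg = {
        "sequence_file": Path(fasta_path).name,
        "name": plasmid.name,
        "cds_start": plasmid.cds_start,
        "cds_strand": plasmid.cds_strand,
        "cds_aa_length": plasmid.cds_aa_length,
        "features": [
            {"label": lab, "start": s, "end": e} for (lab, s, e) in plasmid.vector_features
        ],
    }
    Path(config_path).write_text(yaml.safe_dump(cfg, sort_keys=False))


def read_plasmid(fasta_path: str | Path, config_path: str | Path) -> PlasmidMap:
    name, seq = read_fasta(fasta_path)
    cfg = yaml.safe_load(Path(config_path).read_text())
    return PlasmidMap(
        name=cfg.get("name", name),
        sequence=seq,
        cds_start=int(cfg["cds_start"]),
        cds_strand=str(cfg.get("cds_strand", "+")),
        cds_aa_length=int(cfg["cds_aa_length"]),
        vector_features=[
            (f["label"], int(f["start"]), int(f["end"])) for f in cfg.get("features", [])
        ],
    )
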