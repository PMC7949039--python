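"""Paired-end read simulation and FASTQ I/O.

Selected fragments are sequenced as 2 x ``read_len`` paired-end reads (the
source data are MiSeq 2 x 150 bp).  R1 is the first ``read_len`` bases of
the fragment's cloned strand, R2 the reverse complement of its last
``read_len`` bases; reads truncate to the fragment length when the
fragment is shorter.  A flat substitution-error model is applied per base.
Simulation truth (fragment id, interval, strand) travels in the read name.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .library_sim import Fragment
from .reference import PlasmidMap, revcomp

_BASES = np.frombuffer(b"ACGT", dtype="S1")
DEFAULT_QUAL_CHAR = "F"  # Phred+33 Q37


class PairingError(ValueError):
    """R1/R2 files disagree in record count or read ids."""


@dataclass(frozen=True)
class ErrorModel:
    substitution_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.substitution_rate <= 0.1:
            raise ValueError("substitution_rate must be in [0, 0.1]")


@dataclass
class ReadPair:
    id: str
    r1_seq: str
    r2_seq: str
    r1_qual: str
    r2_qual: str

    def __post_init__(self) -> None:
        if len(self.r1_seq) != len(self.r1_qual) or len(self.r2_seq) != len(self.r2_qual):
            raise ValueError("sequence/quality length mismatch")


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0.0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hit:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = choices[rng.integers(0, len(choices))]
    return arr.tobytes().decode()


def fragment_to_readpair(
    fragment: Fragment,
    plasmid: PlasmidMap,
    read_len: int = 150,
    errors: ErrorModel = ErrorModel(),
    rng: np.random.Generator | None = None,
) -> ReadPair:
    """Sequence one fragment into an error-bearing read pair."""
    if read_len < 20:
        raise ValueError("read_len must be >= 20")
    if rng is None:
        rng = np.random.default_rng(0)
    template = plasmid.fetch(fragment.start, fragment.length)
    cloned = template if fragment.strand == "+" else revcomp(template)
    n = min(read_len, fragment.length)
    r1 = _mutate(cloned[:n], errors.substitution_rate, rng)
    r2 = _mutate(revcomp(cloned[-n:]), errors.substitution_rate, rng)
    name = f"{fragment.id}:{fragment.start}:{fragment.end}:{fragment.strand}"
    return ReadPair(name, r1, r2, DEFAULT_QUAL_CHAR * len(r1), DEFAULT_QUAL_CHAR * len(r2))


def simulate_reads(
    fragments: list[Fragment],
    plasmid: PlasmidMap,
    read_len: int = 150,
    errors: ErrorModel = ErrorModel(),
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> list[ReadPair]:
    """One read pair per fragment copy (amplified clones yield duplicates)."""
    if rng is None:
        rng = np.random.default_rng(seed)
    pairs = []
    for f in fragments:
        for c in range(f.copies):
            p = fragment_to_readpair(f, plasmid, read_len, errors, rng)
            if f.copies > 1:
                p.id = f"{p.id}:c{c}"
            pairs.append(p)
    return pairs


# -- FASTQ I/O -------------------------------------------------------------


def _open(path: str | Path, mode: str):
    path = str(path)
    if path.endswith(".gz"):
        if "w" in mode:
            # mtime=0 keeps rerun outputs byte-identical for checksum tests
            import io

            return io.TextIOWrapper(
                gzip.GzipFile(path, "wb", mtime=0), encoding="ascii", newline=""
            )
        return gzip.open(path, mode + "t")
    return open(path, mode)


def write_fastq(pairs: list[ReadPair], r1_path: str | Path, r2_path: str | Path) -> None:
    with _open(r1_path, "w") as f1, _open(r2_path, "w") as f2:
        for p in pairs:
            f1.write(f"@{p.id}/1\n{p.r1_seq}\n+\n{p.r1_qual}\n")
            f2.write(f"@{p.id}/2\n{p.r2_seq}\n+\n{p.r2_qual}\n")


def _read_records(path: str | Path) -> list[tuple[str, str, str]]:
    records = []
    with _open(path, "r") as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if len(lines) % 4:
        raise ValueError(f"{path}: truncated FASTQ (line count not divisible by 4)")
    for i in range(0, len(lines), 4):
        head, seq, plus, qual = lines[i : i + 4]
        if not head.startswith("@") or not plus.startswith("+"):
            raise ValueError(f"{path}: malformed FASTQ record at line {i + 1} ({head!r})")
        name = head[1:].split()[0]
        records.append((name, seq, qual))
    return records


def read_fastq(r1_path: str | Path, r2_path: str | Path) -> list[ReadPair]:
    rec1 = _read_records(r1_path)
    rec2 = _read_records(r2_path)
    if len(rec1) != len(rec2):
        raise PairingError(f"R1 has {len(rec1)} records but R2 has {len(rec2)}")
    pairs = []
    for (n1, s1, q1), (n2, s2, q2) in zip(rec1, rec2):
        b1 = n1[:-2] if n1.endswith("/1") else n1
        b2 = n2[:-2] if n2.endswith("/2") else n2
        if b1 != b2:
            raise PairingError(f"read ids disagree: {n1!r} vs {n2!r}")
        pairs.append(ReadPair(b1, s1, s2, q1, q2))
    return pairs


def write_truth_tsv(fragments: list[Fragment], path: str | Path) -> None:
    """Sidecar truth table mapping read id to the originating interval."""
    with open(path, "w") as fh:
        fh.write("#read_id\tstart\tend\tstrand\n")
        for f in fragments:
            fh.write(f"{f.id}:{f.start}:{f.end}:{f.strand}\t{f.start}\t{f.end}\t{f.strand}\n")
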