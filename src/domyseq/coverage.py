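"""Reading-frame decision, frame-class statistics, and stratified coverage.

This is the analytical core of the method: every properly paired fragment
is assigned one of six reading-frame classes from the offset of its
leftmost base relative to the prey ORF's start codon (negative classes are
reverse-strand inserts); in-frame fragments are extracted; and per-position
depth tracks are built in nucleotide space (whole plasmid) and residue
space (ORF only), stratified as All / UniquePE / InFrame.  Tracks are
persisted as bedGraph, a text stand-in for bigwig with identical content.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .mapping import MappedFragment
from .reference import CODING_LABEL, FRAME_LABELS, PlasmidMap, frame_label, residue_span

MODES = ("All", "UniquePE", "InFrame")


class EmptyDistributionError(ValueError):
    """No framed fragments to summarize."""


class NoFrameError(ValueError):
    """Frame decision requested for a non-proper fragment."""


def decide_frame(fragment: MappedFragment, plasmid: PlasmidMap, label_map=None) -> str:
    """Frame-class label of a mapped fragment relative to the ORF start codon.

    Identical rule to the simulator's truth assignment (one shared
    implementation): offset of the leftmost base on the codon grid, sign
    from the cloned strand.
    """
    if fragment.status != "proper_pair":
        raise NoFrameError(f"{fragment.read_id}: no frame for {fragment.status}")
    label = frame_label(plasmid, fragment.start, fragment.strand, label_map, fragment.length)
    fragment.frame_label = label
    return label


@dataclass
class FrameDistribution:
    """Counts and fractions over the six frame classes, plus the summary
    statistics reported for pre-selection libraries (mean and SD of the six
    class percentages)."""

    counts: dict[str, int]
    n_total: int

    def __post_init__(self) -> None:
        if self.n_total <= 0:
            raise EmptyDistributionError("no framed fragments")
        assert set(self.counts) == set(FRAME_LABELS)

    @property
    def fractions(self) -> dict[str, float]:
        return {k: v / self.n_total for k, v in self.counts.items()}

    @property
    def percentages(self) -> dict[str, float]:
        return {k: 100.0 * v / self.n_total for k, v in self.counts.items()}

    @property
    def mean_pct(self) -> float:
        return float(np.mean(list(self.percentages.values())))

    @property
    def sd_pct(self) -> float:
        return float(np.std(list(self.percentages.values()), ddof=1))

    def to_tsv(self, path: str | Path, header_lines: list[str] | None = None) -> None:
        with open(path, "w") as fh:
            for line in header_lines or []:
                fh.write(f"#{line}\n")
            fh.write("#frame\tcount\tfraction\tpercent\n")
            for lab in FRAME_LABELS:
                fh.write(
                    f"{lab}\t{self.counts[lab]}\t{self.fractions[lab]:.6f}\t"
                    f"{self.percentages[lab]:.3f}\n"
                )
            fh.write(f"#mean_pct={self.mean_pct:.2f}\tsd_pct={self.sd_pct:.3f}\n")


def frame_distribution(framed) -> FrameDistribution:
    """Exact frame-class counts over fragments that carry a frame label."""
    counts = {lab: 0 for lab in FRAME_LABELS}
    n = 0
    for f in framed:
        lab = getattr(f, "frame_label", "")
        if lab in counts:
            counts[lab] += 1
            n += 1
    return FrameDistribution(counts=counts, n_total=n)


def _overlaps_cds(start: int, length: int, plasmid: PlasmidMap) -> bool:
    pl = plasmid.plus_view()
    start, length, _ = plasmid.reflect_interval(start, length, "+")
    rel = (start - pl.cds_start) % pl.length
    cds_nt = 3 * pl.cds_aa_length
    return rel < cds_nt or rel + length > pl.length  # wraps back over the CDS start


def filter_inframe(
    fragments: list[MappedFragment], plasmid: PlasmidMap, label_map=None
) -> list[MappedFragment]:
    """The InFrame stratum: proper, non-duplicate, coding-frame fragments
    overlapping the prey CDS.  Order-stable."""
    coding = (label_map or {}).get(("+", 0), CODING_LABEL)
    out = []
    for f in fragments:
        if f.status != "proper_pair" or f.duplicate:
            continue
        if not f.frame_label:
            decide_frame(f, plasmid, label_map)
        if f.frame_label != coding:
            continue
        if not _overlaps_cds(f.start % plasmid.length, f.length, plasmid):
            continue
        out.append(f)
    return out


@dataclass
class CoverageTrack:
    """Per-position depth over the plasmid (nt space) or the ORF (aa space).

    aa-space index 0 holds residue 1; depth counts fragments whose interval
    contains the position (nt) or the residue's full codon (aa).
    """

    space: str  # "nt" | "aa"
    mode: str  # All | UniquePE | InFrame
    values: np.ndarray
    chrom: str

    def __post_init__(self) -> None:
        if self.space not in ("nt", "aa"):
            raise ValueError(f"unknown space {self.space!r}")
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        self.values = np.asarray(self.values, dtype=np.int64)
        if (self.values < 0).any():
            raise ValueError("negative depth")


def coverage_track(fragments, mode: str, space: str, plasmid: PlasmidMap) -> CoverageTrack:
    """Depth track for one fragment stratum.

    nt space: each fragment adds 1 to every base it covers, circular-aware,
    so total depth equals the sum of fragment lengths.  aa space: each
    fragment adds 1 to every residue whose full codon it covers.
    """
    L = plasmid.length
    if space == "nt":
        values = np.zeros(L, dtype=np.int64)
        for f in fragments:
            s = f.start % L
            e = s + f.length
            if e <= L:
                values[s:e] += 1
            else:
                values[s:] += 1
                values[: e - L] += 1
        chrom = plasmid.name
    else:
        values = np.zeros(plasmid.cds_aa_length, dtype=np.int64)
        for f in fragments:
            span = residue_span(plasmid, f.start, f.length)
            if span is not None:
                values[span.start_res - 1 : span.end_res] += 1
        chrom = f"{plasmid.name}_aa"
    return CoverageTrack(space=space, mode=mode, values=values, chrom=chrom)


# -- bedGraph --------------------------------------------------------------


def write_bedgraph(track: CoverageTrack, path: str | Path, header_lines=None) -> None:
    """Run-length-merged bedGraph (0-based half-open), zero runs included so
    the track round-trips exactly."""
    v = track.values
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"#{line}\n")
        fh.write(f"#domyseq-track space={track.space} mode={track.mode} length={len(v)}\n")
        if len(v) == 0:
            return
        boundaries = np.nonzero(np.diff(v))[0] + 1
        starts = np.concatenate([[0], boundaries])
        ends = np.concatenate([boundaries, [len(v)]])
        for s, e in zip(starts, ends):
            fh.write(f"{track.chrom}\t{s}\t{e}\t{v[s]}\n")


def read_bedgraph(path: str | Path) -> CoverageTrack:
    space = mode = chrom = None
    length = 0
    rows = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#domyseq-track"):
            kv = dict(tok.split("=") for tok in line.split()[1:])
            space, mode, length = kv["space"], kv["mode"], int(kv["length"])
            continue
        if not line or line.startswith("#") or line.startswith("track"):
            continue
        chrom, s, e, val = line.split("\t")
        rows.append((int(s), int(e), int(val)))
    if space is None:
        raise ValueError(f"{path}: missing domyseq track header")
    values = np.zeros(length, dtype=np.int64)
    covered = np.zeros(length, dtype=bool)
    for s, e, val in rows:
        if covered[s:e].any():
            raise ValueError(f"{path}: overlapping bedGraph intervals at [{s},{e})")
        covered[s:e] = True
        values[s:e] = val
    return CoverageTrack(space=space, mode=mode, values=values, chrom=chrom or "")
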