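"""Random-fragment prey library generation and the Y2H selection model.

Emulates the wet half of a domain-mapping screen: a prey plasmid is
acoustically sheared into fragments, each fragment is cloned in a random
orientation downstream of an N-terminal fusion tag (giving six possible
reading-frame classes), and auxotrophic reporter selection retains the
clones whose in-frame, stop-free insert fully covers the bait-binding
interval.  Self-activating (transactivation-domain) fragments and
content-independent background colonies are modelled as additional
selection routes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .reference import (
    AaInterval,
    PlasmidMap,
    frame_label,
    frame_offset,
    residue_span,
    translate,
)

CAUSES = ("binding", "self_activation", "background", "none")


class SelectionError(RuntimeError):
    """Raised when selection retains zero fragments."""


@dataclass(frozen=True)
class ShearModel:
    """Acoustic-shear fragment model: truncated-normal lengths, uniform starts.

    Shear fractions in the source protocol are centred at 200, 350, 500,
    700 and 1000 bp; ``sd_len`` defaults to 25% of the mean, the broad
    spread characteristic of acoustic shearing.
    """

    mean_len: float = 350.0
    sd_len: float = 88.0
    min_len: int = 20
    n_fragments: int = 50_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_len < 1:
            raise ValueError("min_len must be >= 1")
        if self.mean_len < self.min_len:
            raise ValueError("mean_len must be >= min_len")
        if self.n_fragments < 0:
            raise ValueError("n_fragments must be >= 0")


@dataclass
class Fragment:
    """A sheared interval on the plasmid, with its cloning orientation.

    ``strand`` is the orientation of insertion relative to the fusion ORF;
    ``start`` is the leftmost plasmid base (0-based) and the interval is
    ``[start, start+length)`` mod plasmid length.  ``copies`` models clonal
    amplification after selective culture (default 1).
    """

    id: str
    start: int
    length: int
    strand: str
    frame_label: str = ""
    selected: bool = False
    selection_cause: str = "none"
    copies: int = 1

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass(frozen=True)
class BindingModel:
    """Reporter-activation model applied to each cloned fragment.

    ``true_interval`` is the bait-binding motif on the prey ORF; selection
    by binding requires an in-frame, stop-free insert whose residue span
    fully covers it (the high-stringency LTHA behaviour).
    ``coverage_stringency`` > 0 lets partially covering fragments through
    with that probability (LTH leakiness).  ``forbidden_interval`` models a
    region whose inclusion abolishes binding (a sharp 3' coverage edge).
    ``tad_intervals`` are transactivating peptides that activate the
    reporter bait-independently; ``tad_penetrance`` is the probability that
    such a fragment yields a colony.  ``background_rate`` is
    content-independent reporter noise.
    """

    true_interval: AaInterval | None = None
    coverage_stringency: float = 0.0
    forbidden_interval: AaInterval | None = None
    tad_intervals: tuple[AaInterval, ...] = ()
    tad_penetrance: float = 1.0
    background_rate: float = 0.0

    def __post_init__(self) -> None:
        for p, lab in [
            (self.coverage_stringency, "coverage_stringency"),
            (self.tad_penetrance, "tad_penetrance"),
            (self.background_rate, "background_rate"),
        ]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{lab} must be in [0, 1], got {p}")


def _truncnorm_lengths(model: ShearModel, upper: int, rng: np.random.Generator) -> np.ndarray:
    """Truncated-normal lengths in [min_len, upper] by exact rejection."""
    n = model.n_fragments
    out = np.empty(n, dtype=np.int64)
    filled = 0
    while filled < n:
        draw = rng.normal(model.mean_len, model.sd_len, size=max(n - filled, 1000))
        draw = np.rint(draw).astype(np.int64)
        ok = draw[(draw >= model.min_len) & (draw <= upper)]
        take = min(len(ok), n - filled)
        out[filled : filled + take] = ok[:take]
        filled += take
    return out


def shear_plasmid(
    plasmid: PlasmidMap, model: ShearModel, rng: np.random.Generator | None = None
) -> list[Fragment]:
    """Shear the plasmid into ``n_fragments`` random fragments.

    Starts are uniform on the circle, lengths truncated-normal, and the
    cloning orientation uniform on {+,-}.  Deterministic for a fixed seed.
    """
    if rng is None:
        rng = np.random.default_rng(model.seed)
    if model.n_fragments == 0:
        import warnings

        warnings.warn("n_fragments = 0: empty library")
        return []
    upper = min(plasmid.length, int(model.mean_len + 8 * model.sd_len + 1))
    starts = rng.integers(0, plasmid.length, size=model.n_fragments)
    lengths = _truncnorm_lengths(model, upper, rng)
    strands = np.where(rng.random(model.n_fragments) < 0.5, "+", "-")
    frags = []
    for i in range(model.n_fragments):
        f = Fragment(
            id=f"frag{i:06d}",
            start=int(starts[i]),
            length=int(lengths[i]),
            strand=str(strands[i]),
        )
        f.frame_label = assign_frame_label(f, plasmid)
        frags.append(f)
    return frags


def assign_frame_label(fragment: Fragment, plasmid: PlasmidMap, label_map=None) -> str:
    """Frame-class label of a fragment (shared rule with the mapped-read path)."""
    return frame_label(plasmid, fragment.start, fragment.strand, label_map, fragment.length)


def is_coding(fragment: Fragment, plasmid: PlasmidMap) -> bool:
    off, strand = frame_offset(plasmid, fragment.start, fragment.strand, fragment.length)
    return strand == "+" and off == 0


def stop_free_through(
    plasmid: PlasmidMap, start: int, residue_end: int, length: int = 1
) -> bool:
    """True when translation from the junction reaches ``residue_end`` stop-free.

    The translated stretch may cross backbone sequence upstream of the CDS,
    where stop codons are possible and kill the fusion peptide.  When the
    path from the junction to the target codon crosses the origin of a
    plasmid whose length is not a multiple of 3, the reading frame shifts
    along the way even though the linear frame label says "coding"; such a
    fusion cannot translate the motif, so the check fails.
    """
    pl = plasmid.plus_view()
    start, _, _ = plasmid.reflect_interval(start, length, "+")
    d = (pl.cds_start + 3 * residue_end - start) % pl.length
    if d == 0:
        return True
    if d % 3:
        return False  # origin-crossing frame shift (plasmid length % 3 != 0)
    return "*" not in translate(pl.fetch(start, d))


def is_selected(
    fragment: Fragment,
    plasmid: PlasmidMap,
    binding: BindingModel,
    rng: np.random.Generator,
) -> tuple[bool, str]:
    """Apply the reporter-selection model to one fragment.

    Returns ``(selected, cause)`` with cause in ``{binding,
    self_activation, background, none}``.
    """
    span = residue_span(plasmid, fragment.start, fragment.length)
    if is_coding(fragment, plasmid) and span is not None:
        if binding.true_interval is not None:
            clean = (
                binding.forbidden_interval is None
                or not span.overlaps(binding.forbidden_interval)
            )
            if clean and span.contains(binding.true_interval):
                if stop_free_through(
                    plasmid, fragment.start, binding.true_interval.end_res, fragment.length
                ):
                    return True, "binding"
            elif clean and span.overlaps(binding.true_interval):
                covered_end = min(span.end_res, binding.true_interval.end_res)
                if (
                    binding.coverage_stringency > 0
                    and rng.random() < binding.coverage_stringency
                    and stop_free_through(plasmid, fragment.start, covered_end, fragment.length)
                ):
                    return True, "binding"
        for tad in binding.tad_intervals:
            if span.contains(tad) and stop_free_through(
                plasmid, fragment.start, tad.end_res, fragment.length
            ):
                if binding.tad_penetrance >= 1.0 or rng.random() < binding.tad_penetrance:
                    return True, "self_activation"
    if binding.background_rate > 0 and rng.random() < binding.background_rate:
        return True, "background"
    return False, "none"


@dataclass
class SelectionSummary:
    n_input: int
    n_selected: int
    by_cause: dict[str, int]
    by_frame: dict[str, int]


def simulate_selection(
    fragments: list[Fragment],
    plasmid: PlasmidMap,
    binding: BindingModel,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> tuple[list[Fragment], SelectionSummary]:
    """Run reporter selection over a library; returns selected fragments + counts."""
    if not fragments:
        raise SelectionError("empty library")
    if rng is None:
        rng = np.random.default_rng(seed)
    selected: list[Fragment] = []
    by_cause = {c: 0 for c in CAUSES}
    by_frame: dict[str, int] = {}
    for f in fragments:
        ok, cause = is_selected(f, plasmid, binding, rng)
        f.selected = ok
        f.selection_cause = cause
        by_cause[cause] += 1
        if ok:
            selected.append(f)
            by_frame[f.frame_label] = by_frame.get(f.frame_label, 0) + 1
    if not selected:
        raise SelectionError(
            "selection retained zero fragments; increase n_fragments or relax "
            "the binding model"
        )
    summary = SelectionSummary(
        n_input=len(fragments),
        n_selected=len(selected),
        by_cause=by_cause,
        by_frame=dict(sorted(by_frame.items())),
    )
    return selected, summary


def amplify(
    fragments: list[Fragment], mean_copies: float, rng: np.random.Generator
) -> list[Fragment]:
    """Optional clonal-growth skew: geometric per-fragment copy counts."""
    if mean_copies <= 1.0:
        return fragments
    p = 1.0 / mean_copies
    copies = rng.geometric(p, size=len(fragments))
    return [replace(f, copies=int(c)) for f, c in zip(fragments, copies)]


# -- fragment TSV (BED-like) ----------------------------------------------

_TSV_HEADER = "#chrom\tstart\tend\tid\tselection_cause\tstrand\tframe_label\tcopies"


def write_fragments_tsv(
    fragments: list[Fragment], plasmid: PlasmidMap, path: str | Path, header_lines: list[str] | None = None
) -> None:
    """BED-like TSV; ``end`` may exceed plasmid length for origin-wrapping fragments."""
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"#{line}\n")
        fh.write(_TSV_HEADER + "\n")
        for f in fragments:
            fh.write(
                f"{plasmid.name}\t{f.start}\t{f.end}\t{f.id}\t{f.selection_cause}\t"
                f"{f.strand}\t{f.frame_label}\t{f.copies}\n"
            )


def read_fragments_tsv(path: str | Path) -> list[Fragment]:
    frags = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        _, start, end, fid, cause, strand, label, copies = line.split("\t")
        frags.append(
            Fragment(
                id=fid,
                start=int(start),
                length=int(end) - int(start),
                strand=strand,
                frame_label=label,
                selected=cause != "none",
                selection_cause=cause,
                copies=int(copies),
            )
        )
    return frags
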