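"""Nine-residue transactivation-domain (9aaTAD) scanning.

Prey fragments that happen to encode a transactivating peptide switch the
reporter on without any bait contact, so coverage peaks must be audited
against candidate 9aaTAD motifs in the ORF and the vector backbone.  The
scanner tests every 9-residue window against a configurable position-class
pattern.  The shipped default pattern approximates — it does not replicate
— the published 9aaTAD web predictor: it is calibrated to match the known
acidic/hydrophobic/aromatic transactivating peptide EVYQVTVYQ and to
reject featureless (all-basic, all-glycine) windows.  Hits are advisory
annotations on domain calls, never filters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .caller import DomainCall
from .reference import AaInterval, PlasmidMap, revcomp, translate

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")

_ACIDIC = "DE"
_HYDROPHOBIC = "AILMVFWY"
_AROMATIC_HYDRO = "FWYILMV"
_AROMATIC = "FWY"
_POLAR = "QNST"


@dataclass(frozen=True)
class PositionClass:
    """Residue class for one pattern position: an allowed set or, when
    ``deny`` is set, a disallowed set."""

    residues: frozenset
    deny: bool = False

    def matches(self, aa: str) -> bool:
        return (aa not in self.residues) if self.deny else (aa in self.residues)


@dataclass(frozen=True)
class TadPattern:
    name: str
    position_classes: tuple[PositionClass, ...]
    description: str = ""

    def __post_init__(self) -> None:
        if len(self.position_classes) != 9:
            raise ValueError("a 9aaTAD pattern has exactly 9 positions")
        if any(not pc.residues for pc in self.position_classes):
            raise ValueError("empty position class")

    def matches(self, window: str) -> bool:
        return all(pc.matches(aa) for pc, aa in zip(self.position_classes, window))


def _allow(residues: str) -> PositionClass:
    return PositionClass(frozenset(residues))


#: Default acidic/hydrophobic/aromatic transactivation pattern.
DEFAULT_TAD_PATTERN = TadPattern(
    name="acidic_hydrophobic_aromatic",
    position_classes=(
        _allow(_ACIDIC),
        _allow(_HYDROPHOBIC),
        _allow(_AROMATIC_HYDRO),
        _allow(_POLAR + _ACIDIC),
        _allow(_HYDROPHOBIC),
        _allow(_POLAR),
        _allow(_HYDROPHOBIC),
        _allow(_AROMATIC),
        _allow(_POLAR),
    ),
    description=(
        "acidic anchor, alternating hydrophobic/aromatic core, polar spacers; "
        "approximation of published 9aaTAD physicochemical rules"
    ),
)


@dataclass(frozen=True)
class TadHit:
    source: str  # orf | vector_feature | fragment
    frame_label: str
    start_res: int  # 1-based within the scanned peptide
    peptide: str
    pattern_name: str
    nt_start: int = -1  # forward-strand plasmid coords when back-projectable
    nt_end: int = -1
    feature: str = ""

    @property
    def residue_interval(self) -> AaInterval:
        return AaInterval(self.start_res, self.start_res + 8)


def scan_peptide(
    peptide: str, pattern: TadPattern = DEFAULT_TAD_PATTERN, source: str = "orf",
    frame: str = "+0",
) -> list[TadHit]:
    """Test every 9-residue window; hits carry 1-based window starts."""
    peptide = peptide.upper()
    bad = set(peptide) - AA_ALPHABET - {"*"}
    if bad:
        raise ValueError(f"non-standard residues: {sorted(bad)}")
    hits = []
    for i in range(max(0, len(peptide) - 8)):
        window = peptide[i : i + 9]
        if "*" not in window and pattern.matches(window):
            hits.append(
                TadHit(
                    source=source,
                    frame_label=frame,
                    start_res=i + 1,
                    peptide=window,
                    pattern_name=pattern.name,
                )
            )
    return hits


def scan_orf(plasmid: PlasmidMap, pattern: TadPattern = DEFAULT_TAD_PATTERN) -> list[TadHit]:
    """Scan the prey ORF translation; hit coordinates are ORF residues."""
    return scan_peptide(plasmid.orf_peptide(), pattern, source="orf", frame="+0")


def _feature_at(plasmid: PlasmidMap, nt_start: int, nt_end: int) -> str:
    for lab, s, e in plasmid.vector_features:
        if nt_start < e and s < nt_end:
            return lab
    return ""


def scan_plasmid_frames(
    plasmid: PlasmidMap, pattern: TadPattern = DEFAULT_TAD_PATTERN
) -> list[TadHit]:
    """Scan all six frame translations of the whole plasmid.

    The doubled sequence catches windows crossing the origin; hits are
    annotated with overlapping vector features and carry forward-strand nt
    intervals so they can be cross-referenced with coverage peaks.
    """
    L = plasmid.length
    doubled = plasmid.sequence + plasmid.sequence
    hits: list[TadHit] = []
    for strand in ("+", "-"):
        seq = doubled if strand == "+" else revcomp(doubled)
        for offset in (0, 1, 2):
            pep = translate(seq, offset)
            for h in scan_peptide(pep, pattern, source="vector_feature", frame=f"{strand}{offset}"):
                nt_lo = offset + 3 * (h.start_res - 1)
                nt_hi = nt_lo + 27
                if strand == "-":
                    nt_lo, nt_hi = 2 * L - nt_hi, 2 * L - nt_lo
                if nt_lo >= L:  # duplicate of a window already seen mod L
                    continue
                hits.append(
                    TadHit(
                        source="vector_feature",
                        frame_label=f"{strand}{offset}",
                        start_res=h.start_res,
                        peptide=h.peptide,
                        pattern_name=pattern.name,
                        nt_start=nt_lo,
                        nt_end=nt_hi,
                        feature=_feature_at(plasmid, nt_lo % L, (nt_lo % L) + 27),
                    )
                )
    return hits


def hit_nt_peptide(plasmid: PlasmidMap, hit: TadHit) -> str:
    """Re-translate a vector-scan hit's nt interval (round-trip check)."""
    seq = plasmid.fetch(hit.nt_start, 27)
    if hit.frame_label.startswith("-"):
        seq = revcomp(seq)
    return translate(seq)


def annotate_calls_with_tads(call: DomainCall, hits: list[TadHit]) -> DomainCall:
    """Flag calls whose interval overlaps an ORF TAD hit.

    Advisory only: the flag marks a call that could reflect self-activation
    rather than binding; it never suppresses the call.
    """
    for c in [call] + call.secondary_calls:
        c.possible_self_activation = any(
            h.source == "orf" and c.interval.overlaps(h.residue_interval) for h in hits
        )
    return call


def write_hits_tsv(hits: list[TadHit], path: str | Path, header_lines=None) -> None:
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"#{line}\n")
        fh.write("#source\tframe\tstart_res\tpeptide\tpattern\tnt_start\tnt_end\tfeature\n")
        for h in hits:
            fh.write(
                f"{h.source}\t{h.frame_label}\t{h.start_res}\t{h.peptide}\t"
                f"{h.pattern_name}\t{h.nt_start}\t{h.nt_end}\t{h.feature}\n"
            )


# -- pattern definition file ----------------------------------------------


def write_pattern(pattern: TadPattern, path: str | Path) -> None:
    """One line per position: 'allow RESIDUES' or 'deny RESIDUES'."""
    lines = [f"# {pattern.name}: {pattern.description}"]
    for pc in pattern.position_classes:
        mode = "deny" if pc.deny else "allow"
        lines.append(f"{mode} {''.join(sorted(pc.residues))}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_pattern(path: str | Path, name: str | None = None) -> TadPattern:
    classes = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        mode, residues = line.split()
        classes.append(PositionClass(frozenset(residues.upper()), deny=mode == "deny"))
    return TadPattern(name=name or Path(path).stem, position_classes=tuple(classes))
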