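"""Plateau calling: the core binding domain and its flank asymmetry.

In a saturating screen every selected in-frame fragment fully covers the
binding motif, so the in-frame residue-space coverage is flat and maximal
exactly over the motif and falls off on both flanks at the rate at which
admissible fragment start/end positions are lost.  The caller makes the
visual plateau read-out algorithmic: the primary call is the longest run
of residues with depth >= tau * max_depth; further disjoint runs above a
secondary floor are reported as secondary calls (e.g. a transactivating
hotspot elsewhere in the ORF).  Flank slopes are the residue distances
from each plateau edge out to half-maximal depth; a sharp edge (slope of a
residue or two) marks an abrupt loss of selectable fragments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .coverage import CoverageTrack
from .reference import AaInterval


class NoCallError(ValueError):
    """All-zero coverage: nothing to call."""


@dataclass
class DomainCall:
    interval: AaInterval
    plateau_depth: int
    tau: float
    left_slope_aa: int = 0
    right_slope_aa: int = 0
    left_censored: bool = False
    right_censored: bool = False
    secondary: bool = False
    possible_self_activation: bool = False
    secondary_calls: list["DomainCall"] = field(default_factory=list)

    @property
    def width_aa(self) -> int:
        return self.interval.width

    @property
    def slope_ratio(self) -> float:
        return self.left_slope_aa / max(self.right_slope_aa, 1)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs as 0-based half-open (start, end) index pairs."""
    padded = np.concatenate([[False], mask, [False]])
    diff = np.diff(padded.astype(np.int8))
    starts = np.nonzero(diff == 1)[0]
    ends = np.nonzero(diff == -1)[0]
    return list(zip(starts, ends))


def call_plateau(
    track: CoverageTrack,
    tau: float = 0.99,
    secondary_floor: float = 0.5,
    min_secondary_run: int = 10,
) -> DomainCall:
    """Call the core binding domain on an aa-space InFrame coverage track.

    Primary call: longest maximal run with depth >= tau * max depth (ties
    broken by higher mean depth, then leftmost).  Secondary calls: other
    plateau-tier runs, plus disjoint runs of >= ``min_secondary_run``
    residues above ``secondary_floor * max`` — the pattern produced by a
    second binding site or a self-activating region.
    """
    if track.space != "aa":
        raise ValueError("plateau calling operates on aa-space tracks")
    if not 0.0 < tau <= 1.0:
        raise ValueError("tau must be in (0, 1]")
    v = track.values
    max_depth = int(v.max(initial=0))
    if max_depth == 0:
        raise NoCallError("coverage track is all-zero")
    thresh = tau * max_depth - 1e-9
    runs = _runs(v >= thresh)
    runs.sort(key=lambda r: (-(r[1] - r[0]), -float(v[r[0] : r[1]].mean()), r[0]))
    p_start, p_end = runs[0]
    primary = DomainCall(
        interval=AaInterval(p_start + 1, p_end),
        plateau_depth=int(v[p_start:p_end].max()),
        tau=tau,
    )
    _fill_slopes(primary, v)
    secondaries: list[DomainCall] = []
    for s, e in runs[1:]:
        secondaries.append((s, e))
    floor = secondary_floor * max_depth - 1e-9
    for s, e in _runs(v >= floor):
        if e <= p_end and s >= p_start:
            continue
        if s <= p_end and e >= p_start:
            continue  # run containing/adjoining the primary plateau: its own flanks
        if e - s >= min_secondary_run and not any(s < e2 and s2 < e for s2, e2 in secondaries):
            secondaries.append((s, e))
    for s, e in sorted(set(secondaries)):
        sec = DomainCall(
            interval=AaInterval(s + 1, e),
            plateau_depth=int(v[s:e].max()),
            tau=tau,
            secondary=True,
        )
        _fill_slopes(sec, v)
        primary.secondary_calls.append(sec)
    return primary


def _fill_slopes(call: DomainCall, v: np.ndarray) -> None:
    left, lc, right, rc = flank_asymmetry_values(v, call.interval, call.plateau_depth)
    call.left_slope_aa, call.left_censored = left, lc
    call.right_slope_aa, call.right_censored = right, rc


def flank_asymmetry_values(
    v: np.ndarray, interval: AaInterval, plateau_depth: int
) -> tuple[int, bool, int, bool]:
    """Residue distances from the plateau edges to half-maximal depth.

    A flank that reaches the ORF boundary before dropping to half-max is
    reported boundary-censored at the distance walked.
    """
    half = plateau_depth / 2.0
    # left: residues start_res-1, start_res-2, ... (array indices start-2 down)
    dist, censored = 0, True
    for step, idx in enumerate(range(interval.start_res - 2, -1, -1), start=1):
        if v[idx] <= half:
            dist, censored = step, False
            break
        dist = step
    left, left_c = dist, censored and interval.start_res > 1
    if interval.start_res == 1:
        left, left_c = 0, True
    dist, censored = 0, True
    for step, idx in enumerate(range(interval.end_res, len(v)), start=1):
        if v[idx] <= half:
            dist, censored = step, False
            break
        dist = step
    right, right_c = dist, censored and interval.end_res < len(v)
    if interval.end_res == len(v):
        right, right_c = 0, True
    return left, left_c, right, right_c


def flank_asymmetry(track: CoverageTrack, call: DomainCall) -> tuple[int, int, float]:
    """(left_slope_aa, right_slope_aa, left/right ratio) for an existing call."""
    left, lc, right, rc = flank_asymmetry_values(track.values, call.interval, call.plateau_depth)
    return left, right, left / max(right, 1)


def oracle_intersection(spans: list[AaInterval | None]) -> AaInterval | None:
    """Exact intersection of fragment residue spans (the saturation limit).

    Independent brute-force reference for the plateau caller at tau=1.0 on
    noise-free full-coverage selections.
    """
    spans = [s for s in spans if s is not None]
    if not spans:
        return None
    lo = max(s.start_res for s in spans)
    hi = min(s.end_res for s in spans)
    return AaInterval(lo, hi) if lo <= hi else None


def report_calls(
    call: DomainCall | None, orf_name: str, path: str | Path, header_lines=None
) -> list[str]:
    """TSV report, one row per call; empty calls produce a no_call row.

    The human-readable summary mirrors the field's phrasing: "aa X to Y (W aa)".
    """
    rows = []
    header = (
        "#orf\tstart_res\tend_res\twidth_aa\tplateau_depth\ttau\t"
        "left_slope_aa\tright_slope_aa\tsecondary\tpossible_self_activation\tsummary"
    )
    all_calls = [] if call is None else [call] + call.secondary_calls
    for c in all_calls:
        lslope = f"{c.left_slope_aa}{'*' if c.left_censored else ''}"
        rslope = f"{c.right_slope_aa}{'*' if c.right_censored else ''}"
        rows.append(
            f"{orf_name}\t{c.interval.start_res}\t{c.interval.end_res}\t{c.width_aa}\t"
            f"{c.plateau_depth}\t{c.tau}\t{lslope}\t{rslope}\t"
            f"{int(c.secondary)}\t{int(c.possible_self_activation)}\t{c.interval}"
        )
    if not rows:
        rows.append(f"{orf_name}\tno_call\t-\t-\t-\t-\t-\t-\t-\t-\tno_call")
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"#{line}\n")
        fh.write(header + "\n")
        for r in rows:
            fh.write(r + "\n")
    return rows
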