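"""Tandem Cys-box decomposition of modular metallothioneins.

Long fungal MTs are built by tandem amplification of a short Cys-rich
building block. The canonical block carries seven cysteines in the
consensus ``CXCX3CSCPPGXCXCAXCP`` — an inter-Cys spacing (gap) signature
of [1, 3, 1, 4, 1, 2] — and degenerate copies drop one mandatory Cys,
leaving six. This module scans a protein for such boxes by gap-signature
matching with a per-gap tolerance (strict regexes would miss alignable
variants such as the Neurospora crassa arrangement [1, 5, 1, 3, 1, 2]),
then segments the protein into an optimal set of non-overlapping boxes
by dynamic programming.

Scores are in "base units": one unit per mandatory Cys placed within the
gap tolerance (7 for a full box, 6 for a degenerate one — the missing
Cys is a one-unit penalty) plus small bonuses for conserved non-Cys
residues of the consensus (the Ser of the central CSC, the Pro doublet
after the second CXC, small residues Gly/Ala, the Pro after the last
Cys) and half-unit bonuses for charged residues flanking the box.

Coordinates are 1-based inclusive on the protein, matching how
biologists read annotated sequence figures; ``CysBox.as_zero_based``
converts to 0-based half-open for interop.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Literal

from .errors import InvalidProfileError
from .records import ProteinRecord
from .seqstats import cys_positions

BoxKind = Literal["seven_cys", "six_cys", "other"]


@dataclass(frozen=True)
class ConservedPosition:
    """A consensus residue expectation inside or flanking a box.

    ``gap_index`` addresses the inter-Cys gap the residue sits in
    (0..n_gaps-1), ``n_gaps`` for positions after the last Cys, and -1
    for positions before the first Cys. ``offset`` counts residues from
    the gap's 5' end (for -1: from the first Cys, backwards).
    ``residues`` is a string of acceptable amino acids.
    """

    gap_index: int
    offset: int
    residues: str
    weight: float = 1.0


@dataclass(frozen=True)
class BoxProfile:
    """A Cys-box consensus as a gap signature plus conserved-residue bonuses."""

    name: str
    gap_signature: tuple[int, ...]
    conserved: tuple[ConservedPosition, ...] = ()
    gap_tolerance: int = 2
    min_score: float = 6.0

    @property
    def n_cys(self) -> int:
        return len(self.gap_signature) + 1

    def __post_init__(self) -> None:
        if len(self.gap_signature) == 0:
            raise InvalidProfileError(
                f"profile {self.name!r} has an empty gap signature"
            )
        if self.gap_tolerance < 0:
            raise InvalidProfileError("gap_tolerance must be >= 0")


#: The 7-Cys building-block consensus CXCX3CSCPPGXCXCAXCP.
SEVEN_CYS_BOX = BoxProfile(
    name="seven_cys_box",
    gap_signature=(1, 3, 1, 4, 1, 2),
    conserved=(
        ConservedPosition(2, 0, "S", 1.0),    # the S of the central CSC
        ConservedPosition(3, 0, "P", 1.0),    # Pro doublet after 2nd CXC
        ConservedPosition(3, 1, "P", 1.0),
        ConservedPosition(3, 2, "G", 1.0),
        ConservedPosition(5, 0, "A", 1.0),
        ConservedPosition(6, 0, "P", 1.0),    # single Pro after the last Cys
        ConservedPosition(6, 1, "KRED", 0.5),  # charged residues flanking
        ConservedPosition(-1, 0, "KRED", 0.5),
    ),
)

DEFAULT_PROFILES: tuple[BoxProfile, ...] = (SEVEN_CYS_BOX,)


@dataclass(frozen=True)
class CysBox:
    """One placed box: coordinates are 1-based inclusive on the protein."""

    profile_name: str
    start: int
    end: int
    cys_positions: tuple[int, ...]
    score: float
    kind: BoxKind

    def as_zero_based(self) -> tuple[int, int]:
        """(start, end) as a 0-based half-open interval."""
        return self.start - 1, self.end

    @property
    def n_cys(self) -> int:
        return len(self.cys_positions)


@dataclass(frozen=True)
class ModuleArchitecture:
    """Ordered, non-overlapping boxes plus linkers and unassigned Cys."""

    record_id: str
    length: int
    boxes: tuple[CysBox, ...]
    linkers: tuple[tuple[int, int], ...]  # 1-based inclusive inter-box spans
    unassigned_cys: tuple[int, ...]
    totals: dict[str, int] = field(default_factory=dict)

    @property
    def total_cys(self) -> int:
        return sum(box.n_cys for box in self.boxes) + len(self.unassigned_cys)


def _bonus_score(seq: str, window: tuple[int, ...], profile: BoxProfile,
                 skip_gaps: frozenset[int] = frozenset()) -> float:
    """Conserved-residue bonus for a placed Cys window (1-based positions).

    Gaps listed in ``skip_gaps`` (those disturbed by a dropped mandatory
    Cys in degenerate matches) are not scored — their internal geometry
    is ambiguous once a Cys is missing.
    """
    n_gaps = len(window) - 1
    score = 0.0
    for cp in profile.conserved:
        gi = cp.gap_index
        if gi in skip_gaps:
            continue
        if gi == -1:
            pos = window[0] - 1 - cp.offset
        elif gi >= n_gaps:
            if gi > n_gaps:
                continue
            pos = window[-1] + 1 + cp.offset
        else:
            gap_len = window[gi + 1] - window[gi] - 1
            if cp.offset >= gap_len:
                continue
            pos = window[gi] + 1 + cp.offset
        if 1 <= pos <= len(seq) and seq[pos - 1] in cp.residues:
            score += cp.weight
    return score


def _full_matches(seq: str, cys: list[int], profile: BoxProfile) -> list[CysBox]:
    sig = profile.gap_signature
    tol = profile.gap_tolerance
    n = profile.n_cys
    out = []
    for i in range(len(cys) - n + 1):
        window = tuple(cys[i:i + n])
        gaps = [window[j + 1] - window[j] - 1 for j in range(n - 1)]
        if all(abs(g - s) <= tol for g, s in zip(gaps, sig)):
            score = float(n) + _bonus_score(seq, window, profile)
            kind: BoxKind = "seven_cys" if n == 7 else "other"
            out.append(CysBox(profile.name, window[0], window[-1], window,
                              score, kind))
    return out


def _degenerate_matches(seq: str, cys: list[int],
                        profile: BoxProfile) -> list[CysBox]:
    """Matches of the profile with exactly one mandatory Cys absent."""
    sig = list(profile.gap_signature)
    tol = profile.gap_tolerance
    n = profile.n_cys - 1  # Cys actually present
    best: dict[tuple[int, ...], CysBox] = {}
    for drop in range(profile.n_cys):
        if drop == 0:
            dsig, skip = sig[1:], frozenset({-1})
        elif drop == profile.n_cys - 1:
            dsig, skip = sig[:-1], frozenset({len(sig) - 1, len(sig)})
        else:
            merged = sig[drop - 1] + 1 + sig[drop]
            dsig = sig[:drop - 1] + [merged] + sig[drop + 1:]
            skip = frozenset({drop - 1, drop})
        for i in range(len(cys) - n + 1):
            window = tuple(cys[i:i + n])
            gaps = [window[j + 1] - window[j] - 1 for j in range(n - 1)]
            if all(abs(g - s) <= tol for g, s in zip(gaps, dsig)):
                score = float(n) + _bonus_score(seq, window, profile, skip)
                kind: BoxKind = "six_cys" if profile.n_cys == 7 else "other"
                box = CysBox(profile.name, window[0], window[-1], window,
                             score, kind)
                prev = best.get(window)
                if prev is None or box.score > prev.score:
                    best[window] = box
    return list(best.values())


def scan_boxes(record: ProteinRecord, profiles: Iterable[BoxProfile] = DEFAULT_PROFILES,
               include_degenerate: bool = False) -> list[CysBox]:
    """All placements of every profile scoring at least its ``min_score``.

    Placements may overlap; ordering is deterministic by
    (start, -score, end). A window is matched when every inter-Cys gap
    lies within ``gap_tolerance`` of the profile's signature.
    """
    profiles = list(profiles)
    if not profiles:
        raise InvalidProfileError("at least one profile is required")
    seq = record.sequence
    cys = cys_positions(seq)
    candidates: list[CysBox] = []
    for profile in profiles:
        candidates.extend(_full_matches(seq, cys, profile))
        if include_degenerate:
            candidates.extend(_degenerate_matches(seq, cys, profile))
    candidates = [c for c in candidates if c.score >= min(
        p.min_score for p in profiles if p.name == c.profile_name)]
    candidates.sort(key=lambda b: (b.start, -b.score, b.end))
    return candidates


def _select_optimal(candidates: list[CysBox]) -> tuple[float, tuple[CysBox, ...]]:
    """Maximum-total-score non-overlapping subset, deterministic ties.

    Weighted interval scheduling by memoized recursion over candidates
    sorted by (start, -score, end). Ties in total score break toward the
    lexicographically smallest sequence of (start, -score, span length),
    i.e. leftmost start first, then higher score, then shorter box.
    """
    cands = sorted(candidates, key=lambda b: (b.start, -b.score, b.end))
    n = len(cands)

    @lru_cache(maxsize=None)
    def solve(i: int) -> tuple[float, tuple[int, ...]]:
        if i >= n:
            return 0.0, ()
        # option 1: skip candidate i
        best = solve(i + 1)
        # option 2: take candidate i, jump past overlaps
        j = i + 1
        while j < n and cands[j].start <= cands[i].end:
            j += 1
        take_score, take_idx = solve(j)
        take = (take_score + cands[i].score, (i,) + take_idx)
        if take[0] > best[0] + 1e-12:
            return take
        if best[0] > take[0] + 1e-12:
            return best
        # equal score: prefer the lexicographically smaller key sequence
        def keyseq(idx):
            return tuple((cands[k].start, -cands[k].score,
                          cands[k].end - cands[k].start) for k in idx)
        return take if keyseq(take[1]) <= keyseq(best[1]) else best

    total, idx = solve(0)
    solve.cache_clear()
    return total, tuple(cands[k] for k in idx)


def decompose(record: ProteinRecord,
              profiles: Iterable[BoxProfile] = DEFAULT_PROFILES,
              allow_degenerate: bool = True) -> ModuleArchitecture:
    """Segment a protein into an optimal non-overlapping set of Cys boxes.

    The segmentation maximizes total box score over all candidate
    placements (full matches, plus degenerate one-Cys-missing matches
    when ``allow_degenerate``). Cys outside every chosen box are
    reported as unassigned; the Cys-conservation invariant
    (sum of box Cys + unassigned = total Cys) holds on every input.
    """
    candidates = scan_boxes(record, profiles, include_degenerate=allow_degenerate)
    _, chosen = _select_optimal(candidates)
    chosen = tuple(sorted(chosen, key=lambda b: b.start))

    assigned = set()
    for box in chosen:
        assigned.update(box.cys_positions)
    unassigned = tuple(p for p in cys_positions(record.sequence)
                       if p not in assigned)

    linkers = []
    for left, right in zip(chosen, chosen[1:]):
        if right.start - left.end > 1:
            linkers.append((left.end + 1, right.start - 1))

    totals = {"seven_cys": 0, "six_cys": 0, "other": 0}
    for box in chosen:
        totals[box.kind] += 1

    return ModuleArchitecture(
        record_id=record.id,
        length=len(record.sequence),
        boxes=chosen,
        linkers=tuple(linkers),
        unassigned_cys=unassigned,
        totals=totals,
    )


def architecture_report(arch: ModuleArchitecture) -> dict:
    """JSON-ready architecture summary with stable field order."""
    return {
        "record_id": arch.record_id,
        "length": arch.length,
        "boxes": [
            {
                "index": i + 1,
                "kind": box.kind,
                "profile": box.profile_name,
                "start": box.start,
                "end": box.end,
                "n_cys": box.n_cys,
                "cys_positions": list(box.cys_positions),
                "score": round(box.score, 2),
            }
            for i, box in enumerate(arch.boxes)
        ],
        "linkers": [{"start": s, "end": e} for s, e in arch.linkers],
        "unassigned_cys": list(arch.unassigned_cys),
        "totals": dict(arch.totals),
        "summary": (
            f"7-Cys: {arch.totals.get('seven_cys', 0)}, "
            f"6-Cys: {arch.totals.get('six_cys', 0)}, "
            f"unassigned Cys: {len(arch.unassigned_cys)}"
        ),
    }


def render_report_text(report: dict) -> str:
    """Human-readable rendering of an architecture report."""
    lines = [f"architecture of {report['record_id']} ({report['length']} aa)"]
    for box in report["boxes"]:
        lines.append(
            f"  box {box['index']}: {box['kind']} {box['start']}-{box['end']}"
            f" ({box['n_cys']} Cys, score {box['score']})"
        )
    lines.append(f"  {report['summary']}")
    return "\n".join(lines)
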