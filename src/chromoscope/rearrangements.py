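"""Derivative-chromosome reconstruction from breakpoint junctions.

A chromothripsis event shatters one or a few chromosomes and religates the
pieces in scrambled order and orientation, producing derivative chromosomes
and, for the pieces left out, deletions.  This module reconstructs that
structure from the list of novel adjacencies (junctions):

* the reference is cut at every breakend position (`segment_reference`),
* a breakpoint graph is built whose nodes are segment extremities and whose
  edges are surviving reference adjacencies plus the novel junction
  adjacencies (`assemble_derivatives`),
* derivative chromosomes are the maximal telomere-to-telomere paths of that
  graph; segments on no such path are reported as deleted fragments,
* a coordinate map provides reference <-> derivative liftover
  (`build_coordinate_map`, `liftover`).

Breakend encoding
-----------------
A breakend is ``(chrom, pos, side)`` with ``pos`` a 0-based cut coordinate
(between bases) and ``side`` naming the retained flank::

    side = "left"            side = "right"
    ...====|                        |====...
           pos                      pos

i.e. ``side="left"`` keeps the sequence left of ``pos`` and joins it to the
partner; ``side="right"`` keeps the sequence starting at ``pos``.  In BEDPE
input the strand column carries the side ("+" = left flank retained, "-" =
right flank) and the breakend position is the interval end.

The model is copy-number neutral: every segment is used at most once, so
duplication junctions (an extremity claimed by two adjacencies) are rejected
with an explicit error rather than silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

from .util import natural_chrom_key

Side = Literal["left", "right"]
Orientation = Literal["forward", "reverse"]

FORWARD: Orientation = "forward"
REVERSE: Orientation = "reverse"


class RearrangementError(ValueError):
    """Base class for inconsistent junction sets."""


class ConflictingJunctionsError(RearrangementError):
    """An extremity is claimed by two adjacencies (unsupported duplication)."""


class CircularDerivativeError(RearrangementError):
    """A closed path without telomeres (circular chromosomes are out of scope)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Breakend:
    chrom: str
    pos: int
    side: Side

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        mark = "<|" if self.side == "left" else "|>"
        return f"{self.chrom}:{self.pos}{mark}"


@dataclass(frozen=True)
class BreakendJunction:
    """One novel adjacency between two oriented reference loci."""

    id: str
    chrom_a: str
    pos_a: int
    side_a: Side
    chrom_b: str
    pos_b: int
    side_b: Side

    def __post_init__(self) -> None:
        if self.pos_a < 0 or self.pos_b < 0:
            raise ValueError(f"junction {self.id}: negative breakend position")
        if (self.chrom_a, self.pos_a, self.side_a) == (self.chrom_b, self.pos_b, self.side_b):
            raise ValueError(f"junction {self.id}: both breakends are identical")

    @property
    def end_a(self) -> Breakend:
        return Breakend(self.chrom_a, self.pos_a, self.side_a)

    @property
    def end_b(self) -> Breakend:
        return Breakend(self.chrom_b, self.pos_b, self.side_b)


@dataclass(frozen=True)
class GenomeSegment:
    """0-based half-open reference interval produced by the segmentation."""

    chrom: str
    start: int
    end: int
    segment_id: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid segment {self.chrom}:{self.start}-{self.end}")
        if not self.segment_id:
            object.__setattr__(self, "segment_id", f"{self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class DerivativeChromosome:
    """Ordered, oriented list of reference segments."""

    name: str
    parts: list[tuple[str, Orientation]]
    dominant_chrom: str = ""

    def length(self, segments: Mapping[str, GenomeSegment]) -> int:
        return sum(segments[sid].length for sid, _ in self.parts)


@dataclass
class RearrangementSet:
    junctions: list[BreakendJunction]
    segments: list[GenomeSegment]
    derivatives: list[DerivativeChromosome]
    deleted: list[GenomeSegment]
    chrom_lengths: dict[str, int]

    def segments_by_id(self) -> dict[str, GenomeSegment]:
        return {s.segment_id: s for s in self.segments}

    def derivative_lengths(self) -> dict[str, int]:
        by_id = self.segments_by_id()
        return {d.name: d.length(by_id) for d in self.derivatives}

    def deleted_length(self) -> int:
        return sum(s.length for s in self.deleted)

    def breakend_positions(self) -> dict[str, set[int]]:
        """All junction breakend positions per chromosome."""
        out: dict[str, set[int]] = {}
        for j in self.junctions:
            out.setdefault(j.chrom_a, set()).add(j.pos_a)
            out.setdefault(j.chrom_b, set()).add(j.pos_b)
        return out

    def validate_mass_conservation(self) -> None:
        total = sum(self.derivative_lengths().values()) + self.deleted_length()
        ref = sum(self.chrom_lengths.values())
        if total != ref:
            raise RearrangementError(
                f"mass conservation violated: derivatives+deleted={total}, reference={ref}"
            )


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------


def segment_reference(
    junctions: Sequence[BreakendJunction], chrom_lengths: Mapping[str, int]
) -> list[GenomeSegment]:
    """Cut every chromosome at each distinct breakend position.

    Chromosomes without breakends yield a single whole-chromosome segment.
    The result tiles every chromosome exactly (no gaps, no overlaps).
    """
    cuts: dict[str, set[int]] = {c: set() for c in chrom_lengths}
    for j in junctions:
        for chrom, pos in ((j.chrom_a, j.pos_a), (j.chrom_b, j.pos_b)):
            if chrom not in chrom_lengths:
                raise RearrangementError(
                    f"junction {j.id}: chromosome {chrom!r} not in chromosome lengths"
                )
            if not (0 < pos < chrom_lengths[chrom]):
                raise RearrangementError(
                    f"junction {j.id}: breakend {chrom}:{pos} outside chromosome "
                    f"(length {chrom_lengths[chrom]})"
                )
            cuts[chrom].add(pos)
    segments: list[GenomeSegment] = []
    for chrom in sorted(chrom_lengths, key=natural_chrom_key):
        bounds = [0, *sorted(cuts[chrom]), chrom_lengths[chrom]]
        for a, b in zip(bounds[:-1], bounds[1:]):
            segments.append(GenomeSegment(chrom, a, b))
    return segments


# ---------------------------------------------------------------------------
# breakpoint graph assembly
# ---------------------------------------------------------------------------

_L = "L"  # left extremity of a segment (at segment.start)
_R = "R"  # right extremity (at segment.end)


def assemble_derivatives(
    junctions: Sequence[BreakendJunction],
    segments: Sequence[GenomeSegment] | None = None,
    chrom_lengths: Mapping[str, int] | None = None,
) -> RearrangementSet:
    """Assemble derivative chromosomes from the breakpoint graph.

    Nodes are segment extremities.  Edges are (a) reference adjacencies
    between neighbouring segments whose shared breakend position is not used
    by any junction, and (b) novel adjacencies from the junctions.
    Derivatives are the maximal telomere-to-telomere paths; segments on no
    such path become deleted fragments (maximal reference-adjacent runs are
    merged).  Naming and whole-derivative orientation follow a deterministic
    sorted rule, so identical inputs give identical outputs.
    """
    if segments is None:
        if chrom_lengths is None:
            raise ValueError("provide either segments or chrom_lengths")
        segments = segment_reference(junctions, chrom_lengths)
    segments = list(segments)
    if chrom_lengths is None:
        chrom_lengths = {}
        for s in segments:
            chrom_lengths[s.chrom] = max(chrom_lengths.get(s.chrom, 0), s.end)

    by_chrom: dict[str, list[GenomeSegment]] = {}
    for s in segments:
        by_chrom.setdefault(s.chrom, []).append(s)
    for chrom, segs in by_chrom.items():
        segs.sort(key=lambda s: s.start)
        if segs[0].start != 0 or segs[-1].end != chrom_lengths[chrom]:
            raise RearrangementError(f"segments do not tile chromosome {chrom}")
        for a, b in zip(segs[:-1], segs[1:]):
            if a.end != b.start:
                raise RearrangementError(f"segments do not tile chromosome {chrom} at {a.end}")

    junction_positions: dict[str, set[int]] = {}
    for j in junctions:
        junction_positions.setdefault(j.chrom_a, set()).add(j.pos_a)
        junction_positions.setdefault(j.chrom_b, set()).add(j.pos_b)

    # locate the segment extremity a breakend attaches to
    left_at: dict[tuple[str, int], GenomeSegment] = {}  # segment ending at pos
    right_at: dict[tuple[str, int], GenomeSegment] = {}  # segment starting at pos
    for s in segments:
        left_at[(s.chrom, s.end)] = s
        right_at[(s.chrom, s.start)] = s

    def extremity_of(end: Breakend, jid: str) -> tuple[str, str]:
        if end.side == "left":
            seg = left_at.get((end.chrom, end.pos))
        else:
            seg = right_at.get((end.chrom, end.pos))
        if seg is None:
            raise RearrangementError(
                f"junction {jid}: no segment boundary at breakend {end.chrom}:{end.pos} "
                f"(was the reference segmented with these junctions?)"
            )
        return (seg.segment_id, _R if end.side == "left" else _L)

    adjacency: dict[tuple[str, str], tuple[tuple[str, str], str]] = {}

    def add_edge(u: tuple[str, str], v: tuple[str, str], label: str) -> None:
        for node in (u, v):
            if node in adjacency:
                raise ConflictingJunctionsError(
                    f"extremity {node[0]}/{node[1]} claimed by both {adjacency[node][1]!r} "
                    f"and {label!r}: duplications are not supported by the copy-number-"
                    f"neutral model"
                )
        adjacency[u] = (v, label)
        adjacency[v] = (u, label)

    for j in junctions:
        add_edge(extremity_of(j.end_a, j.id), extremity_of(j.end_b, j.id), f"junction {j.id}")

    for chrom, segs in by_chrom.items():
        used = junction_positions.get(chrom, set())
        for a, b in zip(segs[:-1], segs[1:]):
            if a.end not in used:
                add_edge((a.segment_id, _R), (b.segment_id, _L), f"reference {chrom}:{a.end}")

    telomeres: list[tuple[str, str]] = []
    for chrom in sorted(by_chrom, key=natural_chrom_key):
        segs = by_chrom[chrom]
        telomeres.append((segs[0].segment_id, _L))
        telomeres.append((segs[-1].segment_id, _R))
    telomere_set = set(telomeres)

    seg_index = {s.segment_id: s for s in segments}
    visited: set[str] = set()
    paths: list[list[tuple[str, Orientation]]] = []

    for tel in telomeres:
        sid, ext = tel
        if sid in visited:
            continue
        parts: list[tuple[str, Orientation]] = []
        node = tel
        while True:
            sid, ext = node
            visited.add(sid)
            orient: Orientation = FORWARD if ext == _L else REVERSE
            parts.append((sid, orient))
            exit_node = (sid, _R if ext == _L else _L)
            if exit_node in telomere_set and len(parts) >= 1 and exit_node != tel:
                break
            nxt = adjacency.get(exit_node)
            if nxt is None:
                # loose end that is not a reference telomere: the path cannot
                # reach a second telomere, so its segments are lost material.
                break
            node = nxt[0]
        # keep only telomere-to-telomere paths; others fall through to deleted
        last_sid, last_orient = parts[-1]
        last_exit = (last_sid, _R if last_orient == FORWARD else _L)
        if last_exit in telomere_set:
            paths.append(parts)
        else:
            for sid, _ in parts:
                visited.discard(sid)

    # anything not on a telomere-to-telomere path is deleted; a remaining
    # fully-connected component with no telomere would be circular -> error
    remaining = [s for s in segments if s.segment_id not in visited]
    for s in remaining:
        left = (s.segment_id, _L)
        if left in adjacency:
            # walk the component; if we come back, it is a cycle
            start = left
            node = adjacency[start][0]
            steps = 0
            while steps <= 2 * len(segments):
                sid, ext = node
                exit_node = (sid, _R if ext == _L else _L)
                if exit_node == start:
                    raise CircularDerivativeError(
                        f"circular derivative involving segment {s.segment_id}: "
                        f"circular chromosomes are out of scope"
                    )
                nxt = adjacency.get(exit_node)
                if nxt is None:
                    break
                node = nxt[0]
                steps += 1

    deleted = _merge_deleted(remaining, junction_positions)

    derivatives = _normalize_and_name(paths, seg_index)
    rset = RearrangementSet(
        junctions=list(junctions),
        segments=segments,
        derivatives=derivatives,
        deleted=deleted,
        chrom_lengths=dict(chrom_lengths),
    )
    rset.validate_mass_conservation()
    return rset


def _merge_deleted(
    remaining: Sequence[GenomeSegment], junction_positions: Mapping[str, set[int]]
) -> list[GenomeSegment]:
    """Merge reference-adjacent lost segments into maximal deleted fragments."""
    out: list[GenomeSegment] = []
    by_chrom: dict[str, list[GenomeSegment]] = {}
    for s in remaining:
        by_chrom.setdefault(s.chrom, []).append(s)
    for chrom in sorted(by_chrom, key=natural_chrom_key):
        segs = sorted(by_chrom[chrom], key=lambda s: s.start)
        used = junction_positions.get(chrom, set())
        cur = segs[0]
        for s in segs[1:]:
            if s.start == cur.end and s.start not in used:
                cur = GenomeSegment(chrom, cur.start, s.end)
            else:
                out.append(cur)
                cur = s
        out.append(cur)
    return out


def _normalize_and_name(
    paths: list[list[tuple[str, Orientation]]], seg_index: Mapping[str, GenomeSegment]
) -> list[DerivativeChromosome]:
    def part_key(parts: list[tuple[str, Orientation]]) -> tuple:
        first = seg_index[parts[0][0]]
        return (natural_chrom_key(first.chrom), first.start, parts[0][1] == REVERSE)

    normalized = []
    for parts in paths:
        flipped = [(sid, FORWARD if o == REVERSE else REVERSE) for sid, o in reversed(parts)]
        normalized.append(min(parts, flipped, key=part_key))
    normalized.sort(key=part_key)

    derivatives = []
    for i, parts in enumerate(normalized, start=1):
        content: dict[str, int] = {}
        for sid, _ in parts:
            seg = seg_index[sid]
            content[seg.chrom] = content.get(seg.chrom, 0) + seg.length
        dominant = max(sorted(content, key=natural_chrom_key), key=lambda c: content[c])
        first_chrom = seg_index[parts[0][0]].chrom
        derivatives.append(
            DerivativeChromosome(
                name=f"der{i}_{first_chrom}", parts=list(parts), dominant_chrom=dominant
            )
        )
    return derivatives


# ---------------------------------------------------------------------------
# coordinate map and liftover
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MapBlock:
    der_name: str
    der_start: int
    der_end: int
    chrom: str
    ref_start: int
    ref_end: int
    orientation: Orientation


@dataclass
class LiftoverResult:
    name: str | None
    pos: int | None
    orientation: Orientation | None
    deleted: bool = False


class CoordinateMap:
    """Bijective map between non-deleted reference positions and derivatives.

    Derivative coordinates are cumulative sums of part lengths; reverse parts
    map with coordinate reflection: der offset i in a reverse block of
    reference [s, e) maps to reference base e - 1 - i.
    """

    def __init__(self, rearrangement: RearrangementSet):
        self.rearrangement = rearrangement
        by_id = rearrangement.segments_by_id()
        self.blocks: list[MapBlock] = []
        self.der_lengths: dict[str, int] = {}
        for der in rearrangement.derivatives:
            offset = 0
            for sid, orient in der.parts:
                seg = by_id[sid]
                self.blocks.append(
                    MapBlock(der.name, offset, offset + seg.length, seg.chrom, seg.start, seg.end, orient)
                )
                offset += seg.length
            self.der_lengths[der.name] = offset

        self.deleted: dict[str, list[tuple[int, int]]] = {}
        for s in rearrangement.deleted:
            self.deleted.setdefault(s.chrom, []).append((s.start, s.end))
        for iv in self.deleted.values():
            iv.sort()

        # vectorised indices
        self._ref: dict[str, dict[str, np.ndarray]] = {}
        by_chrom: dict[str, list[MapBlock]] = {}
        for b in self.blocks:
            by_chrom.setdefault(b.chrom, []).append(b)
        self._der_names = sorted(self.der_lengths)
        name_idx = {n: i for i, n in enumerate(self._der_names)}
        for chrom, bl in by_chrom.items():
            bl.sort(key=lambda b: b.ref_start)
            self._ref[chrom] = {
                "start": np.array([b.ref_start for b in bl]),
                "end": np.array([b.ref_end for b in bl]),
                "der": np.array([name_idx[b.der_name] for b in bl]),
                "der_start": np.array([b.der_start for b in bl]),
                "rev": np.array([b.orientation == REVERSE for b in bl]),
            }
        self._der: dict[str, dict[str, np.ndarray]] = {}
        by_der: dict[str, list[MapBlock]] = {}
        for b in self.blocks:
            by_der.setdefault(b.der_name, []).append(b)
        self._chrom_names = sorted({b.chrom for b in self.blocks}, key=natural_chrom_key)
        chrom_idx = {c: i for i, c in enumerate(self._chrom_names)}
        for name, bl in by_der.items():
            bl.sort(key=lambda b: b.der_start)
            self._der[name] = {
                "start": np.array([b.der_start for b in bl]),
                "end": np.array([b.der_end for b in bl]),
                "chrom": np.array([chrom_idx[b.chrom] for b in bl]),
                "ref_start": np.array([b.ref_start for b in bl]),
                "ref_end": np.array([b.ref_end for b in bl]),
                "rev": np.array([b.orientation == REVERSE for b in bl]),
            }

    # -- vectorised primitives ------------------------------------------------

    def ref_to_der_many(
        self, chrom: str, pos: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Map reference positions to (der index, der pos, reverse?, deleted?).

        Der index refers to ``self.derivative_names``; deleted positions get
        index -1.  Raises for positions outside the chromosome.
        """
        pos = np.asarray(pos, dtype=np.int64)
        length = self.rearrangement.chrom_lengths.get(chrom)
        if length is None:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if np.any((pos < 0) | (pos >= length)):
            raise ValueError(f"position out of range on {chrom}")
        idx = np.full(pos.shape, -1, dtype=np.int64)
        der_pos = np.full(pos.shape, -1, dtype=np.int64)
        rev = np.zeros(pos.shape, dtype=bool)
        tab = self._ref.get(chrom)
        if tab is not None and len(tab["start"]):
            i = np.searchsorted(tab["start"], pos, side="right") - 1
            ok = (i >= 0) & (pos < tab["end"][np.maximum(i, 0)])
            ii = i[ok]
            offs = pos[ok] - tab["start"][ii]
            fwd = tab["der_start"][ii] + offs
            bwd = tab["der_start"][ii] + (tab["end"][ii] - tab["start"][ii] - 1 - offs)
            der_pos[ok] = np.where(tab["rev"][ii], bwd, fwd)
            idx[ok] = tab["der"][ii]
            rev[ok] = tab["rev"][ii]
        deleted = idx < 0
        return idx, der_pos, rev, deleted

    def der_to_ref_many(
        self, der_name: str, pos: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Map derivative positions to (chrom index, ref pos, reverse?)."""
        pos = np.asarray(pos, dtype=np.int64)
        if der_name not in self._der:
            raise KeyError(f"unknown derivative {der_name!r}")
        if np.any((pos < 0) | (pos >= self.der_lengths[der_name])):
            raise ValueError(f"position out of range on {der_name}")
        tab = self._der[der_name]
        i = np.searchsorted(tab["start"], pos, side="right") - 1
        offs = pos - tab["start"][i]
        fwd = tab["ref_start"][i] + offs
        bwd = tab["ref_end"][i] - 1 - offs
        ref_pos = np.where(tab["rev"][i], bwd, fwd)
        return tab["chrom"][i], ref_pos, tab["rev"][i]

    @property
    def derivative_names(self) -> list[str]:
        return list(self._der_names)

    @property
    def chrom_names(self) -> list[str]:
        return list(self._chrom_names)


def build_coordinate_map(rearrangement: RearrangementSet) -> CoordinateMap:
    return CoordinateMap(rearrangement)


def liftover(
    cmap: CoordinateMap,
    name: str,
    pos: int,
    direction: Literal["ref2der", "der2ref"] = "ref2der",
) -> LiftoverResult:
    """Map a single position between reference and derivative coordinates.

    Deleted reference positions return an explicit deleted marker rather
    than an error; out-of-range positions raise.
    """
    if direction == "ref2der":
        idx, der_pos, rev, deleted = cmap.ref_to_der_many(name, np.array([pos]))
        if deleted[0]:
            return LiftoverResult(None, None, None, deleted=True)
        return LiftoverResult(
            cmap.derivative_names[idx[0]], int(der_pos[0]), REVERSE if rev[0] else FORWARD
        )
    elif direction == "der2ref":
        cidx, ref_pos, rev = cmap.der_to_ref_many(name, np.array([pos]))
        return LiftoverResult(
            cmap.chrom_names[cidx[0]], int(ref_pos[0]), REVERSE if rev[0] else FORWARD
        )
    raise ValueError(f"unknown direction {direction!r}")


# ---------------------------------------------------------------------------
# identity helper
# ---------------------------------------------------------------------------


def identity_rearrangement(chrom_lengths: Mapping[str, int]) -> RearrangementSet:
    """The trivial rearrangement: each chromosome is its own derivative."""
    return assemble_derivatives([], chrom_lengths=chrom_lengths)


# ---------------------------------------------------------------------------
# BEDPE junction IO
# ---------------------------------------------------------------------------


def read_junctions(path) -> list[BreakendJunction]:
    """Read breakend junctions from a BEDPE file.

    Columns: chrom1 start1 end1 chrom2 start2 end2 name score strand1 strand2.
    Strand "+" means the flank LEFT of the breakend is retained, "-" the
    right flank; the breakend position is the interval end.  Missing strands
    are rejected because the adjacency would be ambiguous.
    """
    junctions: list[BreakendJunction] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 10:
                raise ValueError(
                    f"{path}:{lineno}: malformed BEDPE line (expected >= 10 fields, "
                    f"got {len(fields)})"
                )
            c1, s1, e1, c2, s2, e2, name, _score, st1, st2 = fields[:10]
            if st1 not in "+-" or st2 not in "+-":
                raise ValueError(
                    f"{path}:{lineno}: missing or invalid strand ({st1!r}, {st2!r}); "
                    f"strands are required to orient the adjacency"
                )
            try:
                pos_a, pos_b = int(e1), int(e2)
                int(s1), int(s2)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
            if name in seen:
                raise ValueError(f"{path}:{lineno}: duplicate junction id {name!r}")
            seen.add(name)
            junctions.append(
                BreakendJunction(
                    id=name,
                    chrom_a=c1,
                    pos_a=pos_a,
                    side_a="left" if st1 == "+" else "right",
                    chrom_b=c2,
                    pos_b=pos_b,
                    side_b="left" if st2 == "+" else "right",
                )
            )
    return junctions


def write_junctions_bedpe(junctions: Iterable[BreakendJunction], path) -> None:
    """Write junctions as BEDPE (inverse of :func:`read_junctions`)."""
    with open(path, "w") as fh:
        for j in junctions:
            st1 = "+" if j.side_a == "left" else "-"
            st2 = "+" if j.side_b == "left" else "-"
            fh.write(
                f"{j.chrom_a}\t{j.pos_a - 1}\t{j.pos_a}\t"
                f"{j.chrom_b}\t{j.pos_b - 1}\t{j.pos_b}\t{j.id}\t.\t{st1}\t{st2}\n"
            )


# ---------------------------------------------------------------------------
# AGP v2.1 IO
# ---------------------------------------------------------------------------


def write_agp(rearrangement: RearrangementSet, path) -> None:
    """Write derivative structures as AGP v2.1.

    One AGP object per derivative (component ids are the reference segment
    ids, orientation +/-); deleted fragments are emitted as their own
    single-component objects named ``deleted_<i>`` so the file round-trips
    to the full rearrangement set (minus junction provenance).
    """
    by_id = rearrangement.segments_by_id()
    with open(path, "w") as fh:
        fh.write("##agp-version\t2.1\n")
        for der in rearrangement.derivatives:
            offset = 0
            for n, (sid, orient) in enumerate(der.parts, start=1):
                seg = by_id[sid]
                fh.write(
                    f"{der.name}\t{offset + 1}\t{offset + seg.length}\t{n}\tW\t"
                    f"{sid}\t{seg.start + 1}\t{seg.end}\t"
                    f"{'+' if orient == FORWARD else '-'}\n"
                )
                offset += seg.length
        for i, seg in enumerate(rearrangement.deleted, start=1):
            fh.write(
                f"deleted_{i}\t1\t{seg.length}\t1\tW\t"
                f"{seg.segment_id}\t{seg.start + 1}\t{seg.end}\t+\n"
            )


def read_agp(path, chrom_lengths: Mapping[str, int]) -> RearrangementSet:
    """Read an AGP file written by :func:`write_agp`."""
    derivatives: dict[str, list[tuple[str, Orientation]]] = {}
    deleted: list[GenomeSegment] = []
    segments: dict[str, GenomeSegment] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 9 or f[4] != "W":
                raise ValueError(f"{path}:{lineno}: unsupported AGP line")
            obj, _, _, _, _, comp, beg, end, orient = f
            chrom = comp.rsplit(":", 1)[0]
            seg = GenomeSegment(chrom, int(beg) - 1, int(end), segment_id=comp)
            segments[comp] = seg
            if obj.startswith("deleted_"):
                deleted.append(seg)
            else:
                derivatives.setdefault(obj, []).append(
                    (comp, FORWARD if orient == "+" else REVERSE)
                )
    ders = [
        DerivativeChromosome(name=name, parts=parts) for name, parts in derivatives.items()
    ]
    seg_index = {s.segment_id: s for s in segments.values()}
    for d in ders:
        content: dict[str, int] = {}
        for sid, _ in d.parts:
            seg = seg_index[sid]
            content[seg.chrom] = content.get(seg.chrom, 0) + seg.length
        d.dominant_chrom = max(sorted(content, key=natural_chrom_key), key=lambda c: content[c])
    rset = RearrangementSet(
        junctions=[],
        segments=sorted(segments.values(), key=lambda s: (natural_chrom_key(s.chrom), s.start)),
        derivatives=ders,
        deleted=deleted,
        chrom_lengths=dict(chrom_lengths),
    )
    rset.validate_mass_conservation()
    return rset


def write_deleted_bed(rearrangement: RearrangementSet, path) -> None:
    """BED3 of the deleted fragments."""
    with open(path, "w") as fh:
        for seg in rearrangement.deleted:
            fh.write(f"{seg.chrom}\t{seg.start}\t{seg.end}\n")
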