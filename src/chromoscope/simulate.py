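"""Synthetic-data generators with recorded ground truth.

Every pipeline stage is exercised on data from this module, emulating the
study design the package targets: a patient with germline chromothripsis
and both healthy parents, profiled in blood, iPSC, and iPSC-derived neural
progenitors (NPC), plus chromosome-conformation assays of the derivative
chromosomes.

Three generators are provided:

* :func:`simulate_chromothripsis` — random shatter-and-religate events with
  deletions and inversions, emitting junctions consistent with the planted
  derivative structures so reconstruction is an exact round trip;
* :func:`fig1_like` — a deterministic preset reproducing the published
  topology of the study patient: 17 junctions over 4 chromosomes, 4
  derivative chromosomes, 4 deleted fragments (10 genes on three of them),
  6 truncated genes including one same-strand and one opposite-strand
  gene-gene junction, 67 genes within 1 Mb of the rearrangement (60
  expressed), 13 disrupted TADs and 5 deleted TAD boundaries, and an
  NPC-only positional-effect gene.  Chromosome sizes are scaled down to
  desk scale (48 Mb total) while distance thresholds keep their real
  values, so gene placement respects the 1-Mb window;
* count/contact samplers layered on a rearrangement: negative-binomial trio
  counts with planted dosage, fragment, and positional effects
  (variance = mu + alpha*mu^2, alpha default 0.05), and Poisson 4C/Hi-C
  signal built from power-law distance decay with the patient modelled as a
  50:50 mixture of the unaffected and the rearranged allele.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .contacts import ContactMatrix, ViewpointProfile, normalize_profile
from .effects import GeneModel
from .rearrangements import (
    FORWARD,
    REVERSE,
    BreakendJunction,
    CoordinateMap,
    DerivativeChromosome,
    GenomeSegment,
    Orientation,
    RearrangementSet,
    write_junctions_bedpe,
)
from .util import natural_chrom_key

MB = 1_000_000
KB = 1_000


# ---------------------------------------------------------------------------
# configuration and truth containers
# ---------------------------------------------------------------------------


@dataclass
class SimulationConfig:
    """Knobs of the random chromothripsis generator.

    Defaults mirror the scale of the emulated event: a handful of
    chromosomes, up to ~a dozen breakpoints, a quarter of the internal
    fragments lost.
    """

    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 12 * MB, "chr2": 9 * MB, "chr3": 10 * MB}
    )
    n_breakpoints: int = 12
    n_chromosomes_affected: int = 3
    deletion_fraction: float = 0.25
    n_deleted: int | None = None  # exact count; None = Bernoulli per fragment
    nb_dispersion: float = 0.05
    baseline_mean: float = 200.0
    decay_alpha: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.deletion_fraction <= 1:
            raise ValueError("deletion_fraction must be in [0, 1]")
        if self.n_breakpoints < 0:
            raise ValueError("n_breakpoints must be >= 0")


@dataclass
class GroundTruth:
    """What the generator planted, for recovery checks."""

    rearrangement: RearrangementSet
    gene_categories: dict[str, str] = field(default_factory=dict)
    causal_genes: list[str] = field(default_factory=list)
    expression_multipliers: dict[str, dict[str, float]] = field(default_factory=dict)
    # gene (or gene|part fragment id) -> cell type -> patient multiplier
    enhancer_calls: dict[str, str] = field(default_factory=dict)
    n_tads_disrupted: int | None = None
    n_boundaries_deleted: int | None = None

    def to_json(self) -> str:
        payload = {
            "derivatives": [
                {"name": d.name, "parts": d.parts} for d in self.rearrangement.derivatives
            ],
            "deleted": [
                [s.chrom, s.start, s.end] for s in self.rearrangement.deleted
            ],
            "gene_categories": self.gene_categories,
            "causal_genes": self.causal_genes,
            "expression_multipliers": self.expression_multipliers,
            "enhancer_calls": self.enhancer_calls,
            "n_tads_disrupted": self.n_tads_disrupted,
            "n_boundaries_deleted": self.n_boundaries_deleted,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# random chromothripsis events
# ---------------------------------------------------------------------------


def _merge_oriented_runs(
    parts: list[tuple[str, int, int, Orientation]]
) -> list[tuple[str, int, int, Orientation]]:
    """Collapse consecutive parts religated in reference configuration."""
    out = [parts[0]]
    for chrom, s, e, o in parts[1:]:
        pc, ps, pe, po = out[-1]
        if chrom == pc and o == po:
            if o == FORWARD and ps < pe == s:
                out[-1] = (chrom, ps, e, o)
                continue
            if o == REVERSE and e == ps:
                out[-1] = (chrom, s, pe, o)
                continue
        out.append((chrom, s, e, o))
    return out


def _junction_between(
    prev: tuple[str, int, int, Orientation],
    nxt: tuple[str, int, int, Orientation],
    jid: str,
) -> BreakendJunction:
    pc, ps, pe, po = prev
    nc, ns, ne, no = nxt
    if po == FORWARD:
        pos_a, side_a = pe, "left"
    else:
        pos_a, side_a = ps, "right"
    if no == FORWARD:
        pos_b, side_b = ns, "right"
    else:
        pos_b, side_b = ne, "left"
    return BreakendJunction(jid, pc, pos_a, side_a, nc, pos_b, side_b)


def _normalize_truth_parts(
    paths: list[list[tuple[str, int, int, Orientation]]]
) -> list[tuple[str, list[tuple[str, int, int, Orientation]]]]:
    """Apply the documented orientation/naming rule to planted part lists."""

    def flip(parts):
        return [
            (c, s, e, FORWARD if o == REVERSE else REVERSE) for c, s, e, o in reversed(parts)
        ]

    def key(parts):
        c, s, _e, o = parts[0]
        return (natural_chrom_key(c), s, o == REVERSE)

    normalized = sorted((min(p, flip(p), key=key) for p in paths), key=key)
    return [
        (f"der{i}_{parts[0][0]}", parts) for i, parts in enumerate(normalized, start=1)
    ]


def simulate_chromothripsis(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[list[BreakendJunction], GroundTruth]:
    """Shatter, drop, shuffle, religate; emit junctions plus planted truth.

    The emitted junction set reconstructs exactly to the planted derivative
    structures: cut positions whose two flanks are religated in reference
    configuration are removed from the truth (they leave no junction), and
    reference-adjacent lost fragments merge into single deleted fragments.
    """
    chroms = sorted(config.chrom_lengths, key=natural_chrom_key)
    n_aff = min(config.n_chromosomes_affected, len(chroms))
    affected = sorted(
        rng.choice(chroms, size=n_aff, replace=False).tolist(), key=natural_chrom_key
    )

    # distribute cuts over affected chromosomes
    cuts: dict[str, list[int]] = {c: [] for c in affected}
    for _ in range(config.n_breakpoints):
        c = affected[rng.integers(len(affected))]
        while True:
            p = int(rng.integers(1, config.chrom_lengths[c]))
            if p not in cuts[c]:
                cuts[c].append(p)
                break
    for c in cuts:
        cuts[c].sort()

    first: dict[str, tuple] = {}
    last: dict[str, tuple] = {}
    internal: list[tuple] = []
    for c in affected:
        bounds = [0, *cuts[c], config.chrom_lengths[c]]
        segs = [(c, a, b) for a, b in zip(bounds[:-1], bounds[1:])]
        first[c] = segs[0]
        last[c] = segs[-1] if len(segs) > 1 else None
        internal.extend(segs[1:-1])

    if config.n_deleted is not None:
        if config.n_deleted > len(internal):
            raise ValueError(
                f"cannot delete {config.n_deleted} fragments: only {len(internal)} internal"
            )
        drop_idx = set(
            rng.choice(len(internal), size=config.n_deleted, replace=False).tolist()
        )
    else:
        drop_idx = {i for i in range(len(internal)) if rng.random() < config.deletion_fraction}
    lost = [internal[i] for i in sorted(drop_idx)]
    kept = [internal[i] for i in range(len(internal)) if i not in drop_idx]

    # shuffle and orient the retained internal fragments, then deal them out
    order = rng.permutation(len(kept))
    oriented = [
        (*kept[i], FORWARD if rng.random() < 0.5 else REVERSE) for i in order
    ]
    # only chromosomes that were actually cut can absorb shuffled fragments
    hosts = [c for c in affected if last[c] is not None]
    pieces: list[list] = [[] for _ in hosts]
    if hosts:
        splits = sorted(rng.integers(0, len(oriented) + 1, size=len(hosts) - 1).tolist())
        prev = 0
        for k, s in enumerate([*splits, len(oriented)]):
            pieces[k] = oriented[prev:s]
            prev = s

    paths = []
    for c, middle in zip(hosts, pieces):
        path = [(*first[c], FORWARD), *middle, (*last[c], FORWARD)]
        paths.append(_merge_oriented_runs(path))
    # uncut chromosomes ride along as identity derivatives
    for c in chroms:
        if c not in hosts:
            paths.append([(c, 0, config.chrom_lengths[c], FORWARD)])

    named = _normalize_truth_parts(paths)

    junctions: list[BreakendJunction] = []
    for name, parts in named:
        for prev_part, nxt_part in zip(parts[:-1], parts[1:]):
            junctions.append(
                _junction_between(prev_part, nxt_part, f"jun_{len(junctions) + 1:03d}")
            )

    junction_pos: dict[str, set[int]] = {}
    for j in junctions:
        junction_pos.setdefault(j.chrom_a, set()).add(j.pos_a)
        junction_pos.setdefault(j.chrom_b, set()).add(j.pos_b)

    # merge reference-adjacent lost fragments (their shared cut leaves no junction)
    deleted: list[GenomeSegment] = []
    for c in affected:
        runs = [seg for seg in lost if seg[0] == c]
        runs.sort(key=lambda s: s[1])
        i = 0
        while i < len(runs):
            _, s, e = runs[i]
            while (
                i + 1 < len(runs)
                and runs[i + 1][1] == e
                and e not in junction_pos.get(c, set())
            ):
                e = runs[i + 1][2]
                i += 1
            deleted.append(GenomeSegment(c, s, e))
            i += 1

    segments = [
        GenomeSegment(c, s, e)
        for name, parts in named
        for c, s, e, _o in parts
    ] + deleted
    segments.sort(key=lambda s: (natural_chrom_key(s.chrom), s.start))

    derivatives = [
        DerivativeChromosome(
            name=name,
            parts=[(GenomeSegment(c, s, e).segment_id, o) for c, s, e, o in parts],
            dominant_chrom=max(
                {c for c, *_ in parts},
                key=lambda cc: sum(e - s for c, s, e, _ in parts if c == cc),
            ),
        )
        for name, parts in named
    ]
    truth_set = RearrangementSet(
        junctions=junctions,
        segments=segments,
        derivatives=derivatives,
        deleted=deleted,
        chrom_lengths=dict(config.chrom_lengths),
    )
    truth_set.validate_mass_conservation()
    return junctions, GroundTruth(rearrangement=truth_set)


# ---------------------------------------------------------------------------
# the fig1-topology preset
# ---------------------------------------------------------------------------

FIG1_CHROM_LENGTHS = {"chr1": 14 * MB, "chr3": 12 * MB, "chr7": 14 * MB, "chr12": 8 * MB}

_FIG1_SEGMENTS: dict[str, tuple[str, int, int]] = {
    # chr1
    "A1": ("chr1", 0, 2_000_000), "A2": ("chr1", 2_000_000, 3_200_000),
    "A3": ("chr1", 3_200_000, 5_000_000), "A4": ("chr1", 5_000_000, 6_100_000),
    "A5": ("chr1", 6_100_000, 8_400_000), "A6": ("chr1", 8_400_000, 14_000_000),
    # chr3
    "B1": ("chr3", 0, 1_500_000), "B2": ("chr3", 1_500_000, 3_000_000),
    "B3": ("chr3", 3_000_000, 4_600_000), "B4": ("chr3", 4_600_000, 6_200_000),
    "B5": ("chr3", 6_200_000, 7_400_000), "B6": ("chr3", 7_400_000, 12_000_000),
    # chr7
    "C1": ("chr7", 0, 1_800_000), "C2": ("chr7", 1_800_000, 3_100_000),
    "C3": ("chr7", 3_100_000, 4_000_000), "C4": ("chr7", 4_000_000, 5_500_000),
    "C5": ("chr7", 5_500_000, 7_000_000), "C6": ("chr7", 7_000_000, 8_200_000),
    "C7": ("chr7", 8_200_000, 9_000_000), "C8": ("chr7", 9_000_000, 14_000_000),
    # chr12
    "D1": ("chr12", 0, 1_200_000), "D2": ("chr12", 1_200_000, 2_500_000),
    "D3": ("chr12", 2_500_000, 3_900_000), "D4": ("chr12", 3_900_000, 5_000_000),
    "D5": ("chr12", 5_000_000, 8_000_000),
}

_FIG1_DELETED = ("A4", "B5", "C3", "C6")

_FIG1_DERIVATIVES: list[list[tuple[str, Orientation]]] = [
    [("A1", FORWARD), ("C4", REVERSE), ("B3", FORWARD), ("D3", REVERSE), ("A6", FORWARD)],
    [("B1", FORWARD), ("A3", REVERSE), ("C7", FORWARD), ("B2", REVERSE), ("B6", FORWARD)],
    [("C1", FORWARD), ("D2", REVERSE), ("A5", FORWARD), ("C5", FORWARD), ("B4", REVERSE),
     ("C8", FORWARD)],
    [("D1", FORWARD), ("A2", REVERSE), ("D4", REVERSE), ("C2", FORWARD), ("D5", FORWARD)],
]

# special genes: id -> (chrom, start, end, strand, exons or None)
_FIG1_SPECIAL_GENES: dict[str, tuple] = {
    # truncated six; FOXP1L x HDAC9L meet in opposite orientation (read-through
    # candidate), ETV1L x DPYDL collinearly (canonical fusion candidate)
    "FOXP1L": ("chr1", 1_700_000, 2_600_000, "+",
               [(1_700_000, 1_712_000), (1_800_000, 1_812_000), (1_950_000, 1_962_000),
                (2_050_000, 2_062_000), (2_200_000, 2_212_000), (2_350_000, 2_362_000),
                (2_480_000, 2_492_000), (2_580_000, 2_592_000)]),
    "HDAC9L": ("chr7", 5_200_000, 6_000_000, "+", None),
    "ETV1L": ("chr3", 4_200_000, 5_000_000, "-", None),
    "DPYDL": ("chr7", 8_600_000, 9_500_000, "+", None),
    "AGMOL": ("chr7", 1_500_000, 2_200_000, "+", None),
    "BRK6L": ("chr12", 2_100_000, 2_800_000, "+", None),
    # intact positional genes on inverted fragments
    "TWIST1L": ("chr7", 4_300_000, 4_350_000, "+", None),
    "CNTN3L": ("chr3", 2_000_000, 2_100_000, "+", None),
    # ten genes on three deleted fragments
    "DEL01": ("chr1", 5_050_000, 5_250_000, "+", None),
    "DEL02": ("chr1", 5_300_000, 5_500_000, "-", None),
    "DEL03": ("chr1", 5_550_000, 5_750_000, "+", None),
    "DEL04": ("chr1", 5_800_000, 6_000_000, "+", None),
    "DEL05": ("chr3", 6_250_000, 6_500_000, "+", None),
    "DEL06": ("chr3", 6_600_000, 6_850_000, "-", None),
    "DEL07": ("chr3", 6_950_000, 7_300_000, "+", None),
    "DEL08": ("chr7", 3_150_000, 3_350_000, "+", None),
    "DEL09": ("chr7", 3_450_000, 3_650_000, "-", None),
    "DEL10": ("chr7", 3_700_000, 3_950_000, "+", None),
}

FIG1_VIEWPOINT = ("chr7", 4_325_000)  # inside TWIST1L, on the inverted C4 fragment

_FIG1_TADS = [
    ("chr1", 500_000, 2_400_000), ("chr1", 2_440_000, 3_500_000),
    ("chr1", 3_540_000, 4_800_000), ("chr1", 4_840_000, 5_800_000),
    ("chr1", 5_840_000, 6_500_000), ("chr1", 6_540_000, 8_000_000),
    ("chr1", 8_040_000, 8_900_000), ("chr1", 8_940_000, 10_000_000),
    ("chr3", 800_000, 1_800_000), ("chr3", 1_840_000, 2_600_000),
    ("chr3", 2_640_000, 3_400_000), ("chr3", 3_440_000, 5_000_000),
    ("chr3", 5_040_000, 6_400_000), ("chr3", 6_440_000, 7_000_000),
    ("chr3", 7_040_000, 7_800_000), ("chr3", 7_840_000, 9_000_000),
    ("chr7", 500_000, 6_200_000), ("chr7", 6_500_000, 7_500_000),
    ("chr7", 7_540_000, 8_200_000), ("chr7", 8_240_000, 9_000_000),
    ("chr7", 9_040_000, 10_000_000),
    ("chr12", 1_000_000, 4_000_000), ("chr12", 4_040_000, 5_000_000),
    ("chr12", 5_040_000, 6_500_000),
]

_FIG1_BOUNDARIES = [
    ("chr1", 2_400_000, 2_440_000), ("chr1", 3_500_000, 3_540_000),
    ("chr1", 4_800_000, 4_840_000), ("chr1", 5_800_000, 5_840_000),  # deleted (A4)
    ("chr1", 6_500_000, 6_540_000), ("chr1", 8_000_000, 8_040_000),
    ("chr1", 8_900_000, 8_940_000),
    ("chr3", 1_800_000, 1_840_000), ("chr3", 2_600_000, 2_640_000),
    ("chr3", 3_400_000, 3_440_000), ("chr3", 5_000_000, 5_040_000),
    ("chr3", 6_400_000, 6_440_000),  # deleted (B5)
    ("chr3", 7_000_000, 7_040_000),  # deleted (B5)
    ("chr3", 7_800_000, 7_840_000),
    ("chr7", 3_400_000, 3_440_000),  # deleted (C3)
    ("chr7", 6_300_000, 6_340_000),
    ("chr7", 7_500_000, 7_540_000),  # deleted (C6)
    ("chr7", 8_200_000, 8_240_000), ("chr7", 9_000_000, 9_040_000),
    ("chr12", 4_000_000, 4_040_000), ("chr12", 5_000_000, 5_040_000),
]

_FIG1_ENHANCERS = [
    # (name, chrom, start, end, activity, truth call for the TWIST1L viewpoint)
    ("E_MES1", "chr7", 5_600_000, 5_640_000, "mesodermal", "loss"),
    ("E_MES2", "chr7", 6_500_000, 6_540_000, "mesodermal", "loss"),
    ("E_MES3", "chr7", 7_300_000, 7_340_000, "mesodermal", "loss"),
    ("E_CIS", "chr7", 4_500_000, 4_530_000, "mesodermal", "unchanged"),
    ("E_NEU1", "chr1", 1_800_000, 1_840_000, "neural", "gain"),
    ("E_NEU2", "chr3", 3_300_000, 3_340_000, "neural", "gain"),
]

# patient-specific expression multipliers (per cell type; "*" = all)
_FIG1_EFFECTS: dict[str, dict[str, float]] = {
    "DEL01": {"*": 0.5}, "DEL02": {"*": 0.5}, "DEL03": {"*": 0.5}, "DEL04": {"*": 0.5},
    # DEL05-08 dosage-compensated at the RNA level, DEL09/10 not expressed
    "FOXP1L|5prime": {"*": 1.6},
    "FOXP1L|3prime": {"*": 0.5},
    "HDAC9L|5prime": {"*": 0.85}, "HDAC9L|3prime": {"*": 0.85},
    "ETV1L|5prime": {"*": 0.7}, "ETV1L|3prime": {"*": 0.7},
    "DPYDL|5prime": {"*": 1.0}, "DPYDL|3prime": {"*": 1.3},
    "TWIST1L": {"NPC": 4.0},
}

_FIG1_BASELINES: dict[str, float] = {
    "FOXP1L": 1200.0, "HDAC9L": 600.0, "ETV1L": 450.0, "DPYDL": 500.0,
    "AGMOL": 0.3, "BRK6L": 300.0, "TWIST1L": 400.0, "CNTN3L": 350.0,
    "DEL01": 300.0, "DEL02": 250.0, "DEL03": 400.0, "DEL04": 350.0,
    "DEL05": 300.0, "DEL06": 250.0, "DEL07": 350.0, "DEL08": 300.0,
    "DEL09": 0.3, "DEL10": 0.3,
}

N_FIG1_NOT_EXPRESSED_BYSTANDERS = 4  # proximal genes silent in every cell type
N_FIG1_PROXIMAL_BYSTANDERS = 49  # + TWIST1L + CNTN3L = 51 proximal
N_FIG1_DISTAL_BYSTANDERS = 333


@dataclass
class Fig1Fixture:
    """The deterministic preset bundle (randomness only enters the samplers)."""

    rearrangement: RearrangementSet
    junctions: list[BreakendJunction]
    genes: list[GeneModel]
    tads: pd.DataFrame
    boundaries: pd.DataFrame
    enhancers: pd.DataFrame
    viewpoint: tuple[str, int]
    truth: GroundTruth
    baselines: dict[str, float]
    effect_multipliers: dict[str, dict[str, float]]

    @property
    def cmap(self) -> CoordinateMap:
        return CoordinateMap(self.rearrangement)


def _default_exons(start: int, end: int, n: int) -> list[tuple[int, int]]:
    length = end - start
    size = max(200, length // (3 * n))
    step = (length - size) // max(n - 1, 1)
    return [(start + i * step, start + i * step + size) for i in range(n)]


def _fig1_rearrangement() -> tuple[RearrangementSet, list[BreakendJunction]]:
    seg = {k: GenomeSegment(*v) for k, v in _FIG1_SEGMENTS.items()}
    paths = [
        [(seg[k].chrom, seg[k].start, seg[k].end, o) for k, o in parts]
        for parts in _FIG1_DERIVATIVES
    ]
    named = _normalize_truth_parts(paths)
    junctions: list[BreakendJunction] = []
    for _name, parts in named:
        for a, b in zip(parts[:-1], parts[1:]):
            junctions.append(_junction_between(a, b, f"jun_{len(junctions) + 1:03d}"))
    deleted = [seg[k] for k in _FIG1_DELETED]
    segments = sorted(
        [*(seg[k] for k in _FIG1_SEGMENTS)], key=lambda s: (natural_chrom_key(s.chrom), s.start)
    )
    derivatives = [
        DerivativeChromosome(
            name=name,
            parts=[(GenomeSegment(c, s, e).segment_id, o) for c, s, e, o in parts],
            dominant_chrom=max(
                {c for c, *_ in parts},
                key=lambda cc: sum(e - s for c, s, e, _ in parts if c == cc),
            ),
        )
        for name, parts in named
    ]
    rset = RearrangementSet(
        junctions=junctions,
        segments=segments,
        derivatives=derivatives,
        deleted=deleted,
        chrom_lengths=dict(FIG1_CHROM_LENGTHS),
    )
    rset.validate_mass_conservation()
    return rset, junctions


def _fig1_bystanders(rset: RearrangementSet, special: list[GeneModel]) -> list[GeneModel]:
    cuts: dict[str, list[int]] = {}
    for j in rset.junctions:
        cuts.setdefault(j.chrom_a, []).append(j.pos_a)
        cuts.setdefault(j.chrom_b, []).append(j.pos_b)
    cuts = {c: sorted(set(p)) for c, p in cuts.items()}
    occupied: dict[str, list[tuple[int, int]]] = {}
    for g in special:
        occupied.setdefault(g.chrom, []).append((g.start, g.end))
    for s in rset.deleted:
        occupied.setdefault(s.chrom, []).append((s.start, s.end))

    def gap(chrom: str, s: int, e: int) -> float:
        pos = np.array(cuts.get(chrom, []))
        if pos.size == 0:
            return np.inf
        if ((pos > s) & (pos < e)).any():
            return 0.0
        left = pos[pos <= s]
        right = pos[pos >= e]
        d = np.inf
        if left.size:
            d = min(d, s - left[-1])
        if right.size:
            d = min(d, right[0] - e)
        return float(d)

    def free(chrom: str, s: int, e: int) -> bool:
        return all(not (s < oe and os_ < e) for os_, oe in occupied.get(chrom, []))

    chroms = sorted(FIG1_CHROM_LENGTHS, key=natural_chrom_key)
    proximal_cand: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    distal_cand: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    for chrom in chroms:
        length = FIG1_CHROM_LENGTHS[chrom]
        for start in range(100_000, length - 40_000, 40_000):
            end = start + 30_000
            if not free(chrom, start, end):
                continue
            g = gap(chrom, start, end)
            if 30_000 <= g <= 850_000:
                proximal_cand[chrom].append((start, end))
                occupied.setdefault(chrom, []).append((start, end))
            elif g >= 1_200_000:
                distal_cand[chrom].append((start, end))
                occupied.setdefault(chrom, []).append((start, end))

    def round_robin(cands: dict[str, list], n: int) -> list[tuple[str, int, int]]:
        out = []
        i = 0
        while len(out) < n:
            progressed = False
            for chrom in chroms:
                if i < len(cands[chrom]):
                    out.append((chrom, *cands[chrom][i]))
                    progressed = True
                    if len(out) == n:
                        break
            if not progressed:
                raise RuntimeError("not enough candidate gene positions")
            i += 1
        return out

    genes = []
    picked = round_robin(proximal_cand, N_FIG1_PROXIMAL_BYSTANDERS) + round_robin(
        distal_cand, N_FIG1_DISTAL_BYSTANDERS
    )
    picked.sort(key=lambda t: (natural_chrom_key(t[0]), t[1]))
    for i, (chrom, s, e) in enumerate(picked, start=1):
        gid = f"G{i:04d}"
        strand = "+" if i % 2 else "-"
        genes.append(GeneModel(gid, gid, chrom, s, e, strand, _default_exons(s, e, 4 + i % 4)))
    return genes


def fig1_like() -> Fig1Fixture:
    """Build the deterministic fig1-topology fixture with full ground truth."""
    rset, junctions = _fig1_rearrangement()
    special = []
    for gid, (chrom, s, e, strand, exons) in _FIG1_SPECIAL_GENES.items():
        if exons is None:
            exons = _default_exons(s, e, 4)
        special.append(GeneModel(gid, gid, chrom, s, e, strand, exons))
    bystanders = _fig1_bystanders(rset, special)
    genes = sorted(special + bystanders, key=lambda g: (natural_chrom_key(g.chrom), g.start))

    truncated = {"FOXP1L", "HDAC9L", "ETV1L", "DPYDL", "AGMOL", "BRK6L"}
    deleted_genes = {f"DEL{i:02d}" for i in range(1, 11)}
    categories: dict[str, str] = {}
    cuts: dict[str, np.ndarray] = {
        c: np.array(sorted(p)) for c, p in rset.breakend_positions().items()
    }
    for g in genes:
        if g.gene_id in deleted_genes:
            categories[g.gene_id] = "deleted"
        elif g.gene_id in truncated:
            categories[g.gene_id] = "truncated"
        else:
            pos = cuts.get(g.chrom, np.array([]))
            left = pos[pos <= g.start]
            right = pos[pos >= g.end]
            d = min(
                (g.start - left[-1]) if left.size else np.inf,
                (right[0] - g.end) if right.size else np.inf,
            )
            categories[g.gene_id] = "proximal" if d <= 1_000_000 else "distal"

    baselines = dict(_FIG1_BASELINES)
    # bystander baselines are part of the fixture: drawn once from a fixed
    # stream so the preset is deterministic regardless of the caller's seed.
    # Floored at 10x the expression threshold so the planted expressed /
    # not-expressed labels are unambiguous at any sampling seed.
    base_rng = np.random.default_rng(799_001)
    for g in genes:
        if g.gene_id not in baselines:
            baselines[g.gene_id] = max(
                100.0, float(np.exp(base_rng.normal(np.log(200.0), 0.6)))
            )
    proximal_ids = [
        g.gene_id for g in genes
        if categories[g.gene_id] == "proximal" and g.gene_id not in _FIG1_BASELINES
    ]
    for gid in proximal_ids[:N_FIG1_NOT_EXPRESSED_BYSTANDERS]:
        baselines[gid] = 0.3

    truth = GroundTruth(
        rearrangement=rset,
        gene_categories=categories,
        causal_genes=sorted(truncated | deleted_genes | {"TWIST1L"}),
        expression_multipliers=dict(_FIG1_EFFECTS),
        enhancer_calls={name: call for name, *_rest, call in _FIG1_ENHANCERS},
        n_tads_disrupted=13,
        n_boundaries_deleted=5,
    )
    return Fig1Fixture(
        rearrangement=rset,
        junctions=junctions,
        genes=genes,
        tads=pd.DataFrame(_FIG1_TADS, columns=["chrom", "start", "end"]),
        boundaries=pd.DataFrame(_FIG1_BOUNDARIES, columns=["chrom", "start", "end"]),
        enhancers=pd.DataFrame(
            [(c, s, e, n, a) for n, c, s, e, a, _t in _FIG1_ENHANCERS],
            columns=["chrom", "start", "end", "name", "activity"],
        ),
        viewpoint=FIG1_VIEWPOINT,
        truth=truth,
        baselines=baselines,
        effect_multipliers=dict(_FIG1_EFFECTS),
    )


# ---------------------------------------------------------------------------
# trio count simulation
# ---------------------------------------------------------------------------

CELL_TYPES = ("blood", "iPSC", "NPC")


def trio_sample_sheet() -> pd.DataFrame:
    """The emulated sequencing layout: blood plus iPSC lines at days 0/7/10.

    Patient lines L14/L15, father L23 (with a technical replicate at day 0)
    and L32, mother L30; day 0 is the iPSC state, days 7 and 10 the NPC
    state.
    """
    rows = []
    for who in ("patient", "father", "mother"):
        rows.append((f"{who}_blood", who, "blood", f"{who}_blood", "-"))
    lines = [
        ("patient", "L14"), ("patient", "L15"),
        ("father", "L23"), ("father", "L32"), ("mother", "L30"),
    ]
    for who, line in lines:
        rows.append((f"{who}_{line}_d0", who, "iPSC", line, "0"))
    rows.append(("father_L23_d0_tr", "father", "iPSC", "L23", "0"))  # technical replicate
    for day in ("7", "10"):
        for who, line in lines:
            rows.append((f"{who}_{line}_d{day}", who, "NPC", line, day))
    return pd.DataFrame(rows, columns=["sample", "individual", "cell_type", "replicate", "day"])


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB with variance mu + dispersion * mu^2 (Poisson when dispersion ~ 0)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 1e-12:
        return rng.poisson(mean)
    n = 1.0 / dispersion
    p = n / (n + np.maximum(mean, 1e-12))
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    out[pos] = rng.negative_binomial(n, p[pos])
    return out


def simulate_trio_counts(
    genes: Sequence[GeneModel],
    baselines: Mapping[str, float],
    effect_multipliers: Mapping[str, Mapping[str, float]],
    rng: np.random.Generator,
    samples: pd.DataFrame | None = None,
    dispersion: float = 0.05,
    cell_type_programs: Mapping[str, Mapping[str, float]] | None = None,
    fragment_bounds: Mapping[str, Mapping[str, tuple[int, int]]] | None = None,
    library_sd: float = 0.15,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw exon- and gene-level NB counts for the trio layout.

    ``effect_multipliers`` maps gene ids (or ``gene|part`` fragment ids,
    resolved through ``fragment_bounds``) to per-cell-type patient
    multipliers ("*" applies to every cell type).  Library size factors are
    log-normal per sample; a technical replicate shares its line's
    biological mean and differs only by its library factor and counting
    noise.  Returns (gene_counts, exon_counts, sample_sheet).
    """
    if samples is None:
        samples = trio_sample_sheet()
    if cell_type_programs is None:
        cell_type_programs = {}
    lib = np.exp(rng.normal(0.0, library_sd, size=len(samples)))

    exon_index: list[str] = []
    exon_base: list[float] = []
    exon_gene: list[str] = []
    exon_mult_keys: list[tuple[str, str | None]] = []
    for g in genes:
        exons = g.exons or [(g.start, g.end)]
        total_len = sum(e - s for s, e in exons)
        for idx, (s, e) in enumerate(exons):
            exon_index.append(f"{g.gene_id}|e{idx}")
            exon_gene.append(g.gene_id)
            exon_base.append(baselines.get(g.gene_id, 0.0) * (e - s) / total_len)
            part = None
            if fragment_bounds and g.gene_id in fragment_bounds:
                mid = (s + e) // 2
                for part_name, (fs, fe) in fragment_bounds[g.gene_id].items():
                    if fs <= mid < fe:
                        part = part_name
                        break
            exon_mult_keys.append((g.gene_id, part))

    base = np.array(exon_base)
    counts = np.zeros((len(exon_index), len(samples)), dtype=np.int64)
    for j, row in enumerate(samples.itertuples(index=False)):
        mean = base.copy()
        prog = cell_type_programs.get(row.cell_type, {})
        if prog:
            mean = mean * np.array([prog.get(g, 1.0) for g in exon_gene])
        if row.individual == "patient":
            mult = np.ones(len(exon_index))
            for i, (gid, part) in enumerate(exon_mult_keys):
                for key in ((f"{gid}|{part}",) if part else ()) + (gid,):
                    eff = effect_multipliers.get(key)
                    if eff is not None:
                        mult[i] = eff.get(row.cell_type, eff.get("*", 1.0))
                        break
            mean = mean * mult
        counts[:, j] = _nb_draw(rng, mean * lib[j], dispersion)

    exon_counts = pd.DataFrame(counts, index=exon_index, columns=samples["sample"])
    gene_counts = exon_counts.groupby(pd.Index(exon_gene, name="gene"), sort=True).sum()
    gene_counts.index.name = None
    return gene_counts, exon_counts, samples.copy()


def fig1_cell_type_programs(fixture: "Fig1Fixture") -> dict[str, dict[str, float]]:
    """Cell-type expression programs for the fixture's background genes.

    Roughly a tenth of the distal background follows an iPSC program and a
    tenth an NPC program (days 7/10 nearly identical), giving the sample
    clustering real structure; the TWIST1L-like positional gene is silent
    in blood for every individual, as observed for the emulated gene.
    Programs are confined to distal genes so the near-rearrangement panel
    keeps its planted per-cell-type truth.
    """
    programs: dict[str, dict[str, float]] = {"blood": {}, "iPSC": {}, "NPC": {}}
    distal = [
        g.gene_id
        for g in fixture.genes
        if fixture.truth.gene_categories[g.gene_id] == "distal"
    ]
    for i, gid in enumerate(distal):
        if i % 10 == 3:
            programs["iPSC"][gid] = 3.0
            programs["NPC"][gid] = 0.5
            programs["blood"][gid] = 0.3
        elif i % 10 == 7:
            programs["iPSC"][gid] = 0.5
            programs["NPC"][gid] = 3.0
            programs["blood"][gid] = 0.3
    programs["blood"]["TWIST1L"] = 0.005
    programs["blood"]["CNTN3L"] = 0.01
    return programs


def fig1_fragment_bounds() -> dict[str, dict[str, tuple[int, int]]]:
    """Reference intervals of the 5'/3' parts of the six truncated genes."""
    cuts = {
        "FOXP1L": 2_000_000, "HDAC9L": 5_500_000, "ETV1L": 4_600_000,
        "DPYDL": 9_000_000, "AGMOL": 1_800_000, "BRK6L": 2_500_000,
    }
    out: dict[str, dict[str, tuple[int, int]]] = {}
    for gid, cut in cuts.items():
        chrom, s, e, strand, _ = _FIG1_SPECIAL_GENES[gid]
        left, right = (s, cut), (cut, e)
        if strand == "+":
            out[gid] = {"5prime": left, "3prime": right}
        else:
            out[gid] = {"3prime": left, "5prime": right}
    return out


# ---------------------------------------------------------------------------
# contact simulation (4C profiles and Hi-C matrices)
# ---------------------------------------------------------------------------


def _reference_decay(
    chrom_lengths: Mapping[str, int],
    viewpoint: tuple[str, int],
    bin_size: int,
    alpha: float,
    trans_distance: float,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-bin expected contact for an unrearranged allele."""
    rows = []
    values = []
    vchrom, vpos = viewpoint
    trans_level = trans_distance ** (-alpha)
    for chrom in sorted(chrom_lengths, key=natural_chrom_key):
        nb = -(-chrom_lengths[chrom] // bin_size)
        for i in range(nb):
            start = i * bin_size
            rows.append((chrom, start, min(start + bin_size, chrom_lengths[chrom])))
            if chrom == vchrom:
                d = max(abs(start + bin_size // 2 - vpos), bin_size / 2)
                values.append(d ** (-alpha))
            else:
                values.append(trans_level)
    return pd.DataFrame(rows, columns=["chrom", "start", "end"]), np.array(values)


def _derivative_allele_decay(
    cmap: CoordinateMap,
    bins: pd.DataFrame,
    viewpoint: tuple[str, int],
    alpha: float,
    trans_distance: float,
) -> np.ndarray:
    """Expected contact of the rearranged allele, on reference bins."""
    vchrom, vpos = viewpoint
    vidx, vdpos, _vrev, vdel = cmap.ref_to_der_many(vchrom, np.array([vpos]))
    if vdel[0]:
        raise ValueError("viewpoint falls in a deleted fragment")
    vname = cmap.derivative_names[vidx[0]]
    vdpos = int(vdpos[0])
    trans_level = trans_distance ** (-alpha)
    values = np.zeros(len(bins))
    for chrom, grp in bins.groupby("chrom", sort=False):
        mids = np.minimum(
            ((grp["start"] + grp["end"]) // 2).to_numpy(),
            cmap.rearrangement.chrom_lengths[chrom] - 1,
        )
        idx, dpos, _rev, deleted = cmap.ref_to_der_many(chrom, mids)
        v = np.full(len(grp), trans_level)
        same = (idx >= 0) & (np.array(cmap.derivative_names, dtype=object)[np.maximum(idx, 0)] == vname)
        bin_size = int((grp["end"] - grp["start"]).max())
        d = np.maximum(np.abs(dpos - vdpos), bin_size / 2).astype(float)
        v[same] = d[same] ** (-alpha)
        v[deleted] = 0.0
        values[grp.index.to_numpy()] = v
    return values


def simulate_viewpoint_profiles(
    rset: RearrangementSet,
    viewpoint: tuple[str, int],
    rng: np.random.Generator,
    bin_size: int = 20_000,
    alpha: float = 1.0,
    depth: float = 300_000.0,
    trans_distance: float = 20 * MB,
    enhancers: pd.DataFrame | None = None,
    enhancer_boost: float = 3.0,
    mixture: float = 0.5,
) -> tuple[ViewpointProfile, ViewpointProfile]:
    """Poisson-sampled, normalized (patient, control) viewpoint profiles.

    Control is pure reference decay; the patient is a ``mixture`` blend of
    the rearranged allele (decay along its derivative, projected back to
    reference bins) and the unaffected allele.  Enhancer bins get a
    multiplicative contact boost on every allele carrying them.
    """
    cmap = CoordinateMap(rset)
    bins, ref_exp = _reference_decay(rset.chrom_lengths, viewpoint, bin_size, alpha, trans_distance)
    der_exp = _derivative_allele_decay(cmap, bins, viewpoint, alpha, trans_distance)
    if enhancers is not None:
        boost = np.ones(len(bins))
        for _, enh in enhancers.iterrows():
            hit = (
                (bins["chrom"] == enh.chrom)
                & (bins["start"] < enh.end)
                & (bins["end"] > enh.start)
            ).to_numpy()
            boost[hit] = enhancer_boost
        ref_exp = ref_exp * boost
        der_exp = der_exp * boost
    pat_exp = mixture * der_exp + (1.0 - mixture) * ref_exp

    def sample(expect: np.ndarray) -> ViewpointProfile:
        scale = depth / expect.sum()
        b = bins.copy()
        b["value"] = rng.poisson(expect * scale).astype(float)
        return normalize_profile(
            ViewpointProfile(viewpoint[0], viewpoint[1], b), target_total=1e6,
            exclusion_zone=10_000,
        )

    return sample(pat_exp), sample(ref_exp)


def simulate_contact_matrices(
    rset: RearrangementSet,
    rng: np.random.Generator,
    bin_size: int = 100_000,
    alpha: float = 1.0,
    depth: float = 2_000_000.0,
    trans_distance: float = 20 * MB,
    mixture: float = 0.5,
) -> tuple[ContactMatrix, ContactMatrix]:
    """Poisson-sampled (patient, control) all-vs-all contact matrices.

    Expected contact between two bins follows power-law decay in their
    separation on the chromosome (control) or on the derivative carrying
    them (rearranged allele); bins on different molecules sit at a flat
    trans level, deleted bins contribute nothing on the rearranged allele.
    """
    cmap = CoordinateMap(rset)
    chroms = sorted(rset.chrom_lengths, key=natural_chrom_key)
    layout = {c: rset.chrom_lengths[c] for c in chroms}
    nb = {c: -(-layout[c] // bin_size) for c in chroms}
    n = sum(nb.values())
    chrom_of = np.empty(n, dtype=object)
    mid = np.zeros(n, dtype=np.int64)
    i0 = 0
    for c in chroms:
        k = nb[c]
        chrom_of[i0:i0 + k] = c
        mid[i0:i0 + k] = np.minimum(np.arange(k) * bin_size + bin_size // 2, layout[c] - 1)
        i0 += k

    trans_level = trans_distance ** (-alpha)

    # reference allele expectation
    ref = np.full((n, n), trans_level)
    i0 = 0
    for c in chroms:
        k = nb[c]
        m = mid[i0:i0 + k].astype(float)
        d = np.abs(m[:, None] - m[None, :])
        np.maximum(d, bin_size / 2.0, out=d)
        ref[i0:i0 + k, i0:i0 + k] = d ** (-alpha)
        i0 += k

    # derivative allele expectation
    der_idx = np.full(n, -1, dtype=np.int64)
    der_pos = np.zeros(n, dtype=np.int64)
    i0 = 0
    for c in chroms:
        k = nb[c]
        idx, dpos, _rev, _deleted = cmap.ref_to_der_many(c, mid[i0:i0 + k])
        der_idx[i0:i0 + k] = idx
        der_pos[i0:i0 + k] = dpos
        i0 += k
    der = np.full((n, n), trans_level)
    same = (der_idx[:, None] == der_idx[None, :]) & (der_idx[:, None] >= 0)
    d = np.abs(der_pos[:, None] - der_pos[None, :]).astype(float)
    np.maximum(d, bin_size / 2.0, out=d)
    der = np.where(same, d ** (-alpha), der)
    lost = der_idx < 0
    der[lost, :] = 0.0
    der[:, lost] = 0.0

    pat = mixture * der + (1.0 - mixture) * ref

    def sample(expect: np.ndarray) -> ContactMatrix:
        scale = depth / np.triu(expect).sum()
        upper = rng.poisson(np.triu(expect * scale)).astype(float)
        full = upper + np.triu(upper, 1).T
        return ContactMatrix(bin_size, dict(layout), full)

    return sample(pat), sample(ref)


# ---------------------------------------------------------------------------
# focused screens used by the operating-characteristics experiments
# ---------------------------------------------------------------------------


def simulate_effect_screen(
    rng: np.random.Generator,
    n_genes: int = 2000,
    n_up: int = 100,
    n_down: int = 100,
    effect_fold: float = 2.0,
    baseline_mean: float = 200.0,
    dispersion: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, str]]:
    """Flat gene panel with planted patient effects, for sensitivity/FPR.

    Effect genes carry a ``effect_fold`` (or its reciprocal) patient
    multiplier; all other genes are null.  The sample layout mirrors the
    emulated NPC arm (patient 2 lines x 2 days, father 2 x 2, mother
    1 x 2).  Returns (counts, sample sheet, truth direction per gene).
    """
    gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    truth = {g: "none" for g in gene_ids}
    for g in gene_ids[:n_up]:
        truth[g] = "up"
    for g in gene_ids[n_up:n_up + n_down]:
        truth[g] = "down"
    samples = pd.DataFrame(
        [
            (f"{who}_{line}_d{day}", who, "NPC", line, day)
            for who, lines in (
                ("patient", ("L14", "L15")),
                ("father", ("L23", "L32")),
                ("mother", ("L30",)),
            )
            for line in lines
            for day in ("7", "10")
        ],
        columns=["sample", "individual", "cell_type", "replicate", "day"],
    )
    lib = np.exp(rng.normal(0.0, 0.15, size=len(samples)))
    mult = np.ones(n_genes)
    mult[:n_up] = effect_fold
    mult[n_up:n_up + n_down] = 1.0 / effect_fold
    counts = np.zeros((n_genes, len(samples)), dtype=np.int64)
    for j, row in enumerate(samples.itertuples(index=False)):
        mean = np.full(n_genes, baseline_mean)
        if row.individual == "patient":
            mean = mean * mult
        counts[:, j] = _nb_draw(rng, mean * lib[j], dispersion)
    return pd.DataFrame(counts, index=gene_ids, columns=samples["sample"]), samples, truth


def simulate_enhancer_relocation(
    rng: np.random.Generator,
    bin_size: int = 20_000,
    depth: float = 200_000.0,
    alpha: float = 1.0,
) -> tuple[ViewpointProfile, ViewpointProfile, pd.DataFrame, dict[str, str]]:
    """Reciprocal translocation moving enhancers across derivatives.

    The viewpoint stays on one derivative; a cluster of enhancers that was
    cis to it moves to the other derivative (expected loss under the 50:50
    mixture) and a cluster that was on the other chromosome becomes cis
    (expected gain); a control cluster stays put.  Distances change far
    more than 5-fold (cis megabases vs trans).  Breakpoints jitter per seed.
    """
    la, lb = 8 * MB, 8 * MB
    bp_a = int(rng.integers(190, 211)) * bin_size  # ~4 Mb, bin-aligned
    bp_b = int(rng.integers(190, 211)) * bin_size
    junctions = [
        BreakendJunction("t1", "chrA", bp_a, "left", "chrB", bp_b, "right"),
        BreakendJunction("t2", "chrA", bp_a, "right", "chrB", bp_b, "left"),
    ]
    from .rearrangements import assemble_derivatives

    rset = assemble_derivatives(junctions, chrom_lengths={"chrA": la, "chrB": lb})
    viewpoint = ("chrA", bp_a - 1 * MB)
    enh_rows = []
    truth: dict[str, str] = {}
    for i in range(3):  # was cis, now trans
        s = bp_a + 500_000 + i * 400_000
        enh_rows.append(("chrA", s, s + 40_000, f"LOSS{i}"))
        truth[f"LOSS{i}"] = "loss"
    for i in range(3):  # was trans, now cis at ~1.3-2.1 Mb
        s = bp_b + 300_000 + i * 400_000
        enh_rows.append(("chrB", s, s + 40_000, f"GAIN{i}"))
        truth[f"GAIN{i}"] = "gain"
    for i in range(2):  # stays with the viewpoint
        s = viewpoint[1] - 900_000 + i * 300_000
        enh_rows.append(("chrA", s, s + 40_000, f"STAY{i}"))
        truth[f"STAY{i}"] = "unchanged"
    enhancers = pd.DataFrame(enh_rows, columns=["chrom", "start", "end", "name"])
    pat, ctrl = simulate_viewpoint_profiles(
        rset, viewpoint, rng, bin_size=bin_size, alpha=alpha, depth=depth,
        enhancers=enhancers,
    )
    return pat, ctrl, enhancers, truth


# ---------------------------------------------------------------------------
# fixture export
# ---------------------------------------------------------------------------


def write_gtf(genes: Sequence[GeneModel], path) -> None:
    """Minimal GTF with gene and exon features (1-based closed on write)."""
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}"; gene_name "{g.name}";'
            fh.write(
                f"{g.chrom}\tchromoscope\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for s, e in g.exons:
                fh.write(
                    f"{g.chrom}\tchromoscope\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n"
                )


def write_fixture(fixture: Fig1Fixture, outdir, rng: np.random.Generator) -> dict[str, Path]:
    """Emit every input format the pipeline reads, plus the truth JSON."""
    from . import io as cio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "junctions": outdir / "junctions.bedpe",
        "chrom_sizes": outdir / "chrom.sizes",
        "genes_gtf": outdir / "genes.gtf",
        "genes_bed12": outdir / "genes.bed12",
        "tads": outdir / "tads.bed",
        "boundaries": outdir / "boundaries.bed",
        "enhancers": outdir / "enhancers.bed",
        "gene_counts": outdir / "gene_counts.tsv",
        "exon_counts": outdir / "exon_counts.tsv",
        "samples": outdir / "samples.tsv",
        "profile_patient": outdir / "viewpoint_patient.tsv",
        "profile_control": outdir / "viewpoint_control.tsv",
        "matrix_patient": outdir / "hic_patient.tsv",
        "matrix_control": outdir / "hic_control.tsv",
        "truth": outdir / "truth.json",
    }
    write_junctions_bedpe(fixture.junctions, paths["junctions"])
    cio.write_chrom_sizes(fixture.rearrangement.chrom_lengths, paths["chrom_sizes"])
    write_gtf(fixture.genes, paths["genes_gtf"])
    from .effects import write_genes_bed12

    write_genes_bed12(fixture.genes, paths["genes_bed12"])
    cio.write_bed(fixture.tads, paths["tads"])
    cio.write_bed(fixture.boundaries, paths["boundaries"])
    cio.write_bed(fixture.enhancers, paths["enhancers"])
    gene_counts, exon_counts, samples = simulate_trio_counts(
        fixture.genes, fixture.baselines, fixture.effect_multipliers, rng,
        cell_type_programs=fig1_cell_type_programs(fixture),
        fragment_bounds=fig1_fragment_bounds(),
    )
    cio.write_counts(gene_counts, paths["gene_counts"])
    cio.write_counts(exon_counts, paths["exon_counts"])
    cio.write_sample_sheet(samples, paths["samples"])
    pat, ctrl = simulate_viewpoint_profiles(
        fixture.rearrangement, fixture.viewpoint, rng, enhancers=fixture.enhancers
    )
    cio.write_profile(pat.bins, paths["profile_patient"])
    cio.write_profile(ctrl.bins, paths["profile_control"])
    mpat, mctrl = simulate_contact_matrices(fixture.rearrangement, rng)
    cio.write_dense_matrix(mpat.to_frame(), paths["matrix_patient"])
    cio.write_dense_matrix(mctrl.to_frame(), paths["matrix_control"])
    paths["truth"].write_text(fixture.truth.to_json())
    return paths
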