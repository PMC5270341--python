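"""Gene- and TAD-level consequences of a rearrangement.

Genes are classified relative to the reconstructed event with a documented
precedence (deleted > truncated > proximal > distal; fusion candidacy is a
flag on truncated genes):

* deleted   — gene body fully inside the union of deleted fragments,
* truncated — at least one breakend strictly inside the gene body (this
  includes genes straddling a deleted-fragment edge, whose removed part is
  marked deleted),
* proximal  — gap distance from the gene body to the nearest breakend is at
  most ``window`` (default 1 Mb),
* distal    — everything else.

A breakend exactly at a gene or TAD edge counts as outside (strict interior
rule).  Truncated genes are decomposed into 5'/internal/3' fragments by gene
strand, exons are assigned to fragments (split exons flagged and counted
once), and every junction whose two breakends both fall inside gene bodies
is evaluated for fusion configuration by orientation algebra: the two genes
read collinearly across the junction (canonical fusion candidate) or collide
in opposite orientation (read-through candidate).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .rearrangements import (
    BreakendJunction,
    CoordinateMap,
    GenomeSegment,
    RearrangementSet,
    liftover,
)
from .util import natural_chrom_key

Category = Literal["deleted", "truncated", "proximal", "distal"]
Part = Literal["5prime", "3prime", "internal"]
Configuration = Literal["same_strand", "opposite_strand"]


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------


@dataclass
class GeneModel:
    gene_id: str
    name: str
    chrom: str
    start: int
    end: int
    strand: Literal["+", "-"]
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"gene {self.gene_id}: invalid body interval")
        self.exons = sorted(self.exons)
        for s, e in self.exons:
            if s < self.start or e > self.end:
                raise ValueError(f"gene {self.gene_id}: exon outside gene body")
        for (s1, e1), (s2, e2) in zip(self.exons[:-1], self.exons[1:]):
            if s2 < e1:
                raise ValueError(f"gene {self.gene_id}: overlapping exons")


def read_genes_bed12(path) -> list[GeneModel]:
    """Gene models from BED12 (block fields give the exons)."""
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}:{lineno}: expected 12 BED columns")
            chrom, start, end, name, _score, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = [(start + o, start + o + s) for o, s in zip(starts, sizes)]
            genes.append(GeneModel(name, name, chrom, start, end, strand, exons))
    return genes


def read_genes_gtf(path) -> list[GeneModel]:
    """Gene models from GTF (1-based closed coordinates converted on read)."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique", disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genes = []
    for g in db.features_of_type("gene"):
        exons = [
            (e.start - 1, e.end)
            for e in db.children(g, featuretype="exon", order_by="start")
        ]
        gid = g.attributes.get("gene_id", [g.id])[0]
        gname = g.attributes.get("gene_name", [gid])[0]
        genes.append(GeneModel(gid, gname, g.seqid, g.start - 1, g.end, g.strand, exons))
    return genes


def write_genes_bed12(genes: Iterable[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            exons = g.exons or [(g.start, g.end)]
            sizes = ",".join(str(e - s) for s, e in exons)
            starts = ",".join(str(s - g.start) for s, _ in exons)
            fh.write(
                f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\t"
                f"{g.start}\t{g.end}\t0\t{len(exons)}\t{sizes}\t{starts}\n"
            )


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


@dataclass
class GeneFragment:
    gene_id: str
    part: Part
    start: int
    end: int
    exons: list[tuple[int, int, int, bool]] = field(default_factory=list)
    # (start, end, original exon index, split?)
    der_name: str | None = None
    der_start: int | None = None
    der_orientation: str | None = None
    deleted: bool = False

    @property
    def exon_count(self) -> int:
        """Distinct original exons touching this fragment."""
        return len({idx for _s, _e, idx, _split in self.exons})


@dataclass
class GeneEffect:
    gene_id: str
    category: Category
    distance_to_nearest_breakpoint: float
    fragments: list[GeneFragment] = field(default_factory=list)
    fusion_partners: list[tuple[str, Configuration]] = field(default_factory=list)


@dataclass
class FusionCandidate:
    junction_id: str
    gene_5: str
    gene_3: str
    configuration: Configuration


@dataclass
class GeneBreakendRecord:
    """A junction breakend inside a gene whose partner breakend is intergenic."""

    junction_id: str
    gene_id: str
    chrom: str
    pos: int
    side: str


def _breakends_per_chrom(rearrangement: RearrangementSet) -> dict[str, np.ndarray]:
    pos = rearrangement.breakend_positions()
    return {c: np.array(sorted(p)) for c, p in pos.items()}


def _gap_distance(start: int, end: int, positions: np.ndarray) -> float:
    """Gap between interval [start, end) and the nearest cut position."""
    if positions.size == 0:
        return math.inf
    left = positions[positions <= start]
    right = positions[positions >= end]
    inside = positions[(positions > start) & (positions < end)]
    if inside.size:
        return 0.0
    best = math.inf
    if left.size:
        best = min(best, float(start - left[-1]))
    if right.size:
        best = min(best, float(right[0] - end))
    # a breakend exactly at the edge gives gap 0 (touching)
    return best


def classify_genes(
    genes: Sequence[GeneModel],
    rearrangement: RearrangementSet,
    window: int = 1_000_000,
    cmap: CoordinateMap | None = None,
    on_unknown_chrom: Literal["warn", "error"] = "warn",
) -> list[GeneEffect]:
    """Classify every gene relative to the rearrangement.

    Categories follow the documented precedence; truncated genes carry their
    fragment decomposition.  Genes on chromosomes outside the rearrangement
    namespace are distal by definition (with a warning, or an error if
    requested).
    """
    cuts = _breakends_per_chrom(rearrangement)
    deleted_by_chrom: dict[str, list[GenomeSegment]] = {}
    for seg in rearrangement.deleted:
        deleted_by_chrom.setdefault(seg.chrom, []).append(seg)
    if cmap is None:
        cmap = CoordinateMap(rearrangement)

    effects = []
    for gene in genes:
        if gene.chrom not in rearrangement.chrom_lengths:
            msg = f"gene {gene.gene_id}: chromosome {gene.chrom!r} not in rearrangement"
            if on_unknown_chrom == "error":
                raise KeyError(msg)
            warnings.warn(msg + "; classified distal", stacklevel=2)
            effects.append(GeneEffect(gene.gene_id, "distal", math.inf))
            continue
        positions = cuts.get(gene.chrom, np.array([]))
        distance = _gap_distance(gene.start, gene.end, positions)
        fully_deleted = any(
            seg.start <= gene.start and gene.end <= seg.end
            for seg in deleted_by_chrom.get(gene.chrom, [])
        )
        inside = positions[(positions > gene.start) & (positions < gene.end)]
        if fully_deleted:
            category: Category = "deleted"
            fragments: list[GeneFragment] = []
        elif inside.size:
            category = "truncated"
            fragments = fragment_gene(gene, rearrangement, cmap=cmap)
        elif distance <= window:
            category = "proximal"
            fragments = []
        else:
            category = "distal"
            fragments = []
        effects.append(GeneEffect(gene.gene_id, category, distance, fragments))
    return effects


def fragment_gene(
    gene: GeneModel,
    rearrangement: RearrangementSet,
    cmap: CoordinateMap | None = None,
) -> list[GeneFragment]:
    """Split a truncated gene at its internal breakends.

    Fragments are labelled 5prime/internal/3prime relative to gene strand;
    exons are assigned to fragments, an exon spanning a breakend is split
    into both pieces and flagged; each fragment is located on its derivative
    (or marked deleted) through the coordinate map.
    """
    positions = _breakends_per_chrom(rearrangement).get(gene.chrom, np.array([]))
    inside = sorted(int(p) for p in positions if gene.start < p < gene.end)
    if not inside:
        raise ValueError(f"gene {gene.gene_id} is not truncated (no internal breakend)")
    bounds = [gene.start, *inside, gene.end]
    if cmap is None:
        cmap = CoordinateMap(rearrangement)

    n = len(bounds) - 1
    fragments = []
    for i, (a, b) in enumerate(zip(bounds[:-1], bounds[1:])):
        if gene.strand == "+":
            part: Part = "5prime" if i == 0 else ("3prime" if i == n - 1 else "internal")
        else:
            part = "3prime" if i == 0 else ("5prime" if i == n - 1 else "internal")
        exons = []
        for idx, (es, ee) in enumerate(gene.exons):
            s, e = max(es, a), min(ee, b)
            if s < e:
                exons.append((s, e, idx, not (es >= a and ee <= b)))
        frag = GeneFragment(gene.gene_id, part, a, b, exons)
        res = liftover(cmap, gene.chrom, a, "ref2der")
        if res.deleted:
            frag.deleted = True
        else:
            frag.der_name = res.name
            frag.der_start = res.pos
            frag.der_orientation = res.orientation
        fragments.append(frag)
    return fragments


# ---------------------------------------------------------------------------
# fusion nomination
# ---------------------------------------------------------------------------


def _reads_rightward_at_junction(side: str, strand: str, position: Literal["a", "b"]) -> bool:
    """Does the gene transcribe in the derivative's forward direction?

    Locally orient the derivative as [flank_a][flank_b]: flank_a ends at the
    junction (reference forward if side_a == left, reflected otherwise) and
    flank_b starts at it (reference forward if side_b == right).  A gene on
    flank_a transcribes rightward iff (side == left) == (strand == '+');
    on flank_b iff (side == right) == (strand == '+').
    """
    if position == "a":
        return (side == "left") == (strand == "+")
    return (side == "right") == (strand == "+")


def nominate_fusions(
    gene_effects: Sequence[GeneEffect],
    rearrangement: RearrangementSet,
    genes: Sequence[GeneModel],
) -> tuple[list[FusionCandidate], list[GeneBreakendRecord]]:
    """Nominate fusion/read-through candidates from gene-gene junctions.

    For every junction whose two breakends each fall strictly inside a gene
    body: if both genes read in the same direction across the junction the
    candidate is a canonical same-strand fusion (the retained 5' fragment of
    one gene runs into the retained 3' fragment of the other); otherwise the
    genes meet in opposite orientation and the candidate is a read-through.
    Junctions with exactly one genic breakend are reported separately.
    Fusion partners are attached to the corresponding gene effects.
    """
    by_id = {g.gene_id: g for g in genes}
    effect_by_id = {e.gene_id: e for e in gene_effects}

    def genes_at(chrom: str, pos: int) -> list[GeneModel]:
        return [g for g in genes if g.chrom == chrom and g.start < pos < g.end]

    candidates: list[FusionCandidate] = []
    intergenic: list[GeneBreakendRecord] = []
    for j in rearrangement.junctions:
        hits_a = genes_at(j.chrom_a, j.pos_a)
        hits_b = genes_at(j.chrom_b, j.pos_b)
        if hits_a and hits_b:
            for ga in hits_a:
                for gb in hits_b:
                    da = _reads_rightward_at_junction(j.side_a, ga.strand, "a")
                    db = _reads_rightward_at_junction(j.side_b, gb.strand, "b")
                    config: Configuration = "same_strand" if da == db else "opposite_strand"
                    # the gene whose retained fragment carries the promoter
                    # (reads into the junction) is the 5' partner
                    if da:
                        g5, g3 = ga.gene_id, gb.gene_id
                    elif not db:
                        g5, g3 = gb.gene_id, ga.gene_id
                    else:  # da False, db True: both retained fragments are 3'
                        g5, g3 = ga.gene_id, gb.gene_id
                    candidates.append(FusionCandidate(j.id, g5, g3, config))
                    for gid, partner in ((ga.gene_id, gb.gene_id), (gb.gene_id, ga.gene_id)):
                        eff = effect_by_id.get(gid)
                        if eff is not None and (partner, config) not in eff.fusion_partners:
                            eff.fusion_partners.append((partner, config))
        elif hits_a or hits_b:
            side = "a" if hits_a else "b"
            for g in hits_a or hits_b:
                intergenic.append(
                    GeneBreakendRecord(
                        j.id,
                        g.gene_id,
                        j.chrom_a if side == "a" else j.chrom_b,
                        j.pos_a if side == "a" else j.pos_b,
                        j.side_a if side == "a" else j.side_b,
                    )
                )
    return candidates, intergenic


# ---------------------------------------------------------------------------
# TAD disruption
# ---------------------------------------------------------------------------


@dataclass
class TadDisruptionReport:
    n_tads_disrupted: int
    n_boundaries_deleted: int
    tads: pd.DataFrame
    boundaries: pd.DataFrame


def derive_boundaries(tads: pd.DataFrame, flank: int = 40_000) -> pd.DataFrame:
    """Boundaries as inter-TAD gaps widened by a symmetric flank.

    The flank default matches the Hi-C bin scale at which the input domains
    were called; abutting TADs give a 2*flank boundary centred on the shared
    edge.
    """
    rows = []
    for chrom, grp in tads.groupby("chrom", sort=False):
        grp = grp.sort_values("start")
        for (_, a), (_, b) in zip(grp.iterrows(), grp.iloc[1:].iterrows()):
            rows.append((chrom, max(0, int(a.end) - flank), int(b.start) + flank))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def tad_disruption(
    tads: pd.DataFrame,
    boundaries: pd.DataFrame | None,
    rearrangement: RearrangementSet,
    count_deletion_overlap: bool = False,
) -> TadDisruptionReport:
    """Count TADs containing breakends and boundaries lost to deletions.

    A TAD is disrupted iff at least one breakend lies strictly inside it
    (optionally also when it overlaps a deleted fragment); a boundary is
    deleted iff its interval lies fully inside the deleted-fragment union.
    """
    for chrom, grp in tads.groupby("chrom"):
        grp = grp.sort_values("start")
        if (grp["start"].values[1:] < grp["end"].values[:-1]).any():
            raise ValueError(f"overlapping TADs on {chrom}")
    if boundaries is None:
        boundaries = derive_boundaries(tads)

    cuts = _breakends_per_chrom(rearrangement)
    deleted_by_chrom: dict[str, list[GenomeSegment]] = {}
    for seg in rearrangement.deleted:
        deleted_by_chrom.setdefault(seg.chrom, []).append(seg)

    tad_rows = []
    for _, t in tads.iterrows():
        positions = cuts.get(t.chrom, np.array([]))
        n_inside = int(((positions > t.start) & (positions < t.end)).sum())
        overlaps_deletion = any(
            seg.start < t.end and t.start < seg.end
            for seg in deleted_by_chrom.get(t.chrom, [])
        )
        disrupted = n_inside > 0 or (count_deletion_overlap and overlaps_deletion)
        tad_rows.append(
            (t.chrom, t.start, t.end, n_inside, overlaps_deletion, disrupted)
        )
    tad_df = pd.DataFrame(
        tad_rows,
        columns=["chrom", "start", "end", "n_breakends", "overlaps_deletion", "disrupted"],
    )

    boundary_rows = []
    for _, b in boundaries.iterrows():
        deleted = any(
            seg.start <= b.start and b.end <= seg.end
            for seg in deleted_by_chrom.get(b.chrom, [])
        )
        boundary_rows.append((b.chrom, b.start, b.end, deleted))
    boundary_df = pd.DataFrame(boundary_rows, columns=["chrom", "start", "end", "deleted"])

    return TadDisruptionReport(
        n_tads_disrupted=int(tad_df["disrupted"].sum()),
        n_boundaries_deleted=int(boundary_df["deleted"].sum()),
        tads=tad_df,
        boundaries=boundary_df,
    )


def effects_table(effects: Sequence[GeneEffect], genes: Sequence[GeneModel]) -> pd.DataFrame:
    """One-row-per-gene TSV-ready summary of the classification."""
    by_id = {g.gene_id: g for g in genes}
    rows = []
    for e in effects:
        g = by_id.get(e.gene_id)
        rows.append(
            {
                "gene_id": e.gene_id,
                "chrom": g.chrom if g else "",
                "start": g.start if g else -1,
                "end": g.end if g else -1,
                "strand": g.strand if g else "",
                "category": e.category,
                "distance_to_nearest_breakpoint": e.distance_to_nearest_breakpoint,
                "n_fragments": len(e.fragments),
                "fusion_partners": ";".join(f"{p}({c})" for p, c in e.fusion_partners),
            }
        )
    return pd.DataFrame(rows)
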