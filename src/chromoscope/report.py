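"""Per-gene evidence integration and candidate shortlisting.

The report joins the outputs of the upstream stages — gene classification,
trio expression comparisons (gene and fragment level), and enhancer contact
calls — into one row per gene within the analysis window, without
recomputing anything.  Fold-change cells follow the blanking rule of the
source heatmaps: no value is shown for a cell type in which neither the
patient nor the parents exceed the expression floor.

The shortlist applies the molecular-evidence funnel: a gene is a candidate
when its coding sequence is disrupted, it is deleted, or it shows an
expression effect (|log2 fold change| at or above the threshold in at least
one cell type, at gene or fragment level).  Disease-association evidence is
a user-supplied annotation, never fetched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .effects import GeneEffect, GeneModel
from .rearrangements import CoordinateMap, RearrangementSet, liftover
from .util import natural_chrom_key

CELL_TYPE_ORDER = ("blood", "iPSC", "NPC")


@dataclass
class ShortlistRules:
    """Declarative funnel configuration."""

    include_coding_disruption: bool = True
    include_deletion: bool = True
    min_abs_log2_fc: float = 1.0


def build_report(
    effects: Sequence[GeneEffect],
    genes: Sequence[GeneModel],
    comparisons: pd.DataFrame,
    rearrangement: RearrangementSet,
    fragment_comparisons: pd.DataFrame | None = None,
    contact_calls: pd.DataFrame | None = None,
    window: int = 1_000_000,
) -> pd.DataFrame:
    """One evidence row per gene within ``window`` of the rearrangement.

    Ordering is deterministic by derivative position of the gene start
    (deleted genes follow, in reference order).  Cell-type fold-change
    columns are NaN wherever the comparison was not_expressed (or missing),
    with the expressed flags alongside.
    """
    gene_by_id = {g.gene_id: g for g in genes}
    cmap = CoordinateMap(rearrangement)
    cell_types = [
        ct for ct in CELL_TYPE_ORDER if ct in set(comparisons["cell_type"])
    ] + sorted(set(comparisons["cell_type"]) - set(CELL_TYPE_ORDER))
    comp_idx = comparisons.set_index(["feature", "cell_type"])
    frag_idx = (
        fragment_comparisons.set_index(["fragment", "cell_type"])
        if fragment_comparisons is not None
        else None
    )

    rows = []
    for eff in effects:
        in_window = eff.category in ("deleted", "truncated") or (
            eff.distance_to_nearest_breakpoint <= window
        )
        if not in_window:
            continue
        g = gene_by_id[eff.gene_id]
        if eff.category == "deleted":
            order_key = (1, 0, natural_chrom_key(g.chrom), g.start)
            placement = "deleted"
        else:
            res = liftover(cmap, g.chrom, g.start, "ref2der")
            if res.deleted:
                order_key = (1, 0, natural_chrom_key(g.chrom), g.start)
                placement = "deleted"
            else:
                order_key = (0, cmap.derivative_names.index(res.name), (res.pos,), 0)
                placement = f"{res.name}:{res.pos}({res.orientation})"
        row: dict = {
            "gene_id": eff.gene_id,
            "chrom": g.chrom,
            "start": g.start,
            "end": g.end,
            "strand": g.strand,
            "category": eff.category,
            "distance_to_nearest_breakpoint": eff.distance_to_nearest_breakpoint,
            "derivative_placement": placement,
            "fusion_partners": ";".join(f"{p}({c})" for p, c in eff.fusion_partners),
            "_order": order_key,
        }
        for ct in cell_types:
            try:
                rec = comp_idx.loc[(eff.gene_id, ct)]
            except KeyError:
                row[f"log2_fc_{ct}"] = np.nan
                row[f"expressed_{ct}"] = False
                row[f"effect_{ct}"] = "missing"
                continue
            blank = rec["effect"] == "not_expressed"
            row[f"log2_fc_{ct}"] = np.nan if blank else float(rec["log2_fc"])
            row[f"expressed_{ct}"] = bool(rec["expressed_patient"] or rec["expressed_parents"])
            row[f"effect_{ct}"] = rec["effect"]
        frag_summaries = []
        max_frag_fc = np.nan
        if frag_idx is not None and eff.fragments:
            for frag in eff.fragments:
                fid = f"{eff.gene_id}|{frag.part}"
                for ct in cell_types:
                    try:
                        rec = frag_idx.loc[(fid, ct)]
                    except KeyError:
                        continue
                    if rec["effect"] == "not_expressed":
                        continue
                    fc = float(rec["log2_fc"])
                    frag_summaries.append(f"{frag.part}/{ct}:{fc:+.2f}")
                    if math.isnan(max_frag_fc) or abs(fc) > abs(max_frag_fc):
                        max_frag_fc = fc
        row["fragment_log2_fc"] = ";".join(frag_summaries)
        row["max_abs_fragment_log2_fc"] = max_frag_fc
        rows.append(row)

    if not rows:
        cols = [
            "gene_id", "chrom", "start", "end", "strand", "category",
            "distance_to_nearest_breakpoint", "derivative_placement",
            "fusion_partners", "fragment_log2_fc", "max_abs_fragment_log2_fc",
        ]
        return pd.DataFrame(columns=cols)
    df = pd.DataFrame(rows).sort_values("_order", kind="stable").drop(columns="_order")
    if contact_calls is not None and len(contact_calls):
        flags = []
        for _, r in df.iterrows():
            hits = contact_calls[
                (contact_calls["chrom"] == r["chrom"])
                & (contact_calls["start"] < r["end"] + 500_000)
                & (contact_calls["end"] > r["start"] - 500_000)
                & (contact_calls["call"].isin(["gain", "loss"]))
            ]
            flags.append(";".join(f"{h['name']}:{h.call}" for _, h in hits.iterrows()))
        df["enhancer_contact_changes"] = flags
    return df.reset_index(drop=True)


def candidate_shortlist(
    report: pd.DataFrame, rules: ShortlistRules | None = None
) -> pd.DataFrame:
    """Rank the genes passing the molecular-evidence funnel.

    Tightening the fold-change rule can only shrink the shortlist.  Ranking
    is by strongest absolute fold change (gene or fragment level), ties by
    gene id.
    """
    if rules is None:
        rules = ShortlistRules()
    if report.empty:
        return report.copy()
    fc_cols = [c for c in report.columns if c.startswith("log2_fc_")]
    fc = report[fc_cols].abs().max(axis=1, skipna=True)
    if "max_abs_fragment_log2_fc" in report.columns:
        fc = pd.concat([fc, report["max_abs_fragment_log2_fc"].abs()], axis=1).max(
            axis=1, skipna=True
        )
    keep = fc >= rules.min_abs_log2_fc
    keep = keep.fillna(False)
    if rules.include_coding_disruption:
        keep |= report["category"] == "truncated"
    if rules.include_deletion:
        keep |= report["category"] == "deleted"
    out = report.loc[keep].copy()
    out["shortlist_score"] = fc[keep].fillna(0.0)
    return out.sort_values(
        ["shortlist_score", "gene_id"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
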