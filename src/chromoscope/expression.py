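"""Trio expression analysis: normalization, thresholds, and clustering.

The analysis follows the trio design (patient child vs both healthy
parents) across three cell types: blood, iPSC, and iPSC-derived neural
progenitors (NPC).  Counts are normalized for library size with
median-of-ratios size factors; a feature counts as expressed on a compared
side when its normalized mean exceeds ten counts; a molecular effect is a
fold change of at least ``fc_threshold`` (default twofold) between patient
and the parents' mean, evaluated only when at least one side is expressed.
NPC samples collected at differentiation days 7 and 10 behave as one
population and are merged before comparison.

Because the effect definition is a fold-change gate rather than a p-value,
no multiple-testing machinery is involved; per-parent fold changes are
emitted alongside the parent-mean comparison so stricter vs-each-parent
rules can be applied downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence
import warnings

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage, fcluster

INDIVIDUALS = ("patient", "father", "mother")
EXPRESSION_THRESHOLD = 10.0


# ---------------------------------------------------------------------------
# size factors
# ---------------------------------------------------------------------------


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library size factors.

    For each sample the factor is the median, over features with a positive
    geometric mean across all samples, of count / geometric mean.  Dividing
    counts by the factors yields normalized counts.
    """
    mat = counts.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        logs = np.log(mat)
    finite = np.isfinite(logs).all(axis=1)
    if not finite.any():
        raise ValueError(
            "no feature has positive counts in every sample; filter features "
            "before computing size factors"
        )
    log_geomean = logs[finite].mean(axis=1)
    factors = np.exp(np.median(logs[finite] - log_geomean[:, None], axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize_counts(counts: pd.DataFrame, factors: pd.Series | None = None) -> pd.DataFrame:
    if factors is None:
        factors = size_factors(counts)
    return counts / factors


# ---------------------------------------------------------------------------
# group merging
# ---------------------------------------------------------------------------


def default_merge_rule(samples: pd.DataFrame) -> pd.Series:
    """Map samples to merge groups: one group per individual/cell-type/line.

    NPC day-7 and day-10 samples of a line fall in the same group, as do
    technical replicates of a line; parents stay separate (they are pooled
    at the comparison stage, not the count stage).
    """
    rep = samples["replicate"] if "replicate" in samples else samples["sample"]
    return (
        samples["individual"].astype(str)
        + "|"
        + samples["cell_type"].astype(str)
        + "|"
        + rep.astype(str)
    )


def merge_groups(
    normalized: pd.DataFrame,
    samples: pd.DataFrame,
    rule: Callable[[pd.DataFrame], pd.Series] | Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Average member samples' normalized counts into merge groups.

    Returns the merged matrix (one column per group) and a group sheet with
    individual/cell-type columns and member provenance.
    """
    samples = samples.set_index("sample", drop=False).loc[list(normalized.columns)]
    if rule is None:
        groups = default_merge_rule(samples)
    elif callable(rule):
        groups = rule(samples)
    else:
        groups = samples["sample"].map(dict(rule))
    if groups.isna().any() or (groups == "").any():
        raise ValueError("merge rule produced an empty group for some sample")
    merged = normalized.T.groupby(groups.values).mean().T
    sheet_rows = []
    for group, members in samples.groupby(groups.values):
        sheet_rows.append(
            {
                "sample": group,
                "individual": members["individual"].iloc[0],
                "cell_type": members["cell_type"].iloc[0],
                "members": ",".join(members["sample"]),
            }
        )
    return merged, pd.DataFrame(sheet_rows)


# ---------------------------------------------------------------------------
# trio comparison
# ---------------------------------------------------------------------------


def trio_compare(
    normalized: pd.DataFrame,
    samples: pd.DataFrame,
    expr_threshold: float = EXPRESSION_THRESHOLD,
    fc_threshold: float = 2.0,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Patient-vs-parents comparison per feature per cell type.

    The parent reference is the arithmetic mean of the two parents'
    normalized means (each parent averaged over replicates first).  Features
    with both sides at or below ``expr_threshold`` are reported
    ``not_expressed`` and excluded from effect calls; otherwise the effect is
    ``up``/``down`` when |log2 fold change| reaches log2(fc_threshold).
    """
    samples = samples.set_index("sample", drop=False).loc[list(normalized.columns)]
    log_thr = np.log2(fc_threshold)
    frames = []
    for cell_type, grp in samples.groupby("cell_type", sort=False):
        means: dict[str, pd.Series] = {}
        for who in INDIVIDUALS:
            cols = grp.loc[grp["individual"] == who, "sample"]
            if len(cols) == 0:
                break
            if "replicate" in grp.columns:
                sub = grp.loc[grp["individual"] == who]
                per_rep = normalized[sub["sample"]].T.groupby(sub["replicate"].values).mean()
                means[who] = per_rep.mean(axis=0)
            else:
                means[who] = normalized[cols].mean(axis=1)
        if len(means) < len(INDIVIDUALS):
            warnings.warn(
                f"cell type {cell_type!r} lacks patient or parent samples; skipped",
                stacklevel=2,
            )
            continue
        pat = means["patient"]
        parents = (means["father"] + means["mother"]) / 2.0
        log2_fc = np.log2((pat + pseudocount) / (parents + pseudocount))
        expressed_patient = pat > expr_threshold
        expressed_parents = parents > expr_threshold
        not_expressed = ~(expressed_patient | expressed_parents)
        effect = np.where(
            not_expressed,
            "not_expressed",
            np.where(log2_fc >= log_thr, "up", np.where(log2_fc <= -log_thr, "down", "none")),
        )
        frames.append(
            pd.DataFrame(
                {
                    "feature": normalized.index,
                    "cell_type": cell_type,
                    "norm_mean_patient": pat.values,
                    "norm_mean_father": means["father"].values,
                    "norm_mean_mother": means["mother"].values,
                    "norm_mean_parents": parents.values,
                    "log2_fc": log2_fc.values,
                    "log2_fc_vs_father": np.log2(
                        (pat + pseudocount) / (means["father"] + pseudocount)
                    ).values,
                    "log2_fc_vs_mother": np.log2(
                        (pat + pseudocount) / (means["mother"] + pseudocount)
                    ).values,
                    "expressed_patient": expressed_patient.values,
                    "expressed_parents": expressed_parents.values,
                    "effect": effect,
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=[
                "feature", "cell_type", "norm_mean_patient", "norm_mean_father",
                "norm_mean_mother", "norm_mean_parents", "log2_fc",
                "log2_fc_vs_father", "log2_fc_vs_mother", "expressed_patient",
                "expressed_parents", "effect",
            ]
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# fragment-level expression
# ---------------------------------------------------------------------------


def fragment_counts(exon_counts: pd.DataFrame, fragments: Sequence) -> pd.DataFrame:
    """Aggregate exon-level counts into gene-fragment counts.

    Exon row ids follow ``<gene_id>|e<exon index>``.  An exon split by a
    breakend contributes to each touching fragment pro-rata by overlap
    length.  Fragments with no exons get a zero row (flagged downstream by
    their zero counts).
    """
    rows = []
    index = []
    for frag in fragments:
        fid = f"{frag.gene_id}|{frag.part}"
        total = np.zeros(exon_counts.shape[1])
        for s, e, idx, split in frag.exons:
            key = f"{frag.gene_id}|e{idx}"
            if key not in exon_counts.index:
                raise KeyError(f"exon counts missing row {key!r}")
            weight = 1.0
            if split:
                full = exon_counts.loc[key]
                # overlap fraction of the original exon kept in this fragment
                orig_len = _original_exon_length(fragments, frag.gene_id, idx)
                weight = (e - s) / orig_len
            total = total + exon_counts.loc[key].to_numpy(dtype=float) * weight
        rows.append(total)
        index.append(fid)
    return pd.DataFrame(rows, index=index, columns=exon_counts.columns)


def _original_exon_length(fragments: Sequence, gene_id: str, idx: int) -> int:
    pieces = [
        (s, e)
        for frag in fragments
        if frag.gene_id == gene_id
        for s, e, i, _ in frag.exons
        if i == idx
    ]
    return sum(e - s for s, e in pieces)


def fragment_expression(
    exon_counts: pd.DataFrame,
    fragments: Sequence,
    samples: pd.DataFrame,
    factors: pd.Series | None = None,
    **compare_kwargs,
) -> pd.DataFrame:
    """Trio comparison at gene-fragment resolution.

    Size factors are computed from (or supplied for) the full exon matrix so
    fragment counts share the gene-level library scaling.
    """
    if factors is None:
        factors = size_factors(exon_counts)
    frags = fragment_counts(exon_counts, fragments)
    normalized = frags / factors
    out = trio_compare(normalized, samples, **compare_kwargs)
    out = out.rename(columns={"feature": "fragment"})
    out.insert(1, "gene_id", out["fragment"].str.split("|").str[0])
    out.insert(2, "part", out["fragment"].str.split("|").str[1])
    return out


# ---------------------------------------------------------------------------
# variance-ranked clustering
# ---------------------------------------------------------------------------


@dataclass
class ClusteringResult:
    features: list[str]
    linkage: np.ndarray
    leaf_order: list[str]
    labels: pd.Series


def variance_top_clustering(
    normalized: pd.DataFrame,
    n: int = 500,
    n_clusters: int = 2,
    method: str = "complete",
    metric: str = "euclidean",
) -> ClusteringResult:
    """Hierarchical clustering of samples on the top-variance features.

    Features are ranked by descending variance of log2(normalized + 1)
    across samples (ties broken by feature id for determinism); samples are
    clustered agglomeratively on those features.
    """
    if normalized.shape[1] < 2:
        raise ValueError("need at least two samples to cluster")
    if n > normalized.shape[0]:
        warnings.warn(
            f"requested top {n} features but only {normalized.shape[0]} available; using all",
            stacklevel=2,
        )
        n = normalized.shape[0]
    logged = np.log2(normalized + 1.0)
    variances = logged.var(axis=1, ddof=1)
    order = sorted(normalized.index, key=lambda f: (-variances[f], f))
    top = order[:n]
    data = logged.loc[top].T.to_numpy()
    Z = linkage(data, method=method, metric=metric)
    leaf_order = [normalized.columns[i] for i in leaves_list(Z)]
    labels = pd.Series(
        fcluster(Z, t=n_clusters, criterion="maxclust"),
        index=normalized.columns,
        name="cluster",
    )
    return ClusteringResult(features=top, linkage=Z, leaf_order=leaf_order, labels=labels)
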