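"""Viewpoint (4C-style) profiles and binned contact matrices.

Profiles are normalized to a fixed number of captured reads per sample
(default one million), with a configurable exclusion zone around the
viewpoint whose self-ligation signal would otherwise dominate the total.
Per-enhancer contact changes between patient and control are called with a
ratio rule that accounts for the patient's 50:50 allelic mixture: the
affected and unaffected chromosomes cannot be distinguished in capture
data, so even a complete loss on the rearranged allele at most halves the
total signal.  With mixture fraction m and fold threshold t the gain
threshold is G = 1 + m*(t - 1) and the loss threshold 1/G, which keeps the
calls exactly antisymmetric under swapping patient and control.

Binned symmetric matrices (Hi-C style, default 100-kb resolution) can be
projected onto derivative-chromosome coordinates through a coordinate map,
which exposes the junction-crossing interactions as ordinary near-diagonal
signal on the derivative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .rearrangements import CoordinateMap
from .util import natural_chrom_key

DISPLAY_CAP = 500.0  # normalized-read ceiling used in report tracks only

Call = Literal["gain", "loss", "unchanged", "low_signal"]


# ---------------------------------------------------------------------------
# viewpoint profiles
# ---------------------------------------------------------------------------


@dataclass
class ViewpointProfile:
    """Per-bin contact signal of a single viewpoint, on reference coordinates."""

    viewpoint_chrom: str
    viewpoint_pos: int
    bins: pd.DataFrame  # chrom, start, end, value; sorted, non-overlapping
    normalized: bool = False
    target_total: float | None = None

    def __post_init__(self) -> None:
        b = self.bins
        if (b["value"] < 0).any():
            raise ValueError("negative bin values")
        for chrom, grp in b.groupby("chrom"):
            grp = grp.sort_values("start")
            if (grp["start"].values[1:] < grp["end"].values[:-1]).any():
                raise ValueError(f"overlapping profile bins on {chrom}")

    def exclusion_mask(self, zone: int) -> np.ndarray:
        """Bins overlapping the +/- zone window around the viewpoint."""
        b = self.bins
        return (
            (b["chrom"] == self.viewpoint_chrom)
            & (b["start"] < self.viewpoint_pos + zone)
            & (b["end"] > self.viewpoint_pos - zone)
        ).to_numpy()


def normalize_profile(
    profile: ViewpointProfile,
    target_total: float = 1e6,
    exclusion_zone: int = 10_000,
) -> ViewpointProfile:
    """Scale a profile so captured reads outside the exclusion zone sum to
    ``target_total``.

    Doubling all raw counts leaves the result unchanged (pure scale
    invariance); a zero captured total is an error.
    """
    mask = profile.exclusion_mask(exclusion_zone)
    total = float(profile.bins.loc[~mask, "value"].sum())
    if total <= 0:
        raise ValueError("profile has zero captured reads outside the exclusion zone")
    bins = profile.bins.copy()
    bins["value"] = bins["value"] * (target_total / total)
    return replace(profile, bins=bins, normalized=True, target_total=target_total)


def display_track(profile: ViewpointProfile, cap: float = DISPLAY_CAP) -> pd.DataFrame:
    """Report/plotting track with values capped; calls never use the cap."""
    out = profile.bins.copy()
    out["value"] = np.minimum(out["value"], cap)
    return out


def smooth_profile(profile: ViewpointProfile, window: int = 5) -> ViewpointProfile:
    """Centred running mean over ``window`` bins, per chromosome.

    Off by default in the pipeline; totals are preserved up to edge
    effects, so re-normalize after smoothing if exact totals matter.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd bin count")
    bins = profile.bins.copy()
    bins["value"] = (
        bins.groupby("chrom", sort=False)["value"]
        .transform(lambda s: s.rolling(window, center=True, min_periods=1).mean())
    )
    return replace(profile, bins=bins)


# ---------------------------------------------------------------------------
# enhancer contact calls
# ---------------------------------------------------------------------------


def _enhancer_signal(profile: ViewpointProfile, chrom: str, start: int, end: int) -> float:
    """Sum of overlapping normalized bins, partial bins pro-rated."""
    b = profile.bins
    sel = b[(b["chrom"] == chrom) & (b["start"] < end) & (b["end"] > start)]
    if sel.empty:
        return 0.0
    overlap = np.minimum(sel["end"], end) - np.maximum(sel["start"], start)
    frac = overlap / (sel["end"] - sel["start"])
    return float((sel["value"] * frac).sum())


def enhancer_contact_change(
    profile_patient: ViewpointProfile,
    profile_control: ViewpointProfile,
    enhancers: pd.DataFrame,
    ratio_threshold: float = 2.0,
    pseudocount: float = 5.0,
    floor: float = 50.0,
    mixture: float = 0.5,
) -> pd.DataFrame:
    """Call per-enhancer contact gain/loss between patient and control.

    Both profiles must be normalized to the same target total.  Per
    enhancer the signal is the pro-rated sum of overlapping bins; the call
    is low_signal when both signals are below ``floor``, otherwise gain
    (loss) when the pseudocounted ratio reaches the mixture-adjusted
    threshold (its reciprocal).
    """
    if not (profile_patient.normalized and profile_control.normalized):
        raise ValueError("normalize both profiles before calling changes")
    if profile_patient.target_total != profile_control.target_total:
        raise ValueError("profiles were normalized to different targets")
    if not 0 < mixture <= 1:
        raise ValueError("mixture must be in (0, 1]")
    gain_threshold = 1.0 + mixture * (ratio_threshold - 1.0)

    chroms = set(profile_patient.bins["chrom"]) | set(profile_control.bins["chrom"])
    rows = []
    for _, enh in enhancers.iterrows():
        if enh.chrom not in chroms:
            warnings.warn(
                f"enhancer {enh.get('name', '')} on {enh.chrom} absent from profiles",
                stacklevel=2,
            )
            rows.append((enh.chrom, enh.start, enh.end, enh.get("name", ""), 0.0, 0.0,
                         np.nan, "low_signal"))
            continue
        sp = _enhancer_signal(profile_patient, enh.chrom, enh.start, enh.end)
        sc = _enhancer_signal(profile_control, enh.chrom, enh.start, enh.end)
        ratio = (sp + pseudocount) / (sc + pseudocount)
        if sp < floor and sc < floor:
            call: Call = "low_signal"
        elif ratio >= gain_threshold:
            call = "gain"
        elif ratio <= 1.0 / gain_threshold:
            call = "loss"
        else:
            call = "unchanged"
        rows.append((enh.chrom, enh.start, enh.end, enh.get("name", ""), sp, sc, ratio, call))
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "name", "signal_patient", "signal_control",
                 "ratio", "call"],
    )


# ---------------------------------------------------------------------------
# contact matrices
# ---------------------------------------------------------------------------


@dataclass
class ContactMatrix:
    """Symmetric binned all-vs-all contact matrix over named sequences."""

    bin_size: int
    chrom_lengths: dict[str, int]  # insertion order defines bin layout
    matrix: np.ndarray

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin size must be positive")
        n = self.n_bins
        if self.matrix.shape != (n, n):
            raise ValueError(f"matrix shape {self.matrix.shape} != layout bins {n}")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("matrix is not symmetric")

    @property
    def chrom_bins(self) -> dict[str, int]:
        return {
            c: -(-length // self.bin_size) for c, length in self.chrom_lengths.items()
        }

    @property
    def n_bins(self) -> int:
        return sum(self.chrom_bins.values())

    @property
    def offsets(self) -> dict[str, int]:
        out, acc = {}, 0
        for c, nb in self.chrom_bins.items():
            out[c] = acc
            acc += nb
        return out

    def bin_index(self, chrom: str, pos: int) -> int:
        return self.offsets[chrom] + pos // self.bin_size

    def bin_labels(self) -> list[str]:
        labels = []
        for c, nb in self.chrom_bins.items():
            labels.extend(f"{c}:{i * self.bin_size}" for i in range(nb))
        return labels

    def to_frame(self) -> pd.DataFrame:
        labels = self.bin_labels()
        return pd.DataFrame(self.matrix, index=labels, columns=labels)

    def total_mass(self) -> float:
        return float(self.matrix.sum())


def rebin_matrix(cm: ContactMatrix, bin_size: int) -> ContactMatrix:
    """Coarsen to an integer multiple of the current resolution (sum pooling)."""
    if bin_size == cm.bin_size:
        return cm
    if bin_size % cm.bin_size != 0:
        raise ValueError(
            f"cannot rebin {cm.bin_size} bp bins to {bin_size} bp: not an integer multiple"
        )
    k = bin_size // cm.bin_size
    old_offsets = cm.offsets
    old_bins = cm.chrom_bins
    groups: list[np.ndarray] = []
    for c, nb in old_bins.items():
        for i in range(0, nb, k):
            groups.append(np.arange(old_offsets[c] + i, old_offsets[c] + min(i + k, nb)))
    n = len(groups)
    out = np.zeros((n, n))
    for i, gi in enumerate(groups):
        for j, gj in enumerate(groups):
            out[i, j] = cm.matrix[np.ix_(gi, gj)].sum()
    return ContactMatrix(bin_size, dict(cm.chrom_lengths), out)


def project_matrix_to_derivative(
    cm: ContactMatrix,
    cmap: CoordinateMap,
    bin_size: int | None = None,
) -> ContactMatrix:
    """Reorder a reference-coordinate matrix onto derivative coordinates.

    Each derivative bin pulls the value of the reference bin containing its
    source midpoint (orientation-aware); deleted reference bins simply do
    not appear.  Exact mass conservation (total minus deleted bins) holds
    when segment boundaries are aligned to the bin grid, the scale at which
    rearranged maps are interpreted.
    """
    if bin_size is not None and bin_size != cm.bin_size:
        cm = rebin_matrix(cm, bin_size)
    b = cm.bin_size
    der_lengths = {name: cmap.der_lengths[name] for name in cmap.derivative_names}
    src: list[int] = []
    for name in cmap.derivative_names:
        nb = -(-der_lengths[name] // b)
        mids = np.minimum(np.arange(nb) * b + b // 2, der_lengths[name] - 1)
        cidx, ref_pos, _rev = cmap.der_to_ref_many(name, mids)
        for ci, rp in zip(cidx, ref_pos):
            src.append(cm.bin_index(cmap.chrom_names[ci], int(rp)))
    src_arr = np.array(src)
    out = cm.matrix[np.ix_(src_arr, src_arr)]
    out = (out + out.T) / 2.0  # exact symmetry despite midpoint rounding
    return ContactMatrix(b, der_lengths, out)


# ---------------------------------------------------------------------------
# distance-decay null profile
# ---------------------------------------------------------------------------


def expected_decay_profile(
    cmap: CoordinateMap,
    der_name: str,
    der_pos: int,
    bin_size: int,
    alpha: float = 1.0,
    target_total: float = 1e6,
) -> ViewpointProfile:
    """Power-law distance-decay expectation for a viewpoint on a derivative.

    Expected contact of a bin is (distance on the derivative)^(-alpha),
    normalized to ``target_total``; bins equidistant from the viewpoint get
    equal expectation, and alpha = 0 gives a uniform profile.  The result is
    expressed on reference coordinates through the map, so it can be
    compared to measured profiles directly.
    """
    length = cmap.der_lengths[der_name]
    nb = -(-length // bin_size)
    mids = np.minimum(np.arange(nb) * bin_size + bin_size // 2, length - 1)
    dist = np.abs(mids - der_pos).astype(float)
    dist = np.maximum(dist, bin_size / 2.0)  # floor at half a bin (the viewpoint's own bin)
    values = dist ** (-alpha)
    values *= target_total / values.sum()

    cidx, ref_pos, _ = cmap.der_to_ref_many(der_name, mids)
    rows = []
    for i in range(nb):
        chrom = cmap.chrom_names[cidx[i]]
        start = (int(ref_pos[i]) // bin_size) * bin_size
        rows.append((chrom, start, start + bin_size, values[i]))
    bins = (
        pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
        .groupby(["chrom", "start", "end"], as_index=False)["value"]
        .sum()
        .sort_values(["chrom", "start"], key=lambda s: s.map(natural_chrom_key) if s.name == "chrom" else s)
        .reset_index(drop=True)
    )
    vp = cmap.der_to_ref_many(der_name, np.array([der_pos]))
    return ViewpointProfile(
        viewpoint_chrom=cmap.chrom_names[vp[0][0]],
        viewpoint_pos=int(vp[1][0]),
        bins=bins,
        normalized=True,
        target_total=target_total,
    )
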