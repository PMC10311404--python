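"""Selection profiles and sweep localization.

The classifier emits one "selection" probability per SNP window.  A
selection profile smooths these into a 1D array of probabilities indexed
by genomic position, using one of three averaging configurations:

``snp``
    moving average over ``k`` consecutive windows of the probability
    array; each entry sits at the midpoint of the genomic span covered by
    the averaged windows (granularity follows SNP density);
``pos``
    for each window, average all windows whose center lies within a bp
    span around that window's center;
``grid``
    evaluate ``G`` evenly spaced genomic positions, each averaging the
    windows whose center falls within half the averaging span; grid
    points covered by no window carry NaN (a no-data marker, not 0).

The sweep is called at the profile maximum; its extent is the maximal
contiguous run of positions around the peak with probability at or above
a threshold.  The per-replicate scan score used for thresholding in the
evaluation protocol is the profile maximum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cnn import ProbMatrix
from .windows import WindowSet

__all__ = ["SelectionProfile", "SweepCall", "make_profile", "call_sweep",
           "replicate_score"]


@dataclass
class SelectionProfile:
    """Averaged selection-class probability along the genome."""

    positions_bp: np.ndarray
    probs: np.ndarray
    mode: str
    params: dict

    def __post_init__(self):
        self.positions_bp = np.asarray(self.positions_bp, dtype=float)
        self.probs = np.asarray(self.probs, dtype=float)
        if self.positions_bp.shape != self.probs.shape:
            raise ValueError("positions/probs length mismatch")
        finite = self.probs[np.isfinite(self.probs)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("probabilities must lie in [0, 1]")

    def to_tsv(self) -> str:
        lines = ["position\tprobability"]
        for p, v in zip(self.positions_bp, self.probs):
            lines.append(f"{p:.1f}\t" + ("NA" if np.isnan(v) else f"{v:.6f}"))
        return "\n".join(lines) + "\n"


@dataclass
class SweepCall:
    """Reported sweep location, extent, and peak probability."""

    location_bp: float
    extent: tuple[float, float]
    peak_prob: float
    tie: bool = False

    def __post_init__(self):
        lo, hi = self.extent
        if not (lo <= self.location_bp <= hi):
            raise ValueError("extent must bracket the reported location")


def _window_meta(windows):
    if isinstance(windows, WindowSet):
        return windows.centers_bp, windows.first_snp_bp, windows.last_snp_bp
    centers = np.array([w.center_bp for w in windows], dtype=float)
    firsts = np.array([w.first_snp_bp for w in windows], dtype=float)
    lasts = np.array([w.last_snp_bp for w in windows], dtype=float)
    return centers, firsts, lasts


def make_profile(
    probs: ProbMatrix | np.ndarray,
    windows,
    mode: str = "snp",
    k: int = 10,
    span_bp: float | None = None,
    grid_size: int | None = None,
    region_len: int | None = None,
    class_label: str = "selection",
) -> SelectionProfile:
    """Average window probabilities into a per-position profile.

    ``probs`` is either the classifier's probability matrix (the
    ``class_label`` row is used) or a plain 1D probability array with one
    entry per window.
    """
    if isinstance(probs, ProbMatrix):
        p = probs.class_row(class_label)
    else:
        p = np.asarray(probs, dtype=float)
    if p.ndim != 1:
        raise ValueError("probability array must be 1D")
    n_win = windows.n_windows if isinstance(windows, WindowSet) else len(windows)
    if n_win != p.size:
        raise ValueError(
            f"probability count {p.size} != window count {n_win}"
        )
    if p.size == 0:
        raise ValueError("empty probability array")
    centers, firsts, lasts = _window_meta(windows)

    if mode == "snp":
        if k < 1 or k > p.size:
            raise ValueError(
                f"k={k} outside [1, number of windows={p.size}]"
            )
        kernel = np.ones(k) / k
        smoothed = np.convolve(p, kernel, mode="valid")
        # entry i averages windows i..i+k-1; position = midpoint of span
        pos = (firsts[: p.size - k + 1] + lasts[k - 1:]) / 2.0
        return SelectionProfile(pos, smoothed, "snp", {"k": k})

    if mode == "pos":
        if span_bp is None or span_bp <= 0:
            raise ValueError("pos mode requires span_bp > 0")
        half = span_bp / 2.0
        out = np.empty_like(p)
        for i, c in enumerate(centers):
            sel = np.abs(centers - c) <= half
            out[i] = p[sel].mean()
        return SelectionProfile(centers.copy(), out, "pos",
                                {"span_bp": span_bp})

    if mode == "grid":
        if grid_size is None or grid_size < 1:
            raise ValueError("grid mode requires grid_size >= 1")
        if span_bp is None or span_bp <= 0:
            raise ValueError("grid mode requires span_bp > 0")
        if region_len is None:
            region_len = int(np.ceil(lasts.max()))
        pos = np.linspace(1, region_len, grid_size)
        half = span_bp / 2.0
        out = np.full(grid_size, np.nan)
        for i, g in enumerate(pos):
            sel = np.abs(centers - g) <= half
            if sel.any():
                out[i] = p[sel].mean()
        return SelectionProfile(
            pos, out, "grid", {"grid_size": grid_size, "span_bp": span_bp,
                               "region_len": region_len}
        )

    raise ValueError(f"unknown mode {mode!r}; expected snp/pos/grid")


def call_sweep(profile: SelectionProfile, extent_threshold: float = 0.5) -> SweepCall:
    """Localize the sweep at the profile maximum and report its extent.

    The location is the position of the maximum probability (leftmost on
    ties, flagged); the extent is the maximal contiguous run of
    positions around the peak with probability >= ``extent_threshold``.
    NaN (no-data) entries break contiguity.
    """
    probs = profile.probs
    finite = np.isfinite(probs)
    if not finite.any():
        raise ValueError("profile contains no data")
    vals = np.where(finite, probs, -np.inf)
    peak = int(np.argmax(vals))
    peak_prob = float(vals[peak])
    tie = bool(np.sum(vals == peak_prob) > 1)
    above = finite & (probs >= extent_threshold)
    lo = hi = peak
    if above[peak]:
        while lo > 0 and above[lo - 1]:
            lo -= 1
        while hi < probs.size - 1 and above[hi + 1]:
            hi += 1
    return SweepCall(
        location_bp=float(profile.positions_bp[peak]),
        extent=(float(profile.positions_bp[lo]), float(profile.positions_bp[hi])),
        peak_prob=peak_prob,
        tie=tie,
    )


def replicate_score(profile: SelectionProfile) -> float:
    """Scan score of one replicate: the profile maximum."""
    if not np.isfinite(profile.probs).any():
        raise ValueError("profile contains no data")
    return float(np.nanmax(profile.probs))
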