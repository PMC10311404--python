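"""Sliding SNP windows and their grayscale image encoding.

A window covers ``W`` consecutive SNP columns; consecutive windows are
``S`` columns apart, so a matrix with ``T`` sites yields
``floor((T - W) / S) + 1`` windows (overlap ``W - S`` when ``S < W``).
Windows are placed on SNPs, not on physical coordinates, so resolution
adapts to SNP density.

Each window is rendered as an ``N x W`` grayscale image by multiplying
the allelic state by 127: ancestral -> 0 (black), derived -> 127 (gray),
other -> 254 (near white).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .seqio import SNPMatrix

__all__ = [
    "GRAY_FACTOR",
    "GRAY_MAX",
    "WindowImage",
    "make_windows",
    "encode_window",
    "window_images",
    "image_stack",
    "WindowSet",
    "window_set",
    "dump_png",
]

GRAY_FACTOR = 127
GRAY_MAX = 254


@dataclass(frozen=True)
class WindowImage:
    """A rendered SNP window: pixels plus its genomic span."""

    pixels: np.ndarray  # N x W uint8, values in {0, 127, 254}
    first_snp_bp: int
    last_snp_bp: int
    window_index: int

    @property
    def center_bp(self) -> float:
        """Representative coordinate: midpoint of the spanned SNPs."""
        return (self.first_snp_bp + self.last_snp_bp) / 2.0


def make_windows(n_sites: int, width: int = 50, step: int = 1) -> list[tuple[int, int]]:
    """Column ranges ``[start, stop)`` of the sliding windows.

    Returns an empty list (with a warning) when there are fewer than
    ``width`` SNPs.
    """
    if width < 1 or step < 1:
        raise ValueError("width and step must be >= 1")
    if isinstance(n_sites, SNPMatrix):
        n_sites = n_sites.n_sites
    if n_sites < width:
        warnings.warn(
            f"insufficient SNPs: {n_sites} < window width {width}; "
            "no windows produced"
        )
        return []
    n_windows = (n_sites - width) // step + 1
    return [(i * step, i * step + width) for i in range(n_windows)]


def encode_window(m: SNPMatrix, window: tuple[int, int], index: int = 0) -> WindowImage:
    """Render one window of the SNP matrix as a grayscale image."""
    start, stop = window
    if not (0 <= start < stop <= m.n_sites):
        raise ValueError(f"window {window} outside matrix with T={m.n_sites}")
    pixels = (m.states[:, start:stop] * GRAY_FACTOR).astype(np.uint8)
    return WindowImage(
        pixels=pixels,
        first_snp_bp=int(m.positions_bp[start]),
        last_snp_bp=int(m.positions_bp[stop - 1]),
        window_index=index,
    )


def window_images(m: SNPMatrix, width: int = 50, step: int = 1) -> list[WindowImage]:
    """All windows of ``m`` rendered as images, in genomic order."""
    return [
        encode_window(m, w, i) for i, w in enumerate(make_windows(m.n_sites, width, step))
    ]


def image_stack(images: list[WindowImage]) -> np.ndarray:
    """Stack window images into an ``L x N x W`` array for the classifier."""
    if not images:
        return np.zeros((0, 0, 0), dtype=np.uint8)
    return np.stack([im.pixels for im in images])


@dataclass(frozen=True)
class WindowSet:
    """All windows of one matrix in array form (the bulk counterpart of a
    list of :class:`WindowImage`, used by the scan pipeline)."""

    images: np.ndarray  # L x N x W uint8
    first_snp_bp: np.ndarray
    last_snp_bp: np.ndarray

    @property
    def centers_bp(self) -> np.ndarray:
        return (self.first_snp_bp + self.last_snp_bp) / 2.0

    @property
    def n_windows(self) -> int:
        return self.images.shape[0]

    def subset(self, idx) -> "WindowSet":
        return WindowSet(self.images[idx], self.first_snp_bp[idx],
                         self.last_snp_bp[idx])


def dump_png(images: list[WindowImage], directory) -> list[str]:
    """Write each window image as a PNG for visual inspection (requires
    pillow).  Files are named ``window_<index>_<first>-<last>.png``."""
    from PIL import Image
    import pathlib

    d = pathlib.Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = []
    for im in images:
        path = d / (f"window_{im.window_index:05d}_"
                    f"{im.first_snp_bp}-{im.last_snp_bp}.png")
        Image.fromarray(im.pixels, mode="L").save(path)
        paths.append(str(path))
    return paths


def window_set(m: SNPMatrix, width: int = 50, step: int = 1) -> WindowSet:
    """Vectorized equivalent of :func:`window_images`."""
    ranges = make_windows(m.n_sites, width, step)
    L = len(ranges)
    if L == 0:
        return WindowSet(np.zeros((0, m.n_samples, width), np.uint8),
                         np.zeros(0), np.zeros(0))
    sv = np.lib.stride_tricks.sliding_window_view(m.states, width, axis=1)
    images = (sv[:, ::step][:, :L].transpose(1, 0, 2) * GRAY_FACTOR).astype(np.uint8)
    starts = np.arange(L) * step
    firsts = m.positions_bp[starts].astype(float)
    lasts = m.positions_bp[starts + width - 1].astype(float)
    return WindowSet(images, firsts, lasts)
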