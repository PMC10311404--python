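"""High-level glue: simulate -> images -> train -> scan -> evaluate.

These functions tie the stages together the way the command-line
interface and the evaluation protocol use them: build a labeled training
set of window images from neutral and sweep replicates, train the
classifier, and scan test replicates into per-replicate scores (profile
maxima) and reported sweep locations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import seqio
from .cnn import ArchSpec, TrainedModel, build_model, infer, train
from .scan import call_sweep, make_profile, replicate_score
from .simulate import MsReplicate
from .windows import window_set

__all__ = [
    "training_set_from_replicates",
    "train_scan_model",
    "scan_replicates",
    "ScanResult",
]


def _select_windows(ws, mode: str, central_fraction: float, region_len: int,
                    max_per_rep: int | None):
    idx = np.arange(ws.n_windows)
    if mode == "center":
        idx = idx[ws.n_windows // 2: ws.n_windows // 2 + 1]
    elif mode == "central-fraction":
        lo = region_len * (0.5 - central_fraction / 2)
        hi = region_len * (0.5 + central_fraction / 2)
        centers = ws.centers_bp
        idx = idx[(centers >= lo) & (centers <= hi)]
    elif mode != "all":
        raise ValueError("window mode must be center/central-fraction/all")
    if max_per_rep is not None and idx.size > max_per_rep:
        # even subsample across the region, deterministic
        sub = np.linspace(0, idx.size - 1, max_per_rep).round().astype(int)
        idx = idx[sub]
    return ws.subset(idx)


def training_set_from_replicates(
    neutral: list[MsReplicate],
    selection: list[MsReplicate],
    width: int = 50,
    step: int = 1,
    neutral_mode: str = "all",
    selection_mode: str = "central-fraction",
    central_fraction: float = 0.2,
    max_windows_per_rep: int | None = 60,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Labeled window images from simulated replicates.

    Neutral replicates contribute windows from anywhere in the region;
    sweep replicates contribute windows centered on the middle fraction
    of the region (the sweep sits at the center in the training models),
    so the "selection" class is not diluted with effectively neutral
    flanking windows.  ``max_windows_per_rep`` caps the contribution of
    each replicate by even subsampling.  Labels: 0 = neutral,
    1 = selection.
    """
    images, labels = [], []
    for reps, label, mode in (
        (neutral, 0, neutral_mode),
        (selection, 1, selection_mode),
    ):
        for rep in reps:
            m = seqio.from_replicate(rep)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ws = window_set(m, width, step)
            ws = _select_windows(
                ws, mode, central_fraction, rep.region_len, max_windows_per_rep
            )
            if ws.n_windows:
                images.append(ws.images)
                labels.append(np.full(ws.n_windows, label, dtype=np.int64))
    if not images:
        raise ValueError("no training windows produced")
    return np.concatenate(images), np.concatenate(labels)


def train_scan_model(
    neutral: list[MsReplicate],
    selection: list[MsReplicate],
    spec: ArchSpec | None = None,
    width: int = 50,
    step: int = 1,
    epochs: int = 6,
    seed: int = 0,
    neutral_mode: str = "all",
    selection_mode: str = "central-fraction",
    central_fraction: float = 0.2,
    max_windows_per_rep: int | None = 60,
    **train_kwargs,
) -> TrainedModel:
    """Train the default classifier on simulated neutral/sweep data."""
    x, y = training_set_from_replicates(
        neutral, selection, width=width, step=step, seed=seed,
        neutral_mode=neutral_mode, selection_mode=selection_mode,
        central_fraction=central_fraction,
        max_windows_per_rep=max_windows_per_rep,
    )
    spec = spec or ArchSpec()
    net = build_model(spec, input_shape=x.shape[1:], seed=seed)
    model = train(net, x, y, epochs=epochs, seed=seed, **train_kwargs)
    model.meta.update({"width": width, "step": step})
    return model


@dataclass
class ScanResult:
    """Per-replicate scan outcomes, aligned with the input replicates.

    A replicate with fewer SNPs than one window cannot be scanned: its
    score and location are NaN.  Such replicates can never exceed a
    detection threshold (they count as negatives), which keeps TPR/FPR
    denominators equal to the number of simulated replicates.
    """

    scores: np.ndarray  # profile maxima; NaN = unscannable
    locations_bp: np.ndarray  # reported sweep locations; NaN = no call
    n_skipped: int  # replicates with too few SNPs for one window


def scan_replicates(
    model: TrainedModel,
    reps: list[MsReplicate],
    width: int | None = None,
    step: int | None = None,
    mode: str = "snp",
    k: int = 10,
    **profile_kwargs,
) -> ScanResult:
    """Scan replicates: classify windows, build a profile, score and
    localize.  Window width/step default to the model's training values."""
    width = width or model.meta.get("width", 50)
    step = step or model.meta.get("step", 1)
    scores, locs = [], []
    n_skipped = 0
    for rep in reps:
        m = seqio.from_replicate(rep)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ws = window_set(m, width, step)
        if ws.n_windows == 0:
            n_skipped += 1
            scores.append(np.nan)
            locs.append(np.nan)
            continue
        probs = infer(model, ws.images, window_centers_bp=ws.centers_bp)
        eff_k = min(k, ws.n_windows)
        profile = make_profile(probs, ws, mode=mode, k=eff_k,
                               **profile_kwargs)
        scores.append(replicate_score(profile))
        locs.append(call_sweep(profile).location_bp)
    if n_skipped:
        warnings.warn(f"{n_skipped} replicates had fewer than {width} SNPs "
                      "and were skipped")
    return ScanResult(
        scores=np.asarray(scores), locations_bp=np.asarray(locs),
        n_skipped=n_skipped,
    )
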