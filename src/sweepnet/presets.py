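"""Named evolutionary-model presets.

The benchmark suite spans 101 models: hard complete sweeps confounded by
population bottlenecks (datasets 1-60), continent-island migration
(61-70), neutral recombination-hotspot models (71-91), and sweeps in or
near a recombination hotspot (92-101).  The published parameter grids give
ranges for the varying parameters; where only a range is printed the
presets use a documented representative grid over it, anchored at the
values that are printed (e.g. the hotspot-intensity ladder passes through
2, 10 and 100; the migration-time ladder starts at 0.003 and ends at 3).

All presets share: sample size 20 haplotypes, 100-kb region,
``theta = rho = 2000`` for the region, present-day size 50 000 diploids,
selection coefficient 0.02 for sweep models.  Use
``get_preset(name).scaled(k)`` for desk-scale runs.
"""

from __future__ import annotations

import itertools

import numpy as np

from .simulate import Hotspot, SimConfig, SweepParams

__all__ = ["get_preset", "preset_names", "HOTSPOT_FPR_DATASETS"]

_SWEEP_CENTER = 50_000.0

# bottleneck grids (datasets 1-60): severity x beginning x duration,
# 5 x 4 x 3 representative values spanning the published ranges
_SEVERITIES = tuple(np.round(np.geomspace(0.5, 0.005, 5), 4))
_BEGINNINGS = tuple(np.round(np.geomspace(0.004, 0.1, 4), 4))
_DURATIONS = (0.0004, 0.001, 0.002)

# migration population-join times (datasets 61-70), most recent printed
# value 0.003 up to 3, log-spaced
_JOIN_TIMES = tuple(np.round(np.geomspace(0.003, 3.0, 10), 5))

# neutral hotspot models (datasets 71-91): 3 layouts x 7 intensities; the
# intensity ladder passes through the printed anchors 2 (first), 10
# (fourth) and 100 (seventh)
_HOTSPOT_INTENSITIES = (2, 3, 5, 10, 22, 46, 100)
_HOTSPOT_LAYOUTS = {
    "5kb": (Hotspot(47_500, 52_500, 1.0),),
    "10kb": (Hotspot(45_000, 55_000, 1.0),),
    "3x5kb": (
        Hotspot(22_500, 27_500, 1.0),
        Hotspot(47_500, 52_500, 1.0),
        Hotspot(72_500, 77_500, 1.0),
    ),
}

# sweep-plus-hotspot models (92-101): one central 5-kb hotspot, sweep at
# 50 kb (inside) or 30 kb (outside), intensities 2..10
_SWEEP_HOTSPOT_INTENSITIES = (2, 4, 6, 8, 10)

#: the nine neutral hotspot datasets used for the FPR robustness table
#: (5 kb / 10 kb / 3x5 kb at intensities 2, 10, 100)
HOTSPOT_FPR_DATASETS = (71, 74, 77, 78, 81, 84, 85, 88, 91)


def _with_intensity(layout, intensity) -> tuple[Hotspot, ...]:
    return tuple(
        Hotspot(h.start_bp, h.end_bp, float(intensity)) for h in layout
    )


def _build_registry() -> dict[str, SimConfig]:
    reg: dict[str, SimConfig] = {}
    reg["neutral"] = SimConfig(label="neutral")
    reg["sweep"] = SimConfig(
        label="sweep",
        sweep=SweepParams(s=0.02, start_time=0.005, position_bp=_SWEEP_CENTER),
    )

    i = 1
    for sev, begin, dur in itertools.product(_SEVERITIES, _BEGINNINGS, _DURATIONS):
        epochs = ((begin, sev), (begin + dur, 1.0))
        reg[f"dataset-{i}"] = SimConfig(
            label=f"dataset-{i}",
            epochs=epochs,
            sweep=SweepParams(s=0.02, start_time=0.016,
                              position_bp=_SWEEP_CENTER),
        )
        i += 1
    assert i == 61
    for tm in _JOIN_TIMES:
        reg[f"dataset-{i}"] = SimConfig(
            label=f"dataset-{i}",
            pop_join_time=float(tm), migration_rate=3.0,
            continent_size_ratio=20.0,
            sweep=SweepParams(s=0.02, start_time=0.005,
                              position_bp=_SWEEP_CENTER),
        )
        i += 1
    assert i == 71
    for layout in _HOTSPOT_LAYOUTS.values():
        for intensity in _HOTSPOT_INTENSITIES:
            reg[f"dataset-{i}"] = SimConfig(
                label=f"dataset-{i}",
                hotspots=_with_intensity(layout, intensity),
            )
            i += 1
    assert i == 92
    for pos_bp in (50_000.0, 30_000.0):
        for intensity in _SWEEP_HOTSPOT_INTENSITIES:
            reg[f"dataset-{i}"] = SimConfig(
                label=f"dataset-{i}",
                hotspots=_with_intensity(_HOTSPOT_LAYOUTS["5kb"], intensity),
                sweep=SweepParams(s=0.02, start_time=0.005, position_bp=pos_bp),
            )
            i += 1
    assert i == 102
    return reg


_REGISTRY = _build_registry()


def preset_names() -> list[str]:
    return sorted(_REGISTRY)


def get_preset(name: str) -> SimConfig:
    """Look up a named model (``neutral``, ``sweep``, ``dataset-1`` ...
    ``dataset-101``).  The neutral counterpart of a sweep dataset is the
    same config with ``sweep=None``."""
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; known: neutral, sweep, "
            "dataset-1 .. dataset-101"
        ) from None
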