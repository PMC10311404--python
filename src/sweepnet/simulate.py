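"""Coalescent simulation of neutral and selective-sweep models, with ms-format output.

This module generates the evolutionary scenarios used for training and
benchmarking the sweep classifier: neutral equilibrium, population
bottlenecks, continent-island (ghost) migration with a population join,
recombination hotspots, and hard complete selective sweeps.  Simulation is
driven by msprime; hard sweeps use the structured-coalescent sweep model
conditioned on a genic-selection frequency trajectory.

Conventions
-----------
* ``theta = 4*N0*mu`` and ``rho = 4*N0*r`` are population-scaled rates for
  the whole region.
* Demographic event times are given in units of ``4*N0`` generations,
  except the continent-island population-join time which is in units of
  ``4*Nc`` generations (``Nc`` = continent effective size).
* ``N0`` defaults to 50 000 diploids, the reference present-day size used
  to convert coalescent time units to generations.
* Samples are haplotypes (sequences), not diploid individuals.
"""

from __future__ import annotations

import io as _io
import math
from dataclasses import dataclass, replace

import msprime
import numpy as np

__all__ = [
    "SweepParams",
    "Hotspot",
    "SimConfig",
    "Trajectory",
    "MsReplicate",
    "sweep_trajectory",
    "simulate",
    "write_ms",
]

#: decimal places used when printing relative positions in ms output
POSITION_DECIMALS = 6

#: default present-day diploid population size used for time conversion
DEFAULT_N0 = 50_000


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SweepParams:
    """A hard, complete selective sweep.

    Parameters
    ----------
    s:
        Selection coefficient of the beneficial allele (genic selection;
        heterozygote advantage ``s/2``).
    start_time:
        Time of fixation of the beneficial allele, backwards from the
        present, in units of ``4*N0`` generations.  The sweep phase of the
        coalescent occupies the interval ``[start_time, start_time +
        duration]`` (backwards).
    position_bp:
        Genomic position of the selected site in bp.
    """

    s: float
    start_time: float
    position_bp: float


@dataclass(frozen=True)
class Hotspot:
    """A recombination hotspot: ``intensity`` times the background rate
    inside ``[start_bp, end_bp)``."""

    start_bp: float
    end_bp: float
    intensity: float


@dataclass(frozen=True)
class SimConfig:
    """One evolutionary model (demography, hotspots, sweep).

    ``epochs`` is a sequence of ``(time, relative_size)`` step changes of
    the (island) population size, times in ``4*N0`` generations backwards
    and sizes relative to ``N0``.  A bottleneck of severity 0.05 beginning
    0.004 and lasting 0.002 is written ``epochs=((0.004, 0.05), (0.006,
    1.0))``.
    """

    n_samples: int = 20
    region_len: int = 100_000
    theta: float = 2000.0
    rho: float = 2000.0
    epochs: tuple[tuple[float, float], ...] = ()
    pop_join_time: float | None = None  # in 4*Nc generations
    migration_rate: float | None = None  # M = 4*Nc*m
    continent_size_ratio: float = 20.0
    hotspots: tuple[Hotspot, ...] = ()
    sweep: SweepParams | None = None
    n0: int = DEFAULT_N0
    seed: int | None = None
    label: str = ""

    def __post_init__(self):
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.theta <= 0:
            raise ValueError("theta must be > 0")
        if self.rho < 0:
            raise ValueError("rho must be >= 0")
        if self.region_len <= 0:
            raise ValueError("region_len must be > 0")
        times = [t for t, _ in self.epochs]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("epoch times must be strictly increasing")
        if any(size <= 0 for _, size in self.epochs):
            raise ValueError("epoch relative sizes must be > 0")
        hs = sorted(self.hotspots, key=lambda h: h.start_bp)
        for h in hs:
            if not (0 <= h.start_bp < h.end_bp <= self.region_len):
                raise ValueError(f"hotspot {h} outside [0, region_len]")
            if h.intensity < 1:
                raise ValueError("hotspot intensity must be >= 1")
        for h1, h2 in zip(hs, hs[1:]):
            if h2.start_bp < h1.end_bp:
                raise ValueError("hotspots must not overlap")
        if self.sweep is not None:
            if self.sweep.s <= 0:
                raise ValueError("selection coefficient must be > 0")
            if not (0 <= self.sweep.position_bp <= self.region_len):
                raise ValueError("sweep position outside region")
        if (self.pop_join_time is None) != (self.migration_rate is None):
            raise ValueError(
                "pop_join_time and migration_rate must be set together"
            )
        if self.continent_size_ratio <= 0:
            raise ValueError("continent_size_ratio must be > 0")

    # convenience -----------------------------------------------------------
    def scaled(self, factor: float) -> "SimConfig":
        """Return a copy with ``theta`` and ``rho`` divided by ``factor``.

        Desk-scale runs reduce the mutation and recombination rates while
        keeping ``N0`` (and therefore all event times, in generations)
        unchanged.
        """
        return replace(self, theta=self.theta / factor, rho=self.rho / factor)

    @property
    def mu_per_bp(self) -> float:
        return self.theta / (4 * self.n0 * self.region_len)

    @property
    def r_per_bp(self) -> float:
        return self.rho / (4 * self.n0 * self.region_len)


@dataclass(frozen=True)
class Trajectory:
    """Beneficial-allele frequency path of a complete hard sweep.

    ``times`` are generations before the present (decreasing towards
    fixation is *not* required: the array is ordered forward in time, i.e.
    from the origin of the allele to its fixation, so ``times`` decreases
    and ``freqs`` increases).
    """

    times: np.ndarray
    freqs: np.ndarray

    @property
    def duration(self) -> float:
        """Sweep duration in generations."""
        return float(self.times[0] - self.times[-1])


@dataclass
class MsReplicate:
    """One simulated replicate: binary haplotypes at segregating sites.

    ``positions`` are relative coordinates in [0, 1]; ``haplotypes`` is an
    ``n_samples x T`` array over {0 = ancestral, 1 = derived}.
    """

    positions: np.ndarray
    haplotypes: np.ndarray
    region_len: int = 100_000

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotypes must be a 2D array")
        if self.haplotypes.shape[1] != self.positions.shape[0]:
            raise ValueError("positions/haplotypes length mismatch")
        if np.any(np.diff(self.positions) < 0):
            raise ValueError("positions must be non-decreasing")

    @property
    def n_samples(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def segsites(self) -> int:
        return self.haplotypes.shape[1]


# ---------------------------------------------------------------------------
# sweep trajectory
# ---------------------------------------------------------------------------

def sweep_trajectory(
    s: float,
    pop_size: int,
    start_time: float,
    n_points: int = 1000,
) -> Trajectory:
    """Deterministic logistic frequency path of a complete hard sweep.

    The beneficial allele follows the deterministic genic-selection
    logistic ``x(t) = x0 / (x0 + (1 - x0) * exp(-s * t))`` starting from
    ``x0 = 1/(2N)``, discretised on a uniform grid of ``n_points`` time
    points.  The path is anchored so that fixation (frequency reaching
    ``1 - 1/(2N)``, rounded up to 1) occurs ``start_time`` generations
    before the present; the fixation time is the closed form
    ``t* = (2/s) * log(2N - 1)``.

    Parameters
    ----------
    s:
        Selection coefficient (> 0), per generation.
    pop_size:
        Diploid population size ``N``.
    start_time:
        Time of fixation, generations before present.
    """
    if s <= 0:
        raise ValueError("selection coefficient s must be > 0 for a sweep")
    if pop_size < 2:
        raise ValueError("pop_size must be >= 2")
    x0 = 1.0 / (2 * pop_size)
    duration = (2.0 / s) * math.log(2 * pop_size - 1)
    t = np.linspace(0.0, duration, n_points)  # forward time since origin
    freqs = x0 / (x0 + (1 - x0) * np.exp(-s * t))
    freqs[-1] = 1.0  # complete sweep
    times = start_time + duration - t  # generations before present
    return Trajectory(times=times, freqs=freqs)


# ---------------------------------------------------------------------------
# msprime model construction
# ---------------------------------------------------------------------------

def _island_demography(config: SimConfig) -> msprime.Demography:
    """Single-population demography with the configured size epochs."""
    dem = msprime.Demography()
    dem.add_population(name="island", initial_size=config.n0)
    for t, rel in config.epochs:
        dem.add_population_parameters_change(
            time=t * 4 * config.n0, initial_size=rel * config.n0,
            population="island",
        )
    return dem


def _two_pop_demography(config: SimConfig) -> msprime.Demography:
    """Continent-island demography: sampled island plus a ghost continent
    that the island joins backwards in time."""
    nc = config.continent_size_ratio * config.n0
    dem = msprime.Demography()
    dem.add_population(name="island", initial_size=config.n0)
    # active from the start: the continent exists as a ghost population
    # exchanging migrants with the island until the (backwards) join
    dem.add_population(name="continent", initial_size=nc, initially_active=True)
    for t, rel in config.epochs:
        dem.add_population_parameters_change(
            time=t * 4 * config.n0, initial_size=rel * config.n0,
            population="island",
        )
    # the island receives continent immigrants forward in time, so island
    # lineages jump to the continent backwards at rate m = M/(4*Nc)
    dem.set_migration_rate(
        source="island", dest="continent", rate=config.migration_rate / (4 * nc)
    )
    dem.add_population_split(
        time=config.pop_join_time * 4 * nc,
        derived=["island"], ancestral="continent",
    )
    dem.sort_events()
    return dem


def _recomb_rate(config: SimConfig):
    r = config.r_per_bp
    if not config.hotspots:
        return r
    pos = [0.0]
    rate = []
    for h in sorted(config.hotspots, key=lambda x: x.start_bp):
        if h.start_bp > pos[-1]:
            rate.append(r)
            pos.append(h.start_bp)
        rate.append(r * h.intensity)
        pos.append(h.end_bp)
    if pos[-1] < config.region_len:
        rate.append(r)
        pos.append(config.region_len)
    return msprime.RateMap(position=pos, rate=rate)


def _sweep_model(config: SimConfig) -> msprime.SweepGenicSelection:
    n = config.n0
    return msprime.SweepGenicSelection(
        position=config.sweep.position_bp,
        start_frequency=1.0 / (2 * n),
        end_frequency=1.0 - 1.0 / (2 * n),
        s=config.sweep.s,
        dt=1.0 / (40 * n),
    )


def _to_replicate(mts, region_len: int) -> MsReplicate:
    positions = mts.sites_position / mts.sequence_length
    haps = mts.genotype_matrix().T.astype(np.uint8)
    return MsReplicate(positions=positions, haplotypes=haps,
                       region_len=region_len)


def simulate(config: SimConfig, n_reps: int, seed: int | None = None) -> list[MsReplicate]:
    """Draw ``n_reps`` replicates from the configured coalescent model.

    Mutations are placed under the infinite-sites model (continuous
    coordinates, one mutation per site), so every column of every
    replicate is bi-allelic and segregating.  The same ``(config, seed)``
    pair always produces identical output.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)

    def next_seed() -> int:
        return int(rng.integers(1, 2**31 - 1))

    two_pop = config.pop_join_time is not None
    recomb = _recomb_rate(config)
    samples = [msprime.SampleSet(config.n_samples, population="island", ploidy=1)]
    reps: list[MsReplicate] = []

    if config.sweep is None:
        dem = _two_pop_demography(config) if two_pop else _island_demography(config)
        ancestries = msprime.sim_ancestry(
            samples=samples, demography=dem, ploidy=2,
            sequence_length=config.region_len, recombination_rate=recomb,
            num_replicates=n_reps, random_seed=next_seed(),
        )
        for ts in ancestries:
            mts = msprime.sim_mutations(
                ts, rate=config.mu_per_bp,
                model=msprime.BinaryMutationModel(),
                discrete_genome=False, random_seed=next_seed(),
            )
            reps.append(_to_replicate(mts, config.region_len))
        return reps

    # hard complete sweep: neutral recent phase, then the structured
    # coalescent conditioned on the sweep, then neutral ancient phase
    t_fix = config.sweep.start_time * 4 * config.n0
    sweep = _sweep_model(config)
    if not two_pop:
        dem = _island_demography(config)
        models = [msprime.StandardCoalescent(duration=t_fix), sweep,
                  msprime.StandardCoalescent()]
        ancestries = msprime.sim_ancestry(
            samples=samples, demography=dem, ploidy=2,
            sequence_length=config.region_len, recombination_rate=recomb,
            model=models, num_replicates=n_reps, random_seed=next_seed(),
        )
        for ts in ancestries:
            mts = msprime.sim_mutations(
                ts, rate=config.mu_per_bp,
                model=msprime.BinaryMutationModel(),
                discrete_genome=False, random_seed=next_seed(),
            )
            reps.append(_to_replicate(mts, config.region_len))
        return reps

    # sweep within the continent-island model: the sweep phase is run in
    # the island population alone (backward migration during the sweep
    # epoch is negligible at the rates considered here), after which the
    # uncoalesced lineages continue under the full two-population model.
    join_gens = config.pop_join_time * 4 * config.continent_size_ratio * config.n0
    dem2 = _two_pop_demography(config)
    for _ in range(n_reps):
        ts1 = msprime.sim_ancestry(
            samples=samples, demography=_island_demography(config), ploidy=2,
            sequence_length=config.region_len, recombination_rate=recomb,
            model=[msprime.StandardCoalescent(duration=t_fix), sweep],
            random_seed=next_seed(),
        )
        if ts1.max_root_time >= join_gens:
            raise ValueError(
                "population join time falls inside the sweep epoch "
                f"(sweep ends at {ts1.max_root_time:.0f} generations, join at "
                f"{join_gens:.0f}); this time ordering is not supported"
            )
        tables = ts1.dump_tables()
        tables.populations.clear()
        for name in ("island", "continent"):
            tables.populations.add_row(metadata={"name": name, "description": ""})
        ts2 = msprime.sim_ancestry(
            initial_state=tables.tree_sequence(), demography=dem2,
            recombination_rate=recomb, random_seed=next_seed(),
        )
        mts = msprime.sim_mutations(
            ts2, rate=config.mu_per_bp,
            model=msprime.BinaryMutationModel(),
            discrete_genome=False, random_seed=next_seed(),
        )
        reps.append(_to_replicate(mts, config.region_len))
    return reps


# ---------------------------------------------------------------------------
# ms output (Hudson dialect)
# ---------------------------------------------------------------------------

def write_ms(replicates, command_line: str | None = None, file=None) -> str | None:
    """Serialize replicates in Hudson's ms dialect.

    The stream starts with a command line and a seeds line, then one block
    per replicate::

        //
        segsites: T
        positions: 0.123456 ...
        010...
        ...

    ``segsites: 0`` blocks carry no positions line.  Returns the text when
    ``file`` is None, otherwise writes to ``file`` (a path or file object).
    """
    replicates = list(replicates)
    if not replicates:
        raise ValueError("no replicates to write")
    n = replicates[0].n_samples
    if any(r.n_samples != n for r in replicates):
        raise ValueError("replicates must share n_samples")
    if command_line is None:
        command_line = f"ms {n} {len(replicates)}"
    buf = _io.StringIO()
    buf.write(command_line + "\n")
    buf.write("0 0 0\n")
    for rep in replicates:
        buf.write("\n//\n")
        buf.write(f"segsites: {rep.segsites}\n")
        if rep.segsites > 0:
            pos = " ".join(
                f"{p:.{POSITION_DECIMALS}f}" for p in rep.positions
            )
            buf.write(f"positions: {pos}\n")
            for row in rep.haplotypes:
                buf.write("".join("01"[v] if v < 2 else "2" for v in row))
                buf.write("\n")
    text = buf.getvalue()
    if file is None:
        return text
    if hasattr(file, "write"):
        file.write(text)
    else:
        with open(file, "w") as fh:
            fh.write(text)
    return None
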