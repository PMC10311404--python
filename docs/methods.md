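# Methods

## Overview

sweepnet detects hard selective sweeps by image classification of raw
haplotype data. The pipeline has four stages:

1. **Input encoding.** Phased SNP data (ms, VCF or FASTA) become an
   `n x T` matrix of per-site states: ancestral, derived, or other
   (missing alleles, ambiguity codes, alignment gaps). Sites that are
   monomorphic among called alleles, or whose source record carries more
   than two alleles (infinite-sites violations), are filtered out.
2. **Window images.** A window of `W` consecutive SNPs (default 50),
   advanced `S` SNPs at a time (default 1), is rendered as an `N x W`
   grayscale image by multiplying the state code by 127: ancestral
   pixels are black (0), derived gray (127), everything else near-white
   (254). A matrix with `T` sites yields `floor((T-W)/S) + 1` windows.
   Windows ride on SNP indices, not physical coordinates, so resolution
   follows SNP density.
3. **Classification.** A small CNN assigns each window posterior
   probabilities of "neutral" vs "selection", producing a `c x L`
   probability matrix over the `L` windows.
4. **Selection profile.** The selection-class probabilities are averaged
   into a 1D profile along the genome (moving average over `k` windows,
   a bp-span average, or a fixed grid of evaluation points). The sweep
   is called at the profile maximum; its extent is the contiguous run of
   positions with probability at or above a threshold (default 0.5)
   around the peak. The per-replicate scan score is the profile maximum.

Detection performance is evaluated the way neutrality-test scans are
benchmarked: the detection threshold is the nearest-rank 95th percentile
of neutral per-replicate scores (5% false positive rate), TPR is the
fraction of sweep replicates scoring strictly above it, the success rate
is the fraction localized within `e = 1%` of the region length
(inclusive), and detection accuracy is the mean distance from the true
target as a percentage of region length.

## The classifier

The default architecture is three "combined layers" (a 3x3
same-padded convolution with ReLU followed by 2x2 max pooling), all with
32 filters, then one dense layer of 32 units and a 2-way softmax. The
surrounding search space — 2-5 combined layers; filter sizes 8/16/32/64
in constant, increasing or decreasing form; 1-2 dense layers of
16/32/64 units — is expressible through `ArchSpec` and the `search`
command.

The network is implemented directly in NumPy (float32, im2col
convolutions as BLAS matrix products, analytic backprop verified against
central differences in the test suite). Choices the architecture
description leaves open are set to field conventions and exposed as
parameters: ReLU activations, 2x2 max pooling (gradient split evenly on
ties), softmax cross-entropy loss, Adam at its conventional default rate
1e-3, batch size 64. Pixel values are divided by 254 into [0, 1] before
entering the network.

Training runs for 6 epochs by default with a 10% stratified validation
split; after every epoch the validation accuracy is recorded and the
returned weights are those of the best epoch (earliest on ties) — a
checkpoint-on-validation rule. All randomness (weight initialization,
split, batch order) derives from one seed, so training is reproducible
on one device, and saved bundles (`weights.npz` + `meta.json`) reload
bit-for-bit.

Training sets pair neutral replicates (windows drawn from anywhere in
the region, capped and evenly subsampled per replicate) with sweep
replicates (windows whose centers fall in the central fifth of the
region, where the training sweeps sit), so the selection class is not
diluted with effectively neutral flanking windows.

## The simulator

Training and benchmark data come from a built-in coalescent simulator
(backed by msprime) covering:

* **Neutral equilibrium** with region-scaled rates `theta = 4*N0*mu*L`
  and `rho = 4*N0*r*L`.
* **Bottlenecks**: piecewise-constant size epochs `(time, relative
  size)`, times in units of `4*N0` generations.
* **Continent-island (ghost) migration**: the sampled island exchanges
  migrants with an unsampled continent of `20x` its size
  (`M = 4*Nc*m = 3` by default); the island joins the continent
  backwards in time at `tm` (in `4*Nc` generations).
* **Recombination hotspots**: intervals whose local recombination rate
  is an integer multiple (>= 1) of the background.
* **Hard complete sweeps**: the structured coalescent conditioned on a
  genic-selection trajectory (fitnesses 1, 1+s/2, 1+s), with the sweep
  anchored so fixation occurs `start_time * 4 * N0` generations before
  the present. The deterministic logistic trajectory
  `x(t) = x0 / (x0 + (1-x0) e^{-st})`, `x0 = 1/(2N)`, with closed-form
  fixation time `(2/s) ln(2N - 1)`, is exposed as `sweep_trajectory`;
  for `s = 0.02` and `N = 50 000` the sweep lasts ~1150 generations.

Mutations follow the infinite-sites model on a continuous coordinate
axis, so every segregating site is bi-allelic with known
ancestral/derived states — matching the 0/1 encoding of ms files.
`N0 = 50 000` diploids converts coalescent units to generations.

Sweeps inside the two-population migration model run in two phases: the
recent history and the sweep itself in the island alone, then the
remaining lineages continue under the full two-population model
(migration plus the population join). Backward migration during the
sweep epoch is ignored; at the default rates the per-lineage probability
of migrating during that epoch is ~1e-3. The simulator refuses
configurations where the population join would fall inside the sweep
epoch.

The test suite checks the simulator two independent ways: against closed
forms (Watterson's `E[S] = theta * a_n`, Tajima's D centred at zero) and
against a from-scratch Kingman coalescent written directly from the
textbook definition (Kolmogorov–Smirnov agreement on the distribution of
segregating sites, for equilibrium and bottleneck demographies). Sweep
replicates are checked for the three classic signatures: diversity
trough at the target, excess high-frequency derived variants, and
elevated LD within each flank relative to LD across the target.

101 named model presets (`dataset-1` ... `dataset-101`) cover the
benchmark grid: sweeps with bottlenecks of varying severity/onset/
duration (1-60), sweeps under migration with join times from 0.003 to 3
(61-70), neutral hotspot models (71-91), and sweeps in or near a 5-kb
hotspot (92-101). Where the benchmark grid publishes only parameter
ranges, the presets use representative ladders anchored at the published
values (e.g. the hotspot-intensity ladder passes through 2, 10, 100; the
join-time ladder starts at 0.003). Individual parameters can be
overridden via `dataclasses.replace` or YAML configs.

## Problem sizes for desk runs

Full-scale benchmark simulations use `theta = rho = 2000` over 100 kb.
The package's own evaluation runs (`scripts/acceptance.py`, the
benchmark-level tests) scale these down so a complete run fits in tens
of minutes on one CPU core: by 20x (`theta = rho = 100`) for
equilibrium and hotspot models, and by 50x (`theta = rho = 40`) for the
migration model, whose deep continent genealogies carry several-fold
more polymorphism per replicate. Training uses 300+300 replicates (250
or 200 in the quicker test variants), at most 60 windows per replicate,
6 epochs; testing uses 100 replicates per arm. `N0` and all event times
in generations are kept at full scale: scaling `N0` instead would
reorder the logistic sweep duration (logarithmic in `N`) relative to
demographic event times (linear in `N`).

Two desk-scale artifacts deserve note:

* Lower `theta` stretches the sweep's hitchhiking footprint relative to
  the region (the footprint scales as `~s/r`), so at 20-50x reduction a
  central sweep sheds diversity across most of the 100-kb region and
  window-level classification is easier than at full scale.
* A replicate with fewer than `W` SNPs cannot be scanned; it receives a
  no-data (NaN) score and counts as a negative, never as a detection.
  At the migration model's desk scale roughly a third of sweep
  replicates fall in this regime (the sweep removes most island
  variation), so measured TPR there mostly reflects how many replicates
  are scannable. At full scale every replicate carries thousands of
  SNPs and this regime does not occur.

What passing desk-scale checks shows is that the pipeline's mechanics —
calibration, thresholding, scanning, localization — behave correctly
and reproduce the published operating points within stochastic
tolerance; it does not certify classification power at full-scale
polymorphism densities.

## What the synthetic data does not emulate

The simulator covers the evolutionary models above but not: soft or
incomplete sweeps, gene conversion, variable mutation rate along the
genome, genotyping error, unphased or low-coverage data, or ascertainment
bias. Real-data scans (VCF input) additionally depend on polarisation
quality: by default the AA (ancestral allele) INFO tag is used when
present and REF otherwise; FASTA input polarises by a named outgroup or
by majority allele. Misspecified polarisation swaps black and gray
pixels for affected sites, which the published encoding treats as
distinct classes.

## Numerical and tie-breaking conventions

* ms relative positions are written with 6 decimals; parsed positions
  map to bp by `ceil(pos * region_len)` with ties bumped upward so
  coordinates stay strictly increasing (1-based, VCF-style).
* The detection threshold is the nearest-rank percentile; positives are
  strictly greater than the threshold. With all-equal calibration
  scores the FPR is therefore 0, not 5%.
* Profile peaks tie-break leftmost and set a `tie` flag; grid points
  covered by no window carry NaN (a no-data marker, never 0), and NaN
  breaks extent contiguity.
* A window's probability is assigned to the midpoint of its genomic
  span (first to last SNP); profile entries in `snp` mode sit at the
  midpoint of the span covered by the `k` averaged windows.
* F1 is `2TP / (2TP + FP + FN)`, defined as 0 when precision and recall
  are both 0.

## Known limitations

* The CNN is CPU-bound NumPy: fine at desk scale (~1-2k images/s
  through the default network on one core), not meant for
  chromosome-scale training runs.
* Only haplotype-level (phased) data are supported; unphased
  heterozygotes are rejected by default or split with a warning.
* One contig per run; no multi-chromosome batching.
* The sweep model is a hard complete sweep; the migration+sweep
  composition ignores migration during the sweep epoch (see above).
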