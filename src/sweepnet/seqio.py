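"""Parsers: ms / VCF / FASTA into the internal SNP matrix, plus site filters.

Every parser produces an :class:`SNPMatrix` with per-site states drawn
from {ANCESTRAL, DERIVED, OTHER}; OTHER covers missing genotypes,
ambiguous characters and alignment gaps.  Coordinates are 1-based and
strictly increasing; ms relative positions are mapped to bp by
``ceil(pos * region_len)`` with ties resolved upward so ordering is
preserved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .simulate import MsReplicate

__all__ = [
    "ANCESTRAL",
    "DERIVED",
    "OTHER",
    "SNPMatrix",
    "FilterReport",
    "parse_ms",
    "parse_vcf",
    "parse_fasta",
    "filter_sites",
]

ANCESTRAL = 0
DERIVED = 1
OTHER = 2


@dataclass
class SNPMatrix:
    """``n_samples x T`` grid of polarised allelic states.

    ``n_source_alleles`` records, per column, how many distinct alleles the
    source record carried (used to flag infinite-sites violations); None
    means bi-allelic throughout.
    """

    states: np.ndarray
    positions_bp: np.ndarray
    region_len: int
    sample_ids: list[str] = field(default_factory=list)
    n_source_alleles: np.ndarray | None = None

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=np.uint8)
        self.positions_bp = np.asarray(self.positions_bp, dtype=np.int64)
        if self.states.ndim != 2:
            raise ValueError("states must be 2D (samples x sites)")
        if self.states.shape[1] != self.positions_bp.shape[0]:
            raise ValueError("states/positions length mismatch")
        if self.positions_bp.size and np.any(np.diff(self.positions_bp) <= 0):
            raise ValueError("positions must be strictly increasing")
        if not self.sample_ids:
            self.sample_ids = [f"hap_{i}" for i in range(self.states.shape[0])]

    @property
    def n_samples(self) -> int:
        return self.states.shape[0]

    @property
    def n_sites(self) -> int:
        return self.states.shape[1]


@dataclass
class FilterReport:
    n_input: int
    n_kept: int
    n_monomorphic: int
    n_infinite_sites_violations: int

    def to_tsv(self) -> str:
        rows = [
            ("sites_input", self.n_input),
            ("sites_kept", self.n_kept),
            ("removed_monomorphic", self.n_monomorphic),
            ("removed_infinite_sites_violation",
             self.n_infinite_sites_violations),
        ]
        return "\n".join(f"{k}\t{v}" for k, v in rows) + "\n"


# ---------------------------------------------------------------------------
# position mapping
# ---------------------------------------------------------------------------

def _relative_to_bp(rel: np.ndarray, region_len: int) -> np.ndarray:
    """Map relative [0, 1] positions to 1-based bp; ties bumped upward to
    keep coordinates strictly increasing."""
    bp = np.ceil(np.asarray(rel, dtype=float) * region_len).astype(np.int64)
    bp = np.maximum(bp, 1)
    for i in range(1, bp.size):
        if bp[i] <= bp[i - 1]:
            bp[i] = bp[i - 1] + 1
    return bp


# ---------------------------------------------------------------------------
# ms (Hudson dialect)
# ---------------------------------------------------------------------------

def parse_ms(source, region_len: int = 100_000) -> list[SNPMatrix]:
    """Parse a Hudson-dialect ms stream into one SNPMatrix per replicate.

    ``source`` may be a path, a file object, or the text itself.  0 maps
    to ANCESTRAL, 1 to DERIVED; any other haplotype character maps to
    OTHER.  Relative positions are scaled to bp by ``region_len``.
    """
    text = _read_text(source)
    lines = text.splitlines()
    matrices: list[SNPMatrix] = []
    i = 0
    rep_index = 0
    while i < len(lines):
        if not lines[i].startswith("//"):
            i += 1
            continue
        rep_index += 1
        i += 1
        while i < len(lines) and not lines[i].startswith("segsites:"):
            i += 1
        if i >= len(lines):
            raise ValueError(
                f"replicate {rep_index}: missing 'segsites:' line"
            )
        segsites = int(lines[i].split(":", 1)[1])
        i += 1
        if segsites == 0:
            matrices.append(
                SNPMatrix(
                    states=np.zeros((0, 0), dtype=np.uint8),
                    positions_bp=np.zeros(0, dtype=np.int64),
                    region_len=region_len,
                )
            )
            continue
        while i < len(lines) and not lines[i].startswith("positions:"):
            if lines[i].strip() and not lines[i].startswith("segsites"):
                raise ValueError(
                    f"replicate {rep_index}: missing 'positions:' line"
                )
            i += 1
        rel = np.array(
            [float(x) for x in lines[i].split(":", 1)[1].split()], dtype=float
        )
        if rel.size != segsites:
            raise ValueError(
                f"replicate {rep_index}: positions length {rel.size} != "
                f"segsites {segsites}"
            )
        i += 1
        rows: list[np.ndarray] = []
        while i < len(lines):
            line = lines[i].strip()
            if not line or line.startswith("//"):
                break
            if len(line) != segsites:
                raise ValueError(
                    f"replicate {rep_index}: haplotype row length "
                    f"{len(line)} != segsites {segsites}"
                )
            row = np.frombuffer(line.encode(), dtype=np.uint8)
            states = np.full(segsites, OTHER, dtype=np.uint8)
            states[row == ord("0")] = ANCESTRAL
            states[row == ord("1")] = DERIVED
            rows.append(states)
            i += 1
        matrices.append(
            SNPMatrix(
                states=np.vstack(rows) if rows else np.zeros((0, segsites), np.uint8),
                positions_bp=_relative_to_bp(rel, region_len),
                region_len=region_len,
            )
        )
    return matrices


def _read_text(source) -> str:
    if hasattr(source, "read"):
        return source.read()
    if isinstance(source, str) and ("\n" in source or source.startswith("ms ")):
        return source
    with open(source) as fh:
        return fh.read()


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def parse_vcf(
    path,
    sample_subset: list[str] | None = None,
    ancestral: str = "aa",
    on_unphased: str = "error",
    region_len: int | None = None,
) -> SNPMatrix:
    """Parse phased haplotypes from a VCF (plain or bgzipped).

    Each diploid sample contributes two haplotype rows.  Polarisation:
    with ``ancestral="aa"`` the AA INFO tag is used when present and
    matching REF or ALT, falling back to REF-as-ancestral; ``"ref"``
    always treats REF as ancestral.  Missing alleles become OTHER.
    Multi-allelic records are kept but marked as infinite-sites
    violations for :func:`filter_sites`.
    """
    from cyvcf2 import VCF

    if on_unphased not in ("error", "warn"):
        raise ValueError("on_unphased must be 'error' or 'warn'")
    vcf = VCF(str(path))
    if sample_subset is not None:
        vcf.set_samples(sample_subset)
    samples = list(vcf.samples)

    columns: list[np.ndarray] = []
    positions: list[int] = []
    n_alleles: list[int] = []
    warned = False
    for var in vcf:
        gts = var.genotypes  # [[a0, a1, phased], ...]
        states = np.full(2 * len(samples), OTHER, dtype=np.uint8)
        anc_is_alt = False
        if ancestral == "aa":
            aa = var.INFO.get("AA")
            if aa is not None:
                aa = str(aa).upper().rstrip("|").split("|")[0]
                if var.ALT and aa == str(var.ALT[0]).upper():
                    anc_is_alt = True
        for si, gt in enumerate(gts):
            alleles, phased = gt[:-1], gt[-1]
            if len(alleles) != 2:
                raise ValueError(
                    f"sample {samples[si]} at {var.POS}: ploidy "
                    f"{len(alleles)} not supported"
                )
            if not phased and alleles[0] != alleles[1]:
                msg = (f"unphased heterozygote for {samples[si]} at position "
                       f"{var.POS}")
                if on_unphased == "error":
                    raise ValueError(msg)
                if not warned:
                    warnings.warn(msg + " (treating alleles as haplotypes)")
                    warned = True
            for hi, a in enumerate(alleles):
                if a < 0:
                    continue  # missing -> OTHER
                if anc_is_alt:
                    s = ANCESTRAL if a == 1 else (DERIVED if a == 0 else OTHER)
                else:
                    s = ANCESTRAL if a == 0 else (DERIVED if a == 1 else OTHER)
                states[2 * si + hi] = s
        columns.append(states)
        positions.append(var.POS)
        n_alleles.append(1 + len(var.ALT))

    ids = [f"{s}_{h}" for s in samples for h in (1, 2)]
    if not columns:
        return SNPMatrix(
            states=np.zeros((2 * len(samples), 0), np.uint8),
            positions_bp=np.zeros(0, np.int64),
            region_len=region_len or 0,
            sample_ids=ids,
        )
    states = np.column_stack(columns)
    pos = np.asarray(positions, dtype=np.int64)
    order = np.argsort(pos, kind="stable")
    keep = np.ones(pos.size, dtype=bool)
    keep[1:] = np.diff(pos[order]) > 0  # drop exact duplicate coordinates
    order = order[keep]
    return SNPMatrix(
        states=states[:, order],
        positions_bp=pos[order],
        region_len=region_len or int(pos.max()),
        sample_ids=ids,
        n_source_alleles=np.asarray(n_alleles, np.int64)[order],
    )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

_DNA = frozenset("ACGT")


def parse_fasta(
    path,
    ancestral_source: str = "majority",
    region_len: int | None = None,
) -> SNPMatrix:
    """Extract polymorphic columns from an aligned FASTA.

    ``ancestral_source`` is either ``"majority"`` (most frequent base per
    column, ties broken alphabetically) or ``"outgroup:NAME"`` (the named
    sequence supplies the ancestral base and is excluded from the sample
    rows).  Gaps and ambiguity codes become OTHER.  Columns with more
    than two proper bases are kept but flagged for :func:`filter_sites`.
    """
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no sequences in {path}")
    lengths = {len(r.seq) for r in records}
    if len(lengths) != 1:
        raise ValueError(f"ragged alignment: sequence lengths {sorted(lengths)}")
    aln_len = lengths.pop()

    outgroup = None
    if ancestral_source.startswith("outgroup:"):
        name = ancestral_source.split(":", 1)[1]
        matches = [r for r in records if r.id == name]
        if not matches:
            raise ValueError(f"outgroup sequence {name!r} not found")
        outgroup = str(matches[0].seq).upper()
        records = [r for r in records if r.id != name]
    elif ancestral_source != "majority":
        raise ValueError("ancestral_source must be 'majority' or 'outgroup:NAME'")

    seqs = np.array([list(str(r.seq).upper()) for r in records])
    ids = [r.id for r in records]

    cols: list[np.ndarray] = []
    positions: list[int] = []
    n_alleles: list[int] = []
    for j in range(aln_len):
        col = seqs[:, j]
        bases = [b for b in col if b in _DNA]
        distinct = sorted(set(bases))
        if len(distinct) < 2:
            continue  # monomorphic among called bases
        if outgroup is not None and outgroup[j] in _DNA:
            anc = outgroup[j]
        else:
            counts = {b: bases.count(b) for b in distinct}
            anc = min(distinct, key=lambda b: (-counts[b], b))
        derived = [b for b in distinct if b != anc]
        states = np.full(col.size, OTHER, dtype=np.uint8)
        states[col == anc] = ANCESTRAL
        if derived:
            states[col == derived[0]] = DERIVED
        cols.append(states)
        positions.append(j + 1)
        n_alleles.append(len(distinct) if anc in distinct else len(distinct) + 1)

    if not cols:
        return SNPMatrix(
            states=np.zeros((len(ids), 0), np.uint8),
            positions_bp=np.zeros(0, np.int64),
            region_len=region_len or aln_len,
            sample_ids=ids,
        )
    return SNPMatrix(
        states=np.column_stack(cols),
        positions_bp=np.asarray(positions, np.int64),
        region_len=region_len or aln_len,
        sample_ids=ids,
        n_source_alleles=np.asarray(n_alleles, np.int64),
    )


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def filter_sites(m: SNPMatrix) -> tuple[SNPMatrix, FilterReport]:
    """Drop monomorphic columns and infinite-sites violations.

    A column is monomorphic when fewer than two distinct states from
    {ANCESTRAL, DERIVED} occur among called alleles; a column violates the
    infinite-sites assumption when its source record carried more than
    two alleles.  Idempotent: filtering a filtered matrix is a no-op.
    """
    if m.n_sites == 0:
        return m, FilterReport(0, 0, 0, 0)
    has_anc = (m.states == ANCESTRAL).any(axis=0)
    has_der = (m.states == DERIVED).any(axis=0)
    segregating = has_anc & has_der
    if m.n_source_alleles is None:
        biallelic = np.ones(m.n_sites, dtype=bool)
    else:
        biallelic = m.n_source_alleles <= 2
    keep = segregating & biallelic
    n_multi = int((~biallelic).sum())
    n_mono = int((~segregating & biallelic).sum())
    filtered = SNPMatrix(
        states=m.states[:, keep],
        positions_bp=m.positions_bp[keep],
        region_len=m.region_len,
        sample_ids=list(m.sample_ids),
        n_source_alleles=(None if m.n_source_alleles is None
                          else m.n_source_alleles[keep]),
    )
    return filtered, FilterReport(
        n_input=m.n_sites,
        n_kept=int(keep.sum()),
        n_monomorphic=n_mono,
        n_infinite_sites_violations=n_multi,
    )


def from_replicate(rep: MsReplicate) -> SNPMatrix:
    """Convert an in-memory simulated replicate to an SNPMatrix."""
    return SNPMatrix(
        states=rep.haplotypes.astype(np.uint8),
        positions_bp=_relative_to_bp(rep.positions, rep.region_len),
        region_len=rep.region_len,
    )
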