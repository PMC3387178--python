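"""Watterson's theta and effective population size from haplotype alignments.

The simulation scenarios need absolute effective sizes.  These are
derived from plastid haplotype data: count segregating sites S in an
alignment of n haplotypes over L sites, estimate the population
mutation rate per site as theta_w = S / (a_{n-1} * L) with
a_{n-1} = sum_{i=1}^{n-1} 1/i, and convert to an effective size via the
organellar convention theta_w = 2 * mu * Ne (mu per site per
generation).  Nuclear sizes follow from the fixed x2 nuclear/plastid
relationship (plastid genomes are haploid and uniparentally inherited),
which reproduces the three reference scenario pairs
190000/95000, 320000/160000 and 680000/340000 exactly.

Missing data: gaps, N and any non-ACGT IUPAC code are treated as
missing; a column needs at least two called bases differing to count as
segregating.  L counts all alignment columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import SeqIO

from .coalescent import ORGANELLAR_SCALING_DEFAULT

__all__ = [
    "HaplotypeAlignment",
    "NeEstimate",
    "read_fasta_alignment",
    "segregating_sites",
    "harmonic_number",
    "watterson_theta",
    "mu_per_generation",
    "ne_from_theta",
    "scale_ne_for_locus",
    "estimate_ne",
]

_CALLED = frozenset("ACGT")


@dataclass
class HaplotypeAlignment:
    """Equal-length nucleotide haplotypes with labels (alphabet ACGTN-)."""

    labels: list[str]
    sequences: list[str]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.sequences):
            raise ValueError("labels and sequences differ in number")
        if len(self.sequences) < 2:
            raise ValueError("need at least 2 haplotypes")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise ValueError(f"unequal sequence lengths: {sorted(lengths)}")
        self.sequences = [s.upper() for s in self.sequences]

    @property
    def n(self) -> int:
        return len(self.sequences)

    @property
    def length(self) -> int:
        return len(self.sequences[0])


@dataclass
class NeEstimate:
    """Per-locus effective size with the quantities it was derived from."""

    species: str
    locus: str
    n: int
    length: int
    s: int
    theta_w: float  # per site
    mu: float  # per site per generation
    ne: float


def read_fasta_alignment(path: str) -> HaplotypeAlignment:
    records = list(SeqIO.parse(path, "fasta"))
    if not records:
        raise ValueError(f"no sequences in {path!r}")
    return HaplotypeAlignment(
        labels=[r.id for r in records], sequences=[str(r.seq) for r in records]
    )


def segregating_sites(aln: HaplotypeAlignment) -> int:
    """Columns with >= 2 distinct called (ACGT) bases."""
    s = 0
    for col in zip(*aln.sequences):
        called = {c for c in col if c in _CALLED}
        if len(called) >= 2:
            s += 1
    return s


def harmonic_number(k: int) -> float:
    """a_k = sum_{i=1}^{k} 1/i (Watterson's denominator uses a_{n-1})."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return float(np.sum(1.0 / np.arange(1, k + 1)))


def watterson_theta(s: int, n: int, length: int) -> float:
    """Per-site Watterson estimator: S / (a_{n-1} * L)."""
    if n < 2:
        raise ValueError("sample size must be >= 2")
    if length < 1:
        raise ValueError("alignment length must be >= 1")
    if s < 0:
        raise ValueError("segregating sites must be nonnegative")
    return s / (harmonic_number(n - 1) * length)


def mu_per_generation(rate_per_ma: float, generation_time: float) -> float:
    """Convert substitutions/site/Ma to per site per generation."""
    if generation_time <= 0:
        raise ValueError("generation time must be positive")
    if rate_per_ma < 0:
        raise ValueError("rate must be nonnegative")
    return rate_per_ma * generation_time / 1.0e6


def ne_from_theta(theta_w: float, mu: float) -> float:
    """Ne = theta_w / (2 * mu) (organellar convention theta = 2*mu*Ne)."""
    if mu <= 0:
        raise ValueError("mutation rate must be positive")
    if theta_w < 0:
        raise ValueError("theta must be nonnegative")
    return theta_w / (2.0 * mu)


def scale_ne_for_locus(
    nuclear_ne: float, factor: float = ORGANELLAR_SCALING_DEFAULT
) -> float:
    """Plastid Ne from nuclear Ne (default x0.5)."""
    if nuclear_ne <= 0:
        raise ValueError("Ne must be positive")
    return nuclear_ne * factor


def estimate_ne(
    aln: HaplotypeAlignment,
    mu: float,
    species: str = "",
    locus: str = "plastid",
) -> NeEstimate:
    """Full chain: alignment -> S -> theta_w -> Ne."""
    s = segregating_sites(aln)
    theta = watterson_theta(s, aln.n, aln.length)
    return NeEstimate(
        species=species,
        locus=locus,
        n=aln.n,
        length=aln.length,
        s=s,
        theta_w=theta,
        mu=mu,
        ne=ne_from_theta(theta, mu),
    )
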