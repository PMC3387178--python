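"""Taxon-deletion scan for potential hybrids.

A hybrid carries one locus whose genealogy disagrees with the others,
so its terminal inflates cross-locus (observed) distances without
inflating the ILS baseline.  Deleting that terminal and recomputing
both distributions should therefore pull them together.  The scan:

1. flags terminals whose one-at-a-time pruning reduces cross-locus RF
   conflict (the incongruent candidates);
2. for each candidate, recomputes the baseline/observed separation with
   the candidate pruned — re-simulating the baseline on the pruned
   chronograms — under 3 gene pairings x 3 Ne scenarios;
3. averages the nine step deltas per candidate (the nine replications
   damp the stochastic, non-reproducible effect of a single deletion);
4. classifies candidates with a negative average (deletion brought the
   distributions closer) as potential hybrids.

Step deltas are integers in RF units: negative = approximation of the
two distributions, positive = further separation.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field

import numpy as np

from .coalescent import NeConfig, SimRequest, simulate_baseline_sample
from .incongruence import DistanceDistribution, separation_steps
from .trees import TreeSample, prune_taxa, restrict_splits, rf_from_splits

__all__ = [
    "Gene",
    "GenePairing",
    "StepRecord",
    "StepTable",
    "default_pairings",
    "flag_incongruent_taxa",
    "average_deletion_effect",
    "classify_potential_hybrids",
    "HybridScanEngine",
    "build_step_table",
]


@dataclass
class Gene:
    """A locus: its posterior chronogram sample and genome of origin."""

    name: str
    sample: TreeSample
    locus: str = "nuclear"  # nuclear | plastid


@dataclass(frozen=True)
class GenePairing:
    """One column block of the step table.

    ``baseline_gene`` is the locus whose chronograms seed the coalescent
    simulations; ``observed_pair`` are the two loci whose cross
    distances form the observed distribution.
    """

    name: str
    baseline_gene: str
    observed_pair: tuple[str, str]


def default_pairings(genes: list[str]) -> list[GenePairing]:
    """The canonical three pairings for an ITS/AGT1/cpDNA-style design.

    First two genes are paired against the third (typically the plastid
    locus); the third's baseline is compared to the first-vs-third
    observed distribution.
    """
    if len(genes) != 3:
        raise ValueError("default pairings require exactly 3 genes")
    g1, g2, g3 = genes
    return [
        GenePairing(f"{g1}~{g1}-{g3}", g1, (g1, g3)),
        GenePairing(f"{g2}~{g2}-{g3}", g2, (g2, g3)),
        GenePairing(f"{g3}~{g1}-{g3}", g3, (g1, g3)),
    ]


def average_deletion_effect(deltas) -> float:
    """Mean of the nine step deltas, rounded half-up to 2 decimals."""
    deltas = list(deltas)
    if len(deltas) != 9:
        raise ValueError(f"expected exactly 9 deltas, got {len(deltas)}")
    mean = decimal.Decimal(int(sum(deltas))) / decimal.Decimal(9)
    return float(
        mean.quantize(decimal.Decimal("0.01"), rounding=decimal.ROUND_HALF_UP)
    )


@dataclass
class StepRecord:
    """Per-taxon deletion effects: 9 cells (pairing x Ne scenario)."""

    taxon: str
    deltas: dict  # (pairing name, scenario name) -> int
    average: float = field(init=False)

    def __post_init__(self) -> None:
        self.average = average_deletion_effect(self.deltas.values())


@dataclass
class StepTable:
    records: list[StepRecord]
    threshold: float = 0.0

    def __post_init__(self) -> None:
        taxa = [r.taxon for r in self.records]
        if len(set(taxa)) != len(taxa):
            raise ValueError("duplicate taxa in step table")
        self.records = sorted(self.records, key=lambda r: (r.average, r.taxon))

    def __len__(self) -> int:
        return len(self.records)

    def to_dataframe(self):
        import pandas as pd

        if not self.records:
            return pd.DataFrame(columns=["taxon", "average", "potential_hybrid"])
        cells = list(self.records[0].deltas.keys())
        rows = []
        for r in self.records:
            row = {"taxon": r.taxon}
            row.update({f"{p}|{s}": r.deltas[(p, s)] for (p, s) in cells})
            row["average"] = r.average
            row["potential_hybrid"] = r.average < self.threshold
            rows.append(row)
        return pd.DataFrame(rows)


def classify_potential_hybrids(table: StepTable) -> tuple[list[str], list[str]]:
    """Split taxa into potential hybrids (average < 0) and the rest.

    Hybrids are returned most-negative first; ties at exactly 0 are
    classified non-hybrid (strict inequality).
    """
    hybrids = [r.taxon for r in table.records if r.average < table.threshold]
    non = [r.taxon for r in table.records if r.average >= table.threshold]
    return hybrids, non


def flag_incongruent_taxa(
    a: TreeSample, b: TreeSample, min_drop: int = 2
) -> set[str]:
    """Terminals whose pruning reduces cross-sample RF conflict.

    Taxon ``t`` is flagged iff the median over all cross pairs of
    ``rf(x, y) - rf(x - t, y - t)`` is at least ``min_drop``
    (``min_drop=2`` corresponds to at least one shared conflicting
    split attributable to ``t``).  Deterministic.
    """
    if min_drop < 1:
        raise ValueError("min_drop must be >= 1")
    if a.taxa != b.taxa:
        shared = a.taxa & b.taxa
        if len(shared) < 4:
            raise ValueError("fewer than 4 shared taxa")
        a, b = a.restrict_to(shared), b.restrict_to(shared)
    taxa = a.taxa
    if len(taxa) < 4:
        raise ValueError("fewer than 4 shared taxa")
    sa, sb = a.split_sets(), b.split_sets()
    base = np.array(
        [rf_from_splits(x, y) for x in sa for y in sb], dtype=int
    )
    flagged = set()
    for t in sorted(taxa):
        ra = [restrict_splits(x, taxa, (t,)) for x in sa]
        rb = [restrict_splits(y, taxa, (t,)) for y in sb]
        after = np.array(
            [rf_from_splits(x, y) for x in ra for y in rb], dtype=int
        )
        if np.median(base - after) >= min_drop:
            flagged.add(t)
    return flagged


class HybridScanEngine:
    """Shared state for a full deletion scan over one set of loci.

    Restricts all gene samples to the common taxon set, caches split
    sets and pruned chronograms, and re-simulates baselines on pruned
    chronograms for every deletion cell (a fresh simulation, not a
    pruning of cached simulated trees — deletions must not inherit the
    stochastic noise of the unpruned baseline).
    """

    def __init__(
        self,
        genes: list[Gene],
        scenarios: list[NeConfig],
        pairings: list[GenePairing] | None = None,
        replicates: int = 5,
        seed: int = 0,
        require_nine: bool = True,
    ):
        names = [g.name for g in genes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate gene names")
        if pairings is None:
            pairings = default_pairings(names)
        if require_nine and (len(scenarios) != 3 or len(pairings) != 3):
            raise ValueError(
                "the nine-replicate design requires 3 Ne scenarios x 3 gene "
                "pairings (pass require_nine=False to override)"
            )
        for p in pairings:
            for g in (p.baseline_gene, *p.observed_pair):
                if g not in names:
                    raise ValueError(f"pairing {p.name!r} references unknown gene {g!r}")
        shared = frozenset.intersection(*(g.sample.taxa for g in genes))
        if len(shared) < 4:
            raise ValueError("genes share fewer than 4 taxa")
        self.genes = {
            g.name: Gene(g.name, g.sample.restrict_to(shared), g.locus)
            for g in genes
        }
        self.taxa = shared
        self.scenarios = scenarios
        self.pairings = pairings
        self.replicates = replicates
        self._rng = np.random.default_rng(seed)
        self._splits = {n: g.sample.split_sets() for n, g in self.genes.items()}
        self._pruned_chrono: dict = {}
        self._present_sep: dict = {}

    # -- internals ---------------------------------------------------

    def _next_seed(self) -> int:
        return int(self._rng.integers(2**31 - 1))

    def _baseline_values(self, gene: str, ne: NeConfig, taxon: str | None) -> np.ndarray:
        """Posterior-vs-simulated RF values, optionally with taxon pruned."""
        g = self.genes[gene]
        if taxon is None:
            chronos = g.sample
            post_splits = self._splits[gene]
        else:
            key = (gene, taxon)
            if key not in self._pruned_chrono:
                self._pruned_chrono[key] = TreeSample(
                    [prune_taxa(t, (taxon,)) for t in g.sample],
                    source=f"{g.sample.source}-{taxon}",
                )
            chronos = self._pruned_chrono[key]
            post_splits = [
                restrict_splits(s, self.taxa, (taxon,)) for s in self._splits[gene]
            ]
        sim = simulate_baseline_sample(
            SimRequest(
                chronograms=chronos,
                locus=g.locus,
                replicates=self.replicates,
                seed=self._next_seed(),
            ),
            ne,
        )
        sim_splits = sim.split_sets()
        return np.array(
            [rf_from_splits(x, y) for x in post_splits for y in sim_splits],
            dtype=int,
        )

    def _observed_values(self, pair: tuple[str, str], taxon: str | None) -> np.ndarray:
        s1, s2 = self._splits[pair[0]], self._splits[pair[1]]
        if taxon is not None:
            s1 = [restrict_splits(s, self.taxa, (taxon,)) for s in s1]
            s2 = [restrict_splits(s, self.taxa, (taxon,)) for s in s2]
        return np.array(
            [rf_from_splits(x, y) for x in s1 for y in s2], dtype=int
        )

    def _separation(self, pairing: GenePairing, ne: NeConfig, taxon: str | None) -> int:
        obs = DistanceDistribution(self._observed_values(pairing.observed_pair, taxon))
        base = DistanceDistribution(self._baseline_values(pairing.baseline_gene, ne, taxon))
        return separation_steps(obs, base)

    # -- public API --------------------------------------------------

    def candidate_taxa(self, min_drop: int = 2) -> set[str]:
        """Union of incongruent terminals over all configured observed pairs."""
        pairs = {p.observed_pair for p in self.pairings}
        out: set[str] = set()
        for g1, g2 in sorted(pairs):
            out |= flag_incongruent_taxa(
                self.genes[g1].sample, self.genes[g2].sample, min_drop=min_drop
            )
        return out

    def present_separation(self, pairing: GenePairing, ne: NeConfig) -> int:
        key = (pairing.name, ne.name)
        if key not in self._present_sep:
            self._present_sep[key] = self._separation(pairing, ne, None)
        return self._present_sep[key]

    def deletion_effect(self, taxon: str, pairing: GenePairing, ne: NeConfig) -> int:
        """Step delta for one (taxon, pairing, scenario) cell.

        ``separation(after pruning taxon, fresh baseline) - separation
        (taxon present)``; negative means the distributions approached.
        """
        if taxon not in self.taxa:
            raise ValueError(f"taxon {taxon!r} not present in the shared taxon set")
        before = self.present_separation(pairing, ne)
        after = self._separation(pairing, ne, taxon)
        return int(after - before)

    def run(self, candidates=None, min_drop: int = 2) -> StepTable:
        """Full scan: one StepRecord (9 cells + average) per candidate."""
        if candidates is None:
            candidates = self.candidate_taxa(min_drop=min_drop)
        records = []
        for taxon in sorted(candidates):
            deltas = {}
            for pairing in self.pairings:
                for ne in self.scenarios:
                    deltas[(pairing.name, ne.name)] = self.deletion_effect(
                        taxon, pairing, ne
                    )
            records.append(StepRecord(taxon=taxon, deltas=deltas))
        return StepTable(records)


def build_step_table(
    candidates,
    genes: list[Gene],
    scenarios: list[NeConfig],
    pairings: list[GenePairing] | None = None,
    replicates: int = 5,
    seed: int = 0,
    require_nine: bool = True,
) -> StepTable:
    """Convenience wrapper: scan ``candidates`` and return the step table."""
    engine = HybridScanEngine(
        genes,
        scenarios,
        pairings=pairings,
        replicates=replicates,
        seed=seed,
        require_nine=require_nine,
    )
    return engine.run(candidates=candidates)
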