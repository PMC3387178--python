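"""Model/Results interface over the incongruence pipeline.

Two model classes wrap the library the way statistical modelling
packages present estimators: construct from data, call ``fit`` (which
runs the simulations), inspect a Results object.

* :class:`IncongruenceTest` — per (gene pairing x Ne scenario), build
  the baseline and observed distance distributions and decide whether
  ILS alone explains the cross-locus incongruence.
* :class:`HybridDeletionScan` — the taxon-deletion scan: candidate
  flagging, nine-replicate step table, hybrid classification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coalescent import NeConfig, SimRequest, simulate_baseline_sample
from .hybridscan import (
    Gene,
    GenePairing,
    HybridScanEngine,
    StepTable,
    classify_potential_hybrids,
    default_pairings,
)
from .incongruence import (
    DistanceDistribution,
    OverlapResult,
    baseline_distribution,
    ils_only_test,
    observed_distribution,
)

__all__ = [
    "IncongruenceTest",
    "IncongruenceResults",
    "HybridDeletionScan",
    "HybridScanResults",
]


class IncongruenceTest:
    """ILS-only test of cross-locus gene-tree incongruence.

    Parameters
    ----------
    genes
        Loci with their posterior chronogram samples and genome kinds.
    scenarios
        Effective-size scenarios to repeat the test under.
    pairings
        Baseline-locus / observed-pair configuration; defaults to the
        canonical three pairings for a 3-locus design.
    replicates
        MSC gene trees simulated per posterior chronogram (default 5,
        so 20 chronograms give a 100-tree baseline sample).
    """

    def __init__(
        self,
        genes: list[Gene],
        scenarios: list[NeConfig],
        pairings: list[GenePairing] | None = None,
        replicates: int = 5,
    ):
        if not scenarios:
            raise ValueError("need at least one Ne scenario")
        self.genes = {g.name: g for g in genes}
        self.scenarios = list(scenarios)
        self.pairings = pairings or default_pairings([g.name for g in genes])
        self.replicates = replicates

    @classmethod
    def from_files(cls, paths: dict, loci: dict, scenarios, **kw):
        """Build from {gene: tree file path} and {gene: locus kind}."""
        from .trees import read_tree_sample

        genes = [
            Gene(name, read_tree_sample(path, source=name), loci[name])
            for name, path in paths.items()
        ]
        return cls(genes, scenarios, **kw)

    def fit(self, seed: int = 0) -> "IncongruenceResults":
        rng = np.random.default_rng(seed)
        cells = {}
        for pairing in self.pairings:
            g1, g2 = pairing.observed_pair
            obs = observed_distribution(
                self.genes[g1].sample, self.genes[g2].sample
            )
            for ne in self.scenarios:
                gb = self.genes[pairing.baseline_gene]
                sim = simulate_baseline_sample(
                    SimRequest(
                        chronograms=gb.sample,
                        locus=gb.locus,
                        replicates=self.replicates,
                        seed=int(rng.integers(2**31 - 1)),
                    ),
                    ne,
                )
                base = baseline_distribution(gb.sample, sim)
                res = ils_only_test(
                    obs, base, scenario=ne.name, pairing=pairing.name
                )
                cells[(pairing.name, ne.name)] = (obs, base, res)
        return IncongruenceResults(self, cells, seed)


@dataclass
class IncongruenceResults:
    """Per-cell distributions and overlap decisions."""

    model: IncongruenceTest
    cells: dict  # (pairing, scenario) -> (observed, baseline, OverlapResult)
    seed: int

    @property
    def overlap_results(self) -> list[OverlapResult]:
        return [r for (_, _, r) in self.cells.values()]

    def observed(self, pairing: str, scenario: str) -> DistanceDistribution:
        return self.cells[(pairing, scenario)][0]

    def baseline(self, pairing: str, scenario: str) -> DistanceDistribution:
        return self.cells[(pairing, scenario)][1]

    @property
    def n_rejections(self) -> int:
        return sum(r.rejects_ils_only for r in self.overlap_results)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (pairing, scenario), (obs, base, res) in self.cells.items():
            rows.append(
                {
                    "pairing": pairing,
                    "scenario": scenario,
                    "baseline_95": f"[{base.lower95}, {base.upper95}]",
                    "observed_95": f"[{obs.lower95}, {obs.upper95}]",
                    "separation_steps": res.separation,
                    "ils_only_rejected": res.rejects_ils_only,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        frame = self.to_frame()
        lines = [
            "ILS-only incongruence test",
            "=" * 62,
            f"loci: {', '.join(self.model.genes)}   "
            f"scenarios: {', '.join(ne.name for ne in self.model.scenarios)}",
            f"baseline replicates per chronogram: {self.model.replicates}   "
            f"seed: {self.seed}",
            "-" * 62,
            frame.to_string(index=False),
            "-" * 62,
            f"ILS-only rejected in {self.n_rejections}/{len(self.cells)} cells",
        ]
        return "\n".join(lines)


class HybridDeletionScan:
    """Taxon-deletion scan ranking potential hybrids.

    ``fit`` flags incongruent candidates (unless an explicit candidate
    list is given), builds the nine-replicate step table, and
    classifies taxa whose deletion on average pulls the baseline and
    observed distributions together (negative average) as potential
    hybrids.
    """

    def __init__(
        self,
        genes: list[Gene],
        scenarios: list[NeConfig],
        pairings: list[GenePairing] | None = None,
        replicates: int = 5,
        min_drop: int = 2,
        require_nine: bool = True,
    ):
        self.genes = genes
        self.scenarios = list(scenarios)
        self.pairings = pairings
        self.replicates = replicates
        self.min_drop = min_drop
        self.require_nine = require_nine

    def fit(self, seed: int = 0, candidates=None) -> "HybridScanResults":
        engine = HybridScanEngine(
            self.genes,
            self.scenarios,
            pairings=self.pairings,
            replicates=self.replicates,
            seed=seed,
            require_nine=self.require_nine,
        )
        if candidates is None:
            candidates = engine.candidate_taxa(min_drop=self.min_drop)
        table = engine.run(candidates=candidates)
        return HybridScanResults(self, engine, sorted(candidates), table, seed)


@dataclass
class HybridScanResults:
    model: HybridDeletionScan
    engine: HybridScanEngine
    candidates: list[str]
    step_table: StepTable
    seed: int

    @property
    def hybrids(self) -> list[str]:
        return classify_potential_hybrids(self.step_table)[0]

    @property
    def non_hybrids(self) -> list[str]:
        return classify_potential_hybrids(self.step_table)[1]

    def to_frame(self) -> pd.DataFrame:
        return self.step_table.to_dataframe()

    def summary(self) -> str:
        lines = [
            "Taxon-deletion hybrid scan",
            "=" * 62,
            f"candidates: {len(self.candidates)}   "
            f"scenarios: {', '.join(ne.name for ne in self.engine.scenarios)}   "
            f"seed: {self.seed}",
            "-" * 62,
        ]
        frame = self.to_frame()
        if len(frame):
            lines.append(frame.to_string(index=False))
        else:
            lines.append("(no candidate taxa)")
        lines += [
            "-" * 62,
            f"potential hybrids (average < 0): {len(self.hybrids)}",
        ]
        if self.hybrids:
            lines.append("  " + ", ".join(self.hybrids))
        return "\n".join(lines)
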