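"""Baseline vs observed tree-distance distributions and the ILS-only test.

The test asks whether incomplete lineage sorting alone can explain the
incongruence between two loci.  The *baseline* distribution collects
all tree-to-tree distances between a locus's posterior chronograms and
gene trees simulated on those chronograms under the MSC — the amount of
incongruence expected from ILS plus inference uncertainty.  The
*observed* distribution collects cross-locus pairwise distances between
the posterior samples of two loci.  If the central 95% intervals of the
two distributions are disjoint, the observed incongruence exceeds what
ILS can generate at the assumed Ne and the ILS-only null is rejected;
the size of the gap in distance units is the "steps" separation used by
the deletion scan.

Distances are unrooted Robinson-Foulds symmetric differences.  The 95%
interval is the central empirical interval (nearest-rank 2.5th/97.5th
percentiles) — a pragmatic stand-in for an HPD on an integer multiset,
where a true HPD is ill-defined under multimodality.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import dendropy
import numpy as np

from .trees import TreeSample, bipartitions, rf_from_splits, tip_labels

__all__ = [
    "DistanceDistribution",
    "OverlapResult",
    "rf_distance",
    "cross_distances",
    "baseline_distribution",
    "observed_distribution",
    "separation_steps",
    "ils_only_test",
]

logger = logging.getLogger(__name__)


def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Unrooted Robinson-Foulds distance (symmetric split difference).

    Both trees must be on identical tip-label sets; a mismatch is an
    error listing the differing taxa.
    """
    taxa1, taxa2 = tip_labels(t1), tip_labels(t2)
    if taxa1 != taxa2:
        raise ValueError(
            f"tip sets differ (symmetric difference: {sorted(taxa1 ^ taxa2)})"
        )
    return rf_from_splits(bipartitions(t1), bipartitions(t2))


@dataclass
class DistanceDistribution:
    """Multiset of integer tree distances with its central 95% interval."""

    values: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=int)
        if vals.size == 0:
            raise ValueError("distance distribution cannot be empty")
        if (vals < 0).any():
            raise ValueError("tree distances must be nonnegative")
        self.values = vals
        self.lower95 = int(np.quantile(vals, 0.025, method="inverted_cdf"))
        self.upper95 = int(np.quantile(vals, 0.975, method="inverted_cdf"))

    def __len__(self) -> int:
        return self.values.size


@dataclass
class OverlapResult:
    """Decision record of one ILS-only test."""

    overlaps: bool
    separation: int  # steps; positive = disjoint by that many units
    scenario: str = ""
    pairing: str = ""

    def __post_init__(self) -> None:
        assert self.overlaps == (self.separation <= 0)

    @property
    def rejects_ils_only(self) -> bool:
        return not self.overlaps


def _shared_restriction(a: TreeSample, b: TreeSample) -> tuple[TreeSample, TreeSample]:
    if a.taxa == b.taxa:
        return a, b
    shared = a.taxa & b.taxa
    if len(shared) < 4:
        raise ValueError(
            f"samples '{a.source}' and '{b.source}' share fewer than 4 taxa"
        )
    logger.warning(
        "restricting samples '%s' and '%s' to %d shared taxa (dropped: %s)",
        a.source,
        b.source,
        len(shared),
        sorted((a.taxa | b.taxa) - shared),
    )
    return a.restrict_to(shared), b.restrict_to(shared)


def cross_distances(a: TreeSample, b: TreeSample) -> np.ndarray:
    """All |a| x |b| pairwise RF distances, split sets cached per tree."""
    a, b = _shared_restriction(a, b)
    sa, sb = a.split_sets(), b.split_sets()
    out = np.empty(len(sa) * len(sb), dtype=int)
    for k, (x, y) in enumerate(itertools.product(sa, sb)):
        out[k] = rf_from_splits(x, y)
    return out


def baseline_distribution(
    posterior: TreeSample, simulated: TreeSample
) -> DistanceDistribution:
    """Distances between posterior chronograms and MSC-simulated trees.

    With 20 posterior trees and 100 simulated gene trees this is the
    2000-value baseline behind each panel of the distance histograms.
    """
    return DistanceDistribution(
        cross_distances(posterior, simulated),
        source=f"baseline:{posterior.source}|{simulated.source}",
    )


def observed_distribution(a: TreeSample, b: TreeSample) -> DistanceDistribution:
    """Cross-locus distances between two posterior samples (20 x 20 = 400)."""
    return DistanceDistribution(
        cross_distances(a, b), source=f"observed:{a.source}|{b.source}"
    )


def plot_distributions(
    observed: DistanceDistribution,
    baseline: DistanceDistribution,
    path: str,
    title: str = "",
) -> None:
    """Write a paired histogram of the two distributions to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    lo = int(min(observed.values.min(), baseline.values.min()))
    hi = int(max(observed.values.max(), baseline.values.max()))
    bins = np.arange(lo - 0.5, hi + 1.5)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.hist(baseline.values, bins=bins, alpha=0.6, label="baseline (MSC)")
    ax.hist(observed.values, bins=bins, alpha=0.6, label="observed (cross-locus)")
    ax.set_xlabel("tree-to-tree distance (RF)")
    ax.set_ylabel("frequency")
    if title:
        ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def separation_steps(
    observed: DistanceDistribution, baseline: DistanceDistribution
) -> int:
    """Gap between the two 95% intervals in distance units ("steps").

    ``observed.lower95 - baseline.upper95``: positive means the
    intervals are disjoint by that many steps, zero or negative means
    they overlap (negative values measure the overlap depth).
    """
    return int(observed.lower95 - baseline.upper95)


def ils_only_test(
    observed: DistanceDistribution,
    baseline: DistanceDistribution,
    scenario: str = "",
    pairing: str = "",
) -> OverlapResult:
    """Decide whether ILS alone explains the observed incongruence.

    Overlapping 95% intervals mean the ILS-only null is *not* rejected.
    """
    sep = separation_steps(observed, baseline)
    return OverlapResult(
        overlaps=sep <= 0, separation=sep, scenario=scenario, pairing=pairing
    )
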