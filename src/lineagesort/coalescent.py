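"""Multispecies-coalescent simulation of gene trees within a chronogram.

Backward-in-time simulation: one (by default) gene lineage is sampled
per species at the tips of an ultrametric species tree whose branch
lengths are absolute time (Ma).  Within each species-tree branch, every
pair of co-occurring lineages coalesces as a continuous-time process at
rate ``1/(2*Ne)`` per pair per generation; lineages that fail to
coalesce by the top of a branch are pooled at the ancestral node, and
the process continues above the root until a single lineage remains.
Under this rate convention the expected pairwise TMRCA within one
population is ``2*Ne`` generations, and the probability that a 3-taxon
internal branch of ``t`` generations sorts concordantly is
``1 - (2/3) * exp(-t / (2*Ne))``.

Effective sizes are constant across all branches (single global Ne per
locus), with the plastid genome scaled down relative to the nuclear one
(default factor 0.5, matching the nuclear/plastid pairing used for the
three reference scenarios).  All time bookkeeping is in generations;
the chronogram's Ma branch lengths are converted with a configurable
generation time (default 1 year, appropriate for a genus that includes
annuals).
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from .trees import TreeSample, is_ultrametric

__all__ = [
    "NeConfig",
    "SimRequest",
    "time_to_generations",
    "simulate_msc_gene_tree",
    "simulate_baseline_sample",
    "simulate_single_population_genealogy",
]

ORGANELLAR_SCALING_DEFAULT = 0.5


@dataclass(frozen=True)
class NeConfig:
    """One effective-population-size scenario.

    ``plastid_ne`` defaults to ``nuclear_ne * organellar_scaling``
    (0.5), the haploid/uniparental reduction used for the plastid
    genome in the three reference scenarios (small 190000/95000,
    medium 320000/160000, large 680000/340000).
    """

    name: str
    nuclear_ne: float
    plastid_ne: float | None = None
    generation_time: float = 1.0  # years per generation
    organellar_scaling: float = ORGANELLAR_SCALING_DEFAULT

    def __post_init__(self) -> None:
        if self.nuclear_ne <= 0:
            raise ValueError("nuclear Ne must be positive")
        if self.generation_time <= 0:
            raise ValueError("generation time must be positive")
        if self.plastid_ne is None:
            object.__setattr__(
                self, "plastid_ne", self.nuclear_ne * self.organellar_scaling
            )
        if self.plastid_ne <= 0:
            raise ValueError("plastid Ne must be positive")

    def ne_for(self, locus: str) -> float:
        if locus == "nuclear":
            return self.nuclear_ne
        if locus == "plastid":
            return self.plastid_ne
        raise ValueError(f"unknown locus kind {locus!r} (nuclear|plastid)")


@dataclass
class SimRequest:
    """Batch request: simulate gene trees on a set of chronograms."""

    chronograms: TreeSample
    locus: str = "nuclear"
    replicates: int = 5
    samples_per_species: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.samples_per_species < 1:
            raise ValueError("samples_per_species must be >= 1")


def time_to_generations(duration_ma: float, generation_time: float) -> float:
    """Convert a duration in Ma to generations (``Ma * 1e6 / gt``)."""
    if generation_time <= 0:
        raise ValueError("generation time must be positive")
    if duration_ma < 0:
        raise ValueError("duration must be nonnegative")
    return duration_ma * 1.0e6 / generation_time


def _node_ages_generations(
    chronogram: dendropy.Tree, generation_time: float, tol: float = 1e-6
) -> dict:
    """Node age (generations before present) for every node; tips at 0."""
    depth: dict = {chronogram.seed_node: 0.0}
    maxdepth = 0.0
    for node in chronogram.preorder_node_iter():
        if node.parent_node is not None:
            bl = node.edge.length
            if bl is None:
                raise ValueError("chronogram has missing branch lengths")
            depth[node] = depth[node.parent_node] + bl
            if node.is_leaf():
                maxdepth = max(maxdepth, depth[node])
    ages = {}
    for node, d in depth.items():
        age_ma = maxdepth - d
        if node.is_leaf():
            age_ma = 0.0
        ages[node] = time_to_generations(age_ma, generation_time)
    return ages


class _Lineage:
    __slots__ = ("node", "time")

    def __init__(self, node: dendropy.Node, time: float):
        self.node = node
        self.time = time


def _coalesce_in_interval(
    lineages: list[_Lineage],
    t_start: float,
    t_end: float,  # inf for the root stem
    ne: float,
    rng: np.random.Generator,
) -> list[_Lineage]:
    t = t_start
    while len(lineages) >= 2:
        k = len(lineages)
        rate = k * (k - 1) / 2.0 / (2.0 * ne)  # per generation
        t = t + rng.exponential(1.0 / rate)
        if t > t_end:
            break
        i, j = rng.choice(k, size=2, replace=False)
        a, b = lineages[i], lineages[j]
        parent = dendropy.Node()
        parent.add_child(a.node)
        parent.add_child(b.node)
        a.node.edge.length = t - a.time
        b.node.edge.length = t - b.time
        merged = _Lineage(parent, t)
        lineages = [l for idx, l in enumerate(lineages) if idx not in (i, j)]
        lineages.append(merged)
    return lineages


def simulate_msc_gene_tree(
    chronogram: dendropy.Tree,
    ne: NeConfig,
    locus: str = "nuclear",
    seed: int | np.random.Generator = 0,
    samples_per_species: int = 1,
    ultrametric_tol: float | None = None,
) -> dendropy.Tree:
    """Simulate one gene tree under the MSC within ``chronogram``.

    Returns a binary rooted gene tree with branch lengths in
    generations and tip labels equal to the species labels (suffixed
    ``_1 .. _k`` when more than one lineage is sampled per species).
    Fully reproducible from ``seed``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ne_val = ne.ne_for(locus)
    height = max(
        lf.distance_from_root() for lf in chronogram.leaf_node_iter()
    )
    tol = ultrametric_tol if ultrametric_tol is not None else 1e-6 * max(1.0, height)
    if not is_ultrametric(chronogram, tol=tol):
        raise ValueError("chronogram is not ultrametric within tolerance")
    ages = _node_ages_generations(chronogram, ne.generation_time)

    active: dict = {}
    for node in chronogram.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label
            tips = []
            for i in range(samples_per_species):
                name = label if samples_per_species == 1 else f"{label}_{i + 1}"
                gnode = dendropy.Node()
                gnode.taxon = dendropy.Taxon(label=name)
                tips.append(_Lineage(gnode, 0.0))
            pool = tips
        else:
            pool = []
            for child in node.child_nodes():
                pool.extend(active.pop(child))
        if node.parent_node is None:
            pool = _coalesce_in_interval(pool, ages[node], np.inf, ne_val, rng)
            root_lineage = pool[0]
        else:
            pool = _coalesce_in_interval(
                pool, ages[node], ages[node.parent_node], ne_val, rng
            )
            active[node] = pool

    ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.seed_node = root_lineage.node
    tree.seed_node.edge.length = None
    for lf in tree.leaf_node_iter():
        lf.taxon = ns.require_taxon(label=lf.taxon.label)
    tree.is_rooted = True
    return tree


def simulate_baseline_sample(request: SimRequest, ne: NeConfig) -> TreeSample:
    """Simulate ``replicates`` gene trees on every chronogram in the request.

    With the defaults of 20 posterior chronograms and 5 replicates this
    yields the 100 simulated gene trees behind each baseline
    distribution.  Per-replicate RNG streams are spawned from the master
    seed; the returned sample carries a ``metadata`` list of dicts
    (chronogram index, replicate, spawn key) in simulation order.
    """
    ss = np.random.SeedSequence(request.seed)
    children = ss.spawn(len(request.chronograms) * request.replicates)
    trees = []
    metadata = []
    k = 0
    for ci, chrono in enumerate(request.chronograms):
        for rep in range(request.replicates):
            rng = np.random.default_rng(children[k])
            trees.append(
                simulate_msc_gene_tree(
                    chrono,
                    ne,
                    locus=request.locus,
                    seed=rng,
                    samples_per_species=request.samples_per_species,
                )
            )
            metadata.append(
                {
                    "chronogram_index": ci,
                    "replicate": rep,
                    "spawn_key": k,
                    "ne_scenario": ne.name,
                    "locus": request.locus,
                }
            )
            k += 1
    sample = TreeSample(trees, source=f"simulated:{request.chronograms.source}")
    sample.metadata = metadata
    return sample


def simulate_single_population_genealogy(
    n: int, ne: float, seed: int | np.random.Generator = 0
) -> dendropy.Tree:
    """Coalescent genealogy of ``n`` lineages in a single population.

    Branch lengths in generations under the ``1/(2*Ne)`` pair rate, so
    the expected pairwise TMRCA is ``2*Ne`` and the expected total tree
    length is ``4*Ne*a_{n-1}``.  Used as the substrate for
    Watterson-recovery checks.
    """
    if n < 2:
        raise ValueError("need at least two lineages")
    if ne <= 0:
        raise ValueError("Ne must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lineages = []
    for i in range(n):
        node = dendropy.Node()
        node.taxon = dendropy.Taxon(label=f"h{i + 1}")
        lineages.append(_Lineage(node, 0.0))
    lineages = _coalesce_in_interval(lineages, 0.0, np.inf, ne, rng)
    ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.seed_node = lineages[0].node
    tree.seed_node.edge.length = None
    for lf in tree.leaf_node_iter():
        lf.taxon = ns.require_taxon(label=lf.taxon.label)
    tree.is_rooted = True
    return tree
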