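"""Synthetic-data generators with known ground truth.

Everything the pipeline consumes can be generated here: a birth-death
species chronogram, per-locus gene trees drawn from the MSC on that
chronogram, pseudo-posterior samples (branch-length jitter + sparse NNI
moves emulating Bayesian topological/branch-length uncertainty),
an optional injected hybridization event (one locus of one taxon
re-attached to a donor lineage, i.e. a fixed introgressed locus),
Jukes-Cantor alignments, and step-table fixtures.  All generators are
pure functions of (config, seed).

Default scenario conditions: 12 species radiating over a 4 Ma crown,
birth 1.0 / death 0.2 per Ma, one sampled haplotype per species,
nuclear Ne 320000 (plastid half that), generation time 1 year,
posterior jitter CV 0.1 with NNI probability 0.1 per internal node
(mean within-posterior RF about 2, emulating the topological
uncertainty of a weakly informative single locus), and three analysis
Ne scenarios of 190000/320000/680000 (nuclear).  This places the
system in a moderate-ILS regime: discordance is common but an injected
cross-clade introgression remains identifiable.
"""

from __future__ import annotations

import importlib.resources
import random
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
from dendropy.simulate import treesim

from .coalescent import NeConfig, simulate_msc_gene_tree
from .hybridscan import StepRecord, StepTable
from .popgen import HaplotypeAlignment
from .trees import TreeSample, tip_labels

__all__ = [
    "HybridSpec",
    "ScenarioConfig",
    "SyntheticScenario",
    "DEFAULT_SCENARIOS",
    "simulate_birth_death_chronogram",
    "perturb_posterior_sample",
    "inject_hybridization",
    "choose_cross_clade_hybrid",
    "simulate_sequences",
    "generations_to_ma_tree",
    "generate_scenario",
    "make_step_table_fixture",
    "load_reference_step_table",
]

DEFAULT_SCENARIOS = (
    NeConfig("small", 190000.0),
    NeConfig("medium", 320000.0),
    NeConfig("large", 680000.0),
)


@dataclass(frozen=True)
class HybridSpec:
    """One instantaneous, fixed introgression event.

    In ``affected_locus`` only, the hybrid's lineage is detached and
    re-attached to the donor's lineage at ``event_time_ma``; all other
    loci are untouched.
    """

    hybrid_taxon: str
    donor_taxon: str
    event_time_ma: float
    affected_locus: str = "cpDNA"


@dataclass(frozen=True)
class ScenarioConfig:
    n_species: int = 12
    birth_rate: float = 1.0  # per Ma
    death_rate: float = 0.2
    crown_age: float = 4.0  # Ma
    generating_ne: NeConfig = NeConfig("medium", 320000.0)
    generation_time: float = 1.0
    genes: tuple = (("ITS", "nuclear"), ("AGT1", "nuclear"), ("cpDNA", "plastid"))
    posterior_size: int = 20
    jitter_cv: float = 0.1
    nni_prob: float = 0.1
    hybrid: HybridSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.birth_rate <= self.death_rate or self.death_rate < 0:
            raise ValueError("need birth rate > death rate >= 0")
        if not 0 <= self.nni_prob <= 1:
            raise ValueError("nni_prob must be a probability")
        if self.hybrid is not None and self.hybrid.event_time_ma >= self.crown_age:
            raise ValueError("hybridization event must be younger than the crown age")


def simulate_birth_death_chronogram(
    n_species: int,
    birth_rate: float = 1.0,
    death_rate: float = 0.2,
    crown_age: float = 2.0,
    seed: int = 0,
    max_tries: int = 100,
) -> dendropy.Tree:
    """Birth-death chronogram conditioned on ``n_species`` extant tips.

    Simulated with the general sampling approach (so conditioning on n
    does not bias branch lengths), then rescaled to the requested crown
    age.  Tips are relabeled ``sp1..spN``.  Total-extinction retries
    are capped at ``max_tries``; exhausting the cap is an error.
    """
    if n_species < 4:
        raise ValueError("need at least 4 species")
    if birth_rate <= death_rate or death_rate < 0:
        raise ValueError("need birth rate > death rate >= 0")
    rng = random.Random(int(seed))
    last_exc: Exception | None = None
    for _ in range(max_tries):
        try:
            tree = treesim.birth_death_tree(
                birth_rate=birth_rate,
                death_rate=death_rate,
                num_extant_tips=n_species,
                gsa_ntax=2 * n_species,
                rng=rng,
            )
            break
        except Exception as exc:  # total extinction under GSA
            last_exc = exc
    else:
        raise RuntimeError(
            f"birth-death simulation failed {max_tries} times: {last_exc}"
        )
    tree.seed_node.edge.length = None
    height = max(lf.distance_from_root() for lf in tree.leaf_node_iter())
    factor = crown_age / height
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= factor
    for i, lf in enumerate(sorted(tree.leaf_node_iter(), key=lambda l: l.taxon.label)):
        lf.taxon.label = f"sp{i + 1}"
    return tree


def _node_ages(tree: dendropy.Tree) -> dict:
    depth = {tree.seed_node: 0.0}
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            depth[node] = depth[node.parent_node] + (node.edge.length or 0.0)
    height = max(d for n, d in depth.items() if n.is_leaf())
    return {n: (0.0 if n.is_leaf() else height - d) for n, d in depth.items()}


def _rebuild_lengths_from_ages(tree: dendropy.Tree, ages: dict) -> None:
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = ages[node.parent_node] - ages[node]
    tree.seed_node.edge.length = None


def perturb_posterior_sample(
    chronogram: dendropy.Tree,
    k: int = 20,
    jitter_cv: float = 0.1,
    nni_prob: float = 0.0,
    seed: int = 0,
) -> TreeSample:
    """Emulate a posterior sample of ``k`` chronograms.

    Each copy receives (i) NNI rearrangements, applied independently
    with probability ``nni_prob`` at each eligible internal node, and
    (ii) multiplicative lognormal jitter of internal-node ages with
    coefficient of variation ``jitter_cv`` (mean 1), clamped so the
    result stays a valid ultrametric chronogram.  ``jitter_cv=0`` and
    ``nni_prob=0`` return ``k`` identical copies.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    sigma = float(np.sqrt(np.log1p(jitter_cv**2)))
    out = []
    for _ in range(k):
        t = chronogram.clone(depth=1)
        ages = _node_ages(t)
        # sparse NNI moves
        if nni_prob > 0:
            for node in list(t.preorder_internal_node_iter()):
                parent = node.parent_node
                if parent is None or len(node.child_nodes()) < 2:
                    continue
                if rng.random() >= nni_prob:
                    continue
                siblings = [c for c in parent.child_nodes() if c is not node]
                if not siblings:
                    continue
                s = siblings[int(rng.integers(len(siblings)))]
                b = node.child_nodes()[int(rng.integers(len(node.child_nodes())))]
                parent.remove_child(s)
                node.remove_child(b)
                node.add_child(s)
                parent.add_child(b)
                top = max(ages[c] for c in node.child_nodes())
                if ages[node] <= top:
                    ages[node] = 0.5 * (ages[parent] + top)
        # lognormal age jitter, root-down with clamping
        if jitter_cv > 0:
            for node in t.preorder_internal_node_iter():
                factor = float(rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma))
                a = ages[node] * factor
                parent = node.parent_node
                if parent is not None:
                    a = min(a, ages[parent] * (1.0 - 1e-9))
                # children are clamped later in preorder, so only guard > 0
                ages[node] = max(a, 1e-12)
        _rebuild_lengths_from_ages(t, ages)
        # preorder clamping guarantees child < parent except where a child
        # was visited after its parent shrank: enforce monotonicity
        for node in t.preorder_internal_node_iter():
            parent = node.parent_node
            if parent is not None and node.edge.length < 0:
                ages[node] = ages[parent] * (1.0 - 1e-9)
        _rebuild_lengths_from_ages(t, ages)
        out.append(t)
    sample = TreeSample(out, source="pseudo-posterior")
    return sample


def inject_hybridization(
    gene_trees: dict, spec: HybridSpec
) -> tuple[dict, dict]:
    """Re-attach the hybrid's lineage to the donor in the affected locus.

    ``gene_trees`` maps locus name -> ultrametric tree in Ma.  Returns
    (new mapping, ground-truth record).  Unaffected loci are returned
    untouched (same objects).  The event must be younger than the
    hybrid/donor divergence in the affected tree.
    """
    if spec.affected_locus not in gene_trees:
        raise ValueError(f"affected locus {spec.affected_locus!r} not present")
    src = gene_trees[spec.affected_locus]
    labels = tip_labels(src)
    for t in (spec.hybrid_taxon, spec.donor_taxon):
        if t not in labels:
            raise ValueError(f"taxon {t!r} not in the affected locus tree")
    tree = src.clone(depth=1)
    ages = _node_ages(tree)
    leaves = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}
    hyb, donor = leaves[spec.hybrid_taxon], leaves[spec.donor_taxon]
    mrca_age = ages[_mrca(hyb, donor)]
    if spec.event_time_ma >= mrca_age:
        raise ValueError(
            f"event time {spec.event_time_ma} Ma is not younger than the "
            f"hybrid/donor divergence ({mrca_age:.4f} Ma)"
        )
    # detach hybrid tip, suppressing the resulting unifurcation
    parent = hyb.parent_node
    parent.remove_child(hyb)
    if len(parent.child_nodes()) == 1:
        only = parent.child_nodes()[0]
        grand = parent.parent_node
        if grand is None:
            parent.remove_child(only)
            tree.seed_node = only
            only.edge.length = None
        else:
            grand.remove_child(parent)
            grand.add_child(only)
            only.edge.length = ages[grand] - ages[only]
    # find the donor-lineage edge spanning the event time
    node = donor
    while node.parent_node is not None and ages[node.parent_node] < spec.event_time_ma:
        node = node.parent_node
    upper = node.parent_node  # age >= event (or None if event above root)
    if upper is None:
        raise ValueError("event time lies above the root of the affected tree")
    upper.remove_child(node)
    mid = dendropy.Node()
    upper.add_child(mid)
    mid.add_child(node)
    mid.edge.length = ages[upper] - spec.event_time_ma
    node.edge.length = spec.event_time_ma - ages[node]
    hyb.edge.length = spec.event_time_ma
    mid.add_child(hyb)
    tree.update_taxon_namespace()
    out = dict(gene_trees)
    out[spec.affected_locus] = tree
    truth = {
        "hybrid_taxon": spec.hybrid_taxon,
        "donor_taxon": spec.donor_taxon,
        "event_time_ma": spec.event_time_ma,
        "affected_locus": spec.affected_locus,
    }
    return out, truth


def choose_cross_clade_hybrid(
    species_tree: dendropy.Tree,
    event_time_ma: float = 0.1,
    locus: str = "cpDNA",
) -> HybridSpec:
    """Deterministically pick a *detectable* hybrid/donor pair.

    Hybridization between lineages that both sit adjacent to the root
    path is nearly invisible to unrooted tree distances, so the chooser
    takes the first tips of the two most anciently diverging cherries:
    both endpoints are nested inside clades and the transfer crosses a
    deep split, mirroring hybrids formed between well-separated
    subclades.  Falls back to cherry-vs-farthest-tip when the tree has
    a single cherry.
    """
    ages = _node_ages(species_tree)
    cherries = [
        node
        for node in species_tree.postorder_internal_node_iter()
        if len(node.child_nodes()) == 2
        and all(k.is_leaf() for k in node.child_nodes())
    ]
    if not cherries:
        raise ValueError("tree has no cherries")
    first = lambda nd: min(l.taxon.label for l in nd.leaf_iter())
    if len(cherries) >= 2:
        best = None
        for i, c1 in enumerate(cherries):
            for c2 in cherries[i + 1 :]:
                depth = ages[_mrca(c1, c2)]
                key = (depth, first(c1), first(c2))
                if best is None or key > best[0]:
                    best = (key, c1, c2)
        _, c1, c2 = best
        hybrid, donor = first(c1), first(c2)
    else:
        c1 = cherries[0]
        hybrid = first(c1)
        donor = max(
            (
                (ages[_mrca(c1, lf)], lf.taxon.label)
                for lf in species_tree.leaf_node_iter()
                if lf.parent_node is not c1
            )
        )[1]
    return HybridSpec(hybrid, donor, event_time_ma, locus)


def _mrca(a: dendropy.Node, b: dendropy.Node) -> dendropy.Node:
    anc = set()
    node = a
    while node is not None:
        anc.add(id(node))
        node = node.parent_node
    node = b
    while node is not None:
        if id(node) in anc:
            return node
        node = node.parent_node
    raise ValueError("nodes share no ancestor")


def simulate_sequences(
    tree: dendropy.Tree, length: int, rate: float, seed: int = 0
) -> HaplotypeAlignment:
    """Jukes-Cantor nucleotide evolution along ``tree``.

    ``rate`` is substitutions/site per branch-length unit, so the
    expected substitution distance of an edge is ``rate * length_of_edge``
    and two tips at total distance d differ at an expected fraction
    ``(3/4) * (1 - exp(-4 d / 3))`` of sites.
    """
    if length < 1:
        raise ValueError("alignment length must be >= 1")
    if rate < 0:
        raise ValueError("rate must be nonnegative")
    rng = np.random.default_rng(seed)
    alphabet = np.array(list("ACGT"))
    seqs: dict = {}
    root_state = rng.integers(0, 4, size=length)
    seqs[tree.seed_node] = root_state
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        d = rate * (node.edge.length or 0.0)
        p_change = 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))
        parent_seq = seqs[node.parent_node]
        child = parent_seq.copy()
        hit = rng.random(length) < p_change
        nhit = int(hit.sum())
        if nhit:
            # uniform among the three other bases
            child[hit] = (parent_seq[hit] + rng.integers(1, 4, size=nhit)) % 4
        seqs[node] = child
    labels, rows = [], []
    for lf in sorted(tree.leaf_node_iter(), key=lambda l: l.taxon.label):
        labels.append(lf.taxon.label)
        rows.append("".join(alphabet[seqs[lf]]))
    return HaplotypeAlignment(labels=labels, sequences=rows)


def generations_to_ma_tree(
    tree: dendropy.Tree, generation_time: float
) -> dendropy.Tree:
    """Rescale a gene tree from generations to Ma (in place on a clone)."""
    out = tree.clone(depth=1)
    factor = generation_time / 1.0e6
    for edge in out.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= factor
    return out


@dataclass
class SyntheticScenario:
    """A fully generated study: species tree, gene trees, posteriors."""

    config: ScenarioConfig
    species_chronogram: dendropy.Tree
    gene_trees_ma: dict  # locus -> ultrametric gene tree (Ma)
    posteriors: dict  # locus -> TreeSample of 20 jittered chronograms
    loci: dict  # locus -> "nuclear" | "plastid"
    ground_truth: dict | None = None


def generate_scenario(config: ScenarioConfig) -> SyntheticScenario:
    """Generate the full input set for one synthetic study.

    Species chronogram under birth-death; per-locus true gene trees
    under the MSC at the generating Ne; optional hybridization injected
    into the affected locus; per-locus pseudo-posterior samples of
    ``posterior_size`` chronograms.  Pure function of the config.
    """
    ss = np.random.SeedSequence(config.seed)
    seeds = ss.generate_state(2 + 2 * len(config.genes))
    species = simulate_birth_death_chronogram(
        config.n_species,
        config.birth_rate,
        config.death_rate,
        config.crown_age,
        seed=int(seeds[0]),
    )
    ne = replace(config.generating_ne, generation_time=config.generation_time)
    gene_trees: dict = {}
    loci: dict = {}
    for i, (name, kind) in enumerate(config.genes):
        gt = simulate_msc_gene_tree(
            species, ne, locus=kind, seed=int(seeds[2 + i])
        )
        gene_trees[name] = generations_to_ma_tree(gt, config.generation_time)
        loci[name] = kind
    truth = None
    if config.hybrid is not None:
        gene_trees, truth = inject_hybridization(gene_trees, config.hybrid)
    posteriors = {
        name: perturb_posterior_sample(
            gene_trees[name],
            k=config.posterior_size,
            jitter_cv=config.jitter_cv,
            nni_prob=config.nni_prob,
            seed=int(seeds[2 + len(config.genes) + i]),
        )
        for i, (name, _) in enumerate(config.genes)
    }
    for name in posteriors:
        posteriors[name].source = name
    return SyntheticScenario(
        config=config,
        species_chronogram=species,
        gene_trees_ma=gene_trees,
        posteriors=posteriors,
        loci=loci,
        ground_truth=truth,
    )


def make_step_table_fixture(spec: dict | None = None) -> StepTable:
    """StepTable with prescribed deltas.

    ``spec`` maps taxon -> dict of 9 (pairing, scenario) -> delta; with
    ``spec=None`` the packaged reference table (the published 18-taxon
    deletion-step grid for Mediterranean Linaria sect. Supinae) is
    returned.
    """
    if spec is None:
        return load_reference_step_table()[0]
    records = [StepRecord(taxon=t, deltas=dict(d)) for t, d in spec.items()]
    return StepTable(records)


def load_reference_step_table():
    """The packaged reference deletion-step grid and its published averages.

    Returns ``(StepTable, {taxon: published average})``.  Column blocks
    correspond to the three gene pairings (ITS, AGT1, cpDNA baselines)
    under Ne scenarios A (small), B (medium), C (large).
    """
    text = (
        importlib.resources.files("lineagesort.data")
        .joinpath("linaria_deletion_steps.tsv")
        .read_text()
    )
    lines = [l for l in text.strip().split("\n")]
    header = lines[0].split("\t")
    cell_cols = header[1:-1]
    records, published = [], {}
    for line in lines[1:]:
        fields = line.split("\t")
        taxon = fields[0]
        deltas = {}
        for col, val in zip(cell_cols, fields[1:-1]):
            pairing, scenario = col.rsplit("_", 1)
            deltas[(pairing, scenario)] = int(val)
        records.append(StepRecord(taxon=taxon, deltas=deltas))
        published[taxon] = float(fields[-1])
    return StepTable(records), published
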