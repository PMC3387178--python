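"""Multilabelled dataset construction and audit.

A taxon of hybrid origin carries two parental genome contributions, so
in a coalescent species-tree analysis it is represented by *two*
terminals: label L1 carries the two mutually congruent loci, label L2
carries the remaining (most incongruent) locus, and each label is
scored as missing data for the loci not assigned to it.  The
multispecies-coalescent engine that infers the multilabelled species
tree is external; this module builds its inputs (per-locus alignments
with missing-data rows and a label-to-terminal assignment table) and
audits an inferred multilabelled tree against the per-locus gene trees.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .popgen import HaplotypeAlignment
from .trees import (
    TreeSample,
    prune_taxa,
    restrict_splits,
    rf_from_splits,
    tip_labels,
)

__all__ = [
    "LabelMap",
    "most_incongruent_gene",
    "build_label_map",
    "export_label_matrix",
    "import_label_matrix",
    "write_nexus_alignment",
    "audit_multilabel_tree",
]

logger = logging.getLogger(__name__)

MISSING = "?"


@dataclass
class LabelMap:
    """Assignment of loci to terminal labels.

    For each hybrid ``T``: ``T_L1`` -> the two most congruent loci,
    ``T_L2`` -> the single most incongruent locus.  Non-hybrids keep a
    single label carrying every locus.
    """

    genes: list[str]
    assignments: dict  # label -> (taxon, frozenset of genes)
    hybrids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        geneset = frozenset(self.genes)
        by_taxon: dict = {}
        for label, (taxon, gs) in self.assignments.items():
            by_taxon.setdefault(taxon, []).append((label, frozenset(gs)))
        for taxon, entries in by_taxon.items():
            union = frozenset().union(*(g for _, g in entries))
            if union != geneset:
                raise ValueError(f"labels of {taxon!r} do not cover all genes")
            if taxon in self.hybrids:
                if len(entries) != 2:
                    raise ValueError(f"hybrid {taxon!r} must have exactly 2 labels")
                g1, g2 = (g for _, g in entries)
                if g1 & g2:
                    raise ValueError(f"labels of {taxon!r} overlap")
                l2 = [g for label, g in entries if label.endswith("_L2")]
                if not l2 or len(l2[0]) != 1:
                    raise ValueError(f"L2 of {taxon!r} must carry exactly one gene")
            elif len(entries) != 1:
                raise ValueError(f"non-hybrid {taxon!r} must have a single label")

    @property
    def labels(self) -> list[str]:
        return sorted(self.assignments)

    def mask(self) -> dict:
        """(label, gene) -> True where the gene is *unassigned* (missing)."""
        return {
            (label, g): g not in gs
            for label, (_, gs) in self.assignments.items()
            for g in self.genes
        }

    def n_terminals(self) -> int:
        return len(self.assignments)


def _median_drop(
    taxon: str, a: TreeSample, b: TreeSample
) -> float:
    """Median over cross pairs of rf(x,y) - rf(x - taxon, y - taxon)."""
    shared = a.taxa & b.taxa
    if taxon not in shared:
        raise ValueError(f"taxon {taxon!r} absent from one of the samples")
    a, b = a.restrict_to(shared), b.restrict_to(shared)
    sa, sb = a.split_sets(), b.split_sets()
    ra = [restrict_splits(s, a.taxa, (taxon,)) for s in sa]
    rb = [restrict_splits(s, b.taxa, (taxon,)) for s in sb]
    drops = [
        rf_from_splits(x, y) - rf_from_splits(xr, yr)
        for (x, xr) in zip(sa, ra)
        for (y, yr) in zip(sb, rb)
    ]
    return float(np.median(drops))


def most_incongruent_gene(
    taxon: str,
    samples: dict,
    priority: list[str] | None = None,
) -> str:
    """The locus whose placement of ``taxon`` conflicts most with the rest.

    For each locus ``g`` the score is the median pruning-drop of
    ``taxon`` between ``g`` and every other locus (pooled); the argmax
    is returned.  Ties are broken by the configured ``priority`` order
    (default: insertion order of ``samples``) with a logged warning.
    """
    genes = list(samples)
    if len(genes) < 3:
        raise ValueError("need at least 3 loci to define 'two most congruent'")
    order = priority if priority is not None else genes
    scores: dict = {}
    for g in genes:
        pooled = [
            _median_drop(taxon, samples[g], samples[h]) for h in genes if h != g
        ]
        scores[g] = float(np.median(pooled))
    best = max(scores.values())
    winners = [g for g in order if scores.get(g) == best]
    if len(winners) > 1:
        logger.warning(
            "tie for most incongruent gene of %r (%s); using priority order -> %s",
            taxon,
            {g: scores[g] for g in winners},
            winners[0],
        )
    return winners[0]


def build_label_map(
    hybrids,
    samples: dict,
    priority: list[str] | None = None,
) -> LabelMap:
    """LabelMap assigning loci to L1/L2 for hybrids, one label otherwise."""
    genes = list(samples)
    taxa = frozenset.intersection(*(s.taxa for s in samples.values()))
    hybrids = sorted(hybrids)
    missing = set(hybrids) - taxa
    if missing:
        raise ValueError(f"hybrids not in the shared taxon set: {sorted(missing)}")
    assignments: dict = {}
    for taxon in sorted(taxa):
        if taxon in hybrids:
            worst = most_incongruent_gene(taxon, samples, priority=priority)
            l1 = frozenset(g for g in genes if g != worst)
            assignments[f"{taxon}_L1"] = (taxon, l1)
            assignments[f"{taxon}_L2"] = (taxon, frozenset((worst,)))
        else:
            assignments[taxon] = (taxon, frozenset(genes))
    return LabelMap(genes=genes, assignments=assignments, hybrids=hybrids)


def export_label_matrix(label_map: LabelMap, alignments: dict) -> dict:
    """Per-locus matrices with hybrid rows routed to their labels.

    ``alignments`` maps locus -> :class:`HaplotypeAlignment` whose rows
    are taxon-labeled.  Each returned matrix has one row per terminal
    label: the taxon's sequence where the locus is assigned to the
    label, an all-missing row otherwise.  A missing sequence for an
    *assigned* (label, locus) cell is an error.
    """
    for g in label_map.genes:
        if g not in alignments:
            raise ValueError(f"no alignment for locus {g!r}")
    out: dict = {}
    for g in label_map.genes:
        aln = alignments[g]
        rows = dict(zip(aln.labels, aln.sequences))
        labels, seqs = [], []
        for label in label_map.labels:
            taxon, assigned = label_map.assignments[label]
            if g in assigned:
                if taxon not in rows:
                    raise ValueError(
                        f"missing sequence for assigned cell ({label!r}, {g!r})"
                    )
                seqs.append(rows[taxon])
            else:
                seqs.append(MISSING * aln.length)
            labels.append(label)
        out[g] = HaplotypeAlignment(labels=labels, sequences=seqs)
    return out


def import_label_matrix(matrices: dict, genes: list[str] | None = None) -> LabelMap:
    """Reconstruct the LabelMap from exported matrices (round-trip)."""
    genes = genes or list(matrices)
    labels = matrices[genes[0]].labels
    assignments: dict = {}
    hybrid_taxa = set()
    for label in labels:
        if label.endswith("_L1") or label.endswith("_L2"):
            taxon = label[:-3]
            hybrid_taxa.add(taxon)
        else:
            taxon = label
        assigned = set()
        for g in genes:
            aln = matrices[g]
            seq = dict(zip(aln.labels, aln.sequences))[label]
            if set(seq) != {MISSING}:
                assigned.add(g)
        assignments[label] = (taxon, frozenset(assigned))
    return LabelMap(genes=genes, assignments=assignments, hybrids=sorted(hybrid_taxa))


def _nexus_quote(label: str) -> str:
    if any(c in label for c in " '()[]{}/\\,;:=*\"`+<>~"):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_nexus_alignment(aln: HaplotypeAlignment, path: str) -> None:
    """Write a simple NEXUS DATA block (MISSING=?, GAP=-)."""
    with open(path, "w") as fh:
        fh.write("#NEXUS\nBEGIN DATA;\n")
        fh.write(f"  DIMENSIONS NTAX={aln.n} NCHAR={aln.length};\n")
        fh.write("  FORMAT DATATYPE=DNA MISSING=? GAP=-;\n  MATRIX\n")
        for label, seq in zip(aln.labels, aln.sequences):
            fh.write(f"    {_nexus_quote(label)}  {seq}\n")
        fh.write("  ;\nEND;\n")


def audit_multilabel_tree(
    tree,
    label_map: LabelMap,
    samples: dict,
    threshold: float = 0.0,
) -> list[dict]:
    """Audit an inferred multilabelled tree against per-locus gene trees.

    For every hybrid reports (i) whether its L1/L2 labels attach as
    sisters ("congruent placement" — the non-hybrid signal), and (ii)
    per label, whether its placement is consistent with its assigned
    loci (median pruning-drop of the relabeled terminal against each
    assigned locus's tree sample ``<= threshold``).
    """
    tips = tip_labels(tree)
    unknown = set(label_map.labels) - tips
    if unknown:
        raise ValueError(f"labels absent from the inferred tree: {sorted(unknown)}")
    reports = []
    for hybrid in label_map.hybrids:
        l1, l2 = f"{hybrid}_L1", f"{hybrid}_L2"
        sisters = frozenset((l1, l2)) in {
            frozenset(s) for s in _cherries(tree)
        }
        entry = {
            "hybrid": hybrid,
            "congruent_placement": sisters,
            "labels": {},
        }
        for label in (l1, l2):
            _, assigned = label_map.assignments[label]
            # reduce the inferred tree to: this label (renamed to the
            # taxon) plus all single-label terminals
            keep = {
                lb for lb in label_map.labels
                if label_map.assignments[lb][0] not in label_map.hybrids
            } | {label}
            sub = prune_taxa(tree, tips - keep)
            for lf in sub.leaf_node_iter():
                if lf.taxon.label == label:
                    # fresh Taxon: the pruned clone shares taxon objects
                    # with the input tree, which must stay unmodified
                    import dendropy

                    lf.taxon = dendropy.Taxon(label=hybrid)
            sub_sample = TreeSample([sub], source=f"audit:{label}")
            drops = {
                g: _median_drop(hybrid, sub_sample, samples[g]) for g in assigned
            }
            entry["labels"][label] = {
                "assigned_genes": sorted(assigned),
                "median_drop": drops,
                "consistent": all(v <= threshold for v in drops.values()),
            }
        reports.append(entry)
    return reports


def _cherries(tree):
    out = []
    for node in tree.postorder_internal_node_iter():
        kids = node.child_nodes()
        if len(kids) == 2 and all(k.is_leaf() for k in kids):
            out.append((kids[0].taxon.label, kids[1].taxon.label))
    return out
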