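# Methods

## The model and the test

The pipeline treats gene-tree incongruence as a mixture of two
processes and asks which are needed to explain the data.

**Multispecies coalescent simulator.**  Gene trees are simulated
backward in time within an ultrametric species (or gene) chronogram
whose branch lengths are in Ma.  One lineage is sampled per species
(configurable).  Within every chronogram branch, each pair of
co-occurring lineages coalesces at rate 1/(2·Ne) per generation, so the
expected pairwise TMRCA in a single population is 2·Ne generations and
the probability that an internal branch of t generations sorts
concordantly in the 3-taxon case is 1 − (2/3)·e^(−t/(2Ne)).  Lineages
that fail to coalesce are pooled at ancestral nodes; above the root the
process runs to completion.  Ne is constant across branches (one global
value per locus per scenario); the plastid genome uses Ne scaled by 0.5
relative to the nuclear value, reproducing the three reference scenario
pairs (190000/95000, 320000/160000, 680000/340000).  Time conversion
uses a generation time of 1 year by default (the group contains
annuals); both the scaling factor and generation time are parameters.

The rate convention matters: under 1/(2·Ne) per pair, the single-
population expectation is E[S] = 4·Ne·µ·L·a_{n−1} for Watterson's S.
The Ne-*derivation* module instead applies the organellar convention
θ_w = 2·µ·Ne exactly as used for the reference estimates, because its
job is to reproduce those numbers; the two conventions are documented
separately and never mixed inside one computation.

**Distance distributions.**  All tree comparisons use the unrooted
Robinson–Foulds symmetric difference on nontrivial bipartitions.
Rooting is deliberately ignored for distances (outgroup placement
differs across genes); it is retained only where the coalescent needs
node ages.  The "95% HPD" of an integer distance multiset is
implemented as the central empirical interval (nearest-rank 2.5th and
97.5th percentiles): a true HPD is ill-defined on multimodal integer
data.  The baseline distribution is the 20 × 100 cross product of
posterior chronograms and MSC-simulated trees; the observed
distribution is the 20 × 20 cross product of two loci's posterior
samples.  Separation = observed.lower95 − baseline.upper95, in distance
units ("steps"); intervals overlap iff separation ≤ 0, in which case
ILS alone is not rejected.

**Deletion scan.**  Candidates are terminals whose one-at-a-time
pruning reduces cross-locus conflict (median pruning-drop of RF over
all cross pairs ≥ min_drop, default 2 = one shared conflicting split).
The candidate detector deliberately over-flags: pruning any taxon near
a conflict path collapses one split pair (background drop of exactly
2), so neighbours of a genuine hybrid are often carried along.  This is
harmless — their step averages land near zero — and mirrors the
inclusive candidate sets used in practice.  For each candidate and each
of 3 pairings × 3 Ne scenarios the separation is recomputed with the
candidate pruned; the baseline is *re-simulated* on the pruned
chronograms rather than pruned from cached simulations, so each cell is
an independent replicate and deletions cannot inherit the noise of the
unpruned baseline.  The nine deltas are averaged (rounded half-up to 2
decimals, matching the reference table's printed style); negative
average ⇒ potential hybrid, ties at zero ⇒ not a hybrid.

**Multilabelling.**  For each potential hybrid the most incongruent
locus is the argmax over loci of the median pruning-drop of that taxon
between the locus and each other locus — the same statistic as
candidate flagging, for internal consistency; ties break by a
configured locus priority order and are logged, never silent.  L1
carries the two congruent loci, L2 the remaining one; exported NEXUS
matrices contain all-missing rows for unassigned (label, locus) cells,
and the export/import round-trip is lossless.  The audit of an
externally inferred multilabelled tree reports, per hybrid, whether
L1/L2 attach as sisters (a non-hybrid signal) and whether each label's
placement is consistent with its assigned loci (pruning-drop ≤
threshold).

## Synthetic data: what it emulates and what it does not

The generator produces a birth–death species chronogram conditioned on
the number of extant species (general sampling approach, rescaled to
the crown age), MSC gene trees on it, pseudo-posterior samples, and
optional introgression.  Default conditions, chosen once to place the
system in a moderate-ILS regime — discordance common, but a cross-clade
introgression identifiable:

| parameter | default | notes |
| --- | --- | --- |
| species | 12 | radiation size |
| crown age | 4 Ma | Plio-Pleistocene scale |
| birth / death | 1.0 / 0.2 per Ma | mild extinction |
| nuclear Ne (generating) | 320 000 | mid reference scenario |
| plastid scaling | × 0.5 | haploid, uniparental |
| generation time | 1 yr | annuals present |
| posterior size | 20 trees/locus | matches the test design |
| jitter CV | 0.1 | lognormal node-age noise |
| NNI probability | 0.1 per internal node | mean within-posterior RF ≈ 2 (max 18) |
| analysis Ne scenarios | 190k / 320k / 680k | small / medium / large |

Posterior emulation is multiplicative lognormal jitter of internal-node
ages plus sparse NNI moves, re-ultrametricized — not a real MCMC
posterior.  It reproduces the two features the test consumes
(branch-length uncertainty and topological spread of roughly the right
magnitude) but not posterior correlation structure, clade-support
heterogeneity (real uncertainty concentrates on short branches), or
alignment-level noise.  Hybridization is modeled as one instantaneous,
fully fixed lineage transfer per event affecting one locus completely;
sequence-level mosaics, partial introgression and recombination are out
of scope.  Consequently, passing the pipeline's power checks on
synthetics demonstrates internal correctness and sensitivity under
idealized introgression, not performance on real posteriors with
alignment noise or partial gene flow.

The power-study event chooser (`choose_cross_clade_hybrid`) picks the
first tips of the two most anciently diverging cherries.  Transfers
between root-adjacent lineages are nearly invisible to unrooted tree
distances — such events are undetectable by construction, and using
them in power studies would measure the geometry of the tree, not the
method.

## Numerical and design choices

- **Distance metric** is pluggable behind `rf_distance`; unrooted RF is
  the default because the source procedure's metric is not documented.
- **Seeding**: every simulation consumes a numpy `SeedSequence`-derived
  stream; batch runs spawn one child stream per replicate and record it
  in the output metadata, so any single tree is reproducible in
  isolation.  All deliverable outputs are byte-stable under a fixed
  seed (timestamps appear only in logs).
- **Degenerate inputs**: pruning below 3 tips, non-ultrametric
  chronograms (tolerance 1e-6 relative to tree height), duplicate or
  empty tip labels, mismatched taxon sets, and empty distance multisets
  are hard errors.  When loci differ in taxon coverage, all samples are
  restricted to the shared taxon set and the restriction is logged.
- **Zero-length branches** are allowed; they contribute bipartitions
  only where the node is resolved.  Polytomies are allowed in inputs
  (Bayesian consensus trees may contain them) and simply contribute
  fewer bipartitions.
- **Rounding** of step averages is decimal half-up (away from zero) at
  2 decimals, implemented with exact decimal arithmetic.
- **Birth–death conditioning** uses rejection with a retry cap (100);
  cap exhaustion raises rather than looping forever.
- **Watterson recovery tests** use alignments long enough (L = 20 000
  at per-site θ = 2.5 × 10⁻⁴) that finite-sites repeat mutation bias is
  negligible against the 5% tolerance; at L = 2000 the collision bias
  is already ≈ 5% and would dominate.

## Problem sizes

Unit tests run the pipeline on 8-species scenarios; the end-to-end
calibration and power checks use the default 12-species conditions with
100 null runs and 50 hybrid runs, the same sizes
`scripts/acceptance.py` recomputes.  At these sizes the full test suite
and the acceptance script each complete in minutes on a single core.

## Known limitations

- The ILS-only test is inherently mildly anti-conservative: observed
  cross-locus distances accumulate two independent ILS realizations
  while the baseline contains one; overlap of 95% intervals absorbs
  this at the default conditions, but run-level rejection rates rise
  under heavier ILS or weaker posterior jitter.
- Locus assignment for hybrids is identifiability-limited: when ILS
  makes the two non-introgressed loci disagree about the hybrid as
  strongly as the introgressed one, no pairwise statistic can recover
  the truth.  Under heavy ILS (e.g. 8 species on a 2 Ma crown at the
  default Ne) up to ~20% of replicates are structurally ambiguous.
- Constant Ne across branches and a single global generation time are
  simplifications; per-branch demography is out of scope.
- The multilabelled species-tree inference itself is external; this
  package prepares its inputs and audits its outputs only.
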