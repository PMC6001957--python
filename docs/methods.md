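# Methods

This note documents the models implemented in `ervpipe`, the defaults and
why they were chosen, what the synthetic generators do and do not emulate,
and the numerical conventions that make every run reproducible.

## Coordinates and formats

All internal intervals are 0-based half-open on the plus strand with an
explicit strand flag. Tabular similarity input (12-column tblastn/blastn
format) is 1-based inclusive with subject start > end marking the minus
strand; conversion happens once, at the file boundary, and re-serialization
reproduces the input rows. Trees are newick (quoted labels and
scientific-notation lengths accepted; internal support labels parsed but
ignored); FASTA, TSV association/group tables and YAML configs cover the
rest. Branch lengths never enter any analysis here — only topology does.

## ERV mining

Decayed proviruses produce several partial hits against a Pol query because
frameshifts interrupt the reading frame. Two hits are chained into one
locus iff they share contig, strand and query, their genomic gap is at most
`max_genomic_gap` (default 2,000 nt) and their query gap at most
`max_query_gap` (default 50 residues), and query order is colinear with
genomic order given the strand. Chaining is transitive (union–find);
loci from different queries that overlap genomically by ≥1 bp on the same
strand are unified — the unit being counted is the insertion, not the hit —
keeping the lower-e-value query as seed. The default screening threshold is
*e* ≤ 10⁻⁵; the chaining distances are configurable because they are
operating choices, not measured quantities. The initial hit-level e-value
screen and the paralog cutoff (10⁻¹⁰, see below) are both inclusive (≤).

Classification is deliberately support-free and auditable: the input tree
is rooted on the branch separating the outgroup references (error if they
are not monophyletic in the unrooted sense), and each candidate is judged
by the smallest clade containing it and at least one classifying reference
— all-retrovirus → `erv`, all-retrotransposon → `rejected`, mixed →
`unclassified` (surfaced, never silently dropped). Tree inference itself is
out of scope; the tree is an input.

## Consensus reconstruction

Within a cluster the representative is the longest member (ties broken by
smallest (contig, start)). Paralog hits seeded by the representative are
kept at *e* ≤ 10⁻¹⁰ and, when a pol interval is given, restricted to hits
overlapping that interval extended by 5,000 nt on each side, clipped to the
representative (the window is anchored on the representative's pol region;
anchoring per paralog would make the admitted set depend on alignment
details the hits do not carry). Consensus columns are representative
positions; each admitted segment votes its residues at the positions its
hit covers, with proportional index projection when segment and window
lengths differ (indels inside a segment are absorbed, not re-aligned — a
deterministic substitute for an interactive alignment tool, chosen for
reproducibility). The representative casts one vote per column; strict
majority wins and ties become the IUPAC code of the tied residue set.
Clusters spanning two species are processed independently per species; more
than two species is an error by construction. With 10 paralogs at 5%
independent divergence, majority voting recovers ≥99% of the ancestral
sequence (the binomial chance that a site's true residue loses the vote is
below 1%), which the test suite verifies.

## Dating

For copies of a single germline invasion (monophyly is asserted by the
caller, not tested here), divergence accumulates independently in each copy
at the host neutral rate, so the age is t = d / (2μ) with d the largest
pairwise Kimura two-parameter distance,
d = −½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q), P and Q the transition and
transversion proportions. Sites with a gap or ambiguity in either sequence
are excluded pairwise; natural logarithms throughout; pairs outside the
formula's domain raise a saturation error and are skipped (with a warning)
in the maximum. The rate window μ ∈ [1.9, 2.4] × 10⁻⁹ substitutions/site/
year gives a time window: t_low uses the fast bound, t_high the slow one.
Using the *maximum* pairwise distance biases the estimate slightly upward
(order +5% at d ≈ 0.13 with 10 copies of 10 kb), which is inside the 10%
recovery tolerance the tests enforce.

## Cophylogeny reconciliation

Each virus-tree node maps onto the host tree. Internal nodes are explained
by cospeciation (maps to a host node, children diverge into its two child
lineages), duplication (both children stay in the lineage) or duplication &
host switching (one child stays, the other lands on any host branch that is
neither ancestral nor descendant of the current one — the *untimed* switch
model). A loss is charged each time a lineage rides through a host
speciation without diverging. A virus tip associated to k > 1 host tips
maps to their MRCA and is charged k−1 failure-to-diverge events (one per
branching node of the hosts' Steiner tree) plus a loss per pass-through
speciation on that Steiner tree; richer widespread-parasite semantics are
out of model. Costs are arbitrary finite reals (negative allowed — the
cospeciation-rewarding scheme −1,0,0,0,0 requires it).

The untimed model admits an exact O(|V|·|H|²) dynamic program (descend-with-
losses tables plus best-incomparable-placement tables), unlike timed
genetic-algorithm searches, whose results it can therefore only match or
beat on total cost; divergence on loss-heavy instances is expected and
deliberate. Event-count ranges over *all* co-optimal reconciliations are
exact at every problem size: for each event the DP is re-run minimizing
(total cost, ±count) lexicographically, which is valid because subproblems
combine additively and independently. A witness mapping is recovered by
traceback; an independent enumeration oracle (per-state sets of count
vectors at the state minimum) cross-checks both cost and ranges on small
instances. Floating-point ties are detected at 10⁻⁹; published schemes are
integer-valued, so sums are exact.

The congruence null samples virus-tree topologies uniformly over labeled
rooted binary topologies by sequential random edge insertion (tip k+1 onto
one of the 2k−1 branches), i.e. probability 1/(2n−3)!! each — note that
random coalescence of tip lineages would *not* be uniform over topologies,
and the 4-tip exact-enumeration check in the tests depends on uniformity.
p is the fraction of random topologies whose minimal cost is ≤ the observed
minimal cost (ties count against the observed tree); with n = 500 this
matches the published test's resolution. Multifurcating inputs are
rejected, not auto-resolved.

### Benchmark instances

The published congruence analyses are figures, not machine-readable trees,
so `synthetic_instances.py` carries synthetic stand-ins built to the same
reconciliation structure as the published summaries: an 11-tip pair
congruent up to one host switch (optimal: 9 cospeciations + 1 duplication &
host switch; totals −9 / 1 / 2 under the three standard schemes, p < 0.01),
and a 37-virus/20-host instance with a 14-tip codivergent backbone, nine
within-host duplicates and fourteen cross-host jumpers (exact optimum ≤ −13
under −1,0,0,0,0). They are labeled synthetic throughout; conclusions about
the real lineages require the real trees.

## Transmission networks

Every maximal clade whose tips share one host group (class granularity;
order for the paraphyletic reptiles — the granularity is the caller's
mapping) collapses to a single group-labeled leaf. Each cherry of the
collapsed tree with two different groups contributes one undirected event
to that group pair's edge; equal-group cherries cannot survive collapsing
and are treated as a usage error. Only binary cherries are counted (a
multi-leaf fan after collapse would be ambiguous between one and several
events). Direction is never inferred, because ancestral host states deep in
the tree are not reconstructable with certainty; the counts are biased
toward recent events by construction. For the water–land layer, a collapsed
leaf's habitat is the habitat shared by all tips it absorbed ("both" if
they disagree); a cherry counts only when one side is aquatic and the other
terrestrial — "both" matches either side and never counts.

## Synthetic data: what it emulates, and what it does not

Sequence decay uses a proper continuous-time Kimura two-parameter process
(transition rate = 4 × each transversion rate, i.e. instantaneous
transition:transversion 2:1, normalized to one expected substitution per
unit branch length), so multiple hits occur and the K2P estimator is the
matched, consistent estimator — a single-event-per-site shortcut would bias
the dating recovery tests upward by over 10% at d ≈ 0.3.

The genome generator implants `n_copies` (default 20) decayed copies of a
7.2 kb master provirus with a 4.5 kb in-frame pol region into an i.i.d.
background genome (default 400 kb, GC 0.41). Per-copy divergence is uniform
on 1–20% (converted to ages via μ = 2.15 × 10⁻⁹/site/year, the midpoint of
the published rate window); each copy receives Poisson(1) indels of 1–2 nt,
and with probability 0.5 is split once inside the pol region (each side
keeping ≥600 nt of pol so both fragments stay detectable), the gap filled
with background sequence of mean 400 nt, capped at 1.5 kb — below the
miner's default 2 kb chaining distance, which is the condition under which
recovery is claimed. Implants sit ≥3 kb apart so separate copies never
chain. The truth table records full spans, fragment spans, realized
divergence and the pol-anchored *recoverable* span; recall/precision and
the ±50 nt boundary tolerance are scored against the recoverable span,
since flanks outside the pol homology are invisible to a pol-seeded search
by construction. Emulated e-values follow the declared monotone surrogate
e = 10^(−0.1 · identity% · length_aa / 100); tests depend only on
configured thresholds, never on this formula's scale. Not emulated: repeat
landscapes and isochores, selection, recombination, LTRs, and search-tool
score statistics.

The co-evolution simulator grows a Yule host topology and runs the virus
down it: at each host speciation the virus cospeciates with probability
p_c, otherwise follows one side (a loss); on each host branch a duplication
& host switch fires with probability p_s toward a uniformly chosen
non-ancestral, non-descendant branch. Regimes: cospeciation-only (1, 0),
switch-dominated (0.2, 0.5), mixed (0.8, 0.15); simulation is conditioned
on ≥3 surviving virus lineages. In recovery tests the cospeciation-only
regime yields p = 0 structurally (only a topology-identical random tree
ties, probability 1/(2n−3)!!), and each replicate is asserted individually;
a switch-dominated replicate's p is approximately uniform under the null,
so that regime is asserted on the median across the 5 replicates — the
statistically stable summary for a "no better than random" claim.

## Problem sizes and determinism

Test and acceptance workloads are desk-scale by design: 100 random
instances of ≤7 virus tips for the enumeration cross-check, 500-tree nulls,
10 replicate genomes of 20 implants, 20 dating replicates of 10 kb, 100
random 20-tip trees for transmission counting. Every stochastic component
takes an explicit seed (numpy `default_rng` or `random.Random`), generators
are bit-reproducible given (spec, seed), and the pipeline writes per-stage
seeds and output checksums into its run report; identical config + seed
gives byte-identical outputs.

## Known limitations

- The miner's boundary accuracy is measured against pol-anchored spans;
  full-length provirus boundaries (with LTRs) are out of scope.
- Consensus projection does not re-align indels inside hit segments; at
  high indel density columns can blur toward ambiguity codes.
- The reconciliation model is untimed: switch targets ignore
  contemporaneity, so loss-heavy timed optima can differ.
- The dating module assumes a single invasion (monophyly asserted by the
  caller) and neutral post-insertion decay.
- Transmission counts at terminal nodes underestimate interclass
  transfer and cannot assign direction.
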