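# Methods

## Problem setting

Two homologous protein families (the running example is seryl- and
threonyl-tRNA synthetase, SerRS and ThrRS) each contain a taxon-rich
*common* form and a deeply divergent *rare* form. Whether the rare forms
are genuinely ancient — splitting from the common forms before the
families' own divergence — or are long-branch artifacts nested inside the
common forms cannot be settled by tree inference alone, because the rare
forms sit on long branches that attract each other and the root.
`paralogsites` implements two tree-free analyses of this question, plus a
simulator that generates both scenarios with known ground truth.

## Alignment decomposition

Let M be the master alignment of both families. Three column sets are
taken as input (from an alignment-confidence program run on the full
alignment and on each family's sub-alignment, or from the built-in
surrogate scorer):

* S — columns well aligned across both families;
* C_k — columns well aligned within family k's sub-alignment.

`exclusive_partition` makes these mutually exclusive: each C_k loses
columns in S and columns claimed by an earlier clade in declared order
(first-come-wins tie-break, logged; the tie-break only matters when two
clade masks overlap, which well-formed inputs avoid).
`decompose_alignment` concatenates the blocks — shared first, then each
clade block, each ascending by master coordinate — and records per-column
provenance `(partition label, master coordinate)`, a bijection onto the
union of the masks. The number of sites informative for clade k's
internal placement is |S| + |C_k|.

Two composites are offered. `retain` (default) copies residues verbatim
for all taxa, yielding a single alignment of all taxa. `gap-nonfocal`
blanks taxa outside clade k at C_k columns, since those columns were never
validated outside their clade; this trades information for conservatism
and is the right input for methods sensitive to misaligned blocks.

### Surrogate column scorer

When no external confidence scores are available,
`surrogate_column_scores` assigns each column
(mean pairwise identity among non-gap residue pairs) × (non-gap fraction),
zero for columns with fewer than two residues. It is plumbing for
exercising the pipeline, deliberately simple, and not a replacement for a
bootstrap-based confidence method: it conflates conservation with
alignability and will over-score conserved but misaligned blocks.

## Relaxed character-site detection

For a focal ingroup (family F, form φ), the sister group is F's other
form and the outgroup is the entire opposing family. At column j, with
shares computed over non-gap, non-X residues:

* **symplesiomorphy** — ∃ residue class C with ingroup share > t and
  outgroup share > t, and no sister taxon carries C;
* **synapomorphy** — ∃ class C with ingroup share > t, and no sister or
  outgroup taxon carries C;

with t = 0.5 strict (">50%"). The relaxation (shares rather than fixed
states) admits sites where derived lineages took further substitutions.
Absence is absolute: one sister taxon carrying the class vetoes the call
regardless of group sizes.

Choices the definition leaves open, and how they are resolved here:

* **Denominator.** Shares are fractions of non-gap residues; a group with
  more than half gaps at a column is ineligible and the column is not
  called (reason `coverage`). Non-gap denominators are the only choice
  under which heavily gapped columns cannot fake conservation.
* **Outgroup pooling** (default `pooled`). The outgroup share is computed
  over all outgroup taxa combined, weighting forms by taxon count. The
  alternative `per-form-majority` demands the class clear the threshold
  within every outgroup form separately — stricter, and it suppresses
  calls supported only by the larger outgroup form.
* **Residue classes.** Physiochemically similar residues pool into a
  candidate class opportunistically: a configured class (defaults
  {K,R}, {D,E}, {L,M,I,V}, {F,Y,W}, {S,T}) contributes a pooled candidate
  only when at least two of its members are present in the group.
  Candidates are examined in decreasing share order; a pooled candidate
  whose member occurs in the sister group fails the absence test, so
  pooling never rescues a vetoed residue. `absence_scope="class"`
  optionally extends the veto to the whole scheme class.
* **Weak calls.** A class that clears the ingroup threshold and the
  sister-absence test, and is the outgroup's plurality class without
  clearing the outgroup threshold, is emitted as a symplesiomorphy with
  `weak=True` and excluded from headline counts. This captures
  low-conservation ancestral sites without letting them inflate counts.
* **Rounding.** All threshold comparisons use raw fractions; percentages
  are rounded half-up for display and for the reported mean conservation.

`radicality` grades the defining class against the sister's dominant
class: conservative iff all residues of both fall in a single
physiochemical super-category (hydrophobic A,V,L,I,M,F,W,C; polar
S,T,N,Q,Y,G; positive K,R,H; negative D,E; proline alone), else radical.

Mirror calls are expected: a column that is a symplesiomorphy for the
rare form is often simultaneously a synapomorphy for the common form
(the sister changed; from the sister's perspective its own state is
derived). Headline symplesiomorphy counts are therefore reported per
ingroup, never summed across forms.

## The benchmark fixture

`make_benchmark_fixture` builds a 400-taxon, 31-column alignment (100
taxa per group) whose first seven columns reproduce, as exact residue
counts, the per-group conservation profiles of seven published
SerRS/ThrRS character sites (master sites 598, 758, 995 — rare-SerRS
symplesiomorphies — and 568, 994, 1082, 1101 — common-SerRS
symplesiomorphies). Unprinted remainders are filled so that exactly the
published calls fire. Two deliberate fixture choices:

* With equal group sizes, site 1082's pooled-ThrRS V share must exceed
  50% for the common-SerRS call; the real data achieve this through a
  common-ThrRS group much larger than the rare one. The fixture instead
  places V in the rare-ThrRS remainder (83 E + 17 V), preserving the
  printed E(83) profile while making pooled V = 103/200.
* At site 995 the common-ThrRS remainder contains L so that the
  common-SerRS L/M class is vetoed in the outgroup and produces no
  spurious call.

The 24 filler columns cycle through four engineered non-call shapes:
uniform columns (no absence anywhere), 50/50 two-residue columns (no
class clears the strict threshold), family-uniform columns (the residue
is shared with the sister), and columns with one group fully gapped
(coverage ineligibility).

## Scenario simulator

`simulate_alignment` evolves sequences down one of two topologies:
`deep_divergence` — ((commonA, rareA), (commonB, rareB)) rooted at the
family split — or `lba` — the rare-A ancestor hangs off the common-A
ancestor, nesting rare A inside common A. Within each group, tips hang
off the group ancestor in a star with a common branch length; this
ignores within-group phylogenetic structure deliberately, since the
detector only consumes per-group residue frequencies.

The substitution process is uniform-exchange: on a branch of length t
(expected substitutions/site at rate 1), a site with rate multiplier r
receives Poisson(r·t·μ) substitutions, each a uniform draw from the other
19 residues. A uniform model rather than an empirical matrix (LG/WAG)
keeps every expectation hand-calculable, and the character-site argument
depends only on slow sites and topology, not exchangeabilities. Sites
split into a fast background class (rate 1) and a slow class
(`slow_site_fraction`, default 0.3) with multiplier
`slow_rate_multiplier` (default 0 = invariant).

Planted sites occupy the slow class (switchable, for power studies). A
planted symplesiomorphy for ingroup X puts the defining residue at the
root and overrides X's sister ancestor to the background residue — the
single sister-stem substitution the site records; a planted synapomorphy
puts the background residue at the root and overrides X's own ancestor.
Plants that presuppose a bipartition the preset topology lacks (a rare-A
symplesiomorphy, or a common-A synapomorphy, under `lba`) raise a
validation error. At slow rate 0 the truth table is exact by
construction.

Default scenario parameters (group sizes 20/8/20/8, rare stems 1.2 vs
common stems 0.6/0.3, within-group length 0.3, 200 columns) echo the
qualitative shape of the real families — taxon-rich common forms,
smaller rare forms on long stems — at a size where a hundred replicates
run in seconds. `scenario_experiment` derives disjoint per-replicate
seeds from the master seed, scans each replicate with the default
detector, and reports mean non-weak symplesiomorphy counts per ingroup
and the planted-site recovery fraction.

What the simulator does **not** emulate: indels and alignment error
(alignments are simulated gap-free and correctly aligned), empirical
amino-acid exchangeabilities and site-specific profiles, within-group
tree structure, and rate variation beyond the two-class model.
Recovery and discrimination results on simulated data therefore bound
the detector's behavior under ideal alignment; on real data,
misalignment and compositional heterogeneity can only add noise.

## Validation strategy

The detector is checked exhaustively against a literal enumeration of
the definition on all 2^8 two-letter columns of an 8-taxon toy, and
property tests assert taxon-permutation invariance, monotone shrinkage
of the call set in the threshold, family-label symmetry and the absolute
sister veto. Decomposition is checked against brute-force set arithmetic
on random masks, with provenance bijectivity and column-multiset
conservation asserted on every build. Simulation-based tests assert
exact recovery at rate 0, monotone degradation across three slow-class
rates, and that rare-ingroup symplesiomorphy counts are systematically
higher under `deep_divergence` than under `lba` and scale directionally
with the sister stem length (100 replicates each).

## Known limitations

* The detector is frequency-based and tree-free; it cannot distinguish
  retained ancestral states from convergence at a single site — that
  inference comes from comparing counts across scenarios.
* Statistical significance of count differences is out of scope; raw
  counts (and simulation distributions) are reported.
* The surrogate scorer is not a substitute for bootstrap-based
  alignment-confidence methods.
* `per-form-majority` pooling is one strict reading of form-aware outgroup
  support; others (e.g. majority of forms) are possible but not
  implemented.
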