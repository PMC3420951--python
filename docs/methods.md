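# Methods

## The analysis

`dinobarcode` implements a distance-based DNA-barcoding workflow for
aligned ITS (internal transcribed spacer) rDNA sequences from
culture-collection strains. The workflow takes a pre-aligned
multi-FASTA plus a strain metadata table and produces:

1. an **uncorrected pairwise-distance (p-distance) matrix** computed
   from the single global alignment;
2. a **species delimitation**: single-linkage clusters at a distance
   cutoff θ, with naming, mismatch, cryptic-species and
   synonym-concordance rules applied;
3. **barcode-gap statistics** (intra- vs interspecific distance
   distributions, their mean ratio, a binned histogram);
4. **clonal paralogue summaries** (max/min/mean/SD of distances among
   the cloned rDNA copies of one strain);
5. **barcoding-efficiency accounting** over sequencing-outcome statuses;
6. a **neighbour-joining tree** with per-group monophyly checks.

Alignment itself is upstream (e.g. MAFFT); the package rejects unequal
sequence lengths rather than aligning.

## Distances

The p-distance between two aligned sequences is the fraction of
compared columns at which they differ. Column exclusion follows one of
two policies. Under **complete deletion** (the default) a single mask
is built for the whole alignment: any column containing a gap (`-`) or
an IUPAC ambiguity code in *any* record is excluded, so every pair is
compared over the same site set. Under **pairwise deletion** a column
contributes to a pair when both sequences carry an unambiguous A/C/G/T
there. Ambiguity codes are excluded outright, never scored as partial
matches. A pair with zero comparable sites is an error, not a distance
of 0. Distances are held at full precision internally and rounded to
3 decimals only in written tables.

P-distances after column exclusion need not obey the triangle
inequality; nothing downstream assumes they do.

## Species delimitation

Two sequences are conspecific when their distance is **at or below**
θ (default 0.02, i.e. 2%); `--strict-threshold` switches to a strict
`<`. Barcode groups are the connected components of the resulting
graph — single-linkage clustering, so chains can join strains whose
mutual distance exceeds θ. Chained over-threshold pairs are reported
(`chained_pairs`) rather than silently accepted or split, because a
distance threshold and a clustering of it are genuinely different
objects and users should see where they diverge.

Labelling rules, in order:

- a group with named members takes the **majority given species name**
  (`confirmed_species`); members carrying a different name are flagged
  `mismatch`, unnamed members are `newly_identified`;
- a group of two or more wholly unnamed strains becomes
  `"<Genus> group <n>"` (`new_group`), numbered per genus in order of
  first appearance;
- a **singleton** — no neighbour within θ — is `undetermined`; its
  given name, if any, is retained;
- groups whose members carry a declared **species-complex** name take
  `"<Complex> <RomanNumeral>"` labels in discovery order
  (`complex_subgroup`);
- a given species name that spans several groups marks **cryptic**
  variation: those groups are relabelled `"<name> group <k>"` and every
  bearer of the name is cryptic-flagged. Complex subgroups are exempt —
  complexes are known structure, not cryptic discovery.

Majority-vote **ties** are resolved by preferring the name with the
fewest bearers outside the group, then lexicographically. The
rationale: when a group holds equal numbers of two names, the name
whose other bearers sit in a different group is most plausibly the
imported (mislabelled) one. Either way the group keeps a
`name_conflicts` audit list, so a curator can override.

**Synonym checks** compare each declared strain-synonym pair:
`identical` at distance ≤ `identity_tol` (default 0), `within_species`
at ≤ θ, `discordant` above θ. Discordant synonyms are the signature of
mislabelled or contaminated cultures.

Group numbering follows first-member appearance in the input; this
plus the tie rules makes every output deterministic for a given input.

## Barcode gap and QC

Pairs are labelled intra/inter by the **given** species names (the gap
argument is about named species); strains without a name are omitted
and counted. An option relabels pairs by assigned barcode groups for
post-hoc analysis. The summary reports means/mins/maxes of both
distributions, the ratio of means (undefined when the intra mean is 0,
reported as such), a histogram with half-open bins of width 0.02 (last
bin closed), and every conspecific pair exceeding θ.

The mean ratio can be computed from pair values (default) or from
per-species(-pair) means first (`mean_mode="species"`); both are
exposed because "mean intra/inter distance" is ambiguous between the
two constructions and they differ whenever species contribute unequal
pair counts.

Clonal variation summarises all C(n,2) distances among one strain's
clones. The SD is the **population** standard deviation (ddof = 0) by
default; at 3-decimal table precision the divisor choice is visible on
small clone libraries, so it is pinned and configurable rather than
implicit.

Efficiency accounting needs only a status table (most failed strains
never produce a sequence): failure-cause percentages are shares of all
failures to 2 decimals (summing to 100 ± 0.02 after rounding),
per-genus success is barcoded/total within the genus, and totals are
split by a `source` column (`this_study` vs `database`) when present.

## Neighbour joining

Classic Saitou–Nei agglomeration on the same masked distance matrix
used for delimitation. At each step the pair minimising
Q(i,j) = (N−2)·d(i,j) − Σ_k d(i,k) − Σ_k d(j,k) is joined; branch
lengths come from the standard three-point formulas. Two choices that
published NJ implementations leave opaque are pinned for determinism:
ties are broken by the first pair in index order, and negative branch
length estimates are clamped to zero with the raw value retained on
the node. The unrooted tree is represented with a trifurcating root
(the final three-way join) and serialised to Newick with 6-decimal
branch lengths. On additive matrices this recovers the generating
topology and branch lengths exactly, which the test suite exercises
against randomly generated trees up to 16 leaves and cross-checks
against scikit-bio's NJ.

Group annotation tests each barcode group for monophyly: a group is
monophyletic on the unrooted tree iff its member set equals one side
of some edge bipartition.

## The synthetic generator

The generator emulates the statistical shape of an ITS barcode
database so the whole pipeline can be exercised without downloads:
~550-column alignments, conspecific divergence well below the 2%
cutoff, heterospecific divergence an order of magnitude larger,
near-identical paralogue copies per strain, and injected anomalies
(mislabels, synonym twins, alignment gaps) with a ground-truth table.

Defaults: 550 bp, intraspecies expected p-distance 0.01 (the
empirical 0–2% conspecific range), interspecies 0.20 (well inside the
observed ~5–40% heterospecific range), paralogue divergence 0.005
(clone-library magnitudes), no anomalies. The `database_scale` preset
scales a full database to desk size: 78 species analogues × 2 strains,
interspecies target 0.287 (the database-wide mean), 4 synonym twins.

Divergence targets are **expected p-distances**. Each lineage applies
one round of per-site replacement to a uniformly random different base
with probability q. This channel is closed under composition with
decay factor λ = 1 − (4/3)q, and two leaves differ per site with
probability (3/4)(1 − λ_path). The generator inverts this closed form:
q for the strain step solves 2q − (4/3)q² = intra target, and the
species step is solved so the **leaf-to-leaf** inter-species distance
(which also crosses two strain steps) hits the inter target exactly in
expectation under the star model. Realised means match targets to
Monte-Carlo noise for targets ≤ 0.3; near 0.75 the channel saturates.

The species tree is a **star** by default (all ancestors equidistant
from one root), keeping the inter target exactly interpretable;
`species_tree="random"` evolves ancestors down a random bifurcating
tree instead (targets then hold on average) for tree-shape exercises.

What the generator does *not* emulate — and hence what passing tests
do not establish about real data: indel evolution and realignment
(gaps are injected post hoc, only to exercise masking), rate variation
across sites and lineages, base-composition bias, chimeric sequences,
heterogeneous cultures, and the phylogenetic correlation structure of
real genera. Recovery rates on synthetic data are a correctness check
of the pipeline's logic under its own model, not an accuracy claim for
dinoflagellate ITS at large.

## Numerical and degenerate-input choices

- Inclusive threshold (≤ θ) is the operative definition; strictness is
  a flag, never a silent change.
- `U` → `T` and case-folding happen at load; distances are computed on
  the DNA alphabet.
- Zero comparable sites → error; empty strain table → error; clone
  groups with < 2 clones present → skipped with a warning; synonym
  pairs missing from the matrix → non-fatal `missing` entries.
- All randomness flows through a single integer seed
  (`numpy.random.default_rng`); identical configs reproduce
  byte-identical outputs, which the pipeline manifest (input SHA-256s,
  config, version) makes auditable.

## Problem sizes in the test suite

Oracle tests run on small instances where exhaustive recomputation is
trivial: alignments up to ~8 × 40 for the brute-force distance oracle,
matrices up to 12 strains for the transitive-closure oracle, trees up
to 16 leaves for NJ recovery, and 50-replicate simulations at
5 species × 4 strains for partition recovery and mislabel detection.
These sizes make every oracle exact while keeping the default suite
fast; the pipeline itself is routinely run on hundreds of sequences
(the `database_scale` preset has 160 records).

## Known limitations

- Single-linkage chaining is reported but not resolved; no alternative
  linkage is offered because the delimitation definition is explicitly
  threshold-graph connectivity.
- No model-corrected distances (K2P etc.) and no automatic cutoff
  optimisation (ABGD-style); θ is user-set.
- Labels are bookkeeping strings for curation, not nomenclatural acts.
- No bootstrap support on NJ trees.
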