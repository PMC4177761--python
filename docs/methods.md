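# Methods

## Model and assumptions

`lcaprof` implements a taxonomic-fraction heuristic for ancestral
gene-content inference, not a tree-based ancestral state reconstruction.
The working assumption is that an enzymatic activity found broadly and
independently across Bacteria, Archaea and Eukarya is more parsimoniously
explained by vertical inheritance from their last common ancestor (LCA)
than by repeated convergent gain, while activities confined to one domain
or a few clades reflect later innovation or horizontal spread. The method
therefore never dates events or reconstructs internal tree nodes; it
classifies present-day taxonomic distributions and applies a fixed
attribution rule. Dollo or maximum-likelihood reconstruction over an
explicit phylogeny is deliberately out of scope.

Three sources of bias are addressed structurally rather than
statistically:

* **Genome reduction.** Obligate parasites and genomes with fewer than
  1 000 genes are excluded before any statistic is computed, because
  their massive gene loss would register as ancestral absence. The
  boundary is strict (exactly 1 000 genes is retained). Parasite status
  is an input flag; no classifier is inferred.
* **Sampling redundancy.** Heavily sequenced genera (many genomes) and
  heavily sampled clades (many genera) would dominate naive pooled
  fractions. The two-step average — genome → genus mean, genus → clade
  mean, each level unweighted — gives every genus weight 1 inside its
  clade and every clade weight 1 inside its domain. A pooled
  genome-weighted mean is easy to compute for comparison but never feeds
  classification.
* **Multi-family activities.** One EC number can be carried by a protein
  complex (subunit profiles, combined with AND: the activity exists only
  when all components are present), by non-homologous analogous families
  or by paralogous families (combined with OR). EC-level presence is
  resolved from profile-level presence before averaging and attribution;
  per-profile outputs are also available.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `evalue_max` | 1e-10 | expectation value | hit significance, inclusive (`≤`) |
| `coverage_min` | 0.55 | fraction of profile length | hit significance, inclusive (`≥`); span is 1-based inclusive on the profile |
| `min_genes` | 1000 | genes | genome-reduction filter, strict (`<` removed) |
| `wide_fraction` | 0.5 | fraction of a domain's clades | "widely distributed" threshold, strict (`>`) |
| `presence_cutoff` | 0.0 | clade-average value | a clade "contains" an enzyme when its average exceeds this; 0 means any retained member genus suffices |
| `sparse_fraction` | 0.1 | fraction of clades | reporting boundary between *sparsely* and *partially* |

The first four are the field's conventional annotation and inclusion
criteria and are the package defaults everywhere (library, CLI, and the
simulated-data inverse). `presence_cutoff` and `sparse_fraction` are
conventions of this implementation: the qualitative labels *partially*
and *sparsely* have no standard quantitative definition, so both are
reported together with the numeric clade fraction and no downstream
logic depends on where that boundary sits. `sparse_fraction = 0.1` makes
a single-clade occurrence in a ten-clade domain read as sparse.

Best-hit resolution defaults to per (genome, query, profile): a single
protein may legitimately match several distinct profiles (bifunctional
enzymes such as the AICAR-transformylase/IMP-cyclohydrolase fusion carry
two activities). The `exclusive_best_hit` switch restricts each query to
its single best profile for users who want the narrowest reading of
"best hit per sequence". Ties on E-value break by higher bitscore, then
lower profile start, then lexicographic profile id, making output
independent of input order.

## LCA rule and pathway projection

An enzyme is attributed to the LCA iff its distribution class is
*widely* in all three domains; a missing domain classification is an
error, not a false verdict. On pathway graphs each step carries a set of
alternative ECs and is labelled `lca` when any alternative is
LCA-attributed (a reaction was available to the ancestor if any
catalysing family was), `non_lca` when all alternatives resolve false,
and `undetermined` when none is true and at least one EC has no verdict
— or when the step is tagged `nonenzymatic`, since spontaneous
chemistry is outside the attribution rule. Route completeness between
two metabolites is directed reachability using only steps of the
required label; reversibility is an explicit per-step flag, default
irreversible in the drawn direction.

Note that the strict rule is intentionally conservative: steps whose
families are individually narrow (e.g. the two thymidylate synthase
families, or the three dihydroorotate dehydrogenase families) come out
`non_lca` even where domain experts argue for ancestral presence on
superfamily or cofactor grounds. Such arguments are narrative, not
computable from distributions, and the package does not attempt them.

## Packaged data

The shipped inventories cover 120 distinct EC numbers across the purine
and pyrimidine maps, served by 151 profiles in the catalogue; files that
stand in for external reference objects are suffixed `.synthetic.tsv`
and documented as reconstructions in `lcaprof.datasets`. Grouping in the
catalogue follows the biology: PurQ/PurL subunits for FGAM synthase,
carbamoyl-phosphate synthase small/large chains, GMP-synthase subunits,
ribonucleotide-reductase components; PurN/PurT (folate- vs
formate-dependent GAR transformylases), PurH's two half-reactions vs the
archaeal PurP and PurO as analog groups; and 22 paralog pairs. Pathway
fixtures encode the de novo purine route to IMP (including both the
one-step CO₂-dependent and two-step HCO₃⁻-dependent AIR → CAIR
branches and the archaea-specific AICAR → IMP steps), the de novo
pyrimidine route to UMP, and pyrimidine metabolism from UMP onward. The
packaged distribution-class table for the purine route makes the five
PRPP → AIR steps widely distributed in all three domains and the
folate-dependent completion not, so the annotated graph shows an
LCA-complete PRPP → AIR trunk and an LCA-incomplete PRPP → IMP route.

## Synthetic generator

`ScenarioConfig` describes one scenario: a balanced hierarchy
(`n_clades_per_domain × n_genera_per_clade × n_genomes_per_genus` per
domain), ancestral enzymes present everywhere then lost i.i.d. per
genome with `loss_prob`, optional genus-level correlated loss
(`genus_loss_prob`) because clustered loss is the realistic stressor for
the clade-fraction rule, domain-restricted gains, and uniform HGT noise
applied to absent cells. Parasite genomes draw gene counts in
[400, 1000) and are flagged; non-parasites draw [1500, 6000]. The hit
emitter inverts the annotation stage: every present cell produces a hit
that passes both thresholds (E-value log-uniform down to 1e-40, span at
least the smallest integer whose float coverage passes), and absent
cells produce, with probability `decoy_prob`, a hit that provably fails
one threshold (coverage in [0.30, 0.55) or E-value in (1e-10, 1e-6]),
exercising the boundary logic. Filtering and re-binarizing the emitted
files reproduces the input matrix exactly, including the printed-and-
reparsed E-value edge cases. All sampling flows through one seeded
generator; equal seeds give byte-identical files.

What the generator does *not* emulate: sequence-level evolution and
realistic score/E-value joint distributions, tree-correlated loss beyond
the genus level, unbalanced taxonomies, or annotation error that is
correlated with phylogeny. Passing tests therefore demonstrate the
pipeline's correctness and the attribution rule's behaviour under the
stated noise model — not the biological accuracy of any particular LCA
call on real genomes.

## Numerical choices

Averages are computed in floats by default; `exact=True` switches
genus/clade averaging to `fractions.Fraction`, which the test suite uses
to compare against an independent brute-force nested-mean oracle with
exact equality (float mode is additionally held to an additive 1e-12 of
the rational value). Clade "presence" compares strictly (`>`)
against `presence_cutoff`, and the wide rule compares the clade fraction
strictly against `wide_fraction`, so 5 of 10 clades is not wide and 6 of
10 is. Exported matrices print floats with `repr`, which round-trips
bit-identically; rows are ordered numerically on the four EC fields
(2.4.2.14 before 2.7.6.1). Genera or clades emptied by the genome filter
are pruned from all denominators. Degenerate inputs behave as documented:
an empty hit file yields an empty hit list with a warning, a filter that
removes every genome yields an empty taxonomy with a warning, and a
domain left with zero clades raises during classification.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic data
at deliberately modest scale: averaging-oracle checks on hierarchies up
to 3 domains × 4 clades × 4 genera × 5 genomes, round-trip checks on
20 × 15 matrices, and recovery/specificity on 10 clades × 3 genera × 3
genomes per domain (270 genomes) with 50 enzymes over 40 seeds. At these
sizes the full suite completes in well under a minute; the pipeline
itself is linear in hits and in genomes × profiles and handles
thousand-genome scans comfortably.
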