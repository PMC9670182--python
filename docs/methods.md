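# Methods

## The detection procedure

An allopolyploid species carries two subgenomes, one per parental lineage,
so each of its nuclear gene families is expected to contain two homeologous
copies whose phylogenetic positions track the two parents. The pipeline
turns that expectation into a counting procedure:

1. **Filtering.** A gene family tree enters the analysis only if its taxon
   coverage exceeds a threshold (strictly greater than, matching the usual
   "more than X%" phrasing; default 0.5), the outgroup is present, every
   required taxon group has at least one representative, and any configured
   family-monophyly constraints hold on the outgroup-rooted tree. Monophyly
   is checked *after* pruning non-hybrid paralogs by default
   (`evaluate_after_pruning`), because isoform tips trivially break
   monophyly in transcriptome-derived trees. An optional minimum alignment
   length applies only when a per-orthogroup length table is supplied;
   tree-only inputs skip it with a logged notice.

2. **MUL conversion.** The tree is rooted on the edge separating the
   outgroup. Every non-hybrid species is reduced to its single best copy —
   "best" meaning longest, by the sequence-length table when available
   (isoform semantics: assembled transcripts of the true ortholog tend to be
   full-length) and by terminal branch length otherwise; ties break toward
   the lexicographically smallest gene id. All copies of hypothesized
   hybrids are retained. Each hybrid copy is then labeled by walking
   rootward to the first ancestor containing at least one *non-hybrid*
   witness taxon: label A if the witnesses fall entirely inside parental
   lineage A, B if inside lineage B, unassigned otherwise. Witness search
   skips tips of **all** hybrid taxa, not just the focal one — co-occurring
   hybrids are frequently nested together in the donor lineage and would
   otherwise block each other circularly. Within each (hybrid, label) the
   longest copy is kept; unassigned copies are dropped; remaining tips are
   renamed to bare taxon names with `A-`/`B-` prefixes on hybrid tips. The
   output topology is always a restriction of the input — the conversion
   never rearranges.

3. **Concordance counting.** For each internal clade of the rooted
   reference phylogeny (subgenome labels are ordinary taxa), each MUL gene
   tree is classified after mutual restriction to shared taxa: concordant if
   the restricted gene tree contains the clade, conflicting if some gene
   clade properly overlaps it, uninformative if missing taxa reduce the
   comparison below two-versus-one or an unresolved polytomy neither matches
   nor contradicts. Rooted-clade semantics (not unrooted bipartitions) are
   used because the counts annotate a rooted phylogeny, and the shared
   outgroup makes rootings comparable. Counts at every clade sum to the
   number of gene trees. The hybridization report gives, per subgenome
   label, the concordant count at its attachment clade (the smallest
   reference clade joining the labeled tip to a parental taxon), the
   fraction of informative trees that are concordant there, and the modal
   nearest-parental witness across gene trees; a hypothesis is *supported*
   when both labels' attachment clades have more concordant than conflicting
   trees.

4. **Quartet summary.** The summary species tree maximizes the number of
   (gene tree, four-taxon subset) pairs whose induced quartet topology the
   candidate reproduces — the statistically consistent core of coalescent
   summary methods, applied directly to MUL-labeled trees. Exact mode
   enumerates all (2n−5)!! unrooted topologies (limited to 8 taxa, 10,395
   trees); above that a heuristic starts from neighbor joining on
   quartet-mismatch distances (fraction of quartet votes separating each
   pair) and hill-climbs with nearest-neighbor interchanges, taking the best
   improving move each round. Per-branch support is the fraction of
   gene-tree quartets spanning the branch that agree with it.

## The simulator

Gene families are simulated under the multispecies coalescent on an
ultrametric species tree with branch lengths in coalescent units (time /
2N; the population size is implicitly one per branch, so no separate N
parameter exists). Each allopolyploidy event attaches the hybrid twice — at
time `t_hyb` on each donor's branch — giving a MUL species tree. One
haploid lineage is sampled per MUL tip (the hybrid's two subgenome tips
each contribute one copy of the hybrid taxon), and lineages coalesce within
each branch with pairwise rate 1 and uniform pair choice. Paralogs are
injected by grafting a copy of the subtree below a uniformly chosen edge as
its sister at the edge midpoint, with fresh gene ids mapped to their source
genes; optional per-tip dropout models incomplete transcriptomes (the
outgroup is never dropped, since outgroup-free trees are unrootable);
per-tip lengths are Normal(mean 1000 bp, sd 200 bp), clipped positive, with
an optional flag making true orthologs the longest copies (full-length
ortholog vs fragmentary isoform semantics).

**Randomness contract:** numpy PCG64 generators seeded via
`SeedSequence(seed, spawn_key=(gene_index, stage))`, one substream per gene
and stage (coalescent, duplication, dropout, lengths), so per-gene output is
independent of `n_genes` and datasets replay bit-for-bit.

**What passing tests show.** The simulator reproduces the closed-form
rooted-triple discordance `(2/3)e^(−T)` (verified at T = 0.5 and 2 with
10,000 genes), so recovery results quantify the method's behavior under
ILS, gene duplication and missing data. It does not emulate gene-tree
estimation error, alignment artifacts, gene loss beyond tip dropout,
introgression, or repeated/stacked hybridization — recovery rates on real
transcriptome data will be lower than on these idealized inputs.

### The demonstration setting

`nymphaeales_demo()` provides an 18-taxon water-lily-like arrangement: an
outgroup, a two-taxon sister family, an early-diverging genus pair, and
successively diverging subgenera, with two hybrid cultivars (`mid`, `wbg`)
sharing donor `col` (subgenome A) and donor `cae` (subgenome B) — nine
disjoint taxon groups cover all 18 taxa for the group-representation
filter. Every internal branch is `unit` coalescent units (5.0 = low ILS,
0.5 = moderate ILS). Donor terminal branches are three units deep and the
hybrids attach one and two units before present, so every internal branch
of the MUL species tree, including the segments between attachment points,
is at least one full unit — attaching hybrids near the tips of short donor
branches would otherwise create short internal branches that silently
reintroduce ILS into a nominally low-ILS setting. Default duplication rate
is 0.5 expected events per gene tree; default dropout is 0 (dropout is an
option, not part of the reference conditions, because a missing subgenome
copy is indistinguishable from an unassignable one).

## Numerical and design choices

- **Strict coverage bound** (`>` not `≥`), configurable.
- **Non-monophyletic species copies:** keep the single longest copy and log
  a `paraphyletic_copies` warning (strict mode discards the tree). Keeping
  maximizes usable signal while the conversion log preserves auditability.
- **Hybrids with more than two copies:** copies are grouped by assigned
  label and the longest per label wins; all copies landing in one lineage
  leaves one labeled tip and flags the tree uninformative for that hybrid's
  A/B split; zero assigned copies leaves the tree intact but flagged.
- **Non-monophyletic outgroup:** root above the largest outgroup-only
  clade, ties to the lexicographically smallest tip label, with a warning
  record.
- **Polytomies** are preserved on read and by support-collapsing
  (`--min-support`), score no quartet votes when unresolved, and count as
  uninformative rather than conflicting.
- **Determinism:** exact-mode enumeration adds taxa in sorted order onto
  edges in creation order; ties are broken toward the first topology and
  reported. The summary tree is serialized canonically (anchored at the
  smallest leaf, subtrees ordered by smallest leaf) so reruns are
  byte-identical.
- **Ultrametricity tolerance:** node ages must agree within a relative
  1e-6 when read from branch lengths.
- **Degenerate inputs:** fewer than four taxa yield a star tree with a
  note; empty restriction sets, absent outgroups, unknown taxa in group
  definitions, and invalid simulator configs raise before any work is done.

## Problem sizes

The test suite and the acceptance script run entirely on simulated data:
300-gene datasets on 18 taxa (20 MUL tips) for the recovery analyses, five
replicates for the moderate-ILS setting, 200 trees for invariant checks,
10,000 four-taxon genes for the coalescent calibration, and 20 random
6-taxon datasets against brute-force quartet oracles. The full suite
completes in well under a minute of simulation-dominated work per analysis
on one CPU.

## Limitations

- Hypotheses name the putative hybrids and candidate parental lineages;
  the package does not discover hybrids de novo.
- The quartet search above 8 taxa is a local-optimum heuristic (NJ + NNI);
  no optimality guarantee, though exact mode bounds it from above on small
  instances.
- Duplication/loss reconciliation (GRAMPA-style search over MUL
  placements) is out of scope; so are sequence simulation, alignment, and
  gene-tree inference — inputs are trees, not reads.
- A hybrid whose two subgenome copies both attach inside the same parental
  lineage (e.g. after donor extinction or missing sampling) yields a
  single-label tree: the method reports it as uninformative for the A/B
  split rather than guessing.
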