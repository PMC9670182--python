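"""Gene-tree / species-tree concordance counting on MUL-labeled trees.

For every internal clade of a rooted reference phylogeny, each MUL gene tree
is classified as concordant (the clade is present after mutual restriction to
shared taxa), conflicting (some gene-tree clade properly overlaps it), or
uninformative (missing taxa reduce the clade below a 2-vs-1 comparison, or an
unresolved polytomy neither matches nor contradicts).  Subgenome labels
(``A-hybrid`` / ``B-hybrid``) are ordinary taxa here, so the counts directly
quantify how many gene families support each hybrid copy's placement beside
its candidate parental lineage.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import dendropy
import pandas as pd

from .treeio import clade_sets, leaf_labels, restrict, tree_to_newick
from .mulprune import HybridHypothesis, MulLabeledTree

CONCORDANT = "concordant"
CONFLICTING = "conflicting"
UNINFORMATIVE = "uninformative"


def _as_tree(tree) -> dendropy.Tree:
    return tree.tree if isinstance(tree, MulLabeledTree) else tree


def _gene_clades(gene_tree: dendropy.Tree, shared: frozenset[str]) -> set[frozenset[str]]:
    """Clades of the gene tree restricted to the shared taxon set."""
    if not shared:
        return set()
    sub = restrict(gene_tree, shared)
    return clade_sets(sub, include_trivial=False)


def _classify_restricted(
    clades: set[frozenset[str]],
    shared: frozenset[str],
    ref_clade: frozenset[str],
) -> str:
    cp = frozenset(ref_clade & shared)
    if len(cp) < 2 or len(shared - cp) < 1:
        return UNINFORMATIVE
    if cp in clades:
        return CONCORDANT
    for g in clades:
        if g & cp and not g <= cp and not cp <= g:
            return CONFLICTING
    return UNINFORMATIVE


def classify(
    gene_tree: dendropy.Tree | MulLabeledTree,
    ref_clade: Iterable[str],
    ref_taxa: Iterable[str],
) -> str:
    """Classify one gene tree against one reference clade.

    Both sides are restricted to their shared taxa first (phyparts-style
    missing-taxon handling); the reference clade must be a subset of the
    reference taxon set.
    """
    gene_tree = _as_tree(gene_tree)
    ref_clade = frozenset(ref_clade)
    ref_taxa = frozenset(ref_taxa)
    if not ref_clade <= ref_taxa:
        raise ValueError("ref_clade is not a subset of ref_taxa")
    shared = frozenset(leaf_labels(gene_tree)) & ref_taxa
    return _classify_restricted(_gene_clades(gene_tree, shared), shared, ref_clade)


@dataclass
class NodeSupportTable:
    """Per reference clade: concordant / conflicting / uninformative counts."""

    ref: dendropy.Tree
    n_trees: int
    counts: dict[frozenset[str], dict[str, int]]
    supporting: dict[frozenset[str], list[int]]
    gene_trees: list[dendropy.Tree] = field(default_factory=list, repr=False)

    def row(self, clade: Iterable[str]) -> dict[str, int]:
        return self.counts[frozenset(clade)]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for clade in sorted(self.counts, key=lambda c: (len(c), sorted(c))):
            c = self.counts[clade]
            rows.append(
                {"clade": ",".join(sorted(clade)),
                 "n_concordant": c[CONCORDANT],
                 "n_conflicting": c[CONFLICTING],
                 "n_uninformative": c[UNINFORMATIVE]}
            )
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_trees": self.n_trees,
                "clades": [
                    {"clade": sorted(clade),
                     **self.counts[clade],
                     "supporting_trees": self.supporting[clade]}
                    for clade in sorted(self.counts,
                                        key=lambda c: (len(c), sorted(c)))
                ],
            },
            indent=2,
        )

    def annotated_newick(self) -> str:
        """Reference tree with concordant counts as internal-node labels."""
        annotated = self.ref.clone(depth=1)
        for node in annotated.preorder_node_iter():
            if node.is_leaf() or node.parent_node is None:
                continue
            clade = frozenset(lf.taxon.label for lf in node.leaf_iter())
            if clade in self.counts:
                node.label = str(self.counts[clade][CONCORDANT])
        return tree_to_newick(annotated)


def count_support(
    gene_trees: Sequence[dendropy.Tree | MulLabeledTree],
    ref: dendropy.Tree,
) -> NodeSupportTable:
    """Classify every (gene tree, reference clade) pair.

    At every clade the three counts sum to the number of gene trees.
    """
    trees = [_as_tree(t) for t in gene_trees]
    ref_taxa = frozenset(leaf_labels(ref))
    ref_clades = [
        frozenset(lf.taxon.label for lf in node.leaf_iter())
        for node in ref.preorder_node_iter()
        if not node.is_leaf() and node.parent_node is not None
    ]
    # de-duplicate (a MUL ref could in principle repeat a clade set)
    seen = set()
    ref_clades = [c for c in ref_clades if not (c in seen or seen.add(c))]

    counts = {c: {CONCORDANT: 0, CONFLICTING: 0, UNINFORMATIVE: 0}
              for c in ref_clades}
    supporting: dict[frozenset[str], list[int]] = {c: [] for c in ref_clades}
    for idx, gt in enumerate(trees):
        shared = frozenset(leaf_labels(gt)) & ref_taxa
        clades = _gene_clades(gt, shared)
        for ref_clade in ref_clades:
            verdict = _classify_restricted(clades, shared, ref_clade)
            counts[ref_clade][verdict] += 1
            if verdict == CONCORDANT:
                supporting[ref_clade].append(idx)
    return NodeSupportTable(
        ref=ref, n_trees=len(trees), counts=counts,
        supporting=supporting, gene_trees=trees,
    )


def _attachment_clade(
    ref: dendropy.Tree, tip_label: str, parents: frozenset[str]
) -> Optional[frozenset[str]]:
    """Smallest ref clade containing the labeled tip and >=1 parental taxon."""
    leaf = next((lf for lf in ref.leaf_node_iter()
                 if lf.taxon.label == tip_label), None)
    if leaf is None:
        return None
    node = leaf.parent_node
    while node is not None:
        clade = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if clade & parents:
            return clade
        node = node.parent_node
    return None


def _gene_attachments(
    gene_trees: Sequence[dendropy.Tree],
    tip_label: str,
    parents: frozenset[str],
) -> Counter:
    """Per gene tree, the parental taxa in the smallest clade holding the tip."""
    tally: Counter = Counter()
    for gt in gene_trees:
        leaf = next((lf for lf in gt.leaf_node_iter()
                     if lf.taxon.label == tip_label), None)
        if leaf is None:
            continue
        node = leaf.parent_node
        while node is not None:
            witnesses = frozenset(
                lf.taxon.label for lf in node.leaf_iter()
            ) & parents
            if witnesses:
                tally[",".join(sorted(witnesses))] += 1
                break
            node = node.parent_node
    return tally


def hybridization_report(
    table: NodeSupportTable,
    hypotheses: Iterable[HybridHypothesis],
    ref: Optional[dendropy.Tree] = None,
) -> dict:
    """Summarize the hybridization signal per (hybrid, subgenome label).

    For each labeled hybrid tip the report gives the concordant count of its
    attachment clade on the reference (the smallest clade joining the tip to
    a parental-lineage taxon), the fraction of informative gene trees that
    are concordant there, the distribution of nearest parental witnesses
    across gene trees, and a supported/unsupported verdict (supported when
    both labels' attachment clades have more concordant than conflicting
    trees).
    """
    ref = ref if ref is not None else table.ref
    ref_labels = set(leaf_labels(ref))
    out = {"n_trees": table.n_trees, "hypotheses": []}
    for hyp in hypotheses:
        entry = {"hybrid": hyp.hybrid, "labels": {}}
        verdict_ok = True
        for label in ("A", "B"):
            tip = hyp.prefix(label) + hyp.hybrid
            parents = frozenset(hyp.lineage_A | hyp.lineage_B)
            rec: dict = {"tip": tip}
            if tip not in ref_labels:
                rec["testable"] = False
                verdict_ok = False
                entry["labels"][label] = rec
                continue
            rec["testable"] = True
            clade = _attachment_clade(ref, tip, parents)
            if clade is None or clade not in table.counts:
                rec["testable"] = False
                verdict_ok = False
                entry["labels"][label] = rec
                continue
            c = table.counts[clade]
            informative = c[CONCORDANT] + c[CONFLICTING]
            rec.update(
                attachment_clade=sorted(clade),
                attachment_parents=sorted(clade & parents),
                n_concordant=c[CONCORDANT],
                n_conflicting=c[CONFLICTING],
                n_uninformative=c[UNINFORMATIVE],
                fraction_concordant=(
                    c[CONCORDANT] / informative if informative else 0.0
                ),
            )
            tally = _gene_attachments(table.gene_trees, tip, parents)
            rec["attachment_counts"] = dict(
                sorted(tally.items(), key=lambda kv: (-kv[1], kv[0]))
            )
            if tally:
                top = min(tally, key=lambda k: (-tally[k], k))
                rec["top_attachment"] = sorted(top.split(","))
            else:
                rec["top_attachment"] = []
            if not (c[CONCORDANT] > c[CONFLICTING]):
                verdict_ok = False
            entry["labels"][label] = rec
        entry["verdict"] = "supported" if verdict_ok else "unsupported"
        out["hypotheses"].append(entry)
    return out


def report_to_text(report: dict) -> str:
    """Human-readable summary mirroring a per-hypothesis results paragraph."""
    lines = [f"Gene trees analyzed: {report['n_trees']}"]
    for entry in report["hypotheses"]:
        lines.append(f"\nHybrid {entry['hybrid']}: {entry['verdict']}")
        for label, rec in entry["labels"].items():
            if not rec.get("testable"):
                lines.append(f"  {rec['tip']}: untestable (absent from reference)")
                continue
            lines.append(
                f"  {rec['tip']} attaches beside "
                f"{'+'.join(rec['attachment_parents']) or '?'}: "
                f"{rec['n_concordant']} concordant, "
                f"{rec['n_conflicting']} conflicting, "
                f"{rec['n_uninformative']} uninformative "
                f"(fraction concordant {rec['fraction_concordant']:.3f}; "
                f"modal witness {'+'.join(rec['top_attachment']) or 'none'})"
            )
    return "\n".join(lines)
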