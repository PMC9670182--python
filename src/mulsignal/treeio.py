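"""Tree input/output and manipulation primitives.

Gene family trees arrive as newick, one tree per line, with tip labels that
encode both the species and a gene/transcript identifier (default convention
``species__geneid``).  Multi-labeled (MUL) trees additionally carry a
subgenome prefix (``A-`` / ``B-``) on hybrid tips.  This module provides the
label-parsing, rooting and taxon-restriction primitives every downstream
stage builds on; all trees are :class:`dendropy.Tree` objects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import dendropy

logger = logging.getLogger("mulsignal")

DEFAULT_DELIMITER = "__"
DEFAULT_MUL_PREFIXES = ("A-", "B-")


class UnparseableLabelError(ValueError):
    """A tip label could not be split into species and gene id."""


class MissingOutgroupError(ValueError):
    """No tip of the requested outgroup taxa is present in the tree."""


@dataclass(frozen=True)
class TipLabel:
    """A parsed tip label.

    Attributes
    ----------
    raw : str
        The label exactly as it appears in the tree.
    species : str
        Taxon name.
    gene_id : str
        Gene / transcript identifier, unique within a tree.
    mul_label : str or None
        ``"A"`` or ``"B"`` when the raw label carries a subgenome prefix,
        else ``None``.
    """

    raw: str
    species: str
    gene_id: str
    mul_label: Optional[str] = None


@dataclass(frozen=True)
class LabelParser:
    """Policy object mapping raw tip labels to :class:`TipLabel`.

    The in-label convention (``species<delimiter>gene_id``) is the default;
    an external two-column taxon map (gene_id -> taxon) overrides it for
    datasets whose transcript names do not embed the species.
    """

    delimiter: str = DEFAULT_DELIMITER
    mul_prefixes: tuple[str, str] = DEFAULT_MUL_PREFIXES
    taxon_map: Optional[Mapping[str, str]] = None
    #: accept labels that are bare taxon names (species == gene_id == label),
    #: the convention of MUL-labeled trees
    bare: bool = False

    def parse(self, raw: str) -> TipLabel:
        if not raw:
            raise UnparseableLabelError("empty tip label")
        mul_label = None
        body = raw
        for prefix, code in zip(self.mul_prefixes, ("A", "B")):
            if body.startswith(prefix):
                mul_label = code
                body = body[len(prefix):]
                break
        if self.taxon_map is not None and body in self.taxon_map:
            return TipLabel(raw, self.taxon_map[body], body, mul_label)
        if self.delimiter in body:
            species, gene_id = body.split(self.delimiter, 1)
            if species and gene_id:
                return TipLabel(raw, species, gene_id, mul_label)
        if self.bare:
            return TipLabel(raw, body, body, mul_label)
        raise UnparseableLabelError(
            f"tip label {raw!r}: no delimiter {self.delimiter!r} and no "
            f"taxon-map entry"
        )

    def species(self, raw: str) -> str:
        return self.parse(raw).species


DEFAULT_PARSER = LabelParser()
#: parser for trees whose tips are already bare taxon names (e.g. MUL trees)
BARE_PARSER = LabelParser(bare=True)


def parse_tip(
    raw_label: str,
    delimiter: str = DEFAULT_DELIMITER,
    mul_prefixes: tuple[str, str] = DEFAULT_MUL_PREFIXES,
    taxon_map: Optional[Mapping[str, str]] = None,
) -> TipLabel:
    """Parse one raw tip label (see :class:`LabelParser`)."""
    return LabelParser(delimiter, mul_prefixes, taxon_map).parse(raw_label)


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

def tree_from_newick(newick: str, rooted: Optional[bool] = None) -> dendropy.Tree:
    """Parse a single newick string, preserving underscores in labels."""
    tree = dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True
    )
    if rooted is not None:
        tree.is_rooted = rooted
    return tree


def read_trees(path: str | Path) -> list[dendropy.Tree]:
    """Read a multi-tree newick file (one tree per line)."""
    trees = dendropy.TreeList.get(
        path=str(path), schema="newick", preserve_underscores=True
    )
    return list(trees)


def tree_to_newick(tree: dendropy.Tree, suppress_internal_labels: bool = False) -> str:
    """Serialize to a single-line newick string with unquoted-safe labels."""
    clone = tree.clone(depth=1)
    for leaf in clone.leaf_node_iter():
        if leaf.taxon is not None and leaf.taxon.label:
            leaf.taxon.label = leaf.taxon.label.replace(" ", "_")
    return clone.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        suppress_internal_node_labels=suppress_internal_labels,
    ).strip()


def write_trees(trees: Iterable[dendropy.Tree], path: str | Path) -> None:
    with open(path, "w") as fh:
        for tree in trees:
            fh.write(tree_to_newick(tree) + "\n")


def read_taxon_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV mapping gene_id -> taxon."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0] or not parts[1]:
                raise ValueError(f"{path}:{lineno}: expected 'gene_id<TAB>taxon'")
            if parts[0] in mapping and mapping[parts[0]] != parts[1]:
                raise ValueError(f"{path}:{lineno}: conflicting entry for {parts[0]!r}")
            mapping[parts[0]] = parts[1]
    return mapping


# ---------------------------------------------------------------------------
# basic queries
# ---------------------------------------------------------------------------

def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def species_set(tree: dendropy.Tree, parser: LabelParser = DEFAULT_PARSER) -> set[str]:
    return {parser.species(lbl) for lbl in leaf_labels(tree)}


def clade_sets(tree: dendropy.Tree, include_trivial: bool = False) -> set[frozenset[str]]:
    """All rooted clades (leaf-label sets of nodes) of the tree.

    By default only internal nodes are reported; ``include_trivial`` adds the
    single-leaf clades.
    """
    out: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            if include_trivial:
                out.add(frozenset([node.taxon.label]))
            continue
        out.add(frozenset(lf.taxon.label for lf in node.leaf_iter()))
    return out


def unrooted_bipartitions(tree: dendropy.Tree) -> set[frozenset[frozenset[str]]]:
    """Non-trivial bipartitions of the leaf set, as unordered side pairs."""
    all_leaves = frozenset(leaf_labels(tree))
    out: set[frozenset[frozenset[str]]] = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        other = all_leaves - side
        if len(side) >= 2 and len(other) >= 2:
            out.add(frozenset([side, other]))
    return out


# ---------------------------------------------------------------------------
# rooting
# ---------------------------------------------------------------------------

def _reroot_above(tree: dendropy.Tree, node: dendropy.Node) -> None:
    edge = node.edge
    if edge.length is not None:
        half = edge.length / 2.0
        tree.reroot_at_edge(edge, length1=half, length2=half,
                            update_bipartitions=False)
    else:
        tree.reroot_at_edge(edge, update_bipartitions=False)
    tree.suppress_unifurcations()
    tree.is_rooted = True


def root_with_outgroup(
    tree: dendropy.Tree,
    outgroup: Iterable[str],
    parser: LabelParser = DEFAULT_PARSER,
    log: Optional[list] = None,
) -> dendropy.Tree:
    """Root a (possibly unrooted) tree on the outgroup edge.

    The returned tree is a copy rooted on the edge separating all outgroup
    tips from the ingroup.  If the outgroup tips cannot be separated
    (non-monophyletic outgroup), the root is placed above the largest
    outgroup-only clade (ties broken by the lexicographically smallest tip
    label) and a warning record is emitted.
    """
    outgroup = set(outgroup)
    t = tree.clone(depth=1)
    og_leaves = [lf for lf in t.leaf_node_iter()
                 if parser.species(lf.taxon.label) in outgroup]
    if not og_leaves:
        raise MissingOutgroupError(
            f"no tip of outgroup taxa {sorted(outgroup)} in tree"
        )
    og_labels = {lf.taxon.label for lf in og_leaves}
    in_leaves = [lf for lf in t.leaf_node_iter()
                 if lf.taxon.label not in og_labels]
    if not in_leaves:
        logger.warning("tree consists only of outgroup tips; left unrooted")
        return t

    # already correctly rooted: root has two children, one of which is
    # exactly the outgroup clade
    root = t.seed_node
    children = root.child_nodes()
    if len(children) == 2:
        for child in children:
            below = {lf.taxon.label for lf in child.leaf_iter()}
            if below == og_labels:
                t.is_rooted = True
                return t

    # view the tree from inside the ingroup so outgroup monophyly is
    # well-defined, then look for a single clade holding every outgroup tip
    t.reroot_at_edge(in_leaves[0].edge, update_bipartitions=False)
    t.suppress_unifurcations()
    mrca = None
    if len(og_leaves) == 1:
        mrca = og_leaves[0]
    else:
        cand = t.mrca(taxa=[lf.taxon for lf in og_leaves])
        if cand is not None:
            below = {lf.taxon.label for lf in cand.leaf_iter()}
            if below == og_labels:
                mrca = cand
    if mrca is not None:
        _reroot_above(t, mrca)
        return t

    # non-monophyletic outgroup: largest outgroup-only clade wins
    best = None  # (size, min_label, node)
    for node in t.postorder_node_iter():
        if node.parent_node is None:
            continue
        below = {lf.taxon.label for lf in node.leaf_iter()}
        if below <= og_labels:
            key = (-len(below), min(below))
            if best is None or key < best[0]:
                best = (key, node)
    assert best is not None
    record = {
        "event": "non_monophyletic_outgroup",
        "detail": f"rooted above outgroup-only clade {sorted({lf.taxon.label for lf in best[1].leaf_iter()})}",
    }
    logger.warning(record["detail"])
    if log is not None:
        log.append(record)
    _reroot_above(t, best[1])
    return t


# ---------------------------------------------------------------------------
# restriction
# ---------------------------------------------------------------------------

def restrict(tree: dendropy.Tree, keep: Iterable[str]) -> dendropy.Tree:
    """Induced tree on a subset of tips.

    Unary nodes are suppressed with branch lengths summed; the root is kept
    whenever at least two children remain.  ``keep`` must be a non-empty
    subset of the tip labels.
    """
    keep = set(keep)
    if not keep:
        raise ValueError("restrict: empty keep set")
    present = set(leaf_labels(tree))
    missing = keep - present
    if missing:
        raise ValueError(f"restrict: tips not in tree: {sorted(missing)}")
    if keep == present:
        out = tree.clone(depth=1)
        out.is_rooted = tree.is_rooted
        return out
    out = tree.extract_tree_with_taxa_labels(labels=keep)
    out.is_rooted = tree.is_rooted
    return out


def relabel_tips(tree: dendropy.Tree, mapping: Mapping[str, str]) -> dendropy.Tree:
    """Copy of the tree with tip labels renamed through ``mapping``."""
    out = tree_from_newick(tree_to_newick(tree), rooted=tree.is_rooted)
    for leaf in out.leaf_node_iter():
        if leaf.taxon.label in mapping:
            leaf.taxon.label = mapping[leaf.taxon.label]
    return out


def collapse_low_support(tree: dendropy.Tree, min_support: float) -> dendropy.Tree:
    """Collapse internal edges whose support label is below ``min_support``.

    Internal-node newick labels are interpreted as support values when they
    parse as numbers; unlabeled edges are left alone.  Polytomies created by
    collapsing are preserved.
    """
    t = tree.clone(depth=1)
    to_collapse = []
    for node in t.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        if node.label is None:
            continue
        try:
            support = float(node.label)
        except ValueError:
            continue
        if support < min_support:
            to_collapse.append(node.edge)
    for edge in to_collapse:
        edge.collapse()
    return t
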