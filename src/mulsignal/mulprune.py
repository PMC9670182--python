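"""Conversion of multi-copy gene family trees into MUL-labeled trees.

An allopolyploid carries two homeologous gene copies, one per parental
subgenome.  Given a multi-copy gene family tree and a hybridization
hypothesis (the putative hybrid plus two disjoint candidate parental
lineages), the conversion

1. roots the tree on the outgroup,
2. prunes every non-hybrid species down to its single best (longest) copy,
3. assigns each surviving hybrid copy to parental lineage A or B by the
   first non-hybrid taxa encountered walking rootward, and
4. renames tips to bare taxon names, hybrids prefixed ``A-``/``B-``.

The result is a single-copy tree in which the hybrid appears up to twice —
the "multi-labeled" (MUL) representation whose topology is the hybridization
signal counted downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import dendropy
import pandas as pd

from .treeio import (
    DEFAULT_PARSER,
    LabelParser,
    leaf_labels,
    restrict,
    relabel_tips,
    root_with_outgroup,
    collapse_low_support,
)

logger = logging.getLogger("mulsignal")

UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class HybridHypothesis:
    """One putative hybrid and its two candidate parental lineages."""

    hybrid: str
    lineage_A: frozenset[str]
    lineage_B: frozenset[str]
    prefix_A: str = "A-"
    prefix_B: str = "B-"

    def __post_init__(self):
        la = frozenset(self.lineage_A)
        lb = frozenset(self.lineage_B)
        object.__setattr__(self, "lineage_A", la)
        object.__setattr__(self, "lineage_B", lb)
        if la & lb:
            raise ValueError(f"hypothesis {self.hybrid}: parental lineages overlap")
        if self.hybrid in la | lb:
            raise ValueError(f"hypothesis {self.hybrid}: hybrid inside a parental lineage")
        if not la or not lb:
            raise ValueError(f"hypothesis {self.hybrid}: empty parental lineage")

    def prefix(self, label: str) -> str:
        return self.prefix_A if label == "A" else self.prefix_B

    def lineage(self, label: str) -> frozenset[str]:
        return self.lineage_A if label == "A" else self.lineage_B


def read_length_table(path: str | Path) -> dict[str, int]:
    """Read a TSV of ``gene_id<TAB>length_bp``; lengths must be positive."""
    table: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'gene_id<TAB>length'")
            length = int(parts[1])
            if length <= 0:
                raise ValueError(f"{path}:{lineno}: non-positive length")
            table[parts[0]] = length
    return table


@dataclass
class ConversionLog:
    """Audit trail of every pruning, labeling, and drop decision."""

    records: list[dict] = field(default_factory=list)
    uninformative_for: list[str] = field(default_factory=list)

    def add(self, event: str, **detail) -> None:
        self.records.append({"event": event, **detail})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)


@dataclass
class MulLabeledTree:
    """Single-copy-per-taxon tree; hybrids appear as <=1 tip per label.

    ``provenance`` maps each output tip label back to the original gene tip
    label it was kept from.
    """

    tree: dendropy.Tree
    provenance: dict[str, str]

    def check_invariants(self, hybrids: Iterable[str]) -> None:
        hybrids = set(hybrids)
        seen: dict[str, int] = {}
        for lbl in leaf_labels(self.tree):
            seen[lbl] = seen.get(lbl, 0) + 1
        for lbl, n in seen.items():
            if n > 1:
                raise AssertionError(f"tip {lbl!r} appears {n} times")


def _copy_score(
    leaf: dendropy.Node,
    parser: LabelParser,
    lengths: Optional[Mapping[str, int]],
) -> tuple[float, str]:
    """Sort key for 'longest copy': (-length, gene_id); smaller is better."""
    tip = parser.parse(leaf.taxon.label)
    if lengths is not None:
        value = float(lengths.get(tip.gene_id, 0))
    else:
        value = float(leaf.edge.length or 0.0)
    return (-value, tip.gene_id)


def best_copy(
    tree: dendropy.Tree,
    species: str,
    parser: LabelParser = DEFAULT_PARSER,
    lengths: Optional[Mapping[str, int]] = None,
    log: Optional[ConversionLog] = None,
) -> dendropy.Node:
    """The single best (longest) copy of a species.

    Length is taken from the sequence-length table when given, else from the
    terminal branch length; ties break toward the lexicographically smallest
    gene id.  A warning is recorded when the species' copies are not
    monophyletic.
    """
    tips = [lf for lf in tree.leaf_node_iter()
            if parser.species(lf.taxon.label) == species]
    if not tips:
        raise ValueError(f"species {species!r} absent from tree")
    if len(tips) > 1:
        mrca_leaves = {
            parser.species(lf.taxon.label)
            for lf in tree.mrca(taxa=[t.taxon for t in tips]).leaf_iter()
        }
        if mrca_leaves != {species}:
            msg = f"paraphyletic-copies: {species} copies are not monophyletic"
            logger.debug(msg)
            if log is not None:
                log.add("paraphyletic_copies", species=species)
    return min(tips, key=lambda lf: _copy_score(lf, parser, lengths))


def prune_paralogs(
    tree: dendropy.Tree,
    hybrids: Iterable[str],
    parser: LabelParser = DEFAULT_PARSER,
    lengths: Optional[Mapping[str, int]] = None,
    log: Optional[ConversionLog] = None,
) -> dendropy.Tree:
    """Reduce every non-hybrid species to its best copy; keep all hybrid tips.

    The output topology is exactly the restriction of the input to the kept
    tips (no rearrangement).
    """
    hybrids = set(hybrids)
    by_species: dict[str, list[str]] = {}
    for lbl in leaf_labels(tree):
        by_species.setdefault(parser.species(lbl), []).append(lbl)
    kept: list[str] = []
    for species, labels in by_species.items():
        if species in hybrids:
            kept.extend(labels)
            continue
        if len(labels) == 1:
            kept.append(labels[0])
            continue
        best = best_copy(tree, species, parser, lengths, log)
        kept.append(best.taxon.label)
        if log is not None:
            for lbl in labels:
                if lbl != best.taxon.label:
                    log.add("pruned_paralog", species=species, tip=lbl,
                            kept=best.taxon.label)
    return restrict(tree, kept)


def assign_parent_lineage(
    tree: dendropy.Tree,
    hybrid_tip: dendropy.Node | str,
    hyp: HybridHypothesis,
    parser: LabelParser = DEFAULT_PARSER,
    all_hybrids: Optional[Iterable[str]] = None,
) -> str:
    """Label one hybrid copy ``"A"``, ``"B"``, or ``"unassigned"``.

    Walks rootward from the copy to the first ancestor whose descendants
    include at least one non-hybrid taxon; those taxa are the witnesses W.
    Tips of *any* hybrid taxon are skipped as witnesses, which breaks the
    circularity of co-occurring hybrids nested together.  Returns ``A`` if
    W is inside lineage A, ``B`` if inside lineage B, else ``unassigned``.
    """
    skip = set(all_hybrids) if all_hybrids is not None else set()
    skip.add(hyp.hybrid)
    if isinstance(hybrid_tip, str):
        matches = [lf for lf in tree.leaf_node_iter()
                   if lf.taxon.label == hybrid_tip]
        if not matches:
            raise ValueError(f"tip {hybrid_tip!r} not in tree")
        hybrid_tip = matches[0]
    if parser.species(hybrid_tip.taxon.label) != hyp.hybrid:
        raise ValueError(
            f"tip {hybrid_tip.taxon.label!r} does not belong to {hyp.hybrid!r}"
        )
    non_hybrid_exists = any(
        parser.species(lbl) not in skip for lbl in leaf_labels(tree)
    )
    if not non_hybrid_exists:
        raise ValueError("tree contains no non-hybrid tip")
    node = hybrid_tip.parent_node
    while node is not None:
        witnesses = {
            parser.species(lf.taxon.label) for lf in node.leaf_iter()
        } - skip
        if witnesses:
            if witnesses <= hyp.lineage_A:
                return "A"
            if witnesses <= hyp.lineage_B:
                return "B"
            return UNASSIGNED
        node = node.parent_node
    return UNASSIGNED


def mul_convert(
    tree: dendropy.Tree,
    hypotheses: Iterable[HybridHypothesis],
    outgroup: Iterable[str],
    parser: LabelParser = DEFAULT_PARSER,
    lengths: Optional[Mapping[str, int]] = None,
    min_support: Optional[float] = None,
) -> tuple[MulLabeledTree, ConversionLog]:
    """Full conversion: root, prune, assign, keep one copy per label, rename.

    Within each (hybrid, label) the longest assigned copy is kept; unassigned
    copies are dropped.  A hybrid that ends with no assigned copy leaves the
    tree intact but flags it uninformative for that hybrid.
    """
    hypotheses = list(hypotheses)
    hybrids = {h.hybrid for h in hypotheses}
    log = ConversionLog()
    rooted = root_with_outgroup(tree, outgroup, parser, log=log.records)
    if min_support is not None:
        rooted = collapse_low_support(rooted, min_support)
    pruned = prune_paralogs(rooted, hybrids, parser, lengths, log)

    rename: dict[str, str] = {}
    drop: set[str] = set()
    for lbl in leaf_labels(pruned):
        species = parser.species(lbl)
        if species not in hybrids:
            rename[lbl] = species

    for hyp in hypotheses:
        copies = [lf for lf in pruned.leaf_node_iter()
                  if parser.species(lf.taxon.label) == hyp.hybrid]
        by_label: dict[str, list[dendropy.Node]] = {}
        for lf in copies:
            label = assign_parent_lineage(pruned, lf, hyp, parser, hybrids)
            log.add("assigned", hybrid=hyp.hybrid, tip=lf.taxon.label,
                    label=label)
            if label == UNASSIGNED:
                drop.add(lf.taxon.label)
            else:
                by_label.setdefault(label, []).append(lf)
        for label, members in by_label.items():
            winner = min(members, key=lambda lf: _copy_score(lf, parser, lengths))
            rename[winner.taxon.label] = hyp.prefix(label) + hyp.hybrid
            for lf in members:
                if lf is not winner:
                    drop.add(lf.taxon.label)
                    log.add("dropped_extra_copy", hybrid=hyp.hybrid,
                            tip=lf.taxon.label, label=label)
        if not by_label:
            log.uninformative_for.append(hyp.hybrid)
            log.add("uninformative", hybrid=hyp.hybrid,
                    detail=f"no copy of {hyp.hybrid} could be assigned")
        elif len(by_label) == 1:
            only = next(iter(by_label))
            log.add("single_lineage", hybrid=hyp.hybrid, label=only,
                    detail="all assigned copies map to one parental lineage")

    kept = [lbl for lbl in leaf_labels(pruned) if lbl not in drop]
    out = restrict(pruned, kept)
    out = relabel_tips(out, rename)
    provenance = {new: old for old, new in rename.items() if old not in drop}
    mul = MulLabeledTree(tree=out, provenance=provenance)
    mul.check_invariants(hybrids)
    return mul, log
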