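"""Selection of gene family trees suitable for MUL conversion.

Orthogroup trees inferred from transcriptomes are noisy: fragmentary
assemblies miss taxa, isoforms inflate copy numbers, and hidden paralogy
breaks expected family monophyly.  This module applies the standard
filtering battery — taxon coverage, outgroup presence, representation of
named taxon groups, family monophyly, and optional alignment length — and
reports exactly why each tree was kept or rejected.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import dendropy
import pandas as pd

from .treeio import DEFAULT_PARSER, LabelParser, species_set, root_with_outgroup

logger = logging.getLogger("mulsignal")


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class TaxonGroups:
    """Named, pairwise-disjoint taxon sets; required groups need >=1 member."""

    groups: dict[str, frozenset[str]]
    required: frozenset[str] = None  # default: all groups required

    def __post_init__(self):
        groups = {k: frozenset(v) for k, v in self.groups.items()}
        object.__setattr__(self, "groups", groups)
        seen: dict[str, str] = {}
        for name, members in groups.items():
            for taxon in members:
                if taxon in seen:
                    raise ConfigurationError(
                        f"taxon {taxon!r} in groups {seen[taxon]!r} and {name!r}"
                    )
                seen[taxon] = name
        req = self.required if self.required is not None else frozenset(groups)
        object.__setattr__(self, "required", frozenset(req))
        unknown = self.required - set(groups)
        if unknown:
            raise ConfigurationError(f"required groups not defined: {sorted(unknown)}")

    def validate_against(self, universe: Iterable[str]) -> None:
        universe = set(universe)
        for name, members in self.groups.items():
            unknown = members - universe
            if unknown:
                raise ConfigurationError(
                    f"group {name!r} names unknown taxa: {sorted(unknown)}"
                )


@dataclass(frozen=True)
class FilterCriteria:
    """Tree-selection thresholds.

    ``min_coverage`` is a strict lower bound (a tree passes with coverage
    strictly greater), matching the usual "more than X%" phrasing; set
    ``strict_coverage=False`` for >=.
    """

    min_coverage: float = 0.5
    require_outgroup: bool = True
    groups: Optional[TaxonGroups] = None
    monophyly_constraints: tuple[frozenset[str], ...] = ()
    min_alignment_length: Optional[int] = None
    evaluate_after_pruning: bool = True
    strict_coverage: bool = True

    def __post_init__(self):
        if not (0.0 <= self.min_coverage <= 1.0):
            raise ConfigurationError("min_coverage must lie in [0, 1]")
        object.__setattr__(
            self,
            "monophyly_constraints",
            tuple(frozenset(c) for c in self.monophyly_constraints),
        )


@dataclass
class FilterReport:
    """Per-tree pass/fail plus ordered failed-criterion names."""

    entries: list[dict] = field(default_factory=list)

    def add(self, tree_id: str, failures: Sequence[str]) -> None:
        self.entries.append(
            {"tree_id": tree_id, "passed": not failures,
             "failures": list(failures)}
        )

    @property
    def n_kept(self) -> int:
        return sum(e["passed"] for e in self.entries)

    def aggregate(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for e in self.entries:
            for f in e["failures"]:
                counts[f] = counts.get(f, 0) + 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"tree_id": e["tree_id"], "passed": e["passed"],
                 "failures": ";".join(e["failures"])}
                for e in self.entries
            ]
        )

    def to_json(self) -> str:
        return json.dumps(
            {"n_trees": len(self.entries), "n_kept": self.n_kept,
             "failure_counts": self.aggregate(), "trees": self.entries},
            indent=2,
        )


def coverage(
    tree: dendropy.Tree,
    universe: Iterable[str],
    parser: LabelParser = DEFAULT_PARSER,
) -> float:
    """Fraction of the taxon universe present; copy multiplicity is ignored."""
    universe = set(universe)
    if not universe:
        raise ValueError("coverage: empty taxon universe")
    return len(species_set(tree, parser) & universe) / len(universe)


def is_monophyletic(
    tree: dendropy.Tree,
    taxa: Iterable[str],
    parser: LabelParser = DEFAULT_PARSER,
) -> bool:
    """Whether some clade of the rooted tree holds exactly the present members
    of ``taxa`` (all copies of each member included).

    Absent members are ignored; with no member present the constraint is
    vacuously true (with a warning).
    """
    if not tree.is_rooted:
        raise ValueError("is_monophyletic: tree must be rooted (root first)")
    taxa = set(taxa)
    tips = [lf for lf in tree.leaf_node_iter()
            if parser.species(lf.taxon.label) in taxa]
    if not tips:
        logger.warning("monophyly of %s: no member present (vacuously true)",
                       sorted(taxa))
        return True
    if len(tips) == 1:
        return True
    mrca = tree.mrca(taxa=[t.taxon for t in tips])
    below = {parser.species(lf.taxon.label) for lf in mrca.leaf_iter()}
    return below <= taxa


def select_trees(
    trees: Sequence[dendropy.Tree],
    criteria: FilterCriteria,
    universe: Iterable[str],
    outgroup: Iterable[str] = (),
    parser: LabelParser = DEFAULT_PARSER,
    hybrids: Iterable[str] = (),
    lengths: Optional[Mapping[str, int]] = None,
    alignment_lengths: Optional[Mapping[str, int]] = None,
) -> tuple[list[dendropy.Tree], FilterReport]:
    """Apply the full criteria battery and report every failure.

    Monophyly constraints are evaluated on the outgroup-rooted tree, after
    pruning non-hybrid paralogs when ``criteria.evaluate_after_pruning`` is
    set (isoform tips would otherwise trivially break monophyly).
    Alignment-length filtering only runs when a per-tree length table is
    supplied; ``alignment_lengths`` is keyed by tree label (or index as a
    string when trees are unlabeled).
    """
    universe = set(universe)
    outgroup = set(outgroup)
    if criteria.groups is not None:
        criteria.groups.validate_against(universe)
    for constraint in criteria.monophyly_constraints:
        unknown = constraint - universe
        if unknown:
            raise ConfigurationError(
                f"monophyly constraint names unknown taxa: {sorted(unknown)}"
            )
    if criteria.min_alignment_length is not None and alignment_lengths is None:
        logger.info(
            "min_alignment_length set but no alignment-length table supplied; "
            "length criterion skipped"
        )

    report = FilterReport()
    kept: list[dendropy.Tree] = []
    for idx, tree in enumerate(trees):
        tree_id = tree.label or str(idx)
        failures: list[str] = []
        present = species_set(tree, parser)

        cov = coverage(tree, universe, parser)
        cov_ok = cov > criteria.min_coverage if criteria.strict_coverage \
            else cov >= criteria.min_coverage
        if not cov_ok:
            failures.append("coverage")

        has_outgroup = bool(present & outgroup)
        if criteria.require_outgroup and not has_outgroup:
            failures.append("outgroup")

        if criteria.groups is not None:
            for name in sorted(criteria.groups.required):
                if not (criteria.groups.groups[name] & present):
                    failures.append(f"group:{name}")

        if (criteria.min_alignment_length is not None
                and alignment_lengths is not None):
            length = alignment_lengths.get(tree_id)
            if length is None or length <= criteria.min_alignment_length:
                failures.append("alignment_length")

        if criteria.monophyly_constraints:
            if not has_outgroup:
                failures.append("monophyly:unrootable")
            else:
                rooted = root_with_outgroup(tree, outgroup, parser)
                if criteria.evaluate_after_pruning:
                    from .mulprune import prune_paralogs
                    rooted = prune_paralogs(rooted, hybrids, parser, lengths)
                for constraint in criteria.monophyly_constraints:
                    if not is_monophyletic(rooted, constraint, parser):
                        failures.append(
                            "monophyly:" + ",".join(sorted(constraint)[:3])
                        )

        report.add(tree_id, failures)
        if not failures:
            kept.append(tree)
    return kept, report
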