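"""End-to-end orchestration: filter -> mulify -> count -> summarize -> report.

A single YAML config names the inputs (gene trees, reference tree, optional
taxon map and length table), the filter criteria, the hybridization
hypotheses and the mode flags; :func:`run_pipeline` executes the stages in
order, writes every intermediate artifact to the output directory (so any
downstream stage can be resumed from disk), and returns the final report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import concord, mulprune, ogfilter, summarize, treeio

logger = logging.getLogger("mulsignal")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    gene_trees: Path
    reference_tree: Path
    outgroup: frozenset[str]
    hypotheses: list[mulprune.HybridHypothesis]
    criteria: ogfilter.FilterCriteria
    universe: frozenset[str]
    taxon_map: Optional[Path] = None
    lengths: Optional[Path] = None
    alignment_lengths: Optional[Path] = None
    delimiter: str = treeio.DEFAULT_DELIMITER
    mul_prefixes: tuple[str, str] = treeio.DEFAULT_MUL_PREFIXES
    min_support: Optional[float] = None
    strict_pruning: bool = False
    summary_mode: str = "heuristic"
    seed: int = 0

    def parser(self) -> treeio.LabelParser:
        taxon_map = treeio.read_taxon_map(self.taxon_map) if self.taxon_map else None
        return treeio.LabelParser(self.delimiter, self.mul_prefixes, taxon_map)


def load_config(path: str | Path) -> RunConfig:
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    base = path.parent

    def resolve(key) -> Optional[Path]:
        if raw.get(key) is None:
            return None
        p = Path(raw[key])
        p = p if p.is_absolute() else base / p
        if not p.exists():
            raise PipelineError("config", f"{key}: {p} does not exist")
        return p

    groups_raw = raw.get("filter", {}).get("groups")
    groups = None
    if groups_raw:
        groups = ogfilter.TaxonGroups(
            groups={k: frozenset(v) for k, v in groups_raw.items()},
            required=frozenset(raw["filter"].get("required_groups", groups_raw)),
        )
    fr = raw.get("filter", {})
    criteria = ogfilter.FilterCriteria(
        min_coverage=fr.get("min_coverage", 0.5),
        require_outgroup=fr.get("require_outgroup", True),
        groups=groups,
        monophyly_constraints=tuple(
            frozenset(c) for c in fr.get("monophyly", [])
        ),
        min_alignment_length=fr.get("min_alignment_length"),
        evaluate_after_pruning=fr.get("evaluate_after_pruning", True),
    )
    hypotheses = [
        mulprune.HybridHypothesis(
            hybrid=h["hybrid"],
            lineage_A=frozenset(h["lineage_A"]),
            lineage_B=frozenset(h["lineage_B"]),
        )
        for h in raw.get("hypotheses", [])
    ]
    universe = frozenset(raw["taxa"])
    return RunConfig(
        gene_trees=resolve("gene_trees"),
        reference_tree=resolve("reference_tree"),
        taxon_map=resolve("taxon_map"),
        lengths=resolve("lengths"),
        alignment_lengths=resolve("alignment_lengths"),
        outgroup=frozenset(raw["outgroup"]),
        hypotheses=hypotheses,
        criteria=criteria,
        universe=universe,
        delimiter=raw.get("delimiter", treeio.DEFAULT_DELIMITER),
        mul_prefixes=tuple(raw.get("mul_prefixes", treeio.DEFAULT_MUL_PREFIXES)),
        min_support=raw.get("min_support"),
        strict_pruning=raw.get("strict_pruning", False),
        summary_mode=raw.get("summary_mode", "heuristic"),
        seed=raw.get("seed", 0),
    )


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute every stage and write all artifacts under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    parser = config.parser()

    try:
        trees = treeio.read_trees(config.gene_trees)
        ref = treeio.read_trees(config.reference_tree)[0]
        ref.is_rooted = True
        lengths = (mulprune.read_length_table(config.lengths)
                   if config.lengths else None)
        align_lengths = None
        if config.alignment_lengths:
            align_lengths = mulprune.read_length_table(config.alignment_lengths)
    except (OSError, ValueError) as exc:
        raise PipelineError("load", str(exc)) from exc

    hybrids = {h.hybrid for h in config.hypotheses}
    try:
        kept, filter_report = ogfilter.select_trees(
            trees, config.criteria, config.universe, config.outgroup,
            parser, hybrids=hybrids, lengths=lengths,
            alignment_lengths=align_lengths,
        )
    except (ValueError, treeio.UnparseableLabelError) as exc:
        raise PipelineError("filter", str(exc)) from exc
    filter_report.to_frame().to_csv(out / "filter_report.tsv", sep="\t",
                                    index=False)
    (out / "filter_report.json").write_text(filter_report.to_json())
    if not kept:
        raise PipelineError("filter", "no trees passed filtering")
    logger.info("filter: kept %d / %d trees", len(kept), len(trees))

    mul_trees: list[mulprune.MulLabeledTree] = []
    log_frames = []
    try:
        for idx, tree in enumerate(kept):
            mul, conv_log = mulprune.mul_convert(
                tree, config.hypotheses, config.outgroup, parser,
                lengths=lengths, min_support=config.min_support,
            )
            if config.strict_pruning and any(
                r["event"] == "paraphyletic_copies" for r in conv_log.records
            ):
                logger.info("mulify: dropping tree %d (paraphyletic copies)", idx)
                continue
            mul.tree.label = tree.label or f"tree{idx}"
            mul_trees.append(mul)
            frame = conv_log.to_frame()
            if not frame.empty:
                frame.insert(0, "tree_id", mul.tree.label)
                log_frames.append(frame)
    except (ValueError, treeio.UnparseableLabelError) as exc:
        raise PipelineError("mulify", str(exc)) from exc
    if not mul_trees:
        raise PipelineError("mulify", "no usable MUL trees after conversion")
    treeio.write_trees([m.tree for m in mul_trees], out / "mul_trees.nwk")
    if log_frames:
        import pandas as pd
        pd.concat(log_frames).to_csv(out / "conversion_log.tsv", sep="\t",
                                     index=False)

    try:
        table = concord.count_support(mul_trees, ref)
        report = concord.hybridization_report(table, config.hypotheses)
    except ValueError as exc:
        raise PipelineError("count", str(exc)) from exc
    table.to_frame().to_csv(out / "node_support.tsv", sep="\t", index=False)
    (out / "node_support.json").write_text(table.to_json())
    (out / "node_support_annotated.nwk").write_text(
        table.annotated_newick() + "\n")

    try:
        summary = summarize.infer_summary_tree(
            [m.tree for m in mul_trees], mode=config.summary_mode
        )
    except ValueError as exc:
        raise PipelineError("summarize", str(exc)) from exc
    (out / "summary_tree.nwk").write_text(summary.annotated_newick() + "\n")

    final = {
        "n_input_trees": len(trees),
        "n_kept_trees": len(kept),
        "n_mul_trees": len(mul_trees),
        "filter_failure_counts": filter_report.aggregate(),
        "hybridization": report,
        "summary": {
            "mode": summary.mode,
            "score": summary.score,
            "tree": treeio.tree_to_newick(summary.tree,
                                          suppress_internal_labels=True),
            "note": summary.note,
        },
    }
    (out / "report.json").write_text(json.dumps(final, indent=2))
    (out / "report.txt").write_text(
        concord.report_to_text(report)
        + f"\n\nSummary tree ({summary.mode}, quartet score {summary.score}):\n"
        + treeio.tree_to_newick(summary.tree, suppress_internal_labels=True)
        + "\n"
    )
    return final
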