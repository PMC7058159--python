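"""The canary-sequence classification pipeline.

Given a full alignment and a designated set of "sequences of interest",
the pipeline classifies each interest sequence by how it behaves when
added, alone, to the base alignment (the full alignment minus all interest
sequences):

1.  Infer the base tree and the full tree.
2.  For each interest sequence, build the checking dataset (base plus that
    sequence) and infer its checking tree.
3.  If the checking tree, after removal of the focal sequence, is not
    isomorphic to the base tree, the sequence perturbs the base
    relationships and joins the noncanary pool.
4.  Otherwise a compositional homogeneity test is run on the checking
    dataset; heterogeneous sequences join the noncanary pool irrespective
    of placement. A homogeneous sequence whose position differs between
    checking and full tree is a CANARY (unstable but harmless); one whose
    position agrees is STABLE.
5.  If any canaries exist, they are added to the base alignment to form the
    canary dataset and its canary tree; stable sequences are relabeled into
    the noncanary pool.
6.  Each noncanary sequence is added, alone, to the canary dataset; if the
    resulting canary-checking tree is isomorphic to the canary tree after
    its removal it is NONPROBLEMATIC, otherwise POTENTIALLY_PROBLEMATIC
    (it perturbs the canaries and is excluded).
7.  The minimal dataset is base + canaries + nonproblematic sequences; its
    tree is the minimal tree, the final product.
8.  If no canaries were found, the minimal dataset is instead base + stable
    sequences.

All trees, verdicts and seeds are recorded so a run can be reproduced
byte-for-byte from its configuration echo.
"""

from __future__ import annotations

import enum
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from canaryseq.composition import CompTestEntry, ppred_comp_test
from canaryseq.errors import AlignmentError
from canaryseq.inference import EngineConfig, infer_tree
from canaryseq.seqs import (
    Alignment,
    DatasetRole,
    SequenceRecord,
    partition_roles,
    write_alignment,
)
from canaryseq.simulate import derive_seed
from canaryseq.treeops import (
    Tree,
    prune_leaves,
    rf_distance,
    same_placement,
    write_newick,
)

logger = logging.getLogger("canaryseq.pipeline")

__all__ = [
    "InterestLabel",
    "SequenceVerdict",
    "CanaryRunResult",
    "PipelineConfig",
    "build_checking_dataset",
    "classify_interest_sequence",
    "run_canary",
    "write_report",
]


class InterestLabel(enum.Enum):
    CANARY = "canary"
    STABLE = "stable"
    NONCANARY = "noncanary"
    POTENTIALLY_PROBLEMATIC = "potentially_problematic"
    NONPROBLEMATIC = "nonproblematic"


#: Terminal label sets for a completed run, by whether canaries were found.
TERMINAL_WITH_CANARIES = {
    InterestLabel.CANARY,
    InterestLabel.POTENTIALLY_PROBLEMATIC,
    InterestLabel.NONPROBLEMATIC,
}
TERMINAL_WITHOUT_CANARIES = {InterestLabel.STABLE, InterestLabel.NONCANARY}


@dataclass(frozen=True)
class SequenceVerdict:
    """Final label of one interest sequence with its recorded evidence."""

    id: str
    label: InterestLabel
    checking_isomorphic_to_base: bool
    comp_p: float | None = None
    placement_matches_full: bool | None = None
    canary_checking_isomorphic: bool | None = None


@dataclass(frozen=True)
class PipelineConfig:
    """Full configuration of a canary pipeline run."""

    interest_ids: tuple[str, ...]
    engine: EngineConfig = field(default_factory=EngineConfig)
    comp_n_sims: int = 99
    comp_seed: int = 0
    comp_alpha: float = 0.05
    recompute_full: bool = False
    base_tree: Tree | None = None
    full_tree: Tree | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "interest_ids", tuple(self.interest_ids))
        if not self.interest_ids:
            raise ValueError("at least one sequence of interest is required")

    def with_comp_seed(self, seed: int) -> "PipelineConfig":
        return replace(self, comp_seed=int(seed))

    def echo(self) -> dict:
        """JSON-serializable record sufficient to reproduce the run."""
        model = self.engine.model
        return {
            "interest_ids": list(self.interest_ids),
            "engine": {
                "engine": self.engine.engine,
                "model": {
                    "kind": model.kind,
                    "state_freqs": list(model.state_freqs),
                    "exchangeabilities": list(model.exchangeabilities),
                    "gamma_shape": model.gamma_shape,
                    "n_rate_categories": model.n_rate_categories,
                },
                "nni_max_rounds": self.engine.nni_max_rounds,
                "seed": self.engine.seed,
                "external_command_template":
                    self.engine.external_command_template,
                "saturation_ceiling": self.engine.saturation_ceiling,
                "brlen_tol": self.engine.brlen_tol,
                "brlen_max_sweeps": self.engine.brlen_max_sweeps,
            },
            "comp": {
                "n_sims": self.comp_n_sims,
                "seed": self.comp_seed,
                "alpha": self.comp_alpha,
            },
            "recompute_full": self.recompute_full,
        }


@dataclass(frozen=True)
class CanaryRunResult:
    """Everything a completed pipeline run produced."""

    verdicts: tuple[SequenceVerdict, ...]
    base_tree: Tree
    full_tree: Tree
    canary_tree: Tree | None
    minimal_tree: Tree
    checking_trees: dict[str, Tree]
    canary_checking_trees: dict[str, Tree]
    base_alignment: Alignment
    minimal_alignment: Alignment
    config_echo: dict

    @property
    def labels(self) -> dict[str, InterestLabel]:
        return {v.id: v.label for v in self.verdicts}

    def ids_with(self, label: InterestLabel) -> list[str]:
        return [v.id for v in self.verdicts if v.label is label]


def build_checking_dataset(base: Alignment, record: SequenceRecord) -> Alignment:
    """Base alignment plus one interest sequence, appended last."""
    if record.id in base:
        raise AlignmentError(
            f"interest sequence {record.id!r} collides with a base id"
        )
    return Alignment(base.records + (record,), role=DatasetRole.CHECKING)


def classify_interest_sequence(
    base_tree: Tree,
    full_tree: Tree,
    checking_tree: Tree,
    comp: CompTestEntry | None,
    focal: str,
) -> InterestLabel:
    """Classification rules for one interest sequence.

    In order: (1) if the checking tree minus the focal leaf is not
    isomorphic to the base tree, NONCANARY; (2) if the composition test
    finds the sequence heterogeneous, NONCANARY irrespective of placement;
    (3) if its placement differs between checking and full tree, CANARY;
    (4) otherwise STABLE. A sequence failing rule 1 needs no composition
    entry; one passing it does.
    """
    pruned = prune_leaves(checking_tree, {focal})
    if rf_distance(pruned, base_tree) > 0:
        return InterestLabel.NONCANARY
    if comp is None:
        raise ValueError(
            f"sequence {focal!r} passed the isomorphism check but has no "
            "composition-test entry"
        )
    if not comp.homogeneous:
        return InterestLabel.NONCANARY
    if not same_placement(checking_tree, full_tree, focal):
        return InterestLabel.CANARY
    return InterestLabel.STABLE


def run_canary(full_aln: Alignment, config: PipelineConfig) -> CanaryRunResult:
    """Execute the complete canary pipeline on *full_aln*.

    Deterministic: identical alignment, configuration and seeds yield
    identical verdicts and trees.
    """
    engine = config.engine
    logger.info("step 1: partitioning full dataset and inferring base/full trees")
    base_aln, interest_records = partition_roles(full_aln, config.interest_ids)
    full_aln = full_aln.with_role(DatasetRole.FULL)

    base_tree = config.base_tree
    if base_tree is None or config.recompute_full:
        base_tree = infer_tree(base_aln, engine)
    full_tree = config.full_tree
    if full_tree is None or config.recompute_full:
        full_tree = infer_tree(full_aln, engine)

    verdict_draft: dict[str, dict] = {}
    checking_trees: dict[str, Tree] = {}
    logger.info(
        "step 2: building %d checking datasets and trees", len(interest_records)
    )
    for idx, record in enumerate(interest_records):
        checking_aln = build_checking_dataset(base_aln, record)
        checking_tree = infer_tree(checking_aln, engine)
        checking_trees[record.id] = checking_tree
        logger.info("step 3: isomorphism check for %s", record.id)
        pruned = prune_leaves(checking_tree, {record.id})
        iso = rf_distance(pruned, base_tree) == 0
        entry: CompTestEntry | None = None
        if iso:
            logger.info("step 4: composition test and placement for %s", record.id)
            comp_result = ppred_comp_test(
                checking_aln,
                checking_tree,
                engine.model,
                n_sims=config.comp_n_sims,
                seed=derive_seed(config.comp_seed, idx),
                alpha=config.comp_alpha,
            )
            entry = comp_result[record.id]
        label = classify_interest_sequence(
            base_tree, full_tree, checking_tree, entry, record.id
        )
        verdict_draft[record.id] = {
            "checking_isomorphic_to_base": iso,
            "comp_p": entry.p_value if entry is not None else None,
            "placement_matches_full": (
                same_placement(checking_tree, full_tree, record.id)
                if iso and entry is not None and entry.homogeneous
                else None
            ),
            "label": label,
        }

    canary_ids = [
        r.id for r in interest_records
        if verdict_draft[r.id]["label"] is InterestLabel.CANARY
    ]

    canary_tree: Tree | None = None
    canary_checking_trees: dict[str, Tree] = {}

    if not canary_ids:
        logger.info("step 8: no canaries; minimal dataset = base + stable")
        stable_ids = [
            r.id for r in interest_records
            if verdict_draft[r.id]["label"] is InterestLabel.STABLE
        ]
        minimal_ids = set(base_aln.ids) | set(stable_ids)
        minimal_aln = full_aln.subset(minimal_ids, role=DatasetRole.MINIMAL)
        minimal_tree = infer_tree(minimal_aln, engine)
        verdicts = tuple(
            SequenceVerdict(
                id=r.id,
                label=verdict_draft[r.id]["label"],
                checking_isomorphic_to_base=
                    verdict_draft[r.id]["checking_isomorphic_to_base"],
                comp_p=verdict_draft[r.id]["comp_p"],
                placement_matches_full=
                    verdict_draft[r.id]["placement_matches_full"],
            )
            for r in interest_records
        )
        return CanaryRunResult(
            verdicts=verdicts,
            base_tree=base_tree,
            full_tree=full_tree,
            canary_tree=None,
            minimal_tree=minimal_tree,
            checking_trees=checking_trees,
            canary_checking_trees={},
            base_alignment=base_aln,
            minimal_alignment=minimal_aln,
            config_echo=config.echo(),
        )

    logger.info(
        "step 5: canary dataset = base + %d canaries; inferring canary tree",
        len(canary_ids),
    )
    # stable sequences join the noncanary pool once canaries exist
    noncanary_ids = [r.id for r in interest_records if r.id not in canary_ids]
    canary_aln = full_aln.subset(
        set(base_aln.ids) | set(canary_ids), role=DatasetRole.CANARY
    )
    canary_tree = infer_tree(canary_aln, engine)

    nonproblematic: list[str] = []
    for q in noncanary_ids:
        logger.info("step 6: canary-checking analysis for %s", q)
        cc_aln = Alignment(
            canary_aln.records + (full_aln[q],),
            role=DatasetRole.CANARY_CHECKING,
        )
        cc_tree = infer_tree(cc_aln, engine)
        canary_checking_trees[q] = cc_tree
        iso = rf_distance(prune_leaves(cc_tree, {q}), canary_tree) == 0
        verdict_draft[q]["canary_checking_isomorphic"] = iso
        if iso:
            nonproblematic.append(q)
            verdict_draft[q]["label"] = InterestLabel.NONPROBLEMATIC
        else:
            verdict_draft[q]["label"] = InterestLabel.POTENTIALLY_PROBLEMATIC

    logger.info(
        "step 7: minimal dataset = base + canaries + %d nonproblematic",
        len(nonproblematic),
    )
    minimal_ids = set(base_aln.ids) | set(canary_ids) | set(nonproblematic)
    minimal_aln = full_aln.subset(minimal_ids, role=DatasetRole.MINIMAL)
    minimal_tree = infer_tree(minimal_aln, engine)

    verdicts = tuple(
        SequenceVerdict(
            id=r.id,
            label=verdict_draft[r.id]["label"],
            checking_isomorphic_to_base=
                verdict_draft[r.id]["checking_isomorphic_to_base"],
            comp_p=verdict_draft[r.id]["comp_p"],
            placement_matches_full=
                verdict_draft[r.id]["placement_matches_full"],
            canary_checking_isomorphic=
                verdict_draft[r.id].get("canary_checking_isomorphic"),
        )
        for r in interest_records
    )
    return CanaryRunResult(
        verdicts=verdicts,
        base_tree=base_tree,
        full_tree=full_tree,
        canary_tree=canary_tree,
        minimal_tree=minimal_tree,
        checking_trees=checking_trees,
        canary_checking_trees=canary_checking_trees,
        base_alignment=base_aln,
        minimal_alignment=minimal_aln,
        config_echo=config.echo(),
    )


def _fmt(value) -> str:
    if value is None:
        return "n/a"
    if isinstance(value, bool):
        return str(value).lower()
    if isinstance(value, float):
        return f"{value:.6g}"
    return str(value)


def write_report(result: CanaryRunResult, outdir: str | Path) -> None:
    """Write the per-sequence TSV, all trees, the minimal FASTA and a summary.

    Output is deterministic: re-running an identical configuration
    reproduces every file byte for byte.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = [
        {
            "id": v.id,
            "label": v.label.value,
            "checking_isomorphic_to_base": _fmt(v.checking_isomorphic_to_base),
            "comp_p": _fmt(v.comp_p),
            "placement_matches_full": _fmt(v.placement_matches_full),
            "canary_checking_isomorphic": _fmt(v.canary_checking_isomorphic),
        }
        for v in result.verdicts
    ]
    pd.DataFrame(rows).to_csv(outdir / "verdicts.tsv", sep="\t", index=False)

    def dump_tree(name: str, tree: Tree) -> None:
        (outdir / f"{name}.nwk").write_text(write_newick(tree) + "\n")

    dump_tree("base", result.base_tree)
    dump_tree("full", result.full_tree)
    if result.canary_tree is not None:
        dump_tree("canary", result.canary_tree)
    dump_tree("minimal", result.minimal_tree)
    for seq_id, tree in sorted(result.checking_trees.items()):
        dump_tree(f"checking_{seq_id}", tree)
    for seq_id, tree in sorted(result.canary_checking_trees.items()):
        dump_tree(f"canary_checking_{seq_id}", tree)

    write_alignment(result.minimal_alignment, outdir / "minimal.fasta")

    counts = {
        label.value: sum(1 for v in result.verdicts if v.label is label)
        for label in InterestLabel
    }
    summary = {
        "config": result.config_echo,
        "label_counts": counts,
        "n_interest": len(result.verdicts),
        "n_base": len(result.base_alignment),
        "n_minimal": len(result.minimal_alignment),
    }
    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
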