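"""Parametric-bootstrap test of per-sequence compositional homogeneity.

Inaccurate gene trees can arise from compositional heterogeneity: a
sequence whose state frequencies deviate from the rest of the alignment
violates the stationarity assumption of the usual reversible models. The
screen implemented here is the plug-in predictive analogue of the
posterior-predictive composition checks used in Bayesian practice:
alignments are simulated on the fitted tree and model, and each observed
sequence's deviation from the pooled composition is compared against the
null distribution of the same statistic for the matching taxon in the
simulated alignments.

The statistic is the L1 deviation sum_s |f_seq(s) - f_pooled(s)|, bounded
by 2 and insensitive to alignment length differences between sequences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from canaryseq.errors import AlignmentError, TreeError
from canaryseq.models import SubstitutionModel
from canaryseq.seqs import Alignment, CONCRETE_STATES, SequenceRecord
from canaryseq.treeops import Tree

__all__ = [
    "CompTestEntry",
    "CompTestResult",
    "composition_vector",
    "comp_deviation",
    "pooled_composition",
    "ppred_comp_test",
]


@dataclass(frozen=True)
class CompTestEntry:
    """Per-sequence outcome of the composition test."""

    observed_stat: float
    null_stats: tuple[float, ...]
    p_value: float
    homogeneous: bool


@dataclass(frozen=True)
class CompTestResult:
    """Composition-test outcomes keyed by sequence id."""

    entries: dict[str, CompTestEntry]
    n_sims: int
    alpha: float
    seed: int

    def __getitem__(self, seq_id: str) -> CompTestEntry:
        return self.entries[seq_id]

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self.entries


def _counts(residues: str, concrete: str) -> np.ndarray:
    counts = np.zeros(len(concrete))
    for i, ch in enumerate(concrete):
        counts[i] = residues.count(ch)
    return counts


def composition_vector(record: SequenceRecord) -> np.ndarray:
    """State frequencies of a sequence, gaps and ambiguities excluded."""
    concrete = CONCRETE_STATES[record.alphabet]
    counts = _counts(record.residues, concrete)
    total = counts.sum()
    if total == 0:
        raise AlignmentError(
            f"sequence {record.id!r} has no unambiguous residues"
        )
    return counts / total


def pooled_composition(aln: Alignment) -> np.ndarray:
    """State frequencies pooled over every sequence in the alignment."""
    concrete = CONCRETE_STATES[aln.alphabet]
    counts = np.zeros(len(concrete))
    for rec in aln.records:
        counts += _counts(rec.residues, concrete)
    total = counts.sum()
    if total == 0:
        raise AlignmentError("alignment has no unambiguous residues")
    return counts / total


def comp_deviation(record: SequenceRecord, pooled: np.ndarray) -> float:
    """L1 deviation of a sequence's composition from the pooled composition."""
    return float(np.abs(composition_vector(record) - pooled).sum())


def _missing_masks(aln: Alignment) -> dict[str, np.ndarray]:
    """Boolean mask of non-concrete (gap/ambiguity) positions per sequence."""
    concrete = set(CONCRETE_STATES[aln.alphabet])
    return {
        rec.id: np.array([ch not in concrete for ch in rec.residues])
        for rec in aln.records
    }


def _apply_masks(sim: Alignment, masks: dict[str, np.ndarray]) -> Alignment:
    """Impose the observed missing-data pattern on a simulated alignment.

    Null statistics must reflect the site counts actually available to each
    observed sequence, so simulated residues at observed-missing positions
    are masked out before computing compositions.
    """
    records = []
    for rec in sim.records:
        mask = masks[rec.id]
        if mask.any():
            residues = np.array(list(rec.residues))
            residues[mask] = "-"
            rec = SequenceRecord(rec.id, "".join(residues), rec.alphabet)
        records.append(rec)
    return Alignment(tuple(records))


def ppred_comp_test(
    aln: Alignment,
    tree: Tree,
    model: SubstitutionModel,
    n_sims: int = 99,
    seed: int = 0,
    alpha: float = 0.05,
) -> CompTestResult:
    """Parametric-bootstrap compositional homogeneity test, per sequence.

    ``n_sims`` alignments are simulated on the fitted (tree, model); the
    Monte-Carlo p-value for sequence i is
    ``(1 + #{null >= observed}) / (1 + n_sims)`` with the null statistics
    taken from the matching taxon in each simulated alignment. A sequence is
    homogeneous iff its p-value is at least ``alpha``. Deterministic for a
    fixed seed; requires ``n_sims >= 19`` so alpha = 0.05 is reachable.
    """
    if n_sims < 19:
        raise ValueError(
            f"n_sims={n_sims} cannot resolve alpha=0.05; need >= 19"
        )
    if tree.leaf_set != set(aln.ids):
        raise TreeError("composition test: tree and alignment ids differ")
    from canaryseq.simulate import simulate_alignment  # deferred: cyclic module pair

    pooled = pooled_composition(aln)
    observed = {rec.id: comp_deviation(rec, pooled) for rec in aln.records}
    null: dict[str, list[float]] = {seq_id: [] for seq_id in aln.ids}
    sim_seeds = np.random.SeedSequence(seed).generate_state(n_sims) % (2**31)
    masks = _missing_masks(aln)
    for k in range(n_sims):
        sim = simulate_alignment(tree, model, aln.ncols, int(sim_seeds[k]))
        sim = _apply_masks(sim, masks)
        sim_pooled = pooled_composition(sim)
        for rec in sim.records:
            null[rec.id].append(comp_deviation(rec, sim_pooled))
    entries: dict[str, CompTestEntry] = {}
    for seq_id in aln.ids:
        obs = observed[seq_id]
        exceed = sum(1 for s in null[seq_id] if s >= obs)
        p = (1 + exceed) / (1 + n_sims)
        entries[seq_id] = CompTestEntry(
            observed_stat=obs,
            null_stats=tuple(null[seq_id]),
            p_value=p,
            homogeneous=p >= alpha,
        )
    return CompTestResult(entries=entries, n_sims=n_sims, alpha=alpha, seed=seed)
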