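"""Engineered test fixtures with known expected verdicts.

Each scenario constructs an alignment whose interest sequences are built,
by construction, to land in a particular verdict class:

* ``clean`` — every interest sequence is simulated on the generating tree
  with full-length signal; nothing should be flagged (all STABLE, no-canary
  branch of the pipeline).
* ``canary_lba`` — a weak "canary" sequence and an attracting "problematic"
  sequence. The canary evolves normally and is then signal-eroded by
  masking most of its sites to missing data, leaving too little signal to
  resolve its position firmly. The problematic sequence is a fast-evolving,
  compositionally biased sequence that additionally shares a copied stretch
  of the canary's surviving sites — the signature of contamination or
  partial chimerism. In the full alignment it therefore captures the weak
  canary into a cherry and drags it away from its true clade, while its
  biased composition marks it for the compositional screen. Analysis under
  JC69 of data simulated under GTR+Gamma reproduces the
  model-misspecification regime in which such attraction artifacts thrive.
* ``saturated`` — two pure-noise sequences drawn i.i.d. from the model's
  stationary frequencies; they carry no signal at all and are expected to
  behave as canaries.
* ``no_canary`` — two interest sequences evolved at their true positions
  but with strongly biased (GC-swapped) composition. The compositional
  screen routes such sequences to the noncanary pool irrespective of their
  placement, so the run finishes with no canaries and the minimal dataset
  collapses to the base dataset (the pipeline's no-canary branch).

Expected labels encode the construction intent; end-to-end tests verify
that the pipeline reproduces them for the scenarios whose outcome is
deterministic enough to assert.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from canaryseq.models import SubstitutionModel
from canaryseq.seqs import Alignment, CONCRETE_STATES, SequenceRecord
from canaryseq.simulate import (
    derive_seed,
    elongate_terminal_branches,
    simulate_alignment,
)
from canaryseq.treeops import Tree, parse_newick

__all__ = ["FixtureSpec", "generate_fixture", "target_backbone", "fixture_model"]

SCENARIOS = ("clean", "canary_lba", "saturated", "no_canary")

#: Generating-tree branch lengths (substitutions/site).
_PENDANT = 0.08
_INTERNAL = 0.05
_CENTRAL = 0.08

#: canary_lba construction: fraction of canary sites masked to missing,
#: problematic-sequence pendant elongation, extra branch length evolved
#: under swapped (GC-rich) frequencies to bias its composition, and the
#: fraction of the canary's surviving sites copied into it (the
#: contamination-style attraction glue).
_ERODE_FRACTION = 0.85
_LBA_FACTOR = 2.0
_SKEW_BRANCH = 0.25
_COPY_FRACTION = 0.85

CANARY_ID = "CNRY"
LBA_ID = "LBAX"
SATURATED_IDS = ("SAT1", "SAT2")
HETEROGENEOUS_IDS = (CANARY_ID, LBA_ID)


@dataclass(frozen=True)
class FixtureSpec:
    """A reproducible fixture: scenario, size and seed fully determine it."""

    scenario: str
    n_taxa: int = 12
    seq_length: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(
                f"unknown scenario {self.scenario!r}; choose from {SCENARIOS}"
            )
        minimum = 8 if self.scenario == "canary_lba" else 6
        if self.n_taxa < minimum:
            raise ValueError(
                f"scenario {self.scenario!r} needs at least {minimum} taxa"
            )
        if self.seq_length < 100:
            raise ValueError("fixtures need at least 100 sites")


def fixture_model() -> SubstitutionModel:
    """The generating model: GTR with skewed frequencies, transition bias
    and gamma rate variation — data that JC69 analysis mis-specifies."""
    return SubstitutionModel.gtr(
        state_freqs=(0.35, 0.15, 0.15, 0.35),
        exchangeabilities=(1.0, 4.0, 1.0, 1.0, 4.0, 1.0),
        gamma_shape=0.5,
        n_rate_categories=4,
    )


def _skew_model() -> SubstitutionModel:
    """Same process with swapped (GC-rich) stationary frequencies."""
    return SubstitutionModel.gtr(
        state_freqs=(0.15, 0.35, 0.35, 0.15),
        exchangeabilities=(1.0, 4.0, 1.0, 1.0, 4.0, 1.0),
        gamma_shape=0.5,
        n_rate_categories=4,
    )


def _caterpillar(members: list[str]) -> str:
    inner = f"({members[0]}:{_PENDANT},{members[1]}:{_PENDANT})"
    for member in members[2:]:
        inner = f"({inner}:{_INTERNAL},{member}:{_PENDANT})"
    return inner


def _base_names(n_base: int) -> list[str]:
    return [f"B{i:02d}" for i in range(1, n_base + 1)]


def _truth_tree(n_taxa: int, with_interest: bool) -> Tree:
    """Two caterpillar clades joined by a central edge.

    With interest leaves, the canary's true position is the innermost
    cherry of clade 1 (maximally far from the central edge) and the
    problematic sequence attaches to clade 2 adjacent to the central edge.
    """
    n_base = n_taxa - 2 if with_interest else n_taxa
    names = _base_names(n_base)
    half = (n_base + 1) // 2
    clade1, clade2 = names[:half], names[half:]
    if with_interest:
        clade1 = [CANARY_ID] + clade1
        clade2 = clade2 + [LBA_ID]
    newick = (
        f"({_caterpillar(clade1)}:{_CENTRAL},{_caterpillar(clade2)});"
    )
    return parse_newick(newick)


def target_backbone(spec: FixtureSpec) -> frozenset[str]:
    """The generating backbone clade whose recovery scores a tree as correct.

    For the LBA scenario this is clade 1 including the canary's true
    position — exactly the grouping the attraction artifact destroys in the
    full tree.
    """
    n_base = spec.n_taxa - 2
    half = (n_base + 1) // 2
    clade = set(_base_names(n_base)[:half])
    if spec.scenario in ("clean", "canary_lba"):
        clade.add(CANARY_ID)
    return frozenset(clade)


def _states_of(record: SequenceRecord) -> np.ndarray:
    concrete = CONCRETE_STATES[record.alphabet]
    idx = {ch: i for i, ch in enumerate(concrete)}
    return np.array([idx[ch] for ch in record.residues])


def _evolve(states: np.ndarray, model: SubstitutionModel, t: float,
            rng: np.random.Generator) -> np.ndarray:
    """One further branch of evolution applied to a state vector."""
    p = np.cumsum(model.transition_matrix(t), axis=1)
    u = rng.random(len(states))
    out = (u[:, None] > p[states]).sum(axis=1)
    return np.minimum(out, model.n_states - 1)


def _random_sequence(
    seq_id: str, length: int, model: SubstitutionModel, rng: np.random.Generator
) -> SequenceRecord:
    chars = np.array(list(CONCRETE_STATES[model.alphabet]))
    states = rng.choice(model.n_states, size=length, p=model.freqs)
    return SequenceRecord(seq_id, "".join(chars[states]), model.alphabet)


def _build_canary_lba(
    spec: FixtureSpec, model: SubstitutionModel, rng: np.random.Generator,
    sim_seed: int,
) -> tuple[Alignment, Tree]:
    tree = _truth_tree(spec.n_taxa, with_interest=True)
    tree = elongate_terminal_branches(tree, {LBA_ID: _LBA_FACTOR})
    aln = simulate_alignment(tree, model, spec.seq_length, sim_seed)
    chars = np.array(list(CONCRETE_STATES[model.alphabet]))
    length = spec.seq_length

    # bias the problematic sequence's composition along an extra segment
    lba_states = _evolve(_states_of(aln[LBA_ID]), _skew_model(),
                         _SKEW_BRANCH, rng)

    # erode the canary: mask most sites to missing data
    canary = np.array(list(aln[CANARY_ID].residues))
    masked = rng.choice(length, size=int(round(_ERODE_FRACTION * length)),
                        replace=False)
    visible = np.setdiff1d(np.arange(length), masked)
    canary_masked = canary.copy()
    canary_masked[masked] = "-"

    # contamination glue: copy most of the canary's surviving sites into
    # the problematic sequence so it captures the weak canary
    n_copy = int(round(_COPY_FRACTION * len(visible)))
    copy_sites = rng.choice(visible, size=n_copy, replace=False)
    lba_residues = chars[lba_states]
    lba_residues[copy_sites] = canary[copy_sites]

    records = []
    for rec in aln.records:
        if rec.id == CANARY_ID:
            records.append(
                SequenceRecord(CANARY_ID, "".join(canary_masked), rec.alphabet)
            )
        elif rec.id == LBA_ID:
            records.append(
                SequenceRecord(LBA_ID, "".join(lba_residues), rec.alphabet)
            )
        else:
            records.append(rec)
    return Alignment(tuple(records)), tree


def generate_fixture(
    spec: FixtureSpec,
) -> tuple[Alignment, tuple[str, ...], dict[str, str], Tree]:
    """Build the fixture alignment for *spec*.

    Returns ``(alignment, interest_ids, expected, truth_tree)`` where
    ``expected`` maps each interest id to the verdict label its
    construction is designed to produce and ``truth_tree`` is the
    generating tree actually used (elongation included). Identical specs
    yield identical fixtures.
    """
    model = fixture_model()
    rng = np.random.default_rng(derive_seed(spec.seed, 99))
    sim_seed = derive_seed(spec.seed, 0)

    if spec.scenario == "canary_lba":
        aln, tree = _build_canary_lba(spec, model, rng, sim_seed)
        expected = {
            CANARY_ID: "canary",
            LBA_ID: "potentially_problematic",
        }
        return aln, (CANARY_ID, LBA_ID), expected, tree

    if spec.scenario == "clean":
        tree = _truth_tree(spec.n_taxa, with_interest=True)
        aln = simulate_alignment(tree, model, spec.seq_length, sim_seed)
        expected = {CANARY_ID: "stable", LBA_ID: "stable"}
        return aln, (CANARY_ID, LBA_ID), expected, tree

    if spec.scenario == "no_canary":
        tree = _truth_tree(spec.n_taxa, with_interest=True)
        aln = simulate_alignment(tree, model, spec.seq_length, sim_seed)
        records = []
        for rec in aln.records:
            if rec.id in HETEROGENEOUS_IDS:
                chars = np.array(list(CONCRETE_STATES[model.alphabet]))
                states = _evolve(_states_of(rec), _skew_model(),
                                 _SKEW_BRANCH + 0.1, rng)
                rec = SequenceRecord(rec.id, "".join(chars[states]),
                                     rec.alphabet)
            records.append(rec)
        expected = {seq_id: "noncanary" for seq_id in HETEROGENEOUS_IDS}
        return Alignment(tuple(records)), HETEROGENEOUS_IDS, expected, tree

    base_tree = _truth_tree(spec.n_taxa - 2, with_interest=False)
    base_aln = simulate_alignment(base_tree, model, spec.seq_length, sim_seed)
    extras = [
        _random_sequence(seq_id, spec.seq_length, model, rng)
        for seq_id in SATURATED_IDS
    ]
    expected = {seq_id: "canary" for seq_id in SATURATED_IDS}
    aln = Alignment(base_aln.records + tuple(extras))
    return aln, SATURATED_IDS, expected, base_tree
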