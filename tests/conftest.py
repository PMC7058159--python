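"""Shared fixtures: models, engine configs, and cached pipeline runs."""

from __future__ import annotations

import pytest

from canaryseq.fixtures import FixtureSpec, generate_fixture
from canaryseq.inference import EngineConfig
from canaryseq.models import SubstitutionModel
from canaryseq.pipeline import PipelineConfig, run_canary
from canaryseq.treeops import Tree, parse_newick


@pytest.fixture(scope="session")
def jc69():
    return SubstitutionModel.jc69()


@pytest.fixture(scope="session")
def engine(jc69):
    return EngineConfig(model=jc69)


def random_tree(labels, rng, min_len=0.05, max_len=0.5) -> Tree:
    """A random binary unrooted tree with uniform branch lengths."""
    def blen() -> str:
        return f"{rng.uniform(min_len, max_len):.6f}"

    clusters = [f"{label}:{blen()}" for label in labels]
    while len(clusters) > 3:
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        b = clusters.pop(j)
        a = clusters.pop(i)
        clusters.append(f"({a},{b}):{blen()}")
    return parse_newick("(" + ",".join(clusters) + ");")


def path_lengths(tree: Tree) -> dict[tuple[str, str], float]:
    """Leaf-to-leaf path lengths by traversal (independent of NJ)."""
    out: dict[tuple[str, str], float] = {}
    for label in sorted(tree.leaf_set):
        start = tree.node_of(label)
        dist = {start: 0.0}
        stack = [start]
        while stack:
            u = stack.pop()
            for v, length in tree.adj[u].items():
                if v not in dist:
                    dist[v] = dist[u] + (length or 0.0)
                    stack.append(v)
        for other in sorted(tree.leaf_set):
            if other != label:
                out[(label, other)] = dist[tree.node_of(other)]
    return out


# Pipeline runs are expensive; run each fixture scenario once per session
# and share the result across the tests that examine it.

_SCENARIO_SETTINGS = {
    "clean": dict(n_taxa=10, seq_length=500, seed=0),
    "canary_lba": dict(n_taxa=12, seq_length=1000, seed=0),
    "saturated": dict(n_taxa=12, seq_length=1000, seed=0),
    "no_canary": dict(n_taxa=10, seq_length=500, seed=0),
}


@pytest.fixture(scope="session")
def scenario_runs(jc69):
    runs = {}
    for scenario, kwargs in _SCENARIO_SETTINGS.items():
        spec = FixtureSpec(scenario=scenario, **kwargs)
        aln, interest, expected, truth = generate_fixture(spec)
        config = PipelineConfig(
            interest_ids=interest,
            engine=EngineConfig(model=jc69),
            comp_seed=spec.seed,
        )
        result = run_canary(aln, config)
        runs[scenario] = dict(
            spec=spec, alignment=aln, interest=interest,
            expected=expected, truth=truth, config=config, result=result,
        )
    return runs
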