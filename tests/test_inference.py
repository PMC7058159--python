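"""Distances, neighbor joining, likelihood, branch optimization, NNI search.

The two-taxon likelihood checks use a three-leaf star whose third sequence
is entirely missing data: an all-gap leaf marginalizes to a constant
factor of one, so the star's likelihood equals the two-taxon closed form
with the two pendant lengths summed.
"""

import numpy as np
import pytest

from canaryseq.errors import AlignmentError, EngineError, SaturationError, TreeError
from canaryseq.inference import (
    DistanceMatrix,
    EngineConfig,
    distance_matrix,
    enumerate_topologies,
    infer_tree,
    jc69_distance,
    log_likelihood,
    nj,
    nni_search,
    optimize_branch_lengths,
    poisson_distance,
)
from canaryseq.models import SubstitutionModel
from canaryseq.seqs import make_alignment
from canaryseq.simulate import simulate_alignment
from canaryseq.treeops import parse_newick, rf_distance, write_newick

from conftest import path_lengths, random_tree


def two_taxon_loglik_jc(seqs: tuple[str, str], t: float) -> float:
    """Independent closed-form JC69 likelihood for two sequences."""
    same = 0.25 + 0.75 * np.exp(-4.0 * t / 3.0)
    diff = 0.25 - 0.25 * np.exp(-4.0 * t / 3.0)
    out = 0.0
    for a, b in zip(*seqs):
        out += np.log(0.25 * (same if a == b else diff))
    return out


def star_with_gap_leaf(seqs: tuple[str, str], t: float):
    tree = parse_newick(f"(A:{t / 2},B:{t / 2},C:0.0);")
    aln = make_alignment([("A", seqs[0]), ("B", seqs[1]), ("C", "-" * len(seqs[0]))])
    return tree, aln


class TestDistances:
    def test_jc69_zero(self):
        assert jc69_distance(0.0) == 0.0

    def test_jc69_worked_value(self):
        assert jc69_distance(0.3) == pytest.approx(0.38312, abs=1e-5)

    def test_jc69_monotone(self):
        ps = np.linspace(0, 0.7, 30)
        ds = [jc69_distance(p) for p in ps]
        assert all(b > a for a, b in zip(ds, ds[1:]))

    @pytest.mark.parametrize("p", [0.75, 0.9, -0.1])
    def test_jc69_domain(self, p):
        with pytest.raises(SaturationError):
            jc69_distance(p)

    def test_poisson_correction(self):
        assert poisson_distance(0.5) == pytest.approx(np.log(2.0))
        with pytest.raises(SaturationError):
            poisson_distance(0.96)

    def test_matrix_worked_value(self, jc69):
        aln = make_alignment([("A", "ACGT"), ("B", "ACGA")])
        dm = distance_matrix(aln, jc69)
        assert dm.d[0, 1] == pytest.approx(0.30409, abs=1e-5)
        assert dm.d[0, 0] == 0.0

    def test_matrix_ignores_missing_sites(self, jc69):
        aln = make_alignment([("A", "ACGTNN"), ("B", "AC--GA")])
        dm = distance_matrix(aln, jc69)
        # comparable sites: positions 1,2 -> identical
        assert dm.d[0, 1] == 0.0

    def test_matrix_zero_comparable_sites(self, jc69):
        aln = make_alignment([("A", "AC--"), ("B", "--GT")])
        with pytest.raises(AlignmentError, match="A.*B"):
            distance_matrix(aln, jc69)

    def test_saturated_pair_gets_ceiling(self, jc69, caplog):
        aln = make_alignment([("A", "ACGTACGTACGT"), ("B", "CATCCATCCATC")])
        with caplog.at_level("WARNING", logger="canaryseq.inference"):
            dm = distance_matrix(aln, jc69, saturation_ceiling=5.0)
        assert dm.d[0, 1] == 5.0
        assert any("saturated" in rec.message for rec in caplog.records)

    def test_matrix_symmetric_on_random_data(self, jc69):
        rng = np.random.default_rng(0)
        tree = random_tree([f"t{i}" for i in range(6)], rng)
        aln = simulate_alignment(tree, jc69, 200, seed=4)
        dm = distance_matrix(aln, jc69)
        assert np.allclose(dm.d, dm.d.T)

    def test_distance_matrix_type_validation(self):
        with pytest.raises(ValueError):
            DistanceMatrix(("a", "b"), np.array([[0.0, 1.0], [2.0, 0.0]]))


class TestNJ:
    def test_three_taxa(self):
        dm = DistanceMatrix(
            ("A", "B", "C"),
            np.array([[0, 2, 3], [2, 0, 3], [3, 3, 0]], dtype=float),
        )
        t = nj(dm)
        assert t.leaf_set == {"A", "B", "C"}
        assert t.splits() == frozenset()

    def test_additive_four_taxa(self):
        ids = ("A", "B", "C", "D")
        d = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float
        )
        t = nj(DistanceMatrix(ids, d))
        assert t.splits() == frozenset({frozenset({"C", "D"})})

    def test_recovers_random_additive_matrices(self):
        rng = np.random.default_rng(123)
        for _ in range(20):
            n = int(rng.integers(6, 11))
            labels = [f"t{i}" for i in range(n)]
            truth = random_tree(labels, rng)
            paths = path_lengths(truth)
            d = np.zeros((n, n))
            for i, a in enumerate(labels):
                for j, b in enumerate(labels):
                    if i != j:
                        d[i, j] = paths[(a, b)]
            rec = nj(DistanceMatrix(tuple(labels), d))
            assert rf_distance(rec, truth) == 0

    def test_matches_skbio_on_additive_matrix(self):
        import skbio

        rng = np.random.default_rng(77)
        labels = [f"t{i}" for i in range(7)]
        truth = random_tree(labels, rng)
        paths = path_lengths(truth)
        d = np.zeros((7, 7))
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i != j:
                    d[i, j] = paths[(a, b)]
        d = (d + d.T) / 2.0  # exact symmetry (addition order differs by direction)
        ours = nj(DistanceMatrix(tuple(labels), d))
        skb = skbio.tree.nj(skbio.DistanceMatrix(d, ids=labels))
        theirs = parse_newick(str(skb).strip())
        assert rf_distance(ours, theirs) == 0

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            nj(DistanceMatrix(("a", "b"), np.zeros((2, 2))))


class TestLikelihood:
    def test_identical_sequences_at_zero_distance(self, jc69):
        tree, aln = star_with_gap_leaf(("ACGT", "ACGT"), 2e-9)
        assert log_likelihood(tree, aln, jc69) == pytest.approx(
            4 * np.log(0.25), abs=1e-3
        )

    def test_worked_two_site_example(self, jc69):
        tree, aln = star_with_gap_leaf(("AC", "AG"), 0.1)
        assert log_likelihood(tree, aln, jc69) == pytest.approx(-6.3379, abs=1e-3)

    def test_closed_form_grid(self, jc69):
        rng = np.random.default_rng(8)
        for t in (0.01, 0.1, 0.4, 1.0, 2.5):
            seq1 = "".join(rng.choice(list("ACGT"), size=40))
            seq2 = "".join(rng.choice(list("ACGT"), size=40))
            tree, aln = star_with_gap_leaf((seq1, seq2), t)
            assert log_likelihood(tree, aln, jc69) == pytest.approx(
                two_taxon_loglik_jc((seq1, seq2), t), abs=1e-6
            )

    def test_gamma_limit_matches_homogeneous(self, jc69):
        tree = parse_newick("((A:0.2,B:0.1):0.15,(C:0.3,D:0.05):0.1);")
        aln = simulate_alignment(tree, jc69, 300, seed=5)
        plain = log_likelihood(tree, aln, jc69)
        limit = log_likelihood(
            tree, aln, SubstitutionModel.jc69(gamma_shape=1e6)
        )
        assert limit == pytest.approx(plain, abs=1e-3)

    def test_gamma_changes_likelihood(self, jc69):
        tree = parse_newick("((A:0.2,B:0.1):0.15,(C:0.3,D:0.05):0.1);")
        aln = simulate_alignment(tree, jc69, 300, seed=5)
        assert log_likelihood(
            tree, aln, SubstitutionModel.jc69(gamma_shape=0.3)
        ) != pytest.approx(log_likelihood(tree, aln, jc69), abs=1e-6)

    def test_leaf_mismatch_rejected(self, jc69):
        tree = parse_newick("(A:0.1,B:0.1,C:0.1);")
        aln = make_alignment([("A", "ACGT"), ("B", "ACGT"), ("X", "ACGT")])
        with pytest.raises(TreeError):
            log_likelihood(tree, aln, jc69)

    def test_missing_branch_lengths_rejected(self, jc69):
        tree = parse_newick("(A,B,C);")
        aln = make_alignment([("A", "ACGT"), ("B", "ACGT"), ("C", "ACGT")])
        with pytest.raises(TreeError):
            log_likelihood(tree, aln, jc69)


class TestOptimizeBranchLengths:
    def test_two_taxon_mle(self, jc69):
        tree, aln = star_with_gap_leaf(("ACGT", "ACGA"), 0.4)
        opt = optimize_branch_lengths(tree, aln, jc69, tol=1e-6)
        total = opt.pendant_length("A") + opt.pendant_length("B")
        assert total == pytest.approx(jc69_distance(0.25), abs=1e-3)

    def test_never_decreases_likelihood(self, jc69):
        rng = np.random.default_rng(14)
        tree = random_tree([f"t{i}" for i in range(6)], rng)
        aln = simulate_alignment(tree, jc69, 300, seed=3)
        before = log_likelihood(tree, aln, jc69)
        after_tree = optimize_branch_lengths(tree, aln, jc69)
        assert log_likelihood(after_tree, aln, jc69) >= before - 1e-9

    def test_optimum_is_fixed_point(self, jc69):
        tree = parse_newick("((A:0.2,B:0.1):0.1,(C:0.15,D:0.25):0.1);")
        aln = simulate_alignment(tree, jc69, 500, seed=9)
        once = optimize_branch_lengths(tree, aln, jc69, tol=1e-6)
        twice = optimize_branch_lengths(once, aln, jc69, tol=1e-6)
        l1 = log_likelihood(once, aln, jc69)
        l2 = log_likelihood(twice, aln, jc69)
        assert l2 == pytest.approx(l1, abs=1e-2)

    def test_recovers_perturbed_lengths(self, jc69):
        truth = parse_newick("((A:0.2,B:0.1):0.1,(C:0.15,D:0.25):0.1);")
        aln = simulate_alignment(truth, jc69, 2000, seed=10)
        optimal = optimize_branch_lengths(truth, aln, jc69, tol=1e-6)
        perturbed = optimal.copy()
        for u, v, length in perturbed.edges():
            perturbed.adj[u][v] = length * 2.7
            perturbed.adj[v][u] = length * 2.7
        recovered = optimize_branch_lengths(perturbed, aln, jc69, tol=1e-6)
        assert log_likelihood(recovered, aln, jc69) == pytest.approx(
            log_likelihood(optimal, aln, jc69), abs=0.05
        )


def exhaustive_best(aln, model, tol=1e-6):
    """Independent oracle: score every unrooted topology, return the best."""
    best = None
    for cand in enumerate_topologies(sorted(aln.ids)):
        opt = optimize_branch_lengths(cand, aln, model, tol=tol, max_sweeps=30)
        lnl = log_likelihood(opt, aln, model)
        if best is None or lnl > best[0] + 1e-9:
            best = (lnl, opt)
    return best


class TestNNISearch:
    @pytest.mark.parametrize("n_taxa", [4, 5])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_search(self, jc69, n_taxa, seed):
        rng = np.random.default_rng(100 + seed)
        truth = random_tree([f"t{i}" for i in range(n_taxa)], rng,
                            min_len=0.05, max_len=0.4)
        aln = simulate_alignment(truth, jc69, 400, seed=seed)
        dm = distance_matrix(aln, jc69)
        start = optimize_branch_lengths(nj(dm), aln, jc69)
        found = nni_search(start, aln, jc69)
        best_lnl, best_tree = exhaustive_best(aln, jc69)
        assert rf_distance(found, best_tree) == 0
        assert log_likelihood(found, aln, jc69) == pytest.approx(
            best_lnl, abs=0.05
        )

    def test_likelihood_never_decreases(self, jc69):
        rng = np.random.default_rng(21)
        truth = random_tree([f"t{i}" for i in range(7)], rng)
        aln = simulate_alignment(truth, jc69, 300, seed=2)
        start = optimize_branch_lengths(nj(distance_matrix(aln, jc69)), aln, jc69)
        start_lnl = log_likelihood(start, aln, jc69)
        found = nni_search(start, aln, jc69)
        assert log_likelihood(found, aln, jc69) >= start_lnl - 1e-6

    def test_strong_signal_keeps_true_topology(self, jc69):
        truth = parse_newick(
            "((A:0.1,B:0.1):0.2,(C:0.1,(D:0.1,E:0.1):0.2):0.2);"
        )
        aln = simulate_alignment(truth, jc69, 5000, seed=6)
        start = optimize_branch_lengths(truth, aln, jc69)
        found = nni_search(start, aln, jc69)
        assert rf_distance(found, truth) == 0


class TestInferTree:
    def test_simulation_recovery(self, jc69, engine):
        truth = parse_newick(
            "((A:0.1,B:0.1):0.08,(C:0.1,(D:0.1,E:0.1):0.08):0.08);"
        )
        aln = simulate_alignment(truth, jc69, 2000, seed=42)
        inferred = infer_tree(aln, engine)
        assert rf_distance(inferred, truth) == 0

    def test_deterministic(self, jc69, engine):
        truth = parse_newick("((A:0.2,B:0.1):0.1,(C:0.15,D:0.25):0.1);")
        aln = simulate_alignment(truth, jc69, 400, seed=1)
        t1 = infer_tree(aln, engine)
        t2 = infer_tree(aln, engine)
        assert write_newick(t1) == write_newick(t2)

    def test_three_taxon_alignment(self, jc69, engine):
        aln = make_alignment([("A", "ACGTACGT"), ("B", "ACGAACGA"), ("C", "AGGTAGGT")])
        tree = infer_tree(aln, engine)
        assert tree.leaf_set == {"A", "B", "C"}

    def test_gtr_engine_runs(self):
        gtr = SubstitutionModel.gtr(
            (0.35, 0.15, 0.15, 0.35), (1, 4, 1, 1, 4, 1)
        )
        truth = parse_newick("((A:0.2,B:0.1):0.15,(C:0.15,D:0.25):0.1);")
        aln = simulate_alignment(truth, gtr, 500, seed=11)
        tree = infer_tree(aln, EngineConfig(model=gtr))
        assert tree.leaf_set == truth.leaf_set

    def test_external_engine_stub(self, tmp_path, jc69):
        fixed = "((A:1.0,B:1.0):1.0,(C:1.0,D:1.0):1.0);"
        stub = tmp_path / "stub.py"
        stub.write_text(
            "import sys\n"
            f"open(sys.argv[2], 'w').write({fixed!r})\n"
        )
        config = EngineConfig(
            engine="external",
            model=jc69,
            external_command_template=(
                f"python {stub} {{alignment_phylip}} {{out_newick}}"
            ),
        )
        aln = make_alignment(
            [("A", "ACGT"), ("B", "ACGA"), ("C", "AGGT"), ("D", "AGGA")]
        )
        tree = infer_tree(aln, config)
        assert tree.splits() == frozenset({frozenset({"C", "D"})})

    def test_external_engine_failure_carries_diagnostics(self, tmp_path, jc69):
        config = EngineConfig(
            engine="external",
            model=jc69,
            external_command_template=(
                "python -c 'import sys; sys.exit(3)' "
                "{alignment_phylip} {out_newick}"
            ),
        )
        aln = make_alignment(
            [("A", "ACGT"), ("B", "ACGA"), ("C", "AGGT"), ("D", "AGGA")]
        )
        with pytest.raises(EngineError) as err:
            infer_tree(aln, config)
        assert err.value.command is not None

    def test_engine_config_validation(self, jc69):
        with pytest.raises(ValueError):
            EngineConfig(engine="external", model=jc69)
        with pytest.raises(ValueError):
            EngineConfig(engine="internal", model=jc69,
                         external_command_template="x {out_newick}")
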