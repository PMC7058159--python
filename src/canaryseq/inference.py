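"""Internal maximum-likelihood tree inference and the external-engine adapter.

The internal engine is deliberately desk-scale: JC69/GTR(+Gamma) for
nucleotides and Poisson/LG(+Gamma) for proteins, neighbor joining on
corrected distances for the starting tree, Felsenstein pruning for
likelihoods (with site-pattern compression and per-node rescaling),
per-branch Brent optimization, and hill-climbing NNI search. Every tie is
broken canonically so that identical input plus configuration yields a
byte-identical canonical Newick tree.

An external engine (e.g. PhyML or PhyloBayes wrappers) can be substituted
through a command template; the contract is "read a relaxed-PHYLIP
alignment, write one Newick tree, exit 0".
"""

from __future__ import annotations

import logging
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import minimize, minimize_scalar

from canaryseq.errors import AlignmentError, EngineError, SaturationError, TreeError
from canaryseq.models import SubstitutionModel
from canaryseq.seqs import Alignment, Alphabet, CONCRETE_STATES, state_sets
from canaryseq.treeops import Tree, parse_newick, write_newick
from canaryseq import seqs as _seqs

logger = logging.getLogger("canaryseq.inference")

__all__ = [
    "EngineConfig",
    "DistanceMatrix",
    "jc69_distance",
    "poisson_distance",
    "distance_matrix",
    "nj",
    "log_likelihood",
    "optimize_branch_lengths",
    "nni_search",
    "infer_tree",
    "enumerate_topologies",
]

#: Branch-length search interval (substitutions/site) for all optimizations.
_BL_MIN, _BL_MAX = 1e-9, 10.0


@dataclass(frozen=True)
class EngineConfig:
    """Configuration of a tree-inference engine.

    ``engine`` is "internal" or "external". The external command template
    must contain the placeholders ``{alignment_phylip}`` and
    ``{out_newick}``. ``saturation_ceiling`` replaces distances beyond the
    domain of the correction formula. ``brlen_tol`` is the log-likelihood
    improvement below which branch-length sweeps stop.
    """

    engine: str = "internal"
    model: SubstitutionModel = field(default_factory=SubstitutionModel.jc69)
    nni_max_rounds: int = 20
    seed: int = 0
    external_command_template: str | None = None
    saturation_ceiling: float = 5.0
    brlen_tol: float = 1e-3
    brlen_max_sweeps: int = 5
    estimate_gtr: bool = True

    def __post_init__(self) -> None:
        if self.engine not in ("internal", "external"):
            raise ValueError(f"unknown engine {self.engine!r}")
        if self.engine == "external" and not self.external_command_template:
            raise ValueError("external engine requires a command template")
        if self.engine == "internal" and self.external_command_template:
            raise ValueError("internal engine takes no external template")


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distances with a zero diagonal."""

    ids: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        object.__setattr__(self, "d", d)
        n = len(self.ids)
        if d.shape != (n, n):
            raise ValueError(f"distance matrix shape {d.shape} != ({n},{n})")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.abs(np.diag(d)) > 1e-12) or np.any(d < 0):
            raise ValueError("distances must be nonnegative with zero diagonal")


# ---------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------

def jc69_distance(p: float) -> float:
    """JC69 correction d = -(3/4) ln(1 - 4p/3) for 0 <= p < 0.75."""
    if not 0.0 <= p < 0.75:
        raise SaturationError(
            f"proportion of differing sites p={p} outside [0, 0.75)"
        )
    return -0.75 * np.log1p(-4.0 * p / 3.0)


def poisson_distance(p: float) -> float:
    """Poisson correction d = -ln(1 - p) for protein distances."""
    if not 0.0 <= p < 1.0 - 1.0 / 20.0:
        raise SaturationError(
            f"proportion of differing sites p={p} outside [0, 0.95)"
        )
    return -np.log1p(-p)


def _encode_concrete(aln: Alignment) -> np.ndarray:
    """(ntaxa, nsites) int codes; -1 for gaps/ambiguities (missing)."""
    concrete = CONCRETE_STATES[aln.alphabet]
    lut = np.full(128, -1, dtype=np.int8)
    for i, ch in enumerate(concrete):
        lut[ord(ch)] = i
    rows = [
        lut[np.frombuffer(rec.residues.encode(), dtype=np.uint8)]
        for rec in aln.records
    ]
    return np.vstack(rows)


def distance_matrix(
    aln: Alignment,
    model: SubstitutionModel,
    saturation_ceiling: float = 5.0,
) -> DistanceMatrix:
    """Pairwise corrected distances on jointly non-missing sites.

    Nucleotide models use the JC69 correction, protein models the Poisson
    correction. Saturated pairs are replaced by ``saturation_ceiling`` with
    a logged warning so that neighbor joining stays finite.
    """
    if len(aln) < 2:
        raise AlignmentError("distance matrix needs at least 2 sequences")
    codes = _encode_concrete(aln)
    n = len(aln)
    corr = jc69_distance if model.alphabet is Alphabet.NUCLEOTIDE else poisson_distance
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = (codes[i] >= 0) & (codes[j] >= 0)
            m = int(both.sum())
            if m == 0:
                raise AlignmentError(
                    f"sequences {aln.ids[i]!r} and {aln.ids[j]!r} share no "
                    "comparable sites"
                )
            p = float((codes[i][both] != codes[j][both]).sum()) / m
            try:
                dij = corr(p)
            except SaturationError:
                logger.warning(
                    "saturated pair (%s, %s): p=%.4f; substituting ceiling %.2f",
                    aln.ids[i], aln.ids[j], p, saturation_ceiling,
                )
                dij = saturation_ceiling
            d[i, j] = d[j, i] = dij
    return DistanceMatrix(aln.ids, d)


# ---------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------

def nj(dm: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining with canonical tie-breaking.

    Joins are chosen by the minimum Q criterion, ties broken by the
    lexicographically smallest pair of current cluster labels; negative
    branch lengths are clamped to zero. On additive matrices the generating
    topology is recovered.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    # cluster keys: ("L", label) for leaves, ("I", k) for internal nodes
    active: list[tuple] = [("L", lab) for lab in dm.ids]
    d = {frozenset((a, b)): dm.d[i, j]
         for i, a in enumerate(active) for j, b in enumerate(active) if i < j}
    edges: list[tuple[tuple, tuple, float]] = []
    next_internal = 0

    def dist(a: tuple, b: tuple) -> float:
        return d[frozenset((a, b))]

    while len(active) > 3:
        m = len(active)
        totals = {a: sum(dist(a, b) for b in active if b != a) for a in active}
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                a, b = active[i], active[j]
                q = (m - 2) * dist(a, b) - totals[a] - totals[b]
                key = (q, min(a, b), max(a, b))
                if best is None or key < best[0]:
                    best = (key, a, b)
        _, a, b = best
        new = ("I", next_internal)
        next_internal += 1
        dab = dist(a, b)
        la = 0.5 * dab + (totals[a] - totals[b]) / (2.0 * (m - 2))
        lb = dab - la
        edges.append((a, new, max(la, 0.0)))
        edges.append((b, new, max(lb, 0.0)))
        for c in active:
            if c not in (a, b):
                d[frozenset((new, c))] = 0.5 * (
                    dist(a, c) + dist(b, c) - dab
                )
        active = [c for c in active if c not in (a, b)]
        active.append(new)

    a, b, c = active
    center = ("I", next_internal)
    la = 0.5 * (dist(a, b) + dist(a, c) - dist(b, c))
    lb = 0.5 * (dist(a, b) + dist(b, c) - dist(a, c))
    lc = 0.5 * (dist(a, c) + dist(b, c) - dist(a, b))
    edges.append((a, center, max(la, 0.0)))
    edges.append((b, center, max(lb, 0.0)))
    edges.append((c, center, max(lc, 0.0)))
    leaf_labels = {("L", lab): lab for lab in dm.ids}
    return Tree.from_edges(edges, leaf_labels)


# ---------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------

def _leaf_partial_codes(aln: Alignment) -> tuple[np.ndarray, np.ndarray]:
    """Encode each residue as an index into the partial-vector table.

    Returns (codes matrix ntaxa x nsites, table ncodes x nstates of 0/1
    partial vectors); gaps and ambiguities marginalize over their allowed
    states.
    """
    table_map = state_sets(aln.alphabet)
    concrete = CONCRETE_STATES[aln.alphabet]
    chars = sorted(table_map)
    char_index = {ch: k for k, ch in enumerate(chars)}
    nstates = len(concrete)
    table = np.zeros((len(chars), nstates))
    for ch, k in char_index.items():
        for s in table_map[ch]:
            table[k, concrete.index(s)] = 1.0
    lut = np.full(128, -1, dtype=np.int16)
    for ch, k in char_index.items():
        lut[ord(ch)] = k
    rows = [
        lut[np.frombuffer(rec.residues.encode(), dtype=np.uint8)]
        for rec in aln.records
    ]
    return np.vstack(rows), table


class _PatternData:
    """Compressed site patterns of one alignment, shareable across trees."""

    __slots__ = ("patterns", "table", "counts", "row_of", "n_patterns")

    def __init__(self, aln: Alignment):
        codes, table = _leaf_partial_codes(aln)
        patterns, counts = np.unique(codes, axis=1, return_counts=True)
        self.patterns = patterns
        self.table = table
        self.counts = counts.astype(float)
        self.row_of = {seq_id: k for k, seq_id in enumerate(aln.ids)}
        self.n_patterns = patterns.shape[1]


class _Pruner:
    """Felsenstein-pruning machinery for one (tree topology, aln, model).

    Likelihoods are computed from directional "messages": for each directed
    edge u->v and rate category, the per-pattern likelihood of the data on
    u's side conditional on the state at v. A two-pass computation fills
    every message, after which the full-tree likelihood is available at any
    edge and single-branch optimization costs one small matrix product per
    function evaluation. Messages are rescaled per pattern to avoid
    underflow; the log scales are carried alongside.
    """

    def __init__(
        self,
        tree: Tree,
        aln: Alignment,
        model: SubstitutionModel,
        data: _PatternData | None = None,
    ):
        if tree.leaf_set != set(aln.ids):
            raise TreeError(
                "tree leaves and alignment ids differ: "
                f"{sorted(tree.leaf_set ^ set(aln.ids))}"
            )
        self.tree = tree
        self.model = model
        self.data = data if data is not None else _PatternData(aln)
        self.counts = self.data.counts
        self.n_patterns = self.data.n_patterns
        self.leaf_partials = {
            tree.node_of(lab): self.data.table[
                self.data.patterns[self.data.row_of[lab]]
            ]
            for lab in tree.leaf_set
        }
        self.root = tree.any_internal_node()
        self.preorder = tree.preorder_edges(self.root)
        self.edge_lengths: dict[tuple[int, int], float] = {}
        for u, v, length in tree.edges():
            if length is None:
                raise TreeError("branch lengths required for likelihood")
            self.edge_lengths[(u, v)] = float(length)
        # messages[(u, v)] = (values (ncat, npat, nstates), logscale (ncat, npat))
        self.messages: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}
        self._p_cache: dict[tuple[int, int], np.ndarray] = {}

    # -- message machinery --------------------------------------------

    def edge_keys(self) -> list[tuple[int, int]]:
        return sorted(self.edge_lengths)

    def _p_stack(self, t: float) -> np.ndarray:
        """(ncat, nstates, nstates) transition matrices for length *t*."""
        return np.stack(
            [self.model.transition_matrix(t * r)
             for r in self.model.category_rates]
        )

    def _edge_P(self, u: int, v: int) -> np.ndarray:
        key = (u, v) if u < v else (v, u)
        cached = self._p_cache.get(key)
        if cached is None:
            cached = self._p_stack(self.edge_lengths[key])
            self._p_cache[key] = cached
        return cached

    def _side_partial(
        self, node: int, exclude: int
    ) -> tuple[np.ndarray, np.ndarray]:
        """Partial at *node* for all data away from *exclude*.

        Product of the messages into *node* from every neighbor except
        *exclude* (the bare leaf partial when *node* is a leaf).
        """
        ncat = len(self.model.category_rates)
        if node in self.tree.labels:
            values = np.broadcast_to(
                self.leaf_partials[node],
                (ncat,) + self.leaf_partials[node].shape,
            )
            return values, np.zeros((ncat, self.n_patterns))
        values = None
        scale = None
        for nbr in self.tree.adj[node]:
            if nbr == exclude:
                continue
            m_val, m_scale = self.messages[(nbr, node)]
            values = m_val if values is None else values * m_val
            scale = m_scale if scale is None else scale + m_scale
        return values, scale

    def compute_messages(self) -> None:
        """Two-pass computation of every directional message."""
        self.messages.clear()
        self._p_cache.clear()
        down = self.preorder  # (parent, child) away from root
        for parent, child, _ in reversed(down):
            self._set_message(child, parent)
        for parent, child, _ in down:
            self._set_message(parent, child)

    def _set_message(self, src: int, dst: int) -> None:
        values, scale = self._side_partial(src, dst)
        p = self._edge_P(src, dst)
        out = np.einsum("cps,cts->cpt", values, p)
        mx = out.max(axis=2)
        safe = np.where(mx > 0, mx, 1.0)
        out = out / safe[:, :, None]
        self.messages[(src, dst)] = (
            out, scale + np.where(mx > 0, np.log(safe), 0.0)
        )

    def _edge_loglik_terms(
        self, u: int, v: int
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(weighted u-side partial, v-side partial, total logscale)."""
        su, sc_u = self._side_partial(u, v)
        sv, sc_v = self._side_partial(v, u)
        return su * self.model.freqs[None, None, :], sv, sc_u + sc_v

    def _lnl_from_terms(
        self, su_pi: np.ndarray, sv: np.ndarray, scale: np.ndarray, t: float
    ) -> float:
        rates = self.model.category_rates
        p = self._p_stack(t)
        lik = np.einsum("cpi,cij,cpj->cp", su_pi, p, sv)
        with np.errstate(divide="ignore"):
            log_cat = np.log(lik) + scale
        if len(rates) == 1:
            log_site = log_cat[0]
        else:
            peak = log_cat.max(axis=0)
            log_site = (
                peak
                + np.log(np.exp(log_cat - peak).sum(axis=0))
                - np.log(len(rates))
            )
        return float((self.counts * log_site).sum())

    def loglik(self) -> float:
        """Full-tree log-likelihood at the current branch lengths."""
        self.compute_messages()
        u, v = self.edge_keys()[0]
        su_pi, sv, scale = self._edge_loglik_terms(u, v)
        key = (u, v) if u < v else (v, u)
        return self._lnl_from_terms(su_pi, sv, scale, self.edge_lengths[key])

    def optimize_lengths(
        self,
        tol: float = 1e-3,
        max_sweeps: int = 5,
        edges: list[tuple[int, int]] | None = None,
    ) -> float:
        """Brent optimization per branch, sweeping until improvement < tol.

        Within a sweep the directional messages are refreshed only across
        the branch just changed (a Gauss-Seidel-style update); the exact
        likelihood is recomputed at every sweep boundary and the best exact
        assignment seen is returned, so the result never falls below the
        input. ``self.edge_lengths`` is updated in place.
        """
        keys = edges if edges is not None else self.edge_keys()
        current = self.loglik()
        best_exact = current
        best_lengths = dict(self.edge_lengths)
        for _ in range(max_sweeps):
            start = best_exact
            self.compute_messages()
            for u, v in keys:
                su_pi, sv, scale = self._edge_loglik_terms(u, v)

                def neg(t: float) -> float:
                    return -self._lnl_from_terms(su_pi, sv, scale, t)

                here = -neg(self.edge_lengths[(u, v)])
                res = minimize_scalar(
                    neg, bounds=(_BL_MIN, _BL_MAX), method="bounded",
                    options={"xatol": 1e-5},
                )
                if -res.fun > here:
                    self.edge_lengths[(u, v)] = float(res.x)
                    self._p_cache.pop((u, v), None)
                    self._set_message(u, v)
                    self._set_message(v, u)
            exact = self.loglik()
            if exact > best_exact:
                best_exact = exact
                best_lengths = dict(self.edge_lengths)
            if exact - start < tol:
                break
        self.edge_lengths = dict(best_lengths)
        return best_exact

    def tree_with_lengths(self) -> Tree:
        work = self.tree.copy()
        for (u, v), t in self.edge_lengths.items():
            work.adj[u][v] = t
            work.adj[v][u] = t
        return work


def log_likelihood(tree: Tree, aln: Alignment, model: SubstitutionModel) -> float:
    """Felsenstein-pruning log-likelihood of *aln* on *tree* under *model*.

    Gaps and ambiguity codes are marginalized; discrete-gamma category
    likelihoods are averaged per site with equal weights.
    """
    return _Pruner(tree, aln, model).loglik()


def optimize_branch_lengths(
    tree: Tree,
    aln: Alignment,
    model: SubstitutionModel,
    tol: float = 1e-3,
    max_sweeps: int = 5,
) -> Tree:
    """Return *tree* with branch lengths optimized; likelihood never drops."""
    pruner = _Pruner(tree, aln, model)
    pruner.optimize_lengths(tol=tol, max_sweeps=max_sweeps)
    return pruner.tree_with_lengths()


# ---------------------------------------------------------------------
# NNI search
# ---------------------------------------------------------------------

def _internal_edges(tree: Tree) -> list[tuple[int, int]]:
    return sorted(
        (min(u, v), max(u, v))
        for u, v, _ in tree.edges()
        if u not in tree.labels and v not in tree.labels
    )


def _nni_neighbors(tree: Tree) -> list[tuple[Tree, tuple[int, int]]]:
    """The two NNI rearrangements across every internal edge, in fixed order.

    Each entry carries the rearranged central edge so searches can
    re-optimize locally. Node ids are preserved by the rearrangement.
    """
    out: list[tuple[Tree, tuple[int, int]]] = []
    for u, v in _internal_edges(tree):
        u_nbrs = sorted(n for n in tree.adj[u] if n != v)
        v_nbrs = sorted(n for n in tree.adj[v] if n != u)
        if len(u_nbrs) != 2 or len(v_nbrs) != 2:
            raise TreeError("NNI search requires a fully binary tree")
        b = u_nbrs[1]
        for c in v_nbrs:
            work = tree.copy()
            lb = work.adj[u].pop(b)
            work.adj[b].pop(u)
            lc = work.adj[v].pop(c)
            work.adj[c].pop(v)
            work.adj[u][c] = lc
            work.adj[c][u] = lc
            work.adj[v][b] = lb
            work.adj[b][v] = lb
            out.append((work, (min(u, v), max(u, v))))
    return out


def nni_search(
    start: Tree,
    aln: Alignment,
    model: SubstitutionModel,
    config: EngineConfig | None = None,
) -> Tree:
    """Hill-climb over nearest-neighbor interchanges with re-optimization.

    Candidates on small trees (<= 8 leaves) get a full branch-length
    re-optimization; on larger trees each candidate is screened by
    re-optimizing the five branches around the rearranged edge, and the
    accepted rearrangement is then fully re-optimized. The returned tree's
    log-likelihood is never below the start tree's; ties are broken by
    canonical Newick order.
    """
    config = config or EngineConfig(model=model)
    data = _PatternData(aln)
    pruner = _Pruner(start, aln, model, data)
    current_lnl = pruner.optimize_lengths(
        tol=config.brlen_tol, max_sweeps=config.brlen_max_sweeps
    )
    current = pruner.tree_with_lengths()
    full_eval = start.n_leaves <= 8
    for _ in range(config.nni_max_rounds):
        best: tuple[float, str, Tree] | None = None
        for cand, central in _nni_neighbors(current):
            cp = _Pruner(cand, aln, model, data)
            if full_eval:
                lnl = cp.optimize_lengths(
                    tol=config.brlen_tol, max_sweeps=config.brlen_max_sweeps
                )
            else:
                local = _edges_around(cand, central)
                lnl = cp.optimize_lengths(tol=config.brlen_tol, max_sweeps=1,
                                          edges=local)
            cand_opt = cp.tree_with_lengths()
            key = write_newick(cand_opt, lengths=False)
            if lnl > current_lnl + 1e-9 and (
                best is None
                or lnl > best[0] + 1e-9
                or (abs(lnl - best[0]) <= 1e-9 and key < best[1])
            ):
                best = (lnl, key, cand_opt)
        if best is None:
            break
        # full re-optimization of the accepted rearrangement
        bp = _Pruner(best[2], aln, model, data)
        current_lnl = bp.optimize_lengths(
            tol=config.brlen_tol, max_sweeps=config.brlen_max_sweeps
        )
        current = bp.tree_with_lengths()
    return current


def _edges_around(tree: Tree, central: tuple[int, int]) -> list[tuple[int, int]]:
    """The central edge plus the four edges incident to its endpoints."""
    u, v = central
    out = {central}
    for node in (u, v):
        for nbr in tree.adj[node]:
            out.add((min(node, nbr), max(node, nbr)))
    return sorted(out)


def enumerate_topologies(labels: list[str], branch_length: float = 0.1):
    """Yield every unrooted binary topology on *labels* (for small n).

    Built by stepwise insertion of each successive leaf on every edge;
    intended as an exhaustive-search oracle for <= 6 taxa.
    """
    labels = sorted(labels)
    if len(labels) < 3:
        raise ValueError("need at least 3 labels")
    base = Tree.from_edges(
        [(("L", lab), ("I", 0), branch_length) for lab in labels[:3]],
        {("L", lab): lab for lab in labels[:3]},
    )

    def insert_all(tree: Tree, label: str):
        for u, v, length in sorted(tree.edges()):
            work = tree.copy()
            new_internal = max(work.adj) + 1
            new_leaf = new_internal + 1
            work.adj[u].pop(v)
            work.adj[v].pop(u)
            work.adj[u][new_internal] = length
            work.adj.setdefault(new_internal, {})[u] = length
            work.adj[new_internal][v] = length
            work.adj[v][new_internal] = length
            work.adj[new_internal][new_leaf] = branch_length
            work.adj[new_leaf] = {new_internal: branch_length}
            work.labels[new_leaf] = label
            yield Tree(
                {a: dict(nb) for a, nb in work.adj.items()}, dict(work.labels)
            )

    trees = [base]
    for label in labels[3:]:
        trees = [t2 for t in trees for t2 in insert_all(t, label)]
    return trees


# ---------------------------------------------------------------------
# GTR parameter estimation
# ---------------------------------------------------------------------

def _empirical_freqs(aln: Alignment) -> np.ndarray:
    codes = _encode_concrete(aln)
    nstates = len(CONCRETE_STATES[aln.alphabet])
    counts = np.bincount(codes[codes >= 0].ravel(), minlength=nstates).astype(float)
    counts += 0.5  # avoid zero frequencies
    return counts / counts.sum()


def _estimate_gtr(
    tree: Tree, aln: Alignment, model: SubstitutionModel
) -> SubstitutionModel:
    """Plug-in GTR fit on a fixed topology.

    State frequencies are the pooled empirical frequencies; the five free
    exchangeabilities (GT fixed at 1) are optimized numerically with branch
    lengths re-optimized before and after.
    """
    freqs = _empirical_freqs(aln)
    base = SubstitutionModel.gtr(
        freqs, model.exchangeabilities,
        gamma_shape=model.gamma_shape,
        n_rate_categories=model.n_rate_categories,
    )
    tree = optimize_branch_lengths(tree, aln, base)

    def build(x: np.ndarray) -> SubstitutionModel:
        exch = tuple(np.exp(x)) + (1.0,)
        return SubstitutionModel.gtr(
            freqs, exch, gamma_shape=model.gamma_shape,
            n_rate_categories=model.n_rate_categories,
        )

    def nll(x: np.ndarray) -> float:
        return -log_likelihood(tree, aln, build(x))

    x0 = np.log(np.maximum(np.asarray(model.exchangeabilities[:5]), 1e-3))
    res = minimize(nll, x0, method="L-BFGS-B", options={"maxiter": 40})
    return build(res.x)


# ---------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------

def infer_tree(aln: Alignment, config: EngineConfig) -> Tree:
    """Infer a tree for *aln* under *config*; deterministic given inputs.

    Internal engine: corrected distances -> neighbor joining -> (GTR
    parameter fit, if applicable) -> branch-length optimization -> NNI
    search. External engine: render the command template, run it, parse the
    resulting Newick.
    """
    if config.engine == "external":
        return _run_external(aln, config)
    if len(aln) < 3:
        raise AlignmentError("tree inference needs at least 3 sequences")
    model = config.model
    dm = distance_matrix(aln, model, config.saturation_ceiling)
    tree = nj(dm)
    if model.kind == "GTR" and config.estimate_gtr:
        model = _estimate_gtr(tree, aln, model)
    tree = optimize_branch_lengths(
        tree, aln, model, tol=config.brlen_tol,
        max_sweeps=config.brlen_max_sweeps,
    )
    if len(aln) >= 4:
        tree = nni_search(tree, aln, model, config)
    return tree


def _run_external(aln: Alignment, config: EngineConfig) -> Tree:
    with tempfile.TemporaryDirectory(prefix="canaryseq_engine_") as tmp:
        aln_path = Path(tmp) / "alignment.phy"
        out_path = Path(tmp) / "out.nwk"
        _seqs.write_alignment(aln, aln_path, format="phylip")
        command = config.external_command_template.format(
            alignment_phylip=str(aln_path), out_newick=str(out_path)
        )
        proc = subprocess.run(
            command, shell=True, capture_output=True, text=True
        )
        if proc.returncode != 0:
            raise EngineError(
                f"external engine exited with status {proc.returncode}",
                command=command, stdout=proc.stdout, stderr=proc.stderr,
            )
        if not out_path.exists():
            raise EngineError(
                "external engine produced no output tree",
                command=command, stdout=proc.stdout, stderr=proc.stderr,
            )
        try:
            return parse_newick(out_path.read_text())
        except Exception as exc:
            raise EngineError(
                f"cannot parse external engine output: {exc}",
                command=command, stdout=proc.stdout, stderr=proc.stderr,
            ) from exc
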