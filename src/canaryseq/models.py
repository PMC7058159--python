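"""Substitution models and their transition probabilities.

Supported models: JC69 and GTR for nucleotides, Poisson and LG for
proteins, each optionally with discrete-gamma among-site rate variation
(mean-one category rates from equal-probability quantile bins). Rate
matrices are normalized to one expected substitution per site per unit
branch length, so branch lengths are in substitutions/site.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from canaryseq.lg_data import LG_FREQS, LG_UPPER
from canaryseq.seqs import Alphabet

__all__ = ["SubstitutionModel", "discrete_gamma_rates"]

_N_NUC_EXCH = 6      # AC, AG, AT, CG, CT, GT
_N_AA_EXCH = 190


def discrete_gamma_rates(shape: float, n_categories: int) -> np.ndarray:
    """Mean rates of equal-probability gamma categories, normalized to mean 1.

    The gamma distribution has shape = rate = ``shape`` (mean 1); category
    k is the conditional mean between the k/K and (k+1)/K quantiles,
    computed from the regularized incomplete gamma function.
    """
    if shape <= 0:
        raise ValueError("gamma shape must be positive")
    if n_categories < 1:
        raise ValueError("need at least one rate category")
    if n_categories == 1:
        return np.ones(1)
    k = n_categories
    bounds = gamma_dist.ppf(np.arange(1, k) / k, a=shape, scale=1.0 / shape)
    bounds = np.concatenate(([0.0], bounds, [np.inf]))
    upper = np.where(np.isinf(bounds[1:]), 1.0, gammainc(shape + 1, shape * bounds[1:]))
    lower = gammainc(shape + 1, shape * bounds[:-1])
    rates = k * (upper - lower)
    return rates / rates.mean()


@dataclass(frozen=True)
class SubstitutionModel:
    """A reversible substitution model with optional discrete-gamma rates.

    ``exchangeabilities`` is the strict upper triangle of the symmetric
    exchangeability matrix in canonical state order (nucleotides ACGT:
    AC, AG, AT, CG, CT, GT). JC69 and Poisson force uniform frequencies and
    equal exchangeabilities.
    """

    kind: str  # one of {"JC69", "GTR", "Poisson", "LG"}
    state_freqs: tuple[float, ...]
    exchangeabilities: tuple[float, ...]
    gamma_shape: float | None = None
    n_rate_categories: int = 4

    def __post_init__(self) -> None:
        freqs = np.asarray(self.state_freqs, dtype=float)
        if abs(freqs.sum() - 1.0) > 1e-9:
            raise ValueError(f"state frequencies sum to {freqs.sum()}, not 1")
        if np.any(freqs <= 0):
            raise ValueError("state frequencies must be strictly positive")
        n = len(freqs)
        n_exch = n * (n - 1) // 2
        if len(self.exchangeabilities) != n_exch:
            raise ValueError(
                f"expected {n_exch} exchangeabilities, got "
                f"{len(self.exchangeabilities)}"
            )
        if any(x < 0 for x in self.exchangeabilities):
            raise ValueError("exchangeabilities must be nonnegative")
        if self.kind in ("JC69", "Poisson"):
            if np.ptp(freqs) > 1e-12 or np.ptp(self.exchangeabilities) > 1e-12:
                raise ValueError(
                    f"{self.kind} requires uniform frequencies and equal rates"
                )
        if self.gamma_shape is not None and self.gamma_shape <= 0:
            raise ValueError("gamma shape must be positive")
        if self.n_rate_categories < 1:
            raise ValueError("n_rate_categories must be >= 1")

    # -- constructors --------------------------------------------------

    @classmethod
    def jc69(cls, gamma_shape: float | None = None,
             n_rate_categories: int = 4) -> "SubstitutionModel":
        return cls("JC69", (0.25,) * 4, (1.0,) * _N_NUC_EXCH,
                   gamma_shape, n_rate_categories)

    @classmethod
    def gtr(cls, state_freqs, exchangeabilities,
            gamma_shape: float | None = None,
            n_rate_categories: int = 4) -> "SubstitutionModel":
        freqs = tuple(float(f) for f in state_freqs)
        total = sum(freqs)
        freqs = tuple(f / total for f in freqs)
        return cls("GTR", freqs, tuple(float(x) for x in exchangeabilities),
                   gamma_shape, n_rate_categories)

    @classmethod
    def poisson(cls, gamma_shape: float | None = None,
                n_rate_categories: int = 4) -> "SubstitutionModel":
        return cls("Poisson", (0.05,) * 20, (1.0,) * _N_AA_EXCH,
                   gamma_shape, n_rate_categories)

    @classmethod
    def lg(cls, gamma_shape: float | None = None,
           n_rate_categories: int = 4) -> "SubstitutionModel":
        freqs = np.asarray(LG_FREQS)
        freqs = freqs / freqs.sum()
        return cls("LG", tuple(freqs), tuple(LG_UPPER),
                   gamma_shape, n_rate_categories)

    # -- derived quantities --------------------------------------------

    @property
    def n_states(self) -> int:
        return len(self.state_freqs)

    @property
    def alphabet(self) -> Alphabet:
        return Alphabet.NUCLEOTIDE if self.n_states == 4 else Alphabet.PROTEIN

    @cached_property
    def freqs(self) -> np.ndarray:
        return np.asarray(self.state_freqs, dtype=float)

    @cached_property
    def rate_matrix(self) -> np.ndarray:
        """Q with rows summing to zero, scaled to mean rate 1."""
        n = self.n_states
        s = np.zeros((n, n))
        iu = np.triu_indices(n, k=1)
        s[iu] = self.exchangeabilities
        s = s + s.T
        q = s * self.freqs[np.newaxis, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        mean_rate = -(self.freqs * np.diag(q)).sum()
        return q / mean_rate

    @cached_property
    def _eigen(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Eigendecomposition of Q via the symmetrized form (reversibility)."""
        sqrt_pi = np.sqrt(self.freqs)
        sym = self.rate_matrix * (sqrt_pi[:, None] / sqrt_pi[None, :])
        sym = (sym + sym.T) / 2.0
        eigvals, eigvecs = np.linalg.eigh(sym)
        left = eigvecs.T * sqrt_pi[None, :]
        right = eigvecs / sqrt_pi[:, None]
        return eigvals, right, left

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); rows are conditional distributions."""
        if t < 0:
            raise ValueError("branch length must be nonnegative")
        eigvals, right, left = self._eigen
        p = (right * np.exp(eigvals * t)[None, :]) @ left
        np.clip(p, 0.0, None, out=p)
        p /= p.sum(axis=1, keepdims=True)
        return p

    @cached_property
    def category_rates(self) -> np.ndarray:
        """Discrete-gamma category rates (a single rate 1 when no gamma)."""
        if self.gamma_shape is None:
            return np.ones(1)
        return discrete_gamma_rates(self.gamma_shape, self.n_rate_categories)
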