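"""Reversible nucleotide substitution models (JC, K2P, HKY, GTR) with
optional discrete-gamma rate heterogeneity.

State order is A, C, G, T.  Rate matrices are scaled to one expected
substitution per unit branch length, so branch lengths are expected
substitutions per site at the mean site rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

MODEL_KINDS = ("JC", "K2P", "HKY", "GTR")

# exchangeability order: AC, AG, AT, CG, CT, GT
_PAIRS = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
_TRANSITIONS = {(0, 2), (2, 0), (1, 3), (3, 1)}  # A<->G, C<->T


def discrete_gamma_rates(alpha: float, ncat: int) -> np.ndarray:
    """Category mean rates of the equal-probability discrete gamma.

    Shape and rate both equal ``alpha`` so the mean rate is one; each
    category rate is the conditional mean within its probability bin.
    """
    if ncat <= 1:
        return np.ones(1)
    edges = gamma_dist.ppf(np.linspace(0, 1, ncat + 1), a=alpha, scale=1.0 / alpha)
    # partial expectations via the regularized incomplete gamma of shape a+1
    upper = gammainc(alpha + 1.0, edges[1:] * alpha)
    lower = gammainc(alpha + 1.0, edges[:-1] * alpha)
    rates = ncat * (upper - lower)
    rates[-1] = ncat * (1.0 - lower[-1])
    return np.clip(rates, 1e-8, None)


@dataclass
class SubstitutionModel:
    """A reversible 4-state model, optionally with gamma rate classes.

    ``alpha=None`` (or ``ncat<=1``) means rate homogeneity.
    """

    kind: str = "GTR"
    freqs: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    exchangeabilities: np.ndarray = field(default_factory=lambda: np.ones(6))
    alpha: float | None = None
    ncat: int = 4

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}")
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.exchangeabilities = np.asarray(self.exchangeabilities, dtype=float)
        if self.freqs.shape != (4,) or not np.isclose(self.freqs.sum(), 1.0):
            raise ValueError("base frequencies must be 4 values summing to 1")
        if self.exchangeabilities.shape != (6,) or (self.exchangeabilities < 0).any():
            raise ValueError("need 6 non-negative exchangeabilities")
        self._decomposition: tuple | None = None

    # ------------------------------------------------------------- builders

    @classmethod
    def jc(cls, alpha: float | None = None, ncat: int = 4) -> "SubstitutionModel":
        return cls("JC", np.full(4, 0.25), np.ones(6), alpha, ncat)

    @classmethod
    def k2p(
        cls, kappa: float = 2.0, alpha: float | None = None, ncat: int = 4
    ) -> "SubstitutionModel":
        ex = np.ones(6)
        for i, pair in enumerate(_PAIRS):
            if pair in _TRANSITIONS:
                ex[i] = kappa
        return cls("K2P", np.full(4, 0.25), ex, alpha, ncat)

    @classmethod
    def hky(
        cls,
        freqs,
        kappa: float = 2.0,
        alpha: float | None = None,
        ncat: int = 4,
    ) -> "SubstitutionModel":
        ex = np.ones(6)
        for i, pair in enumerate(_PAIRS):
            if pair in _TRANSITIONS:
                ex[i] = kappa
        return cls("HKY", np.asarray(freqs, dtype=float), ex, alpha, ncat)

    @classmethod
    def gtr(
        cls,
        freqs,
        exchangeabilities,
        alpha: float | None = None,
        ncat: int = 4,
    ) -> "SubstitutionModel":
        return cls(
            "GTR",
            np.asarray(freqs, dtype=float),
            np.asarray(exchangeabilities, dtype=float),
            alpha,
            ncat,
        )

    def with_params(self, **kwargs) -> "SubstitutionModel":
        return replace(self, **kwargs)

    @property
    def kappa(self) -> float:
        return self.exchangeabilities[1] / self.exchangeabilities[0]

    # ------------------------------------------------------------- matrices

    def rate_matrix(self) -> np.ndarray:
        """Scaled instantaneous rate matrix Q (rows sum to zero)."""
        q = np.zeros((4, 4))
        for rate, (i, j) in zip(self.exchangeabilities, _PAIRS):
            q[i, j] = rate * self.freqs[j]
            q[j, i] = rate * self.freqs[i]
        np.fill_diagonal(q, -q.sum(axis=1))
        mean_rate = -(self.freqs * np.diag(q)).sum()
        if mean_rate <= 0:
            raise ValueError("degenerate rate matrix (zero mean rate)")
        return q / mean_rate

    def _decompose(self):
        if self._decomposition is None:
            q = self.rate_matrix()
            sqrt_pi = np.sqrt(self.freqs)
            sym = (sqrt_pi[:, None] * q) / sqrt_pi[None, :]
            eigval, eigvec = np.linalg.eigh((sym + sym.T) / 2.0)
            left = eigvec.T * sqrt_pi[None, :]
            right = eigvec / sqrt_pi[:, None]
            self._decomposition = (eigval, right, left)
        return self._decomposition

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); rows sum to one."""
        if t < 0:
            raise ValueError("negative branch length")
        eigval, right, left = self._decompose()
        p = (right * np.exp(eigval * t)) @ left
        return np.clip(p, 0.0, None)

    def category_rates(self) -> np.ndarray:
        if self.alpha is None or self.ncat <= 1:
            return np.ones(1)
        return discrete_gamma_rates(self.alpha, self.ncat)

    def n_free_parameters(self) -> int:
        """Free parameters counted for AIC (frequencies included)."""
        k = {"JC": 0, "K2P": 1, "HKY": 4, "GTR": 8}[self.kind]
        if self.alpha is not None and self.ncat > 1:
            k += 1
        return k

    def short_name(self) -> str:
        suffix = f"+G{self.ncat}" if self.alpha is not None and self.ncat > 1 else ""
        return self.kind + suffix
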