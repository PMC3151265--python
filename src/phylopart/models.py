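"""Reversible nucleotide substitution models and discrete-gamma rate heterogeneity.

Implements the JC, HKY and REV (general time-reversible) rate matrices, the
spectral computation of transition probabilities, equal-probability
discrete-gamma rate categories with conditional-mean rates, and the
stationary-flux average transition/transversion ratio ``R``.

Nucleotide state order is (A, C, G, T) throughout; exchangeabilities are
ordered (AC, AG, AT, CG, CT, GT).  Generators are calibrated to one expected
substitution per site per unit time, so branch lengths are in expected
substitutions per site.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np
from scipy import special

__all__ = [
    "ModelKind",
    "NucleotideModel",
    "GammaRateModel",
    "build_generator",
    "transition_probabilities",
    "discretize_gamma",
    "average_ts_tv_ratio",
    "SpectralDecomposition",
]

STATES = "ACGT"
N_STATES = 4

# index pairs for the six unordered exchangeabilities (AC, AG, AT, CG, CT, GT)
PAIR_INDEX = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
TRANSITION_PAIRS = frozenset([(0, 2), (1, 3)])  # A<->G, C<->T

FREQ_FLOOR = 1e-8


class ModelKind(str, Enum):
    JC = "JC"
    HKY = "HKY"
    REV = "REV"


def _as_freqs(frequencies) -> np.ndarray:
    f = np.asarray(frequencies, dtype=float)
    if f.shape != (4,):
        raise ValueError("frequencies must be a 4-vector")
    if not np.all(np.isfinite(f)):
        raise ValueError("frequencies must be finite")
    if np.any(f < FREQ_FLOOR):
        raise ValueError(f"frequencies below {FREQ_FLOOR} are rejected")
    if abs(f.sum() - 1.0) > 1e-12:
        raise ValueError("frequencies must sum to 1 within 1e-12")
    return f


@dataclass(frozen=True)
class NucleotideModel:
    """A reversible nucleotide substitution model (JC, HKY or REV).

    ``exchangeabilities`` are the six relative rates (AC, AG, AT, CG, CT, GT)
    with GT conventionally the reference (fixed to 1 in optimization).  For
    HKY they are derived from ``kappa`` (transitions = kappa, transversions
    = 1); for JC they are all equal.
    """

    kind: ModelKind
    frequencies: np.ndarray
    exchangeabilities: np.ndarray
    kappa: Optional[float] = None

    def __post_init__(self):
        object.__setattr__(self, "frequencies", _as_freqs(self.frequencies))
        r = np.asarray(self.exchangeabilities, dtype=float)
        if r.shape != (6,):
            raise ValueError("exchangeabilities must be a 6-vector")
        if not np.all(np.isfinite(r)) or np.any(r < 0):
            raise ValueError("exchangeabilities must be finite and >= 0")
        object.__setattr__(self, "exchangeabilities", r)
        if self.kind == ModelKind.JC:
            if not np.allclose(self.frequencies, 0.25, atol=1e-12):
                raise ValueError("JC requires equal frequencies")
            if not np.allclose(r, r[0]):
                raise ValueError("JC requires equal exchangeabilities")
        elif self.kind == ModelKind.HKY:
            if self.kappa is None or not (self.kappa > 0):
                raise ValueError("HKY requires kappa > 0")
            tv = r[[0, 2, 3, 5]]
            if not (np.allclose(tv, tv[0]) and np.allclose(r[[1, 4]], self.kappa * tv[0])):
                raise ValueError("HKY exchangeabilities inconsistent with kappa")

    # -- constructors -------------------------------------------------

    @classmethod
    def jc(cls) -> "NucleotideModel":
        return cls(ModelKind.JC, np.full(4, 0.25), np.ones(6))

    @classmethod
    def hky(cls, frequencies, kappa: float) -> "NucleotideModel":
        r = np.ones(6)
        r[1] = r[4] = kappa
        return cls(ModelKind.HKY, np.asarray(frequencies, float), r, kappa=float(kappa))

    @classmethod
    def rev(cls, frequencies, exchangeabilities) -> "NucleotideModel":
        return cls(ModelKind.REV, np.asarray(frequencies, float),
                   np.asarray(exchangeabilities, float))

    def n_free_rate_params(self) -> int:
        """Free parameters in the rate matrix beyond branch lengths."""
        if self.kind == ModelKind.JC:
            return 0
        if self.kind == ModelKind.HKY:
            return 1 + 3  # kappa + 3 frequencies
        return 5 + 3  # five relative exchangeabilities + 3 frequencies

    def to_dict(self) -> dict:
        d = {
            "kind": self.kind.value,
            "frequencies": [float(x) for x in self.frequencies],
            "exchangeabilities": [float(x) for x in self.exchangeabilities],
        }
        if self.kappa is not None:
            d["kappa"] = float(self.kappa)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NucleotideModel":
        kind = ModelKind(d["kind"])
        return cls(kind, np.asarray(d["frequencies"], float),
                   np.asarray(d["exchangeabilities"], float),
                   kappa=d.get("kappa"))


@dataclass(frozen=True)
class GammaRateModel:
    """Discrete-gamma among-site rate variation (mean rate exactly 1)."""

    alpha: float
    n_categories: int
    category_rates: np.ndarray
    category_probs: np.ndarray

    def __post_init__(self):
        rates = np.asarray(self.category_rates, float)
        probs = np.asarray(self.category_probs, float)
        if rates.shape != (self.n_categories,) or probs.shape != (self.n_categories,):
            raise ValueError("rates/probs length mismatch with n_categories")
        if abs(probs.sum() - 1.0) > 1e-12:
            raise ValueError("category_probs must sum to 1")
        if abs(float(probs @ rates) - 1.0) > 1e-10:
            raise ValueError("mean rate must be 1 within 1e-10")
        if np.any(np.diff(rates) < -1e-12):
            raise ValueError("category rates must be nondecreasing")
        object.__setattr__(self, "category_rates", rates)
        object.__setattr__(self, "category_probs", probs)


def build_generator(model: NucleotideModel) -> np.ndarray:
    """Build the 4x4 rate matrix Q with q_ij = scale * r_ij * pi_j.

    Calibrated so the expected substitution rate at stationarity,
    ``-sum_i pi_i q_ii``, is exactly 1.
    """
    pi = model.frequencies
    r = model.exchangeabilities
    if np.all(r == 0):
        raise ValueError("degenerate process: all exchangeabilities are zero")
    Q = np.zeros((4, 4))
    for k, (i, j) in enumerate(PAIR_INDEX):
        Q[i, j] = r[k] * pi[j]
        Q[j, i] = r[k] * pi[i]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    rate = -float(pi @ np.diag(Q))
    if rate <= 0:
        raise ValueError("degenerate process: zero total substitution rate")
    return Q / rate


class SpectralDecomposition:
    """Cached spectral form of a reversible generator for fast P(t).

    Uses the symmetrization B = D^{1/2} Q D^{-1/2} (D = diag(pi)), which is
    symmetric for reversible Q, so P(t) = D^{-1/2} U exp(L t) U^T D^{1/2}.
    """

    def __init__(self, Q: np.ndarray, pi: np.ndarray):
        d = np.sqrt(pi)
        B = (Q * d[:, None]) / d[None, :]
        B = 0.5 * (B + B.T)
        lam, U = np.linalg.eigh(B)
        self.eigenvalues = lam
        # P(t) = left @ diag(exp(lam t)) @ right
        self.left = U / d[:, None]
        self.right = U.T * d[None, :]
        self.pi = pi

    def probabilities(self, t) -> np.ndarray:
        """P(t) for scalar t, or a stack of P for an array of times."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("branch length must be >= 0")
        e = np.exp(np.multiply.outer(t, self.eigenvalues))
        P = np.einsum("ik,...k,kj->...ij", self.left, e, self.right)
        return np.clip(P, 0.0, 1.0)


def transition_probabilities(Q: np.ndarray, t: float) -> np.ndarray:
    """Stochastic matrix P(t) = exp(Qt) for a calibrated reversible Q."""
    if t < 0:
        raise ValueError("branch length must be >= 0")
    pi = _stationary_from_generator(Q)
    P = SpectralDecomposition(Q, pi).probabilities(float(t))
    # renormalize away eigensolver round-off so rows sum to 1 exactly
    return P / P.sum(axis=1, keepdims=True)


def _stationary_from_generator(Q: np.ndarray) -> np.ndarray:
    # left null vector of Q; reversible Q has a unique stationary law
    w, v = np.linalg.eig(Q.T)
    k = int(np.argmin(np.abs(w)))
    pi = np.real(v[:, k])
    pi = np.abs(pi)
    return pi / pi.sum()


def discretize_gamma(alpha: float, n_categories: int = 6) -> GammaRateModel:
    """Equal-probability discrete gamma with conditional-mean category rates.

    Category boundaries are the i/K quantiles of Gamma(alpha, rate=alpha);
    each rate is the mean of the density restricted to its bin, then the
    whole set is renormalized so the weighted mean is exactly 1.
    """
    if not (alpha > 0):
        raise ValueError("alpha must be > 0")
    if n_categories < 1:
        raise ValueError("need at least one rate category")
    K = int(n_categories)
    if K == 1:
        return GammaRateModel(alpha, 1, np.array([1.0]), np.array([1.0]))
    probs = np.full(K, 1.0 / K)
    edges = special.gammaincinv(alpha, np.arange(1, K) / K) / alpha
    # E[X | bin] * P(bin) = gammainc(alpha+1, alpha*edge) differences,
    # since the mean of Gamma(alpha, rate=alpha) is 1
    cum = np.concatenate([[0.0], special.gammainc(alpha + 1.0, alpha * edges), [1.0]])
    rates = np.diff(cum) * K
    rates /= float(probs @ rates)
    return GammaRateModel(float(alpha), K, rates, probs)


def average_ts_tv_ratio(model: NucleotideModel) -> float:
    """Average transition/transversion ratio R (stationary flux ratio).

    R = (pi_A pi_G r_AG + pi_C pi_T r_CT) /
        (pi_A pi_C r_AC + pi_A pi_T r_AT + pi_C pi_G r_CG + pi_G pi_T r_GT)
    """
    pi = model.frequencies
    r = model.exchangeabilities
    num = pi[0] * pi[2] * r[1] + pi[1] * pi[3] * r[4]
    den = (pi[0] * pi[1] * r[0] + pi[0] * pi[3] * r[2]
           + pi[1] * pi[2] * r[3] + pi[2] * pi[3] * r[5])
    if den <= 0:
        raise ValueError("degenerate model: no transversion flux")
    return float(num / den)
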