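"""Reversible amino-acid substitution models with discrete gamma rates."""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from scipy.stats import gamma as gamma_dist

from ._alphabet import N_STATES


@dataclass
class SubstitutionModel:
    """Time-reversible CTMC over 20 amino acids.

    The rate matrix Q = S diag(pi) is rescaled so the expected
    substitution rate at stationarity is 1 (branch lengths are then in
    expected substitutions per site).
    """

    exchangeabilities: np.ndarray  # (20, 20) symmetric, zero diagonal
    frequencies: np.ndarray  # (20,) sums to 1
    gamma_alpha: float | None = None  # None -> rate-homogeneous
    n_rate_categories: int = 4
    name: str = "custom"

    # eigendecomposition cache, filled in __post_init__
    _evals: np.ndarray = field(init=False, repr=False)
    _right: np.ndarray = field(init=False, repr=False)
    _left: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        S = np.asarray(self.exchangeabilities, dtype=float)
        pi = np.asarray(self.frequencies, dtype=float)
        if S.shape != (N_STATES, N_STATES):
            raise ValueError("exchangeability matrix must be 20x20")
        if not np.allclose(S, S.T):
            raise ValueError("exchangeability matrix must be symmetric")
        if pi.shape != (N_STATES,) or not np.isclose(pi.sum(), 1.0):
            raise ValueError("frequencies must be a 20-vector summing to 1")
        Q = S * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        # rescale to one expected substitution per unit branch length
        mu = -(pi * np.diag(Q)).sum()
        Q /= mu
        self.rate_matrix = Q
        # symmetrize: B = diag(sqrt(pi)) Q diag(1/sqrt(pi)) is symmetric
        sq = np.sqrt(pi)
        B = (Q * sq[:, None]) / sq[None, :]
        B = 0.5 * (B + B.T)  # clean numerical asymmetry
        evals, U = np.linalg.eigh(B)
        self._evals = evals
        self._right = U / sq[:, None] * 1.0  # diag(1/sqrt(pi)) U
        self._left = (U * sq[:, None]).T  # U^T diag(sqrt(pi))

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Q t); rows sum to 1."""
        if t < 0:
            raise ValueError("branch length must be >= 0")
        if t == 0:
            return np.eye(N_STATES)
        P = (self._right * np.exp(self._evals * t)[None, :]) @ self._left
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P

    def category_rates(self) -> np.ndarray:
        """Equal-weight discrete gamma rates (median method), mean 1."""
        if self.gamma_alpha is None:
            return np.ones(1)
        k = self.n_rate_categories
        a = self.gamma_alpha
        quantiles = (2.0 * np.arange(k) + 1.0) / (2.0 * k)
        rates = gamma_dist.ppf(quantiles, a, scale=1.0 / a)
        return rates / rates.mean()

    def with_alpha(self, alpha: float | None) -> "SubstitutionModel":
        return SubstitutionModel(
            self.exchangeabilities,
            self.frequencies,
            gamma_alpha=alpha,
            n_rate_categories=self.n_rate_categories,
            name=self.name,
        )


def read_paml_dat(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Parse a PAML-dialect dat file: 19 lower-triangle rows then frequencies."""
    tokens = Path(path).read_text().split()
    values = [float(t) for t in tokens]
    if len(values) < 190 + 20:
        raise ValueError("dat file too short for a 20-state model")
    S = np.zeros((N_STATES, N_STATES))
    k = 0
    for i in range(1, N_STATES):
        for j in range(i):
            S[i, j] = S[j, i] = values[k]
            k += 1
    pi = np.array(values[k : k + N_STATES])
    pi = pi / pi.sum()
    return S, pi


def load_model(
    name: str = "LG",
    gamma_alpha: float | None = None,
    n_rate_categories: int = 4,
) -> SubstitutionModel:
    """Load a packaged model ('LG' or 'poisson') or a dat-file path."""
    lowered = name.lower()
    if lowered == "poisson":
        S = np.ones((N_STATES, N_STATES)) - np.eye(N_STATES)
        pi = np.full(N_STATES, 1.0 / N_STATES)
    elif lowered == "lg":
        ref = resources.files("epocflow.data").joinpath("lg.dat")
        with resources.as_file(ref) as p:
            S, pi = read_paml_dat(p)
    else:
        S, pi = read_paml_dat(name)
    return SubstitutionModel(
        S, pi, gamma_alpha=gamma_alpha, n_rate_categories=n_rate_categories,
        name=lowered,
    )
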