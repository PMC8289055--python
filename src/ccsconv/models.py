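"""JTT amino-acid substitution model with discrete-gamma rate heterogeneity.

The model is a general time-reversible 20-state Markov chain: rate matrix
Q_ij = s_ij * pi_j (i != j) with the symmetric JTT exchangeabilities s and
equilibrium frequencies pi, normalised so that branch lengths are expected
substitutions per site (-sum_i pi_i Q_ii = 1).  Rate variation across sites
follows a discrete gamma with shape alpha and k equal-probability
categories whose rates are the category means (Yang's mean method), so the
average rate is exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from ._jtt_data import AA_ORDER, JTT_EXCH_LOWER, JTT_FREQS

N_STATES = 20
AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}


def jtt_exchangeabilities() -> np.ndarray:
    """Symmetric 20x20 JTT exchangeability matrix (zero diagonal)."""
    s = np.zeros((N_STATES, N_STATES))
    for i, row in enumerate(JTT_EXCH_LOWER, start=1):
        for j, v in enumerate(row):
            s[i, j] = s[j, i] = v
    return s


def jtt_frequencies() -> np.ndarray:
    return np.array(JTT_FREQS, dtype=float)


def discrete_gamma_rates(alpha: float, k: int) -> np.ndarray:
    """Rates of the k equal-probability categories of a Gamma(alpha, alpha)
    distribution (mean 1), each rate being the mean of its category.

    The category mean between quantile boundaries b_i, b_{i+1} is
    k * [I(alpha+1, alpha*b_{i+1}) - I(alpha+1, alpha*b_i)] with I the
    regularised lower incomplete gamma function.
    """
    if alpha <= 0:
        raise ValueError(f"alpha must be > 0, got {alpha}")
    if k < 1:
        raise ValueError(f"need at least 1 rate category, got {k}")
    if k == 1:
        return np.ones(1)
    probs = np.arange(1, k) / k
    bounds = gamma_dist.ppf(probs, a=alpha, scale=1.0 / alpha)
    bounds = np.concatenate(([0.0], bounds, [np.inf]))
    upper = np.where(np.isinf(bounds[1:]), 1.0, gammainc(alpha + 1, alpha * bounds[1:]))
    lower = gammainc(alpha + 1, alpha * bounds[:-1])
    rates = k * (upper - lower)
    return rates / rates.mean()  # exact unit mean despite roundoff


@dataclass
class SubstitutionModel:
    """Reversible amino-acid rate matrix with gamma rate heterogeneity.

    Attributes
    ----------
    exchangeabilities : symmetric non-negative 20x20 matrix
    freqs : equilibrium frequencies pi (sum 1, all > 0)
    alpha : gamma shape parameter for rates across sites
    k : number of discrete gamma categories
    Q : normalised rate matrix (rows sum to 0, mean rate 1)
    rates : the k category rate multipliers (mean 1)
    """

    exchangeabilities: np.ndarray
    freqs: np.ndarray
    alpha: float
    k: int = 4
    Q: np.ndarray = field(init=False)
    rates: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        pi = np.asarray(self.freqs, dtype=float)
        if pi.shape != (N_STATES,):
            raise ValueError("frequencies must be a vector of 20 probabilities")
        if abs(pi.sum() - 1.0) > 1e-8:
            raise ValueError(f"frequencies sum to {pi.sum():.10f}, not 1")
        if np.any(pi <= 0):
            raise ValueError("all equilibrium frequencies must be > 0")
        if self.alpha <= 0:
            raise ValueError(f"alpha must be > 0, got {self.alpha}")
        s = np.asarray(self.exchangeabilities, dtype=float)
        if s.shape != (N_STATES, N_STATES) or not np.allclose(s, s.T):
            raise ValueError("exchangeabilities must be a symmetric 20x20 matrix")
        self.freqs = pi
        Q = s * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -(pi * np.diag(Q)).sum()
        self.Q = Q / mu
        self.rates = discrete_gamma_rates(self.alpha, self.k)
        # eigendecomposition of the symmetrised matrix for stable matrix
        # exponentials: S = D^{1/2} Q D^{-1/2} with D = diag(pi)
        sqrt_pi = np.sqrt(pi)
        S = self.Q * (sqrt_pi[:, None] / sqrt_pi[None, :])
        w, U = np.linalg.eigh((S + S.T) / 2.0)
        self._eigvals = w
        self._left = U.T * sqrt_pi[None, :]      # U^T D^{1/2}
        self._right = U / sqrt_pi[:, None]       # D^{-1/2} U

    def transition_matrix(self, t: float, rate: float = 1.0) -> np.ndarray:
        """P(t) = exp(Q * t * rate); rows sum to 1, entries in [0, 1]."""
        if t < 0:
            raise ValueError(f"branch length must be >= 0, got {t}")
        if rate < 0:
            raise ValueError(f"rate multiplier must be >= 0, got {rate}")
        P = (self._right * np.exp(self._eigvals * t * rate)) @ self._left
        np.clip(P, 0.0, 1.0, out=P)
        return P

    def transition_matrices(self, t: float) -> np.ndarray:
        """Stack of P(t * r) for every gamma category r, shape (k, 20, 20)."""
        return np.stack([self.transition_matrix(t, r) for r in self.rates])

    # -- serialisation ---------------------------------------------------

    def to_paramfile(self, path: str | Path) -> None:
        lines = [
            "model=JTT+G",
            f"alpha={self.alpha!r}",
            f"k={self.k}",
            "freqs=" + ",".join(repr(float(f)) for f in self.freqs),
        ]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_paramfile(cls, path: str | Path) -> "SubstitutionModel":
        kv = {}
        for line in Path(path).read_text().splitlines():
            if "=" in line:
                key, val = line.split("=", 1)
                kv[key.strip()] = val.strip()
        freqs = np.array([float(x) for x in kv["freqs"].split(",")])
        return build_model(freqs, alpha=float(kv["alpha"]), k=int(kv["k"]))


def build_model(
    freqs: np.ndarray | str = "jtt-default", alpha: float = 1.0, k: int = 4
) -> SubstitutionModel:
    """Build a JTT+Gamma model with the given (or the published default)
    equilibrium frequencies."""
    if isinstance(freqs, str):
        if freqs != "jtt-default":
            raise ValueError(f"unknown frequency keyword: {freqs!r}")
        pi = jtt_frequencies()
    else:
        pi = np.asarray(freqs, dtype=float)
    return SubstitutionModel(jtt_exchangeabilities(), pi, alpha, k)


def encode_residues(seq: str) -> np.ndarray:
    """Encode an amino-acid string as int8 indices into AA_ORDER; gap and
    'X' (missing data) become -1."""
    out = np.full(len(seq), -1, dtype=np.int8)
    for i, ch in enumerate(seq):
        out[i] = AA_INDEX.get(ch, -1)
    return out


def decode_residues(codes: np.ndarray) -> str:
    return "".join(AA_ORDER[c] if c >= 0 else "-" for c in codes)


def empirical_frequencies(counts: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Normalise observed residue counts to frequencies, flooring absent
    residues at *floor* so the reversible model stays well-defined."""
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (N_STATES,) or counts.sum() <= 0:
        raise ValueError("need a vector of 20 non-negative counts")
    pi = counts / counts.sum()
    pi = np.maximum(pi, floor)
    return pi / pi.sum()
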