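"""Reversible amino-acid substitution model (WAG) and transition probabilities.

The rate matrix is assembled as Q_ij = s_ij * pi_j from the published WAG
exchangeabilities and scaled so that the expected number of substitutions per
unit time is 1.  Transition matrices P(t) = exp(Qt) are computed through the
symmetric similarity transform diag(sqrt(pi)) Q diag(1/sqrt(pi)), which is
numerically exact for a reversible generator.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from .errors import DataError
from .seqio import AA_ALPHABET, AA_INDEX, GAP, ProteinAlignment

N_STATES = 20
#: pseudocount added per residue when estimating empirical frequencies
FREQ_PSEUDOCOUNT = 0.5


def load_wag() -> tuple[np.ndarray, np.ndarray]:
    """Published WAG exchangeabilities (20x20 symmetric) and frequencies."""
    text = resources.files("depolkit.data").joinpath("wag.dat").read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    S = np.zeros((N_STATES, N_STATES))
    for i, ln in enumerate(lines[:19], start=1):
        vals = [float(x) for x in ln.split()]
        if len(vals) != i:
            raise DataError(f"malformed WAG matrix row {i + 1}")
        S[i, : i] = vals
        S[: i, i] = vals
    pi = np.array([float(x) for x in lines[19].split()])
    if pi.shape != (N_STATES,):
        raise DataError("malformed WAG frequency line")
    return S, pi / pi.sum()


@dataclass(frozen=True)
class SubstitutionModel:
    """Scaled reversible rate matrix with its stationary distribution."""

    exchangeabilities: np.ndarray
    pi: np.ndarray
    Q: np.ndarray
    # eigendecomposition of the symmetrized generator, cached for P(t)
    _eigvals: np.ndarray
    _eigvecs: np.ndarray

    @property
    def n_states(self) -> int:
        return self.pi.shape[0]


def _assemble(S: np.ndarray, pi: np.ndarray) -> SubstitutionModel:
    if np.any(pi <= 0):
        raise DataError("equilibrium frequencies must be strictly positive")
    pi = pi / pi.sum()
    Q = S * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -np.sum(pi * np.diag(Q))  # mean instantaneous rate
    Q = Q / mu
    sqrt_pi = np.sqrt(pi)
    B = (sqrt_pi[:, None] * Q) / sqrt_pi[None, :]
    B = (B + B.T) / 2.0  # exact symmetry despite rounding
    eigvals, eigvecs = np.linalg.eigh(B)
    return SubstitutionModel(S, pi, Q, eigvals, eigvecs)


def empirical_frequencies(
    alignment: ProteinAlignment, pseudocount: float = FREQ_PSEUDOCOUNT
) -> np.ndarray:
    """Residue frequencies of an alignment, gaps excluded, never zero."""
    counts = np.full(N_STATES, pseudocount)
    for row in alignment.rows:
        for c in row:
            if c != GAP and c in AA_INDEX:
                counts[AA_INDEX[c]] += 1
    return counts / counts.sum()


def build_wag(
    frequencies_mode: str = "model",
    alignment: ProteinAlignment | None = None,
) -> SubstitutionModel:
    """WAG model with published ('model') or alignment-derived frequencies."""
    S, pi = load_wag()
    if frequencies_mode == "model":
        return _assemble(S, pi)
    if frequencies_mode == "empirical":
        if alignment is None:
            raise DataError("empirical frequency mode requires an alignment")
        return _assemble(S, empirical_frequencies(alignment))
    raise DataError(f"unknown frequencies_mode {frequencies_mode!r}")


def transition_matrix(model: SubstitutionModel, t: float) -> np.ndarray:
    """P(t) = exp(Qt); rows are renormalized only within 1e-10."""
    if t < 0:
        raise DataError(f"branch length must be non-negative, got {t}")
    sqrt_pi = np.sqrt(model.pi)
    U, lam = model._eigvecs, model._eigvals
    inner = (U * np.exp(lam * t)) @ U.T
    P = inner / sqrt_pi[:, None] * sqrt_pi[None, :]
    np.clip(P, 0.0, None, out=P)
    rowsum = P.sum(axis=1)
    if np.any(np.abs(rowsum - 1.0) > 1e-10):
        raise DataError("transition matrix rows deviate from 1 beyond 1e-10")
    return P / rowsum[:, None]


def discrete_gamma_rates(alpha: float, k: int) -> np.ndarray:
    """Mean rates of k equal-probability discrete-gamma classes (mean 1)."""
    from scipy.stats import gamma

    if alpha <= 0 or k < 1:
        raise DataError("gamma rate classes need alpha > 0 and k >= 1")
    edges = gamma.ppf(np.linspace(0, 1, k + 1), a=alpha, scale=1.0 / alpha)
    # mean of each slice via the incomplete-gamma identity
    upper = gamma.cdf(edges[1:], a=alpha + 1, scale=1.0 / alpha)
    lower = gamma.cdf(edges[:-1], a=alpha + 1, scale=1.0 / alpha)
    rates = (upper - lower) * k
    return rates / rates.mean()


def alphabet() -> str:
    return AA_ALPHABET
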