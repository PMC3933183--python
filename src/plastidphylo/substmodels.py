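"""Substitution models: GTR+G (nt), binary+G (RY), empirical WAG+G (AA).

All rate matrices are reversible, built as Q = S diag(pi) off-diagonal with
rows summing to zero, and rescaled so the expected substitution rate at
stationarity is 1 (branch lengths are then in expected substitutions per
site).  Among-site rate variation uses the discrete gamma approximation
with equal-probability categories represented by their means.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from .types import AA_G, BIN_G, GTR_G, PlastidPhyloError

NT_STATES = "ACGT"
RY_STATES = "RY"
#: PAML / phylogenetics convention for amino-acid state order.
AA_STATES = "ARNDCQEGHILKMFPSTWYV"

# WAG (Whelan & Goldman 2001) exchangeabilities, lower triangle
# column-major in AA_STATES order, and the accompanying equilibrium
# frequencies.
_WAG_LOWER = np.array([
    0.551571, 0.509848, 0.738998, 1.027040, 0.908598, 1.582850, 1.416720, 0.316954, 0.193335, 0.397915,
    0.906265, 0.893496, 0.210494, 1.438550, 3.370790, 2.121110, 0.113133, 0.240735, 2.006010, 0.635346,
    0.147304, 0.528191, 3.035500, 0.439157, 0.584665, 2.137150, 0.186979, 0.497671, 5.351420, 0.683162,
    0.102711, 0.679489, 1.224190, 0.554413, 1.163920, 0.381533, 0.251849, 5.429420, 0.265256, 1.543640,
    0.947198, 1.125560, 3.956290, 0.554236, 0.131528, 3.012010, 0.198221, 0.096162, 0.195081, 3.974230,
    2.030060, 0.071917, 1.086000, 0.196246, 0.030295, 0.616783, 6.174160, 0.865584, 0.930676, 0.039437,
    0.084805, 0.479855, 0.103754, 0.046730, 0.423984, 1.071760, 0.374866, 0.129767, 0.325711, 0.152335,
    0.098818, 0.021352, 0.306674, 0.248972, 0.170135, 0.384287, 0.074034, 0.390482, 0.398020, 0.109404,
    1.407660, 0.512984, 0.717070, 0.543833, 1.002140, 5.469470, 0.330052, 4.294110, 0.113917, 0.869489,
    3.894900, 1.545260, 0.099921, 0.933372, 1.028870, 0.857928, 0.215737, 0.227710, 0.301281, 0.567717,
    0.570025, 0.127395, 0.154263, 2.584430, 0.315124, 0.081134, 0.682355, 0.704939, 0.822765, 0.156557,
    0.196303, 0.588731, 0.249410, 0.030450, 0.061304, 0.373558, 0.174100, 0.049931, 0.243570, 1.341820,
    0.225833, 0.336983, 0.103604, 0.187247, 0.138190, 0.499462, 0.890432, 0.404141, 0.679371, 0.696198,
    0.740169, 0.473307, 0.262569, 3.873440, 0.118358, 3.170970, 0.323832, 4.257460, 1.059470, 0.099929,
    0.319440, 1.458160, 0.212483, 0.420170, 7.821300, 0.257555, 4.854020, 2.115170, 0.415844, 0.344739,
    0.326622, 0.665309, 0.398618, 1.800340, 0.934276, 0.088836, 0.556896, 0.967130, 1.386980, 0.137505,
    0.133264, 0.305434, 1.190630, 0.171329, 0.493905, 1.516120, 0.515706, 0.428437, 2.058450, 0.161444,
    0.545931, 0.171903, 1.529640, 6.454280, 0.649892, 1.613280, 0.795384, 0.139405, 0.216046, 0.314887,
    4.378020, 0.523742, 0.786993, 0.232739, 0.110864, 0.291148, 1.388230, 2.485390, 0.365369, 0.314730,
])

WAG_FREQS = np.array([
    0.086628, 0.043972, 0.039089, 0.057045, 0.019308,
    0.036728, 0.058059, 0.083252, 0.024431, 0.048466,
    0.086209, 0.062029, 0.019503, 0.038432, 0.045763,
    0.069518, 0.061013, 0.014386, 0.035274, 0.070896,
])
WAG_FREQS = WAG_FREQS / WAG_FREQS.sum()


def _wag_exchangeabilities() -> np.ndarray:
    s = np.zeros((20, 20))
    k = 0
    for j in range(19):          # column-major lower triangle
        for i in range(j + 1, 20):
            s[i, j] = s[j, i] = _WAG_LOWER[k]
            k += 1
    return s


WAG_EXCHANGE = _wag_exchangeabilities()


@dataclass
class SubstitutionModel:
    """A reversible substitution model with discrete-gamma rate variation.

    ``exchangeabilities`` is the symmetric relative-rate matrix S (with an
    arbitrary scale); ``freqs`` the stationary state frequencies; ``alpha``
    the gamma shape; ``ncat`` the number of discrete rate categories.
    """

    family: str
    exchangeabilities: np.ndarray
    freqs: np.ndarray
    alpha: float = 1.0
    ncat: int = 4

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.exchangeabilities = np.asarray(self.exchangeabilities, dtype=float)
        if (self.freqs <= 0).any():
            raise PlastidPhyloError("state frequencies must be positive")
        self.freqs = self.freqs / self.freqs.sum()
        if self.alpha <= 0:
            raise PlastidPhyloError(f"gamma shape must be > 0, got {self.alpha}")

    @property
    def n_states(self) -> int:
        return len(self.freqs)

    def with_(self, **kw) -> "SubstitutionModel":
        data = {
            "family": self.family,
            "exchangeabilities": self.exchangeabilities.copy(),
            "freqs": self.freqs.copy(),
            "alpha": self.alpha,
            "ncat": self.ncat,
        }
        data.update(kw)
        return SubstitutionModel(**data)


def gtr_model(
    exchangeabilities: Optional[np.ndarray] = None,
    freqs: Optional[np.ndarray] = None,
    alpha: float = 1.0,
    ncat: int = 4,
) -> SubstitutionModel:
    """GTR+G over ACGT.  ``exchangeabilities`` are the 6 upper-triangle
    rates in order AC, AG, AT, CG, CT, GT (GT conventionally fixed to 1)."""
    if exchangeabilities is None:
        exchangeabilities = np.ones(6)
    exch = np.asarray(exchangeabilities, dtype=float)
    if exch.shape == (6,):
        s = np.zeros((4, 4))
        s[0, 1] = s[1, 0] = exch[0]  # A-C
        s[0, 2] = s[2, 0] = exch[1]  # A-G
        s[0, 3] = s[3, 0] = exch[2]  # A-T
        s[1, 2] = s[2, 1] = exch[3]  # C-G
        s[1, 3] = s[3, 1] = exch[4]  # C-T
        s[2, 3] = s[3, 2] = exch[5]  # G-T
    else:
        s = exch
    if freqs is None:
        freqs = np.full(4, 0.25)
    return SubstitutionModel(GTR_G, s, freqs, alpha, ncat)


def bin_model(freq_r: float = 0.5, alpha: float = 1.0, ncat: int = 4) -> SubstitutionModel:
    """Two-state (R/Y) reversible model with gamma rates."""
    if not (0 < freq_r < 1):
        raise PlastidPhyloError("freq_r must be in (0, 1)")
    s = np.array([[0.0, 1.0], [1.0, 0.0]])
    return SubstitutionModel(BIN_G, s, np.array([freq_r, 1 - freq_r]), alpha, ncat)


def wag_model(
    freqs: Optional[np.ndarray] = None, alpha: float = 1.0, ncat: int = 4
) -> SubstitutionModel:
    """WAG+G with model (or supplied empirical) amino-acid frequencies."""
    if freqs is None:
        freqs = WAG_FREQS.copy()
    return SubstitutionModel(AA_G, WAG_EXCHANGE.copy(), freqs, alpha, ncat)


def discrete_gamma(alpha: float, ncat: int = 4) -> tuple[np.ndarray, np.ndarray]:
    """Equal-probability discrete gamma categories represented by their means.

    Returns ``(rates, probs)`` with sum(probs * rates) == 1 exactly (the
    category means are renormalised to mean one, removing residual
    quadrature error).
    """
    if alpha <= 0:
        raise PlastidPhyloError(f"gamma shape must be > 0, got {alpha}")
    if ncat < 1:
        raise PlastidPhyloError("need at least one rate category")
    if ncat == 1:
        return np.ones(1), np.ones(1)
    # X ~ Gamma(shape=alpha, rate=alpha), mean 1.  Mean of each
    # equal-probability bin via the incomplete-gamma identity:
    # E[X; X<q] = CDF_{alpha+1}(q) (for the mean-1 parameterisation).
    probs = np.full(ncat, 1.0 / ncat)
    edges = stats.gamma.ppf(np.linspace(0, 1, ncat + 1), alpha, scale=1.0 / alpha)
    upper = stats.gamma.cdf(edges[1:], alpha + 1, scale=1.0 / alpha)
    lower = stats.gamma.cdf(edges[:-1], alpha + 1, scale=1.0 / alpha)
    rates = (upper - lower) * ncat
    rates = rates / (rates @ probs)
    return rates, probs


def rate_matrix(model: SubstitutionModel) -> np.ndarray:
    """Scaled reversible rate matrix Q = S diag(pi), mean rate 1."""
    pi = model.freqs
    if (pi <= 0).any():
        raise PlastidPhyloError("non-positive frequency")
    q = model.exchangeabilities * pi[np.newaxis, :]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    scale = -(pi * np.diag(q)).sum()
    if scale <= 0:
        raise PlastidPhyloError("degenerate rate matrix")
    return q / scale


@dataclass
class _Eigen:
    """Eigendecomposition of a reversible Q for fast P(t) = exp(Qt)."""

    vals: np.ndarray
    left: np.ndarray   # rows: pi^{1/2}-weighted eigenvectors
    right: np.ndarray

    def transition_matrix(self, t: float) -> np.ndarray:
        p = (self.right * np.exp(self.vals * t)) @ self.left
        return np.clip(p, 0.0, None)


def eigen_decompose(model: SubstitutionModel) -> _Eigen:
    q = rate_matrix(model)
    pi = model.freqs
    d = np.sqrt(pi)
    b = (q * d[:, None]) / d[None, :]       # symmetric similar matrix
    vals, vecs = np.linalg.eigh((b + b.T) / 2)
    right = vecs / d[:, None]
    left = vecs.T * d[None, :]
    return _Eigen(vals=vals, left=left, right=right)


def transition_matrix(model: SubstitutionModel, t: float) -> np.ndarray:
    """P(t) = exp(Qt) for the scaled rate matrix."""
    if t < 0:
        raise PlastidPhyloError("negative branch length")
    return eigen_decompose(model).transition_matrix(t)
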