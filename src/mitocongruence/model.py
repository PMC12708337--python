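"""TIM2+G+I substitution model.

TIM2 is the GTR submodel with exchangeability constraints AC = AT and
CG = GT, leaving the two transition classes (AG, CT) and two
transversion classes free.  Rate heterogeneity combines a discrete
(mean-of-quartile) gamma with a proportion of invariant sites.

The generator is normalized to one expected substitution per unit time
over the variable fraction; no additional ``1/(1-pinv)`` rescale is
applied, so simulated and inferred branch lengths share one convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import gammainc, gammaincinv

BASES = "ACGT"


@dataclass
class ModelParams:
    """Parameters of TIM2+G+I.

    ``r_ac_at`` is the AC=AT transversion class (conventionally fixed to
    1 for identifiability), ``r_cg_gt`` the other transversion class,
    ``r_ag`` and ``r_ct`` the two transition classes.
    """

    r_ac_at: float = 1.0
    r_ag: float = 4.0
    r_cg_gt: float = 1.0
    r_ct: float = 4.0
    freqs: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    alpha: float = 1.0
    pinv: float = 0.0
    ncat: int = 4

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        for name in ("r_ac_at", "r_ag", "r_cg_gt", "r_ct"):
            if getattr(self, name) <= 0:
                raise ValueError(f"rate class {name} must be > 0")
        if self.freqs.shape != (4,) or np.any(self.freqs <= 0):
            raise ValueError("freqs must be 4 positive numbers")
        if abs(self.freqs.sum() - 1.0) > 1e-8:
            raise ValueError("freqs must sum to 1")
        self.freqs = self.freqs / self.freqs.sum()
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if not (0 <= self.pinv <= 1):
            raise ValueError("pinv must be in [0, 1]")
        if self.ncat < 1:
            raise ValueError("ncat must be >= 1")

    def exchangeabilities(self) -> np.ndarray:
        """Symmetric 4x4 matrix of s_ij under the TIM2 constraints."""
        a, b, c, d = self.r_ac_at, self.r_ag, self.r_cg_gt, self.r_ct
        s = np.zeros((4, 4))
        # order A, C, G, T
        s[0, 1] = s[1, 0] = a  # AC
        s[0, 2] = s[2, 0] = b  # AG (transition)
        s[0, 3] = s[3, 0] = a  # AT (= AC)
        s[1, 2] = s[2, 1] = c  # CG
        s[1, 3] = s[3, 1] = d  # CT (transition)
        s[2, 3] = s[3, 2] = c  # GT (= CG)
        return s

    def with_(self, **kw) -> "ModelParams":
        return replace(self, **kw)


def build_rate_matrix(params: ModelParams) -> np.ndarray:
    """Reversible generator Q with q_ij = s_ij * pi_j, rows summing to
    zero, scaled so the expected substitution rate at stationarity is 1.
    """
    s = params.exchangeabilities()
    pi = params.freqs
    q = s * pi[None, :]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    mu = -float(np.dot(pi, np.diag(q)))
    return q / mu


def gamma_categories(alpha: float, ncat: int) -> tuple[np.ndarray, np.ndarray]:
    """Discrete gamma rates with equal weights (mean-of-quartile rule).

    Category boundaries are the ``i/ncat`` quantiles of Gamma(alpha,
    alpha); each category rate is the conditional mean within its
    quantile band, so the weighted mean rate is exactly 1.
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    if ncat < 1:
        raise ValueError("ncat must be >= 1")
    if ncat == 1:
        return np.array([1.0]), np.array([1.0])
    probs = np.arange(1, ncat) / ncat
    # boundaries of Gamma(shape=alpha, rate=alpha)
    bounds = gammaincinv(alpha, probs) / alpha
    upper = np.concatenate([bounds, [np.inf]])
    lower = np.concatenate([[0.0], bounds])
    # E[X | a < X < b] * P(a < X < b) = I(b; alpha+1) - I(a; alpha+1)
    # for Gamma(alpha, rate alpha) with mean 1
    cdf_hi = np.where(np.isinf(upper), 1.0, gammainc(alpha + 1, upper * alpha))
    cdf_lo = gammainc(alpha + 1, lower * alpha)
    rates = (cdf_hi - cdf_lo) * ncat
    weights = np.full(ncat, 1.0 / ncat)
    return rates, weights


class EigenSystem:
    """Eigendecomposition of a reversible Q for fast P(t) evaluation.

    Uses the symmetrization ``B = D^{1/2} Q D^{-1/2}`` with
    ``D = diag(pi)`` so eigenvalues are real and the decomposition is
    numerically stable.
    """

    def __init__(self, q: np.ndarray, pi: np.ndarray):
        sq = np.sqrt(pi)
        b = (q * sq[:, None]) / sq[None, :]
        b = 0.5 * (b + b.T)
        vals, vecs = np.linalg.eigh(b)
        self.vals = vals
        # P(t) = D^{-1/2} V exp(L t) V^T D^{1/2}
        self.u = (1.0 / sq)[:, None] * vecs
        self.uinv = vecs.T * sq[None, :]

    def p_matrix(self, t: float) -> np.ndarray:
        e = np.exp(self.vals * t)
        p = (self.u * e[None, :]) @ self.uinv
        return np.clip(p, 0.0, None)

    def p_matrices(self, ts: np.ndarray) -> np.ndarray:
        """P for a vector of rate-scaled times; shape (len(ts), 4, 4)."""
        ts = np.asarray(ts, dtype=float)
        e = np.exp(np.multiply.outer(ts, self.vals))  # (k, 4)
        p = np.matmul(self.u[None, :, :] * e[:, None, :], self.uinv)
        return np.clip(p, 0.0, None)


def transition_probabilities(
    q: np.ndarray, t: float, r: float = 1.0,
    pi: np.ndarray | None = None,
) -> np.ndarray:
    """Stochastic matrix P = exp(Q t r)."""
    if t < 0:
        raise ValueError("branch length must be >= 0")
    if pi is None:
        # stationary distribution from the generator's left null vector
        vals, vecs = np.linalg.eig(q.T)
        k = int(np.argmin(np.abs(vals)))
        pi = np.real(vecs[:, k])
        pi = pi / pi.sum()
    eig = EigenSystem(q, np.asarray(pi, dtype=float))
    p = eig.p_matrix(t * r)
    return p / p.sum(axis=1, keepdims=True)


def jc_params(ncat: int = 1, alpha: float = 1.0, pinv: float = 0.0) -> ModelParams:
    """TIM2 parameters collapsed to Jukes-Cantor."""
    return ModelParams(
        r_ac_at=1.0, r_ag=1.0, r_cg_gt=1.0, r_ct=1.0,
        freqs=np.full(4, 0.25), alpha=alpha, pinv=pinv, ncat=ncat,
    )
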