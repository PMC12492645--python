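"""Delete-block jackknife inference and the joint Mahalanobis test.

The variance–covariance matrix of the moment estimates is obtained by the
delete-group jackknife over contiguous groups of genomic LD blocks: the full
estimation chain is re-run with each group removed, and the usual
delete-group covariance

    Σ̂ = (g - 1)/g · Σ_k (θ̂_(k) - θ̄)(θ̂_(k) - θ̄)ᵀ

is formed from the leave-group-out estimates θ̂_(k).

The joint test of the bivariate vector V = (h_I², ρ_IG) against zero uses
the squared Mahalanobis distance d² = V̂ᵀ Σ̂⁻¹ V̂.  With many jackknife
groups d² is referred to a χ²(2) distribution; with few groups Σ̂ is itself
noisy, and the default applies the Hotelling small-sample correction,
referring d²·(g-2)/(2(g-1)) to F(2, g-2), which converges to the χ²(2)
reference as g grows.  Univariate Wald tests likewise use a t reference
with g-1 degrees of freedom when the group count is supplied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import stats

from .estimators import MomentTable

logger = logging.getLogger(__name__)

__all__ = [
    "JackknifeResult",
    "JointTestResult",
    "jackknife",
    "joint_test",
    "wald_test",
    "prs_by_e_ratio",
]

DEFAULT_MAX_GROUPS = 200
_COND_LIMIT = 1e12


@dataclass
class JackknifeResult:
    """Point estimates with delete-group jackknife uncertainty."""

    point: dict[str, float]
    leave_out: list[dict[str, float]]
    sigma_hat: np.ndarray  # 2x2 covariance of (h2i, rho_ig)
    se: dict[str, float]
    n_groups: int
    excluded_groups: list[int] = field(default_factory=list)

    @property
    def v_hat(self) -> np.ndarray:
        return np.array([self.point["h2i"], self.point["rho_ig"]])


def _assign_groups(block_ids: np.ndarray, n_groups: int) -> list[np.ndarray]:
    """Contiguous (genome-order) groups of blocks, as row masks."""
    unique_blocks = list(dict.fromkeys(block_ids.tolist()))
    if n_groups > len(unique_blocks):
        raise ValueError(
            f"n_groups={n_groups} exceeds the {len(unique_blocks)} available blocks"
        )
    chunks = np.array_split(np.array(unique_blocks), n_groups)
    return [np.isin(block_ids, chunk) for chunk in chunks]


def _shrink_offdiagonal(dev: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Schäfer–Strimmer shrinkage of the 2×2 covariance's correlation.

    With few jackknife groups the off-diagonal of Σ̂ is dominated by
    sampling noise, which fattens the tail of the Mahalanobis statistic.
    The standard remedy shrinks the correlation toward zero with the
    data-driven intensity λ = Var̂(r̂)/r̂² (capped at 1), leaving the
    variances untouched.
    """
    g = dev.shape[0]
    sd = dev.std(axis=0, ddof=1)
    if np.any(sd == 0):
        return cov
    xs = dev / sd
    w = xs[:, 0] * xs[:, 1]
    r = w.sum() / (g - 1)
    if r == 0:
        return cov
    var_r = g / (g - 1) ** 3 * ((w - w.mean()) ** 2).sum()
    lam = min(1.0, max(0.0, var_r / r**2))
    out = cov.copy()
    out[0, 1] = out[1, 0] = (1.0 - lam) * r * np.sqrt(cov[0, 0] * cov[1, 1])
    return out


def jackknife(
    moments: MomentTable,
    estimator: Callable[[MomentTable], Mapping[str, float]],
    n_groups: int | None = None,
    joint_keys: tuple[str, str] = ("h2i", "rho_ig"),
    shrink_corr: bool = True,
) -> JackknifeResult:
    """Delete-group jackknife over contiguous groups of LD blocks.

    ``estimator`` maps a (possibly row-restricted) moment table to a flat
    dict of parameter estimates.  Deletions that fail (degenerate designs)
    are excluded with a warning; fewer than two usable groups is an error.
    ``shrink_corr`` applies Schäfer–Strimmer shrinkage to the off-diagonal
    of the joint 2×2 covariance (recommended whenever the group count is
    small); standard errors are always taken from the raw diagonal.
    """
    if n_groups is None:
        n_blocks = len(set(moments.block_ids.tolist()))
        n_groups = min(DEFAULT_MAX_GROUPS, n_blocks)
    if n_groups < 2:
        raise ValueError("need at least 2 jackknife groups")
    point = dict(estimator(moments))
    keys = [
        k
        for k, v in point.items()
        if isinstance(v, (int, float)) and not isinstance(v, bool)
    ]
    masks = _assign_groups(moments.block_ids, n_groups)
    leave_out: list[dict[str, float]] = []
    excluded: list[int] = []
    for k, mask in enumerate(masks):
        try:
            est = dict(estimator(moments.subset(~mask)))
        except Exception as exc:  # degenerate deletion
            logger.warning("jackknife group %d excluded: %s", k, exc)
            excluded.append(k)
            continue
        leave_out.append(est)
    g = len(leave_out)
    if g < 2:
        raise ValueError("fewer than 2 usable jackknife groups")
    theta = np.array([[lo[k] for k in keys] for lo in leave_out], dtype=float)
    center = theta.mean(axis=0)
    dev = theta - center
    cov_full = (g - 1) / g * dev.T @ dev
    se = {k: float(np.sqrt(cov_full[i, i])) for i, k in enumerate(keys)}
    idx = [keys.index(joint_keys[0]), keys.index(joint_keys[1])]
    sigma_hat = cov_full[np.ix_(idx, idx)]
    if shrink_corr:
        sigma_hat = _shrink_offdiagonal(dev[:, idx], sigma_hat)
    return JackknifeResult(
        point=point,
        leave_out=leave_out,
        sigma_hat=sigma_hat,
        se=se,
        n_groups=g,
        excluded_groups=excluded,
    )


@dataclass
class JointTestResult:
    d2: float
    df: int
    p: float
    reference: str


_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(101)


def _p_sum_two_t_squares(c: float, df: int) -> float:
    """Upper tail P(T₁² + T₂² > c) for independent T_i ~ t(df).

    The small-sample reference for the Mahalanobis statistic when the 2×2
    covariance has noisy (chi-square, df-degree) variance estimates and a
    shrunken off-diagonal: after whitening, the statistic behaves as a sum
    of two independent squared t variables, which converges to χ²(2) as df
    grows.  Evaluated by Gauss–Legendre quadrature.
    """
    if c <= 0:
        return 1.0
    lim = np.sqrt(c)
    u = lim * _GL_NODES
    rem = np.maximum(c - u**2, 0.0)
    inner = stats.t.pdf(u, df) * 2.0 * stats.t.sf(np.sqrt(rem), df)
    inside = lim * float(_GL_WEIGHTS @ inner)
    return min(1.0, inside + 2.0 * float(stats.t.sf(lim, df)))


def joint_test(
    v: Sequence[float],
    sigma_hat: np.ndarray,
    n_groups: int | None = None,
    reference: str = "auto",
) -> JointTestResult:
    """Joint Mahalanobis test of (h_I², ρ_IG) = (0, 0).

    ``reference="chisq"`` uses the asymptotic χ²(2) tail.  With few
    jackknife groups g the covariance estimate is noisy and a small-sample
    reference is needed: ``"f"`` (the default when a group count is given)
    follows the Korn–Graubard convention for replicate-based Wald
    statistics, referring d²/2 to F(2, g-2); ``"t2sum"`` refers d² to the
    sum of two independent squared t(g-1) variables; ``"hotelling"``
    applies the classical T² scaling d²(g-2)/(2(g-1)) ~ F(2, g-2).  All
    three converge to χ²(2) as the group count grows; the F convention
    sits between the other two in tail weight.
    """
    v = np.asarray(v, dtype=float)
    sigma_hat = np.asarray(sigma_hat, dtype=float)
    if v.shape != (2,) or sigma_hat.shape != (2, 2):
        raise ValueError("joint test is bivariate: v is length-2, sigma 2x2")
    if np.linalg.cond(sigma_hat) > _COND_LIMIT:
        raise ValueError(
            "jackknife covariance is numerically singular; increase the "
            "number of jackknife groups"
        )
    d2 = float(v @ np.linalg.solve(sigma_hat, v))
    p_dim = 2
    if reference == "auto":
        reference = "f" if n_groups is not None else "chisq"
    if reference == "f":
        # Korn-Graubard convention for replicate-based Wald statistics:
        # W/p referred to F(p, d - p + 1) with design df d = g - 1
        if n_groups is None or n_groups <= p_dim:
            raise ValueError("F reference needs n_groups > 2")
        p = float(stats.f.sf(d2 / p_dim, p_dim, n_groups - p_dim))
    elif reference == "t2sum":
        if n_groups is None or n_groups <= p_dim:
            raise ValueError("t2sum reference needs n_groups > 2")
        p = _p_sum_two_t_squares(d2, n_groups - 1)
    elif reference == "hotelling":
        if n_groups is None or n_groups <= p_dim:
            raise ValueError("hotelling reference needs n_groups > 2")
        f_stat = d2 * (n_groups - p_dim) / (p_dim * (n_groups - 1))
        p = float(stats.f.sf(f_stat, p_dim, n_groups - p_dim))
    elif reference == "chisq":
        p = float(stats.chi2.sf(d2, p_dim))
    else:
        raise ValueError(f"unknown reference {reference!r}")
    return JointTestResult(d2=d2, df=p_dim, p=max(p, np.finfo(float).tiny), reference=reference)


def wald_test(
    estimate: float,
    se: float,
    df: int | None = None,
    alternative: str = "two-sided",
) -> float:
    """Wald p-value for a single parameter against zero.

    Uses a normal reference, or Student t with ``df`` degrees of freedom when
    given (appropriate for jackknife SEs from few groups).  Variance
    components can legitimately go negative under moment estimation, so the
    default is two-sided; ``alternative="greater"`` gives the one-sided test.
    """
    if se <= 0:
        raise ValueError("standard error must be positive")
    z = estimate / se
    dist = stats.t(df) if df is not None else stats.norm
    if alternative == "two-sided":
        p = 2.0 * dist.sf(abs(z))
    elif alternative == "greater":
        p = dist.sf(z)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return float(min(max(p, np.finfo(float).tiny), 1.0))


def prs_by_e_ratio(rho_ig: float, h2g: float) -> float:
    """Expected PRS-by-E regression coefficient under a perfectly fitted PRS.

    In the regression Y ~ PRS + E + PRS·E with an oracle (true-effect) PRS,
    the interaction coefficient has expectation ρ_IG / h_g².
    """
    if h2g <= 0:
        raise ValueError("h2g must be positive to form the PRS-by-E ratio")
    return float(rho_ig / h2g)
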