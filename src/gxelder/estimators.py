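"""Moment-condition estimators on whitened Z-score products.

Under the polygenic random-effects model, after whitening each LD block
(``z̃ = D^(-1/2) Uᵀ z``), the expected per-eigencomponent products are linear
in the eigenvalue ``D_jj``:

* GWAS squares:      E[z̃_G,j²]      = N_G h_g² D_jj / M + 1
* GWIS squares:      E[z̃_I,j²]      = N_I h_I² D_jj / M + 1 + 2(h_I² + σ₁²)
* GWAS×GWIS product: E[z̃_G,j z̃_I,j] = √(N_G N_I) ρ_IG D_jj / M + intercept

where M is the variant count, h_g² the narrow-sense heritability, h_I² the
G×E interaction proportion, σ₁² the residual-interaction variance, and ρ_IG
the G×E genetic covariance.  The cross-product intercept absorbs sample
overlap between the two scans (2 N_S (ρ_IG + ρ₀₁) / √(N_G N_I)), so the
overlap never needs to be known: it cannot move the slope.

Each parameter is the slope of a weighted regression of products on
eigenvalues.  The weights are inverse variances of the products,
``w_j = min(D_jj, 1) / T_jj`` with

    T_jj = (D_jj N_G h_g²/M + 1)(D_jj N_I h_I²/M + 1 + 2(h_I² + σ₁²))
           + (√(N_G N_I) ρ_IG D_jj/M + intercept)²,

the ``min(D_jj, 1)`` factor down-weighting large-eigenvalue components whose
products are noisy.  h_g², then (h_I², σ₁²) are estimated first with their
own marginal weights; ρ_IG follows by iteratively reweighted least squares
with those plug-ins held fixed.

The diagonal-LD baseline regresses raw per-variant products on LD scores
(the diagonal of R²), which uses only partial LD information; it is retained
as the efficiency comparator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .ld import EigenBlock
from .sumstats import HarmonizedPair

__all__ = [
    "MomentTable",
    "EstimateSet",
    "build_moment_table",
    "weighted_moment_regression",
    "estimate_h2g",
    "estimate_h2i",
    "compute_weights",
    "estimate_rho_ig_irls",
    "estimate_all",
    "baseline_h2",
    "baseline_cross_slope",
    "baseline_ldsc_rho_ig",
]

DEFAULT_MAX_ITER = 10
DEFAULT_RTOL = 1e-6
_PLUGIN_ITER = 3  # reweighting passes for the marginal (squares) regressions


@dataclass
class MomentTable:
    """Per-eigencomponent regressors and whitened Z-score products.

    One row per retained eigencomponent across all blocks.  ``d`` holds the
    eigenvalues (the regressors); ``products`` maps a channel name
    (``"gg"``, ``"ii"``, ``"gi"``, optionally ``"ee"``, ``"ei"``, ``"ge"``)
    to the matching componentwise product of whitened Z vectors.  ``M`` is
    the harmonized variant count entering the moment conditions.
    """

    d: np.ndarray
    block_ids: np.ndarray
    products: dict[str, np.ndarray]
    M: int
    n_g: float
    n_i: float
    n_e: float | None = None

    def __post_init__(self) -> None:
        if np.any(self.d <= 0):
            raise ValueError("eigenvalue regressors must be positive")
        for name, y in self.products.items():
            if y.shape != self.d.shape:
                raise ValueError(f"product channel {name!r} length mismatch")
        if self.M <= 0:
            raise ValueError("M must be positive")

    def __len__(self) -> int:
        return self.d.shape[0]

    def subset(self, row_mask: np.ndarray) -> "MomentTable":
        """Row-restricted view (used by the delete-group jackknife)."""
        return replace(
            self,
            d=self.d[row_mask],
            block_ids=self.block_ids[row_mask],
            products={k: v[row_mask] for k, v in self.products.items()},
        )


def build_moment_table(
    pair: HarmonizedPair, eigenblocks: Sequence[EigenBlock]
) -> MomentTable:
    """Whiten the harmonized Z vectors blockwise and form diagonal products."""
    from .ld import transform_z

    ref_ids: list[str] = []
    for eb in eigenblocks:
        ref_ids.extend(eb.variant_ids)
    if ref_ids != list(pair.variant_ids):
        raise ValueError(
            "variant ordering of the harmonized pair does not match the "
            "eigen-decomposed LD reference; subset the reference to the "
            "harmonized variants first"
        )
    vectors = {"g": pair.z_g, "i": pair.z_i}
    if pair.z_e is not None:
        vectors["e"] = pair.z_e
    d_parts, bid_parts = [], []
    tz: dict[str, list[np.ndarray]] = {k: [] for k in vectors}
    offset = 0
    for eb in eigenblocks:
        sl = slice(offset, offset + eb.original_dim)
        offset += eb.original_dim
        d_parts.append(eb.eigenvalues)
        bid_parts.append(np.full(eb.retained_rank, eb.block_id))
        for k, z in vectors.items():
            tz[k].append(transform_z(eb, z[sl]))
    t = {k: np.concatenate(v) for k, v in tz.items()}
    products = {"gg": t["g"] * t["g"], "ii": t["i"] * t["i"], "gi": t["g"] * t["i"]}
    if "e" in t:
        products["ee"] = t["e"] * t["e"]
        products["ei"] = t["e"] * t["i"]
        products["ge"] = t["g"] * t["e"]
    return MomentTable(
        d=np.concatenate(d_parts),
        block_ids=np.concatenate(bid_parts),
        products=products,
        M=pair.m,
        n_g=pair.n_g,
        n_i=pair.n_i,
        n_e=pair.n_e,
    )


def weighted_moment_regression(
    x: np.ndarray, y: np.ndarray, w: np.ndarray
) -> tuple[float, float]:
    """Weighted least-squares fit of ``y`` on ``(x, 1)``: (slope, intercept)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    w = np.asarray(w, float)
    if x.shape != y.shape or x.shape != w.shape:
        raise ValueError("x, y, w must have identical shapes")
    if np.any(w <= 0):
        raise ValueError("weights must be strictly positive")
    if x.size < 2 or np.ptp(x) == 0:
        raise ValueError("degenerate design: need >= 2 distinct x values")
    sw = w.sum()
    xbar = (w * x).sum() / sw
    ybar = (w * y).sum() / sw
    sxx = (w * (x - xbar) ** 2).sum()
    sxy = (w * (x - xbar) * (y - ybar)).sum()
    slope = sxy / sxx
    return float(slope), float(ybar - slope * xbar)


def _marginal_factor_g(d: np.ndarray, h2g: float, N_g: float, M: int) -> np.ndarray:
    return d * N_g * max(h2g, 0.0) / M + 1.0

def _marginal_factor_i(
    d: np.ndarray, h2i: float, sigma1sq: float, N_i: float, M: int
) -> np.ndarray:
    h2i_p = max(h2i, 0.0)
    return d * N_i * h2i_p / M + 1.0 + 2.0 * (h2i_p + max(sigma1sq, 0.0))


def estimate_h2g(
    moments: MomentTable, N_g: float | None = None, M: int | None = None
) -> tuple[float, float]:
    """Narrow-sense heritability from the GWAS-squares channel.

    Regression of z̃_G² on D; h_g² = slope·M/N_G.  The intercept is ≈1 absent
    confounding.  Weights are refreshed from the current estimate over a few
    passes (variance of a squared Gaussian is twice its squared mean).
    """
    N_g = moments.n_g if N_g is None else N_g
    M = moments.M if M is None else M
    d, y = moments.d, moments.products["gg"]
    h2g = 0.0
    for _ in range(_PLUGIN_ITER):
        w = np.minimum(d, 1.0) / _marginal_factor_g(d, h2g, N_g, M) ** 2
        slope, intercept = weighted_moment_regression(d, y, w)
        h2g = slope * M / N_g
    return float(h2g), float(intercept)


def estimate_h2i(
    moments: MomentTable, N_i: float | None = None, M: int | None = None
) -> tuple[float, float, float]:
    """G×E interaction proportion and residual-interaction variance.

    Regression of z̃_I² on D; h_I² = slope·M/N_I.  The intercept equals
    1 + 2(h_I² + σ₁²), from which σ₁² is solved given h_I².  Returns
    (h2i, sigma1sq, intercept); the raw (possibly negative) values are
    reported — clipping happens only inside weight construction.
    """
    N_i = moments.n_i if N_i is None else N_i
    M = moments.M if M is None else M
    d, y = moments.d, moments.products["ii"]
    h2i, sigma1sq = 0.0, 0.0
    for _ in range(_PLUGIN_ITER):
        w = np.minimum(d, 1.0) / _marginal_factor_i(d, h2i, sigma1sq, N_i, M) ** 2
        slope, intercept = weighted_moment_regression(d, y, w)
        h2i = slope * M / N_i
        sigma1sq = (intercept - 1.0) / 2.0 - h2i
    return float(h2i), float(sigma1sq), float(intercept)


def compute_weights(
    d: np.ndarray,
    h2g: float,
    h2i: float,
    sigma1sq: float,
    rho_ig: float,
    fitted_gi_intercept: float,
    N_g: float,
    N_i: float,
    M: int,
) -> np.ndarray:
    """Optimal regression weights ``min(D_jj, 1) / T_jj`` for the cross channel.

    ``T_jj`` is proportional to the variance of the transformed Z-score
    product; the sample-overlap term is represented by the currently fitted
    cross-regression intercept, so the overlap itself need not be known.
    Variance plug-ins are clipped at zero inside ``T`` only.
    """
    d = np.asarray(d, float)
    mean_term = np.sqrt(N_g * N_i) * rho_ig * d / M + fitted_gi_intercept
    T = (
        _marginal_factor_g(d, h2g, N_g, M)
        * _marginal_factor_i(d, h2i, sigma1sq, N_i, M)
        + mean_term**2
    )
    if np.any(T <= 0):
        raise ValueError("nonpositive product variance T_jj: invalid plug-ins")
    return np.minimum(d, 1.0) / T


@dataclass
class IRLSResult:
    rho_ig: float
    intercept: float
    n_iter: int
    converged: bool


def estimate_rho_ig_irls(
    moments: MomentTable,
    h2g: float,
    h2i: float,
    sigma1sq: float,
    N_g: float | None = None,
    N_i: float | None = None,
    M: int | None = None,
    max_iter: int = DEFAULT_MAX_ITER,
    rtol: float = DEFAULT_RTOL,
) -> IRLSResult:
    """G×E genetic covariance by iteratively reweighted least squares.

    Alternates weight construction and WLS of z̃_G·z̃_I on D, starting from
    ρ_IG = 0 and intercept 0, holding the pre-estimated h_g², h_I², σ₁²
    fixed.  ρ_IG = slope·M/√(N_G N_I).
    """
    N_g = moments.n_g if N_g is None else N_g
    N_i = moments.n_i if N_i is None else N_i
    M = moments.M if M is None else M
    d, y = moments.d, moments.products["gi"]
    rho, a = 0.0, 0.0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        w = compute_weights(d, h2g, h2i, sigma1sq, rho, a, N_g, N_i, M)
        slope, a_new = weighted_moment_regression(d, y, w)
        rho_new = slope * M / np.sqrt(N_g * N_i)
        scale = max(abs(rho_new), abs(a_new), 1e-12)
        if max(abs(rho_new - rho), abs(a_new - a)) <= rtol * scale:
            rho, a = rho_new, a_new
            converged = True
            break
        rho, a = rho_new, a_new
    return IRLSResult(float(rho), float(a), it, converged)


@dataclass
class EstimateSet:
    """Point estimates from one run of the moment-condition chain.

    Moment estimates are unbounded, so variance components may come out
    negative; they are reported raw.  ``r_ig`` (the G×E genetic correlation
    ρ_IG/√(h_g²·h_I²)) is defined only when both variance components are
    positive.
    """

    h2g: float
    h2i: float
    sigma1sq: float
    rho_ig: float
    intercepts: dict[str, float]
    M: int
    n_g: float
    n_i: float
    converged: bool = True
    n_iter: int = 0
    warnings: list[str] = field(default_factory=list)

    @property
    def r_ig(self) -> float | None:
        if self.h2g > 0 and self.h2i > 0:
            return self.rho_ig / np.sqrt(self.h2g * self.h2i)
        return None

    def as_dict(self) -> dict:
        out = {
            "h2g": self.h2g,
            "h2i": self.h2i,
            "sigma1sq": self.sigma1sq,
            "rho_ig": self.rho_ig,
            "r_ig": self.r_ig,
            "intercepts": self.intercepts,
            "M": self.M,
            "n_g": self.n_g,
            "n_i": self.n_i,
            "converged": self.converged,
            "n_iter": self.n_iter,
        }
        if self.warnings:
            out["warnings"] = self.warnings
        return out


def estimate_all(
    moments: MomentTable,
    max_iter: int = DEFAULT_MAX_ITER,
    rtol: float = DEFAULT_RTOL,
) -> EstimateSet:
    """Full estimation chain: h_g² → (h_I², σ₁²) → ρ_IG (IRLS)."""
    h2g, int_gg = estimate_h2g(moments)
    h2i, sigma1sq, int_ii = estimate_h2i(moments)
    res = estimate_rho_ig_irls(
        moments, h2g, h2i, sigma1sq, max_iter=max_iter, rtol=rtol
    )
    warnings = [] if res.converged else ["rho_ig IRLS did not converge"]
    return EstimateSet(
        h2g=h2g,
        h2i=h2i,
        sigma1sq=sigma1sq,
        rho_ig=res.rho_ig,
        intercepts={"gg": int_gg, "ii": int_ii, "gi": res.intercept},
        M=moments.M,
        n_g=moments.n_g,
        n_i=moments.n_i,
        converged=res.converged,
        n_iter=res.n_iter,
        warnings=warnings,
    )


# ---------------------------------------------------------------------------
# Diagonal-LD (LD-score) baseline: partial LD information comparator


def _ldsc_weight_base(ld_scores: np.ndarray) -> np.ndarray:
    # heteroscedasticity-and-overcounting correction shared by LD-score
    # regression weights
    return np.maximum(ld_scores, 1.0)


def baseline_h2(
    z: np.ndarray, ld_scores: np.ndarray, N: float, M: int
) -> tuple[float, float]:
    """LD-score-regression heritability: Z² on per-variant LD scores."""
    z = np.asarray(z, float)
    ell = np.asarray(ld_scores, float)
    h2 = 0.0
    for _ in range(_PLUGIN_ITER):
        f = ell * N * max(h2, 0.0) / M + 1.0
        w = 1.0 / (_ldsc_weight_base(ell) * f**2)
        slope, intercept = weighted_moment_regression(ell, z**2, w)
        h2 = slope * M / N
    return float(h2), float(intercept)


def baseline_cross_slope(
    y: np.ndarray,
    ld_scores: np.ndarray,
    var_a: np.ndarray,
    var_b: np.ndarray,
    max_iter: int = DEFAULT_MAX_ITER,
    rtol: float = DEFAULT_RTOL,
) -> tuple[float, float]:
    """IRLS slope of per-variant Z products on LD scores.

    ``var_a``/``var_b`` are the per-variant marginal variances of the two Z
    vectors (plug-in expectations); the weight is the inverse product
    variance with the usual LD-score overcounting factor.
    """
    ell = np.asarray(ld_scores, float)
    slope, a = 0.0, 0.0
    for _ in range(max_iter):
        mean_term = slope * ell + a
        T = var_a * var_b + mean_term**2
        w = 1.0 / (_ldsc_weight_base(ell) * T)
        slope_new, a_new = weighted_moment_regression(ell, y, w)
        scale = max(abs(slope_new), abs(a_new), 1e-12)
        if max(abs(slope_new - slope), abs(a_new - a)) <= rtol * scale:
            slope, a = slope_new, a_new
            break
        slope, a = slope_new, a_new
    return float(slope), float(a)


def baseline_ldsc_rho_ig(
    z_g: np.ndarray,
    z_i: np.ndarray,
    ld_scores: np.ndarray,
    N_g: float,
    N_i: float,
    M: int,
    h2g: float | None = None,
    h2i: float | None = None,
    sigma1sq: float | None = None,
) -> tuple[float, float]:
    """Diagonal-LD estimate of the G×E genetic covariance.

    Regression of per-variant Z_G·Z_I on LD scores; ρ_IG = slope·M/√(N_G N_I).
    Marginal variance plug-ins are estimated by LD-score regression when not
    supplied.
    """
    ell = np.asarray(ld_scores, float)
    if np.ptp(ell) == 0:
        raise ValueError(
            "degenerate design: all LD scores equal (identity LD); the "
            "diagonal-LD baseline cannot separate slope from intercept"
        )
    if h2g is None:
        h2g, _ = baseline_h2(z_g, ell, N_g, M)
    if h2i is None or sigma1sq is None:
        h2i_s, int_ii = baseline_h2(z_i, ell, N_i, M)
        h2i = h2i_s if h2i is None else h2i
        sigma1sq = (int_ii - 1.0) / 2.0 - h2i if sigma1sq is None else sigma1sq
    var_g = ell * N_g * max(h2g, 0.0) / M + 1.0
    var_i = (
        ell * N_i * max(h2i, 0.0) / M
        + 1.0
        + 2.0 * (max(h2i, 0.0) + max(sigma1sq, 0.0))
    )
    slope, a = baseline_cross_slope(
        np.asarray(z_g, float) * np.asarray(z_i, float), ell, var_g, var_i
    )
    return float(slope * M / np.sqrt(N_g * N_i)), float(a)
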