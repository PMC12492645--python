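"""Detection and correction of heritable-environment confounding.

When the environmental variable E is itself heritable (E = Σ G_j α_j + ε₂)
and its genetic effects α correlate with the G×E interaction effects γ
(covariance ρ_IE), the uncorrected moment conditions are biased.  With the
trivariate effect model — cov(β, γ) = ρ_IG, cov(β, α) = ρ_GE,
cov(γ, α) = ρ_IE — the whitened moment conditions become

* E-GWAS × GWIS:  E[z̃_E z̃_I]_j = √(N_E N_I) ρ_IE (1 + h_E²) D_jj/M + c₁
* GWIS squares:   E[z̃_I²]_j     = N_I (h_I² + 2 ρ_IE²) D_jj/M + c₂
* GWAS × GWIS:    E[z̃_G z̃_I]_j = √(N_G N_I) (ρ_IG + ρ_GE ρ_IE) D_jj/M + c₃

so the corrected estimates subtract the confounding contributions:
h_I² = slope·M/N_I − 2ρ̂_IE² and ρ_IG = slope·M/√(N_G N_I) − ρ̂_GE ρ̂_IE.
The corrected h_I² can never exceed the uncorrected one.  The intercepts
c₁–c₃ are fitted freely; they absorb sample overlap and residual
covariance.  Testing ρ_IE = 0 is the confounding test: under the global
null of no G×E interaction ρ_IE is identically zero, so the correction
cannot inflate type-I error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .estimators import (
    DEFAULT_MAX_ITER,
    DEFAULT_RTOL,
    MomentTable,
    _marginal_factor_g,
    _marginal_factor_i,
    baseline_cross_slope,
    baseline_h2,
    estimate_h2g,
    estimate_h2i,
    weighted_moment_regression,
)
from .inference import wald_test

__all__ = [
    "CorrectionResult",
    "estimate_h2e",
    "estimate_rho_ie",
    "corrected_h2i",
    "estimate_rho_ge",
    "corrected_rho_ig",
    "confounding_test",
    "correct_estimates",
    "correct_estimates_ldsc",
]


def _cross_irls(
    d: np.ndarray,
    y: np.ndarray,
    var_a: np.ndarray,
    var_b: np.ndarray,
    max_iter: int = DEFAULT_MAX_ITER,
    rtol: float = DEFAULT_RTOL,
) -> tuple[float, float]:
    """IRLS (slope, intercept) of a cross-product channel on eigenvalues.

    Weight ``min(d,1) / (var_a·var_b + mean²)`` — the inverse variance of a
    product of two correlated Gaussians with the given marginal variances.
    """
    slope, a = 0.0, 0.0
    for _ in range(max_iter):
        mean_term = slope * d + a
        w = np.minimum(d, 1.0) / (var_a * var_b + mean_term**2)
        slope_new, a_new = weighted_moment_regression(d, y, w)
        scale = max(abs(slope_new), abs(a_new), 1e-12)
        if max(abs(slope_new - slope), abs(a_new - a)) <= rtol * scale:
            return float(slope_new), float(a_new)
        slope, a = slope_new, a_new
    return float(slope), float(a)


def _require_channel(moments: MomentTable, name: str) -> np.ndarray:
    if name not in moments.products:
        raise ValueError(
            f"moment table lacks the {name!r} channel; harmonize with an "
            "E-GWAS scan to enable confounding correction"
        )
    return moments.products[name]


def estimate_h2e(
    moments: MomentTable, N_e: float | None = None, M: int | None = None
) -> tuple[float, float]:
    """Heritability of the environment from the E-GWAS squares channel."""
    y = _require_channel(moments, "ee")
    N_e = moments.n_e if N_e is None else N_e
    M = moments.M if M is None else M
    d = moments.d
    h2e = 0.0
    for _ in range(3):
        w = np.minimum(d, 1.0) / _marginal_factor_g(d, h2e, N_e, M) ** 2
        slope, intercept = weighted_moment_regression(d, y, w)
        h2e = slope * M / N_e
    return float(h2e), float(intercept)


def estimate_rho_ie(
    moments: MomentTable,
    h2e: float,
    N_e: float | None = None,
    N_i: float | None = None,
    M: int | None = None,
    h2i_plugin: float = 0.0,
    sigma1sq_plugin: float = 0.0,
) -> tuple[float, float]:
    """Covariance of G×E effects with E's genetic effects.

    The E×I cross slope equals √(N_E N_I)·ρ_IE·(1 + h_E²)/M; the supplied
    h_E² inverts it.  Returns (rho_ie, c1).
    """
    if 1.0 + h2e <= 0:
        raise ValueError("1 + h2e must be positive to invert the E-I slope")
    y = _require_channel(moments, "ei")
    N_e = moments.n_e if N_e is None else N_e
    N_i = moments.n_i if N_i is None else N_i
    M = moments.M if M is None else M
    d = moments.d
    var_e = _marginal_factor_g(d, h2e, N_e, M)
    var_i = _marginal_factor_i(d, h2i_plugin, sigma1sq_plugin, N_i, M)
    slope, c1 = _cross_irls(d, y, var_e, var_i)
    rho_ie = slope * M / (np.sqrt(N_e * N_i) * (1.0 + h2e))
    return float(rho_ie), float(c1)


def corrected_h2i(
    moments: MomentTable,
    rho_ie: float,
    N_i: float | None = None,
    M: int | None = None,
) -> tuple[float, float]:
    """G×E interaction proportion net of the heritable-E contribution.

    The GWIS-squares slope carries h_I² + 2ρ_IE²; subtracting 2ρ̂_IE² gives
    the corrected estimate (≤ the uncorrected one by construction).
    Returns (h2i_corrected, c2).
    """
    h2i_slope, _sigma1sq, c2 = estimate_h2i(moments, N_i=N_i, M=M)
    return float(h2i_slope - 2.0 * rho_ie**2), float(c2)


def estimate_rho_ge(
    moments: MomentTable,
    N_g: float | None = None,
    N_e: float | None = None,
    M: int | None = None,
    h2g_plugin: float = 0.0,
    h2e_plugin: float = 0.0,
) -> tuple[float, float]:
    """Genetic covariance of the phenotype and the environment.

    Standard cross-trait form: slope of z̃_G·z̃_E on D equals
    √(N_G N_E)·ρ_GE/M.  Symmetric in its two scans.
    """
    y = _require_channel(moments, "ge")
    N_g = moments.n_g if N_g is None else N_g
    N_e = moments.n_e if N_e is None else N_e
    M = moments.M if M is None else M
    d = moments.d
    var_g = _marginal_factor_g(d, h2g_plugin, N_g, M)
    var_e = _marginal_factor_g(d, h2e_plugin, N_e, M)
    slope, intercept = _cross_irls(d, y, var_g, var_e)
    return float(slope * M / np.sqrt(N_g * N_e)), float(intercept)


def corrected_rho_ig(
    moments: MomentTable,
    rho_ge: float,
    rho_ie: float,
    N_g: float | None = None,
    N_i: float | None = None,
    M: int | None = None,
    h2g_plugin: float = 0.0,
    h2i_plugin: float = 0.0,
    sigma1sq_plugin: float = 0.0,
) -> tuple[float, float]:
    """G×E genetic covariance net of the confounding pathway ρ_GE·ρ_IE.

    Returns (rho_ig_corrected, c3).
    """
    N_g = moments.n_g if N_g is None else N_g
    N_i = moments.n_i if N_i is None else N_i
    M = moments.M if M is None else M
    d = moments.d
    var_g = _marginal_factor_g(d, h2g_plugin, N_g, M)
    var_i = _marginal_factor_i(d, h2i_plugin, sigma1sq_plugin, N_i, M)
    slope, c3 = _cross_irls(d, moments.products["gi"], var_g, var_i)
    return float(slope * M / np.sqrt(N_g * N_i) - rho_ge * rho_ie), float(c3)


def confounding_test(rho_ie: float, se_rho_ie: float, df: int | None = None) -> float:
    """Two-sided Wald p-value for ρ_IE = 0 (the confounding test)."""
    return wald_test(rho_ie, se_rho_ie, df=df)


@dataclass
class CorrectionResult:
    """Corrected and uncorrected estimates from the heritable-E chain."""

    h2g: float
    h2e: float
    rho_ie: float
    rho_ge: float
    sigma1sq: float
    h2i_uncorrected: float
    rho_ig_uncorrected: float
    h2i: float  # corrected
    rho_ig: float  # corrected
    intercepts: dict[str, float] = field(default_factory=dict)

    def as_dict(self) -> dict[str, float]:
        return {
            "h2g": self.h2g,
            "h2e": self.h2e,
            "rho_ie": self.rho_ie,
            "rho_ge": self.rho_ge,
            "sigma1sq": self.sigma1sq,
            "h2i_uncorrected": self.h2i_uncorrected,
            "rho_ig_uncorrected": self.rho_ig_uncorrected,
            "h2i": self.h2i,
            "rho_ig": self.rho_ig,
        }


def correct_estimates(
    moments: MomentTable,
    n_passes: int = 3,
    h2e_guard: float | None = None,
) -> CorrectionResult:
    """Full confounding-correction chain on one moment table.

    Order per pass: h_E² → ρ_IE → corrected h_I² → ρ_GE → corrected ρ_IG,
    with the later passes refreshing the variance plug-ins inside the IRLS
    weights.  If h_E² is not meaningfully positive (below ``h2e_guard``,
    default disabled) the environment is treated as non-heritable and the
    correction short-circuits to the uncorrected estimates with ρ_IE = 0.
    """
    h2g, _ = estimate_h2g(moments)
    h2i_raw, sigma1sq, c2 = estimate_h2i(moments)
    from .estimators import estimate_rho_ig_irls

    irls = estimate_rho_ig_irls(moments, h2g, h2i_raw, sigma1sq)
    rho_ig_raw = irls.rho_ig

    h2e, _ = estimate_h2e(moments)
    if h2e_guard is not None and h2e <= h2e_guard:
        return CorrectionResult(
            h2g=h2g,
            h2e=h2e,
            rho_ie=0.0,
            rho_ge=0.0,
            sigma1sq=sigma1sq,
            h2i_uncorrected=h2i_raw,
            rho_ig_uncorrected=rho_ig_raw,
            h2i=h2i_raw,
            rho_ig=rho_ig_raw,
            intercepts={"c2": c2},
        )

    rho_ie, rho_ge = 0.0, 0.0
    c1 = c3 = c_ge = 0.0
    for _ in range(max(n_passes, 1)):
        rho_ie, c1 = estimate_rho_ie(
            moments, h2e, h2i_plugin=h2i_raw, sigma1sq_plugin=sigma1sq
        )
        rho_ge, c_ge = estimate_rho_ge(moments, h2g_plugin=h2g, h2e_plugin=h2e)
        h2e, _ = estimate_h2e(moments)
    h2i_corr, c2 = corrected_h2i(moments, rho_ie)
    rho_ig_corr, c3 = corrected_rho_ig(
        moments,
        rho_ge,
        rho_ie,
        h2g_plugin=h2g,
        h2i_plugin=h2i_raw,
        sigma1sq_plugin=sigma1sq,
    )
    return CorrectionResult(
        h2g=h2g,
        h2e=h2e,
        rho_ie=rho_ie,
        rho_ge=rho_ge,
        sigma1sq=sigma1sq,
        h2i_uncorrected=h2i_raw,
        rho_ig_uncorrected=rho_ig_raw,
        h2i=h2i_corr,
        rho_ig=rho_ig_corr,
        intercepts={"c1": c1, "c2": c2, "c3": c3, "ge": c_ge},
    )


def correct_estimates_ldsc(
    z_g: np.ndarray,
    z_i: np.ndarray,
    z_e: np.ndarray,
    ld_scores: np.ndarray,
    N_g: float,
    N_i: float,
    N_e: float,
    M: int,
) -> CorrectionResult:
    """Diagonal-LD (LD-score) version of the correction chain.

    Same moment structure with raw per-variant products regressed on LD
    scores; the partial-information comparator for the corrected estimates.
    """
    ell = np.asarray(ld_scores, float)
    z_g = np.asarray(z_g, float)
    z_i = np.asarray(z_i, float)
    z_e = np.asarray(z_e, float)
    h2g, _ = baseline_h2(z_g, ell, N_g, M)
    h2i_raw, int_ii = baseline_h2(z_i, ell, N_i, M)
    sigma1sq = (int_ii - 1.0) / 2.0 - h2i_raw
    h2e, _ = baseline_h2(z_e, ell, N_e, M)

    var_g = ell * N_g * max(h2g, 0.0) / M + 1.0
    var_e = ell * N_e * max(h2e, 0.0) / M + 1.0
    var_i = (
        ell * N_i * max(h2i_raw, 0.0) / M
        + 1.0
        + 2.0 * (max(h2i_raw, 0.0) + max(sigma1sq, 0.0))
    )
    slope_gi, _ = baseline_cross_slope(z_g * z_i, ell, var_g, var_i)
    rho_ig_raw = slope_gi * M / np.sqrt(N_g * N_i)
    if 1.0 + h2e <= 0:
        raise ValueError("1 + h2e must be positive to invert the E-I slope")
    slope_ei, c1 = baseline_cross_slope(z_e * z_i, ell, var_e, var_i)
    rho_ie = slope_ei * M / (np.sqrt(N_e * N_i) * (1.0 + h2e))
    slope_ge, _ = baseline_cross_slope(z_g * z_e, ell, var_g, var_e)
    rho_ge = slope_ge * M / np.sqrt(N_g * N_e)
    return CorrectionResult(
        h2g=h2g,
        h2e=h2e,
        rho_ie=rho_ie,
        rho_ge=rho_ge,
        sigma1sq=sigma1sq,
        h2i_uncorrected=h2i_raw,
        rho_ig_uncorrected=rho_ig_raw,
        h2i=h2i_raw - 2.0 * rho_ie**2,
        rho_ig=rho_ig_raw - rho_ge * rho_ie,
        intercepts={"c1": c1, "c2": int_ii},
    )
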