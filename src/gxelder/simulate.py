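"""Synthetic genotype / phenotype / summary-statistics generator.

The simulator realizes the study conditions the estimators are built for:
block-structured LD genotypes, polygenic additive and G×E interaction
effects drawn from a bivariate (or, with a heritable environment,
trivariate) Gaussian, the phenotype model

    Y_i = Σ_j G_ji β_j + Σ_j G_ji E_i γ_j + ε₁_i E_i + ε₀_i,

and in-process per-SNP association scans producing GWAS, GWIS, and E-GWAS
Z-scores (closed-form vectorized OLS, mirroring what a linear-regression
scan with an interaction term produces).

Defaults are the scaled experiment: n = 2,000 subjects, m = 1,000 variants
in 10 LD blocks, 5% causal variants, AR(1) within-block LD whose lag-1
correlation varies across blocks (spanning 0.2–0.98), emulating genome-wide
heterogeneity in LD strength — the feature that gives the diagonal-LD
comparator a non-degenerate regression design.  Causal effect variances are
scaled by the causal count M₀ so the realized variance components match
their nominal targets (an ``effect_scale="total"`` switch gives the
h²/M-on-causal-only alternative, whose realized variance is h²·M₀/M).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .confound import correct_estimates, correct_estimates_ldsc
from .estimators import (
    MomentTable,
    baseline_ldsc_rho_ig,
    build_moment_table,
    estimate_all,
)
from .inference import jackknife, joint_test, wald_test
from .ld import (
    LDBlock,
    LDReference,
    chunk_variants,
    eigendecompose,
    make_ld_reference,
)
from .sumstats import HarmonizedPair, SummaryStats

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "SimOutput",
    "GenotypePanel",
    "make_panel",
    "ld_reference_from_sim",
    "population_ld_reference",
    "simulate_genotypes",
    "draw_effects",
    "simulate_phenotype",
    "association_scan",
    "simulate_study",
    "simulate_replicate",
    "run_experiment",
    "summarize_experiment",
    "prs_by_e_check",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Scenario parameters for one simulated study."""

    n: int = 2000
    m: int = 1000
    n_blocks: int = 10
    causal_fraction: float = 0.05
    h2g: float = 0.2
    h2i: float = 0.0
    r_ig: float = 0.0
    heritable_e: bool = False
    h2e: float = 0.0
    r_ge: float = 0.0
    r_ie: float = 0.0
    sigma1sq: float = 0.0
    rho01: float = 0.0
    ld: str = "ar1"  # "ar1" | "exchangeable" | "identity"
    ld_param: float = 0.98
    #: lower end of the per-block within-block correlation range; blocks
    #: span [ld_param_min, ld_param] to emulate genome-wide LD
    #: heterogeneity (set equal to ld_param for a homogeneous profile)
    ld_param_min: float = 0.2
    dosage: bool = False
    effect_scale: str = "causal"  # "causal": var h²/M0 on causal variants
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.causal_fraction <= 1):
            raise ValueError("causal_fraction must be in (0, 1]")
        if round(self.causal_fraction * self.m) < 2:
            raise ValueError("need at least 2 causal variants")
        if self.h2g + self.h2i + self.sigma1sq > 1:
            raise ValueError("variance components exceed 1")
        for r in (self.r_ig, self.r_ge, self.r_ie):
            if abs(r) > 1:
                raise ValueError("effect correlations must lie in [-1, 1]")
        if np.linalg.eigvalsh(self.effect_correlation())[0] < -1e-10:
            raise ValueError("implied effect correlation matrix is not PSD")
        if self.ld not in ("ar1", "exchangeable", "identity"):
            raise ValueError(f"unknown LD profile {self.ld!r}")

    # -- derived quantities -----------------------------------------------

    @property
    def m_causal(self) -> int:
        return int(round(self.causal_fraction * self.m))

    @property
    def rho_ig(self) -> float:
        return self.r_ig * float(np.sqrt(max(self.h2g * self.h2i, 0.0)))

    @property
    def rho_ge(self) -> float:
        return self.r_ge * float(np.sqrt(max(self.h2g * self.h2e, 0.0)))

    @property
    def rho_ie(self) -> float:
        return self.r_ie * float(np.sqrt(max(self.h2i * self.h2e, 0.0)))

    def effect_correlation(self) -> np.ndarray:
        if self.heritable_e:
            return np.array(
                [
                    [1.0, self.r_ig, self.r_ge],
                    [self.r_ig, 1.0, self.r_ie],
                    [self.r_ge, self.r_ie, 1.0],
                ]
            )
        return np.array([[1.0, self.r_ig], [self.r_ig, 1.0]])

    def effect_covariance(self) -> np.ndarray:
        """Per-causal-variant covariance of (β, γ[, α])."""
        m0 = self.m_causal if self.effect_scale == "causal" else self.m
        h = [self.h2g, self.h2i] + ([self.h2e] if self.heritable_e else [])
        s = np.sqrt(np.maximum(np.array(h), 0.0) / m0)
        return self.effect_correlation() * np.outer(s, s)

    def truth(self) -> dict[str, float]:
        t = {
            "h2g": self.h2g,
            "h2i": self.h2i,
            "rho_ig": self.rho_ig,
            "r_ig": self.r_ig,
            "sigma1sq": self.sigma1sq,
        }
        if self.heritable_e:
            t.update(
                h2e=self.h2e, rho_ge=self.rho_ge, rho_ie=self.rho_ie,
                r_ge=self.r_ge, r_ie=self.r_ie,
            )
        return t


@dataclass
class SimOutput:
    """One realized study: genotypes, traits, effects, and scan Z-scores."""

    config: SimulationConfig
    genotypes: np.ndarray
    block_assignments: np.ndarray
    variant_ids: list[str]
    beta: np.ndarray
    gamma: np.ndarray
    alpha: np.ndarray | None
    e: np.ndarray
    y: np.ndarray
    z_g: np.ndarray
    z_i: np.ndarray
    z_e: np.ndarray | None
    n: int

    def to_pair(self) -> HarmonizedPair:
        """Wrap the scan Z-scores as an already-harmonized pair."""
        return HarmonizedPair(
            variant_ids=list(self.variant_ids),
            z_g=self.z_g,
            z_i=self.z_i,
            n_g=float(self.n),
            n_i=float(self.n),
            z_e=self.z_e,
            n_e=float(self.n) if self.z_e is not None else None,
            n_overlap=float(self.n),
        )

    def to_sumstats(self, which: str) -> SummaryStats:
        """Export one scan (``gwas``/``gwis``/``gwas_e``) as a sumstats table."""
        z = {"gwas": self.z_g, "gwis": self.z_i, "gwas_e": self.z_e}[which]
        if z is None:
            raise ValueError("no E-GWAS scan in this simulation")
        return SummaryStats(
            pd.DataFrame(
                {
                    "variant_id": self.variant_ids,
                    "effect_allele": "A",
                    "other_allele": "G",
                    "z": z,
                    "n": float(self.n),
                    "chrom": "1",
                    "pos": np.arange(1, len(self.variant_ids) + 1),
                }
            )
        )

    def variant_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variant_id": self.variant_ids,
                "effect_allele": "A",
                "other_allele": "G",
            }
        )


def _standardize(X: np.ndarray, axis: int = 0) -> np.ndarray:
    mu = X.mean(axis=axis, keepdims=True)
    sd = X.std(axis=axis, keepdims=True)
    if np.any(sd == 0):
        j = int(np.flatnonzero(sd.ravel() == 0)[0])
        raise ValueError(f"zero-variance column {j} after genotype generation")
    return (X - mu) / sd


def _block_rho(cfg: SimulationConfig, block_id: int) -> float:
    """Lag-1 correlation for one block: blocks span a range of LD strengths."""
    if cfg.n_blocks == 1:
        return cfg.ld_param
    lo = min(cfg.ld_param_min, cfg.ld_param)
    return float(lo + (cfg.ld_param - lo) * block_id / (cfg.n_blocks - 1))


def _latent_block(
    rng: np.random.Generator, n: int, m: int, cfg: SimulationConfig, rho: float
) -> np.ndarray:
    eps = rng.standard_normal((n, m))
    if cfg.ld == "identity" or rho == 0.0:
        return eps
    if not -1 < rho < 1:
        raise ValueError("ld_param must lie in (-1, 1)")
    if cfg.ld == "ar1":
        eps[:, 1:] *= np.sqrt(1.0 - rho**2)
        return lfilter([1.0], [1.0, -rho], eps, axis=1)
    if rho < 0:
        raise ValueError("exchangeable correlation must be nonnegative")
    shared = rng.standard_normal((n, 1))
    return np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * eps


def simulate_genotypes(
    cfg: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Standardized n×m genotype matrix with block-structured LD.

    Within each block, columns follow the configured correlation profile
    (AR(1) with lag-1 correlation ``ld_param``, exchangeable, or identity);
    blocks are mutually independent.  In ``dosage`` mode, correlated latent
    Gaussian haplotypes are thresholded at allele-frequency quantiles
    (MAF ~ U(0.05, 0.5)) and summed to 0/1/2 dosages before standardization.
    """
    assignment = chunk_variants(cfg.m, cfg.n_blocks)
    cols = []
    for bid in range(cfg.n_blocks):
        mb = int((assignment == bid).sum())
        rho = _block_rho(cfg, bid)
        if cfg.dosage:
            maf = rng.uniform(0.05, 0.5, size=mb)
            from scipy.stats import norm

            cut = norm.ppf(maf)
            h1 = _latent_block(rng, cfg.n, mb, cfg, rho) < cut
            h2 = _latent_block(rng, cfg.n, mb, cfg, rho) < cut
            cols.append((h1.astype(float) + h2))
        else:
            cols.append(_latent_block(rng, cfg.n, mb, cfg, rho))
    G = np.concatenate(cols, axis=1)
    return _standardize(G), assignment


def draw_effects(
    cfg: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    """Per-variant effect sizes (β, γ[, α]); non-causal effects are zero."""
    cov = cfg.effect_covariance()
    w, V = np.linalg.eigh(cov)
    L = V * np.sqrt(np.clip(w, 0.0, None))
    k = cov.shape[0]
    causal = rng.choice(cfg.m, size=cfg.m_causal, replace=False)
    draws = rng.standard_normal((cfg.m_causal, k)) @ L.T
    out = np.zeros((cfg.m, k))
    out[causal] = draws
    beta, gamma = out[:, 0], out[:, 1]
    alpha = out[:, 2] if cfg.heritable_e else None
    return beta, gamma, alpha


@dataclass
class GenotypePanel:
    """A fixed genotype panel with its in-sample LD reference.

    Replicated experiments redraw effects, environments, and residuals on a
    fixed panel — emulating study designs where one reference genotype panel
    underlies every replication — which also amortizes the genotype
    generation and LD eigen-decomposition across replications.
    """

    genotypes: np.ndarray
    genotypes_sq: np.ndarray  # elementwise squares, precomputed for scans
    block_assignments: np.ndarray
    variant_ids: list[str]
    reference: LDReference

    def ld_scores(self) -> np.ndarray:
        return self.reference.ld_scores()


def make_panel(
    cfg: SimulationConfig,
    rng: np.random.Generator | int | None = None,
    reference: str = "insample",
) -> GenotypePanel:
    """Draw a genotype panel and attach its LD reference.

    ``reference="insample"`` (default) eigen-decomposes the panel's own
    sample LD — under the null, whitening by the panel's realized LD makes
    the transformed products cleanly pivotal, which is what keeps the
    tests calibrated.  ``"population"`` uses the exact generating LD (the
    negligible-reference-noise regime of a reference panel much larger
    than the study); unavailable in dosage mode.
    """
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(cfg.seed if rng is None else int(rng))
    G, assignment = simulate_genotypes(cfg, rng)
    ids = [f"v{j:06d}" for j in range(cfg.m)]
    if reference == "population":
        ref = population_ld_reference(cfg)
    elif reference == "insample":
        ref = make_ld_reference(G, ids, assignment, keep_r=False)
    else:
        raise ValueError(f"unknown reference kind {reference!r}")
    return GenotypePanel(
        genotypes=G,
        genotypes_sq=G * G,
        block_assignments=assignment,
        variant_ids=ids,
        reference=ref,
    )


def population_ld_reference(cfg: SimulationConfig, tol: float = 1e-6) -> LDReference:
    """Exact population LD reference for the configured profile.

    The analytic within-block correlation matrix (AR(1) Toeplitz,
    exchangeable, or identity) plays the role of a reference panel whose
    estimation noise is negligible — the usual regime when the reference
    sample is far larger than the association study.  Unavailable in
    ``dosage`` mode, where thresholding attenuates the latent correlation
    with no closed form.
    """
    if cfg.dosage:
        raise ValueError(
            "no analytic LD form in dosage mode; build an in-sample "
            "reference from simulated genotypes instead"
        )
    from scipy.linalg import toeplitz

    assignment = chunk_variants(cfg.m, cfg.n_blocks)
    ids = [f"v{j:06d}" for j in range(cfg.m)]
    eigenblocks, blocks = [], []
    for bid in range(cfg.n_blocks):
        cols = np.flatnonzero(assignment == bid)
        mb = len(cols)
        rho = _block_rho(cfg, bid)
        if cfg.ld == "identity" or rho == 0.0:
            R = np.eye(mb)
        elif cfg.ld == "ar1":
            R = toeplitz(rho ** np.arange(mb))
        else:  # exchangeable
            R = np.full((mb, mb), rho)
            np.fill_diagonal(R, 1.0)
        blk = LDBlock(int(bid), [ids[j] for j in cols], R)
        blocks.append(blk)
        eigenblocks.append(eigendecompose(blk, tol=tol))
    return LDReference(eigenblocks=eigenblocks, ld_blocks=blocks, tol=tol)


def simulate_phenotype(
    genotypes: np.ndarray,
    beta: np.ndarray,
    gamma: np.ndarray,
    e: np.ndarray,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Phenotype with additive, interaction, and residual components.

    The interaction term Σ_j G_ji E_i γ_j collapses to E ⊙ (Gγ).  Residuals
    (ε₀, ε₁) are bivariate normal with variances (σ₀², σ₁²) and covariance
    ρ₀₁, with σ₀² = 1 − h_g² − h_I² − σ₁² so the phenotypic variance is ≈ 1.
    """
    sigma0sq = 1.0 - cfg.h2g - cfg.h2i - cfg.sigma1sq
    if sigma0sq < 0:
        raise ValueError("negative residual variance: components sum past 1")
    cov = np.array([[sigma0sq, cfg.rho01], [cfg.rho01, cfg.sigma1sq]])
    w, V = np.linalg.eigh(cov)
    if w[0] < -1e-10:
        raise ValueError("residual covariance is not PSD")
    eps = rng.standard_normal((cfg.n, 2)) @ (V * np.sqrt(np.clip(w, 0, None))).T
    return genotypes @ beta + e * (genotypes @ gamma) + eps[:, 0] + eps[:, 1] * e


def _scan_marginal(G: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Z-scores of per-SNP simple regressions y ~ 1 + g (vectorized OLS)."""
    n = G.shape[0]
    yc = y - y.mean()
    bhat = (G.T @ yc) / n
    sse = (yc @ yc) - n * bhat**2
    s2 = sse / (n - 2)
    return bhat / np.sqrt(s2 / n)


def _scan_interaction(
    G: np.ndarray, y: np.ndarray, e: np.ndarray, G2: np.ndarray | None = None
) -> np.ndarray:
    """Interaction-term Z-scores of per-SNP fits y ~ 1 + g + e + g·e.

    Closed-form batched OLS: one 4×4 normal-equation solve per SNP.
    Collinear designs yield NaN for that variant.
    """
    n, m = G.shape
    e2 = e * e
    if G2 is None:
        G2 = G * G
    c_ge = G.T @ e
    c_g2e = G2.T @ e
    c_ge2 = G.T @ e2
    c_g2e2 = G2.T @ e2
    se_sum = float(e.sum())
    se2_sum = float(e2.sum())
    A = np.empty((m, 4, 4))
    A[:, 0, 0] = n
    A[:, 0, 1] = A[:, 1, 0] = 0.0  # columns standardized to mean 0
    A[:, 0, 2] = A[:, 2, 0] = se_sum
    A[:, 0, 3] = A[:, 3, 0] = c_ge
    A[:, 1, 1] = n  # unit variance
    A[:, 1, 2] = A[:, 2, 1] = c_ge
    A[:, 1, 3] = A[:, 3, 1] = c_g2e
    A[:, 2, 2] = se2_sum
    A[:, 2, 3] = A[:, 3, 2] = c_ge2
    A[:, 3, 3] = c_g2e2
    b = np.empty((m, 4))
    b[:, 0] = y.sum()
    b[:, 1] = G.T @ y
    b[:, 2] = e @ y
    b[:, 3] = G.T @ (e * y)
    z = np.full(m, np.nan)
    ok = np.abs(np.linalg.det(A)) > 1e-8 * n**4
    if not np.all(ok):
        logger.warning("%d collinear SNP design(s) flagged", int((~ok).sum()))
    Aok, bok = A[ok], b[ok]
    coef = np.linalg.solve(Aok, bok[:, :, None])[:, :, 0]
    sse = (y @ y) - np.einsum("ij,ij->i", coef, bok)
    s2 = sse / (n - 4)
    inv = np.linalg.inv(Aok)
    se3 = np.sqrt(s2 * inv[:, 3, 3])
    z[ok] = coef[:, 3] / se3
    return z


def association_scan(
    genotypes: np.ndarray,
    y: np.ndarray,
    e: np.ndarray | None,
    mode: str,
    genotypes_sq: np.ndarray | None = None,
) -> tuple[np.ndarray, int]:
    """Per-SNP association Z-scores.

    ``gwas_y``: simple regression of the phenotype on each SNP.
    ``gwis_interaction``: the SNP×E interaction coefficient from the joint
    per-SNP model y ~ g + e + g·e.
    ``gwas_e``: simple regression of the environment on each SNP.
    """
    n = genotypes.shape[0]
    if mode == "gwas_y":
        return _scan_marginal(genotypes, y), n
    if mode == "gwis_interaction":
        if e is None:
            raise ValueError("interaction scan requires the environment vector")
        return _scan_interaction(genotypes, y, e, genotypes_sq), n
    if mode == "gwas_e":
        if e is None:
            raise ValueError("gwas_e requires the environment vector")
        return _scan_marginal(genotypes, e), n
    raise ValueError(f"unknown scan mode {mode!r}")


def simulate_study(
    cfg: SimulationConfig,
    rng: np.random.Generator | int | None = None,
    panel: GenotypePanel | None = None,
) -> SimOutput:
    """Generate one full study: genotypes, E, Y, and all association scans.

    When ``panel`` is given its genotypes are reused and only effects,
    environment, and residuals are redrawn.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    elif isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    if panel is None:
        G, assignment = simulate_genotypes(cfg, rng)
        G2 = None
    else:
        G, assignment, G2 = panel.genotypes, panel.block_assignments, panel.genotypes_sq
    beta, gamma, alpha = draw_effects(cfg, rng)
    if cfg.heritable_e:
        if 1.0 - cfg.h2e < 0:
            raise ValueError("h2e exceeds 1")
        e = G @ alpha + np.sqrt(1.0 - cfg.h2e) * rng.standard_normal(cfg.n)
    else:
        e = rng.standard_normal(cfg.n)
    e = (e - e.mean()) / e.std()
    y = simulate_phenotype(G, beta, gamma, e, cfg, rng)
    z_g, _ = association_scan(G, y, None, "gwas_y")
    z_i, _ = association_scan(G, y, e, "gwis_interaction", genotypes_sq=G2)
    z_e = association_scan(G, None, e, "gwas_e")[0] if cfg.heritable_e else None
    ids = panel.variant_ids if panel is not None else [
        f"v{j:06d}" for j in range(cfg.m)
    ]
    return SimOutput(
        config=cfg,
        genotypes=G,
        block_assignments=assignment,
        variant_ids=ids,
        beta=beta,
        gamma=gamma,
        alpha=alpha,
        e=e,
        y=y,
        z_g=z_g,
        z_i=z_i,
        z_e=z_e,
        n=cfg.n,
    )


def ld_reference_from_sim(sim: SimOutput, tol: float = 1e-6, keep_r: bool = False) -> LDReference:
    """In-sample eigen-decomposed LD reference from the simulated genotypes."""
    return make_ld_reference(
        sim.genotypes, sim.variant_ids, sim.block_assignments, tol=tol, keep_r=keep_r
    )


def simulate_replicate(
    cfg: SimulationConfig,
    seed: int | np.random.SeedSequence,
    do_tests: bool = False,
    do_baseline: bool = False,
    do_correction: bool = False,
    n_jackknife: int | None = None,
    alpha_level: float = 0.05,
    panel: GenotypePanel | None = None,
) -> dict[str, float]:
    """One simulate → scan → estimate (→ test) cycle; returns a flat record."""
    rng = np.random.default_rng(seed)
    sim = simulate_study(cfg, rng, panel=panel)
    ref = panel.reference if panel is not None else ld_reference_from_sim(sim)
    moments = build_moment_table(sim.to_pair(), ref.eigenblocks)
    rec: dict[str, float] = {}
    est = estimate_all(moments)
    rec.update(h2g=est.h2g, h2i=est.h2i, sigma1sq=est.sigma1sq, rho_ig=est.rho_ig)
    if do_tests:
        def _point(mt: MomentTable) -> dict[str, float]:
            e = estimate_all(mt)
            return {"h2g": e.h2g, "h2i": e.h2i, "rho_ig": e.rho_ig}

        jk = jackknife(moments, _point, n_groups=n_jackknife)
        g = jk.n_groups
        rec["se_h2i"] = jk.se["h2i"]
        rec["se_rho_ig"] = jk.se["rho_ig"]
        rec["p_h2i"] = wald_test(jk.point["h2i"], jk.se["h2i"], df=g - 1)
        rec["p_rho_ig"] = wald_test(jk.point["rho_ig"], jk.se["rho_ig"], df=g - 1)
        rec["p_joint"] = joint_test(jk.v_hat, jk.sigma_hat, n_groups=g).p
        rec["reject_h2i"] = float(rec["p_h2i"] < alpha_level)
        rec["reject_rho_ig"] = float(rec["p_rho_ig"] < alpha_level)
        rec["reject_joint"] = float(rec["p_joint"] < alpha_level)
    if do_baseline:
        ell = ref.ld_scores()
        rho_b, _ = baseline_ldsc_rho_ig(
            sim.z_g, sim.z_i, ell, float(sim.n), float(sim.n), cfg.m
        )
        rec["rho_ig_ldsc"] = rho_b
    if do_correction:
        if sim.z_e is None:
            raise ValueError("correction requires a heritable-E simulation")
        corr = correct_estimates(moments)
        rec.update(
            h2e=corr.h2e,
            rho_ie=corr.rho_ie,
            rho_ge=corr.rho_ge,
            h2i_corrected=corr.h2i,
            rho_ig_corrected=corr.rho_ig,
            h2i_uncorrected=corr.h2i_uncorrected,
            rho_ig_uncorrected=corr.rho_ig_uncorrected,
        )
        if do_baseline:
            ell = ref.ld_scores()
            corr_b = correct_estimates_ldsc(
                sim.z_g, sim.z_i, sim.z_e, ell,
                float(sim.n), float(sim.n), float(sim.n), cfg.m,
            )
            rec["h2i_corrected_ldsc"] = corr_b.h2i
            rec["rho_ig_corrected_ldsc"] = corr_b.rho_ig
    return rec


def _rep_seed(master_seed: int, scenario_idx: int, rep: int) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(master_seed), scenario_idx, rep])


def run_experiment(
    scenarios: Sequence[SimulationConfig],
    replications: int,
    seed: int,
    do_tests: bool = False,
    do_baseline: bool = False,
    do_correction: bool = False,
    n_jackknife: int | None = None,
    max_failure_fraction: float = 0.1,
    reuse_genotypes: bool = True,
    panel_refresh: int = 50,
) -> pd.DataFrame:
    """Run replicated simulations over a scenario list.

    Returns one row per (scenario, replication) with the true parameters and
    every computed estimate / rejection indicator.  Per-replication seeds
    are derived deterministically from ``seed`` and the (scenario,
    replication) index, so two runs with the same seed are identical.
    With ``reuse_genotypes`` (the default) replications share a genotype
    panel, redrawn every ``panel_refresh`` replications: sharing amortizes
    the LD eigen-decomposition, while the periodic redraw keeps summary
    rates close to their marginal (panel-averaged) expectations.
    Individual replication failures are recorded; more than
    ``max_failure_fraction`` of failures is an experiment-level error.
    """
    rows = []
    n_fail = 0
    for s_idx, cfg in enumerate(scenarios):
        base = {"scenario": s_idx, **{f"true_{k}": v for k, v in cfg.truth().items()}}
        panel = None
        panel_idx = -1
        for rep in range(replications):
            if reuse_genotypes and rep // panel_refresh != panel_idx:
                panel_idx = rep // panel_refresh
                panel = make_panel(
                    cfg,
                    np.random.default_rng(
                        np.random.SeedSequence([int(seed), s_idx, 10_000 + panel_idx])
                    ),
                )
            try:
                rec = simulate_replicate(
                    cfg,
                    _rep_seed(seed, s_idx, rep),
                    do_tests=do_tests,
                    do_baseline=do_baseline,
                    do_correction=do_correction,
                    n_jackknife=n_jackknife,
                    panel=panel,
                )
            except Exception as exc:
                logger.warning("scenario %d rep %d failed: %s", s_idx, rep, exc)
                n_fail += 1
                continue
            rows.append({**base, "rep": rep, **rec})
    total = len(scenarios) * replications
    if n_fail > max_failure_fraction * total:
        raise RuntimeError(
            f"{n_fail}/{total} replications failed (> {max_failure_fraction:.0%})"
        )
    return pd.DataFrame(rows)


def summarize_experiment(
    results: pd.DataFrame, params: Iterable[str] = ("h2g", "h2i", "rho_ig")
) -> pd.DataFrame:
    """Per-scenario bias / SD / RMSE (and rejection rates when present)."""
    out = []
    for s_idx, grp in results.groupby("scenario"):
        row: dict[str, float] = {"scenario": s_idx, "n_reps": len(grp)}
        for p in params:
            if p not in grp.columns:
                continue
            truth = grp[f"true_{p}"].iloc[0] if f"true_{p}" in grp.columns else np.nan
            est = grp[p].to_numpy(float)
            row[f"true_{p}"] = truth
            row[f"mean_{p}"] = est.mean()
            row[f"bias_{p}"] = est.mean() - truth
            row[f"sd_{p}"] = est.std(ddof=1)
            row[f"rmse_{p}"] = float(np.sqrt(np.mean((est - truth) ** 2)))
        for col in grp.columns:
            if col.startswith("reject_"):
                row[f"rate_{col[7:]}"] = grp[col].mean()
        out.append(row)
    return pd.DataFrame(out)


def prs_by_e_check(
    sim: SimOutput, prs_noise_sd: float = 0.0, rng: np.random.Generator | None = None
) -> dict[str, float]:
    """Compare the PRS-by-E regression coefficient with ρ_IG/h_g².

    Builds the oracle polygenic score PRS = Gβ from the true effects, fits
    Y ~ 1 + PRS + E + PRS·E, and reports the interaction coefficient next to
    the theoretical ratio.  ``prs_noise_sd`` adds measurement error to the
    score to demonstrate attenuation toward zero.
    """
    prs = sim.genotypes @ sim.beta
    if prs_noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        prs = prs + prs_noise_sd * rng.standard_normal(prs.shape)
    X = np.column_stack([np.ones_like(prs), prs, sim.e, prs * sim.e])
    coef, *_ = np.linalg.lstsq(X, sim.y, rcond=None)
    cfg = sim.config
    expected = cfg.rho_ig / cfg.h2g if cfg.h2g > 0 else np.nan
    return {
        "beta3": float(coef[3]),
        "expected_ratio": float(expected),
        "prs_noise_sd": float(prs_noise_sd),
    }
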