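"""Rare-variant association testing.

The testable unit is either a gene (collapsed across its qualifying rare
non-silent variants and tested with SKAT-O) or a single variant (tested with
Fisher's exact test on the 2x2 allelic case/control table, with a Wald
confidence interval on the odds ratio).  Population structure is handled by
including genotype principal components 1-4 as covariates in the logistic
null model of the SKAT-O score statistics.  Each phenotype contrast defines
its own testing family; p-values are Bonferroni-adjusted by the number of
units tested within that family.

SKAT-O follows the optimal-test construction: for each mixing weight rho in a
grid, Q_rho = (1 - rho) * Q_SKAT + rho * Q_burden is formed from the weighted
score vector, converted to a p-value through the tail of the matching mixture
of 1-df chi-squared variables (Imhof characteristic-function inversion with a
Liu moment-matching fallback), and the minimum p over the grid is calibrated
by the one-dimensional conditioning integral of the construction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, NamedTuple, Optional, Sequence

import numpy as np
from scipy import integrate, stats

from .region_mapper import GeneModel, Region, genes_in_region, variants_in_gene
from .twin_genomics import SampleRecord
from .variant_qc import (
    MISSING,
    GenotypeMatrix,
    VariantRecord,
    alt_allele_stats,
    is_nonsilent,
    rare_variant_filter,
)

logger = logging.getLogger("twinrare")

__all__ = [
    "PhenotypeContrast",
    "NullModel",
    "AssociationResult",
    "SkatOResult",
    "standard_contrasts",
    "compute_pcs",
    "fit_null_logistic",
    "quadform_pvalue",
    "skat_o",
    "fisher_exact_2x2",
    "odds_ratio_ci",
    "bonferroni",
    "run_scan",
]

DEFAULT_RHO_GRID = (0.0, 0.01, 0.04, 0.09, 0.16, 0.25, 0.5, 1.0)


# ---------------------------------------------------------------------------
# Phenotype contrasts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhenotypeContrast:
    """Case/control definition for one depression variable.

    ``case_rule`` and ``control_rule`` are disjoint predicates on
    :class:`SampleRecord`; samples matching neither are excluded from the
    contrast.
    """

    name: str
    case_rule: Callable[[SampleRecord], bool]
    control_rule: Callable[[SampleRecord], bool]


def standard_contrasts() -> list[PhenotypeContrast]:
    """The four lifetime depression contrasts.

    * ``severity``: severe depression vs everyone not severe (mild, moderate
      or undiagnosed) with known diagnosis status.
    * ``lifetime_dx``: diagnosed vs never depressed.
    * ``early_onset``: diagnosed with onset age <= 30 vs everyone else with
      the relevant data (late-onset diagnosed or never depressed).
    * ``symptom_count``: all nine symptoms vs fewer than nine.

    Bereavement-labelled samples are excluded from every contrast; samples
    missing the tested variable are excluded from that contrast only.
    """

    def known_dx(s: SampleRecord) -> bool:
        return s.dx in (0, 1)

    return [
        PhenotypeContrast(
            "severity",
            case_rule=lambda s: s.severity == "severe",
            control_rule=lambda s: known_dx(s)
            and s.severity in ("none", "mild", "moderate"),
        ),
        PhenotypeContrast(
            "lifetime_dx",
            case_rule=lambda s: s.dx == 1,
            control_rule=lambda s: s.dx == 0,
        ),
        PhenotypeContrast(
            "early_onset",
            case_rule=lambda s: s.dx == 1 and s.onset_age is not None and s.onset_age <= 30,
            control_rule=lambda s: s.dx == 0
            or (s.dx == 1 and s.onset_age is not None and s.onset_age > 30),
        ),
        PhenotypeContrast(
            "symptom_count",
            case_rule=lambda s: known_dx(s)
            and s.symptom_count is not None
            and s.symptom_count >= 9,
            control_rule=lambda s: known_dx(s)
            and s.symptom_count is not None
            and s.symptom_count < 9,
        ),
    ]


# ---------------------------------------------------------------------------
# Covariates: genotype principal components
# ---------------------------------------------------------------------------

def compute_pcs(matrix: GenotypeMatrix, k: int = 4, maf_min: float = 0.05) -> np.ndarray:
    """Principal-component coordinates of the samples.

    Dosages at common variants (folded MAF >= ``maf_min``) are mean-imputed,
    centred and scaled by sqrt(2 p (1 - p)); the returned ``n x k`` matrix
    holds the orthonormal left singular vectors ordered by decreasing
    singular value.  Signs are fixed so the entry of largest magnitude in
    each column is positive.
    """
    dose = matrix.dosage.astype(float)
    miss = matrix.dosage == MISSING
    dose[miss] = np.nan
    with np.errstate(invalid="ignore"):
        af = np.nanmean(dose, axis=0) / 2.0
    folded = np.minimum(af, 1.0 - af)
    common = np.where(np.nan_to_num(folded) >= maf_min)[0]
    if common.size < k:
        raise ValueError(
            f"only {common.size} common polymorphic variants available; need >= {k}"
        )
    X = dose[:, common]
    p = af[common]
    col_mean = 2.0 * p
    X = np.where(np.isnan(X), col_mean, X)
    X = (X - col_mean) / np.sqrt(2.0 * p * (1.0 - p))
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    if (s[:k] <= 1e-12 * s[0]).any():
        raise ValueError(f"requested {k} components but matrix rank is lower")
    pcs = U[:, :k]
    for j in range(k):
        i = np.argmax(np.abs(pcs[:, j]))
        if pcs[i, j] < 0:
            pcs[:, j] = -pcs[:, j]
    return pcs


# ---------------------------------------------------------------------------
# Logistic null model (IRLS)
# ---------------------------------------------------------------------------

@dataclass
class NullModel:
    coefficients: np.ndarray
    fitted_probabilities: np.ndarray
    residuals: np.ndarray
    design: np.ndarray
    converged: bool = True
    ridged: bool = False


def fit_null_logistic(y: np.ndarray, covariates: np.ndarray) -> NullModel:
    """Maximum-likelihood logistic regression via IRLS.

    ``covariates`` must include the intercept column.  Convergence is
    declared when the largest coefficient change falls below 1e-8 (at most
    100 iterations).  When separation is detected (fitted probabilities
    collapsing onto {0,1} or a singular weighted system) the fit falls back
    to a ridge penalty of 1e-6 and is flagged.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(covariates, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("covariate matrix must be n x p with n = len(y)")
    if y.min() == y.max():
        raise ValueError("outcome has a single class; logistic fit undefined")

    def _irls(ridge: float) -> tuple[np.ndarray, np.ndarray, bool]:
        beta = np.zeros(X.shape[1])
        for _ in range(100):
            eta = np.clip(X @ beta, -30, 30)
            mu = 1.0 / (1.0 + np.exp(-eta))
            w = mu * (1.0 - mu)
            XtWX = X.T @ (X * w[:, None]) + ridge * np.eye(X.shape[1])
            score = X.T @ (y - mu) - ridge * beta
            step = np.linalg.solve(XtWX, score)
            beta = beta + step
            if np.max(np.abs(step)) < 1e-8:
                return beta, mu, True
        return beta, mu, False

    separated = False
    try:
        beta, mu, converged = _irls(0.0)
        if not np.isfinite(beta).all() or mu.min() < 1e-10 or mu.max() > 1 - 1e-10:
            separated = True
    except np.linalg.LinAlgError:
        separated = True
    if separated:
        logger.warning("separation detected in logistic null fit; applying ridge 1e-6")
        beta, mu, converged = _irls(1e-6)
    eta = np.clip(X @ beta, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    return NullModel(
        coefficients=beta,
        fitted_probabilities=mu,
        residuals=y - mu,
        design=X,
        converged=converged,
        ridged=separated,
    )


# ---------------------------------------------------------------------------
# Quadratic-form tail probability (Imhof inversion, Liu fallback)
# ---------------------------------------------------------------------------

def _liu_sf(lambdas: np.ndarray, q: float) -> float:
    """Liu-Tang-Zhang moment-matching approximation to P(sum l_i X_i >= q)."""
    c1 = lambdas.sum()
    c2 = (lambdas**2).sum()
    c3 = (lambdas**3).sum()
    c4 = (lambdas**4).sum()
    s1 = c3 / c2**1.5
    s2 = c4 / c2**2
    if s1**2 > s2:
        a = 1.0 / (s1 - math.sqrt(s1**2 - s2))
        delta = s1 * a**3 - a**2
        df = a**2 - 2 * delta
    else:
        delta = 0.0
        df = 1.0 / s2
        a = math.sqrt(df)
    mu_x = df + delta
    sigma_x = math.sqrt(2.0) * a
    t = (q - c1) / math.sqrt(2.0 * c2)
    return float(stats.ncx2.sf(t * sigma_x + mu_x, df, delta))


def _imhof_sf(lam: np.ndarray, q: float, epsabs: float = 1e-11) -> tuple[float, float]:
    """Imhof inversion of the characteristic function of sum(lam_i chi2_1).

    The Imhof integrand sin(psi(u) - q u / 2) / (u rho(u)) is split into its
    slowly varying factors against cos(q u / 2) and sin(q u / 2); the head of
    the integral is handled by ordinary adaptive quadrature and the
    oscillatory tail by QUADPACK's semi-infinite Fourier integrator, which
    sums over cycles with extrapolation.  Returns (upper-tail p, error bound).
    """

    # Plain-Python loops beat vectorised numpy here: QUADPACK evaluates the
    # integrand one scalar at a time, so per-call array overhead dominates.
    lam_list = [float(l) for l in lam]
    atan, log1p, sin, cos, exp = math.atan, math.log1p, math.sin, math.cos, math.exp

    def _parts(u: float) -> tuple[float, float]:
        theta = 0.0
        logrho = 0.0
        for l in lam_list:
            x = l * u
            theta += atan(x)
            logrho += log1p(x * x)
        return 0.5 * theta, 1.0 / (u * exp(0.25 * logrho))

    def f_head(u: float) -> float:
        psi, r = _parts(u)
        return sin(psi - w * u) * r

    def f_cos(u: float) -> float:
        psi, r = _parts(u)
        return sin(psi) * r

    def f_sin(u: float) -> float:
        psi, r = _parts(u)
        return cos(psi) * r

    w = q / 2.0
    # Head covers at most ~8 oscillation periods; when the integrand decays
    # before the first period ends (q far out in the tail), cut over to the
    # Fourier integrator early instead of resolving thousands of cycles.
    u0 = min(16.0 * math.pi / q, 32.0 / max(lam_list))
    head, e1 = integrate.quad(
        f_head, 0.0, u0, epsabs=epsabs, epsrel=1e-12, limit=200,
    )
    tail_cos, e2 = integrate.quad(
        f_cos, u0, np.inf, weight="cos", wvar=w, epsabs=epsabs, limlst=80, limit=200,
    )
    tail_sin, e3 = integrate.quad(
        f_sin, u0, np.inf, weight="sin", wvar=w, epsabs=epsabs, limlst=80, limit=200,
    )
    p = 0.5 + (head + tail_cos - tail_sin) / math.pi
    return p, (e1 + e2 + e3) / math.pi


def quadform_pvalue(
    eigenvalues: Sequence[float], q: float, epsabs: float = 1e-11
) -> float:
    """Upper-tail probability of a positively weighted sum of 1-df chi-squares.

    Computed by Imhof's numerical inversion of the characteristic function
    (absolute accuracy on the order of 1e-9 or better); the equal-eigenvalue
    case reduces to the exact chi-squared tail.  When the inversion fails or
    returns a non-positive value, a Liu-type moment-matching approximation is
    used and a warning logged.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    if lam.size == 0:
        raise ValueError("at least one eigenvalue is required")
    if (lam <= 0).any():
        lam = lam[lam > 1e-12 * lam.max()]
        if lam.size == 0:
            raise ValueError("no positive eigenvalues")
    if q < 0:
        raise ValueError("the observed statistic must be non-negative")
    if q == 0:
        return 1.0
    # Exact chi-squared tail when all weights coincide.
    if np.allclose(lam, lam[0], rtol=1e-12, atol=0.0):
        return float(stats.chi2.sf(q / lam[0], df=lam.size))

    # Deep tails: the inversion integral is hopelessly oscillatory and the
    # answer is 0 or 1 to far beyond the 1e-9 absolute accuracy target, so
    # the moment-matching approximation is returned directly.
    p_liu = _liu_sf(lam, q)
    if p_liu < 1e-14:
        return float(max(p_liu, np.nextafter(0, 1)))
    if p_liu > 1.0 - 1e-14:
        return 1.0

    try:
        p, err = _imhof_sf(lam, q, epsabs=epsabs)
    except Exception:  # pragma: no cover - inversion failure path
        p, err = -1.0, np.inf
    if not np.isfinite(p) or p <= 0.0 or err > 1e-6:
        logger.warning("Imhof inversion unreliable (p=%.3g); using Liu fallback", p)
        p = _liu_sf(lam, q)
    return float(min(max(p, 0.0), 1.0)) or float(np.nextafter(0, 1))


def _mixture_quantile_liu(lambdas: np.ndarray, prob_tail: float) -> float:
    """Approximate upper-tail quantile of a chi-squared mixture by matching
    the first two moments to a scaled chi-squared distribution."""
    mu_q = lambdas.sum()
    var_q = 2.0 * (lambdas**2).sum()
    df = (lambdas**2).sum() ** 2 / (lambdas**4).sum()
    q = stats.chi2.ppf(1.0 - prob_tail, df)
    return float((q - df) / math.sqrt(2.0 * df) * math.sqrt(var_q) + mu_q)


# ---------------------------------------------------------------------------
# SKAT-O
# ---------------------------------------------------------------------------

class SkatOResult(NamedTuple):
    p_value: float
    rho_grid: tuple
    q_stats: tuple
    p_per_rho: tuple
    rho_min: float


_GAUSS_NODES_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _gauss_legendre(n: int, lo: float, hi: float) -> tuple[np.ndarray, np.ndarray]:
    if n not in _GAUSS_NODES_CACHE:
        _GAUSS_NODES_CACHE[n] = np.polynomial.legendre.leggauss(n)
    x, w = _GAUSS_NODES_CACHE[n]
    mid, half = (hi + lo) / 2.0, (hi - lo) / 2.0
    return mid + half * x, half * w


def skat_o(
    genotypes: np.ndarray,
    null: NullModel,
    weights: Optional[np.ndarray] = None,
    rho_grid: Sequence[float] = DEFAULT_RHO_GRID,
) -> SkatOResult:
    """SKAT-O p-value for one gene block.

    Parameters
    ----------
    genotypes
        ``n x m`` dosage block for the gene's qualifying variants; missing
        entries (-1) are imputed to the variant mean.
    null
        Logistic null model fitted on the same samples (covariates only).
    weights
        Per-variant weights; defaults to the Beta(1, 25) density evaluated at
        each variant's MAF, which up-weights the rarest variants.
    rho_grid
        SKAT/burden mixing grid.  A single value short-circuits to the plain
        test at that rho (rho=0 is SKAT, rho=1 the weighted burden score
        test); otherwise the minimum p over the grid is calibrated by the
        conditioning integral of the optimal-test construction.
    """
    G = np.asarray(genotypes, dtype=float)
    if G.ndim == 1:
        G = G[:, None]
    n, m = G.shape
    if n != null.fitted_probabilities.size:
        raise ValueError("genotype block and null model sample counts differ")
    miss = G < 0
    if miss.any():
        with np.errstate(invalid="ignore"):
            col_mean = np.nanmean(np.where(miss, np.nan, G), axis=0)
        col_mean = np.nan_to_num(col_mean)
        G = np.where(miss, col_mean[None, :], G)
    if np.allclose(G.var(axis=0), 0.0):
        raise ValueError("untestable unit: zero-variance gene block")
    if weights is None:
        maf = G.mean(axis=0) / 2.0
        maf = np.clip(np.minimum(maf, 1.0 - maf), 1e-8, None)
        weights = stats.beta.pdf(maf, 1.0, 25.0)
    w = np.asarray(weights, dtype=float)
    if w.size != m:
        raise ValueError("one weight per variant is required")

    mu = null.fitted_probabilities
    v = mu * (1.0 - mu)
    X = null.design
    r = null.residuals

    GW = G * w[None, :]
    s = GW.T @ r  # weighted score vector, length m
    # A = GW' P0 GW with P0 = V - V X (X'VX)^{-1} X'V
    VG = GW * v[:, None]
    GtVG = GW.T @ VG
    XtVX = X.T @ (X * v[:, None])
    XtVG = X.T @ VG
    A = GtVG - XtVG.T @ np.linalg.solve(XtVX, XtVG)
    A = (A + A.T) / 2.0

    rho_grid = tuple(float(r_) for r_ in rho_grid)
    if any(r_ < 0 or r_ > 1 for r_ in rho_grid):
        raise ValueError("rho values must lie in [0, 1]")
    # A rank-1 correlation structure (rho = 1) makes the omnibus integrand
    # singular; the grid is capped just below 1 inside the omnibus, while a
    # single-rho call keeps the exact value.
    eff_grid = rho_grid if len(rho_grid) == 1 else tuple(
        min(r_, 0.999) for r_ in rho_grid
    )

    ss = float(s @ s)
    s1 = float(s.sum())
    q_stats, p_per_rho, lambdas_per_rho = [], [], []
    for rho in eff_grid:
        q_rho = (1.0 - rho) * ss + rho * s1**2
        if rho >= 1.0:
            lam = np.array([float(np.ones(m) @ A @ np.ones(m))])
        elif rho == 0.0:
            lam = np.linalg.eigvalsh(A)
        else:
            R = (1.0 - rho) * np.eye(m) + rho * np.ones((m, m))
            C = np.linalg.cholesky(R)
            lam = np.linalg.eigvalsh(C.T @ A @ C)
        lam = lam[lam > max(1e-10, 1e-10 * lam.max())]
        if lam.size == 0:
            raise ValueError("untestable unit: degenerate kernel")
        q_stats.append(q_rho)
        lambdas_per_rho.append(lam)
        p_per_rho.append(quadform_pvalue(lam, q_rho))

    if len(rho_grid) == 1:
        p = p_per_rho[0]
        return SkatOResult(p, rho_grid, tuple(q_stats), tuple(p_per_rho), rho_grid[0])

    p_min = min(p_per_rho)
    rho_min = rho_grid[int(np.argmin(p_per_rho))]
    # A single variant makes Q_rho identical for every rho (the SKAT and
    # burden statistics coincide); no multiplicity to calibrate.
    if m == 1:
        return SkatOResult(p_min, rho_grid, tuple(q_stats), tuple(p_per_rho), rho_min)

    # Per-rho quantiles of the mixture at the observed minimum p.
    q_min = np.array(
        [_mixture_quantile_liu(lam, p_min) for lam in lambdas_per_rho]
    )

    # Omnibus parameters, all derived from A (= Z'Z for Z = P0^{1/2} G W).
    A1 = A @ np.ones(m)
    S = float(np.ones(m) @ A1)  # 1'A1
    if S <= 0:
        return SkatOResult(p_min, rho_grid, tuple(q_stats), tuple(p_per_rho), rho_min)
    zbar_sq = S / m**2  # z̄'z̄
    cof = m * A1 / S  # projections of Z columns on z̄
    kernel = A - np.outer(A1, A1) / S
    lam_k = np.linalg.eigvalsh((kernel + kernel.T) / 2.0)
    lam_k = lam_k[lam_k > max(1e-10, 1e-10 * abs(lam_k).max())]
    if lam_k.size == 0:
        # Rank-1 kernel: every rho sees the same burden-direction statistic.
        return SkatOResult(p_min, rho_grid, tuple(q_stats), tuple(p_per_rho), rho_min)
    item1 = zbar_sq * np.outer(cof, cof)  # Z1'Z1 of the projected part
    var_zeta = 4.0 * float((item1 * kernel).sum())
    mu_q = lam_k.sum()
    var_q = 2.0 * (lam_k**2).sum() + var_zeta
    tau = np.array(
        [(m**2 * rho + (1.0 - rho) * float(cof @ cof)) * zbar_sq for rho in eff_grid]
    )
    one_minus_rho = np.array([1.0 - rho for rho in eff_grid])

    # Conditioning integral over the chi-squared(1) component along z̄.
    # Substituting x = t^2 removes the density singularity at zero.
    t_nodes, t_weights = _gauss_legendre(128, 1e-8, math.sqrt(45.0))
    x_nodes = t_nodes**2
    sd_ratio = math.sqrt(max(var_q - var_zeta, 1e-300)) / math.sqrt(var_q)
    bounds = ((q_min[None, :] - np.outer(x_nodes, tau)) / one_minus_rho[None, :]).min(axis=1)
    bounds_std = np.maximum((bounds - mu_q) * sd_ratio + mu_q, 0.0)
    cap = mu_q + 1e4 * max(mu_q, 1.0)
    need = (bounds > 0) & (bounds_std < cap)
    cdf = np.where(bounds <= 0, 0.0, 1.0)
    if need.any():
        # The kernel CDF is analytic, so a Chebyshev interpolant over the
        # needed range (anchored on a handful of exact Imhof evaluations)
        # replaces one inversion per quadrature node.
        lo, hi = float(bounds_std[need].min()), float(bounds_std[need].max())
        if hi - lo < 1e-9 or need.sum() <= 12:
            for i in np.nonzero(need)[0]:
                cdf[i] = 1.0 - quadform_pvalue(
                    lam_k, float(bounds_std[i]), epsabs=1e-9
                )
        else:
            n_cheb = 16
            cheb_x = np.cos(np.pi * (np.arange(n_cheb) + 0.5) / n_cheb)
            nodes = (hi + lo) / 2.0 + (hi - lo) / 2.0 * cheb_x
            vals = np.array(
                [1.0 - quadform_pvalue(lam_k, float(b), epsabs=1e-9) for b in nodes]
            )
            coef = np.polynomial.chebyshev.chebfit(cheb_x, vals, deg=n_cheb - 1)
            scaled = (bounds_std[need] - (hi + lo) / 2.0) / ((hi - lo) / 2.0)
            cdf[need] = np.clip(
                np.polynomial.chebyshev.chebval(scaled, coef), 0.0, 1.0
            )
    dens = 2.0 * t_nodes * stats.chi2.pdf(x_nodes, df=1)
    total = float((t_weights * cdf * dens).sum())
    p = 1.0 - total
    # The omnibus p can never exceed the Bonferroni bound over the grid.
    p = min(p, p_min * len(rho_grid))
    p = float(min(max(p, np.nextafter(0, 1)), 1.0))
    return SkatOResult(p, rho_grid, tuple(q_stats), tuple(p_per_rho), rho_min)


# ---------------------------------------------------------------------------
# Single-variant tests
# ---------------------------------------------------------------------------

def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher's exact p-value by the minimum-likelihood rule.

    Sums the hypergeometric probabilities of every table with the observed
    margins whose probability does not exceed that of the observed table.
    """
    (a, b), (c, d) = table
    if not (type(a) is int and type(b) is int and type(c) is int and type(d) is int):
        cells = (a, b, c, d)
        if any(not float(x).is_integer() for x in cells):
            raise ValueError("non-integer counts in 2x2 table")
        a, b, c, d = (int(x) for x in cells)
    if a < 0 or b < 0 or c < 0 or d < 0:
        raise ValueError("negative counts in 2x2 table")
    r1, r2 = a + b, c + d
    n_total = r1 + r2
    if r1 == 0 or r2 == 0:
        raise ValueError("zero row margin; Fisher's test undefined")
    c1 = a + c
    lo = max(0, r1 + c1 - n_total)
    hi = min(r1, c1)
    # Hypergeometric pmf over the support, seeded at `lo` through log-gamma
    # and extended by the exact ratio recurrence; avoids per-call scipy
    # overhead, which dominates when this runs over millions of tables.
    lg = math.lgamma
    log_pmf_lo = (
        lg(r1 + 1) - lg(lo + 1) - lg(r1 - lo + 1)
        + lg(r2 + 1) - lg(c1 - lo + 1) - lg(r2 - c1 + lo + 1)
        - (lg(n_total + 1) - lg(c1 + 1) - lg(n_total - c1 + 1))
    )
    pmf = [math.exp(log_pmf_lo)]
    for k in range(lo, hi):
        pmf.append(
            pmf[-1] * ((r1 - k) * (c1 - k)) / ((k + 1) * (r2 - c1 + k + 1))
        )
    p_obs = pmf[a - lo]
    # Relative tolerance absorbs floating-point jitter on exact ties.
    cut = p_obs * (1.0 + 1e-11)
    kept = [v for v in pmf if v <= cut]
    if len(kept) == len(pmf):
        return 1.0
    return min(sum(kept), 1.0)


class OddsRatioCI(NamedTuple):
    odds_ratio: float
    ci_low: float
    ci_high: float
    corrected: bool  # Haldane-Anscombe +0.5 applied


def odds_ratio_ci(table: Sequence[Sequence[int]], z: float = 1.96) -> OddsRatioCI:
    """Sample odds ratio with a Wald confidence interval on the log scale.

    Tables containing a zero cell receive the Haldane-Anscombe +0.5
    continuity correction in every cell (flagged in the result).
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("negative counts in 2x2 table")
    corrected = min(a, b, c, d) == 0
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = math.log(or_)
    return OddsRatioCI(
        or_, math.exp(log_or - z * se), math.exp(log_or + z * se), corrected
    )


def bonferroni(p_raw: float, n_tests: int) -> float:
    """Family-wise adjusted p-value: min(1, p * number of tests)."""
    if not (0 < p_raw <= 1):
        raise ValueError("p_raw must lie in (0, 1]")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return min(1.0, p_raw * n_tests)


# ---------------------------------------------------------------------------
# Scan driver
# ---------------------------------------------------------------------------

@dataclass
class AssociationResult:
    unit_id: str
    unit_kind: str  # gene | variant
    contrast: str
    n_variants: int
    case_n: int
    control_n: int
    p_raw: float
    p_adjusted: float = 1.0
    n_tests: int = 1
    table: Optional[tuple] = None  # ((a, b), (c, d)) allelic counts
    odds_ratio: Optional[float] = None
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    chrom: Optional[str] = None
    start: Optional[int] = None
    end: Optional[int] = None


def _allelic_table(dose: np.ndarray, y: np.ndarray) -> tuple:
    """2x2 allelic counts [[case alt, case ref], [ctrl alt, ctrl ref]] over
    non-missing genotypes."""
    known = dose != MISSING
    case = known & (y == 1)
    ctrl = known & (y == 0)
    a = int(dose[case].sum())
    b = 2 * int(case.sum()) - a
    c = int(dose[ctrl].sum())
    d = 2 * int(ctrl.sum()) - c
    return ((a, b), (c, d))


def run_scan(
    matrix: GenotypeMatrix,
    variants: Sequence[VariantRecord],
    samples: Sequence[SampleRecord],
    regions: Sequence[Region],
    gene_models: Sequence[GeneModel],
    contrasts: Sequence[PhenotypeContrast],
    unit_kind: str = "gene",
    maf_max: float = 0.05,
    mac_min: int = 3,
    n_pcs: int = 4,
    rho_grid: Sequence[float] = DEFAULT_RHO_GRID,
) -> list[AssociationResult]:
    """Scan every gene (or non-silent variant) inside the regions, per contrast.

    The matrix rows must align with ``samples`` (the already-selected analysis
    cohort) and its columns with ``variants``.  For each contrast, the cohort
    restricts to samples matching the case or control rule; the rare-variant
    inclusion rules (non-silent class, MAF < ``maf_max`` folded on this
    cohort, MAC >= ``mac_min``) are then applied per variant.  Gene units are
    tested with SKAT-O using principal components 1-``n_pcs`` as covariates;
    variant units with Fisher's exact test on the allelic table.  Results are
    Bonferroni-adjusted within each contrast family and sorted by raw p.
    """
    if unit_kind not in ("gene", "variant"):
        raise ValueError("unit_kind must be 'gene' or 'variant'")
    if matrix.n_samples != len(samples):
        raise ValueError("matrix rows and sample records are misaligned")
    if matrix.n_variants != len(variants):
        raise ValueError("matrix columns and variant records are misaligned")

    region_genes: list[GeneModel] = []
    seen_genes: set[str] = set()
    in_region = np.zeros(len(variants), dtype=bool)
    for region in regions:
        for g in genes_in_region(region, gene_models):
            if g.name not in seen_genes:
                seen_genes.add(g.name)
                region_genes.append(g)
        for idx, v in enumerate(variants):
            if v.chrom == region.chrom and region.start <= v.pos <= region.end:
                in_region[idx] = True

    results: list[AssociationResult] = []
    for contrast in contrasts:
        case_mask = np.array([contrast.case_rule(s) for s in samples], dtype=bool)
        ctrl_mask = np.array([contrast.control_rule(s) for s in samples], dtype=bool)
        if (case_mask & ctrl_mask).any():
            raise ValueError(f"contrast {contrast.name}: case and control rules overlap")
        sel = np.nonzero(case_mask | ctrl_mask)[0]
        n_case, n_ctrl = int(case_mask.sum()), int(ctrl_mask.sum())
        if n_case == 0 or n_ctrl == 0:
            logger.warning(
                "contrast %s skipped: %d cases / %d controls", contrast.name, n_case, n_ctrl
            )
            continue
        sub = matrix.subset_samples(sel)
        y = case_mask[sel].astype(int)

        qualifying = []
        for j in range(len(variants)):
            if not in_region[j] or not is_nonsilent(variants[j]):
                continue
            dose_j = sub.dosage[:, j]
            if (dose_j != MISSING).sum() == 0:
                continue
            st = alt_allele_stats(sub, j)
            if rare_variant_filter(st, maf_max=maf_max, mac_min=mac_min):
                qualifying.append(j)
        qual_set = set(qualifying)

        family: list[AssociationResult] = []
        if unit_kind == "gene":
            k_eff = n_pcs
            pcs = None
            while k_eff > 0:
                try:
                    pcs = compute_pcs(sub, k=k_eff)
                    break
                except ValueError:
                    k_eff -= 1
            if k_eff < n_pcs:
                logger.warning(
                    "contrast %s: only %d principal components available "
                    "(requested %d)", contrast.name, k_eff, n_pcs,
                )
            if pcs is None:
                X = np.ones((len(sel), 1))
            else:
                X = np.column_stack([np.ones(len(sel)), pcs])
            null = fit_null_logistic(y, X)
            for g in region_genes:
                g_idx = [j for j in variants_in_gene(g, variants) if j in qual_set]
                if not g_idx:
                    continue
                block = sub.dosage[:, g_idx].astype(float)
                try:
                    res = skat_o(block, null, rho_grid=rho_grid)
                except ValueError:
                    continue
                family.append(
                    AssociationResult(
                        unit_id=g.name,
                        unit_kind="gene",
                        contrast=contrast.name,
                        n_variants=len(g_idx),
                        case_n=n_case,
                        control_n=n_ctrl,
                        p_raw=res.p_value,
                        chrom=g.chrom,
                        start=g.start + 1,
                        end=g.end,
                    )
                )
        else:
            for j in qualifying:
                tab = _allelic_table(sub.dosage[:, j], y)
                try:
                    p = fisher_exact_2x2(tab)
                except ValueError:
                    continue
                orci = odds_ratio_ci(tab)
                v = variants[j]
                family.append(
                    AssociationResult(
                        unit_id=v.variant_id,
                        unit_kind="variant",
                        contrast=contrast.name,
                        n_variants=1,
                        case_n=n_case,
                        control_n=n_ctrl,
                        p_raw=p,
                        table=tab,
                        odds_ratio=orci.odds_ratio,
                        ci_low=orci.ci_low,
                        ci_high=orci.ci_high,
                        chrom=v.chrom,
                        start=v.pos,
                        end=v.pos,
                    )
                )
        n_tests = len(family)
        for res in family:
            res.n_tests = n_tests
            res.p_adjusted = bonferroni(res.p_raw, n_tests)
        family.sort(key=lambda r: (r.p_raw, r.unit_id))
        results.extend(family)
    return results


def write_results_tsv(path, results: Sequence[AssociationResult]) -> None:
    """Association results table, one row per tested unit."""
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(
            [
                "contrast", "unit_kind", "unit_id", "chrom", "start", "end",
                "n_variants", "cases", "controls", "n_tests", "p", "p_adjusted",
                "odds_ratio", "ci_low", "ci_high",
                "case_alt", "case_ref", "ctrl_alt", "ctrl_ref",
            ]
        )
        for r in results:
            tab = r.table or ((None, None), (None, None))
            w.writerow(
                [
                    r.contrast, r.unit_kind, r.unit_id, r.chrom, r.start, r.end,
                    r.n_variants, r.case_n, r.control_n, r.n_tests,
                    f"{r.p_raw:.6g}", f"{r.p_adjusted:.6g}",
                    "" if r.odds_ratio is None else f"{r.odds_ratio:.6g}",
                    "" if r.ci_low is None else f"{r.ci_low:.6g}",
                    "" if r.ci_high is None else f"{r.ci_high:.6g}",
                    tab[0][0], tab[0][1], tab[1][0], tab[1][1],
                ]
            )
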