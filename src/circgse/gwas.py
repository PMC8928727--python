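"""Mixed-linear-model association scan.

The phenotype model is

    y_i = mu + b_j x_ij + g_i + e_i,   g ~ N(0, sigma_a^2 G),  e ~ N(0, sigma_e^2 I)

with x_ij the allele dosage (0/1/2), G the additive genomic relationship
matrix (VanRaden method 1 over all SNPs) and a single intercept as fixed
effect (phenotypes are assumed pre-adjusted for environmental effects).

Variance components are estimated once by REML (single eigendecomposition of
G, restricted likelihood profiled over delta = sigma_e^2 / sigma_a^2, grid
search plus bounded refinement) and then held fixed across SNPs while each
marker effect is estimated by GLS with a Wald normal-approximation p-value —
the usual EMMAX-style approximation.

``MixedLinearGWAS`` is the model object; ``fit()`` returns
``MLMGwasResults`` holding variance components and the per-SNP table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io import GwasSummary, MarkerPanel

logger = logging.getLogger("circgse")

__all__ = [
    "Grm",
    "VarianceComponents",
    "compute_grm",
    "reml_fit",
    "mlm_scan",
    "MixedLinearGWAS",
    "MLMGwasResults",
]


@dataclass(frozen=True)
class Grm:
    """Additive genomic relationship matrix among individuals.

    VanRaden method 1: dosages mean-imputed and centred by twice the allele
    frequency, ``G = Z Z' / (2 * sum p_k (1 - p_k))``.
    """

    matrix: np.ndarray
    denominator: float

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("GRM must be square")
        if not np.isfinite(m).all():
            raise ValueError("GRM has non-finite entries")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("GRM must be symmetric")
        object.__setattr__(self, "matrix", m)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class VarianceComponents:
    sigma_a2: float
    sigma_e2: float
    log_likelihood: float  # restricted log-likelihood at the optimum

    def __post_init__(self):
        if self.sigma_a2 < 0 or self.sigma_e2 <= 0:
            raise ValueError("require sigma_a2 >= 0 and sigma_e2 > 0")

    @property
    def h2(self) -> float:
        return self.sigma_a2 / (self.sigma_a2 + self.sigma_e2)


def compute_grm(panel: MarkerPanel) -> Grm:
    """VanRaden method-1 GRM from a genotyped panel.

    Missing dosages are imputed to the SNP mean (2 p_k) before centring, so
    they contribute nothing to relationships.  Monomorphic SNPs add zero to
    both numerator and denominator; a panel with no polymorphic SNP is an
    error.
    """
    if panel.genotypes is None:
        raise ValueError("compute_grm requires genotypes")
    g = panel.genotypes
    if g.shape[0] < 2:
        raise ValueError("compute_grm requires >= 2 individuals")
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(g, axis=0) / 2.0
    freq = np.where(np.isnan(freq), 0.0, freq)
    denom = float(2.0 * np.sum(freq * (1.0 - freq)))
    if denom <= 0:
        raise ValueError("no polymorphic SNPs; GRM undefined")
    z = np.where(np.isnan(g), 0.0, g - 2.0 * freq)
    # imputed entries equal the mean dosage, i.e. zero after centring
    return Grm(z @ z.T / denom, denom)


def _reml_profile(delta, d, uty, utx):
    """Profiled restricted log-likelihood at each delta = sigma_e2/sigma_a2.

    Works in the eigenbasis of G (eigenvalues ``d``): H = G + delta I is
    diagonal there.  Returns (log-lik array, sigma_a2 array).
    """
    delta = np.atleast_1d(np.asarray(delta, dtype=float))
    n = d.size
    p = utx.shape[1]
    q = n - p
    w = 1.0 / (d[None, :] + delta[:, None])  # len(delta) x n
    xhx = np.einsum("kn,np,nq->kpq", w, utx, utx)  # X' H^-1 X
    xhy = np.einsum("kn,np,n->kp", w, utx, uty)
    yhy = w @ (uty**2)
    sign, logdet_xhx = np.linalg.slogdet(xhx)
    sol = np.linalg.solve(xhx, xhy[..., None])[..., 0]
    ypy = yhy - np.einsum("kp,kp->k", xhy, sol)
    ypy = np.maximum(ypy, 1e-300)
    sigma_a2 = ypy / q
    logdet_h = np.sum(np.log(d[None, :] + delta[:, None]), axis=1)
    ll = -0.5 * (
        q * (np.log(2 * np.pi) + 1.0)
        + q * np.log(sigma_a2)
        + logdet_h
        + logdet_xhx
    )
    return ll, sigma_a2


def reml_fit(
    y: np.ndarray,
    grm: Grm,
    _eig: tuple[np.ndarray, np.ndarray] | None = None,
) -> VarianceComponents:
    """REML variance components for the one-random-effect model.

    Profiles the restricted log-likelihood over delta = sigma_e2/sigma_a2 on
    a log10 grid spanning [1e-5, 1e6], then refines the best bracket with
    bounded scalar optimisation.  ``_eig`` allows a caller holding the
    eigendecomposition of G to avoid recomputing it.
    """
    y = np.asarray(y, dtype=float).ravel()
    if not np.isfinite(y).all():
        raise ValueError("phenotype contains non-finite values")
    if y.size != grm.n:
        raise ValueError("phenotype length does not match GRM")
    if np.var(y) <= 0:
        raise ValueError("phenotype has zero variance")
    if _eig is None:
        d, u = np.linalg.eigh(grm.matrix)
    else:
        d, u = _eig
    if d.min() < -1e-6 * max(1.0, d.max()):
        raise ValueError("GRM is not positive semidefinite within tolerance")
    d = np.maximum(d, 0.0)
    uty = u.T @ y
    utx = u.T @ np.ones((y.size, 1))

    log_grid = np.linspace(-5.0, 6.0, 56)
    ll_grid, _ = _reml_profile(10.0**log_grid, d, uty, utx)
    k = int(np.argmax(ll_grid))
    lo = log_grid[max(k - 1, 0)]
    hi = log_grid[min(k + 1, log_grid.size - 1)]

    def neg_ll(log_delta):
        return -_reml_profile(10.0**log_delta, d, uty, utx)[0][0]

    res = optimize.minimize_scalar(neg_ll, bounds=(lo, hi), method="bounded")
    best_log = res.x if -res.fun >= ll_grid[k] else log_grid[k]
    delta = 10.0**best_log
    ll, sigma_a2 = _reml_profile(delta, d, uty, utx)
    return VarianceComponents(
        sigma_a2=float(sigma_a2[0]),
        sigma_e2=float(sigma_a2[0] * delta),
        log_likelihood=float(ll[0]),
    )


def mlm_scan(
    y: np.ndarray,
    panel: MarkerPanel,
    grm: Grm,
    varcomps: VarianceComponents,
    _eig: tuple[np.ndarray, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Per-SNP GLS effect estimates with variance components held fixed.

    V = sigma_a^2 G + sigma_e^2 I.  For each SNP, b_hat = (x'V^-1x)^-1 x'V^-1 y
    with an intercept projected out, se from the GLS information, and a Wald
    p-value from the normal approximation.  Monomorphic SNPs are flagged
    (beta/se/p = NaN) and skipped.

    Returns a DataFrame aligned to ``panel.sites`` with columns
    beta / se / wald / p.
    """
    if panel.genotypes is None:
        raise ValueError("mlm_scan requires genotypes")
    y = np.asarray(y, dtype=float).ravel()
    if _eig is None:
        d, u = np.linalg.eigh(grm.matrix)
    else:
        d, u = _eig
    d = np.maximum(d, 0.0)
    scale = 1.0 / np.sqrt(varcomps.sigma_a2 * d + varcomps.sigma_e2)

    g = panel.genotypes
    with np.errstate(invalid="ignore"):
        col_mean = np.nanmean(g, axis=0)
    x = np.where(np.isnan(g), col_mean, g)

    yt = scale * (u.T @ y)
    xt = scale[:, None] * (u.T @ x)
    onet = scale * (u.T @ np.ones_like(y))

    # project the (whitened) intercept out of response and dosages
    denom1 = onet @ onet
    yt = yt - onet * (onet @ yt) / denom1
    xt = xt - onet[:, None] * ((onet @ xt) / denom1)[None, :]

    xtx = np.einsum("ij,ij->j", xt, xt)
    poly = xtx > 1e-12
    beta = np.full(panel.n_snps, np.nan)
    se = np.full(panel.n_snps, np.nan)
    beta[poly] = (yt @ xt[:, poly]) / xtx[poly]
    se[poly] = 1.0 / np.sqrt(xtx[poly])
    if not poly.all():
        logger.info("mlm_scan: %d monomorphic SNPs skipped", int((~poly).sum()))
    wald = beta / se
    p = 2.0 * stats.norm.sf(np.abs(wald))
    p = np.where(np.isnan(p), np.nan, np.maximum(p, np.finfo(float).tiny))
    return pd.DataFrame(
        {"beta": beta, "se": se, "wald": wald, "p": p}, index=panel.sites.index
    )


class MixedLinearGWAS:
    """Mixed-linear-model GWAS of one pre-adjusted phenotype.

    Parameters
    ----------
    y : array-like, length n_individuals
        Pre-adjusted phenotype (fixed environmental effects already removed).
    panel : MarkerPanel
        QC-passed genotyped panel; dosages 0/1/2 with NaN missing.
    grm : Grm, optional
        Genomic relationship matrix; computed from ``panel`` when omitted.

    ``fit()`` estimates (sigma_a2, sigma_e2) by REML and runs the EMMAX-style
    scan, returning :class:`MLMGwasResults`.
    """

    def __init__(self, y, panel: MarkerPanel, grm: Grm | None = None):
        self.y = np.asarray(y, dtype=float).ravel()
        if panel.genotypes is None:
            raise ValueError("MixedLinearGWAS requires genotypes")
        if self.y.size != panel.n_individuals:
            raise ValueError("phenotype length does not match panel individuals")
        self.panel = panel
        self.grm = grm if grm is not None else compute_grm(panel)
        self._eig = None

    def _eigendecomposition(self):
        if self._eig is None:
            self._eig = np.linalg.eigh(self.grm.matrix)
        return self._eig

    def fit(self) -> "MLMGwasResults":
        eig = self._eigendecomposition()
        varcomps = reml_fit(self.y, self.grm, _eig=eig)
        table = mlm_scan(self.y, self.panel, self.grm, varcomps, _eig=eig)
        return MLMGwasResults(self, varcomps, table)


class MLMGwasResults:
    """Fitted MLM GWAS: variance components plus the per-SNP scan table."""

    def __init__(self, model: MixedLinearGWAS, varcomps: VarianceComponents,
                 table: pd.DataFrame):
        self.model = model
        self.varcomps = varcomps
        self.table = table

    @property
    def h2(self) -> float:
        """Heritability estimate sigma_a2 / (sigma_a2 + sigma_e2)."""
        return self.varcomps.h2

    def to_summary(self) -> GwasSummary:
        """Per-SNP results as a GwasSummary (monomorphic SNPs dropped)."""
        df = pd.concat([self.model.panel.sites[["snp_id", "chrom", "pos"]],
                        self.table[["beta", "se", "p"]]], axis=1)
        df = df[np.isfinite(df["beta"])]
        return GwasSummary(df.reset_index(drop=True))

    def summary(self, top: int = 10) -> str:
        vc = self.varcomps
        lines = [
            "Mixed-linear-model GWAS (EMMAX approximation)",
            "=" * 54,
            f"individuals:        {self.model.panel.n_individuals}",
            f"SNPs scanned:       {self.model.panel.n_snps}",
            f"sigma_a^2 (REML):   {vc.sigma_a2:.4f}",
            f"sigma_e^2 (REML):   {vc.sigma_e2:.4f}",
            f"h^2:                {vc.h2:.4f}",
            f"restricted logL:    {vc.log_likelihood:.2f}",
            "",
            f"top {top} SNPs by p-value:",
        ]
        df = self.to_summary().frame.nsmallest(top, "p")
        lines.append(df.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
        return "\n".join(lines)
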