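"""Per-variant marginal regression with configurable ancestry adjustment.

Each variant j is tested with the model

    E[y_i | g_ij, w_i] = alpha + beta_j * g_ij + gamma' w_i,

where w_i is the chosen covariate vector (nothing, estimated admixture
proportion, PC scores, or a custom construction).  H0: beta_j = 0 is tested
with a Wald statistic referred to the large-sample standard normal.  Fits
use the Frisch-Waugh-Lovell decomposition -- y and all genotype columns are
residualized on (1, W) once, then each variant reduces to a simple
regression -- which is algebraically identical to the full per-variant OLS
fit but vectorizes across the genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import VariantPanel

__all__ = [
    "CovariateSet",
    "AssocResult",
    "marginal_gwas",
    "count_spurious_chromosomes",
    "genomic_inflation",
    "GENOME_WIDE_ALPHA_ARRAY",
    "GENOME_WIDE_ALPHA_SEQUENCE",
    "CHI2_1DF_MEDIAN",
]

GENOME_WIDE_ALPHA_ARRAY = 5.0e-8
GENOME_WIDE_ALPHA_SEQUENCE = 5.0e-9
CHI2_1DF_MEDIAN = float(stats.chi2.ppf(0.5, df=1))  # ~0.4549


@dataclass
class CovariateSet:
    """Adjustment covariates for the marginal model (intercept implicit)."""

    label: str
    columns: np.ndarray

    def __post_init__(self):
        if self.label not in ("none", "admixture", "pcs", "custom"):
            raise ValueError(f"unknown covariate-set label {self.label!r}")
        W = np.asarray(self.columns, dtype=float)
        if W.ndim == 1:
            W = W[:, None]
        if W.ndim != 2:
            raise ValueError("columns must be an n x q matrix")
        if W.shape[1] > 0:
            if np.any(W.std(axis=0) == 0.0):
                raise ValueError("constant covariate column (the intercept is implicit)")
            if np.linalg.matrix_rank(np.column_stack([np.ones(W.shape[0]), W])) < W.shape[1] + 1:
                raise ValueError("covariate matrix is rank deficient")
        self.columns = W

    @classmethod
    def none(cls, n: int) -> "CovariateSet":
        return cls(label="none", columns=np.empty((n, 0)))

    @property
    def q(self) -> int:
        return self.columns.shape[1]


@dataclass
class AssocResult:
    """Genome-wide marginal-regression results under one covariate set."""

    chrom: np.ndarray
    pos_bp: np.ndarray
    beta: np.ndarray
    se: np.ndarray
    wald: np.ndarray
    p: np.ndarray
    covariate_label: str = "none"
    nuisance: np.ndarray | None = None  # (q+1) x m: alpha-hat and gamma-hat per fit
    flagged: np.ndarray | None = field(default=None)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "pos_bp": self.pos_bp,
                "beta": self.beta,
                "se": self.se,
                "wald": self.wald,
                "p": self.p,
            }
        )


def marginal_gwas(
    y: np.ndarray, G: np.ndarray, panel: VariantPanel, covs: CovariateSet
) -> AssocResult:
    """OLS of y on (1, g_j, covariates) for every variant j, with Wald p-values.

    Variants whose genotype is (numerically) collinear with the covariates,
    including monomorphic ones, are flagged and reported with missing
    statistics.
    """
    y = np.asarray(y, dtype=float)
    G = np.asarray(G)
    n, m = G.shape
    if y.shape[0] != n or covs.columns.shape[0] != n:
        raise ValueError("dimension mismatch between y, G and covariates")
    q = covs.q
    if n <= q + 2:
        raise ValueError("need n > q + 2 observations")

    W = np.column_stack([np.ones(n), covs.columns])
    Q, _ = np.linalg.qr(W)
    y_r = y - Q @ (Q.T @ y)
    Gf = G.astype(float)
    G_r = Gf - Q @ (Q.T @ Gf)

    denom = np.einsum("ij,ij->j", G_r, G_r)
    col_ss = np.einsum("ij,ij->j", Gf - Gf.mean(axis=0), Gf - Gf.mean(axis=0))
    flagged = denom <= 1e-10 * np.maximum(col_ss, 1.0)

    denom_safe = np.where(flagged, 1.0, denom)
    beta = (G_r.T @ y_r) / denom_safe
    dof = n - q - 2
    rss = (y_r @ y_r) - beta**2 * denom_safe
    rss = np.maximum(rss, 0.0)
    se = np.sqrt(rss / dof / denom_safe)
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = beta / se
    p = 2.0 * stats.norm.sf(np.abs(wald))
    for arr in (beta, se, wald, p):
        arr[flagged] = np.nan

    # nuisance coefficients: gamma_j = (W'W)^{-1} W'(y - g_j beta_j)
    WtW_inv_Wt = np.linalg.solve(W.T @ W, W.T)
    coef_y = WtW_inv_Wt @ y  # (q+1,)
    coef_G = WtW_inv_Wt @ Gf  # (q+1) x m
    nuisance = coef_y[:, None] - coef_G * beta[None, :]

    return AssocResult(
        chrom=panel.chrom,
        pos_bp=panel.pos_bp,
        beta=beta,
        se=se,
        wald=wald,
        p=p,
        covariate_label=covs.label,
        nuisance=nuisance,
        flagged=flagged,
    )


def count_spurious_chromosomes(
    res: AssocResult, causal_chrom, alpha: float = GENOME_WIDE_ALPHA_ARRAY
) -> int:
    """Number of non-causal chromosomes with >= 1 genome-wide-significant variant.

    Spurious associations are counted at the chromosome level (not the
    variant level) because nearby variants in LD show similar association
    results.  Variants with missing p-values are ignored.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    ok = ~np.isnan(res.p)
    hit = ok & (res.p < alpha)
    chroms = {c for c in res.chrom[hit] if c != causal_chrom}
    return len(chroms)


def genomic_inflation(res: AssocResult) -> float:
    """Genomic inflation factor: lambda = median(wald^2) / median(chi^2_1)."""
    w2 = res.wald[~np.isnan(res.wald)] ** 2
    if w2.size == 0:
        raise ValueError("no non-missing test statistics")
    return float(np.median(w2) / CHI2_1DF_MEDIAN)
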