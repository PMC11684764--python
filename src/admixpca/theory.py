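"""Closed-form large-sample expected GWAS effect sizes under mis-adjustment.

Setting: a two-way admixed population with admixture proportion pi (mean
mu_pi, variance v_pi); two unlinked variants with ancestry-specific allele
frequencies (p11, p10) and (p21, p20), conditionally independent given pi
with g_j | pi ~ Binomial(2, p_j0 + delta_j * pi); a trait
y = beta1 * g1 + beta_pi * pi + eps; and an "extraneous PC"
z = (w1 * s(g1) + w2 * s(g2) + eta) / sd(.), a population-standardized
linear combination of the two standardized genotypes.

The expected large-sample OLS coefficient of the tested genotype under any
covariate set is obtained by solving the population normal equations built
from the model-implied first and second moments of (g1, g2, pi, z, y).
Key consequences:

* adjusting for pi gives unbiased estimates at both variants, with or
  without the extraneous z, at the causal variant;
* no adjustment confounds both variants whenever v_pi > 0 and the relevant
  allele-frequency differences are nonzero;
* adjusting for (pi, z) with z correlated with both genotypes given pi
  biases the neutral variant's estimate away from zero -- collider bias.

Every closed-form moment identity is validated against a Monte-Carlo
simulation oracle (`monte_carlo_oracle`) that actually draws cohorts and
fits the regressions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import make_collider_covariate

__all__ = [
    "TheoryParams",
    "MomentStructure",
    "model_moments",
    "expected_coefficient",
    "bias_table",
    "monte_carlo_oracle",
]

_VARS = ("g1", "g2", "pi", "z", "y")
_MODELS = {"unadjusted": (), "pi": ("pi",), "pi_z": ("pi", "z")}


@dataclass(frozen=True)
class TheoryParams:
    """Population parameters of the two-variant collider model."""

    mu_pi: float = 0.8
    v_pi: float = 0.0178
    p11: float = 0.9
    p10: float = 0.1
    p21: float = 0.9
    p20: float = 0.1
    beta1: float = 1.0
    beta_pi: float = 0.0
    z_w1: float = 1.0 / np.sqrt(2.0)
    z_w2: float = 1.0 / np.sqrt(2.0)
    z_noise_sd: float = 0.0
    trait_noise_sd: float = 1.0

    def __post_init__(self):
        for name in ("p11", "p10", "p21", "p20"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0.0 <= self.mu_pi <= 1.0:
            raise ValueError("mu_pi must be in [0, 1]")
        if self.v_pi < 0.0 or self.v_pi > self.mu_pi * (1.0 - self.mu_pi):
            raise ValueError("need 0 <= v_pi <= mu_pi*(1-mu_pi)")
        if self.trait_noise_sd <= 0.0:
            raise ValueError("trait_noise_sd must be positive")
        if self.z_w1 == 0.0 and self.z_w2 == 0.0:
            raise ValueError("z weights must not both be zero")

    @property
    def delta1(self) -> float:
        return self.p11 - self.p10

    @property
    def delta2(self) -> float:
        return self.p21 - self.p20


@dataclass
class MomentStructure:
    """First and second population moments of (g1, g2, pi, z, y)."""

    mean: np.ndarray
    cov: np.ndarray
    names: tuple = _VARS

    def __post_init__(self):
        if not np.allclose(self.cov, self.cov.T):
            raise ValueError("covariance matrix must be symmetric")
        eigmin = np.linalg.eigvalsh(self.cov).min()
        if eigmin < -1e-8:
            raise ValueError("covariance matrix must be positive semi-definite")

    def index(self, name: str) -> int:
        return self.names.index(name)


def model_moments(params: TheoryParams) -> MomentStructure:
    """Model-implied moments of (g1, g2, pi, z, y).

    With delta_j = p_j1 - p_j0 and qbar_j = p_j0 + delta_j * mu_pi:

        E[g_j]        = 2 qbar_j
        Cov(g_j, pi)  = 2 delta_j v_pi
        Var(g_j)      = 2 qbar_j (1 - qbar_j) + 2 delta_j^2 v_pi
        Cov(g1, g2)   = 4 delta1 delta2 v_pi

    y-moments follow from the linear trait model; z-moments propagate
    linearly from the standardized-genotype construction.
    """
    p = params
    d1, d2 = p.delta1, p.delta2
    q1 = p.p10 + d1 * p.mu_pi
    q2 = p.p20 + d2 * p.mu_pi

    e_g1, e_g2 = 2.0 * q1, 2.0 * q2
    var_g1 = 2.0 * q1 * (1.0 - q1) + 2.0 * d1 * d1 * p.v_pi
    var_g2 = 2.0 * q2 * (1.0 - q2) + 2.0 * d2 * d2 * p.v_pi
    cov_g1_g2 = 4.0 * d1 * d2 * p.v_pi
    cov_g1_pi = 2.0 * d1 * p.v_pi
    cov_g2_pi = 2.0 * d2 * p.v_pi
    if var_g1 <= 0.0 or var_g2 <= 0.0:
        raise ValueError("degenerate genotype variance; variants must be polymorphic")

    sd1, sd2 = np.sqrt(var_g1), np.sqrt(var_g2)
    # z0 = w1*(g1 - E g1)/sd1 + w2*(g2 - E g2)/sd2 + eta, then z = z0 / sd(z0)
    w1, w2 = p.z_w1, p.z_w2
    rho12 = cov_g1_g2 / (sd1 * sd2)
    var_z0 = w1 * w1 + w2 * w2 + 2.0 * w1 * w2 * rho12 + p.z_noise_sd**2
    sz = np.sqrt(var_z0)
    cov_z_g1 = (w1 * sd1 + w2 * cov_g1_g2 / sd2) / sz
    cov_z_g2 = (w1 * cov_g1_g2 / sd1 + w2 * sd2) / sz
    cov_z_pi = (w1 * cov_g1_pi / sd1 + w2 * cov_g2_pi / sd2) / sz

    b1, bp = p.beta1, p.beta_pi
    cov_y_g1 = b1 * var_g1 + bp * cov_g1_pi
    cov_y_g2 = b1 * cov_g1_g2 + bp * cov_g2_pi
    cov_y_pi = b1 * cov_g1_pi + bp * p.v_pi
    cov_y_z = b1 * cov_z_g1 + bp * cov_z_pi
    var_y = (
        b1 * b1 * var_g1
        + bp * bp * p.v_pi
        + 2.0 * b1 * bp * cov_g1_pi
        + p.trait_noise_sd**2
    )

    mean = np.array([e_g1, e_g2, p.mu_pi, 0.0, b1 * e_g1 + bp * p.mu_pi])
    cov = np.array(
        [
            [var_g1, cov_g1_g2, cov_g1_pi, cov_z_g1, cov_y_g1],
            [cov_g1_g2, var_g2, cov_g2_pi, cov_z_g2, cov_y_g2],
            [cov_g1_pi, cov_g2_pi, p.v_pi, cov_z_pi, cov_y_pi],
            [cov_z_g1, cov_z_g2, cov_z_pi, 1.0, cov_y_z],
            [cov_y_g1, cov_y_g2, cov_y_pi, cov_y_z, var_y],
        ]
    )
    return MomentStructure(mean=mean, cov=cov)


def expected_coefficient(
    moments: MomentStructure, covariate_labels=(), test_variant: int = 1
) -> float:
    """Large-sample OLS coefficient of g_test in y ~ 1 + g_test + covariates.

    Solves the population normal equations built from the moment structure.
    Raises on a singular design, naming the (near-)collinear pair.
    """
    if test_variant not in (1, 2):
        raise ValueError("test_variant must be 1 or 2")
    # a zero-variance covariate (e.g. pi in a homogeneous population) is a
    # constant, absorbed by the intercept: drop it rather than fail
    covariate_labels = [
        c for c in covariate_labels if moments.cov[moments.index(c), moments.index(c)] > 1e-14
    ]
    design = [f"g{test_variant}"] + list(covariate_labels)
    idx = [moments.index(v) for v in design]
    S = moments.cov[np.ix_(idx, idx)]
    s_y = moments.cov[idx, moments.index("y")]
    if np.linalg.cond(S) > 1e12:
        corr = S / np.sqrt(np.outer(np.diag(S), np.diag(S)))
        pair = ("design",)
        for i in range(len(design)):
            for j in range(i + 1, len(design)):
                if abs(corr[i, j]) > 1.0 - 1e-9:
                    pair = (design[i], design[j])
        raise np.linalg.LinAlgError(f"singular regression design; collinear pair: {pair}")
    return float(np.linalg.solve(S, s_y)[0])


def bias_table(params: TheoryParams) -> pd.DataFrame:
    """Expected coefficients for each adjustment model at both variants.

    Rows: {unadjusted, pi, pi_z} x {variant 1, variant 2}; columns report
    the expected large-sample estimate, the truth (beta1 at the causal
    variant, 0 at the neutral one), their difference, and indicator flags
    for the structural conditions under which confounding / collider bias
    operates (ancestral heterogeneity, differentiated allele frequencies, a
    direct ancestry effect, and residual genotype-z correlation given pi).
    """
    mom = model_moments(params)
    i_pi, i_z = mom.index("pi"), mom.index("z")

    def _partial_with_z(i):  # Cov(g_i, z | pi), linear partial covariance
        if params.v_pi == 0.0:
            return mom.cov[i, i_z]
        return mom.cov[i, i_z] - mom.cov[i, i_pi] * mom.cov[i_z, i_pi] / params.v_pi

    flags = {
        "heterogeneous": params.v_pi > 0.0,
        "causal_differentiated": params.delta1 != 0.0,
        "neutral_differentiated": params.delta2 != 0.0,
        "ancestry_effect": params.beta_pi != 0.0,
        "collider_z": (abs(_partial_with_z(0)) > 1e-12) and (abs(_partial_with_z(1)) > 1e-12),
    }
    rows = []
    for model, covs in _MODELS.items():
        for variant, truth in ((1, params.beta1), (2, 0.0)):
            exp = expected_coefficient(mom, covs, variant)
            rows.append(
                {"model": model, "variant": variant, "expected": exp, "truth": truth,
                 "bias": exp - truth, **flags}
            )
    return pd.DataFrame(rows)


def _pi_sampler(params: TheoryParams):
    """Beta (or degenerate) sampler with mean mu_pi and variance v_pi."""
    mu, v = params.mu_pi, params.v_pi
    if v == 0.0:
        return lambda rng, n: np.full(n, mu)
    nu = mu * (1.0 - mu) / v - 1.0
    if nu <= 0.0:
        raise ValueError("v_pi too large for a Beta law with this mean")
    a, b = mu * nu, (1.0 - mu) * nu
    return lambda rng, n: rng.beta(a, b, size=n)


def simulate_two_variant_cohort(params: TheoryParams, n: int, rng) -> dict:
    """Draw one cohort of (g1, g2, pi, z, y) under the generative model."""
    pi = _pi_sampler(params)(rng, n)
    g1 = rng.binomial(2, np.clip(params.p10 + params.delta1 * pi, 0.0, 1.0))
    g2 = rng.binomial(2, np.clip(params.p20 + params.delta2 * pi, 0.0, 1.0))
    z = make_collider_covariate(
        g1, g2, w1=params.z_w1, w2=params.z_w2, noise_sd=params.z_noise_sd, seed=rng
    )
    y = (
        params.beta1 * g1
        + params.beta_pi * pi
        + rng.normal(0.0, params.trait_noise_sd, n)
    )
    return {"g1": g1.astype(float), "g2": g2.astype(float), "pi": pi, "z": z, "y": y}


def _fit_cells(data: dict) -> dict:
    """OLS coefficient of the tested genotype for each (model, variant) cell."""
    n = data["y"].shape[0]
    cols = {k: data[k] - data[k].mean() for k in ("g1", "g2", "pi", "z", "y")}
    out = {}
    for model, covs in _MODELS.items():
        for variant in (1, 2):
            # constant covariates (pi under a point-mass law) carry no information
            active = [c for c in covs if cols[c].std() > 0.0]
            names = [f"g{variant}"] + active
            X = np.column_stack([cols[v] for v in names])
            XtX = X.T @ X / n
            Xty = X.T @ cols["y"] / n
            out[(model, variant)] = float(np.linalg.solve(XtX, Xty)[0])
    return out


def monte_carlo_oracle(
    params: TheoryParams, n: int = 200_000, reps: int = 200, seed: int = 0
) -> pd.DataFrame:
    """Empirical mean and SE of each bias_table cell over simulated cohorts.

    Independent of the closed-form path: cohorts are drawn from the
    generative model and each regression is fit by OLS on the sample.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(17,)))
    acc = {cell: [] for cell in [(m, v) for m in _MODELS for v in (1, 2)]}
    for _ in range(reps):
        cells = _fit_cells(simulate_two_variant_cohort(params, n, rng))
        for cell, val in cells.items():
            acc[cell].append(val)
    rows = []
    for (model, variant), vals in acc.items():
        vals = np.asarray(vals)
        rows.append(
            {
                "model": model,
                "variant": variant,
                "empirical": vals.mean(),
                "se": vals.std(ddof=1) / np.sqrt(len(vals)),
                "reps": len(vals),
                "n": n,
            }
        )
    return pd.DataFrame(rows)
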