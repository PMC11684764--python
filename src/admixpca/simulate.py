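"""Synthetic admixed cohorts: ancestry, genotypes, traits, and collider covariates.

Generative model
----------------
Each individual ``i`` in a two-way admixed population carries a global
admixture proportion ``pi_i`` in [0, 1] (the genome-wide fraction of the
genome inherited from ancestral population 1).  At variant ``j`` the local
ancestry count ``a_ij`` is the number of allele copies (0, 1 or 2)
inherited from population 1; marginally ``a_ij ~ Binomial(2, pi_i)``.
Conditional on local ancestry, each allele copy carries the counted allele
with the ancestry-specific frequency ``p_j1`` or ``p_j0``, so for a
non-feature variant::

    g_ij | pi_i  ~  Binomial(2, q_j(pi_i)),   q_j(pi) = pi*p_j1 + (1-pi)*p_j0.

Quantitative traits follow a single-causal-variant model::

    y_i = beta1 * g_{i,j*} + beta_pi * pi_i + eps_i,  eps_i ~ N(0, noise_sd^2).

"Features" are latent, per-individual binary indicators that shift allele
frequencies inside one or more genomic regions (possibly on several
chromosomes) at once.  They emulate localized genomic structure -- e.g.
polymorphic inversions or other high-LD haplotypes -- that principal
components can capture instead of genome-wide ancestry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AdmixtureModel",
    "VariantPanel",
    "FeatureSpec",
    "TraitSpec",
    "SimulatedCohort",
    "draw_admixture",
    "draw_local_ancestry",
    "draw_genotypes",
    "simulate_trait",
    "make_collider_covariate",
    "estimate_admixture_from_local",
    "random_panel",
    "simulate_cohort",
    "child_rng",
]

EFFECT_SIZE_GRID = (0.0, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0)
"""Causal effect sizes used in the simulation-study design."""


def child_rng(seed: int, stage: int) -> np.random.Generator:
    """Derive an independent per-stage generator from one global integer seed.

    Uses a counter-based spawn key so each pipeline stage (admixture draw,
    local ancestry, genotypes, trait noise, ...) gets a reproducible,
    statistically independent stream.
    """
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(int(stage),)))


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AdmixtureModel:
    """Distribution of global admixture proportions across individuals.

    ``beta`` draws pi ~ Beta(a, b); ``point_mass`` fixes pi = pi_fixed for
    everyone (the zero-heterogeneity limit, Var(pi) = 0); ``two_point``
    draws pi from {a, b} with equal probability.
    """

    family: str = "beta"
    a: float = 6.4
    b: float = 1.6
    pi_fixed: float = 0.8

    def __post_init__(self):
        if self.family not in ("beta", "point_mass", "two_point"):
            raise ValueError(f"unknown admixture family {self.family!r}")
        if self.family == "beta" and (self.a <= 0 or self.b <= 0):
            raise ValueError("Beta shape parameters must be positive")
        if self.family == "point_mass" and not 0.0 <= self.pi_fixed <= 1.0:
            raise ValueError("pi_fixed must be in [0, 1]")
        if self.family == "two_point" and not (0.0 <= self.a <= 1.0 and 0.0 <= self.b <= 1.0):
            raise ValueError("two_point support values must be in [0, 1]")

    @property
    def mean(self) -> float:
        if self.family == "beta":
            return self.a / (self.a + self.b)
        if self.family == "point_mass":
            return self.pi_fixed
        return 0.5 * (self.a + self.b)

    @property
    def variance(self) -> float:
        if self.family == "beta":
            s = self.a + self.b
            return self.a * self.b / (s * s * (s + 1.0))
        if self.family == "point_mass":
            return 0.0
        return 0.25 * (self.a - self.b) ** 2


@dataclass
class VariantPanel:
    """Per-variant metadata: position and ancestry-specific allele frequencies.

    Positions are 1-based and strictly increasing within each chromosome.
    ``p1``/``p0`` are the counted-allele frequencies in ancestral
    populations 1 and 0; their difference ``delta`` drives both
    ancestry-confounding and the ancestry signal available to PCA.
    """

    chrom: np.ndarray
    pos_bp: np.ndarray
    p1: np.ndarray
    p0: np.ndarray
    feature_id: np.ndarray | None = None

    def __post_init__(self):
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos_bp = np.asarray(self.pos_bp, dtype=np.int64)
        self.p1 = np.asarray(self.p1, dtype=float)
        self.p0 = np.asarray(self.p0, dtype=float)
        m = self.chrom.shape[0]
        if not (self.pos_bp.shape[0] == self.p1.shape[0] == self.p0.shape[0] == m):
            raise ValueError("panel field lengths disagree")
        if np.any((self.p1 < 0) | (self.p1 > 1)) or np.any((self.p0 < 0) | (self.p0 > 1)):
            raise ValueError("allele frequencies must lie in [0, 1]")
        for c in pd.unique(self.chrom):
            pos = self.pos_bp[self.chrom == c]
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on chromosome {c}")
        if self.feature_id is None:
            self.feature_id = np.full(m, None, dtype=object)
        else:
            self.feature_id = np.asarray(self.feature_id, dtype=object)

    @property
    def m(self) -> int:
        return self.chrom.shape[0]

    @property
    def delta(self) -> np.ndarray:
        """Ancestral allele-frequency difference p1 - p0 per variant."""
        return self.p1 - self.p0

    @property
    def chromosomes(self) -> list:
        return list(pd.unique(self.chrom))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "pos_bp": self.pos_bp,
                "p1": self.p1,
                "p0": self.p0,
                "feature_id": self.feature_id,
            }
        )


@dataclass(frozen=True)
class FeatureSpec:
    """A latent multi-region genomic feature.

    ``regions`` is a list of ``(chrom, start_bp, end_bp)`` half-open
    intervals; one feature may span regions on several chromosomes so that a
    single latent axis of variation loads on multiple parts of the genome.
    Carriers (a Bernoulli(``carrier_freq``) draw per individual) have the
    in-region allele frequencies of both ancestral populations shifted by
    ``+strength``; non-carriers by ``-strength``; shifted frequencies are
    clipped to [0.01, 0.99] to keep variants polymorphic.
    """

    name: str
    regions: tuple
    carrier_freq: float = 0.5
    strength: float = 0.4

    def __post_init__(self):
        if not 0.0 <= self.carrier_freq <= 1.0:
            raise ValueError("carrier_freq must be in [0, 1]")
        if not 0.0 <= self.strength <= 0.5:
            raise ValueError("strength must be in [0, 0.5]")

    def member_mask(self, panel: VariantPanel) -> np.ndarray:
        """Boolean mask of panel variants inside any of the feature's regions."""
        mask = np.zeros(panel.m, dtype=bool)
        for chrom, start, end in self.regions:
            hit = (panel.chrom == chrom) & (panel.pos_bp >= start) & (panel.pos_bp < end)
            if not hit.any():
                warnings.warn(
                    f"feature {self.name!r}: region {chrom}:{start}-{end} contains no panel "
                    "variants and is ignored",
                    stacklevel=2,
                )
            mask |= hit
        return mask


@dataclass(frozen=True)
class TraitSpec:
    """Single-causal-variant quantitative trait specification."""

    causal_index: int
    beta1: float = 1.0
    beta_pi: float = 0.0
    noise_sd: float = 1.0

    def __post_init__(self):
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


@dataclass
class SimulatedCohort:
    """A simulated admixed cohort: genotypes, local ancestry, and truth."""

    G: np.ndarray
    A: np.ndarray
    pi_true: np.ndarray
    panel: VariantPanel
    f: dict = field(default_factory=dict)
    seed_record: dict = field(default_factory=dict)

    def __post_init__(self):
        n, m = self.G.shape
        if self.A.shape != (n, m):
            raise ValueError("G and A dimensions disagree")
        if self.pi_true.shape[0] != n:
            raise ValueError("pi_true length disagrees with G")
        if self.panel.m != m:
            raise ValueError("panel size disagrees with G")
        if self.G.max(initial=0) > 2 or self.A.max(initial=0) > 2:
            raise ValueError("dosage / ancestry counts must be at most 2")

    @property
    def n(self) -> int:
        return self.G.shape[0]

    @property
    def m(self) -> int:
        return self.G.shape[1]


# ---------------------------------------------------------------------------
# Draws
# ---------------------------------------------------------------------------


def draw_admixture(model: AdmixtureModel, n: int, seed) -> np.ndarray:
    """Draw global admixture proportions for ``n`` individuals."""
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = _as_rng(seed)
    if model.family == "beta":
        return rng.beta(model.a, model.b, size=n)
    if model.family == "point_mass":
        return np.full(n, model.pi_fixed, dtype=float)
    return np.where(rng.random(n) < 0.5, model.a, model.b).astype(float)


def draw_local_ancestry(
    pi: np.ndarray,
    panel: VariantPanel,
    mode: str = "independent",
    switch_rate_per_mb: float = 1.0,
    seed=None,
) -> np.ndarray:
    """Draw local ancestry counts ``a_ij`` (copies from population 1).

    ``independent`` draws ``a_ij ~ Binomial(2, pi_i)`` i.i.d. across
    variants; ``markov`` runs two independent two-state Markov chains per
    individual along each chromosome, with stationary probability ``pi_i``
    and exponential ancestry-switch kernel at rate ``switch_rate_per_mb``
    (so genome-wide average local ancestry still centers on ``pi_i``, but
    nearby variants share ancestry).
    """
    pi = np.asarray(pi, dtype=float)
    if np.any((pi < 0) | (pi > 1)):
        raise ValueError("pi entries must lie in [0, 1]")
    n, m = pi.shape[0], panel.m
    rng = _as_rng(seed)
    if mode == "independent":
        return rng.binomial(2, pi[:, None], size=(n, m)).astype(np.int8)
    if mode != "markov":
        raise ValueError(f"unknown local-ancestry mode {mode!r}")
    if switch_rate_per_mb <= 0:
        raise ValueError("switch_rate_per_mb must be positive")

    A = np.empty((n, m), dtype=np.int8)
    for chrom in panel.chromosomes:
        idx = np.flatnonzero(panel.chrom == chrom)
        pos = panel.pos_bp[idx]
        block = np.zeros((n, idx.size), dtype=np.int8)
        for _chain in range(2):
            state = (rng.random(n) < pi).astype(np.int8)
            block[:, 0] += state
            for t in range(1, idx.size):
                d_mb = (pos[t] - pos[t - 1]) / 1.0e6
                decay = np.exp(-switch_rate_per_mb * d_mb)
                # two-state chain with stationary prob pi: P(1 | prev) =
                # pi + (prev - pi) * decay
                p_one = pi + (state - pi) * decay
                state = (rng.random(n) < p_one).astype(np.int8)
                block[:, t] += state
        A[:, idx] = block
    return A


def draw_feature_indicators(features, n: int, seed, latent_corr: float = 0.0) -> dict:
    """Draw the latent Bernoulli carrier indicator for each feature.

    With ``latent_corr`` > 0 the indicators of different features share a
    Gaussian factor (probit construction), making carrier status positively
    correlated across features.  Correlated region-factors are what make a
    single principal component load on several genomic regions at once: the
    near-degenerate feature eigenvalues mix the factors in the eigenbasis.
    """
    if not 0.0 <= latent_corr < 1.0:
        raise ValueError("latent_corr must be in [0, 1)")
    rng = _as_rng(seed)
    if latent_corr == 0.0:
        return {
            spec.name: (rng.random(n) < spec.carrier_freq).astype(np.int8)
            for spec in features
        }
    from scipy import stats as _stats

    shared = rng.normal(size=n)
    out = {}
    for spec in features:
        x = np.sqrt(latent_corr) * shared + np.sqrt(1.0 - latent_corr) * rng.normal(size=n)
        thresh = _stats.norm.ppf(1.0 - spec.carrier_freq)
        out[spec.name] = (x > thresh).astype(np.int8)
    return out


def draw_genotypes(
    A: np.ndarray,
    panel: VariantPanel,
    features=(),
    f: dict | None = None,
    seed=None,
) -> np.ndarray:
    """Draw dosages given local ancestry and ancestry-specific frequencies.

    Each of the ``a_ij`` copies from population 1 carries the counted allele
    with probability ``p_j1`` and each of the ``2 - a_ij`` copies from
    population 0 with probability ``p_j0``; inside feature regions both
    frequencies are shifted by ``+/- strength`` according to the
    individual's latent carrier indicator.
    """
    A = np.asarray(A)
    n, m = A.shape
    if panel.m != m:
        raise ValueError("panel size disagrees with A")
    rng = _as_rng(seed)
    f = f or {}

    G = rng.binomial(A.astype(np.int64), panel.p1[None, :]) + rng.binomial(
        (2 - A).astype(np.int64), panel.p0[None, :]
    )
    G = G.astype(np.int8)

    for spec in features:
        if spec.name not in f:
            raise ValueError(f"missing latent indicator for feature {spec.name!r}")
        mask = spec.member_mask(panel)
        if not mask.any():
            continue
        shift = spec.strength * (2.0 * f[spec.name].astype(float) - 1.0)  # length n
        cols = np.flatnonzero(mask)
        p1 = np.clip(panel.p1[cols][None, :] + shift[:, None], 0.01, 0.99)
        p0 = np.clip(panel.p0[cols][None, :] + shift[:, None], 0.01, 0.99)
        sub_a = A[:, cols].astype(np.int64)
        G[:, cols] = (rng.binomial(sub_a, p1) + rng.binomial(2 - sub_a, p0)).astype(np.int8)
    return G


def simulate_trait(cohort: SimulatedCohort, spec: TraitSpec, seed) -> np.ndarray:
    """Simulate y_i = beta1 * g_{i,j*} + beta_pi * pi_i + N(0, noise_sd^2)."""
    if not 0 <= spec.causal_index < cohort.m:
        raise ValueError("causal_index out of range")
    rng = _as_rng(seed)
    g = cohort.G[:, spec.causal_index].astype(float)
    return spec.beta1 * g + spec.beta_pi * cohort.pi_true + rng.normal(0.0, spec.noise_sd, cohort.n)


def make_collider_covariate(
    g_causal: np.ndarray,
    g_other: np.ndarray,
    w1: float = 1.0 / np.sqrt(2.0),
    w2: float = 1.0 / np.sqrt(2.0),
    noise_sd: float = 0.0,
    seed=None,
    chrom_causal=None,
    chrom_other=None,
) -> np.ndarray:
    """Construct an artificial "principal component" from two genotypes.

    ``z`` is a weighted sum of the sample-standardized dosages at the causal
    variant and at a second variant (intended to sit on a distinct
    chromosome), plus optional Gaussian noise, re-standardized to mean 0 and
    variance 1.  Adjusting for ``z`` alongside true ancestry in a GWAS model
    makes ``z`` a collider for the second variant.
    """
    g1 = np.asarray(g_causal, dtype=float)
    g2 = np.asarray(g_other, dtype=float)
    if g1.shape != g2.shape:
        raise ValueError("genotype vectors must have the same length")
    if w1 == 0.0 and w2 == 0.0:
        raise ValueError("weights w1 and w2 must not both be zero")
    if chrom_causal is not None and chrom_causal == chrom_other:
        warnings.warn(
            "collider covariate built from two variants on the same chromosome; "
            "the construction assumes unlinked variants",
            stacklevel=2,
        )

    def _std(v, which):
        sd = v.std()
        if sd == 0.0:
            raise ValueError(f"zero-variance genotype vector ({which}); cannot standardize")
        return (v - v.mean()) / sd

    z = w1 * _std(g1, "g_causal") + w2 * _std(g2, "g_other")
    if noise_sd > 0.0:
        z = z + _as_rng(seed).normal(0.0, noise_sd, z.shape[0])
    return (z - z.mean()) / z.std()


def estimate_admixture_from_local(A: np.ndarray) -> np.ndarray:
    """Genome-wide average local ancestry: pi_hat_i = sum_j a_ij / (2m)."""
    A = np.asarray(A)
    if A.ndim != 2 or A.shape[1] == 0:
        raise ValueError("A must be a non-empty n x m matrix")
    return A.mean(axis=1) / 2.0


# ---------------------------------------------------------------------------
# Convenience constructors
# ---------------------------------------------------------------------------


def random_panel(
    n_chrom: int = 6,
    variants_per_chrom: int = 300,
    spacing_bp: int = 100_000,
    fst: float = 0.15,
    maf_floor: float = 0.02,
    seed=None,
) -> VariantPanel:
    """Build a panel with ancestry-differentiated allele frequencies.

    Frequencies follow a Balding-Nichols divergence model: an ancestral
    frequency is drawn uniformly, then the two population frequencies are
    Beta-distributed around it with divergence ``fst`` (0.15 roughly matches
    continental African/European differentiation).  Positions are evenly
    spaced at ``spacing_bp``.
    """
    rng = _as_rng(seed)
    m = n_chrom * variants_per_chrom
    p_anc = rng.uniform(0.1, 0.9, size=m)
    shape = (1.0 - fst) / fst
    p1 = rng.beta(p_anc * shape, (1.0 - p_anc) * shape)
    p0 = rng.beta(p_anc * shape, (1.0 - p_anc) * shape)
    lo = max(0.01, maf_floor)
    p1 = np.clip(p1, lo, 1.0 - lo)
    p0 = np.clip(p0, lo, 1.0 - lo)
    chrom = np.repeat([f"chr{c + 1}" for c in range(n_chrom)], variants_per_chrom).astype(object)
    pos = np.tile((np.arange(variants_per_chrom) + 1) * spacing_bp, n_chrom).astype(np.int64)
    return VariantPanel(chrom=chrom, pos_bp=pos, p1=p1, p0=p0)


# per-stage counters for the global-seed expansion
_STAGE_PI = 0
_STAGE_FEATURES = 1
_STAGE_ANCESTRY = 2
_STAGE_GENOTYPES = 3
STAGE_TRAIT = 4


def simulate_cohort(
    panel: VariantPanel,
    n: int,
    admixture: AdmixtureModel | None = None,
    features=(),
    feature_corr: float = 0.0,
    ancestry_mode: str = "independent",
    switch_rate_per_mb: float = 1.0,
    seed: int = 0,
) -> SimulatedCohort:
    """Simulate a full cohort from one global seed.

    The seed expands into per-stage child seeds (admixture, feature
    indicators, local ancestry, genotypes) via a counter-based scheme, all
    recorded in ``seed_record`` so a cohort can be reproduced exactly.
    """
    admixture = admixture or AdmixtureModel()
    pi = draw_admixture(admixture, n, child_rng(seed, _STAGE_PI))
    f = draw_feature_indicators(
        features, n, child_rng(seed, _STAGE_FEATURES), latent_corr=feature_corr
    )
    A = draw_local_ancestry(
        pi, panel, mode=ancestry_mode, switch_rate_per_mb=switch_rate_per_mb,
        seed=child_rng(seed, _STAGE_ANCESTRY),
    )
    G = draw_genotypes(A, panel, features=features, f=f, seed=child_rng(seed, _STAGE_GENOTYPES))
    record = {
        "root": int(seed),
        "pi": _STAGE_PI,
        "features": _STAGE_FEATURES,
        "ancestry": _STAGE_ANCESTRY,
        "genotypes": _STAGE_GENOTYPES,
    }
    return SimulatedCohort(G=G, A=A, pi_true=pi, panel=panel, f=f, seed_record=record)
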