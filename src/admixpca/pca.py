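"""Genotype PCA with LD-aware pre-processing and loading diagnostics.

PCA is run as a singular value decomposition of the standardized genotype
matrix X = U D V^T, where x_ij = (g_ij - 2*phat_j) / sqrt(2*phat_j*(1-phat_j))
and phat_j is the sample allele frequency.  PC scores are the columns of U,
SNP loadings the columns of V.  Pre-processing mirrors standard GWAS
practice: a minor-allele-frequency filter, exclusion of known high-LD /
long-range-LD regions, and greedy sliding-window LD pruning on dosage r^2.

The diagnostics (`pc_genotype_correlation`, `detect_loading_peaks`) flag PCs
whose loadings concentrate in a few genomic regions -- the signature of a PC
capturing a local genomic feature rather than genome-wide ancestry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import VariantPanel

__all__ = [
    "RegionList",
    "PruneParams",
    "PCAResult",
    "HIGH_LD_REGIONS_BUILD38",
    "maf_filter",
    "exclude_regions",
    "ld_prune",
    "run_pca",
    "pc_genotype_correlation",
    "detect_loading_peaks",
    "standardize_genotypes",
]

# Literature-recommended exclusion regions (genome build 38, 1-based
# inclusive): genomic segments with high, long-range, or otherwise unusual
# LD (e.g. LCT on chr2, HLA on chr6, inversions on chr8 and chr17) that are
# often removed before running PCA.
HIGH_LD_REGIONS_BUILD38 = (
    ("1", 47_761_741, 51_822_307),
    ("2", 129_125_957, 139_525_961),
    ("2", 182_309_767, 189_427_029),
    ("3", 47_483_506, 49_987_563),
    ("3", 83_368_159, 86_868_160),
    ("3", 161_899_518, 163_699_518),
    ("5", 98_636_396, 101_136_397),
    ("5", 129_636_408, 132_636_409),
    ("5", 136_136_412, 139_136_412),
    ("6", 23_691_793, 38_924_246),
    ("6", 139_637_170, 142_137_170),
    ("8", 6_455_071, 13_598_120),
    ("8", 110_918_595, 113_918_595),
    ("11", 88_127_184, 91_127_184),
    ("12", 110_577_812, 113_099_475),
    ("14", 47_061_047, 47_961_047),
    ("17", 42_394_456, 46_567_318),
    ("20", 33_948_533, 36_438_183),
)


@dataclass
class RegionList:
    """Genomic regions as (chrom, start_bp, end_bp), 1-based inclusive."""

    entries: list
    build_label: str = ""

    def __post_init__(self):
        entries = [(str(c), int(s), int(e)) for c, s, e in self.entries]
        for c, s, e in entries:
            if s > e:
                raise ValueError(f"region {c}:{s}-{e} has start > end")
        self.entries = sorted(entries, key=lambda r: (r[0], r[1]))

    @classmethod
    def high_ld_build38(cls) -> "RegionList":
        return cls(list(HIGH_LD_REGIONS_BUILD38), build_label="GRCh38")

    def __len__(self) -> int:
        return len(self.entries)

    def contains(self, chrom, pos_bp) -> np.ndarray:
        """Vectorized membership: True where (chrom, pos) falls in any region."""
        chrom = np.asarray(chrom, dtype=object)
        pos_bp = np.asarray(pos_bp)
        inside = np.zeros(chrom.shape[0], dtype=bool)
        for c, s, e in self.entries:
            inside |= (chrom == c) & (pos_bp >= s) & (pos_bp <= e)
        return inside


@dataclass(frozen=True)
class PruneParams:
    """LD pruning parameters: r^2 threshold and physical window size."""

    r2_max: float = 0.1
    window_bp: int = 500_000

    def __post_init__(self):
        if not 0.0 < self.r2_max <= 1.0:
            raise ValueError("r2_max must be in (0, 1]")
        if self.window_bp <= 0:
            raise ValueError("window_bp must be positive")


@dataclass
class PCAResult:
    """Top-k SVD of the standardized genotype matrix restricted to a variant subset."""

    scores: np.ndarray
    singular_values: np.ndarray
    loadings: np.ndarray
    used_variants: np.ndarray

    @property
    def k(self) -> int:
        return self.scores.shape[1]

    def variance_explained(self) -> np.ndarray:
        d2 = self.singular_values**2
        return d2 / d2.sum()


# ---------------------------------------------------------------------------
# Pre-processing
# ---------------------------------------------------------------------------


def maf_filter(G: np.ndarray, panel: VariantPanel | None = None, maf_min: float = 0.01) -> np.ndarray:
    """Indices of variants with sample minor allele frequency >= maf_min."""
    if not 0.0 <= maf_min <= 0.5:
        raise ValueError("maf_min must be in [0, 0.5]")
    p = np.asarray(G).mean(axis=0) / 2.0
    maf = np.minimum(p, 1.0 - p)
    return np.flatnonzero(maf >= maf_min)


def exclude_regions(panel: VariantPanel, regions: RegionList) -> np.ndarray:
    """Indices of variants falling in none of the regions (boundaries are inside)."""
    if len(regions) == 0:
        return np.arange(panel.m)
    return np.flatnonzero(~regions.contains(panel.chrom, panel.pos_bp))


def ld_prune(
    G: np.ndarray,
    panel: VariantPanel,
    params: PruneParams = PruneParams(),
    candidates: np.ndarray | None = None,
) -> np.ndarray:
    """Greedy sliding-window LD pruning on dosage r^2.

    Scans each chromosome left to right; a candidate variant is kept iff its
    squared Pearson correlation with every already-kept variant within
    ``window_bp`` is below ``r2_max``.  Guarantees that no kept pair within
    the window has r^2 >= r2_max.  Zero-variance columns never conflict
    (r^2 treated as 0).
    """
    G = np.asarray(G)
    if candidates is None:
        candidates = np.arange(panel.m)
    else:
        candidates = np.asarray(candidates)

    # centered columns and norms, computed lazily per chromosome
    kept_all = []
    for chrom in panel.chromosomes:
        idx = candidates[np.asarray(panel.chrom[candidates] == chrom, dtype=bool)]
        if idx.size == 0:
            continue
        pos = panel.pos_bp[idx]
        X = G[:, idx].astype(float)
        X -= X.mean(axis=0)
        norms = np.sqrt((X * X).sum(axis=0))
        kept = []  # local positions into idx
        for j in range(idx.size):
            if norms[j] == 0.0:
                kept.append(j)
                continue
            lo = pos[j] - params.window_bp
            conflict = False
            for kloc in reversed(kept):
                if pos[kloc] < lo:
                    break
                if norms[kloc] == 0.0:
                    continue
                r = X[:, kloc] @ X[:, j] / (norms[kloc] * norms[j])
                if r * r >= params.r2_max:
                    conflict = True
                    break
            if not conflict:
                kept.append(j)
        kept_all.extend(idx[kept].tolist())
    return np.array(sorted(kept_all), dtype=np.int64)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


def standardize_genotypes(G: np.ndarray, keep: np.ndarray | None = None) -> np.ndarray:
    """Standardize dosages: x_ij = (g_ij - 2*phat_j) / sqrt(2*phat_j*(1-phat_j))."""
    G = np.asarray(G)
    if keep is not None:
        G = G[:, np.asarray(keep)]
    p = G.mean(axis=0) / 2.0
    denom = np.sqrt(2.0 * p * (1.0 - p))
    if np.any(denom == 0.0):
        bad = np.flatnonzero(denom == 0.0)
        raise ValueError(f"zero-variance (monomorphic) columns among kept variants: {bad[:5]}")
    return (G - 2.0 * p) / denom


def run_pca(G: np.ndarray, keep: np.ndarray | None = None, k: int = 10) -> PCAResult:
    """Top-k SVD of the standardized genotype matrix restricted to ``keep``.

    Sign convention: each loading column's largest-magnitude entry is made
    positive (PCs are otherwise sign-ambiguous); the matching score column
    is flipped with it.
    """
    if keep is None:
        keep = np.arange(np.asarray(G).shape[1])
    keep = np.asarray(keep)
    X = standardize_genotypes(G, keep)
    n, mp = X.shape
    if k > min(n, mp):
        raise ValueError(f"k={k} exceeds min(n, kept variants) = {min(n, mp)}")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    U, s, V = U[:, :k], s[:k], Vt[:k].T
    for c in range(k):
        if V[np.argmax(np.abs(V[:, c])), c] < 0:
            V[:, c] = -V[:, c]
            U[:, c] = -U[:, c]
    return PCAResult(scores=U, singular_values=s, loadings=V, used_variants=keep)


def pc_genotype_correlation(result: PCAResult, G: np.ndarray, panel: VariantPanel) -> pd.DataFrame:
    """Pearson correlation of each PC score with every panel variant's dosage.

    Computed for all panel variants, not only those used in the SVD, so
    that excluded/pruned regions still show up in the diagnostic plot.
    Zero-variance variants get correlation 0 and ``zero_variance=True``.
    """
    G = np.asarray(G, dtype=float)
    if G.shape[0] != result.scores.shape[0]:
        raise ValueError("G and PCA scores have different numbers of individuals")
    S = result.scores - result.scores.mean(axis=0)
    S /= np.sqrt((S * S).sum(axis=0))
    Gc = G - G.mean(axis=0)
    gnorm = np.sqrt((Gc * Gc).sum(axis=0))
    zero = gnorm == 0.0
    gnorm[zero] = 1.0
    corr = (Gc / gnorm).T @ S  # m x k
    corr[zero, :] = 0.0
    out = pd.DataFrame(corr, columns=[f"PC{c + 1}" for c in range(result.k)])
    out.insert(0, "chrom", panel.chrom)
    out.insert(1, "pos_bp", panel.pos_bp)
    out["zero_variance"] = zero
    return out


def detect_loading_peaks(
    corr_table: pd.DataFrame, window_bp: int = 1_000_000, abs_corr_min: float = 0.25
) -> list:
    """Find genomic runs of high PC-genotype correlation ("peaks").

    For each PC, maximal runs of consecutive variants with |corr| >=
    ``abs_corr_min`` are found per chromosome and runs closer than
    ``window_bp`` are merged.  Returns a list of ``(pc, chrom, start_bp,
    end_bp)`` tuples; an empty list means no PC concentrates on any region.
    """
    pc_cols = [c for c in corr_table.columns if c.startswith("PC")]
    peaks = []
    for pc in pc_cols:
        for chrom, sub in corr_table.groupby("chrom", sort=False):
            pos = sub["pos_bp"].to_numpy()
            hit = np.abs(sub[pc].to_numpy()) >= abs_corr_min
            if not hit.any():
                continue
            hit_pos = pos[hit]
            start = end = hit_pos[0]
            for p in hit_pos[1:]:
                if p - end <= window_bp:
                    end = p
                else:
                    peaks.append((pc, chrom, int(start), int(end)))
                    start = end = p
            peaks.append((pc, chrom, int(start), int(end)))
    return peaks
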