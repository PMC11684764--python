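"""Text-format readers and writers (VCF, BED, TSV, JSON summaries).

Cohorts round-trip through a minimal unphased VCF (dosages as GT) plus a
TSV sidecar for the simulation truth (admixture proportions and latent
feature indicators); panels and result tables are plain TSV.  Region lists
are read either from BED (0-based half-open, converted to the internal
1-based inclusive convention) or from the 1-based inclusive TSV dialect
used for published high-LD exclusion lists.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .assoc import AssocResult
from .pca import PCAResult, RegionList
from .simulate import SimulatedCohort, VariantPanel

__all__ = [
    "write_vcf",
    "read_vcf",
    "write_panel_tsv",
    "read_panel_tsv",
    "write_truth_tsv",
    "read_truth_tsv",
    "read_regions_bed",
    "read_regions_tsv",
    "write_kept_variants",
    "read_kept_variants",
    "write_pca_tsv",
    "write_assoc_tsv",
    "write_summary_json",
]

_GT = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(cohort: SimulatedCohort, path) -> None:
    """Write dosages as an unphased GT-only VCF (REF=A, ALT=T placeholders)."""
    panel = cohort.panel
    samples = [f"S{i}" for i in range(cohort.n)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=admixpca\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in panel.chromosomes:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for j in range(panel.m):
            gts = "\t".join(_GT[int(g)] for g in cohort.G[:, j])
            fh.write(
                f"{panel.chrom[j]}\t{panel.pos_bp[j]}\tv{j}\tA\tT\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_vcf(path):
    """Read a VCF into (dosage matrix, variant DataFrame) via cyvcf2."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    chroms, positions, rows = [], [], []
    for rec in vcf:
        chroms.append(rec.CHROM)
        positions.append(rec.POS)
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = np.asarray(rec.gt_types)
        rows.append(np.where(gt == 3, 2, np.where(gt == 1, 1, 0)).astype(np.int8))
    G = np.vstack(rows).T if rows else np.empty((len(vcf.samples), 0), dtype=np.int8)
    meta = pd.DataFrame({"chrom": chroms, "pos_bp": positions})
    return G, meta


def write_panel_tsv(panel: VariantPanel, path) -> None:
    panel.to_dataframe().to_csv(path, sep="\t", index=False)


def read_panel_tsv(path) -> VariantPanel:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    feat = df["feature_id"].where(df["feature_id"].notna(), None) if "feature_id" in df else None
    return VariantPanel(
        chrom=df["chrom"].to_numpy(dtype=object),
        pos_bp=df["pos_bp"].to_numpy(),
        p1=df["p1"].to_numpy(),
        p0=df["p0"].to_numpy(),
        feature_id=None if feat is None else feat.to_numpy(dtype=object),
    )


def write_truth_tsv(cohort: SimulatedCohort, path) -> None:
    """Sidecar with per-individual simulation truth (pi and feature indicators)."""
    df = pd.DataFrame({"sample": [f"S{i}" for i in range(cohort.n)], "pi_true": cohort.pi_true})
    for name, f in cohort.f.items():
        df[f"feature_{name}"] = f
    df.to_csv(path, sep="\t", index=False)


def read_truth_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_regions_bed(path, build_label: str = "") -> RegionList:
    """BED (0-based half-open) -> internal 1-based inclusive regions."""
    entries = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            chrom, start, end = line.split("\t")[:3]
            entries.append((chrom, int(start) + 1, int(end)))
    return RegionList(entries, build_label=build_label)


def read_regions_tsv(path, build_label: str = "") -> RegionList:
    """Published-table dialect: columns chrom, start_bp, end_bp (1-based inclusive)."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    cols = list(df.columns[:3])
    entries = [(str(c), int(s), int(e)) for c, s, e in df[cols].itertuples(index=False)]
    return RegionList(entries, build_label=build_label)


def write_kept_variants(keep: np.ndarray, panel: VariantPanel, path) -> None:
    pd.DataFrame(
        {"index": keep, "chrom": panel.chrom[keep], "pos_bp": panel.pos_bp[keep]}
    ).to_csv(path, sep="\t", index=False)


def read_kept_variants(path) -> np.ndarray:
    return pd.read_csv(path, sep="\t")["index"].to_numpy()


def write_pca_tsv(result: PCAResult, scores_path, loadings_path=None) -> None:
    k = result.k
    pd.DataFrame(result.scores, columns=[f"PC{i+1}" for i in range(k)]).to_csv(
        scores_path, sep="\t", index=False
    )
    if loadings_path is not None:
        df = pd.DataFrame(result.loadings, columns=[f"PC{i+1}" for i in range(k)])
        df.insert(0, "variant_index", result.used_variants)
        df.to_csv(loadings_path, sep="\t", index=False)


def write_assoc_tsv(res: AssocResult, path) -> None:
    res.to_frame().to_csv(path, sep="\t", index=False)


def write_summary_json(res: AssocResult, causal_chrom, alpha: float, path) -> None:
    from .assoc import count_spurious_chromosomes, genomic_inflation

    payload = {
        "lambda": genomic_inflation(res),
        "n_spurious_chroms": count_spurious_chromosomes(res, causal_chrom, alpha),
        "alpha": alpha,
        "covariates": res.covariate_label,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
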