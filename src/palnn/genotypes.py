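"""Synthetic SNP-array genotypes, genotype file I/O, LD and PCA covariates.

Genotypes are alt-allele dosages recoded to the symmetric ternary alphabet
{-1, 0, 1} (dosage 0 -> -1, 1 -> 0, 2 -> 1) so that neither allele is
preferred at a position.  The synthetic generator builds block-wise LD by
sampling individual haplotypes from a small per-block founder pool, which
yields elevated within-block correlation and (near) cross-block independence.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeMatrix",
    "generate_genotypes",
    "read_genotypes",
    "write_traw",
    "write_vcf",
    "compute_ld",
    "pca_covariates",
]

_TERNARY = frozenset((-1, 0, 1))


@dataclass
class GenotypeMatrix:
    """n_individuals x n_positions ternary genotype matrix with metadata.

    Attributes
    ----------
    values
        Integer array with entries in {-1, 0, 1}; rows are individuals,
        columns are variants.
    variants
        DataFrame with columns ``chrom`` (str), ``bp`` (1-based int) and
        ``id`` (str), one row per column of ``values``, sorted by
        (chrom, bp) with bp unique within a chromosome.
    sample_ids
        One identifier per row of ``values``.
    """

    values: np.ndarray
    variants: pd.DataFrame
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("genotype values must be a 2-D matrix")
        uniq = np.unique(self.values)
        if not set(uniq.tolist()) <= _TERNARY:
            bad = sorted(set(uniq.tolist()) - _TERNARY)
            raise ValueError(f"genotype values outside {{-1,0,1}}: {bad}")
        self.variants = pd.DataFrame(self.variants).reset_index(drop=True)
        required = {"chrom", "bp", "id"}
        if not required <= set(self.variants.columns):
            raise ValueError(f"variant table must have columns {sorted(required)}")
        if len(self.variants) != self.values.shape[1]:
            raise ValueError("variant count does not match matrix width")
        if len(self.sample_ids) != self.values.shape[0]:
            raise ValueError("sample_ids length does not match matrix height")
        if (self.variants["bp"] < 1).any():
            raise ValueError("bp positions must be 1-based positive integers")
        for chrom, grp in self.variants.groupby("chrom", sort=False):
            bps = grp["bp"].to_numpy()
            if not np.all(np.diff(bps) > 0):
                raise ValueError(f"bp not strictly increasing on chromosome {chrom}")

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_positions(self) -> int:
        return self.values.shape[1]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            np.array_equal(self.values, other.values)
            and self.sample_ids == other.sample_ids
            and self.variants[["chrom", "bp", "id"]].equals(
                other.variants[["chrom", "bp", "id"]]
            )
        )


def generate_genotypes(
    n_individuals: int,
    n_positions: int,
    block_size: int = 20,
    haplotype_pool: int = 8,
    maf_range: tuple[float, float] = (0.05, 0.5),
    bp_spacing: int = 5000,
    mutation_p: float = 0.01,
    chrom: str = "1",
    seed: int = 0,
) -> GenotypeMatrix:
    """Generate a ternary genotype matrix with block-wise LD.

    Within each block of ``block_size`` consecutive positions, a pool of
    ``haplotype_pool`` founder haplotypes is drawn (per-site alt-allele
    frequency uniform in ``maf_range``); every individual then samples two
    haplotypes from the pool and each inherited allele flips with probability
    ``mutation_p``.  Blocks are independent, so within-block |r| exceeds
    cross-block |r| on average.

    Variant positions are ``bp_spacing`` apart on a single chromosome.
    """
    if n_individuals < 2 or n_positions < 1:
        raise ValueError("need n_individuals >= 2 and n_positions >= 1")
    if block_size < 1 or haplotype_pool < 2:
        raise ValueError("block_size >= 1 and haplotype_pool >= 2 required")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must be a non-empty subinterval of (0, 0.5]")
    rng = np.random.default_rng(seed)

    dosage = np.empty((n_individuals, n_positions), dtype=np.int8)
    for start in range(0, n_positions, block_size):
        width = min(block_size, n_positions - start)
        mafs = rng.uniform(lo, hi, size=width)
        founders = (rng.random((haplotype_pool, width)) < mafs).astype(np.int8)
        picks = rng.integers(0, haplotype_pool, size=(n_individuals, 2))
        h1 = founders[picks[:, 0]]
        h2 = founders[picks[:, 1]]
        if mutation_p > 0:
            flip1 = rng.random(h1.shape) < mutation_p
            flip2 = rng.random(h2.shape) < mutation_p
            h1 = h1 ^ flip1
            h2 = h2 ^ flip2
        dosage[:, start : start + width] = h1 + h2

    values = dosage.astype(np.int8) - 1
    bps = (np.arange(n_positions, dtype=np.int64) + 1) * bp_spacing
    variants = pd.DataFrame(
        {
            "chrom": chrom,
            "bp": bps,
            "id": [f"snp{i + 1}" for i in range(n_positions)],
        }
    )
    sample_ids = [f"ind{i + 1}" for i in range(n_individuals)]
    return GenotypeMatrix(values=values, variants=variants, sample_ids=sample_ids)


def _encode_dosage(dosage: np.ndarray) -> np.ndarray:
    """Map alt-allele dosage {0,1,2} to the symmetric {-1,0,1} encoding."""
    dosage = np.asarray(dosage)
    bad = ~np.isin(dosage, (0, 1, 2))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"non-ternary or missing dosage {dosage[i, j]!r} at sample row {i}, variant column {j}"
        )
    return (dosage.astype(np.int8)) - 1


def read_genotypes(path: str | Path, format: str | None = None) -> GenotypeMatrix:
    """Read a genotype matrix from VCF or PLINK dosage text (.traw / .raw).

    ``format`` is one of ``"vcf"`` or ``"plink-dosage"``; when omitted it is
    inferred from the file suffix.  Missing genotypes and non-biallelic
    records are rejected.
    """
    path = Path(path)
    if format is None:
        name = path.name.lower()
        if ".vcf" in name:
            format = "vcf"
        elif name.endswith((".traw", ".raw")):
            format = "plink-dosage"
        else:
            raise ValueError(f"cannot infer genotype format from {path.name!r}")
    if format == "vcf":
        return _read_vcf(path)
    if format == "plink-dosage":
        return _read_plink_dosage(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    rows: list[np.ndarray] = []
    meta: list[tuple[str, int, str]] = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ValueError(
                f"non-biallelic record at {rec.CHROM}:{rec.POS} "
                f"({rec.ID or '.'}: ALT={rec.ALT})"
            )
        gts = np.asarray(rec.genotype.array())[:, :2]
        if (gts < 0).any():
            s = sample_ids[int(np.argwhere(gts < 0)[0][0])]
            raise ValueError(
                f"missing genotype at {rec.CHROM}:{rec.POS} for sample {s}"
            )
        rows.append(gts.sum(axis=1))
        meta.append((rec.CHROM, rec.POS, rec.ID or f"{rec.CHROM}:{rec.POS}"))
    vcf.close()
    if not rows:
        raise ValueError(f"no variant records in {path}")
    dosage = np.stack(rows, axis=1)
    variants = pd.DataFrame(meta, columns=["chrom", "bp", "id"])
    return GenotypeMatrix(
        values=_encode_dosage(dosage), variants=variants, sample_ids=sample_ids
    )


def _read_plink_dosage(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep=r"\s+")
    cols = list(df.columns)
    if cols[:6] == ["CHR", "SNP", "(C)M", "POS", "COUNTED", "ALT"]:
        # .traw orientation: variants as rows, samples as columns
        sample_ids = cols[6:]
        raw = df[sample_ids].to_numpy()
        if np.isnan(raw).any():
            r, c = np.argwhere(np.isnan(raw))[0]
            raise ValueError(
                f"missing dosage for variant {df['SNP'].iloc[r]} sample {sample_ids[c]}"
            )
        variants = pd.DataFrame(
            {
                "chrom": df["CHR"].astype(str),
                "bp": df["POS"].astype(int),
                "id": df["SNP"].astype(str),
            }
        )
        return GenotypeMatrix(
            values=_encode_dosage(raw.T),
            variants=variants,
            sample_ids=[str(s) for s in sample_ids],
        )
    if cols[:6] == ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]:
        # .raw orientation: samples as rows, variants as columns (ID_ALLELE)
        variant_cols = cols[6:]
        raw = df[variant_cols].to_numpy()
        if np.isnan(raw).any():
            r, c = np.argwhere(np.isnan(raw))[0]
            raise ValueError(
                f"missing dosage for sample {df['IID'].iloc[r]} variant {variant_cols[c]}"
            )
        ids = [c.rsplit("_", 1)[0] for c in variant_cols]
        variants = pd.DataFrame(
            {
                "chrom": "0",
                "bp": np.arange(1, len(ids) + 1),
                "id": ids,
            }
        )
        return GenotypeMatrix(
            values=_encode_dosage(raw),
            variants=variants,
            sample_ids=[str(s) for s in df["IID"]],
        )
    raise ValueError(
        f"unrecognized PLINK dosage header in {path}: {cols[:6]}"
    )


def write_traw(g: GenotypeMatrix, path: str | Path) -> None:
    """Write a PLINK .traw dosage file (variants as rows, tab-separated)."""
    path = Path(path)
    dosage = (g.values.astype(np.int16) + 1).T  # back to 0/1/2
    header = ["CHR", "SNP", "(C)M", "POS", "COUNTED", "ALT"] + list(g.sample_ids)
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for k in range(g.n_positions):
            v = g.variants.iloc[k]
            row = [str(v["chrom"]), str(v["id"]), "0", str(int(v["bp"])), "A", "B"]
            row.extend(str(int(d)) for d in dosage[k])
            fh.write("\t".join(row) + "\n")


def write_vcf(g: GenotypeMatrix, path: str | Path) -> None:
    """Write an uncompressed VCF 4.2 file with synthetic A/B alleles."""
    path = Path(path)
    gt_strings = {-1: "0/0", 0: "0/1", 1: "1/1"}
    chroms = list(dict.fromkeys(g.variants["chrom"]))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=palnn\n")
        for c in chroms:
            max_bp = int(g.variants.loc[g.variants["chrom"] == c, "bp"].max())
            fh.write(f"##contig=<ID={c},length={max_bp + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.sample_ids)
            + "\n"
        )
        for k in range(g.n_positions):
            v = g.variants.iloc[k]
            gts = "\t".join(gt_strings[int(x)] for x in g.values[:, k])
            fh.write(
                f"{v['chrom']}\t{int(v['bp'])}\t{v['id']}\tA\tB\t.\tPASS\t.\tGT\t{gts}\n"
            )


def write_variant_metadata(g: GenotypeMatrix, path: str | Path) -> None:
    g.variants[["chrom", "bp", "id"]].to_csv(path, sep="\t", index=False)


def write_generator_sidecar(path: str | Path, **params) -> None:
    Path(path).write_text(json.dumps(params, indent=2, sort_keys=True))


def compute_ld(g: GenotypeMatrix, i: int, j: int) -> float:
    """Pearson correlation of genotype columns i and j over all individuals."""
    xi = g.values[:, i].astype(float)
    xj = g.values[:, j].astype(float)
    if xi.std() == 0.0:
        raise ValueError(f"degenerate SNP: column {i} has zero variance")
    if xj.std() == 0.0:
        raise ValueError(f"degenerate SNP: column {j} has zero variance")
    r = float(np.corrcoef(xi, xj)[0, 1])
    return min(1.0, max(-1.0, r))


def pca_covariates(g: GenotypeMatrix, k: int) -> np.ndarray:
    """Leading ``k`` principal-component scores of the standardized genotypes.

    Columns are standardized to mean 0 / unit variance; zero-variance columns
    are dropped (logged).  Returns an (n_individuals, k) score array.
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    if k == 0:
        return np.empty((g.n_individuals, 0))
    x = g.values.astype(float)
    sd = x.std(axis=0)
    keep = sd > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("pca_covariates: dropped %d zero-variance columns", n_dropped)
    x = x[:, keep]
    if k > min(x.shape):
        raise ValueError(
            f"k={k} exceeds achievable rank min{x.shape} after dropping degenerate columns"
        )
    x = (x - x.mean(axis=0)) / sd[keep]
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    rank = int((s > s[0] * max(x.shape) * np.finfo(float).eps).sum()) if s.size else 0
    if k > rank:
        raise ValueError(f"k={k} exceeds matrix rank {rank}")
    return u[:, :k] * s[:k]
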