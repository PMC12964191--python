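"""Logistic-regression GWAS baseline and LD-aware detection evaluation.

The baseline fits one logistic model per SNP (dosage + optional principal
component covariates + intercept) and reports Wald P-values with a
Bonferroni threshold of alpha over all attempted tests.  Detected SNPs are
grouped into distance blocks; a block is a true positive when any member
lies within +/- 100 kb of a causal position on the same chromosome, and
recall counts causal positions covered by at least one block.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .genotypes import GenotypeMatrix
from .phenosim import EffectSpec

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationResult",
    "DetectionEvaluation",
    "logistic_gwas",
    "label_detections",
    "precision_recall",
    "effect_type_breakdown",
    "read_external_pvalues",
]


@dataclass
class AssociationResult:
    table: pd.DataFrame  # columns: position, id, beta, se, p (NaN where failed)
    n_tested: int
    alpha: float
    bonferroni_threshold: float
    n_covariates: int

    def significant_positions(self, threshold: float | None = None) -> list[int]:
        thr = self.bonferroni_threshold if threshold is None else threshold
        ok = self.table["p"].notna() & (self.table["p"] < thr)
        return self.table.loc[ok, "position"].astype(int).tolist()

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class DetectionEvaluation:
    blocks: list[list[int]]
    block_is_tp: list[bool]
    tp: int
    fp: int
    fn: int
    detected_causal: set[int] = field(default_factory=set)

    @property
    def precision(self) -> float | None:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) > 0 else None


def logistic_gwas(
    g: GenotypeMatrix,
    labels: np.ndarray,
    covariates: np.ndarray | None = None,
    alpha: float = 0.05,
) -> AssociationResult:
    """Per-SNP logistic regression with Wald P-values.

    Non-convergence or separation leaves that SNP's P absent (NaN, logged)
    rather than silently zero; the Bonferroni denominator stays the number
    of attempted tests.
    """
    labels = np.asarray(labels)
    if not set(np.unique(labels).tolist()) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if covariates is not None:
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covariates.shape[0] != g.n_individuals:
            raise ValueError("covariates must be row-aligned with genotypes")
    n_cov = 0 if covariates is None else covariates.shape[1]
    y = labels.astype(float)
    rows = []
    for j in range(g.n_positions):
        x = g.values[:, j].astype(float)
        design = [x[:, None]]
        if covariates is not None and n_cov:
            design.append(covariates)
        X = sm.add_constant(np.hstack(design), has_constant="add")
        beta = se = p = np.nan
        try:
            with np.errstate(all="ignore"):
                fit = sm.Logit(y, X).fit(disp=0, maxiter=100)
            if fit.mle_retvals.get("converged", False) and np.isfinite(fit.bse[1]):
                beta = float(fit.params[1])
                se = float(fit.bse[1])
                p = float(fit.pvalues[1])
            else:
                logger.warning("logistic_gwas: SNP %d did not converge", j)
        except Exception as exc:
            logger.warning("logistic_gwas: SNP %d failed (%s)", j, exc)
        rows.append((j, g.variants["id"].iloc[j], beta, se, p))
    table = pd.DataFrame(rows, columns=["position", "id", "beta", "se", "p"])
    return AssociationResult(
        table=table,
        n_tested=g.n_positions,
        alpha=alpha,
        bonferroni_threshold=alpha / g.n_positions,
        n_covariates=n_cov,
    )


def bonferroni_threshold(alpha: float, n_tested: int) -> float:
    return alpha / n_tested


def label_detections(
    blocks: list[list[int]],
    causal_positions: list[int],
    variants: pd.DataFrame,
    window: int = 100_000,
) -> DetectionEvaluation:
    """Label each detected block TP/FP against causal positions.

    A block is TP when one or more member SNPs lie within ``window`` bp
    (closed interval) of a causal position on the same chromosome; each
    block counts once.  ``detected_causal`` records causal positions within
    the window of any block member (for recall).
    """
    chrom = variants["chrom"].to_numpy()
    bp = variants["bp"].to_numpy()
    causal = list(causal_positions)
    block_is_tp = []
    detected_causal: set[int] = set()
    for block in blocks:
        is_tp = False
        for member in block:
            for c in causal:
                if chrom[member] == chrom[c] and abs(int(bp[member]) - int(bp[c])) <= window:
                    is_tp = True
                    detected_causal.add(int(c))
        block_is_tp.append(is_tp)
    tp = sum(block_is_tp)
    fp = len(blocks) - tp
    fn = len(set(causal)) - len(detected_causal)
    return DetectionEvaluation(
        blocks=blocks,
        block_is_tp=block_is_tp,
        tp=tp,
        fp=fp,
        fn=fn,
        detected_causal=detected_causal,
    )


def precision_recall(
    evaluation: DetectionEvaluation, n_causal: int
) -> dict[str, float | None]:
    """Precision over blocks; recall = covered causal positions / n_causal."""
    recall = len(evaluation.detected_causal) / n_causal if n_causal else 0.0
    return {"precision": evaluation.precision, "recall": recall}


def effect_type_breakdown(
    evaluation: DetectionEvaluation, effects: EffectSpec
) -> dict[str, int]:
    """Count detected causal positions per effect class."""
    counts = {"dominant": 0, "recessive": 0, "two-way": 0, "three-way": 0}
    for pos in evaluation.detected_causal:
        counts[effects.effect_class(pos)] += 1
    counts["dominant_recessive"] = counts["dominant"] + counts["recessive"]
    counts["interactive"] = counts["two-way"] + counts["three-way"]
    return counts


def read_external_pvalues(path) -> pd.DataFrame:
    """Import externally produced per-SNP P-values (TSV: variant_id, p)."""
    df = pd.read_csv(path, sep="\t")
    if not {"variant_id", "p"} <= set(df.columns):
        raise ValueError("external P-value TSV needs columns variant_id, p")
    return df[["variant_id", "p"]]
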