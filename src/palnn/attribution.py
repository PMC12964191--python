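"""Post hoc feature attribution and the mean attribution score (MAS).

Three model-agnostic scores are supported, all reported as absolute values:

* saliency — |d f(x) / d x_j|
* integrated gradients — |(x_j - x'_j) * \\int_0^1 d f(x' + a(x - x')) / d x_j da|
  (midpoint Riemann sum; zero baseline by default)
* permutation importance — |f(x) - f(x^(j))| where coordinate j is perturbed

Per-sample score rows are L1-normalized and averaged over case samples to
give the MAS vector for one trained model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .nnmodel import TrainedModel

logger = logging.getLogger(__name__)

__all__ = [
    "AttributionScores",
    "MASVector",
    "saliency",
    "integrated_gradients",
    "permutation_importance",
    "compute_mas",
    "mas_for_model",
]


@dataclass
class AttributionScores:
    """Non-negative per-sample, per-position importance scores."""

    method: str  # "SM", "IG" or "PM"
    scores: np.ndarray  # (n_samples, L), >= 0
    normalized: bool = False

    def __post_init__(self) -> None:
        self.scores = np.atleast_2d(np.asarray(self.scores, dtype=float))
        if (self.scores < 0).any():
            raise ValueError("attribution scores must be non-negative")
        if self.normalized:
            sums = self.scores.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValueError("normalized rows must sum to 1")


@dataclass
class MASVector:
    values: np.ndarray
    method: str
    n_samples_averaged: int
    model_seed: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if (self.values < 0).any():
            raise ValueError("MAS values must be non-negative")

    def to_tsv(self, path, variants: pd.DataFrame | None = None) -> None:
        if variants is not None:
            df = variants[["id", "chrom", "bp"]].copy()
        else:
            df = pd.DataFrame({"id": [f"pos{i}" for i in range(len(self.values))]})
        df["mas"] = self.values
        df.to_csv(path, sep="\t", index=False)


def saliency(model: TrainedModel, x: np.ndarray) -> AttributionScores:
    """Absolute gradient of the sigmoid output w.r.t. each input coordinate."""
    grad = model.input_gradient(np.atleast_2d(x))
    return AttributionScores(method="SM", scores=np.abs(grad))


def integrated_gradients(
    model: TrainedModel,
    x: np.ndarray,
    baseline: np.ndarray | None = None,
    n_steps: int = 50,
    signed: bool = False,
) -> AttributionScores | np.ndarray:
    """Path-integral attribution from ``baseline`` to ``x``.

    The integral is approximated by an ``n_steps`` midpoint Riemann sum;
    the default baseline is the zero vector (the fully heterozygous genome
    under the {-1, 0, 1} encoding).  Absolute values are taken after the
    (x - baseline)-scaling, so linear models obey |w_j * x_j| exactly.
    With ``signed`` the raw signed attributions are returned instead (for
    completeness diagnostics: their row sums approach f(x) - f(baseline)).
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if baseline is None:
        baseline = np.zeros(x.shape[1])
    baseline = np.asarray(baseline, dtype=float)
    if baseline.shape != (x.shape[1],):
        raise ValueError("baseline length must match input length")
    diff = x - baseline[None, :]
    total = np.zeros_like(x)
    for step in range(n_steps):
        alpha = (step + 0.5) / n_steps
        total += model.input_gradient(baseline[None, :] + alpha * diff)
    ig = diff * total / n_steps
    if signed:
        return ig
    return AttributionScores(method="IG", scores=np.abs(ig))


def permutation_importance(
    model: TrainedModel,
    x: np.ndarray,
    mode: str = "permute-samples",
    reference: np.ndarray | None = None,
    seed: int = 0,
) -> AttributionScores:
    """|f(x) - f(x^(j))| for every coordinate j of every sample.

    ``permute-samples`` replaces coordinate j with feature j's value from a
    random other sample of ``reference`` (preserving the feature marginal);
    ``random-feature`` replaces it with the sample's own value at a random
    other position.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    n, L = x.shape
    if mode not in ("permute-samples", "random-feature"):
        raise ValueError(f"unknown permutation mode {mode!r}")
    if mode == "permute-samples":
        if reference is None:
            reference = x
        reference = np.atleast_2d(np.asarray(reference, dtype=float))
        if reference.shape[0] < 1:
            raise ValueError("permute-samples mode requires a nonempty reference pool")
    rng = np.random.default_rng(seed)
    base = model.predict(x)
    scores = np.empty((n, L))
    for j in range(L):
        xj = x.copy()
        if mode == "permute-samples":
            donors = rng.integers(0, reference.shape[0], size=n)
            xj[:, j] = reference[donors, j]
        else:
            others = rng.integers(0, L - 1, size=n)
            others[others >= j] += 1
            xj[:, j] = x[np.arange(n), others]
        scores[:, j] = np.abs(model.predict(xj) - base)
    return AttributionScores(method="PM", scores=scores)


def l1_normalize(scores: AttributionScores) -> AttributionScores:
    sums = scores.scores.sum(axis=1, keepdims=True)
    zero = np.flatnonzero(sums.ravel() == 0)
    if zero.size:
        raise ValueError(
            f"degenerate attribution: sample rows {zero.tolist()} are all zero"
        )
    return AttributionScores(
        method=scores.method, scores=scores.scores / sums, normalized=True
    )


def compute_mas(scores: AttributionScores, model_seed: int | None = None) -> MASVector:
    """L1-normalize each sample row, then average over samples."""
    if not scores.normalized:
        scores = l1_normalize(scores)
    return MASVector(
        values=scores.scores.mean(axis=0),
        method=scores.method,
        n_samples_averaged=scores.scores.shape[0],
        model_seed=model_seed,
    )


def mas_for_model(
    model: TrainedModel,
    genotypes: np.ndarray,
    labels: np.ndarray,
    method: str = "IG",
    n_steps: int = 50,
    pm_mode: str = "permute-samples",
    pm_subsample: int | None = None,
    case_samples_only: bool = True,
    drop_zero_rows: bool = True,
    seed: int = 0,
) -> MASVector:
    """MAS vector for one trained model (case samples by default).

    Samples whose attribution row is identically zero (e.g. a fully dead
    ReLU path for that input) carry no normalizable signal; by default they
    are dropped with a warning instead of aborting the run.
    """
    genotypes = np.asarray(genotypes, dtype=float)
    labels = np.asarray(labels)
    x = genotypes[labels == 1] if case_samples_only else genotypes
    if x.shape[0] == 0:
        raise ValueError("no samples selected for attribution")
    method = method.upper()
    if method == "SM":
        scores = saliency(model, x)
    elif method == "IG":
        scores = integrated_gradients(model, x, n_steps=n_steps)
    elif method == "PM":
        if pm_subsample is not None and pm_subsample < x.shape[0]:
            keep = np.random.default_rng(seed).choice(
                x.shape[0], size=pm_subsample, replace=False
            )
            logger.info("PM: subsampled %d of %d samples", pm_subsample, x.shape[0])
            pool = x
            x = x[keep]
        else:
            pool = x
        scores = permutation_importance(model, x, mode=pm_mode, reference=pool, seed=seed)
    else:
        raise ValueError(f"unknown attribution method {method!r}")
    if drop_zero_rows:
        keep = scores.scores.sum(axis=1) > 0
        if not keep.all():
            logger.warning(
                "dropping %d sample(s) with all-zero attribution", int((~keep).sum())
            )
            if not keep.any():
                raise ValueError("degenerate attribution: every sample row is zero")
            scores = AttributionScores(method=scores.method, scores=scores.scores[keep])
    return compute_mas(scores, model_seed=model.config.seed)
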