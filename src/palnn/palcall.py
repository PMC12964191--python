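"""Multi-seed aggregation of MAS vectors into PAL calls.

Per-model MAS vectors form an m x L matrix A.  The averaged vector mu gets a
percentile threshold theta; weights w_j count the fraction of models whose
row exceeds theta at position j; AMAS_j = w_j * mu_j for positions with
mu_j > theta.  PAL_AMAS keeps positions with AMAS above theta, PAL_Common
keeps positions above theta in every model.  Positions detected by different
models are merged into common signals when in LD (|r| > 0.5), and detections
are grouped into distance blocks for evaluation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, compute_ld

logger = logging.getLogger(__name__)

__all__ = [
    "MASMatrix",
    "PALReport",
    "percentile_threshold",
    "aggregate",
    "clump_cross_model",
    "block_clump_distance",
    "STRICT_PERCENTILE",
    "RELAXED_PERCENTILE",
]

STRICT_PERCENTILE = 99.99
RELAXED_PERCENTILE = 99.95


@dataclass
class MASMatrix:
    """m x L matrix of per-model MAS vectors (rows sum to 1)."""

    A: np.ndarray
    model_seeds: list[int] = field(default_factory=list)
    method: str = "IG"

    def __post_init__(self) -> None:
        self.A = np.atleast_2d(np.asarray(self.A, dtype=float))
        if not self.model_seeds:
            self.model_seeds = list(range(self.A.shape[0]))
        if len(self.model_seeds) != self.A.shape[0]:
            raise ValueError("model_seeds length must equal the number of rows")
        if (self.A < 0).any():
            raise ValueError("MAS values must be non-negative")
        if not np.allclose(self.A.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each MAS row must sum to 1")

    @property
    def m(self) -> int:
        return self.A.shape[0]

    @property
    def L(self) -> int:
        return self.A.shape[1]


@dataclass
class PALReport:
    mu: np.ndarray
    theta: float
    theta_percentile: float
    weights: np.ndarray
    amas: dict[int, float]  # position -> w_j * mu_j, for positions with mu_j > theta
    pal_amas: set[int]
    pal_common: set[int]
    per_model_detected: list[set[int]] = field(default_factory=list)
    signals: list[dict] = field(default_factory=list)

    @property
    def detected_union(self) -> set[int]:
        """Positions above theta in at least one model."""
        out: set[int] = set()
        for s in self.per_model_detected:
            out |= s
        return out

    def amas_value(self, j: int) -> float:
        """w_j * mu_j regardless of whether mu_j cleared theta."""
        return float(self.weights[j] * self.mu[j])

    def to_tsv(self, path, variants: pd.DataFrame | None = None) -> None:
        L = len(self.mu)
        df = pd.DataFrame({"position": np.arange(L)})
        if variants is not None:
            df["id"] = variants["id"].to_numpy()
            df["chrom"] = variants["chrom"].to_numpy()
            df["bp"] = variants["bp"].to_numpy()
        df["mu"] = self.mu
        df["w"] = self.weights
        df["amas"] = self.weights * self.mu
        df["in_pal_amas"] = df["position"].isin(self.pal_amas)
        df["in_pal_common"] = df["position"].isin(self.pal_common)
        group = np.full(L, -1)
        for gi, sig in enumerate(self.signals):
            for j in sig["members"]:
                group[j] = gi
        df["signal_group"] = group
        df.to_csv(path, sep="\t", index=False)

    def summary(self) -> dict:
        return {
            "theta": self.theta,
            "theta_percentile": self.theta_percentile,
            "n_pal_amas": len(self.pal_amas),
            "n_pal_common": len(self.pal_common),
            "n_detected_union": len(self.detected_union),
            "n_signals": len(self.signals),
        }


def percentile_threshold(values: np.ndarray, q: float) -> float:
    """Order-statistic threshold: exactly floor(N*(1-q/100)) values above.

    theta is the value ranked floor(N*(1-q/100)) + 1 from the top, so with
    distinct values exactly floor(N*(1-q/100)) are strictly greater.
    """
    if not 0 < q < 100:
        raise ValueError("percentile q must lie in (0, 100)")
    values = np.asarray(values, dtype=float).ravel()
    n = values.size
    if n < 1:
        raise ValueError("need at least one value")
    k_above = math.floor(n * (1.0 - q / 100.0))
    # partition for the (k_above+1)-th largest
    idx = n - k_above - 1
    theta = float(np.partition(values, idx)[idx])
    return theta


def aggregate(Amat: MASMatrix, q: float = STRICT_PERCENTILE) -> PALReport:
    """Reduce an m x L MAS matrix to weights, AMAS and PAL sets."""
    A = Amat.A
    mu = A.mean(axis=0)
    theta = percentile_threshold(mu, q)
    exceed = A > theta
    w = exceed.sum(axis=0) / Amat.m
    above_mu = mu > theta
    n_ties = int((mu == theta).sum())
    if n_ties > 1:
        logger.info("aggregate: %d mu values tied exactly at theta fall below", n_ties)
    amas = {int(j): float(w[j] * mu[j]) for j in np.flatnonzero(above_mu)}
    pal_amas = {j for j, v in amas.items() if v > theta}
    pal_common = set(np.flatnonzero(exceed.all(axis=0)).tolist())
    per_model = [set(np.flatnonzero(exceed[a]).tolist()) for a in range(Amat.m)]
    return PALReport(
        mu=mu,
        theta=theta,
        theta_percentile=q,
        weights=w,
        amas=amas,
        pal_amas=pal_amas,
        pal_common=pal_common,
        per_model_detected=per_model,
    )


def aggregate_pooled_theta(Amat: MASMatrix, q: float = STRICT_PERCENTILE) -> PALReport:
    """Variant where theta is the percentile of the pooled per-model values."""
    theta = percentile_threshold(Amat.A.ravel(), q)
    A = Amat.A
    mu = A.mean(axis=0)
    exceed = A > theta
    w = exceed.sum(axis=0) / Amat.m
    amas = {int(j): float(w[j] * mu[j]) for j in np.flatnonzero(mu > theta)}
    return PALReport(
        mu=mu,
        theta=theta,
        theta_percentile=q,
        weights=w,
        amas=amas,
        pal_amas={j for j, v in amas.items() if v > theta},
        pal_common=set(np.flatnonzero(exceed.all(axis=0)).tolist()),
        per_model_detected=[set(np.flatnonzero(exceed[a]).tolist()) for a in range(A.shape[0])],
    )


def clump_cross_model(
    detected: list[set[int]],
    g: GenotypeMatrix,
    r_threshold: float = 0.5,
    amas: dict[int, float] | None = None,
) -> list[dict]:
    """Merge positions detected across models into LD signal groups.

    Edges connect positions with |Pearson r| > ``r_threshold``; connected
    components become signal groups; the representative is the member with
    the highest AMAS (or the smallest index when no AMAS is supplied).
    """
    union = sorted(set().union(*detected)) if detected else []
    usable = []
    for j in union:
        if g.values[:, j].std() == 0:
            logger.warning("clump_cross_model: dropping zero-variance position %d", j)
        else:
            usable.append(j)
    graph = nx.Graph()
    graph.add_nodes_from(usable)
    for a_i, i in enumerate(usable):
        for j in usable[a_i + 1 :]:
            if abs(compute_ld(g, i, j)) > r_threshold:
                graph.add_edge(i, j)
    signals = []
    for comp in nx.connected_components(graph):
        members = sorted(comp)
        if amas:
            rep = max(members, key=lambda j: (amas.get(j, 0.0), -j))
        else:
            rep = members[0]
        signals.append({"members": members, "representative": rep})
    signals.sort(key=lambda s: s["members"][0])
    return signals


def plot_manhattan(
    values: np.ndarray,
    variants: pd.DataFrame,
    path,
    thresholds: dict[str, float] | None = None,
    highlight: set[int] | None = None,
    ylabel: str = "score",
) -> None:
    """Manhattan-style plot of per-position scores (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 3))
    chroms = list(dict.fromkeys(variants["chrom"]))
    offset = 0
    for ci, chrom in enumerate(chroms):
        idx = np.flatnonzero((variants["chrom"] == chrom).to_numpy())
        xs = offset + np.arange(len(idx))
        ax.scatter(xs, values[idx], s=4, color=f"C{ci % 2}")
        if highlight:
            hits = [k for k, j in enumerate(idx) if j in highlight]
            ax.scatter(xs[hits], values[idx[hits]], s=16, color="red", zorder=3)
        offset += len(idx)
    for label, thr in (thresholds or {}).items():
        ax.axhline(thr, linestyle="--", linewidth=0.8, label=label)
    if thresholds:
        ax.legend(fontsize=8)
    ax.set_xlabel("position")
    ax.set_ylabel(ylabel)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def block_clump_distance(
    positions: list[int],
    variants: pd.DataFrame,
    gap: int = 100_000,
) -> list[list[int]]:
    """Group detected positions into blocks of <= ``gap`` bp spacing.

    Consecutive same-chromosome positions at most ``gap`` bp apart share a
    block; a chromosome change or a larger gap starts a new one.
    """
    if not positions:
        return []
    meta = variants.iloc[sorted(positions)][["chrom", "bp"]]
    blocks: list[list[int]] = []
    prev_chrom, prev_bp = None, None
    for pos, (chrom, bp) in zip(meta.index, meta.to_numpy()):
        if prev_chrom == chrom and prev_bp is not None and bp - prev_bp <= gap:
            blocks[-1].append(int(pos))
        else:
            blocks.append([int(pos)])
        prev_chrom, prev_bp = chrom, bp
    return blocks
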