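"""Phenotype simulation with dominant, recessive and epistatic effects.

A continuous phenotype is the sum of four genetic terms plus scaled Gaussian
noise:

    Y_i = sum_{j in D} fD_j(X_ij) + sum_{j in R} fR_j(X_ij)
        + sum_{(j,k)} b_jk X_ij X_ik + sum_{(j,k,l)} b_jkl X_ij X_ik X_il
        + eps_i,      eps_i ~ N(0, k * var(genetic sum))

with fD_j(x) = b_j * x unless x = -1 (then 0), and fR_j(x) = b_j * x only
when x = 1 (else 0).  The binary phenotype is 1 where Y exceeds a threshold
tau chosen to yield a requested case count.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "EffectSpec",
    "PhenotypeSet",
    "EFFECT_RATIO",
    "assign_effects",
    "simulate_continuous",
    "binarize",
]

# dominant : recessive : two-way members : three-way members
EFFECT_RATIO = (5, 5, 4, 6)


@dataclass
class EffectSpec:
    """Causal-position assignment with sampled standard-normal weights."""

    dominant: list[int]
    recessive: list[int]
    pairs: list[tuple[int, int]]
    triplets: list[tuple[int, int, int]]
    beta_dominant: np.ndarray
    beta_recessive: np.ndarray
    beta_pair: np.ndarray
    beta_triplet: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        members = (
            list(self.dominant)
            + list(self.recessive)
            + [p for t in self.pairs for p in t]
            + [p for t in self.triplets for p in t]
        )
        if len(set(members)) != len(members):
            raise ValueError("effect position sets must be mutually disjoint")
        if len(self.beta_dominant) != len(self.dominant):
            raise ValueError("one dominant weight per dominant position required")
        if len(self.beta_recessive) != len(self.recessive):
            raise ValueError("one recessive weight per recessive position required")
        if len(self.beta_pair) != len(self.pairs):
            raise ValueError("one weight per pair required")
        if len(self.beta_triplet) != len(self.triplets):
            raise ValueError("one weight per triplet required")

    @property
    def n_causal(self) -> int:
        return (
            len(self.dominant)
            + len(self.recessive)
            + 2 * len(self.pairs)
            + 3 * len(self.triplets)
        )

    @property
    def all_positions(self) -> list[int]:
        """All causal positions, in class order."""
        return (
            list(self.dominant)
            + list(self.recessive)
            + [p for t in self.pairs for p in t]
            + [p for t in self.triplets for p in t]
        )

    def effect_class(self, position: int) -> str:
        if position in set(self.dominant):
            return "dominant"
        if position in set(self.recessive):
            return "recessive"
        if position in {p for t in self.pairs for p in t}:
            return "two-way"
        if position in {p for t in self.triplets for p in t}:
            return "three-way"
        raise KeyError(f"position {position} is not causal")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "dominant": [int(i) for i in self.dominant],
            "recessive": [int(i) for i in self.recessive],
            "pairs": [[int(i) for i in t] for t in self.pairs],
            "triplets": [[int(i) for i in t] for t in self.triplets],
            "beta_dominant": list(map(float, self.beta_dominant)),
            "beta_recessive": list(map(float, self.beta_recessive)),
            "beta_pair": list(map(float, self.beta_pair)),
            "beta_triplet": list(map(float, self.beta_triplet)),
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "EffectSpec":
        d = json.loads(Path(path).read_text())
        return cls(
            dominant=d["dominant"],
            recessive=d["recessive"],
            pairs=[tuple(t) for t in d["pairs"]],
            triplets=[tuple(t) for t in d["triplets"]],
            beta_dominant=np.asarray(d["beta_dominant"]),
            beta_recessive=np.asarray(d["beta_recessive"]),
            beta_pair=np.asarray(d["beta_pair"]),
            beta_triplet=np.asarray(d["beta_triplet"]),
            seed=d.get("seed"),
        )


@dataclass
class PhenotypeSet:
    y_continuous: np.ndarray
    y_binary: np.ndarray | None = None
    tau: float | None = None
    k: float = 0.0
    sigma2_genetic: float = 0.0
    epsilon_seed: int | None = None
    sample_ids: list[str] = field(default_factory=list)

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "sample_id": self.sample_ids
                or [f"ind{i + 1}" for i in range(len(self.y_continuous))],
                "y_continuous": self.y_continuous,
            }
        )
        if self.y_binary is not None:
            df["y_binary"] = self.y_binary.astype(int)
        df.to_csv(path, sep="\t", index=False)


def assign_effects(g: GenotypeMatrix, n_causal: int, seed: int = 0) -> EffectSpec:
    """Draw causal positions and weights under the 5:5:4:6 effect-type ratio.

    ``n_causal`` must be divisible by 20 so the ratio yields integer class
    sizes.  Positions are drawn uniformly without replacement; interaction
    members are partitioned into disjoint pairs/triplets; all weights are
    standard normal.
    """
    if n_causal % sum(EFFECT_RATIO) != 0:
        raise ValueError(
            f"n_causal must be divisible by {sum(EFFECT_RATIO)} "
            f"to honour the {':'.join(map(str, EFFECT_RATIO))} ratio"
        )
    if n_causal > g.n_positions:
        raise ValueError("n_causal exceeds the number of genotyped positions")
    unit = n_causal // sum(EFFECT_RATIO)
    n_dom, n_rec, n_pairmem, n_tripmem = (r * unit for r in EFFECT_RATIO)

    rng = np.random.default_rng(seed)
    chosen = rng.choice(g.n_positions, size=n_causal, replace=False)
    dom = chosen[:n_dom]
    rec = chosen[n_dom : n_dom + n_rec]
    pair_members = chosen[n_dom + n_rec : n_dom + n_rec + n_pairmem]
    trip_members = chosen[n_dom + n_rec + n_pairmem :]
    pairs = [
        tuple(int(p) for p in pair_members[s : s + 2]) for s in range(0, n_pairmem, 2)
    ]
    triplets = [
        tuple(int(p) for p in trip_members[s : s + 3]) for s in range(0, n_tripmem, 3)
    ]
    return EffectSpec(
        dominant=[int(i) for i in dom],
        recessive=[int(i) for i in rec],
        pairs=pairs,
        triplets=triplets,
        beta_dominant=rng.standard_normal(n_dom),
        beta_recessive=rng.standard_normal(n_rec),
        beta_pair=rng.standard_normal(len(pairs)),
        beta_triplet=rng.standard_normal(len(triplets)),
        seed=seed,
    )


def genetic_sum(g: GenotypeMatrix, e: EffectSpec) -> np.ndarray:
    """Per-individual sum of the four genetic effect terms (no noise)."""
    x = g.values.astype(float)
    y = np.zeros(g.n_individuals)
    for j, b in zip(e.dominant, e.beta_dominant):
        col = x[:, j]
        y += np.where(col != -1, b * col, 0.0)
    for j, b in zip(e.recessive, e.beta_recessive):
        col = x[:, j]
        y += np.where(col == 1, b * col, 0.0)
    for (j, k), b in zip(e.pairs, e.beta_pair):
        y += b * x[:, j] * x[:, k]
    for (j, k, l), b in zip(e.triplets, e.beta_triplet):
        y += b * x[:, j] * x[:, k] * x[:, l]
    return y


def simulate_continuous(
    g: GenotypeMatrix, e: EffectSpec, k: float, seed: int = 0
) -> PhenotypeSet:
    """Continuous phenotypes: genetic sum plus N(0, k * sigma^2) noise.

    sigma^2 is the empirical (ddof=0) variance of the genetic sum over the
    cohort, so k directly scales noise relative to the genetic signal.
    """
    if k < 0:
        raise ValueError("noise scaling factor k must be non-negative")
    gsum = genetic_sum(g, e)
    sigma2 = float(np.var(gsum))
    rng = np.random.default_rng(seed)
    if k * sigma2 > 0:
        eps = rng.normal(0.0, np.sqrt(k * sigma2), size=g.n_individuals)
    else:
        eps = np.zeros(g.n_individuals)
    return PhenotypeSet(
        y_continuous=gsum + eps,
        k=k,
        sigma2_genetic=sigma2,
        epsilon_seed=seed,
        sample_ids=list(g.sample_ids),
    )


def binarize(y: np.ndarray, n_cases: int) -> tuple[np.ndarray, float]:
    """Threshold continuous phenotypes so that ``n_cases`` satisfy Y > tau.

    tau is the (n_cases+1)-th largest value.  If that order statistic is
    tied with larger values the strict rule yields fewer cases; a warning is
    logged (ties are measure-zero for real-valued phenotypes).
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if not 0 < n_cases < n:
        raise ValueError(f"n_cases must be in (0, {n}); got {n_cases}")
    order = np.sort(y)[::-1]
    tau = float(order[n_cases])
    if tau == order[0]:
        raise ValueError("phenotype values are all tied at the threshold")
    y_binary = (y > tau).astype(np.int8)
    if int(y_binary.sum()) != n_cases:
        logger.warning(
            "binarize: ties at tau=%g yield %d cases instead of %d",
            tau,
            int(y_binary.sum()),
            n_cases,
        )
    return y_binary, tau


def simulate_phenotypes(
    g: GenotypeMatrix,
    n_causal: int,
    k: float,
    case_fraction: float = 0.1985,
    seed: int = 0,
) -> tuple[PhenotypeSet, EffectSpec]:
    """End-to-end scenario: assign effects, simulate, binarize.

    The default case fraction mirrors a ~1814 / 9139 case-control cohort.
    """
    e = assign_effects(g, n_causal, seed=seed)
    ph = simulate_continuous(g, e, k, seed=seed + 1)
    n_cases = max(1, int(round(case_fraction * g.n_individuals)))
    ph.y_binary, ph.tau = binarize(ph.y_continuous, n_cases)
    return ph, e
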