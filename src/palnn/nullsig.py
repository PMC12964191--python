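"""Half-normal null model for MAS and rank-matched P-value estimation.

Null MAS vectors come from models trained on permuted labels.  Pooled null
values are fitted with a half-normal (folded normal with location 0) whose
maximum-likelihood scale is sqrt(mean(x^2)); candidate tail distributions
are compared by AIC/BIC.  P-values for observed AMAS are obtained by
repeatedly sampling m half-normal vectors, reordering each to match the rank
order of the corresponding observed MAS row (emulating within- and
between-vector dependence), recomputing theta/weights/AMAS on the sampled
ensemble, and counting pooled null AMAS values above each observed AMAS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .attribution import MASVector
from .palcall import MASMatrix, PALReport, percentile_threshold

logger = logging.getLogger(__name__)

__all__ = [
    "NullModel",
    "PValueSet",
    "pool_null_mas",
    "fit_halfnormal",
    "compare_tail_distributions",
    "rank_match",
    "estimate_pvalues",
]

# candidate family -> (scipy distribution, number of shape parameters)
_TAIL_CANDIDATES = {
    "half-normal": (stats.halfnorm, 0),
    "generalized-Pareto": (stats.genpareto, 1),
    "gamma": (stats.gamma, 1),
    "exponential": (stats.expon, 0),
    "Weibull": (stats.weibull_min, 1),
    "lognormal": (stats.lognorm, 1),
}


@dataclass
class NullModel:
    sigma: float
    n_pooled: int
    tail_quantile: float | None = None
    fit_table: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError("half-normal scale must be positive")


@dataclass
class PValueSet:
    pvalues: dict[int, float]  # position -> p
    n_reps: int
    pool_size: int
    at_floor: set[int] = field(default_factory=set)  # positions where p is a bound

    @property
    def floor(self) -> float:
        return 1.0 / self.pool_size


def pool_null_mas(null_mas: list[MASVector] | list[np.ndarray]) -> np.ndarray:
    """Concatenate null MAS vectors into one pooled value array."""
    if not null_mas:
        raise ValueError("at least one null MAS vector required")
    arrays = [
        np.asarray(v.values if isinstance(v, MASVector) else v, dtype=float)
        for v in null_mas
    ]
    lengths = {a.shape[0] for a in arrays}
    if len(lengths) != 1:
        raise ValueError(f"null MAS vectors have mismatched lengths: {sorted(lengths)}")
    return np.concatenate(arrays)


def fit_halfnormal(pooled: np.ndarray) -> NullModel:
    """Maximum-likelihood half-normal scale: sigma = sqrt(mean(x^2))."""
    pooled = np.asarray(pooled, dtype=float)
    if pooled.size == 0:
        raise ValueError("empty pool")
    if (pooled < 0).any():
        raise ValueError("pooled null MAS must be non-negative")
    sigma = float(np.sqrt(np.mean(pooled**2)))
    if sigma == 0:
        raise ValueError("all pooled values are zero; scale undefined")
    return NullModel(sigma=sigma, n_pooled=int(pooled.size))


def _fit_truncated(dist, n_shapes: int, tail: np.ndarray, cutoff: float):
    """ML fit of a zero-anchored family to exceedances of ``cutoff``.

    Maximizes the conditional (truncated) log-likelihood
    sum log pdf(x) - n log SF(cutoff), so candidates are compared as models
    of the same tail event.  Returns (params, loglik, k).
    """
    from scipy import optimize

    n = tail.size

    def nll(p):
        shapes = p[:n_shapes]
        scale = np.exp(p[n_shapes])
        with np.errstate(all="ignore"):
            ll = dist.logpdf(tail, *shapes, loc=0.0, scale=scale).sum()
            ll -= n * dist.logsf(cutoff, *shapes, loc=0.0, scale=scale)
        return np.inf if not np.isfinite(ll) else -ll

    try:
        p0_full = dist.fit(tail, floc=0.0)
        p0 = list(p0_full[:n_shapes]) + [np.log(p0_full[-1])]
    except Exception:
        p0 = [1.0] * n_shapes + [np.log(tail.std() + 1e-300)]
    res = optimize.minimize(
        nll, p0, method="Nelder-Mead",
        options={"maxiter": 4000, "xatol": 1e-12, "fatol": 1e-12},
    )
    shapes = tuple(float(v) for v in res.x[:n_shapes])
    scale = float(np.exp(res.x[n_shapes]))
    return shapes + (0.0, scale), float(-res.fun), n_shapes + 1


def compare_tail_distributions(
    pooled: np.ndarray,
    tail_quantile: float = 0.999,
    candidates: tuple[str, ...] = tuple(_TAIL_CANDIDATES),
) -> list[dict]:
    """Fit candidate distributions to the pool's upper tail; report AIC/BIC.

    The tail subset holds values above the ``tail_quantile`` quantile of the
    pool.  Each candidate family (anchored at location 0) is fitted by
    maximum likelihood of the truncated density conditional on exceeding the
    cutoff; AIC = 2k - 2logL, BIC = k log(n) - 2logL with k = free
    parameters (shapes + scale).  Rows come back sorted by AIC.
    """
    pooled = np.asarray(pooled, dtype=float)
    cutoff = float(np.quantile(pooled, tail_quantile))
    tail = pooled[pooled > cutoff]
    if tail.size < 50:
        raise ValueError(
            f"tail above quantile {tail_quantile} has only {tail.size} points (< 50)"
        )
    if np.ptp(tail) == 0:
        raise ValueError("degenerate tail: all values equal")
    table = []
    for name in candidates:
        dist, n_shapes = _TAIL_CANDIDATES[name]
        try:
            params, loglik, k = _fit_truncated(dist, n_shapes, tail, cutoff)
            table.append(
                {
                    "name": name,
                    "params": params,
                    "k": k,
                    "loglik": loglik,
                    "aic": 2 * k - 2 * loglik,
                    "bic": k * np.log(tail.size) - 2 * loglik,
                }
            )
        except Exception as exc:  # fit failure for one candidate is non-fatal
            logger.warning("tail fit failed for %s: %s", name, exc)
            table.append(
                {"name": name, "params": None, "k": None, "loglik": None,
                 "aic": np.inf, "bic": np.inf}
            )
    table.sort(key=lambda row: row["aic"])
    return table


def rank_match(sampled: np.ndarray, observed: np.ndarray) -> np.ndarray:
    """Permute ``sampled`` so its rank order matches ``observed``.

    The largest sampled value lands at the argmax of observed, and so on;
    ties in observed are broken by position index (stable argsort).
    """
    sampled = np.asarray(sampled, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if sampled.shape != observed.shape:
        raise ValueError("sampled and observed vectors must have equal length")
    order = np.argsort(observed, kind="stable")
    out = np.empty_like(sampled)
    out[order] = np.sort(sampled)
    return out


def _null_amas(
    samples: np.ndarray, q: float
) -> np.ndarray:
    """AMAS at all L positions for one sampled null ensemble.

    theta is recomputed from the averaged sampled vector with the same
    percentile rule; AMAS is zero wherever w = 0 or mu <= theta.
    """
    mu = samples.mean(axis=0)
    theta = percentile_threshold(mu, q)
    w = (samples > theta).sum(axis=0) / samples.shape[0]
    amas = w * mu
    amas[mu <= theta] = 0.0
    return amas


def estimate_pvalues(
    observed_A: MASMatrix,
    observed_pal: PALReport,
    null: NullModel,
    positions: list[int] | None = None,
    n_reps: int = 100,
    gate_targets: bool = False,
    seed: int = 0,
) -> PValueSet:
    """Monte-Carlo P-values for observed AMAS against the half-normal null.

    Each repetition draws ``m`` half-normal(sigma) vectors of length L,
    rank-matches vector a to observed MAS row a, and recomputes null AMAS
    with the observed percentile rule.  All ``n_reps * L`` null AMAS values
    (zeros included) form the comparison pool; for position j,
    p_j = max(#(null AMAS > AMAS_j), 1) / (n_reps * L).

    Targets default to w_j * mu_j for the requested positions (for PAL
    positions mu_j > theta already holds); ``gate_targets`` zeroes targets
    at positions with mu <= theta, matching the null-side convention exactly
    (used for calibration checks over all positions).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    m, L = observed_A.m, observed_A.L
    if positions is None:
        positions = sorted(observed_pal.pal_amas | observed_pal.detected_union)
    rng = np.random.default_rng(seed)
    q = observed_pal.theta_percentile
    targets = np.array([observed_pal.amas_value(j) for j in positions])
    if gate_targets:
        gate = observed_pal.mu[list(positions)] > observed_pal.theta
        targets = targets * gate
    exceed = np.zeros(len(positions), dtype=np.int64)
    for _rep in range(n_reps):
        draws = np.abs(rng.normal(0.0, null.sigma, size=(m, L)))
        matched = np.empty_like(draws)
        for a in range(m):
            matched[a] = rank_match(draws[a], observed_A.A[a])
        namas = _null_amas(matched, q)
        exceed += (namas[None, :] > targets[:, None]).sum(axis=1)
    pool_size = n_reps * L
    pvalues = {}
    at_floor = set()
    for j, cnt in zip(positions, exceed):
        if cnt == 0:
            at_floor.add(int(j))
            cnt = 1
        pvalues[int(j)] = float(cnt / pool_size)
    return PValueSet(
        pvalues=pvalues, n_reps=n_reps, pool_size=pool_size, at_floor=at_floor
    )
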