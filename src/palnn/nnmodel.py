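"""Feedforward case/control classifier with heavy input masking.

Architecture (fixed):

    input-mask dropout(p_mask)
    -> affine(L -> h1) -> dropout(p) -> ReLU
    -> affine(h1 -> h2) -> dropout(p) -> GELU
    -> affine(h2 -> 1) -> sigmoid

Training uses binary cross-entropy, the Adam optimizer with L2 weight decay,
class balancing by case duplication / control halving, and fresh Gaussian
noise injected into both inputs and labels at every batch.  The network is
implemented directly on numpy arrays: all forward/backward passes are
explicit, which keeps desk-scale training seed-reproducible on CPU and gives
exact input gradients to the attribution code.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy.special import erf, expit

logger = logging.getLogger(__name__)

__all__ = [
    "ModelConfig",
    "TrainedModel",
    "default_hidden_sizes",
    "parameter_count",
    "build_model",
    "balance_dataset",
    "train",
    "train_ensemble",
    "GENOME_WIDE_PRESET",
    "SMALL_PRESET",
]

_SQRT1_2 = 1.0 / np.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / np.sqrt(2.0 * np.pi)


def default_hidden_sizes(input_size: int) -> tuple[int, int]:
    """Hidden-layer widths for an arbitrary input length.

    h1 = max(8, round(L / 1000)); h2 = max(4, round(h1 / 10)).
    """
    h1 = max(8, round(input_size / 1000))
    h2 = max(4, round(h1 / 10))
    return h1, h2


@dataclass
class ModelConfig:
    input_size: int
    hidden1: int | None = None
    hidden2: int | None = None
    input_mask_p: float = 0.99
    hidden_dropout_p: float = 0.6
    learning_rate: float = 1e-5
    weight_decay: float = 1e-3
    epochs: int = 1000
    batch_size: int = 256
    label_noise_sd: float = 0.1
    input_noise_sd: float = 0.1
    n_val_cases: int = 150
    n_val_controls: int = 150
    seed: int = 0
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if self.hidden1 is None or self.hidden2 is None:
            h1, h2 = default_hidden_sizes(self.input_size)
            self.hidden1 = self.hidden1 or h1
            self.hidden2 = self.hidden2 or h2
        if not (0 <= self.input_mask_p < 1 and 0 <= self.hidden_dropout_p < 1):
            raise ValueError("dropout probabilities must lie in [0, 1)")
        if min(self.input_size, self.hidden1, self.hidden2, self.epochs, self.batch_size) < 1:
            raise ValueError("sizes, epochs and batch_size must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.label_noise_sd < 0 or self.input_noise_sd < 0:
            raise ValueError("noise standard deviations must be non-negative")


# the two architectures used at full scale
GENOME_WIDE_PRESET = dict(
    input_size=290_522, hidden1=290, hidden2=29, input_mask_p=0.99
)
SMALL_PRESET = dict(input_size=20_714, hidden1=82, hidden2=8, input_mask_p=0.50)


def parameter_count(input_size: int, hidden1: int, hidden2: int) -> int:
    """Closed-form trainable parameter count of the three affine layers."""
    return (
        input_size * hidden1 + hidden1
        + hidden1 * hidden2 + hidden2
        + hidden2 * 1 + 1
    )


def _gelu(x: np.ndarray) -> np.ndarray:
    return 0.5 * x * (1.0 + erf(x * _SQRT1_2))


def _gelu_grad(x: np.ndarray) -> np.ndarray:
    cdf = 0.5 * (1.0 + erf(x * _SQRT1_2))
    pdf = _INV_SQRT_2PI * np.exp(-0.5 * x * x)
    return cdf + x * pdf


class TrainedModel:
    """Weights + training history for the three-layer classifier."""

    def __init__(self, config: ModelConfig, label_permutation_seed: int | None = None):
        self.config = config
        self.label_permutation_seed = label_permutation_seed
        self.history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}
        dtype = np.dtype(config.dtype)
        rng = np.random.default_rng(config.seed)
        self.params: dict[str, np.ndarray] = {}
        dims = [
            ("1", config.input_size, config.hidden1),
            ("2", config.hidden1, config.hidden2),
            ("3", config.hidden2, 1),
        ]
        # Kaiming-uniform fan-in init: weights U(-1/sqrt(fan_in), 1/sqrt(fan_in)),
        # biases from the same interval
        for tag, fan_in, fan_out in dims:
            bound = 1.0 / np.sqrt(fan_in)
            self.params[f"W{tag}"] = rng.uniform(
                -bound, bound, size=(fan_in, fan_out)
            ).astype(dtype)
            self.params[f"b{tag}"] = rng.uniform(-bound, bound, size=fan_out).astype(
                dtype
            )
        self._adam_state: dict[str, tuple[np.ndarray, np.ndarray]] | None = None
        self._adam_t = 0

    # ---------------------------------------------------------------- forward

    @property
    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    def forward(
        self,
        x: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
        cache: dict | None = None,
    ) -> np.ndarray:
        """Sigmoid output probabilities, shape (n,).

        In training mode the input mask and hidden dropout draw from ``rng``
        with inverted-dropout scaling; in eval mode all dropout is inactive.
        """
        cfg = self.config
        dtype = np.dtype(cfg.dtype)
        x = np.asarray(x, dtype=dtype)
        single = x.ndim == 1
        if single:
            x = x[None, :]
        p = self.params
        rdtype = np.float32 if dtype == np.float32 else np.float64
        if training:
            if rng is None:
                raise ValueError("training-mode forward requires an rng")
            if cfg.input_mask_p > 0:
                mask0 = (rng.random(x.shape, dtype=rdtype) >= cfg.input_mask_p).astype(
                    dtype
                )
                mask0 /= dtype.type(1.0 - cfg.input_mask_p)
            else:
                mask0 = np.ones_like(x)
            xm = x * mask0
        else:
            mask0 = None
            xm = x
        z1 = xm @ p["W1"] + p["b1"]
        if training and cfg.hidden_dropout_p > 0:
            d1 = (rng.random(z1.shape) >= cfg.hidden_dropout_p).astype(dtype)
            d1 /= dtype.type(1.0 - cfg.hidden_dropout_p)
            z1d = z1 * d1
        else:
            d1 = None
            z1d = z1
        a1 = np.maximum(z1d, 0.0)
        z2 = a1 @ p["W2"] + p["b2"]
        if training and cfg.hidden_dropout_p > 0:
            d2 = (rng.random(z2.shape) >= cfg.hidden_dropout_p).astype(dtype)
            d2 /= dtype.type(1.0 - cfg.hidden_dropout_p)
            z2d = z2 * d2
        else:
            d2 = None
            z2d = z2
        a2 = _gelu(z2d)
        z3 = (a2 @ p["W3"] + p["b3"]).ravel()
        out = expit(z3)
        if cache is not None:
            cache.update(
                x=x, mask0=mask0, xm=xm, d1=d1, z1d=z1d, a1=a1, d2=d2, z2d=z2d,
                a2=a2, out=out,
            )
        return out[0] if single else out

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Eval-mode probabilities (dropout inactive, deterministic)."""
        return self.forward(x, training=False)

    # --------------------------------------------------------------- backward

    def _backward(self, cache: dict, dz3: np.ndarray) -> dict[str, np.ndarray]:
        """Gradients of the summed objective given d(objective)/d(logit z3)."""
        p = self.params
        a2, a1 = cache["a2"], cache["a1"]
        grads = {
            "W3": a2.T @ dz3[:, None],
            "b3": np.atleast_1d(dz3.sum()),
        }
        da2 = dz3[:, None] @ p["W3"].T
        dz2d = da2 * _gelu_grad(cache["z2d"])
        dz2 = dz2d * cache["d2"] if cache["d2"] is not None else dz2d
        grads["W2"] = a1.T @ dz2
        grads["b2"] = dz2.sum(axis=0)
        da1 = dz2 @ p["W2"].T
        dz1d = da1 * (cache["z1d"] > 0)
        dz1 = dz1d * cache["d1"] if cache["d1"] is not None else dz1d
        grads["W1"] = cache["xm"].T @ dz1
        grads["b1"] = dz1.sum(axis=0)
        return grads

    def input_gradient(self, x: np.ndarray) -> np.ndarray:
        """d f(x) / d x per sample, eval mode (dropout inactive)."""
        cache: dict = {}
        out = self.forward(np.atleast_2d(x), training=False, cache=cache)
        p = self.params
        dz3 = out * (1.0 - out)  # sigmoid derivative
        da2 = dz3[:, None] @ p["W3"].T
        dz2 = da2 * _gelu_grad(cache["z2d"])
        da1 = dz2 @ p["W2"].T
        dz1 = da1 * (cache["z1d"] > 0)
        grad = dz1 @ p["W1"].T
        return grad[0] if np.asarray(x).ndim == 1 else grad

    # -------------------------------------------------------------- optimizer

    def _adam_step(self, grads: dict[str, np.ndarray]) -> None:
        cfg = self.config
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        if self._adam_state is None:
            self._adam_state = {
                k: (np.zeros_like(v), np.zeros_like(v)) for k, v in self.params.items()
            }
        self._adam_t += 1
        t = self._adam_t
        for k, param in self.params.items():
            g = grads[k].reshape(param.shape).astype(param.dtype)
            if cfg.weight_decay:
                g = g + cfg.weight_decay * param
            m, v = self._adam_state[k]
            m *= beta1
            m += (1 - beta1) * g
            v *= beta2
            v += (1 - beta2) * g * g
            mhat = m / (1 - beta1**t)
            vhat = v / (1 - beta2**t)
            param -= (cfg.learning_rate * mhat / (np.sqrt(vhat) + eps)).astype(
                param.dtype
            )

    # ------------------------------------------------------------ persistence

    def save(self, path: str | Path) -> None:
        """Checkpoint weights (.npz) plus a JSON metadata sidecar."""
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.params)
        meta = {
            "config": asdict(self.config),
            "label_permutation_seed": self.label_permutation_seed,
            "history": self.history,
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        model = cls(
            ModelConfig(**meta["config"]),
            label_permutation_seed=meta["label_permutation_seed"],
        )
        with np.load(path.with_suffix(".npz")) as npz:
            model.params = {k: npz[k] for k in npz.files}
        model.history = meta["history"]
        return model


def build_model(config: ModelConfig) -> TrainedModel:
    """Instantiate an untrained classifier (seeded Kaiming-uniform init)."""
    return TrainedModel(config)


def balance_dataset(
    case_ids: list, control_ids: list, seed: int = 0
) -> list:
    """Duplicate every case and halve the controls by random subsampling."""
    if not case_ids or not control_ids:
        raise ValueError("case and control id lists must be nonempty")
    rng = np.random.default_rng(seed)
    n_keep = len(control_ids) // 2
    kept = rng.choice(len(control_ids), size=n_keep, replace=False)
    controls = [control_ids[i] for i in sorted(kept)]
    return list(case_ids) * 2 + controls


def _bce(pred: np.ndarray, target: np.ndarray) -> float:
    eps = 1e-12
    pred = np.clip(pred, eps, 1 - eps)
    return float(-np.mean(target * np.log(pred) + (1 - target) * np.log(1 - pred)))


def train(
    model: TrainedModel,
    genotypes: np.ndarray,
    labels: np.ndarray,
    config: ModelConfig | None = None,
) -> TrainedModel:
    """Train in place for a fixed number of epochs; returns the model.

    A validation split of ``n_val_cases + n_val_controls`` is drawn (seeded)
    from the original cases/controls before balancing; the remaining samples
    are balanced with :func:`balance_dataset`.  Per batch, fresh N(0, sd^2)
    noise is added to genotype inputs and labels (labels then clipped to
    [0, 1]); final-epoch parameters are kept — no early stopping.
    """
    cfg = config or model.config
    dtype = np.dtype(cfg.dtype)
    rdtype = np.float32 if dtype == np.float32 else np.float64
    x_all = np.asarray(genotypes, dtype=dtype)
    y_all = np.asarray(labels)
    if x_all.shape[0] != y_all.shape[0]:
        raise ValueError("labels must align with genotype rows")
    if not set(np.unique(y_all).tolist()) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")

    rng = np.random.default_rng(cfg.seed)
    case_idx = np.flatnonzero(y_all == 1)
    control_idx = np.flatnonzero(y_all == 0)
    if cfg.n_val_cases > len(case_idx) or cfg.n_val_controls > len(control_idx):
        raise ValueError(
            f"validation split ({cfg.n_val_cases} cases, {cfg.n_val_controls} controls) "
            f"exceeds class counts ({len(case_idx)}, {len(control_idx)})"
        )
    val_cases = rng.choice(case_idx, size=cfg.n_val_cases, replace=False)
    val_controls = rng.choice(control_idx, size=cfg.n_val_controls, replace=False)
    val_idx = np.concatenate([val_cases, val_controls])
    x_val, y_val = x_all[val_idx], y_all[val_idx].astype(dtype)

    train_cases = sorted(set(case_idx.tolist()) - set(val_cases.tolist()))
    train_controls = sorted(set(control_idx.tolist()) - set(val_controls.tolist()))
    train_ids = balance_dataset(
        train_cases, train_controls, seed=int(rng.integers(2**31))
    )
    train_ids = np.asarray(train_ids)
    n_train = len(train_ids)

    model.history = {"train_loss": [], "val_loss": []}
    for _epoch in range(cfg.epochs):
        order = rng.permutation(n_train)
        epoch_loss = 0.0
        for start in range(0, n_train, cfg.batch_size):
            batch = train_ids[order[start : start + cfg.batch_size]]
            xb = x_all[batch]
            yb = y_all[batch].astype(dtype)
            if cfg.input_noise_sd > 0:
                noise = rng.standard_normal(xb.shape, dtype=rdtype)
                xb = xb + cfg.input_noise_sd * noise
            if cfg.label_noise_sd > 0:
                yb = np.clip(
                    yb + cfg.label_noise_sd * rng.standard_normal(yb.shape, dtype=rdtype),
                    0.0,
                    1.0,
                )
            cache: dict = {}
            out = model.forward(xb, training=True, rng=rng, cache=cache)
            # mean BCE; d/dz3 = (sigmoid(z3) - y) / n
            dz3 = (out - yb) / len(yb)
            grads = model._backward(cache, dz3.astype(dtype))
            model._adam_step(grads)
            epoch_loss += _bce(out, yb) * len(yb)
        model.history["train_loss"].append(epoch_loss / n_train)
        model.history["val_loss"].append(_bce(model.predict(x_val), y_val))
    return model


def train_ensemble(
    genotypes: np.ndarray,
    labels: np.ndarray,
    config: ModelConfig,
    seeds: list[int],
    permute_labels: bool = False,
    permutation_seed: int = 0,
    shared_permutation: bool = False,
) -> list[TrainedModel]:
    """Train one model per seed, optionally against permuted labels.

    With ``permute_labels`` each model trains on an independently shuffled
    label vector (seed ``permutation_seed + model index``) unless
    ``shared_permutation`` is set, in which case one shuffle (seed
    ``permutation_seed``) is used by every model.
    """
    if not seeds:
        raise ValueError("at least one seed required")
    if len(set(seeds)) != len(seeds):
        warnings.warn("duplicate seeds in ensemble; models will coincide")
    labels = np.asarray(labels)
    models = []
    shared = None
    if permute_labels and shared_permutation:
        shared = np.random.default_rng(permutation_seed).permutation(labels)
    for i, seed in enumerate(seeds):
        cfg = ModelConfig(**{**asdict(config), "seed": seed})
        perm_seed = None
        if permute_labels:
            if shared is not None:
                y = shared
                perm_seed = permutation_seed
            else:
                perm_seed = permutation_seed + i
                y = np.random.default_rng(perm_seed).permutation(labels)
        else:
            y = labels
        model = TrainedModel(cfg, label_permutation_seed=perm_seed)
        logger.info(
            "training model %d/%d (seed=%d%s)",
            i + 1,
            len(seeds),
            seed,
            ", permuted labels" if permute_labels else "",
        )
        train(model, genotypes, y, cfg)
        models.append(model)
    return models
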