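"""Dataset construction and the training recipe.

The contamination protocol mirrors the public single-channel benchmark:
training clean segments are shuffled ``n_repeats`` times (one shuffle per
nominal SNR level), concatenated, paired cyclically with shuffled artifact
segments and mixed at SNRs drawn uniformly from [-7, 2] dB; validation and
test segments are mixed deterministically at each of the ten integer SNRs
-7..2 dB.  Every (mixture, clean) pair is standardized by the mixture's
standard deviation before entering the loss.

Training minimizes the MSE between the model's configured output and the
standardized clean target with Adam, with early stopping on validation
loss and restoration of the best epoch's parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .segments import Segment1D, MixedTriplet
from .synth import SyntheticConfig, gen_clean, gen_eog, gen_emg, mix, standardize
from .nn import Adam
from .nn.autodiff import mean_square, sub
from .unfolding import UnfoldedDenoiser

__all__ = [
    "TrainConfig",
    "DatasetBundle",
    "TrainHistory",
    "make_synthetic_bundle",
    "build_training_set",
    "build_eval_set",
    "triplets_to_arrays",
    "train",
]

SNR_RANGE = (-7.0, 2.0)
EVAL_SNR_LEVELS = tuple(range(-7, 3))  # ten integer SNR levels


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 1e-4
    batch_size: int = 64
    max_epochs: int = 200
    patience: int = 10
    seed: int = 0
    loss: str = "mse"
    optimizer: str = "adam"

    def __post_init__(self) -> None:
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.loss != "mse" or self.optimizer != "adam":
            raise ValueError("only loss='mse' with optimizer='adam' is supported")


@dataclass
class DatasetBundle:
    """Clean and artifact segments plus a leakage-free split of the clean ones."""

    clean: list[Segment1D]
    artifact: list[Segment1D]
    artifact_kind: str
    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray

    def __post_init__(self) -> None:
        if self.artifact_kind not in ("eog", "emg"):
            raise ValueError("artifact_kind must be 'eog' or 'emg'")
        all_idx = np.concatenate([self.train_idx, self.val_idx, self.test_idx])
        if len(set(all_idx.tolist())) != all_idx.size:
            raise ValueError("train/val/test splits must be disjoint")
        if all_idx.size and (all_idx.min() < 0 or all_idx.max() >= len(self.clean)):
            raise ValueError("split indices out of range")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = 0
    stopped_early: bool = False


def make_synthetic_bundle(
    n_clean: int,
    n_artifact: int,
    artifact_kind: str = "emg",
    config: SyntheticConfig | None = None,
    seed: int = 0,
    split: tuple[float, float, float] = (0.8, 0.1, 0.1),
) -> DatasetBundle:
    """Generate a fully synthetic bundle with a seeded 80/10/10 split."""
    config = config or SyntheticConfig()
    clean = gen_clean(config, n_clean, seed=seed)
    gen = gen_eog if artifact_kind == "eog" else gen_emg
    artifact = gen(config, n_artifact, seed=seed + 1)
    rng = np.random.default_rng(seed + 2)
    perm = rng.permutation(n_clean)
    n_train = int(round(split[0] * n_clean))
    n_val = int(round(split[1] * n_clean))
    return DatasetBundle(
        clean=clean,
        artifact=artifact,
        artifact_kind=artifact_kind,
        train_idx=perm[:n_train],
        val_idx=perm[n_train : n_train + n_val],
        test_idx=perm[n_train + n_val :],
    )


def build_training_set(
    bundle: DatasetBundle,
    n_repeats: int = 10,
    snr_range: tuple[float, float] = SNR_RANGE,
    convention: str = "power",
    seed: int = 0,
) -> list[MixedTriplet]:
    """n_repeats shuffles of the training clean segments, concatenated, each
    entry mixed with a cyclically reused artifact at a uniform random SNR."""
    if bundle.train_idx.size == 0:
        raise ValueError("training split is empty")
    rng = np.random.default_rng(seed)
    order = np.concatenate(
        [rng.permutation(bundle.train_idx) for _ in range(n_repeats)]
    )
    art_order = rng.permutation(len(bundle.artifact))
    snrs = rng.uniform(snr_range[0], snr_range[1], size=order.size)
    triplets = []
    for i, (ci, s) in enumerate(zip(order, snrs)):
        n = bundle.artifact[art_order[i % art_order.size]]
        triplets.append(mix(bundle.clean[ci], n, float(s), convention=convention))
    return triplets


def build_eval_set(
    bundle: DatasetBundle,
    split: str = "test",
    convention: str = "power",
) -> list[MixedTriplet]:
    """Each clean segment of the split mixed at each of the ten integer SNR
    levels; artifact pairing is deterministic index cycling.  Output is
    grouped by SNR level (all segments at -7 dB first, then -6 dB, ...)."""
    idx = {"val": bundle.val_idx, "test": bundle.test_idx}.get(split)
    if idx is None:
        raise ValueError("split must be 'val' or 'test'")
    if idx.size == 0:
        raise ValueError(f"{split} split is empty")
    n_art = len(bundle.artifact)
    triplets = []
    for j, s in enumerate(EVAL_SNR_LEVELS):
        for i, ci in enumerate(idx):
            n = bundle.artifact[(i * len(EVAL_SNR_LEVELS) + j) % n_art]
            triplets.append(mix(bundle.clean[ci], n, float(s), convention=convention))
    return triplets


def triplets_to_arrays(
    triplets: list[MixedTriplet], apply_standardize: bool = True
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack triplets into (Y, X, scales) arrays, standardized per pair."""
    Y, X, scales = [], [], []
    for t in triplets:
        if apply_standardize:
            y_std, x_std, sc = standardize(t.y, t.x)
            Y.append(y_std.samples)
            X.append(x_std.samples)
            scales.append(sc)
        else:
            Y.append(t.y.samples)
            X.append(t.x.samples)
            scales.append(1.0)
    return np.stack(Y), np.stack(X), np.asarray(scales)


def _epoch_loss(model: UnfoldedDenoiser, Y: np.ndarray, X: np.ndarray, batch_size: int) -> float:
    """Validation loss: mean MSE over the set in eval mode."""
    was_train = model.training
    model.eval()
    total, count = 0.0, 0
    for start in range(0, Y.shape[0], batch_size):
        yb = Y[start : start + batch_size]
        xb = X[start : start + batch_size]
        out, _ = model.forward(yb)
        total += float(np.sum((out.data[:, 0, :] - xb) ** 2))
        count += xb.size
    if was_train:
        model.train()
    return total / count


def train(
    model: UnfoldedDenoiser,
    train_set: list[MixedTriplet] | tuple[np.ndarray, np.ndarray],
    val_set: list[MixedTriplet] | tuple[np.ndarray, np.ndarray],
    config: TrainConfig = TrainConfig(),
) -> tuple[dict[str, np.ndarray], TrainHistory]:
    """Fit the model; returns the best parameter state and the history.

    The best (lowest validation loss) parameters are restored into the
    model before returning.  Fully deterministic given ``config.seed``.
    """
    Yt, Xt, _ = (
        triplets_to_arrays(train_set) if isinstance(train_set, list) else (*train_set, None)
    )
    Yv, Xv, _ = (
        triplets_to_arrays(val_set) if isinstance(val_set, list) else (*val_set, None)
    )
    if Yt.shape[0] == 0 or Yv.shape[0] == 0:
        raise ValueError("train and validation sets must be nonempty")

    rng = np.random.default_rng(config.seed)
    optimizer = Adam(model.parameters(), lr=config.lr)
    history = TrainHistory()
    best_val = np.inf
    best_state: dict[str, np.ndarray] = {
        name: arr.copy() for name, arr in model.named_state()
    }
    epochs_since_best = 0

    model.train()
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(Yt.shape[0])
        epoch_losses = []
        for bi, start in enumerate(range(0, order.size, config.batch_size)):
            sel = order[start : start + config.batch_size]
            out, _ = model.forward(Yt[sel])
            target = Xt[sel][:, None, :]
            loss = mean_square(sub(out, target))
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}, batch {bi}"
                )
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            epoch_losses.append(float(loss.data))
        history.train_loss.append(float(np.mean(epoch_losses)))
        val_loss = _epoch_loss(model, Yv, Xv, config.batch_size)
        history.val_loss.append(val_loss)

        if val_loss < best_val:
            best_val = val_loss
            history.best_epoch = epoch
            best_state = {name: arr.copy() for name, arr in model.named_state()}
            epochs_since_best = 0
        else:
            epochs_since_best += 1
            if epochs_since_best >= config.patience:
                history.stopped_early = True
                break

    model.load_state(best_state)
    model.eval()
    return best_state, history
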