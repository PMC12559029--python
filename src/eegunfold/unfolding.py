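"""The deep-unfolded low-rank + sparse denoiser.

Each of K stages mirrors one iteration of the classical alternating solver,
with the hand-derived operators replaced by learnable modules:

* **Net-D** — the clean-signal estimator: a 1-D U-Net (encoder/decoder with
  skip connections) standing in for the singular-value-thresholding /
  approximation operator, wrapped in an outer residual,
  ``D_k = (R_{k-1} - N_{k-1}) + unet(R_{k-1} - N_{k-1})``.
* **Net-N** — the noise estimator: the closed-form surrogate update with the
  regularizer gradient replaced by a small convolutional network ``g`` and a
  learnable scalar step ``rho_k`` per stage, plus a residual enhancement:
  ``N_k = R_{k-1} + N_{k-1} - D_k - rho_k * g(N_{k-1}) + (R_{k-1} - D_k)``.
* **Net-R** — the raw-signal re-synthesizer: ``R_k = netr(D_k + N_k)``, a
  small CNN whose final layer starts near the identity so the stage begins
  as plain addition.

The wiring starts from ``R_0 = y``, ``N_0 = 0``.  The denoised output is
``D_K`` by default (``R_K`` selectable).  The majorization weight ``delta``
is fixed at 0.5 and not learned; only ``rho`` is learned per stage.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .nn import (
    Tensor,
    Module,
    Parameter,
    Conv1d,
    BatchNorm1d,
    ReLU,
    MaxPool1d,
    ZeroUpsample,
    Sequential,
)
from .nn import autodiff as ad

__all__ = [
    "NetDConfig",
    "NetNConfig",
    "NetRConfig",
    "UnfoldConfig",
    "StageState",
    "UNet1d",
    "PlainCNN",
    "NetD",
    "NetN",
    "NetR",
    "UnfoldedDenoiser",
    "build_model",
    "build_lrrnet_variant",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class NetDConfig:
    depth: int = 4
    channels: tuple[int, ...] = (16, 32, 64, 128)
    kernel_size: int = 3
    pool_factor: int = 2
    use_skips: bool = True

    def __post_init__(self) -> None:
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if len(self.channels) != self.depth:
            raise ValueError("channels must have one entry per encoder level")
        if self.kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd")


@dataclass(frozen=True)
class NetNConfig:
    n_layers: int = 3
    channels: int = 16
    kernel_size: int = 3

    def __post_init__(self) -> None:
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")


@dataclass(frozen=True)
class NetRConfig:
    n_layers: int = 2
    channels: int = 16
    kernel_size: int = 3

    def __post_init__(self) -> None:
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")


@dataclass(frozen=True)
class UnfoldConfig:
    K: int = 3
    delta: float = 0.5
    rho_init: float = 0.1
    share_weights_across_stages: bool = False
    output_mode: str = "D_last"
    strict_surrogate: bool = False  # use the delta-weighted closed form instead of the residual-enhanced one
    use_prev_D: bool = False  # feed the previous stage's clean estimate into the noise update
    netd_variant: str = "unet"  # "unet" or "cnn" (plain-CNN ablation)
    netd: NetDConfig = field(default_factory=NetDConfig)
    netn: NetNConfig = field(default_factory=NetNConfig)
    netr: NetRConfig = field(default_factory=NetRConfig)

    def __post_init__(self) -> None:
        if not (1 <= self.K <= 16):
            raise ValueError(f"K must be in [1, 16], got {self.K}")
        if not (0.0 < self.delta < 1.0):
            raise ValueError(f"delta must be in (0, 1), got {self.delta}")
        if self.output_mode not in ("D_last", "R_last"):
            raise ValueError("output_mode must be 'D_last' or 'R_last'")
        if self.netd_variant not in ("unet", "cnn"):
            raise ValueError("netd_variant must be 'unet' or 'cnn'")


@dataclass
class StageState:
    """The (R_k, N_k, D_k) triple carried between stages."""

    R: np.ndarray
    N: np.ndarray
    D: np.ndarray


class UNet1d(Module):
    """1-D encoder/decoder with max-pool downsampling, zero-stuffed
    transposed-convolution upsampling and (optional) skip concatenation."""

    def __init__(self, config: NetDConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        k = config.kernel_size
        ch = config.channels
        self.enc_convs = []
        self.enc_bns = []
        prev = 1
        for c in ch:
            self.enc_convs.append(Conv1d(prev, c, k, rng=rng))
            self.enc_bns.append(BatchNorm1d(c))
            prev = c
        self.pool = MaxPool1d(config.pool_factor)
        self.up = ZeroUpsample(config.pool_factor)
        self.up_convs = []
        self.dec_convs = []
        self.dec_bns = []
        for i in range(config.depth - 2, -1, -1):
            self.up_convs.append(Conv1d(ch[i + 1], ch[i], k, rng=rng))
            dec_in = 2 * ch[i] if config.use_skips else ch[i]
            self.dec_convs.append(Conv1d(dec_in, ch[i], k, rng=rng))
            self.dec_bns.append(BatchNorm1d(ch[i]))
        self.project = Conv1d(ch[0], 1, k, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        cfg = self.config
        skips = []
        h = x
        for i in range(cfg.depth):
            h = ad.relu(self.enc_bns[i](self.enc_convs[i](h)))
            if i < cfg.depth - 1:
                skips.append(h)
                h = self.pool(h)
        for j in range(cfg.depth - 1):
            h = self.up_convs[j](self.up(h))
            if cfg.use_skips:
                h = ad.concat_channels(h, skips[-(j + 1)])
            h = ad.relu(self.dec_bns[j](self.dec_convs[j](h)))
        return self.project(h)

    def min_length_factor(self) -> int:
        return self.config.pool_factor ** (self.config.depth - 1)


class PlainCNN(Module):
    """Stacked Conv+BN+ReLU layers: the non-multiscale stand-in for the
    clean-signal approximation operator used in the ablation."""

    def __init__(self, n_layers: int, channels: int, kernel_size: int, rng: np.random.Generator):
        super().__init__()
        layers: list[Module] = []
        prev = 1
        for _ in range(n_layers):
            layers.append(Conv1d(prev, channels, kernel_size, rng=rng))
            layers.append(BatchNorm1d(channels))
            layers.append(ReLU())
            prev = channels
        self.body = Sequential(*layers)
        self.project = Conv1d(prev, 1, kernel_size, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.project(self.body(x))


class NetD(Module):
    """Clean-signal estimator with the outer residual structure."""

    def __init__(self, net: Module):
        super().__init__()
        self.net = net

    def forward(self, R_prev: Tensor, N_prev: Tensor) -> Tensor:
        z = ad.sub(R_prev, N_prev)
        return ad.add(z, self.net(z))


class _ChannelConstant(Module):
    """A learnable per-channel constant, broadcast over batch and time.

    Used as the first layer of the gradient subnetwork in stage 1 only:
    there the input is ``N_0 = 0`` by definition, so a convolution of it is
    a constant map whose weight could never receive gradient; the constant
    is kept learnable and the dead weight is not instantiated.
    """

    def __init__(self, channels: int, rng: np.random.Generator):
        super().__init__()
        self.value = Parameter(rng.uniform(-0.5, 0.5, size=(channels, 1)))

    def forward(self, x: Tensor) -> Tensor:
        B, _, L = x.data.shape
        return ad.add(Tensor(np.zeros((B, 1, L))), self.value)


class NetN(Module):
    """Noise estimator: learned surrogate-gradient update with residual
    enhancement and a learnable scalar step ``rho``."""

    def __init__(
        self,
        config: NetNConfig,
        rho_init: float,
        rng: np.random.Generator,
        zero_input: bool = False,
    ):
        super().__init__()
        k = config.kernel_size
        layers: list[Module] = []
        prev = 1
        first = True
        for _ in range(config.n_layers - 1):
            if first and zero_input:
                layers.append(_ChannelConstant(config.channels, rng))
            else:
                layers.append(Conv1d(prev, config.channels, k, rng=rng))
            layers.append(ReLU())
            prev = config.channels
            first = False
        if first and zero_input:
            layers.append(_ChannelConstant(1, rng))
        else:
            layers.append(Conv1d(prev, 1, k, rng=rng))
        self.grad_net = Sequential(*layers)
        self.rho = Parameter(np.array(float(rho_init)))

    def forward(
        self,
        R_prev: Tensor,
        N_prev: Tensor,
        D_used: Tensor,
        delta: float,
        strict_surrogate: bool,
    ) -> Tensor:
        step = ad.mul(self.rho, self.grad_net(N_prev))
        resid = ad.sub(R_prev, D_used)
        if strict_surrogate:
            base = ad.add(ad.scale(N_prev, delta), ad.scale(resid, 1.0 - delta))
            return ad.sub(base, step)
        # residual-enhanced update: R + N - D - rho*g(N) + (R - D)
        return ad.sub(ad.add(ad.sub(ad.add(R_prev, N_prev), D_used), resid), step)


class NetR(Module):
    """Raw-signal re-synthesizer.  The final convolution starts near zero on
    top of an additive skip, so ``R ~= D + N`` at initialization."""

    def __init__(self, config: NetRConfig, rng: np.random.Generator):
        super().__init__()
        k = config.kernel_size
        layers: list[Module] = []
        prev = 1
        for _ in range(config.n_layers - 1):
            layers.append(Conv1d(prev, config.channels, k, rng=rng))
            layers.append(ReLU())
            prev = config.channels
        self.body = Sequential(*layers)
        final = Conv1d(prev, 1, k, rng=rng)
        final.weight.data *= 1e-8 / np.max(np.abs(final.weight.data) + 1e-300)
        final.bias.data[...] = 0.0
        self.final = final

    def forward(self, D_cur: Tensor, N_cur: Tensor) -> Tensor:
        z = ad.add(D_cur, N_cur)
        return ad.add(z, self.final(self.body(z)))


class _Stage(Module):
    def __init__(self, netd: NetD, netn: NetN | None, netr: NetR | None):
        super().__init__()
        self.netd = netd
        self.netn = netn
        self.netr = netr


class UnfoldedDenoiser(Module):
    """K unfolded stages of the learned low-rank + sparse iteration.

    For the default clean-signal output (``output_mode="D_last"``) the final
    stage is an estimation-only half-stage: its noise and re-synthesis
    modules would be dead ends (their outputs feed nothing), so they are not
    instantiated; the trajectory records the implied residual
    ``N_K = R_{K-1} - D_K`` and ``R_K = D_K + N_K`` instead.
    """

    def __init__(self, config: UnfoldConfig = UnfoldConfig(), seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        self.stages: list[_Stage] = []
        share = config.share_weights_across_stages
        netd_shared: NetD | None = None
        netr_shared: NetR | None = None
        gradnet_shared = None  # stage 1's gradient net is structurally different
        for k in range(config.K):
            is_last = k == config.K - 1
            needs_tail = config.output_mode == "R_last" or not is_last
            if share and netd_shared is not None:
                netd = netd_shared
            else:
                netd = NetD(self._build_appro(rng))
                netd_shared = netd
            netn = netr = None
            if needs_tail:
                # rho is always per-stage, even under weight sharing
                netn = NetN(config.netn, config.rho_init, rng, zero_input=(k == 0))
                if k >= 1:
                    if share and gradnet_shared is not None:
                        netn.grad_net = gradnet_shared
                    else:
                        gradnet_shared = netn.grad_net
                if share and netr_shared is not None:
                    netr = netr_shared
                else:
                    netr = NetR(config.netr, rng)
                    netr_shared = netr
            self.stages.append(_Stage(netd, netn, netr))

    def _build_appro(self, rng: np.random.Generator) -> Module:
        if self.config.netd_variant == "unet":
            return UNet1d(self.config.netd, rng)
        # plain-CNN ablation: width chosen for a comparable parameter count
        ref = UNet1d(self.config.netd, np.random.default_rng(0)).num_parameters()
        k = self.config.netd.kernel_size
        n_layers = 5
        best_c, best_gap = 4, float("inf")
        for c in range(4, 513, 4):
            cnt = PlainCNN(n_layers, c, k, np.random.default_rng(0)).num_parameters()
            gap = abs(np.log(cnt / ref))
            if gap < best_gap:
                best_c, best_gap = c, gap
        return PlainCNN(n_layers, best_c, k, rng)

    def _as_batch(self, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=np.float64)
        if y.ndim == 1:
            y = y[None, :]
        if y.ndim == 2:
            y = y[:, None, :]
        if y.ndim != 3 or y.shape[1] != 1:
            raise ValueError(f"expected (L,), (B, L) or (B, 1, L) input, got {y.shape}")
        factor = self.config.netd.pool_factor ** (self.config.netd.depth - 1)
        if self.config.netd_variant == "unet" and y.shape[-1] % factor != 0:
            raise ValueError(
                f"segment length {y.shape[-1]} not divisible by {factor} "
                f"(pool_factor^(depth-1))"
            )
        return y

    def forward(self, y: np.ndarray | Tensor) -> tuple[Tensor, list[StageState]]:
        """Run all K stages; returns the configured output as a graph Tensor
        plus the per-stage (R, N, D) trajectory as plain arrays."""
        if isinstance(y, Tensor):
            R = y
        else:
            R = Tensor(self._as_batch(y))
        N = Tensor(np.zeros_like(R.data))
        cfg = self.config
        trajectory: list[StageState] = []
        D_prev = R  # convention: before stage 1 the best clean estimate is the input
        for k, stage in enumerate(self.stages):
            D = stage.netd(R, N)
            if stage.netn is not None:
                D_used = D_prev if cfg.use_prev_D else D
                N = stage.netn(R, N, D_used, cfg.delta, cfg.strict_surrogate)
                R = stage.netr(D, N)
            else:  # estimation-only final half-stage (D_last mode)
                N = ad.sub(R, D)
                R = ad.add(D, N)
            for name, t in (("R", R), ("N", N), ("D", D)):
                if not np.all(np.isfinite(t.data)):
                    raise FloatingPointError(
                        f"non-finite {name} at unfolding stage {k + 1}"
                    )
            trajectory.append(StageState(R=R.data.copy(), N=N.data.copy(), D=D.data.copy()))
            D_prev = D
        out = D if cfg.output_mode == "D_last" else R
        return out, trajectory

    def denoise(self, y: np.ndarray) -> np.ndarray:
        """Inference: returns the denoised batch with the input's shape."""
        y = np.asarray(y, dtype=np.float64)
        squeeze = y.ndim == 1
        was_train = self.training
        self.eval()
        out, _ = self.forward(y)
        if was_train:
            self.train()
        result = out.data[:, 0, :]
        return result[0] if squeeze else result


def build_model(config: UnfoldConfig = UnfoldConfig(), seed: int = 0) -> UnfoldedDenoiser:
    return UnfoldedDenoiser(config, seed=seed)


def build_lrrnet_variant(config: UnfoldConfig = UnfoldConfig(), seed: int = 0) -> UnfoldedDenoiser:
    """The ablation twin: identical stage wiring with the U-Net clean-signal
    estimator replaced by a plain stacked CNN of comparable size."""
    return UnfoldedDenoiser(dataclasses.replace(config, netd_variant="cnn"), seed=seed)


def _config_to_dict(config: UnfoldConfig) -> dict:
    d = dataclasses.asdict(config)
    return d


def _config_from_dict(d: dict) -> UnfoldConfig:
    d = dict(d)
    d["netd"] = NetDConfig(**{**d["netd"], "channels": tuple(d["netd"]["channels"])})
    d["netn"] = NetNConfig(**d["netn"])
    d["netr"] = NetRConfig(**d["netr"])
    return UnfoldConfig(**d)


def save_checkpoint(model: UnfoldedDenoiser, path: str | Path) -> None:
    """Single-file checkpoint: all parameters/buffers plus the full config."""
    state = {name: arr for name, arr in model.named_state()}
    np.savez(
        Path(path),
        __config__=np.frombuffer(
            json.dumps(_config_to_dict(model.config)).encode(), dtype=np.uint8
        ),
        **state,
    )


def load_checkpoint(path: str | Path) -> UnfoldedDenoiser:
    with np.load(Path(path)) as data:
        config = _config_from_dict(json.loads(bytes(data["__config__"]).decode()))
        model = UnfoldedDenoiser(config)
        model.load_state({k: data[k] for k in data.files if k != "__config__"})
    return model
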