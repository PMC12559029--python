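"""Benchmark and ablation runners: per-SNR metric curves, mean tables,
stage-count (K) sweeps, U-Net-vs-CNN ablation, file denoising and PSD
reports.  Tables are pandas DataFrames carrying the seed and a config hash,
serializable to CSV/JSON; nothing here depends on plotting."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from . import metrics as M
from .segments import Segment1D, MixedTriplet, load_segments, save_segments
from .synth import standardize, unstandardize
from .training import (
    TrainConfig,
    DatasetBundle,
    build_training_set,
    build_eval_set,
    triplets_to_arrays,
    train,
    EVAL_SNR_LEVELS,
)
from .unfolding import UnfoldConfig, UnfoldedDenoiser, build_model, build_lrrnet_variant

__all__ = [
    "BenchmarkTable",
    "config_hash",
    "run_benchmark",
    "k_sweep",
    "ablation_unet_vs_cnn",
    "denoise_file",
    "psd_report",
]

Denoiser = Callable[[np.ndarray], np.ndarray]

METRIC_COLS = ["rrmse_t", "rrmse_s", "cc", "snr_db"]


@dataclasses.dataclass
class BenchmarkTable:
    table: pd.DataFrame  # rows keyed by (method, snr_level or "mean")
    metadata: dict

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    def to_json(self, path: str | Path) -> None:
        payload = {"metadata": self.metadata, "rows": self.table.to_dict(orient="records")}
        Path(path).write_text(json.dumps(payload, indent=2))


def config_hash(config) -> str:
    """Stable short hash of a (dataclass) configuration."""
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _as_denoiser(model: UnfoldedDenoiser | Denoiser) -> Denoiser:
    if isinstance(model, UnfoldedDenoiser):
        return model.denoise
    return model


def run_benchmark(
    model: UnfoldedDenoiser | Denoiser,
    eval_set: list[MixedTriplet],
    method: str = "model",
    seed: int | None = None,
) -> BenchmarkTable:
    """Per-SNR-level mean metrics plus the overall unweighted mean row.

    Metrics are computed in the standardized space in which the model
    operates (mixture and clean target divided by the mixture's std).
    """
    fn = _as_denoiser(model)
    by_level: dict[float, list[M.MetricReport]] = {}
    for t in eval_set:
        y_std, x_std, _ = standardize(t.y, t.x)
        x_hat = fn(y_std.samples[None, :])[0]
        by_level.setdefault(t.snr_db, []).append(
            M.evaluate(x_hat, x_std.samples, fs=t.x.fs)
        )
    missing = set(float(s) for s in EVAL_SNR_LEVELS) - set(by_level)
    if missing:
        raise ValueError(f"eval set is missing SNR levels: {sorted(missing)}")
    rows = []
    for level in sorted(by_level):
        reports = by_level[level]
        rows.append(
            {
                "method": method,
                "snr_level": level,
                **{c: float(np.mean([getattr(r, c) for r in reports])) for c in METRIC_COLS},
            }
        )
    mean_row = {
        "method": method,
        "snr_level": "mean",
        **{c: float(np.mean([r[c] for r in rows])) for c in METRIC_COLS},
    }
    rows.append(mean_row)
    meta = {"seed": seed, "n_pairs": len(eval_set)}
    if isinstance(model, UnfoldedDenoiser):
        meta["config_hash"] = config_hash(model.config)
    return BenchmarkTable(table=pd.DataFrame(rows), metadata=meta)


def _train_and_score(
    config: UnfoldConfig,
    bundle: DatasetBundle,
    train_config: TrainConfig,
    n_repeats: int,
    seed: int,
    method: str,
) -> dict:
    model = build_model(config, seed=seed)
    train_set = build_training_set(bundle, n_repeats=n_repeats, seed=seed)
    val_set = build_eval_set(bundle, "val")
    tc = dataclasses.replace(train_config, seed=seed)
    _, history = train(model, train_set, val_set, tc)
    table = run_benchmark(model, build_eval_set(bundle, "test"), method=method, seed=seed)
    mean = table.table[table.table.snr_level == "mean"].iloc[0]
    return {
        "method": method,
        "seed": seed,
        "config_hash": config_hash(config),
        "best_epoch": history.best_epoch,
        **{c: float(mean[c]) for c in METRIC_COLS},
    }


def k_sweep(
    config: UnfoldConfig,
    bundle: DatasetBundle,
    k_values: list[int],
    seeds: list[int],
    train_config: TrainConfig = TrainConfig(),
    n_repeats: int = 1,
) -> pd.DataFrame:
    """Train one model per (K, seed) under an identical protocol and report
    per-K mean test metrics (median across seeds, plus per-run rows)."""
    if not k_values:
        raise ValueError("k_values must be nonempty")
    rows = []
    for K in k_values:
        for seed in seeds:
            cfg = dataclasses.replace(config, K=K)
            try:
                row = _train_and_score(cfg, bundle, train_config, n_repeats, seed, f"K={K}")
                row["K"] = K
                rows.append(row)
            except FloatingPointError as exc:  # record failed runs as missing
                rows.append({"method": f"K={K}", "K": K, "seed": seed, "error": str(exc)})
    return pd.DataFrame(rows)


def ablation_unet_vs_cnn(
    config: UnfoldConfig,
    bundle: DatasetBundle,
    seeds: list[int],
    train_config: TrainConfig = TrainConfig(),
    n_repeats: int = 1,
) -> pd.DataFrame:
    """Train the U-Net model and its plain-CNN twin under identical budgets
    and seeds; returns paired per-run rows."""
    rows = []
    for variant, name in (("unet", "unfolded-unet"), ("cnn", "unfolded-cnn")):
        cfg = dataclasses.replace(config, netd_variant=variant)
        for seed in seeds:
            try:
                rows.append(_train_and_score(cfg, bundle, train_config, n_repeats, seed, name))
            except FloatingPointError as exc:
                rows.append({"method": name, "seed": seed, "error": str(exc)})
    return pd.DataFrame(rows)


def denoise_file(
    model: UnfoldedDenoiser,
    input_path: str | Path,
    output_path: str | Path,
    clean_path: str | Path | None = None,
    report_path: str | Path | None = None,
    frame_length: int | None = None,
) -> pd.DataFrame | None:
    """Denoise a file of segments (rows); optionally score against a clean
    reference file.

    Rows longer than the model's expected frame are split into
    non-overlapping frames (remainder zero-padded, trimmed on output).
    Per-segment standardization is applied and inverted, so the output is
    on the input's scale.
    """
    segments = load_segments(input_path)
    L = len(segments[0])
    frame = frame_length or L
    out_rows = []
    for seg in segments:
        v = seg.samples
        n_frames = int(np.ceil(v.size / frame))
        padded = np.zeros(n_frames * frame)
        padded[: v.size] = v
        frames = padded.reshape(n_frames, frame)
        den = np.empty_like(frames)
        for i, fr in enumerate(frames):
            sd = float(np.std(fr))
            if sd == 0.0:
                den[i] = fr
            else:
                den[i] = model.denoise(fr / sd) * sd
        out_rows.append(den.ravel()[: v.size])
    out = np.stack(out_rows)
    save_segments(output_path, out)

    if clean_path is None:
        return None
    clean = load_segments(clean_path)
    if len(clean) != len(segments):
        raise ValueError(
            f"clean reference {clean_path} has {len(clean)} segments, input has {len(segments)}"
        )
    records = []
    for i, (seg, ref) in enumerate(zip(segments, clean)):
        sd = float(np.std(seg.samples))
        scale = sd if sd > 0 else 1.0
        rep = M.evaluate(out[i] / scale, ref.samples / scale, fs=ref.fs)
        records.append({"segment": i, **rep.as_dict()})
    _, mean = M.evaluate_batch(
        [
            (out[i] / max(float(np.std(s.samples)), 1e-300), r.samples / max(float(np.std(s.samples)), 1e-300))
            for i, (s, r) in enumerate(zip(segments, clean))
        ],
        fs=clean[0].fs,
    )
    records.append({"segment": "mean", **mean.as_dict()})
    report = pd.DataFrame(records)
    if report_path is not None:
        report.to_csv(report_path, index=False)
    return report


def psd_report(
    x_hat: Segment1D | np.ndarray,
    x: Segment1D | np.ndarray,
    y: Segment1D | np.ndarray,
    fs: float | None = None,
    psd_config: M.PSDConfig = M.PSDConfig(),
) -> pd.DataFrame:
    """Aligned Welch PSD columns for the noisy, denoised and clean signals."""
    arrays = []
    for s in (y, x_hat, x):
        v = s.samples if isinstance(s, Segment1D) else np.asarray(s, dtype=np.float64)
        arrays.append(v)
    if not (arrays[0].shape == arrays[1].shape == arrays[2].shape):
        raise ValueError("noisy, denoised and clean signals must share one length")
    if fs is None:
        fs = y.fs if isinstance(y, Segment1D) else 1.0
    cols = {}
    freqs = None
    for name, v in zip(("psd_noisy", "psd_denoised", "psd_clean"), arrays):
        est = M.estimate_psd(v, fs=fs, config=psd_config)
        freqs = est.freqs
        cols[name] = est.power
    return pd.DataFrame({"freq_hz": freqs, **cols})
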