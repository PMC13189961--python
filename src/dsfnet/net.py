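"""Dual-stream fusion network: per-frame waveform CNN + vital-sign MLP,
Transformer temporal encoder with last-step pooling, binary risk head.

Per-second monitor frames carry three waveforms (ECG and respiration at 256
samples/s, plethysmogram at 60 samples/s) and 14 numeric indicators (8 vital
signs + 6 per-minute cardiac-event counters).  The pleth channel is linearly
upsampled to 256 points so the three waveforms stack into a (3, 256) tensor.
Two conv blocks (kernel 7, stride 2, padding 3, channels 3->16->32, each with
batch norm, ReLU and dropout p=0.3) flatten to a 2048-d morphology embedding;
the numeric vector is mapped 14->64->32 by an MLP with batch norm + ReLU.
Concatenation gives a 2080-d fused frame vector.  A window of T=15 fused
frames is projected to d_model=128, offset by a learned positional table,
passed through a small Transformer encoder, and the last step's hidden state
feeds a linear head producing one logit.

The ablation switches mirror the variant grid used to probe the design:
``use_waveform_branch=False`` drops the CNN stream (numeric embeddings only),
``use_temporal_fusion=False`` classifies from the final frame's fused vector
alone, and ``use_positional_encoding=False`` removes the positional table.
"""

from __future__ import annotations

import hashlib
import io
import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import nn

# ---------------------------------------------------------------------------
# Frame layout (one row of the 587-scalar per-second schema)
# ---------------------------------------------------------------------------

NUMERIC_FEATURES = [
    "HR", "PR", "SpO2", "PI", "NIBP_S", "NIBP_D", "NIBP_M", "RR",
    "PVCs", "VPBs", "Pauses", "Missed", "Couplets", "RonT",
]
ECG_LEN, RESP_LEN, PLETH_LEN = 256, 256, 60
FRAME_DIM = 1 + len(NUMERIC_FEATURES) + ECG_LEN + RESP_LEN + PLETH_LEN  # 587

TIME_COL = 0
NUMERIC_SLICE = slice(1, 15)
ECG_SLICE = slice(15, 15 + ECG_LEN)
RESP_SLICE = slice(15 + ECG_LEN, 15 + ECG_LEN + RESP_LEN)
PLETH_SLICE = slice(15 + ECG_LEN + RESP_LEN, FRAME_DIM)

FRAME_COLUMNS = (
    ["Time"] + NUMERIC_FEATURES
    + [f"ECG_{i}" for i in range(ECG_LEN)]
    + [f"Resp_{i}" for i in range(RESP_LEN)]
    + [f"Pleth_{i}" for i in range(PLETH_LEN)]
)


def upsample_pleth(pleth: np.ndarray) -> np.ndarray:
    """Linearly interpolate the 60-sample pleth axis onto 256 points.

    Works on any leading batch shape; the last axis must have length 60.
    Endpoints are preserved and outputs stay within the input's range.
    """
    pleth = np.asarray(pleth)
    if pleth.shape[-1] != PLETH_LEN:
        raise ValueError(f"pleth last axis must be {PLETH_LEN}, got {pleth.shape[-1]}")
    if not np.all(np.isfinite(pleth)):
        raise ValueError("pleth contains non-finite values")
    pos = np.linspace(0.0, PLETH_LEN - 1, ECG_LEN)
    lo = np.floor(pos).astype(int)
    hi = np.minimum(lo + 1, PLETH_LEN - 1)
    frac = pos - lo
    return pleth[..., lo] * (1.0 - frac) + pleth[..., hi] * frac


def pleth_upsample_weights() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(lo index, hi index, hi weight) for each of the 256 interpolated samples."""
    pos = np.linspace(0.0, PLETH_LEN - 1, ECG_LEN)
    lo = np.floor(pos).astype(int)
    hi = np.minimum(lo + 1, PLETH_LEN - 1)
    return lo, hi, pos - lo


def split_frames(frames: np.ndarray):
    """Split (..., 587) frame rows into (numeric, ecg, resp, pleth) blocks."""
    frames = np.asarray(frames)
    if frames.shape[-1] != FRAME_DIM:
        raise ValueError(f"frames last axis must be {FRAME_DIM}, got {frames.shape[-1]}")
    return (frames[..., NUMERIC_SLICE], frames[..., ECG_SLICE],
            frames[..., RESP_SLICE], frames[..., PLETH_SLICE])


def frames_to_model_inputs(frames: np.ndarray):
    """(..., T, 587) frames -> waveform stack (..., T, 3, 256) + numerics (..., T, 14).

    The timestamp column is dropped; the pleth channel is upsampled to 256.
    """
    num, ecg, resp, pleth = split_frames(frames)
    wave = np.stack([ecg, resp, upsample_pleth(pleth)], axis=-2)
    return wave, num


# ---------------------------------------------------------------------------
# Configuration and input normalisation
# ---------------------------------------------------------------------------


@dataclass
class ModelConfig:
    conv_kernel: int = 7
    conv_stride: int = 2
    conv_channels: tuple = (16, 32)
    conv_padding: int = 3
    dropout_p: float = 0.3
    mlp_dims: tuple = (14, 64, 32)
    d_model: int = 128
    n_heads: int = 4
    n_layers: int = 2
    dim_ff: int = 256
    transformer_dropout: float = 0.1
    T: int = 15
    use_waveform_branch: bool = True
    use_temporal_fusion: bool = True
    use_positional_encoding: bool = True
    seed: int = 0

    def __post_init__(self):
        # dimension contract: flattened CNN output must be 2048-d
        flat = self.conv_channels[-1] * (ECG_LEN // self.conv_stride ** 2)
        if flat != 2048:
            raise ValueError(
                f"conv plan violates the 2048-d flatten contract: "
                f"{self.conv_channels[-1]} x {ECG_LEN // self.conv_stride ** 2} = {flat}")
        if self.d_model % self.n_heads:
            raise ValueError(f"d_model {self.d_model} not divisible by n_heads {self.n_heads}")
        if self.mlp_dims[0] != len(NUMERIC_FEATURES) or self.mlp_dims[-1] != 32:
            raise ValueError(f"mlp_dims must run 14 -> ... -> 32, got {self.mlp_dims}")

    @property
    def waveform_dim(self) -> int:
        return 2048

    @property
    def numeric_dim(self) -> int:
        return self.mlp_dims[-1]

    @property
    def fused_dim(self) -> int:
        return (self.waveform_dim if self.use_waveform_branch else 0) + self.numeric_dim


@dataclass
class NormStats:
    """Training-split z-score statistics (per numeric feature, per waveform channel)."""

    num_mean: np.ndarray = field(default=None)
    num_std: np.ndarray = field(default=None)
    wave_mean: np.ndarray = field(default=None)   # (3,) for ECG, Resp, Pleth(upsampled)
    wave_std: np.ndarray = field(default=None)

    @property
    def fitted(self) -> bool:
        return self.num_mean is not None

    @classmethod
    def identity(cls) -> "NormStats":
        """Pass-through statistics (zero mean, unit scale)."""
        return cls(num_mean=np.zeros(len(NUMERIC_FEATURES)),
                   num_std=np.ones(len(NUMERIC_FEATURES)),
                   wave_mean=np.zeros(3), wave_std=np.ones(3))

    @classmethod
    def fit(cls, frames: np.ndarray) -> "NormStats":
        """Fit from a (n, 587) matrix of *training* frames only."""
        wave, num = frames_to_model_inputs(frames)
        eps = 1e-6
        return cls(
            num_mean=num.mean(axis=0),
            num_std=num.std(axis=0) + eps,
            wave_mean=wave.mean(axis=(0, 2)),
            wave_std=wave.std(axis=(0, 2)) + eps,
        )

    def transform(self, wave: np.ndarray, num: np.ndarray):
        if not self.fitted:
            raise RuntimeError("normalization statistics not fitted (fit on the training split first)")
        wave_n = (wave - self.wave_mean[..., :, None]) / self.wave_std[..., :, None]
        num_n = (num - self.num_mean) / self.num_std
        return wave_n.astype(np.float32), num_n.astype(np.float32)

    def to_dict(self) -> dict:
        return {k: getattr(self, k).tolist() for k in
                ("num_mean", "num_std", "wave_mean", "wave_std")}

    @classmethod
    def from_dict(cls, d: dict) -> "NormStats":
        return cls(**{k: np.asarray(v) for k, v in d.items()})


# ---------------------------------------------------------------------------
# Encoders
# ---------------------------------------------------------------------------


class WaveformEncoder(nn.Module):
    """Two conv blocks (k=7, s=2, BN, ReLU, dropout 0.3) -> flatten to 2048-d."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        c1, c2 = cfg.conv_channels
        self.conv1 = nn.Conv1d(3, c1, cfg.conv_kernel, cfg.conv_stride,
                               cfg.conv_padding, rng, dtype)
        self.bn1 = nn.BatchNorm1d(c1, dtype=dtype)
        self.drop1 = nn.Dropout(cfg.dropout_p, rng)
        self.conv2 = nn.Conv1d(c1, c2, cfg.conv_kernel, cfg.conv_stride,
                               cfg.conv_padding, rng, dtype)
        self.bn2 = nn.BatchNorm1d(c2, dtype=dtype)
        self.drop2 = nn.Dropout(cfg.dropout_p, rng)

    def intermediate_lengths(self, length: int = ECG_LEN) -> tuple[int, int]:
        l1 = self.conv1.out_length(length)
        return l1, self.conv2.out_length(l1)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        """(N, 3, 256) -> (N, 2048)."""
        x = self.drop1(self.bn1(self.conv1(x)).relu())
        x = self.drop2(self.bn2(self.conv2(x)).relu())
        n = x.shape[0]
        return x.reshape(n, -1)


class NumericEncoder(nn.Module):
    """Two FC + BN + ReLU blocks projecting the 14-d vitals/events vector to 32-d."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        d_in, d_h, d_out = cfg.mlp_dims
        self.fc1 = nn.Linear(d_in, d_h, rng, dtype)
        self.bn1 = nn.BatchNorm1d(d_h, dtype=dtype)
        self.fc2 = nn.Linear(d_h, d_out, rng, dtype)
        self.bn2 = nn.BatchNorm1d(d_out, dtype=dtype)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        x = self.bn1(self.fc1(x)).relu()
        return self.bn2(self.fc2(x)).relu()


def fuse_frame(wave: nn.Tensor | np.ndarray, num: nn.Tensor | np.ndarray):
    """Concatenate 2048-d waveform and 32-d numeric embeddings -> 2080-d."""
    if isinstance(wave, nn.Tensor) or isinstance(num, nn.Tensor):
        return nn.concat([wave, num], axis=-1)
    wave, num = np.asarray(wave), np.asarray(num)
    if wave.shape[-1] != 2048 or num.shape[-1] != 32:
        raise ValueError(f"expected 2048-d and 32-d inputs, got {wave.shape[-1]}, {num.shape[-1]}")
    return np.concatenate([wave, num], axis=-1)


class DSFNet(nn.Module):
    """End-to-end window classifier (per-frame dual-stream encoders + Transformer)."""

    def __init__(self, cfg: ModelConfig, dtype=np.float32):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        if cfg.use_waveform_branch:
            self.wave_enc = WaveformEncoder(cfg, rng, dtype)
        self.num_enc = NumericEncoder(cfg, rng, dtype)
        self.proj = nn.Linear(cfg.fused_dim, cfg.d_model, rng, dtype)
        if cfg.use_temporal_fusion:
            self.pos = nn.Tensor(
                (rng.normal(0.0, 0.02, (cfg.T, cfg.d_model))).astype(dtype),
                requires_grad=True)
            self.layers = [nn.TransformerEncoderLayer(
                cfg.d_model, cfg.n_heads, cfg.dim_ff, cfg.transformer_dropout,
                rng, dtype) for _ in range(cfg.n_layers)]
        self.head = nn.Linear(cfg.d_model, 1, rng, dtype)

    # -- frame-level pieces -------------------------------------------------
    def encode_waveform(self, wave: np.ndarray | nn.Tensor) -> nn.Tensor:
        """(N, 3, 256) waveform stack -> (N, 2048) morphology embedding."""
        if not self.cfg.use_waveform_branch:
            raise RuntimeError("waveform branch disabled by configuration")
        x = wave if isinstance(wave, nn.Tensor) else nn.Tensor(np.asarray(wave, np.float32))
        if x.shape[-2:] != (3, ECG_LEN):
            raise ValueError(f"expected (N, 3, {ECG_LEN}) waveforms, got {x.shape}")
        return self.wave_enc(x)

    def encode_numeric(self, num: np.ndarray | nn.Tensor) -> nn.Tensor:
        """(N, 14) vitals/events vector -> (N, 32) embedding."""
        x = num if isinstance(num, nn.Tensor) else nn.Tensor(np.asarray(num, np.float32))
        if x.shape[-1] != len(NUMERIC_FEATURES):
            raise ValueError(f"expected {len(NUMERIC_FEATURES)}-d numerics, got {x.shape}")
        return self.num_enc(x)

    # -- window-level forward ------------------------------------------------
    def forward(self, wave, num) -> nn.Tensor:
        """Normalized inputs (B, T, 3, 256) and (B, T, 14) -> logits (B,)."""
        num_t = num if isinstance(num, nn.Tensor) else nn.Tensor(np.asarray(num, np.float32))
        b, t = num_t.shape[0], num_t.shape[1]
        if t != self.cfg.T:
            raise ValueError(f"expected T={self.cfg.T} frames per window, got {t}")
        if self.cfg.use_temporal_fusion:
            num_flat = num_t.reshape(b * t, -1)
            feats = self.num_enc(num_flat)
            if self.cfg.use_waveform_branch:
                wave_t = wave if isinstance(wave, nn.Tensor) else nn.Tensor(
                    np.asarray(wave, np.float32))
                wave_flat = wave_t.reshape(b * t, 3, ECG_LEN)
                feats = fuse_frame(self.wave_enc(wave_flat), feats)
            x = self.proj(feats).reshape(b, t, self.cfg.d_model)
            if self.cfg.use_positional_encoding:
                x = x + self.pos
            for layer in self.layers:
                x = layer(x)
            pooled = x[:, -1, :]                   # last-step pooling
        else:
            # single-frame variant: the final frame's fused vector only
            last_num = num_t[:, -1, :]
            feats = self.num_enc(last_num)
            if self.cfg.use_waveform_branch:
                wave_t = wave if isinstance(wave, nn.Tensor) else nn.Tensor(
                    np.asarray(wave, np.float32))
                feats = fuse_frame(self.wave_enc(wave_t[:, -1, :, :]), feats)
            pooled = self.proj(feats).relu()
        return self.head(pooled).reshape(b)

    def temporal_forward(self, fused_frames) -> nn.Tensor:
        """(B, T, fused_dim) pre-fused frame vectors -> logits (B,).

        Exposes the projection -> positional encoding -> Transformer ->
        last-step pooling -> head tail of the model on its own.
        """
        if not self.cfg.use_temporal_fusion:
            raise RuntimeError("temporal fusion disabled by configuration")
        x = fused_frames if isinstance(fused_frames, nn.Tensor) else nn.Tensor(
            np.asarray(fused_frames, np.float32))
        b, t = x.shape[0], x.shape[1]
        if t != self.cfg.T:
            raise ValueError(f"expected T={self.cfg.T} frames, got {t}")
        x = self.proj(x.reshape(b * t, -1)).reshape(b, t, self.cfg.d_model)
        if self.cfg.use_positional_encoding:
            x = x + self.pos
        for layer in self.layers:
            x = layer(x)
        return self.head(x[:, -1, :]).reshape(b)

    # -- inference helpers ---------------------------------------------------
    def predict_logits(self, frames: np.ndarray, norm: NormStats,
                       batch_size: int = 512) -> np.ndarray:
        """(B, T, 587) raw frame windows -> logits, eval mode, no graph."""
        if norm is None or not norm.fitted:
            raise RuntimeError("normalization statistics not fitted")
        was_training = self.training
        self.eval()
        out = []
        with nn.no_grad():
            for i in range(0, frames.shape[0], batch_size):
                wave, num = frames_to_model_inputs(frames[i:i + batch_size])
                wave_n, num_n = norm.transform(wave, num)
                out.append(self.forward(wave_n, num_n).data)
        if was_training:
            self.train()
        return np.concatenate(out) if out else np.zeros(0)

    def predict_proba(self, frames: np.ndarray, norm: NormStats,
                      batch_size: int = 512) -> np.ndarray:
        """Raw frame windows -> END probabilities in (0, 1)."""
        from scipy.special import expit
        return expit(self.predict_logits(frames, norm, batch_size))

    def forward_window(self, window_frames: np.ndarray, norm: NormStats) -> float:
        """One (T, 587) window -> probability (the model's unit prediction)."""
        return float(self.predict_proba(window_frames[None], norm)[0])

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))


# ---------------------------------------------------------------------------
# Checkpoint I/O
# ---------------------------------------------------------------------------


def config_to_json(cfg: ModelConfig) -> str:
    d = asdict(cfg)
    d["conv_channels"] = list(d["conv_channels"])
    d["mlp_dims"] = list(d["mlp_dims"])
    return json.dumps(d, sort_keys=True)


def config_from_json(s: str) -> ModelConfig:
    d = json.loads(s)
    d["conv_channels"] = tuple(d["conv_channels"])
    d["mlp_dims"] = tuple(d["mlp_dims"])
    return ModelConfig(**d)


def save_checkpoint(path, model: DSFNet, norm: NormStats, extra: dict | None = None):
    """Single-file checkpoint: weights + embedded config + normalisation stats."""
    meta = {"model_config": json.loads(config_to_json(model.cfg)),
            "norm": norm.to_dict() if norm is not None and norm.fitted else None,
            "extra": extra or {}}
    arrays = {k.replace(":", "__"): v for k, v in model.state_dict().items()}
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> tuple[DSFNet, NormStats, dict]:
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        state = {k.replace("__", ":", 1): z[k] for k in z.files if k != "__meta__"}
    cfg = config_from_json(json.dumps(meta["model_config"]))  # re-validates contract
    model = DSFNet(cfg)
    model.load_state_dict(state)
    norm = NormStats.from_dict(meta["norm"]) if meta["norm"] else NormStats()
    return model, norm, meta.get("extra", {})


def state_hash(obj) -> str:
    """Short stable hash of a JSON-serialisable object (config provenance)."""
    buf = io.StringIO()
    json.dump(obj, buf, sort_keys=True)
    return hashlib.sha256(buf.getvalue().encode()).hexdigest()[:16]
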