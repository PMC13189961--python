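"""Integrated-Gradients attribution over a monitoring window, projected onto
the raw waveforms and a vital-sign × time heatmap.

IG attributes the model's probability output F along the straight path from a
baseline x' to the input x:

    attr_j = (x_j − x'_j) · (1/m) Σ_{k=1..m} ∂F/∂x_j |_{x' + (k/m)(x − x')}

(a right-Riemann approximation of the path integral; the trapezoid rule is
available via ``rule="trapezoid"``).  The method satisfies Sensitivity (a
feature identical in x and x' gets attribution exactly 0) and completeness
(Σ attr → F(x) − F(x') as m grows); the residual completeness gap is recorded
in the result rather than hidden.

The baseline is the all-zeros input in normalised space — i.e. the
training-split mean in raw units, the conventional "nothing abnormal"
reference for clinical signals.  Attributions are computed in normalised
coordinates; because the z-score map is affine this only rescales per-channel
units, not the sign or relative weight within a channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .net import DSFNet, ECG_LEN, NormStats, NUMERIC_FEATURES, PLETH_LEN, \
    frames_to_model_inputs, pleth_upsample_weights

WAVE_CHANNELS = ("ecg", "resp", "pleth")


@dataclass
class AttributionResult:
    """Per-input IG attributions for one (T, 587) window.

    ``waveform_attr[c]`` has shape (T, 256) on the model's waveform axis
    (pleth on its upsampled 256-point grid); ``pleth_attr_60`` carries the
    mass-preserving back-mapping onto the original 60-sample axis.
    ``numeric_attr`` is feature × frame (14 × T), sign preserved: positive =
    risk-driving.
    """

    waveform_attr: dict                 # channel -> (T, 256)
    pleth_attr_60: np.ndarray           # (T, 60)
    numeric_attr: np.ndarray            # (14, T)
    baseline_spec: str
    steps: int
    completeness_gap: float
    delta_f: float                      # F(x) − F(baseline)
    f_x: float
    f_baseline: float

    @property
    def total_attribution(self) -> float:
        return float(sum(a.sum() for a in self.waveform_attr.values())
                     + self.numeric_attr.sum())

    @property
    def relative_completeness_gap(self) -> float:
        return self.completeness_gap / max(abs(self.delta_f), 1e-8)


def integrated_gradients(model, norm: NormStats, window_frames: np.ndarray,
                         baseline: np.ndarray | None = None, steps: int = 50,
                         rule: str = "riemann_right",
                         target: str = "probability") -> AttributionResult:
    """IG attributions for one raw (T, 587) window.

    ``baseline`` is an optional raw-space (T, 587) reference window; by
    default the normalised-zero (training-mean) baseline is used.  ``target``
    selects the attributed output: the post-sigmoid "probability" (default —
    the clinical risk reading) or the raw "logit" (exactly linear for a
    linear model, hence the oracle used to validate the path integral).
    """
    if rule not in ("riemann_right", "trapezoid"):
        raise ValueError(f"unknown integration rule {rule!r}")
    if target not in ("probability", "logit"):
        raise ValueError(f"unknown attribution target {target!r}")
    window_frames = np.asarray(window_frames)
    t_frames = window_frames.shape[0]
    wave, num = frames_to_model_inputs(window_frames)
    wave_n, num_n = norm.transform(wave, num)
    if baseline is None:
        wave_b = np.zeros_like(wave_n)
        num_b = np.zeros_like(num_n)
        baseline_spec = "normalized-zero (training-split mean in raw units)"
    else:
        baseline = np.asarray(baseline)
        if baseline.shape != window_frames.shape:
            raise ValueError(f"baseline shape {baseline.shape} does not match "
                             f"window {window_frames.shape}")
        wave_b, num_b = norm.transform(*frames_to_model_inputs(baseline))
        baseline_spec = "user-supplied raw window"
    dwave = wave_n - wave_b
    dnum = num_n - num_b

    if rule == "riemann_right":
        alphas = np.arange(1, steps + 1, dtype=np.float64) / steps
        weights = np.full(steps, 1.0 / steps)
    else:
        alphas = np.arange(0, steps + 1, dtype=np.float64) / steps
        weights = np.full(steps + 1, 1.0 / steps)
        weights[0] = weights[-1] = 0.5 / steps

    was_training = model.training
    model.eval()
    grad_wave = np.zeros_like(wave_n, dtype=np.float64)
    grad_num = np.zeros_like(num_n, dtype=np.float64)
    chunk = 32
    for i in range(0, len(alphas), chunk):
        a = alphas[i:i + chunk].astype(np.float32)[:, None, None, None]
        w_in = nn.Tensor(wave_b[None] + a * dwave[None], requires_grad=True)
        n_in = nn.Tensor(num_b[None] + a[..., 0] * dnum[None], requires_grad=True)
        out = model(w_in, n_in)
        if target == "probability":
            out = out.sigmoid()
        out.backward(weights[i:i + chunk])
        if not np.all(np.isfinite(w_in.grad)) or not np.all(np.isfinite(n_in.grad)):
            raise FloatingPointError("non-finite gradients in IG path integral")
        grad_wave += w_in.grad.sum(axis=0)
        grad_num += n_in.grad.sum(axis=0)
    with nn.no_grad():
        out_x = model(wave_n[None], num_n[None])
        out_b = model(wave_b[None], num_b[None])
        if target == "probability":
            out_x, out_b = out_x.sigmoid(), out_b.sigmoid()
        f_x = float(out_x.data[0])
        f_b = float(out_b.data[0])
    if was_training:
        model.train()

    attr_wave = dwave * grad_wave        # (T, 3, 256)
    attr_num = dnum * grad_num           # (T, 14)
    total = float(attr_wave.sum() + attr_num.sum())
    delta_f = f_x - f_b

    lo, hi, frac = pleth_upsample_weights()
    pleth_60 = np.zeros((t_frames, PLETH_LEN))
    np.add.at(pleth_60, (slice(None), lo), attr_wave[:, 2, :] * (1.0 - frac))
    np.add.at(pleth_60, (slice(None), hi), attr_wave[:, 2, :] * frac)

    return AttributionResult(
        waveform_attr={"ecg": attr_wave[:, 0, :], "resp": attr_wave[:, 1, :],
                       "pleth": attr_wave[:, 2, :]},
        pleth_attr_60=pleth_60,
        numeric_attr=attr_num.T,
        baseline_spec=baseline_spec,
        steps=steps,
        completeness_gap=abs(total - delta_f),
        delta_f=delta_f, f_x=f_x, f_baseline=f_b)


def project_waveform_attributions(attr: AttributionResult) -> dict:
    """Time-aligned saliency tracks, one per signal, at raw sample length.

    ECG and respiration tracks are length T×256; the pleth track is the
    mass-preserving 256→60 back-mapping, length T×60 (its total equals the
    upsampled-axis total exactly).
    """
    return {
        "ecg": attr.waveform_attr["ecg"].reshape(-1),
        "resp": attr.waveform_attr["resp"].reshape(-1),
        "pleth": attr.pleth_attr_60.reshape(-1),
    }


def vital_sign_heatmap(attr: AttributionResult):
    """(14, T) signed contribution matrix + a tidy rendering table.

    Positive entries are risk-driving (rendered orange in the usual scheme),
    negative entries suppressive/stabilising (green).
    """
    import pandas as pd
    matrix = attr.numeric_attr
    t = matrix.shape[1]
    table = pd.DataFrame(matrix, index=NUMERIC_FEATURES,
                         columns=[f"t-{t - 1 - i}" for i in range(t)])
    return matrix, table


def saliency_tables(attr: AttributionResult) -> dict:
    """CSV-ready per-signal saliency DataFrames (sample index, attribution)."""
    import pandas as pd
    tracks = project_waveform_attributions(attr)
    return {name: pd.DataFrame({"sample": np.arange(v.size), "attribution": v})
            for name, v in tracks.items()}
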