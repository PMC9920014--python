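"""Skin-artifact removal for monostatic channel data.

The early-time response of every channel is dominated by the skin reflection
(and any residual antenna/incident contribution), orders of magnitude above
the lymph-node echoes.  Two removal families are provided:

* ``average``: subtract the across-channel mean waveform from every channel.
  Exact when the artifact is identical in all channels (uniform skin), cheap,
  but brittle when the skin-antenna geometry varies across the array.
* ``adaptive``: per channel, estimate the artifact as an FIR-filtered
  combination of all *other* channels, with the taps fitted by regularised
  least squares over an early-time window where the artifact dominates, then
  subtract the filtered prediction over the whole record.  This tracks
  channel-to-channel artifact variation (e.g. a sinusoidally undulating skin)
  while leaving late target echoes — which are uncorrelated in time across
  channels — largely untouched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fdtd import ChannelData

__all__ = [
    "ArtifactConfig",
    "average_subtraction",
    "adaptive_filter_subtraction",
    "remove_artifact",
]


@dataclass(frozen=True)
class ArtifactConfig:
    """Artifact-removal method and adaptive-filter hyperparameters.

    ``taps_half`` is J: each neighbouring channel contributes 2J+1 FIR taps.
    ``fit_start``/``fit_length`` bound the early-time fit window in samples;
    ``fit_length=None`` defaults to 400 ps worth of samples (incident support
    of ~150 ps, doubled for the round trip through skin, plus 100 ps margin).
    ``ridge`` scales a trace-normalised Tikhonov term.
    """

    method: str = "adaptive"
    taps_half: int = 5
    fit_start: int = 0
    fit_length: int | None = None
    ridge: float = 1e-3

    def __post_init__(self) -> None:
        if self.method not in ("average", "adaptive"):
            raise ValueError(f"unknown artifact-removal method {self.method!r}")
        if self.taps_half < 0 or self.fit_start < 0 or self.ridge < 0:
            raise ValueError("taps_half, fit_start and ridge must be >= 0")


def average_subtraction(channels: ChannelData) -> ChannelData:
    """Subtract the across-channel mean waveform from every channel."""
    if channels.n_channels < 2:
        raise ValueError("average subtraction needs at least two channels")
    out = channels.copy()
    # mean via deviations from channel 0: algebraically identical, but exactly
    # zero residual when all channels are identical
    dev = channels.signals - channels.signals[:1]
    out.signals = dev - dev.mean(axis=0, keepdims=True)
    out.meta = {**channels.meta, "artifact": "average"}
    return out


def _lagged(x: np.ndarray, lag: int) -> np.ndarray:
    """x shifted so that result[t] = x[t + lag], zero-padded at the edges."""
    y = np.zeros_like(x)
    if lag == 0:
        y[:] = x
    elif lag > 0:
        y[:-lag] = x[lag:]
    else:
        y[-lag:] = x[:lag]
    return y


def adaptive_filter_subtraction(channels: ChannelData, cfg: ArtifactConfig | None = None) -> ChannelData:
    """Per-channel adaptive (Wiener-style) artifact estimation and removal.

    For channel m the taps ``w`` minimise ``||s_m - A w||^2 + lam ||w||^2``
    over the fit window, where the columns of ``A`` are the 2J+1 lags of each
    other channel; the fitted filter is then applied over the full record and
    subtracted.  The ridge term is ``lam = ridge * trace(A^T A)/n_taps`` so it
    is scale-free; with ``ridge = 0`` a minimum-norm least-squares solution is
    used (singular ensembles, e.g. identical channels, remain well defined).
    """
    if cfg is None:
        cfg = ArtifactConfig()
    M, T = channels.signals.shape
    if M < 2:
        raise ValueError("adaptive filtering needs at least two channels")
    J = cfg.taps_half
    n_fit = cfg.fit_length if cfg.fit_length is not None else int(round(400e-12 / channels.dt))
    n_fit = min(n_fit, T - cfg.fit_start)
    if n_fit <= 0:
        raise ValueError("fit window lies outside the record")
    w0, w1 = cfg.fit_start, cfg.fit_start + n_fit
    lags = range(-J, J + 1)

    out = channels.copy()
    sig = channels.signals
    for m in range(M):
        others = [c for c in range(M) if c != m]
        cols_full = [_lagged(sig[c], lag) for c in others for lag in lags]
        A_full = np.stack(cols_full, axis=1)  # (T, (M-1)(2J+1))
        A = A_full[w0:w1]
        y = sig[m, w0:w1]
        n_taps = A.shape[1]
        if cfg.ridge > 0:
            lam = cfg.ridge * np.trace(A.T @ A) / n_taps
            A_aug = np.vstack([A, np.sqrt(lam) * np.eye(n_taps)])
            y_aug = np.concatenate([y, np.zeros(n_taps)])
        else:
            A_aug, y_aug = A, y
        w, *_ = np.linalg.lstsq(A_aug, y_aug, rcond=None)
        out.signals[m] = sig[m] - A_full @ w
    out.meta = {**channels.meta, "artifact": "adaptive", "taps_half": J, "ridge": cfg.ridge}
    return out


def remove_artifact(channels: ChannelData, cfg: ArtifactConfig | str) -> ChannelData:
    """Dispatch on ``cfg.method`` (or a plain method name)."""
    if isinstance(cfg, str):
        cfg = ArtifactConfig(method=cfg)
    if cfg.method == "average":
        return average_subtraction(channels)
    return adaptive_filter_subtraction(channels, cfg)
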