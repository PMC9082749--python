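"""Time-frequency-electrode power images for the CNN branch.

Each 3 x 500 trial becomes a 90 x 90 image: rows are STFT time frames,
columns are [C3: 16 µ + 14 β | Cz: 16 µ + 14 β | C4: 16 µ + 14 β] power
bins.  The STFT uses Hann-windowed 50-sample frames hopped by 5 and
zero-padded to 500 points, giving 0.5 Hz bin spacing; the 91st (last)
complete frame is cropped so the image is square.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import get_window

__all__ = [
    "STFTConfig",
    "TFImage",
    "frame_count",
    "stft_power",
    "band_image",
    "assemble_image",
    "images_for_trialset",
]


@dataclass
class STFTConfig:
    window: int = 50  # samples per frame
    hop: int = 5  # samples between frame starts
    fft_len: int = 500  # zero-padded FFT length
    fs: float = 250.0
    mu_band: tuple[float, float] = (7.0, 14.5)  # inclusive, 0.5 Hz spacing
    mu_step: float = 0.5
    beta_band: tuple[float, float] = (17.0, 30.0)  # inclusive, 1 Hz spacing
    beta_step: float = 1.0
    n_frames: int = 90  # frames retained (trailing frames cropped)
    log_power: bool = True
    standardize: bool = True

    def __post_init__(self):
        if self.hop < 1:
            raise ValueError("hop must be >= 1")
        if self.window > self.fft_len:
            raise ValueError("window must not exceed fft_len")

    @property
    def freq_resolution(self) -> float:
        return self.fs / self.fft_len

    def _band_bins(self, band: tuple[float, float], step: float) -> np.ndarray:
        freqs = np.arange(band[0], band[1] + 1e-9, step)
        bins = freqs / self.freq_resolution
        idx = np.round(bins).astype(int)
        if not np.allclose(bins, idx):
            raise ValueError(f"band {band} at step {step} does not align with "
                             f"{self.freq_resolution} Hz bins")
        return idx

    @property
    def mu_bins(self) -> np.ndarray:
        return self._band_bins(self.mu_band, self.mu_step)  # 16 bins by default

    @property
    def beta_bins(self) -> np.ndarray:
        return self._band_bins(self.beta_band, self.beta_step)  # 14 bins by default

    @property
    def n_band_bins(self) -> int:
        return len(self.mu_bins) + len(self.beta_bins)


@dataclass
class TFImage:
    pixels: np.ndarray  # (n_frames, 3 * n_band_bins)
    label: int
    domain_id: int = 0

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("TFImage pixels must be finite")


def frame_count(n_samples: int, window: int, hop: int) -> int:
    """Number of complete windows: floor((n_samples - window)/hop) + 1."""
    if n_samples < window:
        raise ValueError(f"signal of {n_samples} samples shorter than window {window}")
    return (n_samples - window) // hop + 1


def stft_power(x: np.ndarray, cfg: STFTConfig | None = None) -> np.ndarray:
    """Power spectrogram of a 1-D signal: Hann-windowed frames, zero-padded
    FFT, squared magnitude.  Returns (n_complete_frames, fft_len//2 + 1)."""
    cfg = cfg or STFTConfig()
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("stft_power expects a 1-D signal")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in input signal")
    n = frame_count(len(x), cfg.window, cfg.hop)
    win = get_window("hann", cfg.window, fftbins=True)
    starts = np.arange(n) * cfg.hop
    frames = x[starts[:, None] + np.arange(cfg.window)] * win
    spec = np.fft.rfft(frames, n=cfg.fft_len, axis=1)
    return np.abs(spec) ** 2


def band_image(power: np.ndarray, cfg: STFTConfig | None = None) -> np.ndarray:
    """Select the µ (16 cols) and β (14 cols) bins and crop to the first
    ``cfg.n_frames`` frames -> per-electrode (90, 30) block.  Pure selection,
    no rescaling."""
    cfg = cfg or STFTConfig()
    mu, beta = cfg.mu_bins, cfg.beta_bins
    needed = max(mu.max(), beta.max())
    if power.shape[1] <= needed:
        raise ValueError(
            f"power matrix covers {power.shape[1]} bins; need > {needed} "
            f"({(needed) * cfg.freq_resolution} Hz at {cfg.freq_resolution} Hz spacing)"
        )
    if power.shape[0] < cfg.n_frames:
        raise ValueError(f"only {power.shape[0]} frames available, need {cfg.n_frames}")
    block = np.concatenate([power[:, mu], power[:, beta]], axis=1)
    return block[: cfg.n_frames]


def assemble_image(
    trial: np.ndarray, cfg: STFTConfig | None = None, label: int = -1, domain_id: int = 0
) -> TFImage:
    """Stack the three per-electrode blocks (C3 | Cz | C4) into one square
    image; optional log-power and per-image standardization."""
    cfg = cfg or STFTConfig()
    trial = np.asarray(trial, dtype=np.float64)
    if trial.ndim != 2 or trial.shape[0] != 3:
        raise ValueError(f"expected a (3, n_samples) trial, got {trial.shape}")
    blocks = [band_image(stft_power(trial[c], cfg), cfg) for c in range(3)]
    img = np.concatenate(blocks, axis=1)
    if cfg.log_power:
        img = np.log(img + 1e-10)
    if cfg.standardize:
        std = img.std()
        img = (img - img.mean()) / (std if std > 0 else 1.0)
    return TFImage(pixels=img, label=label, domain_id=domain_id)


def images_for_trialset(trialset, cfg: STFTConfig | None = None) -> np.ndarray:
    """Vectorized convenience: (n, 90, 90) image stack for a TrialSet."""
    cfg = cfg or STFTConfig()
    return np.stack(
        [
            assemble_image(trialset.trials[k], cfg, int(trialset.labels[k]),
                           int(trialset.domain_ids[k])).pixels
            for k in range(len(trialset))
        ]
    )
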