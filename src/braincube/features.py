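"""Audio feature banks, auxiliary voice descriptors, and modality sync.

Stereo speech is framed at a 10 ms hop (25 ms window) and reduced per
channel to one of four banks: 40-band log mel spectrogram (the default),
12-band mel-FFT, 12-band linear-FFT, or 12 MFCCs. Left-channel rows are
stacked before right-channel rows, so the default bank yields 80 rows.

Facial blendshape tracks (52 named [0,1] coefficients per 10 ms frame) are
read from CSV and duplicated bilaterally to 104 rows. ``synchronise`` stacks
audio over visual rows after truncating both to the common length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.fft
from scipy.fftpack import dct
from scipy.io import wavfile

from .core import BLENDSHAPE_NAMES, DT, FeatureSeries

LOG_FLOOR = 1e-10  # log compression: log(LOG_FLOOR + energy)

_TABLE_DEFAULTS = {
    # bank -> (n_bands, f_low, f_high)
    "mel_spectrogram": (40, 50.0, 8000.0),
    "mel_fft": (12, 50.0, 8000.0),
    "linear_fft": (12, 50.0, 8000.0),
    "mfcc": (12, 50.0, 8000.0),
}


@dataclass
class FeatureBankConfig:
    """Configuration of one audio feature bank.

    Unset fields default to the bank's standard row: 40 bands for the mel
    spectrogram, 12 otherwise, over 50–8000 Hz, 10 ms hop, 25 ms window.
    """

    bank: str = "mel_spectrogram"
    n_bands: int | None = None
    f_low: float = 50.0
    f_high: float = 8000.0
    hop: float = DT
    window: float = 0.025

    def __post_init__(self) -> None:
        if self.bank not in _TABLE_DEFAULTS:
            raise ValueError(f"unknown bank {self.bank!r}; choose from {sorted(_TABLE_DEFAULTS)}")
        if self.n_bands is None:
            self.n_bands = _TABLE_DEFAULTS[self.bank][0]
        if self.n_bands <= 0:
            raise ValueError("n_bands must be positive")
        if not 0 <= self.f_low < self.f_high:
            raise ValueError("need 0 <= f_low < f_high")


# ---------------------------------------------------------------------------
# mel scale and filterbanks
# ---------------------------------------------------------------------------

def hz_to_mel(f):
    """HTK mel scale: mel = 2595 log10(1 + f/700)."""
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)


def mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)


def mel_band_edges(n_bands: int, f_low: float, f_high: float) -> np.ndarray:
    """``n_bands + 2`` frequencies evenly spaced on the mel axis."""
    return mel_to_hz(np.linspace(hz_to_mel(f_low), hz_to_mel(f_high), n_bands + 2))


def _triangular_filterbank(edges: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """Triangular filters (rows) over FFT bin frequencies (columns)."""
    n_bands = len(edges) - 2
    fb = np.zeros((n_bands, len(freqs)))
    for b in range(n_bands):
        lo, mid, hi = edges[b], edges[b + 1], edges[b + 2]
        up = (freqs - lo) / max(mid - lo, 1e-12)
        down = (hi - freqs) / max(hi - mid, 1e-12)
        fb[b] = np.clip(np.minimum(up, down), 0.0, None)
    return fb


def _frame_signal(x: np.ndarray, sr: float, hop: float, window: float):
    hop_n = max(int(round(hop * sr)), 1)
    win_n = max(int(round(window * sr)), hop_n)
    if win_n > len(x):
        raise ValueError("window longer than signal")
    n_frames = 1 + (len(x) - win_n) // hop_n
    idx = np.arange(win_n)[None, :] + hop_n * np.arange(n_frames)[:, None]
    return x[idx] * np.hanning(win_n)[None, :], n_frames


def _power_spectrogram(x: np.ndarray, sr: float, hop: float, window: float):
    frames, _ = _frame_signal(x, sr, hop, window)
    spec = np.abs(scipy.fft.rfft(frames, axis=1)) ** 2
    freqs = scipy.fft.rfftfreq(frames.shape[1], d=1.0 / sr)
    return spec, freqs  # [frames x bins]


def _bank_matrix(cfg: FeatureBankConfig, freqs: np.ndarray) -> np.ndarray:
    if cfg.bank in ("mel_spectrogram", "mel_fft", "mfcc"):
        edges = mel_band_edges(cfg.n_bands, cfg.f_low, cfg.f_high)
    else:  # linear_fft: linearly spaced band edges
        edges = np.linspace(cfg.f_low, cfg.f_high, cfg.n_bands + 2)
    return _triangular_filterbank(edges, freqs)


def _channel_features(x: np.ndarray, sr: float, cfg: FeatureBankConfig) -> np.ndarray:
    spec, freqs = _power_spectrogram(x, sr, cfg.hop, cfg.window)
    if cfg.bank == "mfcc":
        # c1..c_n cepstra of a 26-filter log mel bank (standard speech front end)
        mel_cfg = FeatureBankConfig(bank="mel_spectrogram", n_bands=max(26, cfg.n_bands + 1),
                                    f_low=cfg.f_low, f_high=cfg.f_high,
                                    hop=cfg.hop, window=cfg.window)
        log_e = np.log(LOG_FLOOR + spec @ _bank_matrix(mel_cfg, freqs).T)
        cep = dct(log_e, type=2, axis=1, norm="ortho")
        return cep[:, 1 : cfg.n_bands + 1].T
    fb = _bank_matrix(cfg, freqs)
    log_e = np.log(LOG_FLOOR + spec @ fb.T)
    return log_e.T  # [bands x frames]


def extract_feature_bank(waveform: np.ndarray, sample_rate: float,
                         cfg: FeatureBankConfig | None = None) -> FeatureSeries:
    """Frame a stereo waveform and compute the configured band energies.

    ``waveform`` must have shape ``(2, n_samples)`` (or ``(n_samples, 2)``);
    left rows are stacked before right rows in the output.
    """
    cfg = cfg or FeatureBankConfig()
    w = np.asarray(waveform, dtype=float)
    if w.ndim != 2:
        raise ValueError(
            "stereo waveform required; for mono input duplicate the channel "
            "explicitly or pick one"
        )
    if w.shape[0] != 2 and w.shape[1] == 2:
        w = w.T
    if w.shape[0] != 2:
        raise ValueError(
            "stereo waveform required; for mono input duplicate the channel "
            "explicitly or pick one"
        )
    if sample_rate < 2 * cfg.f_high:
        raise ValueError("sample rate must be at least 2 * f_high")
    left = _channel_features(w[0], sample_rate, cfg)
    right = _channel_features(w[1], sample_rate, cfg)
    prefix = {"mfcc": "mfcc"}.get(cfg.bank, "band")
    labels = [f"{prefix}_{b}_L" for b in range(cfg.n_bands)] + [
        f"{prefix}_{b}_R" for b in range(cfg.n_bands)
    ]
    tags = ["L"] * cfg.n_bands + ["R"] * cfg.n_bands
    return FeatureSeries(np.vstack([left, right]), labels, "audio", tags, cfg.hop)


AUX_ROWS = ("rms_energy", "spectral_centroid", "spectral_flux", "low_freq_energy")
LOW_FREQ_CUTOFF = 345.0  # Hz: fundamental-frequency / lower-harmonic band


def auxiliary_descriptors(waveform: np.ndarray, sample_rate: float,
                          hop: float = DT, window: float = 0.025) -> FeatureSeries:
    """Per-frame prosodic descriptors of a stereo waveform (averaged L/R).

    Rows: RMS energy, spectral centroid (amplitude-weighted mean frequency),
    spectral flux (L2 change between consecutive magnitude spectra), and
    summed energy below 345 Hz.
    """
    w = np.asarray(waveform, dtype=float)
    if w.ndim != 2:
        raise ValueError("stereo waveform required")
    if w.shape[0] != 2 and w.shape[1] == 2:
        w = w.T
    mono = w.mean(axis=0)
    frames, _ = _frame_signal(mono, sample_rate, hop, window)
    rms = np.sqrt(np.mean(frames**2, axis=1))
    spec, freqs = _power_spectrogram(mono, sample_rate, hop, window)
    mag = np.sqrt(spec)
    denom = mag.sum(axis=1)
    centroid = np.where(denom > 0, (mag * freqs[None, :]).sum(axis=1) / np.maximum(denom, 1e-30), 0.0)
    flux = np.zeros(len(mag))
    flux[1:] = np.linalg.norm(np.diff(mag, axis=0), axis=1)
    low = spec[:, freqs < LOW_FREQ_CUTOFF].sum(axis=1)
    vals = np.vstack([rms, centroid, flux, low])
    return FeatureSeries(vals, list(AUX_ROWS), "audio", None, hop)


def read_wav(path) -> tuple[np.ndarray, float]:
    """Read a PCM WAV file; returns float waveform in [-1, 1], shape (ch, n)."""
    sr, data = wavfile.read(path)
    if data.dtype.kind == "i":
        data = data.astype(float) / np.iinfo(data.dtype).max
    elif data.dtype.kind == "u":
        info = np.iinfo(data.dtype)
        data = (data.astype(float) - info.max / 2) / (info.max / 2)
    else:
        data = data.astype(float)
    if data.ndim == 1:
        data = data[None, :]
    else:
        data = data.T
    return data, float(sr)


class MissingBlendshapeError(ValueError):
    """Raised when a blendshape CSV lacks recognised columns."""

    def __init__(self, missing: list[str]):
        self.missing = list(missing)
        super().__init__(f"missing blendshape columns: {', '.join(missing)}")


def load_blendshapes(path_or_df, dt: float = DT) -> FeatureSeries:
    """Read a 52-column blendshape CSV into a bilateral 104-row series.

    Columns are reordered to the canonical face-region order, values clipped
    to [0, 1], and each coefficient is duplicated into identical left and
    right copies (the mapping is bilateral).
    """
    df = path_or_df if isinstance(path_or_df, pd.DataFrame) else pd.read_csv(path_or_df)
    missing = [n for n in BLENDSHAPE_NAMES if n not in df.columns]
    if missing:
        raise MissingBlendshapeError(missing)
    vals = df[list(BLENDSHAPE_NAMES)].to_numpy(dtype=float).T
    vals = np.clip(vals, 0.0, 1.0)
    full = np.vstack([vals, vals])
    labels = [f"{n}_L" for n in BLENDSHAPE_NAMES] + [f"{n}_R" for n in BLENDSHAPE_NAMES]
    tags = ["L"] * 52 + ["R"] * 52
    return FeatureSeries(full, labels, "visual", tags, dt)


def synchronise(audio: FeatureSeries, visual: FeatureSeries) -> FeatureSeries:
    """Stack audio rows over visual rows on the common 10 ms grid.

    Both series are truncated to the shorter duration; labels and L/R tags
    are concatenated so the stacked rows keep their modality of origin.
    """
    if audio.n_timesteps == 0 or visual.n_timesteps == 0:
        raise ValueError("cannot synchronise an empty series")
    if not np.isclose(audio.dt, visual.dt):
        raise ValueError(f"mismatched dt: {audio.dt} vs {visual.dt}")
    T = min(audio.n_timesteps, visual.n_timesteps)
    values = np.vstack([audio.values[:, :T], visual.values[:, :T]])
    labels = list(audio.feature_labels) + list(visual.feature_labels)
    tags = None
    if audio.channel_tags is not None and visual.channel_tags is not None:
        tags = list(audio.channel_tags) + list(visual.channel_tags)
    return FeatureSeries(values, labels, "multimodal", tags, audio.dt)
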