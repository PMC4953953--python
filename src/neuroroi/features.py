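"""Spectral, time-domain and wavelet feature extraction for EEG-like signals.

Per input signal the extractor returns 45 named statistics:

* PSD (12): {max, mean, var} of the Welch power spectral density within
  the alpha, beta, gamma and delta bands.
* Hjorth (9): {max, mean, var} across windowed segments of the activity,
  mobility and complexity parameters.
* CWT (12): {max, mean, var} of the complex Morlet wavelet amplitude at
  centre frequencies 10 Hz (alpha), 20 Hz (beta), 50 Hz (gamma) and
  2 Hz (delta).
* DWT (12): {max, mean, var} of the absolute per-band detail
  reconstructions of a multilevel discrete wavelet decomposition.

A trial-by-feature matrix concatenates the 45-vectors of every signal
(channel or ROI time course) in a trial.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pywt
import scipy.signal

logger = logging.getLogger(__name__)

__all__ = [
    "SpectralBands", "WelchConfig", "WaveletConfig",
    "welch_psd", "psd_band_features", "hjorth_features", "cwt_features",
    "dwt_features", "extract_signal_features", "feature_names",
    "build_feature_matrix",
]

#: statistic order applied within every feature block
_STATS = ("max", "mean", "var")
#: band order of the feature table (alpha, beta, gamma, delta)
_BAND_ORDER = ("alpha", "beta", "gamma", "delta")


@dataclass(frozen=True)
class SpectralBands:
    """Clinical EEG band edges in Hz (half-open intervals [lo, hi))."""

    delta: tuple[float, float] = (0.5, 4.0)
    theta: tuple[float, float] = (4.0, 8.0)
    alpha: tuple[float, float] = (8.0, 13.0)
    beta: tuple[float, float] = (13.0, 30.0)
    gamma: tuple[float, float] = (30.0, 64.0)

    def edges(self, name: str, fs: float) -> tuple[float, float]:
        lo, hi = getattr(self, name)
        return lo, min(hi, fs / 2.0)


@dataclass(frozen=True)
class WelchConfig:
    """Segmentation for Welch PSD and the Hjorth statistics.

    The segment must cover at least one period of the lowest analysed
    frequency (4 Hz), so the default length is one second of samples
    with 50% overlap under a Hamming taper.
    """

    L: int
    overlap_frac: float = 0.5
    window: str = "hamming"

    def __post_init__(self):
        if self.L < 2:
            raise ValueError("segment length L must be >= 2")
        if not 0.0 <= self.overlap_frac < 1.0:
            raise ValueError("overlap_frac must lie in [0, 1)")

    @classmethod
    def for_fs(cls, fs: float, lowest_hz: float = 4.0) -> "WelchConfig":
        return cls(L=max(int(round(fs / lowest_hz)), int(round(fs))))


@dataclass(frozen=True)
class WaveletConfig:
    """Wavelet analysis settings.

    ``cwt_centers_hz`` maps bands to Morlet centre frequencies; centres
    at or above the Nyquist frequency are dropped with a warning.  The
    discrete transform uses ``dwt_levels`` levels of ``dwt_wavelet``;
    ``level_band_map`` assigns each detail level to a band (levels beyond
    the map, and the final approximation, aggregate into ``delta``).
    """

    cwt_centers_hz: dict = field(default_factory=lambda: {
        "alpha": 10.0, "beta": 20.0, "gamma": 50.0, "delta": 2.0})
    morlet_omega0: float = 6.0
    dwt_wavelet: str = "db4"
    dwt_levels: int = 5
    level_band_map: dict = field(default_factory=lambda: {
        1: "gamma", 2: "beta", 3: "alpha"})


def welch_psd(y: np.ndarray, cfg: WelchConfig, fs: float
              ) -> tuple[np.ndarray, np.ndarray]:
    """One-sided Welch power spectral density.

    Overlapping segments of length ``cfg.L`` are tapered, their squared
    DFT magnitudes averaged and normalized by the window energy and the
    one-sided density convention (units signal^2/Hz).  Returns
    ``(frequencies, psd)``.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1:
        raise ValueError("y must be one-dimensional")
    if cfg.L > y.size:
        raise ValueError(f"segment length {cfg.L} exceeds signal length {y.size}")
    noverlap = int(round(cfg.overlap_frac * cfg.L))
    f, s = scipy.signal.welch(
        y, fs=fs, window=cfg.window, nperseg=cfg.L, noverlap=noverlap,
        detrend=False, scaling="density", average="mean",
    )
    return f, s


def psd_band_features(s: np.ndarray, freqs: np.ndarray, fs: float,
                      bands: SpectralBands | None = None) -> np.ndarray:
    """{max, mean, var} of the PSD within each of alpha, beta, gamma, delta."""
    bands = bands or SpectralBands()
    s = np.asarray(s, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    out = []
    for name in _BAND_ORDER:
        lo, hi = bands.edges(name, fs)
        sel = (freqs >= lo) & (freqs < hi)
        if not np.any(sel):
            raise ValueError(f"band {name} [{lo}, {hi}) Hz contains no PSD bins")
        sb = s[sel]
        out.extend([sb.max(), sb.mean(), sb.var()])
    return np.asarray(out)


def _segments(y: np.ndarray, cfg: WelchConfig) -> tuple[np.ndarray, np.ndarray]:
    """Raw overlapping segments and the taper, Welch-style."""
    step = cfg.L - int(round(cfg.overlap_frac * cfg.L))
    starts = range(0, y.size - cfg.L + 1, step)
    win = scipy.signal.get_window(cfg.window, cfg.L)
    return np.asarray([y[s:s + cfg.L] for s in starts]), win


def hjorth_features(y: np.ndarray, cfg: WelchConfig, fs: float) -> np.ndarray:
    """Hjorth activity, mobility, complexity summarized across segments.

    Per windowed segment v (same segmentation as the Welch PSD):

        activity   = var(v)
        mobility   = sqrt(var(dv/dt) / var(v))      [rad/s]
        complexity = mobility(dv/dt) / mobility(v)  [dimensionless]

    with the derivative taken as the first difference times the sampling
    rate.  Constant segments are dropped with a warning; returns the
    {max, mean, var} of the three parameters across segments (9 values).
    """
    y = np.asarray(y, dtype=float)
    segs, win = _segments(y, cfg)
    if segs.size == 0:
        raise ValueError("signal shorter than one segment")
    act, mob, comp = [], [], []
    n_dropped = 0
    for raw in segs:
        # a constant raw segment carries no dynamics; tapering it would
        # fabricate the window's own shape, so drop it before windowing
        if raw.var() <= 0:
            n_dropped += 1
            continue
        v = raw * win
        var_v = v.var()
        dv = np.diff(v) * fs
        ddv = np.diff(dv) * fs
        var_dv = dv.var()
        m_v = np.sqrt(var_dv / var_v)
        m_dv = np.sqrt(ddv.var() / var_dv) if var_dv > 0 else np.nan
        act.append(var_v)
        mob.append(m_v)
        comp.append(m_dv / m_v if np.isfinite(m_dv) else np.nan)
    if n_dropped:
        logger.warning("hjorth: dropped %d constant segment(s)", n_dropped)
    if not act:
        raise ValueError("all segments are constant; Hjorth parameters undefined")
    out = []
    for series in (act, mob, comp):
        a = np.asarray(series, dtype=float)
        a = a[np.isfinite(a)]
        if a.size == 0:
            raise ValueError("degenerate segments: Hjorth parameters undefined")
        out.extend([a.max(), a.mean(), a.var()])
    return np.asarray(out)


def _morlet_name(omega0: float) -> str:
    # pywt 'cmorB-C': exp(-t^2/B) * exp(2j*pi*C*t); omega0 cycles parameter
    # maps to bandwidth B=2 and centre frequency C = omega0 / (2 pi)
    return f"cmor2.0-{omega0 / (2.0 * np.pi):.6f}"


def cwt_features(z: np.ndarray, cfg: WaveletConfig, fs: float) -> np.ndarray:
    """{max, mean, var} of Morlet CWT amplitude at the four band centres.

    Centre frequencies at or above Nyquist are dropped with a warning and
    their three statistics reported as zero, keeping the vector length
    fixed.
    """
    z = np.asarray(z, dtype=float)
    wav = _morlet_name(cfg.morlet_omega0)
    out = []
    for band in _BAND_ORDER:
        f0 = cfg.cwt_centers_hz[band]
        if f0 >= fs / 2.0:
            logger.warning(
                "cwt: centre %.1f Hz (%s band) at/above Nyquist %.1f Hz; dropped",
                f0, band, fs / 2.0)
            out.extend([0.0, 0.0, 0.0])
            continue
        scale = pywt.frequency2scale(wav, f0 / fs)
        coef, _ = pywt.cwt(z, [scale], wav, sampling_period=1.0 / fs)
        amp = np.abs(coef[0])
        out.extend([amp.max(), amp.mean(), amp.var()])
    return np.asarray(out)


def _dwt_band_details(z: np.ndarray, cfg: WaveletConfig) -> dict[str, np.ndarray]:
    """Per-band detail reconstructions of the multilevel DWT.

    Levels named in ``level_band_map`` reconstruct into their band;
    remaining detail levels and the final approximation sum into the
    ``delta`` band (the slowest content).
    """
    coeffs = pywt.wavedec(z, cfg.dwt_wavelet, level=cfg.dwt_levels)
    bands: dict[str, np.ndarray] = {b: np.zeros_like(z, dtype=float)
                                    for b in _BAND_ORDER}
    # coeffs = [A_L, D_L, ..., D_1]
    for lvl in range(1, cfg.dwt_levels + 1):
        sel = [np.zeros_like(c) for c in coeffs]
        sel[len(coeffs) - lvl] = coeffs[len(coeffs) - lvl]
        rec = pywt.waverec(sel, cfg.dwt_wavelet)[: z.size]
        bands[cfg.level_band_map.get(lvl, "delta")] += rec
    sel = [np.zeros_like(c) for c in coeffs]
    sel[0] = coeffs[0]
    bands["delta"] += pywt.waverec(sel, cfg.dwt_wavelet)[: z.size]
    return bands


def dwt_features(z: np.ndarray, cfg: WaveletConfig, fs: float) -> np.ndarray:
    """{max, mean, var} of |detail reconstruction| per band (12 values)."""
    z = np.asarray(z, dtype=float)
    if z.size < 2**cfg.dwt_levels:
        raise ValueError(
            f"signal of {z.size} samples too short for {cfg.dwt_levels} DWT levels")
    details = _dwt_band_details(z, cfg)
    out = []
    for band in _BAND_ORDER:
        a = np.abs(details[band])
        out.extend([a.max(), a.mean(), a.var()])
    return np.asarray(out)


def feature_names() -> list[str]:
    """The 45 feature names in extraction order."""
    names = [f"psd_{b}_{s}" for b in _BAND_ORDER for s in _STATS]
    names += [f"hjorth_{p}_{s}" for p in ("activity", "mobility", "complexity")
              for s in _STATS]
    names += [f"cwt_{b}_{s}" for b in _BAND_ORDER for s in _STATS]
    names += [f"dwt_{b}_{s}" for b in _BAND_ORDER for s in _STATS]
    return names


def extract_signal_features(
    y: np.ndarray,
    fs: float,
    welch_cfg: WelchConfig | None = None,
    wavelet_cfg: WaveletConfig | None = None,
    bands: SpectralBands | None = None,
) -> pd.Series:
    """The full 45-statistic feature vector of one signal.

    Blocks are concatenated as PSD(12) + Hjorth(9) + CWT(12) + DWT(12).
    A failure in any stage re-raises with the stage name prefixed.
    """
    welch_cfg = welch_cfg or WelchConfig.for_fs(fs)
    wavelet_cfg = wavelet_cfg or WaveletConfig()
    def _psd_block():
        freqs, s = welch_psd(y, welch_cfg, fs)
        return psd_band_features(s, freqs, fs, bands)

    parts = []
    stages = [
        ("psd", _psd_block),
        ("hjorth", lambda: hjorth_features(y, welch_cfg, fs)),
        ("cwt", lambda: cwt_features(y, wavelet_cfg, fs)),
        ("dwt", lambda: dwt_features(y, wavelet_cfg, fs)),
    ]
    for name, fn in stages:
        try:
            parts.append(fn())
        except Exception as exc:
            raise type(exc)(f"[{name} stage] {exc}") from exc
    vec = np.concatenate(parts)
    assert vec.size == 45
    return pd.Series(vec, index=feature_names())


def build_feature_matrix(
    trials: list[np.ndarray],
    fs: float,
    signal_ids: list[str] | None = None,
    welch_cfg: WelchConfig | None = None,
    wavelet_cfg: WaveletConfig | None = None,
    bands: SpectralBands | None = None,
) -> pd.DataFrame:
    """Trial x feature matrix over multichannel trials.

    Each trial is an (n_signals, T) array; row n of the result
    concatenates the 45-vectors of every signal, with columns named
    ``<signal_id>::<feature_name>``.
    """
    if not trials:
        raise ValueError("no trials given")
    n_sig = trials[0].shape[0]
    if any(tr.shape[0] != n_sig for tr in trials):
        raise ValueError("all trials must have the same signal count")
    ids = signal_ids or [f"s{i:02d}" for i in range(n_sig)]
    if len(ids) != n_sig:
        raise ValueError("signal_ids length mismatch")
    cols = [f"{sid}::{fn}" for sid in ids for fn in feature_names()]
    rows = []
    for tr in trials:
        rows.append(np.concatenate([
            extract_signal_features(tr[i], fs, welch_cfg, wavelet_cfg, bands).values
            for i in range(n_sig)
        ]))
    return pd.DataFrame(np.asarray(rows), columns=cols)
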