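"""Acoustic feature extraction.

Three feature sets feed the analysis:

* ``egemaps88`` — the 88 functionals of the extended Geneva Minimalistic
  Acoustic Parameter Set (eGeMAPS v02), computed here by an in-repo
  extractor built on numpy/scipy (STFT, autocorrelation F0, LPC formants,
  mel-filterbank cepstral coefficients). The contract is the standard name
  set and count plus physically correct responsiveness (jitter features rise
  with injected jitter, HNR falls with aspiration noise, the equivalent
  sound level follows channel gain, ...), not bit-level agreement with any
  particular reference extractor.
* ``cpp4`` — four summary statistics of the cepstral peak prominence track
  (mean, coefficient of variation, 20th and 80th percentile), matching the
  summarization style the eGeMAPS functionals use. CPP is the height of the
  cepstral peak at the quefrency of glottal periodicity above a regression
  line fit to the cepstrum; it drops with breathiness and dysphonia.
* ``duration1`` — audio duration alone, used as a probe for the duration
  recording bias.

Every feature carries a category (vocal folds / intensity / vocal tract /
spectral balance / prosody) shipped as a CSV resource.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.fft import irfft, rfft
from scipy.linalg import solve_toeplitz

# ---------------------------------------------------------------------------
# Analysis configuration
# ---------------------------------------------------------------------------

FRAME_LEN_S = 0.032          # LLD frame length
HOP_S = 0.010                # LLD hop
F0_SEARCH_HZ = (55.0, 450.0)
VOICING_PEAK_MIN = 0.45      # normalized autocorrelation peak for voicing
F0_LOWPASS_HZ = 900.0        # pre-filter for pitch/HNR autocorrelation

CPP_FRAME_S = 0.040
CPP_HOP_S = 0.010
CPP_F0_BAND = (60.0, 330.0)
CPP_REGRESSION_START_S = 0.001

FEATURE_SETS = ("egemaps88", "cpp4", "duration1", "clinician6", "clinician2")
TASK_FILTERS = ("reading", "vowel", "reading+vowel")

_EPS = 1e-12


def _functional_block(base: str) -> list[str]:
    return [f"{base}_amean", f"{base}_stddevNorm"]


def _contour_block(base: str) -> list[str]:
    return [f"{base}_amean", f"{base}_stddevNorm",
            f"{base}_percentile20.0", f"{base}_percentile50.0",
            f"{base}_percentile80.0", f"{base}_pctlrange0-2",
            f"{base}_meanRisingSlope", f"{base}_stddevRisingSlope",
            f"{base}_meanFallingSlope", f"{base}_stddevFallingSlope"]


EGEMAPS_NAMES: tuple[str, ...] = tuple(
    _contour_block("F0semitoneFrom27.5Hz_sma3nz")
    + _functional_block("jitterLocal_sma3nz")
    + _functional_block("shimmerLocaldB_sma3nz")
    + _contour_block("loudness_sma3")
    + _functional_block("HNRdBACF_sma3nz")
    + _functional_block("alphaRatioV_sma3nz")
    + _functional_block("hammarbergIndexV_sma3nz")
    + _functional_block("slopeV0-500_sma3nz")
    + _functional_block("slopeV500-1500_sma3nz")
    + _functional_block("spectralFlux_sma3")
    + _functional_block("spectralFluxV_sma3nz")
    + [n for k in range(1, 5) for n in _functional_block(f"mfcc{k}_sma3")]
    + [n for k in range(1, 5) for n in _functional_block(f"mfcc{k}V_sma3nz")]
    + _functional_block("logRelF0-H1-H2_sma3nz")
    + _functional_block("logRelF0-H1-A3_sma3nz")
    + [n for k in (1, 2, 3) for n in
       _functional_block(f"F{k}frequency_sma3nz")
       + _functional_block(f"F{k}bandwidth_sma3nz")
       + _functional_block(f"F{k}amplitudeLogRelF0_sma3nz")]
    + ["alphaRatioUV_sma3nz_amean", "hammarbergIndexUV_sma3nz_amean",
       "slopeUV0-500_sma3nz_amean", "slopeUV500-1500_sma3nz_amean",
       "spectralFluxUV_sma3nz_amean",
       "loudnessPeaksPerSec",
       "VoicedSegmentsPerSec", "MeanVoicedSegmentLengthSec",
       "StddevVoicedSegmentLengthSec", "MeanUnvoicedSegmentLength",
       "StddevUnvoicedSegmentLength",
       "equivalentSoundLevel_dBp"]
)
assert len(EGEMAPS_NAMES) == 88

CATEGORIES = ("vocal folds", "intensity", "vocal tract",
              "spectral balance", "prosody")


def load_category_map() -> dict[str, str]:
    """Feature name -> category, from the shipped CSV resource."""
    with resources.files("voiceaudit").joinpath(
            "data/feature_categories.csv").open() as fh:
        df = pd.read_csv(fh)
    mapping = dict(zip(df["feature"], df["category"]))
    missing = set(EGEMAPS_NAMES) - set(mapping)
    if missing:
        raise RuntimeError(f"category map incomplete: {sorted(missing)[:3]}...")
    return mapping


def intensity_features(category_map: dict[str, str] | None = None) -> list[str]:
    cmap = category_map or load_category_map()
    return [n for n in EGEMAPS_NAMES if cmap[n] == "intensity"]


# ---------------------------------------------------------------------------
# Low-level descriptor extraction
# ---------------------------------------------------------------------------

def _frame(x: np.ndarray, flen: int, hop: int) -> np.ndarray:
    if len(x) < flen:
        return np.empty((0, flen))
    return np.lib.stride_tricks.sliding_window_view(x, flen)[::hop].copy()


def _autocorr(frames: np.ndarray, nfft: int) -> np.ndarray:
    spec = rfft(frames, n=nfft, axis=1)
    ac = irfft(np.abs(spec) ** 2, n=nfft, axis=1)
    return ac


def _lin_slope(freqs: np.ndarray, db: np.ndarray) -> np.ndarray:
    """Per-row least-squares slope of db vs freqs (dB/Hz)."""
    f = freqs - freqs.mean()
    denom = float((f**2).sum())
    return (db - db.mean(axis=1, keepdims=True)) @ f / denom


def _mel_filterbank(n_filters: int, nfft: int, sr: int,
                    fmin: float = 20.0, fmax: float = 8000.0) -> np.ndarray:
    def hz2mel(h):
        return 2595.0 * np.log10(1.0 + np.asarray(h) / 700.0)

    def mel2hz(m):
        return 700.0 * (10.0 ** (np.asarray(m) / 2595.0) - 1.0)

    pts = mel2hz(np.linspace(hz2mel(fmin), hz2mel(fmax), n_filters + 2))
    bins = np.floor((nfft + 1) * pts / sr).astype(int)
    fb = np.zeros((n_filters, nfft // 2 + 1))
    for i in range(n_filters):
        a, b, c = bins[i], bins[i + 1], bins[i + 2]
        if b > a:
            fb[i, a:b] = (np.arange(a, b) - a) / (b - a)
        if c > b:
            fb[i, b:c] = (c - np.arange(b, c)) / (c - b)
    return fb


def _dct_ortho(n_out: int, n_in: int) -> np.ndarray:
    k = np.arange(n_out)[:, None]
    n = np.arange(n_in)[None, :]
    mat = np.cos(np.pi * k * (2 * n + 1) / (2 * n_in)) * np.sqrt(2.0 / n_in)
    mat[0] /= np.sqrt(2.0)
    return mat


def _cycle_marks(w: np.ndarray, sr: int, f0_med: float,
                 voiced_mask_t: np.ndarray, times: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Glottal cycle times and per-cycle amplitudes via fundamental-band
    peak picking. Returns (cycle peak sample indices, peak amplitudes)."""
    lo = max(0.6 * f0_med, 40.0)
    hi = min(1.5 * f0_med, sr / 2 - 100.0)
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=sr, output="sos")
    band = sps.sosfiltfilt(sos, w)
    dist = max(int(0.6 * sr / f0_med), 2)
    height = 0.15 * np.percentile(np.abs(band), 95)
    peaks, _ = sps.find_peaks(band, distance=dist, height=height)
    if len(peaks) == 0:
        return np.array([], dtype=int), np.array([])
    # keep peaks inside voiced frames
    if len(times):
        vt = np.interp(peaks / sr, times, voiced_mask_t.astype(float),
                       left=0.0, right=0.0)
        peaks = peaks[vt > 0.5]
    # cycle amplitude from the fundamental-band envelope: the narrow band
    # rejects most aspiration noise, so shimmer reads amplitude perturbation
    # rather than the noise floor
    amps = np.abs(band[peaks])
    return peaks, amps


def _perturbation_series(peaks: np.ndarray, amps: np.ndarray, sr: int,
                         f0_med: float) -> tuple[np.ndarray, np.ndarray]:
    """Relative period perturbation (jitter, fraction) and absolute dB
    amplitude perturbation (shimmer) series over valid consecutive cycles."""
    if len(peaks) < 3:
        return np.array([]), np.array([])
    periods = np.diff(peaks) / sr
    t0 = 1.0 / f0_med
    ok = (periods > 0.6 * t0) & (periods < 1.6 * t0)
    jit, shim = [], []
    mean_t = np.mean(periods[ok]) if ok.any() else t0
    for i in range(len(periods) - 1):
        if ok[i] and ok[i + 1]:
            jit.append(abs(periods[i + 1] - periods[i]) / mean_t)
            a0, a1 = amps[i + 1], amps[i + 2]
            if a0 > 0 and a1 > 0:
                shim.append(abs(20.0 * np.log10(a1 / a0)))
    return np.asarray(jit), np.asarray(shim)


def extract_lld(waveform: np.ndarray, sample_rate: int) -> dict:
    """Frame-level low-level descriptors for one recording."""
    w = np.asarray(waveform, dtype=float)
    sr = sample_rate
    flen = int(round(FRAME_LEN_S * sr))
    hop = int(round(HOP_S * sr))
    nfft = int(2 ** np.ceil(np.log2(2 * flen)))
    frames = _frame(w, flen, hop)
    n = len(frames)
    times = (np.arange(n) * hop + flen / 2) / sr
    win = np.hamming(flen)

    # --- pitch & HNR on low-passed signal -------------------------------
    sos_lp = sps.butter(4, F0_LOWPASS_HZ, btype="low", fs=sr, output="sos")
    frames_lp = _frame(sps.sosfilt(sos_lp, w), flen, hop) * win
    ac = _autocorr(frames_lp, nfft)
    ac0 = np.maximum(ac[:, 0], _EPS)
    # undo the taper bias of the analysis window (Praat-style correction)
    ac_win = _autocorr(win[None, :], nfft)[0]
    win_norm = np.maximum(ac_win / ac_win[0], 1e-3)
    lmin = int(np.floor(sr / F0_SEARCH_HZ[1]))
    lmax = min(int(np.ceil(sr / F0_SEARCH_HZ[0])), flen - 1)
    band = ac[:, lmin:lmax + 1] / ac0[:, None] / win_norm[None, lmin:lmax + 1]
    band = np.clip(band, -1.0, 1.0)
    peak_idx = np.argmax(band, axis=1)
    # octave-error guard: prefer the shortest lag whose local peak is within
    # 10% of the global maximum (subharmonics score equally on periodic input)
    vmax = band[np.arange(n), peak_idx]
    interior = band[:, 1:-1]
    is_peak = (interior >= band[:, :-2]) & (interior >= band[:, 2:]) \
        & (interior >= 0.9 * vmax[:, None])
    has_early = is_peak.any(axis=1)
    first_peak = np.argmax(is_peak, axis=1) + 1
    peak_idx = np.where(has_early & (first_peak < peak_idx),
                        first_peak, peak_idx)
    r_peak = band[np.arange(n), peak_idx]
    lag = (lmin + peak_idx).astype(float)
    # parabolic refinement
    for i in range(n):
        li = int(lag[i])
        if lmin < li < lmax:
            y0, y1, y2 = ac[i, li - 1], ac[i, li], ac[i, li + 1]
            d = y0 - 2 * y1 + y2
            if abs(d) > _EPS:
                lag[i] += 0.5 * (y0 - y2) / d
    f0_hz = sr / np.maximum(lag, 1.0)

    rms = np.sqrt(np.mean((frames * win) ** 2, axis=1) + _EPS)
    energy_floor = 0.10 * (np.percentile(rms, 90) if n else 0.0)
    voiced = (r_peak > VOICING_PEAK_MIN) & (rms > max(energy_floor, 1e-6)) \
        & (f0_hz >= F0_SEARCH_HZ[0]) & (f0_hz <= F0_SEARCH_HZ[1])

    # --- spectra --------------------------------------------------------
    spec = rfft(frames * win, n=nfft, axis=1)
    mag = np.abs(spec)
    power = mag**2
    freqs = np.arange(nfft // 2 + 1) * sr / nfft

    # harmonics-to-noise ratio from the spectral comb: power at multiples of
    # f0 vs power midway between them (f0-normalized, so the estimate tracks
    # aspiration noise rather than pitch). A dedicated 64 ms window keeps
    # the mainlobe narrower than half the harmonic spacing down to ~80 Hz.
    flen_h = 1024
    nfft_h = 2048
    w_pad = np.pad(w, (flen_h // 2, flen_h // 2))
    starts = np.arange(n) * hop + flen // 2
    frames_h = np.lib.stride_tricks.sliding_window_view(
        w_pad, flen_h)[starts]
    power_h = np.abs(rfft(frames_h * np.hanning(flen_h), n=nfft_h,
                          axis=1)) ** 2
    df_h = sr / nfft_h
    k = np.arange(1, 17)
    harm_f = f0_hz[:, None] * k[None, :]
    inter_f = f0_hz[:, None] * (k[None, :] + 0.5)
    valid = harm_f < 4000.0
    rows = np.arange(n)[:, None]

    def comb_power(freq_grid):
        pos = np.clip(freq_grid / df_h, 1, nfft_h // 2 - 2)
        i0 = pos.astype(int)
        return np.maximum.reduce([power_h[rows, i0 - 1], power_h[rows, i0],
                                  power_h[rows, i0 + 1],
                                  power_h[rows, i0 + 2]])

    p_harm = np.where(valid, comb_power(harm_f), 0.0).sum(axis=1)
    p_inter = np.where(valid, comb_power(inter_f), 0.0).sum(axis=1)
    hnr_db = 10.0 * np.log10((p_harm + _EPS) / (p_inter + _EPS))

    def band_sum(lo, hi):
        sel = (freqs >= lo) & (freqs < hi)
        return power[:, sel].sum(axis=1) + _EPS

    alpha = 10.0 * np.log10(band_sum(50, 1000) / band_sum(1000, 5000))
    sel_lo = (freqs >= 0) & (freqs < 2000)
    sel_hi = (freqs >= 2000) & (freqs < 5000)
    hammarberg = 10.0 * np.log10(
        (power[:, sel_lo].max(axis=1) + _EPS)
        / (power[:, sel_hi].max(axis=1) + _EPS))
    db_spec = 10.0 * np.log10(power + _EPS)
    sel_s1 = (freqs >= 0) & (freqs <= 500)
    sel_s2 = (freqs > 500) & (freqs <= 1500)
    slope1 = _lin_slope(freqs[sel_s1], db_spec[:, sel_s1])
    slope2 = _lin_slope(freqs[sel_s2], db_spec[:, sel_s2])
    flux = np.zeros(n)
    if n > 1:
        d = np.diff(mag, axis=0)
        flux[1:] = (d**2).sum(axis=1) / (nfft // 2 + 1)

    fb = _mel_filterbank(26, nfft, sr)
    mel = np.log(power @ fb.T + _EPS)
    mfcc = mel @ _dct_ortho(5, 26).T   # coefficients 0..4; keep 1..4
    mfcc = mfcc[:, 1:5]

    # --- harmonic structure (voiced frames) -----------------------------
    def mag_at(freq_hz: np.ndarray) -> np.ndarray:
        pos = np.clip(freq_hz / (sr / nfft), 0, nfft // 2 - 1)
        i0 = pos.astype(int)
        frac = pos - i0
        rows = np.arange(n)
        return mag[rows, i0] * (1 - frac) + mag[rows, i0 + 1] * frac

    h1 = mag_at(f0_hz) + _EPS
    h2 = mag_at(2 * f0_hz) + _EPS
    h1h2 = 20.0 * np.log10(h1 / h2)

    # --- formants via LPC on pre-emphasized voiced frames ---------------
    order = 12
    f_freq = np.zeros((n, 3))
    f_bw = np.zeros((n, 3))
    f_amp_rel = np.zeros((n, 3))
    vidx = np.where(voiced)[0]
    if len(vidx):
        pre = frames[vidx] - 0.97 * np.concatenate(
            [frames[vidx, :1], frames[vidx, :-1]], axis=1)
        pre = pre * win
        ac_pe = _autocorr(pre, nfft)[:, :order + 1]
        ac_pe[:, 0] += 1e-9 * ac_pe[:, 0].max() + _EPS
        comp = np.zeros((len(vidx), order, order))
        ok_rows = []
        for j, row in enumerate(ac_pe):
            try:
                a = solve_toeplitz((row[:-1], row[:-1]), row[1:])
            except np.linalg.LinAlgError:
                continue
            comp[j, 0, :] = a
            comp[j, 1:, :-1] = np.eye(order - 1)
            ok_rows.append(j)
        if ok_rows:
            roots = np.linalg.eigvals(comp[ok_rows])
            ang = np.angle(roots)
            rad = np.abs(roots)
            cand_f = ang * sr / (2 * np.pi)
            cand_bw = -sr / np.pi * np.log(np.maximum(rad, 1e-9))
            for j_local, j in enumerate(ok_rows):
                i = vidx[j]
                sel = (cand_f[j_local] > 150) & (cand_f[j_local] < 5500) \
                    & (cand_bw[j_local] > 0) & (cand_bw[j_local] < 700)
                fs_sorted = np.sort(cand_f[j_local][sel])
                bws = cand_bw[j_local][sel][np.argsort(cand_f[j_local][sel])]
                for k in range(min(3, len(fs_sorted))):
                    f_freq[i, k] = fs_sorted[k]
                    f_bw[i, k] = bws[k]
        row_amp = mag[vidx]
        for k in range(3):
            fk = f_freq[vidx, k]
            pos = np.clip(fk / (sr / nfft), 0, nfft // 2 - 1).astype(int)
            a = row_amp[np.arange(len(vidx)), pos] + _EPS
            f_amp_rel[vidx, k] = 20.0 * np.log10(a / h1[vidx])

    # A3: strongest harmonic near F3 (fallback band 2500-3500 Hz)
    a3 = np.zeros(n)
    sel_a3 = (freqs >= 2500) & (freqs <= 3500)
    a3_default = mag[:, sel_a3].max(axis=1) + _EPS
    a3[:] = a3_default
    has_f3 = f_freq[:, 2] > 0
    if has_f3.any():
        centers = f_freq[has_f3, 2]
        local = np.array([
            mag[i, (freqs >= c - 300) & (freqs <= c + 300)].max()
            if ((freqs >= c - 300) & (freqs <= c + 300)).any() else a3[i]
            for i, c in zip(np.where(has_f3)[0], centers)])
        a3[has_f3] = local + _EPS
    h1a3 = 20.0 * np.log10(h1 / a3)

    # --- cycle-level jitter & shimmer -----------------------------------
    if voiced.any():
        f0_med = float(np.median(f0_hz[voiced]))
        peaks, amps = _cycle_marks(w, sr, f0_med, voiced, times)
        jit_series, shim_series = _perturbation_series(peaks, amps, sr, f0_med)
    else:
        jit_series, shim_series = np.array([]), np.array([])

    loudness = rms**0.6   # Stevens-law proxy for perceived loudness

    return {
        "times": times, "voiced": voiced, "f0_hz": f0_hz, "rms": rms,
        "loudness": loudness, "hnr_db": hnr_db, "alpha": alpha,
        "hammarberg": hammarberg, "slope1": slope1, "slope2": slope2,
        "flux": flux, "mfcc": mfcc, "h1h2": h1h2, "h1a3": h1a3,
        "f_freq": f_freq, "f_bw": f_bw, "f_amp_rel": f_amp_rel,
        "jitter_series": jit_series, "shimmer_series": shim_series,
        "duration": len(w) / sr, "hop_s": hop / sr,
        "eq_level_db": 10.0 * np.log10(float(np.mean(w**2)) + _EPS),
    }


# ---------------------------------------------------------------------------
# Functionals
# ---------------------------------------------------------------------------

def _amean(x: np.ndarray) -> float:
    return float(np.mean(x)) if len(x) else 0.0


def _stddev_norm(x: np.ndarray) -> float:
    if len(x) < 2:
        return 0.0
    m = np.mean(x)
    if abs(m) < _EPS:
        return 0.0
    return float(np.std(x) / abs(m))


def _run_slopes(t: np.ndarray, x: np.ndarray, rising: bool) -> np.ndarray:
    """Slopes of maximal strictly rising (or falling) runs of the contour."""
    if len(x) < 2:
        return np.array([])
    d = np.diff(x)
    active = d > 0 if rising else d < 0
    slopes = []
    i = 0
    while i < len(d):
        if active[i]:
            j = i
            while j < len(d) and active[j]:
                j += 1
            dt = t[j] - t[i]
            if dt > 0:
                slopes.append((x[j] - x[i]) / dt)
            i = j
        else:
            i += 1
    return np.asarray(slopes)


def _contour_functionals(t: np.ndarray, x: np.ndarray) -> list[float]:
    if len(x) == 0:
        return [0.0] * 10
    p20, p50, p80 = np.percentile(x, [20, 50, 80])
    rise = _run_slopes(t, x, rising=True)
    fall = _run_slopes(t, x, rising=False)
    return [_amean(x), _stddev_norm(x), float(p20), float(p50), float(p80),
            float(p80 - p20), _amean(rise),
            float(np.std(rise)) if len(rise) > 1 else 0.0,
            _amean(fall), float(np.std(fall)) if len(fall) > 1 else 0.0]


def _segments(mask: np.ndarray) -> list[int]:
    """Lengths (in frames) of runs of True."""
    runs, count = [], 0
    for v in mask:
        if v:
            count += 1
        elif count:
            runs.append(count)
            count = 0
    if count:
        runs.append(count)
    return runs


def extract_egemaps(recording, sample_rate: int | None = None) -> pd.Series:
    """The 88-functional feature vector for one recording.

    Accepts either a :class:`voiceaudit.synth.Recording` or a raw waveform
    plus ``sample_rate``. Raises on silent input or input shorter than 0.5 s.
    """
    if hasattr(recording, "waveform"):
        w, sr = np.asarray(recording.waveform, float), recording.sample_rate
    else:
        if sample_rate is None:
            raise ValueError("sample_rate required for raw waveform input")
        w, sr = np.asarray(recording, float), sample_rate
    if len(w) / sr < 0.5:
        raise ValueError("recording shorter than 0.5 s")
    if not np.any(w != 0):
        raise ValueError("silent (all-zero) recording is unusable")

    lld = extract_lld(w, sr)
    t, v = lld["times"], lld["voiced"]
    uv = ~v
    dur = lld["duration"]
    out: list[float] = []

    # vocal folds ---------------------------------------------------------
    f0_semi = 12.0 * np.log2(np.maximum(lld["f0_hz"][v], 1.0) / 27.5)
    out += _contour_functionals(t[v], f0_semi)
    jit = 100.0 * lld["jitter_series"]
    out += [_amean(jit), _stddev_norm(jit)]
    shim = lld["shimmer_series"]
    out += [_amean(shim), _stddev_norm(shim)]

    # loudness contour (all frames) --------------------------------------
    out += _contour_functionals(t, lld["loudness"])

    # HNR (voiced) --------------------------------------------------------
    out += [_amean(lld["hnr_db"][v]), _stddev_norm(lld["hnr_db"][v])]

    # spectral balance, voiced --------------------------------------------
    for key in ("alpha", "hammarberg", "slope1", "slope2"):
        out += [_amean(lld[key][v]), _stddev_norm(lld[key][v])]
    out += [_amean(lld["flux"]), _stddev_norm(lld["flux"])]
    out += [_amean(lld["flux"][v]), _stddev_norm(lld["flux"][v])]

    # MFCC 1-4, all frames then voiced ------------------------------------
    for k in range(4):
        out += [_amean(lld["mfcc"][:, k]), _stddev_norm(lld["mfcc"][:, k])]
    for k in range(4):
        out += [_amean(lld["mfcc"][v, k]), _stddev_norm(lld["mfcc"][v, k])]

    # harmonic differences -------------------------------------------------
    out += [_amean(lld["h1h2"][v]), _stddev_norm(lld["h1h2"][v])]
    out += [_amean(lld["h1a3"][v]), _stddev_norm(lld["h1a3"][v])]

    # formants -------------------------------------------------------------
    for k in range(3):
        have = v & (lld["f_freq"][:, k] > 0)
        out += [_amean(lld["f_freq"][have, k]),
                _stddev_norm(lld["f_freq"][have, k])]
        out += [_amean(lld["f_bw"][have, k]),
                _stddev_norm(lld["f_bw"][have, k])]
        out += [_amean(lld["f_amp_rel"][have, k]),
                _stddev_norm(lld["f_amp_rel"][have, k])]

    # unvoiced spectral balance -------------------------------------------
    out += [_amean(lld["alpha"][uv]), _amean(lld["hammarberg"][uv]),
            _amean(lld["slope1"][uv]), _amean(lld["slope2"][uv]),
            _amean(lld["flux"][uv])]

    # prosody ---------------------------------------------------------------
    loud = lld["loudness"]
    if len(loud) > 2:
        pk, _ = sps.find_peaks(loud, prominence=0.25 * (np.max(loud) + _EPS))
        out.append(len(pk) / dur)
    else:
        out.append(0.0)
    vruns = _segments(v)
    uruns = _segments(uv)
    hop_s = lld["hop_s"]
    out += [len(vruns) / dur,
            _amean(np.asarray(vruns) * hop_s),
            float(np.std(np.asarray(vruns) * hop_s)) if len(vruns) > 1 else 0.0,
            _amean(np.asarray(uruns) * hop_s),
            float(np.std(np.asarray(uruns) * hop_s)) if len(uruns) > 1 else 0.0]

    # intensity ------------------------------------------------------------
    out.append(lld["eq_level_db"])

    vec = pd.Series(out, index=list(EGEMAPS_NAMES), dtype=float)
    return vec.replace([np.inf, -np.inf], np.nan)


# ---------------------------------------------------------------------------
# Cepstral peak prominence
# ---------------------------------------------------------------------------

@dataclass
class CPPTrack:
    frame_times: np.ndarray
    cpp_db: np.ndarray
    peak_quefrency: np.ndarray


@dataclass(frozen=True)
class CPPSummary:
    cpp_mean: float
    cpp_cov: float
    cpp_p20: float
    cpp_p80: float

    def as_series(self) -> pd.Series:
        return pd.Series({"cpp_mean": self.cpp_mean, "cpp_cov": self.cpp_cov,
                          "cpp_p20": self.cpp_p20, "cpp_p80": self.cpp_p80})


def compute_cpp_track(waveform: np.ndarray, sample_rate: int,
                      frame_len: float = CPP_FRAME_S, hop: float = CPP_HOP_S,
                      f0_band: tuple[float, float] = CPP_F0_BAND,
                      regression_band: tuple[float, float | None] =
                      (CPP_REGRESSION_START_S, None)) -> CPPTrack:
    """Per-frame cepstral peak prominence.

    Per frame: Hamming window, FFT zero-padded to the next power of two at
    least twice the window, real cepstrum as the inverse transform of the
    20*log10 magnitude spectrum, peak located in the quefrency band
    [1/f0_max, 1/f0_min], and a least-squares line fit to the cepstrum over
    ``regression_band``; CPP (dB) is the peak height above that line.
    """
    if f0_band[0] >= f0_band[1]:
        raise ValueError("f0_band must be (low, high) with low < high")
    if f0_band[1] >= sample_rate / 2:
        raise ValueError("f0_band exceeds Nyquist")
    if frame_len < 2.0 / f0_band[0]:
        raise ValueError("frame_len must cover >= 2 periods of the lowest f0")
    w = np.asarray(waveform, dtype=float)
    sr = sample_rate
    flen = int(round(frame_len * sr))
    hop_n = int(round(hop * sr))
    frames = _frame(w, flen, hop_n)
    if len(frames) == 0:
        raise ValueError("waveform shorter than one CPP frame")
    nfft = int(2 ** np.ceil(np.log2(2 * flen)))
    spec = rfft(frames * np.hamming(flen), n=nfft, axis=1)
    log_mag = 20.0 * np.log10(np.abs(spec) + _EPS)
    cep = irfft(log_mag, n=nfft, axis=1)[:, : nfft // 2]
    quef = np.arange(nfft // 2) / sr

    q_lo = int(np.ceil(sr / f0_band[1]))
    q_hi = min(int(np.floor(sr / f0_band[0])), nfft // 2 - 1)
    reg_lo = int(np.ceil(regression_band[0] * sr))
    reg_hi = (nfft // 2 if regression_band[1] is None
              else min(int(regression_band[1] * sr), nfft // 2))

    band = cep[:, q_lo:q_hi + 1]
    pk = np.argmax(band, axis=1) + q_lo
    peak_val = cep[np.arange(len(cep)), pk]
    # least-squares trend over the regression band
    q_reg = quef[reg_lo:reg_hi]
    qc = q_reg - q_reg.mean()
    denom = float((qc**2).sum())
    y = cep[:, reg_lo:reg_hi]
    slope = y @ qc / denom
    intercept = y.mean(axis=1) - slope * q_reg.mean()
    trend_at_peak = slope * quef[pk] + intercept
    cpp = peak_val - trend_at_peak
    times = (np.arange(len(frames)) * hop_n + flen / 2) / sr
    return CPPTrack(times, cpp, quef[pk])


def summarize_cpp(track: CPPTrack) -> CPPSummary:
    """Mean, coefficient of variation (SD/mean, population SD), and 20th/80th
    percentiles (linear interpolation) of the CPP track."""
    x = np.asarray(track.cpp_db, dtype=float)
    if len(x) < 2:
        raise ValueError("CPP summary requires >= 2 analyzed frames")
    mean = float(np.mean(x))
    sd = float(np.std(x))
    cov = sd / mean if abs(mean) > _EPS else 0.0
    p20, p80 = np.percentile(x, [20, 80])
    return CPPSummary(mean, float(cov), float(p20), float(p80))


def compute_duration(recording) -> float:
    """Audio duration in seconds."""
    if hasattr(recording, "waveform"):
        n, sr = len(recording.waveform), recording.sample_rate
    else:
        raise ValueError("compute_duration expects a Recording")
    if n == 0:
        raise ValueError("empty recording")
    return n / sr


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------

@dataclass
class FeatureTable:
    """Samples x features with labels and participant group keys."""

    X: pd.DataFrame          # index: recording_id
    y: pd.Series             # 1 = patient, 0 = control
    groups: pd.Series        # participant_id per row
    feature_set: str
    task: str

    def __post_init__(self) -> None:
        if not (len(self.X) == len(self.y) == len(self.groups)):
            raise ValueError("X, y and groups must align")

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)

    def subset(self, features: list[str]) -> "FeatureTable":
        return FeatureTable(self.X[list(features)].copy(), self.y, self.groups,
                            self.feature_set, self.task)


class MedianImputer:
    """Replace non-finite cells with per-feature medians learned on a
    training split only (no test-side leakage)."""

    def __init__(self) -> None:
        self.medians_: pd.Series | None = None

    def fit(self, X: pd.DataFrame) -> "MedianImputer":
        clean = X.replace([np.inf, -np.inf], np.nan)
        med = clean.median()
        self.medians_ = med.fillna(0.0)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if self.medians_ is None:
            raise RuntimeError("imputer not fitted")
        clean = X.replace([np.inf, -np.inf], np.nan)
        return clean.fillna(self.medians_)


def extract_feature_frame(recordings, feature_set: str = "egemaps88",
                          progress: bool = False) -> pd.DataFrame:
    """Extract the named feature set for every recording (rows keyed by
    recording_id)."""
    rows = {}
    for rec in recordings:
        if feature_set == "egemaps88":
            rows[rec.recording_id] = extract_egemaps(rec)
        elif feature_set == "cpp4":
            track = compute_cpp_track(rec.waveform, rec.sample_rate)
            rows[rec.recording_id] = summarize_cpp(track).as_series()
        elif feature_set == "duration1":
            rows[rec.recording_id] = pd.Series(
                {"audio_duration_s": compute_duration(rec)})
        else:
            raise ValueError(f"unknown feature set: {feature_set!r}")
    return pd.DataFrame(rows).T


def build_feature_table(recordings, manifest: pd.DataFrame,
                        feature_set: str = "egemaps88",
                        task_filter: str = "reading+vowel",
                        features: pd.DataFrame | None = None) -> FeatureTable:
    """Assemble a labelled feature table for one task filter.

    ``features`` may carry a precomputed frame (rows keyed by recording_id)
    so repeated table builds do not re-extract audio.
    """
    if task_filter not in TASK_FILTERS:
        raise ValueError(f"unknown task filter: {task_filter!r}")
    if feature_set not in ("egemaps88", "cpp4", "duration1"):
        raise ValueError(f"unknown feature set: {feature_set!r}")
    man = manifest.set_index("recording_id")
    if task_filter != "reading+vowel":
        man = man[man["task"] == task_filter]
    keep = [r for r in recordings if r.recording_id in man.index]
    if features is None:
        features = extract_feature_frame(keep, feature_set)
    X = features.loc[[r.recording_id for r in keep]]
    y = (man.loc[X.index, "group"] == "UVFP").astype(int)
    groups = man.loc[X.index, "participant_id"]
    return FeatureTable(X, y.rename("label"), groups.rename("participant_id"),
                        feature_set, task_filter)
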