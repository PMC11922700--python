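"""Band-power features from Welch spectra, and the session feature table.

One feature per (condition, channel, frequency band): the average power
spectral density within the band, computed with Welch's method
(NFFT = 512 -> 1 s windows at 512 Hz, 0.5 s overlap, Hann taper) and
averaged over the blocks of each condition. With 4 conditions, 32 channels
and 6 bands the standard design yields 768 features per session.

Welch windows that touch any rejected sample are skipped entirely rather
than splicing data across gaps, which would leak spectral energy from the
splice discontinuity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import get_window

#: condition order used everywhere a feature axis is laid out
CONDITIONS = ("open_sitting", "closed_sitting", "open_standing", "closed_standing")

_DEFAULT_EDGES = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta1": (13.0, 20.0),
    "beta2": (20.0, 30.0),
    "gamma": (30.0, 50.0),
}


@dataclass(frozen=True)
class BandScheme:
    """Named half-open frequency intervals [low, high) in Hz.

    Half-open edges mean adjacent bands (which share printed endpoints,
    e.g. 4 Hz between delta and theta) never double-count a frequency bin.
    """

    edges: dict = field(default_factory=lambda: dict(_DEFAULT_EDGES))

    def __post_init__(self) -> None:
        # canonical order: ascending low edge (serialization may scramble)
        ordered = dict(sorted(self.edges.items(), key=lambda kv: kv[1][0]))
        object.__setattr__(self, "edges", ordered)
        prev_hi = None
        for name, (lo, hi) in self.edges.items():
            if not lo < hi:
                raise ValueError(f"band {name!r}: low must be < high")
            if prev_hi is not None and lo < prev_hi:
                raise ValueError(f"band {name!r} overlaps its predecessor")
            prev_hi = hi

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.edges)

    def band_of(self, freq_hz: float) -> str | None:
        for name, (lo, hi) in self.edges.items():
            if lo <= freq_hz < hi:
                return name
        return None


def default_bands() -> BandScheme:
    """delta 1-4, theta 4-8, alpha 8-13, beta1 13-20, beta2 20-30, gamma 30-50 Hz."""
    return BandScheme()


@dataclass(frozen=True)
class WelchParams:
    """Welch PSD estimation settings. nfft is both FFT and window length."""

    nfft: int = 512
    overlap_s: float = 0.5
    taper: str = "hann"

    def window_duration_s(self, fs: float) -> float:
        """Window length in seconds (1 s at the study's 512 Hz)."""
        return self.nfft / fs

    def hop(self, fs: float) -> int:
        noverlap = int(round(self.overlap_s * fs))
        if not 0 <= noverlap < self.nfft:
            raise ValueError("overlap must be in [0, window length)")
        return self.nfft - noverlap


@dataclass
class BandPowerResult:
    """Per-channel Welch band powers for one block."""

    band_power: dict                 # band -> (n_channels,) mean PSD, uV^2/Hz
    psd: np.ndarray | None           # (n_channels, n_freqs) or None if missing
    freqs: np.ndarray
    n_windows: int
    missing: bool = False


def _recording_and_mask(clean):
    """Accept a CleanRecording (recording + mask) or a bare Recording."""
    rec = getattr(clean, "recording", clean)
    mask_obj = getattr(clean, "mask", None)
    mask = None if mask_obj is None else np.asarray(mask_obj.excluded, dtype=bool)
    return rec, mask


def welch_band_power(clean, params: WelchParams | None = None,
                     scheme: BandScheme | None = None) -> BandPowerResult:
    """Welch PSD averaged over artifact-free windows, reduced to band powers.

    Matches scipy.signal.welch (Hann taper, no detrending, one-sided
    density scaling) exactly when no sample is masked; with a mask, any
    window containing a masked sample is dropped from the average. If no
    valid window remains the result is flagged missing rather than raising.
    Windows are not detrended: the 0.1 Hz high-pass upstream already
    removes drift, and detrending would bias the delta band against the
    generator's stated spectrum.
    """
    params = params or WelchParams()
    scheme = scheme or default_bands()
    rec, mask = _recording_and_mask(clean)
    data = np.asarray(rec.data, dtype=float)
    fs = rec.fs
    n = data.shape[1]
    win = params.nfft
    if win > n:
        raise ValueError("block shorter than one Welch window")
    hop = params.hop(fs)

    starts = np.arange(0, n - win + 1, hop)
    if mask is not None and mask.any():
        bad = np.array([mask[s:s + win].any() for s in starts])
        starts = starts[~bad]
    freqs = np.fft.rfftfreq(win, 1.0 / fs)
    if starts.size == 0:
        nan = np.full(data.shape[0], np.nan)
        return BandPowerResult(band_power={b: nan.copy() for b in scheme.names},
                               psd=None, freqs=freqs, n_windows=0, missing=True)

    w = get_window(params.taper, win)
    norm = fs * (w ** 2).sum()
    acc = np.zeros((data.shape[0], freqs.size))
    for s in starts:
        seg = data[:, s:s + win]
        spec = np.fft.rfft(seg * w)
        p = (spec.real ** 2 + spec.imag ** 2) / norm
        p[:, 1:] *= 2.0
        if win % 2 == 0:
            p[:, -1] /= 2.0
        acc += p
    psd = acc / starts.size

    band_power = {}
    for name, (lo, hi) in scheme.edges.items():
        sel = (freqs >= lo) & (freqs < hi)
        band_power[name] = psd[:, sel].mean(axis=1)
    return BandPowerResult(band_power=band_power, psd=psd, freqs=freqs,
                           n_windows=int(starts.size))


# ---------------------------------------------------------------------------
# session-level features


def feature_names(channels: tuple[str, ...], scheme: BandScheme,
                  conditions: tuple[str, ...] = CONDITIONS) -> list[str]:
    """Deterministic feature column order: condition, then channel, then band."""
    return [f"{c}.{ch}.{b}" for c in conditions for ch in channels
            for b in scheme.names]


@dataclass
class FeatureVector:
    """One session's band-power features (flat, in feature_names order)."""

    subject_id: str
    lag: str
    group: str
    values: pd.Series                   # index = feature names
    missing_conditions: list[str]
    n_windows: dict                     # condition -> summed valid windows


def session_features(blocks, params: WelchParams | None = None,
                     scheme: BandScheme | None = None) -> FeatureVector:
    """Average per-condition band powers over a subject-session's blocks.

    ``blocks`` are CleanRecordings (or Recordings) from one subject and one
    lag; the standard design has 2 blocks per condition. Conditions whose
    every block is fully rejected are flagged missing (NaN features).
    """
    params = params or WelchParams()
    scheme = scheme or default_bands()
    recs = [_recording_and_mask(b)[0] for b in blocks]
    subjects = {r.subject_id for r in recs}
    lags = {r.session.lag for r in recs}
    if len(subjects) != 1 or len(lags) != 1:
        raise ValueError(
            f"blocks span subjects {sorted(subjects)} / lags {sorted(lags)}; "
            "session_features expects a single subject-session")
    channels = recs[0].channel_names

    per_cond: dict[str, list[BandPowerResult]] = {c: [] for c in CONDITIONS}
    for blk, rec in zip(blocks, recs):
        per_cond[rec.session.condition].append(
            welch_band_power(blk, params, scheme))

    names = feature_names(channels, scheme)
    values = pd.Series(np.nan, index=names)
    missing, n_windows = [], {}
    for cond, results in per_cond.items():
        valid = [r for r in results if not r.missing]
        n_windows[cond] = sum(r.n_windows for r in valid)
        if not valid:
            missing.append(cond)
            continue
        for b in scheme.names:
            bp = np.mean([r.band_power[b] for r in valid], axis=0)
            for ci, ch in enumerate(channels):
                values[f"{cond}.{ch}.{b}"] = bp[ci]
    return FeatureVector(subject_id=recs[0].subject_id, lag=recs[0].session.lag,
                         group=recs[0].group, values=values,
                         missing_conditions=missing, n_windows=n_windows)


# ---------------------------------------------------------------------------
# the classification table

LABEL_NAMES = {0: "baseline", 1: "post_impact"}


@dataclass
class FeatureTable:
    """Observations (subject x lag) by features, with binary labels.

    Labels: 0 = baseline (pre-impact), 1 = post-impact. Each subject
    contributes exactly one row per class, so subject-grouped CV folds are
    automatically class-balanced.
    """

    X: np.ndarray                    # (n_obs, n_features)
    feature_names: list[str]
    subject_ids: np.ndarray          # (n_obs,) str
    labels: np.ndarray               # (n_obs,) int {0, 1}
    groups: np.ndarray               # (n_obs,) str, kicking / non_kicking
    lags: np.ndarray                 # (n_obs,) str

    def __post_init__(self) -> None:
        n = self.X.shape[0]
        for arr in (self.subject_ids, self.labels, self.groups, self.lags):
            if len(arr) != n:
                raise ValueError("metadata length must match X rows")
        if self.X.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length must match X columns")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValueError("labels must be binary 0/1")

    @property
    def n_obs(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def subjects(self) -> np.ndarray:
        return np.unique(self.subject_ids)

    def restrict_group(self, group: str) -> "FeatureTable":
        keep = self.groups == group
        if not keep.any():
            raise ValueError(f"no rows in group {group!r}")
        return FeatureTable(self.X[keep], self.feature_names,
                            self.subject_ids[keep], self.labels[keep],
                            self.groups[keep], self.lags[keep])

    def with_labels(self, labels: np.ndarray) -> "FeatureTable":
        return FeatureTable(self.X, self.feature_names, self.subject_ids,
                            np.asarray(labels, dtype=int), self.groups, self.lags)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.feature_names)
        df.insert(0, "lag", self.lags)
        df.insert(0, "group", self.groups)
        df.insert(0, "label", [LABEL_NAMES[l] for l in self.labels])
        df.insert(0, "subject_id", self.subject_ids)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeatureTable":
        meta = ["subject_id", "label", "group", "lag"]
        feats = [c for c in df.columns if c not in meta]
        inv = {v: k for k, v in LABEL_NAMES.items()}
        return cls(X=df[feats].to_numpy(float), feature_names=feats,
                   subject_ids=df["subject_id"].to_numpy(str),
                   labels=df["label"].map(inv).to_numpy(int),
                   groups=df["group"].to_numpy(str),
                   lags=df["lag"].to_numpy(str))

    @classmethod
    def from_csv(cls, path) -> "FeatureTable":
        return cls.from_frame(pd.read_csv(path))


def assemble_table(vectors: list[FeatureVector],
                   lags: tuple[str, str] = ("pre", "post24h")) -> FeatureTable:
    """Build the baseline-vs-post-impact table for one lag contrast.

    ``lags[0]`` becomes the baseline class (label 0), ``lags[1]`` the
    post-impact class (label 1). Subjects missing either lag are dropped
    with a warning.
    """
    base_lag, post_lag = lags
    by_subject: dict[str, dict[str, FeatureVector]] = {}
    for v in vectors:
        if v.lag in lags:
            by_subject.setdefault(v.subject_id, {})[v.lag] = v

    rows, subs, labels, groups, laglist = [], [], [], [], []
    dropped = 0
    names = None
    for sid in sorted(by_subject):
        pair = by_subject[sid]
        if base_lag not in pair or post_lag not in pair:
            dropped += 1
            continue
        for lag, lab in ((base_lag, 0), (post_lag, 1)):
            v = pair[lag]
            if names is None:
                names = list(v.values.index)
            rows.append(v.values.to_numpy(float))
            subs.append(sid)
            labels.append(lab)
            groups.append(v.group)
            laglist.append(lag)
    if dropped:
        warnings.warn(f"dropped {dropped} subject(s) missing a {lags} session")
    if not rows:
        raise ValueError("no subject has both requested lags")
    return FeatureTable(X=np.vstack(rows), feature_names=names,
                        subject_ids=np.array(subs), labels=np.array(labels),
                        groups=np.array(groups), lags=np.array(laglist))
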