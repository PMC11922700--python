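"""Synthetic resting-EEG cohorts with the heading-study design.

The study design being emulated: 36 soccer players, half of whom perform a
control kicking bout before their baseline session; resting EEG recorded at
three lags (pre-impact, 1 h post, 24 h post), each session consisting of
8 blocks of 2.5 min covering the four crossed conditions
{eyes open, eyes closed} x {sitting, standing}; 32-channel 10-10 montage
digitized at 512 Hz.

Signals are drawn by spectral synthesis: each channel is stationary
Gaussian noise with a target one-sided power spectral density

    S_c(f) = [A / max(f, f0)^beta + alpha_bump(f)] * M_c(band(f))

where ``M_c`` collects multiplicative band-power modifiers — the
per-subject log-power offset, the eyes-closed alpha boost, the per-lag
impact effect (band x scalp-region factors), and an exercise effect applied
to sessions recorded within ~1 h of an exercise bout (the kicking group
exercises before its baseline, so pre-vs-post contrasts cancel exercise;
the non-kicking group's post-1h session is its only exercised one).
Because the synthesis is exact in expectation, Welch band-power ratios
converge to the configured factors, which makes every downstream stage
testable against known ground truth.

Stereotyped ocular artifacts (blinks, lateral saccades) and high-amplitude
jump transients are added at Poisson-placed times recorded in a manifest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace, asdict
from typing import Iterator

import numpy as np

from .features import BandScheme, default_bands
from .montage import ChannelMontage, standard_montage

LAGS = ("pre", "post1h", "post24h")
GROUPS = ("kicking", "non_kicking")
EYES = ("open", "closed")
POSTURES = ("sitting", "standing")

# Recording order within a session (repeated twice, 8 blocks total):
# sitting/open, sitting/closed, standing/open, standing/closed.
_BLOCK_CYCLE = [
    ("open", "sitting"), ("closed", "sitting"),
    ("open", "standing"), ("closed", "standing"),
]


@dataclass(frozen=True)
class SessionLabel:
    """Identifies one recording block within the three-session design."""

    lag: str                # pre | post1h | post24h
    eyes: str               # open | closed
    posture: str            # sitting | standing
    block_index: int        # 1..8 position in the session's recording order

    def __post_init__(self) -> None:
        if self.lag not in LAGS:
            raise ValueError(f"unknown lag {self.lag!r}; expected one of {LAGS}")
        if self.eyes not in EYES or self.posture not in POSTURES:
            raise ValueError(
                f"invalid condition ({self.eyes!r}, {self.posture!r})"
            )
        if not 1 <= self.block_index <= 8:
            raise ValueError("block_index must be in 1..8")
        expected = _BLOCK_CYCLE[(self.block_index - 1) % 4]
        if (self.eyes, self.posture) != expected:
            raise ValueError(
                f"block {self.block_index} must be condition {expected}, "
                f"got ({self.eyes!r}, {self.posture!r})"
            )

    @property
    def condition(self) -> str:
        return f"{self.eyes}_{self.posture}"


def session_blocks(lag: str) -> list[SessionLabel]:
    """The 8 block labels of one session, in recording order."""
    return [
        SessionLabel(lag=lag, eyes=e, posture=p, block_index=i + 1)
        for i, (e, p) in enumerate(_BLOCK_CYCLE * 2)
    ]


@dataclass
class Recording:
    """One block of multichannel EEG with its design metadata."""

    subject_id: str
    group: str
    session: SessionLabel
    fs: float
    data: np.ndarray                 # (n_channels, n_samples), microvolts
    channel_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channel_names):
            raise ValueError("data must be (n_channels, n_samples) matching labels")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class BlockArtifacts:
    """Ground-truth sample indices of every injected artifact in a block."""

    blink_onsets: list[int] = field(default_factory=list)
    saccade_onsets: list[int] = field(default_factory=list)
    jumps: list[dict] = field(default_factory=list)  # {channel, start, n_samples}

    @property
    def any(self) -> bool:
        return bool(self.blink_onsets or self.saccade_onsets or self.jumps)


@dataclass
class EffectSpec:
    """Configurable band-power effects and artifact rates.

    ``lag_effects`` maps lag -> band -> scalp region -> multiplicative
    band-power factor (region names from :data:`montage.CHANNEL_GROUPS`,
    or ``"all"``). A factor of 1 everywhere is the null world.
    ``exercise_effect`` (band -> factor) multiplies band power in any
    session recorded within ~1 h of an exercise bout.
    """

    lag_effects: dict = field(default_factory=dict)
    exercise_effect: dict = field(default_factory=dict)
    subject_sd: float = 0.2          # sd of per-subject, per-band log-power offsets
    blink_rate_per_min: float = 12.0
    saccade_rate_per_min: float = 4.0
    jumps_per_block: float = 1.0     # Poisson mean

    def __post_init__(self) -> None:
        for lag, bands in self.lag_effects.items():
            if lag not in LAGS:
                raise ValueError(f"lag_effects key {lag!r} is not a lag")
            for band, groups in bands.items():
                for grp, f in groups.items():
                    if f <= 0:
                        raise ValueError("effect factors must be > 0")
        if any(f <= 0 for f in self.exercise_effect.values()):
            raise ValueError("exercise factors must be > 0")
        if min(self.blink_rate_per_min, self.saccade_rate_per_min,
               self.jumps_per_block) < 0:
            raise ValueError("artifact rates must be >= 0")

    # -- common scenario constructors -------------------------------------

    @classmethod
    def null(cls, **kw) -> "EffectSpec":
        """No impact effect, no exercise effect."""
        return cls(**kw)

    @classmethod
    def late_effect(cls, alpha_occipital: float = 1.5,
                    theta_frontal: float = 1.3, **kw) -> "EffectSpec":
        """A 24 h-only spectral signature (nothing at 1 h)."""
        return cls(lag_effects={
            "post24h": {"alpha": {"occipital": alpha_occipital},
                        "theta": {"frontal": theta_frontal}},
        }, **kw)

    @classmethod
    def disjoint_lags(cls, **kw) -> "EffectSpec":
        """Non-overlapping 1 h and 24 h signatures (different bands/regions)."""
        return cls(lag_effects={
            "post1h": {"beta1": {"central": 1.5},
                       "delta": {"temporal": 1.4}},
            "post24h": {"alpha": {"occipital": 1.5},
                        "theta": {"frontal": 1.3}},
        }, **kw)

    def with_exercise(self, gamma: float = 1.3, beta2: float = 1.2) -> "EffectSpec":
        """Add a broadband high-frequency exercise after-effect."""
        return replace(self, exercise_effect={"gamma": gamma, "beta2": beta2})


@dataclass
class CohortConfig:
    """Full description of a synthetic cohort; seed-identical configs
    produce byte-identical cohorts."""

    n_subjects: int = 36
    fs: float = 512.0
    block_duration_s: float = 150.0
    montage: ChannelMontage = field(default_factory=standard_montage)
    bands: BandScheme = field(default_factory=default_bands)
    effect: EffectSpec = field(default_factory=EffectSpec)
    pink_amplitude: float = 15.0     # uV^2/Hz at 1 Hz
    pink_exponent: float = 1.0       # 1/f^beta
    pink_floor_hz: float = 0.5       # spectrum flattens below this frequency
    alpha_osc_power: float = 10.0    # uV^2 per alpha source at its peak channel
    alpha_freq_range: tuple = (9.0, 11.0)
    beta_osc_power: float = 2.0      # uV^2 per beta source at its peak channel
    beta_freq_range: tuple = (16.0, 19.0)
    alpha_boost_closed: float = 2.0  # eyes-closed alpha band-power factor
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.n_subjects % 2:
            warnings.warn("odd n_subjects: groups will be unbalanced")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.block_duration_s))

    def subject_ids(self) -> list[str]:
        return [f"S{i + 1:02d}" for i in range(self.n_subjects)]

    def group_of(self, subject_id: str) -> str:
        # groups alternate by recruitment order, as in the study
        return GROUPS[self.subject_ids().index(subject_id) % 2]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["montage"] = {"names": list(self.montage.names),
                        "positions": self.montage.positions.tolist()}
        d["bands"] = {k: list(v) for k, v in self.bands.edges.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        if "montage" in d:
            m = d["montage"]
            d["montage"] = ChannelMontage(tuple(m["names"]),
                                          np.asarray(m["positions"]))
        if "bands" in d:
            d["bands"] = BandScheme({k: tuple(v) for k, v in d["bands"].items()})
        if "effect" in d and isinstance(d["effect"], dict):
            d["effect"] = EffectSpec(**d["effect"])
        return cls(**d)


def exercised_lags(group: str) -> frozenset[str]:
    """Sessions recorded within ~1 h of an exercise bout.

    The kicking group exercises (kicking bout) right before its baseline
    session and heads the ball 1 h before the post-1h session; the
    non-kicking group's only bout is the heading itself. The 24 h session
    is a day after any exercise for both groups.
    """
    return frozenset({"pre", "post1h"} if group == "kicking" else {"post1h"})


# ---------------------------------------------------------------------------
# spectral model


def _band_modifiers(config: CohortConfig, group: str, session: SessionLabel,
                    subject_offsets: dict[str, float]) -> dict[str, np.ndarray]:
    """Per-band vectors of multiplicative band-power factors per channel."""
    mont = config.montage
    mods: dict[str, np.ndarray] = {}
    eff = config.effect
    for band in config.bands.names:
        m = np.full(mont.n_channels, np.exp(subject_offsets.get(band, 0.0)))
        if band == "alpha" and session.eyes == "closed":
            m *= config.alpha_boost_closed
        for grp, factor in eff.lag_effects.get(session.lag, {}).get(band, {}).items():
            m[mont.group_indices(grp)] *= factor
        if session.lag in exercised_lags(group):
            m *= eff.exercise_effect.get(band, 1.0)
        mods[band] = m
    return mods


def _target_psd(config: CohortConfig, freqs: np.ndarray,
                mods: dict[str, np.ndarray]) -> np.ndarray:
    """One-sided broadband PSD (n_channels, n_freqs) in uV^2/Hz."""
    f = np.maximum(freqs, config.pink_floor_hz)
    base = config.pink_amplitude / f ** config.pink_exponent
    S = np.tile(base, (config.montage.n_channels, 1))
    for band, m in mods.items():
        lo, hi = config.bands.edges[band]
        sel = (freqs >= lo) & (freqs < hi)
        S[:, sel] *= m[:, None]
    S[:, freqs == 0] = 0.0
    return S


def _oscillator_sources(config: CohortConfig) -> list[dict]:
    """Narrow-band oscillator sources: (topography, band, base power).

    Bilateral occipito-parietal alpha and central beta generators. Shared
    sinusoidal sources with scalp topographies are what makes ICA
    decomposition of the synthetic data well-posed (pure Gaussian noise has
    no identifiable components) — and they mimic volume-conducted rhythms.
    """
    pos = config.montage.positions
    out = []
    for cx, cy, sd, band_range, power in (
            (-0.30, -0.75, 0.50, config.alpha_freq_range, config.alpha_osc_power),
            (+0.30, -0.75, 0.50, config.alpha_freq_range, config.alpha_osc_power),
            (-0.40, +0.15, 0.45, config.beta_freq_range, config.beta_osc_power),
            (+0.40, +0.15, 0.45, config.beta_freq_range, config.beta_osc_power)):
        d2 = ((pos - np.array([cx, cy])) ** 2).sum(axis=1)
        g = np.exp(-d2 / (2 * sd ** 2))
        band = config.bands.band_of(float(np.mean(band_range)))
        out.append({"topography": g / g.max(), "freq_range": band_range,
                    "band": band, "power": power})
    return out


def _welch_expectation_operator(n: int, fs: float, nfft: int):
    """E[Welch PSD] as a linear map of the target fine-grid PSD.

    A Welch periodogram estimates the true spectrum convolved with the
    taper's power kernel; for a steep 1/f spectrum this smoothing shifts
    band means by 10-20%, so the ground-truth expectation must go through
    the same measurement operator as the features. Returns a function
    mapping a one-sided fine-grid PSD (length n//2+1) to the expected
    Welch PSD at the nfft bins. Requires nfft | n.
    """
    from scipy.signal import get_window
    if n % nfft:
        raise ValueError("block length must be a multiple of nfft")
    r = n // nfft
    w = np.zeros(n)
    w[:nfft] = get_window("hann", nfft)
    kernel = np.abs(np.fft.fft(w)) ** 2
    norm = fs * (w ** 2).sum()
    fk = np.fft.fft(kernel)

    def apply(S_one: np.ndarray) -> np.ndarray:
        S_two = np.empty(n)
        S_two[:n // 2 + 1] = S_one / 2.0
        S_two[n // 2 + 1:] = S_one[1:n // 2][::-1] / 2.0
        # circular cross-correlation: sum_m S[m] * kernel[(m - p) mod n]
        corr = np.real(np.fft.ifft(np.fft.fft(S_two) * np.conj(fk)))
        est = 2.0 * corr[::r][:nfft // 2 + 1] * (fs / n) / norm
        est[0] /= 2.0
        est[-1] /= 2.0
        return est

    return apply


def expected_band_power(config: CohortConfig, subject_offsets: dict[str, float],
                        group: str, session: SessionLabel,
                        nfft: int = 512) -> dict[str, np.ndarray]:
    """Analytic mean Welch band power (band -> per-channel uV^2/Hz density),
    the ground truth the generator realizes in expectation.

    Accounts for the Hann-taper spectral smoothing of the Welch estimate,
    so Monte-Carlo means over generated blocks converge to these values."""
    n = config.n_samples
    fs = config.fs
    fine = np.fft.rfftfreq(n, 1.0 / fs)
    op = _welch_expectation_operator(n, fs, nfft)
    mods = _band_modifiers(config, group, session, subject_offsets)

    f = np.maximum(fine, config.pink_floor_hz)
    base = config.pink_amplitude / f ** config.pink_exponent
    base[fine == 0] = 0.0

    # smoothed per-band basis spectra (channel multipliers factor out)
    band_sel = {}
    covered = np.zeros(fine.size, dtype=bool)
    for band in config.bands.names:
        lo, hi = config.bands.edges[band]
        band_sel[band] = (fine >= lo) & (fine < hi)
        covered |= band_sel[band]
    smoothed = {band: op(base * sel) for band, sel in band_sel.items()}
    smoothed["_out"] = op(base * ~covered)

    osc_smoothed = []
    for osc in _oscillator_sources(config):
        if osc["band"] is None:
            continue
        lo_r, hi_r = osc["freq_range"]
        sel = (fine >= lo_r) & (fine <= hi_r)
        basis = sel / (sel.sum() * (fs / n))  # unit total power, uniform f0
        osc_smoothed.append((osc, op(basis)))

    welch_f = np.fft.rfftfreq(nfft, 1.0 / fs)
    n_ch = config.montage.n_channels
    out = {}
    for band in config.bands.names:
        lo, hi = config.bands.edges[band]
        wsel = (welch_f >= lo) & (welch_f < hi)
        psd = np.tile(smoothed["_out"][wsel].mean(), n_ch)
        for other in config.bands.names:
            psd = psd + mods[other] * smoothed[other][wsel].mean()
        for osc, sm in osc_smoothed:
            psd = psd + (osc["topography"] ** 2 * osc["power"]
                         * mods[osc["band"]]) * sm[wsel].mean()
        out[band] = psd
    return out


# ---------------------------------------------------------------------------
# artifact templates


def _blink_topography(mont: ChannelMontage) -> np.ndarray:
    """Positive frontal-polar map, maximal at Fp1/Fpz/Fp2, Gaussian falloff."""
    d2 = ((mont.positions - np.array([0.0, 1.05])) ** 2).sum(axis=1)
    w = np.exp(-d2 / (2 * 0.35 ** 2))
    return w / w.max()


def _saccade_topography(mont: ChannelMontage) -> np.ndarray:
    """Antisymmetric lateral-frontal map (left/right opposite polarity)."""
    x, y = mont.positions.T
    w = x * np.exp(-((y - 0.6) ** 2) / (2 * 0.35 ** 2))
    return w / np.abs(w).max()


def _blink_waveform(fs: float, duration_s: float = 0.3) -> np.ndarray:
    n = int(round(duration_s * fs))
    return 0.5 * (1 - np.cos(2 * np.pi * np.arange(n) / n))


def _saccade_waveform(fs: float) -> np.ndarray:
    """Step up (~30 ms ramp), fixation plateau (~250 ms), step back."""
    ramp = int(round(0.03 * fs))
    hold = int(round(0.25 * fs))
    up = np.linspace(0, 1, ramp, endpoint=False)
    return np.concatenate([up, np.ones(hold), up[::-1]])


# ---------------------------------------------------------------------------
# generation


def draw_subject_offsets(config: CohortConfig, subject_index: int) -> dict[str, float]:
    """Per-subject, per-band log-power offsets, drawn once per subject."""
    rng = np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(0, subject_index)))
    return {band: float(rng.normal(0.0, config.effect.subject_sd))
            for band in config.bands.names}


def generate_block(config: CohortConfig, subject_id: str, session: SessionLabel,
                   subject_offsets: dict[str, float], *,
                   seed_key: tuple[int, ...] | None = None,
                   ) -> tuple[Recording, BlockArtifacts]:
    """Synthesize one EEG block.

    The returned recording's expected Welch band powers equal the analytic
    :func:`expected_band_power` for this subject/session; injected artifact
    positions are returned as ground truth. ``seed_key`` overrides the
    default (subject, lag, block) counter-based sub-seed.
    """
    ids = config.subject_ids()
    if subject_id not in ids:
        raise ValueError(f"unknown subject {subject_id!r}")
    si = ids.index(subject_id)
    group = config.group_of(subject_id)
    if seed_key is None:
        seed_key = (1, si, LAGS.index(session.lag), session.block_index)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=seed_key))

    n = config.n_samples
    freqs = np.fft.rfftfreq(n, 1.0 / config.fs)
    mods = _band_modifiers(config, group, session, subject_offsets)
    S = _target_psd(config, freqs, mods)

    # Gaussian process with exactly the target spectrum: random-phase synthesis.
    scale = np.sqrt(S * config.fs * n / 2.0)
    z = rng.standard_normal((config.montage.n_channels, freqs.size, 2))
    coef = scale * (z[..., 0] + 1j * z[..., 1]) / np.sqrt(2.0)
    coef[:, 0] = 0.0
    if n % 2 == 0:  # real Nyquist bin
        coef[:, -1] = scale[:, -1] * z[:, -1, 0]
    data = np.fft.irfft(coef, n=n)

    # shared narrow-band oscillator sources (random frequency/phase per block)
    t = np.arange(n) / config.fs
    for osc in _oscillator_sources(config):
        if osc["band"] is None:
            continue
        f0 = rng.uniform(*osc["freq_range"])
        phase = rng.uniform(0, 2 * np.pi)
        src = np.sin(2 * np.pi * f0 * t + phase)
        amp = osc["topography"] * np.sqrt(2.0 * osc["power"] * mods[osc["band"]])
        data += amp[:, None] * src[None, :]

    art = BlockArtifacts()
    eff = config.effect
    minutes = config.block_duration_s / 60.0

    blink_map = _blink_topography(config.montage)
    blink_wf = _blink_waveform(config.fs)
    for _ in range(rng.poisson(eff.blink_rate_per_min * minutes)):
        t0 = int(rng.integers(0, max(1, n - blink_wf.size)))
        amp = rng.normal(120.0, 15.0)
        data[:, t0:t0 + blink_wf.size] += amp * blink_map[:, None] * blink_wf[None, :]
        art.blink_onsets.append(t0)

    sac_map = _saccade_topography(config.montage)
    sac_wf = _saccade_waveform(config.fs)
    for _ in range(rng.poisson(eff.saccade_rate_per_min * minutes)):
        t0 = int(rng.integers(0, max(1, n - sac_wf.size)))
        amp = rng.normal(60.0, 10.0) * rng.choice([-1.0, 1.0])
        data[:, t0:t0 + sac_wf.size] += amp * sac_map[:, None] * sac_wf[None, :]
        art.saccade_onsets.append(t0)

    # channel-wise background sd from the target spectrum (Parseval)
    df = freqs[1] - freqs[0]
    chan_sd = np.sqrt((S * df).sum(axis=1))
    for _ in range(rng.poisson(eff.jumps_per_block)):
        ch = int(rng.integers(0, config.montage.n_channels))
        dur = int(round(rng.uniform(0.05, 0.2) * config.fs))
        t0 = int(rng.integers(0, max(1, n - dur)))
        # >= 20x background SD guarantees the 15-SD peak-to-trough rule fires
        data[ch, t0:t0 + dur] += 25.0 * chan_sd[ch]
        art.jumps.append({"channel": ch, "start": t0, "n_samples": dur})

    rec = Recording(subject_id=subject_id, group=group, session=session,
                    fs=config.fs, data=data,
                    channel_names=config.montage.names)
    art.blink_onsets.sort()
    art.saccade_onsets.sort()
    return rec, art


def enumerate_blocks(config: CohortConfig) -> list[tuple[str, SessionLabel]]:
    """The cohort's full design grid: (subject_id, session) per block."""
    return [(sid, sess)
            for sid in config.subject_ids()
            for lag in LAGS
            for sess in session_blocks(lag)]


def iter_cohort(config: CohortConfig
                ) -> Iterator[tuple[Recording, BlockArtifacts]]:
    """Stream the cohort block by block (constant memory).

    Order: subjects, then lags, then blocks — but every block is seeded by
    its (subject, lag, block) coordinates, so the realization is
    independent of iteration order.
    """
    offsets = {sid: draw_subject_offsets(config, i)
               for i, sid in enumerate(config.subject_ids())}
    for sid, sess in enumerate_blocks(config):
        yield generate_block(config, sid, sess, offsets[sid])


@dataclass
class Cohort:
    """A fully materialized synthetic cohort plus its ground-truth manifest."""

    config: CohortConfig
    recordings: list[Recording]
    manifest: dict

    def blocks_for(self, subject_id: str, lag: str) -> list[Recording]:
        return [r for r in self.recordings
                if r.subject_id == subject_id and r.session.lag == lag]


def generate_cohort(config: CohortConfig) -> Cohort:
    """Materialize every block (n_subjects x 3 sessions x 8 blocks).

    Memory scales with n_subjects x block duration; for full-size cohorts
    at the default 2.5 min blocks prefer :func:`iter_cohort`.
    """
    offsets = {sid: draw_subject_offsets(config, i)
               for i, sid in enumerate(config.subject_ids())}
    recordings, blocks_manifest = [], []
    for sid, sess in enumerate_blocks(config):
        rec, art = generate_block(config, sid, sess, offsets[sid])
        recordings.append(rec)
        blocks_manifest.append({
            "subject_id": sid, "lag": sess.lag, "block_index": sess.block_index,
            "condition": sess.condition,
            "blink_onsets": list(art.blink_onsets),
            "saccade_onsets": list(art.saccade_onsets),
            "jumps": [dict(j) for j in art.jumps],
        })
    manifest = {
        "seed": config.seed,
        "subjects": {sid: {"group": config.group_of(sid),
                           "log_power_offsets": offsets[sid]}
                     for sid in config.subject_ids()},
        "blocks": blocks_manifest,
    }
    return Cohort(config=config, recordings=recordings, manifest=manifest)
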