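"""Synthetic ECG with analytically known ground truth.

Each beat is a sum of five Gaussian bumps (P, Q, R, S, T) placed in a
per-beat linear phase coordinate — the classical sum-of-Gaussians ECG
morphology, without ODE integration.  Phase runs over ``[-pi, pi)`` per beat
with the R-peak at phase 0; a wave with phase center ``c`` (radians) and
width ``w`` (radians) is rendered in time by scaling with the local RR
interval (waves before the R-peak use the preceding interval, waves after it
the following one), so RR variability stretches the morphology the way real
heart-rate variability does.

Because the morphology is analytic, every landmark is known exactly:
R-peaks land on sample-grid times, the QRS onset is the 3-sigma point of the
Q wave and the T-wave offset the 3-sigma point of the T wave.  That makes
the generator a ground-truth oracle for R-peak detectors, for phase-domain
template recovery, and for QT-interval error measurement.

White-noise contamination is power-matched: the drawn noise vector is
rescaled so the realized sample SNR equals the request exactly, making SNR
calibration deterministic rather than a distributional statement.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .records import EcgRecord

__all__ = [
    "WaveParams",
    "SynthSpec",
    "GroundTruth",
    "DEFAULT_WAVES",
    "generate_clean",
    "add_noise",
    "add_baseline_wander",
]

_WAVE_ORDER = ("P", "Q", "R", "S", "T")


@dataclass(frozen=True)
class WaveParams:
    """Gaussian bump parameters per wave: ``{wave: (amplitude_mV, center_rad, width_rad)}``.

    Centers live in ``[-pi, pi)`` with the R-peak at 0 and must increase in
    the order P < Q < R < S < T; widths are strictly positive; the R
    amplitude must dominate Q and S in magnitude so the R-peak is the beat's
    extremum.
    """

    waves: dict[str, tuple[float, float, float]]

    def __post_init__(self) -> None:
        missing = set(_WAVE_ORDER) - set(self.waves)
        if missing:
            raise ValueError(f"missing wave parameters for {sorted(missing)}")
        centers = [self.waves[w][1] for w in _WAVE_ORDER]
        if not all(a < b for a, b in zip(centers, centers[1:])):
            raise ValueError("wave centers must be strictly increasing P < Q < R < S < T")
        if any(self.waves[w][2] <= 0 for w in _WAVE_ORDER):
            raise ValueError("wave widths must be strictly positive")
        a_r = abs(self.waves["R"][0])
        if any(abs(self.waves[w][0]) >= a_r for w in ("Q", "S")) and a_r > 0:
            raise ValueError("R amplitude must strictly dominate Q and S")

    def scaled(self, factor: float) -> "WaveParams":
        return WaveParams(
            {w: (a * factor, c, s) for w, (a, c, s) in self.waves.items()}
        )


#: Lead-II-like default morphology (amplitude mV, center rad, width rad).
DEFAULT_WAVES = WaveParams(
    {
        "P": (0.15, -1.00, 0.15),
        "Q": (-0.10, -0.12, 0.03),
        "R": (1.00, 0.00, 0.09),
        "S": (-0.25, 0.15, 0.04),
        "T": (0.35, 2.00, 0.11),
    }
)


@dataclass(frozen=True)
class SynthSpec:
    """Full specification of a synthetic record.

    ``mean_rr`` / ``rr_jitter_sd`` control heart rate and its variability
    (RR intervals are i.i.d. normal truncated positive), ``amplitude_jitter_cv``
    the per-beat morphology scaling (normal with mean 1), and ``fs`` /
    ``duration`` the sampling grid.
    """

    wave_params: WaveParams = field(default_factory=lambda: DEFAULT_WAVES)
    mean_rr: float = 0.8
    rr_jitter_sd: float = 0.04
    amplitude_jitter_cv: float = 0.05
    fs: float = 250.0
    duration: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_rr <= 0 or self.fs <= 0 or self.duration <= 0:
            raise ValueError("mean_rr, fs and duration must be positive")
        if self.mean_rr * self.fs < 20:
            raise ValueError("mean_rr * fs must be at least 20 samples per beat")
        if self.rr_jitter_sd < 0 or self.rr_jitter_sd >= self.mean_rr / 3:
            raise ValueError("rr_jitter_sd must lie in [0, mean_rr/3)")
        if self.amplitude_jitter_cv < 0:
            raise ValueError("amplitude_jitter_cv must be non-negative")


@dataclass(frozen=True)
class GroundTruth:
    """Analytic landmarks of a generated record (all 0-based sample indices).

    ``true_qt`` is per-beat QT in seconds, computed from the continuous
    (unrounded) landmark times: QRS onset at the Q wave's ``center - 3*width``
    and T-wave offset at the T wave's ``center + 3*width``.
    """

    r_peaks: np.ndarray
    q_onsets: np.ndarray
    t_offsets: np.ndarray
    true_qt: np.ndarray

    def __post_init__(self) -> None:
        for name in ("r_peaks", "q_onsets", "t_offsets"):
            idx = getattr(self, name)
            if np.any(np.diff(idx) <= 0):
                raise ValueError(f"{name} must be strictly increasing")
        if not np.all((self.q_onsets < self.r_peaks) & (self.r_peaks < self.t_offsets)):
            raise ValueError("each beat must satisfy q_onset < r_peak < t_offset")


def _draw_rr(rng: np.random.Generator, mean: float, sd: float) -> float:
    if sd == 0:
        return mean
    for _ in range(100):
        rr = rng.normal(mean, sd)
        if rr > 0:
            return rr
    raise RuntimeError("failed to draw a positive RR interval in 100 attempts")


def generate_clean(spec: SynthSpec) -> tuple[EcgRecord, GroundTruth]:
    """Generate a clean single-lead record and its analytic ground truth.

    R-peak times are snapped to the sample grid (so the R sample is the
    beat's exact extremum); each beat's waves are scaled per beat by the
    amplitude jitter and in time by the adjacent RR intervals.  Deterministic
    for a fixed ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.fs))
    t = np.arange(n) / spec.fs

    # R-peak times on the sample grid, first beat centred ~half an interval in
    r_times: list[float] = []
    r = spec.mean_rr / 2
    while True:
        r_snap = round(r * spec.fs) / spec.fs
        if r_snap >= spec.duration:
            break
        r_times.append(r_snap)
        r += _draw_rr(rng, spec.mean_rr, spec.rr_jitter_sd)
    if len(r_times) < 1:
        raise ValueError("duration too short to contain a single beat")
    r_arr = np.array(r_times)
    rr_pre = np.diff(r_arr, prepend=np.nan)
    rr_post = np.diff(r_arr, append=np.nan)
    # edge beats reuse their single adjacent interval (or the mean if alone)
    rr_pre[0] = rr_post[0] if len(r_arr) > 1 else spec.mean_rr
    rr_post[-1] = rr_pre[-1] if len(r_arr) > 1 else spec.mean_rr

    scales = (
        rng.normal(1.0, spec.amplitude_jitter_cv, size=len(r_arr))
        if spec.amplitude_jitter_cv > 0
        else np.ones(len(r_arr))
    )

    x = np.zeros(n)
    for i, r_time in enumerate(r_arr):
        for wave in _WAVE_ORDER:
            amp, c, w = spec.wave_params.waves[wave]
            rr = rr_pre[i] if c < 0 else rr_post[i]
            tc = r_time + c * rr / (2 * np.pi)
            tw = w * rr / (2 * np.pi)
            lo = max(0, int(np.floor((tc - 5 * tw) * spec.fs)))
            hi = min(n, int(np.ceil((tc + 5 * tw) * spec.fs)) + 1)
            if lo >= hi:
                continue
            x[lo:hi] += scales[i] * amp * np.exp(
                -0.5 * ((t[lo:hi] - tc) / tw) ** 2
            )

    aq, cq, wq = spec.wave_params.waves["Q"]
    at, ct, wt = spec.wave_params.waves["T"]
    q_times = r_arr + (cq - 3 * wq) * rr_pre / (2 * np.pi)
    t_off_times = r_arr + (ct + 3 * wt) * rr_post / (2 * np.pi)
    truth = GroundTruth(
        r_peaks=np.round(r_arr * spec.fs).astype(int),
        q_onsets=np.round(q_times * spec.fs).astype(int),
        t_offsets=np.round(t_off_times * spec.fs).astype(int),
        true_qt=t_off_times - q_times,
    )
    record = EcgRecord(x, spec.fs, ["synthetic"])
    return record, truth


def generate_clean_multilead(
    spec: SynthSpec, lead_waves: dict[str, WaveParams]
) -> tuple[EcgRecord, GroundTruth]:
    """Generate a multi-lead record: one morphology per lead, shared rhythm.

    All leads share the R-peak times and per-beat amplitude jitter (the
    random draws depend only on ``spec.seed``, not on the morphology), so
    the leads describe the same heart with different projections.  Ground
    truth landmarks are those of the first lead's morphology.
    """
    if not lead_waves:
        raise ValueError("need at least one lead")
    leads = []
    truth = None
    for name, waves in lead_waves.items():
        rec_i, truth_i = generate_clean(replace(spec, wave_params=waves))
        leads.append(rec_i.samples[0])
        if truth is None:
            truth = truth_i
    record = EcgRecord(np.vstack(leads), spec.fs, list(lead_waves))
    return record, truth


#: A second, lower-amplitude morphology for multi-lead synthesis.
LEAD_I_WAVES = WaveParams(
    {
        "P": (0.08, -1.00, 0.15),
        "Q": (-0.06, -0.12, 0.03),
        "R": (0.60, 0.00, 0.09),
        "S": (-0.12, 0.15, 0.04),
        "T": (0.22, 2.00, 0.12),
    }
)


def add_noise(
    record: EcgRecord, snr_db: float, seed: int
) -> tuple[EcgRecord, np.ndarray]:
    """Add white Gaussian noise, power-matched per lead to ``snr_db`` exactly.

    The drawn noise vector is rescaled so the realized sample powers satisfy
    ``10*log10(P_signal / P_noise) == snr_db`` to machine precision.  Returns
    the noisy record and the realized noise power (variance) per lead — the
    oracle value for noise-variance estimators.
    """
    if np.isinf(snr_db) and snr_db > 0:
        return record.copy_with(record.samples.copy()), np.zeros(record.n_leads)
    rng = np.random.default_rng(seed)
    out = np.empty_like(record.samples)
    v_realized = np.empty(record.n_leads)
    for i, x in enumerate(record.samples):
        p_sig = float(np.mean(x**2))
        if p_sig == 0:
            raise ValueError(f"lead {i} has zero power; finite SNR is undefined")
        n0 = rng.standard_normal(x.size)
        p_target = p_sig * 10 ** (-snr_db / 10)
        noise = n0 * np.sqrt(p_target / np.mean(n0**2))
        out[i] = x + noise
        v_realized[i] = p_target
    return record.copy_with(out), v_realized


def add_baseline_wander(
    record: EcgRecord, amplitude: float, freq: float = 0.3, seed: int = 0
) -> EcgRecord:
    """Add low-frequency drift: a sinusoid plus a smoothed random walk.

    ``amplitude`` (mV) sets the sinusoid amplitude; the random-walk component
    is normalised to 30% of it.  ``amplitude == 0`` returns the record
    unchanged.  Deterministic for fixed ``seed``.
    """
    if amplitude == 0:
        return record.copy_with(record.samples.copy())
    rng = np.random.default_rng(seed)
    t = np.arange(record.n_samples) / record.fs
    out = np.empty_like(record.samples)
    for i, x in enumerate(record.samples):
        phase0 = rng.uniform(0, 2 * np.pi)
        walk = np.cumsum(rng.standard_normal(record.n_samples))
        peak = np.max(np.abs(walk))
        if peak > 0:
            walk = walk / peak * 0.3 * amplitude
        out[i] = x + amplitude * np.sin(2 * np.pi * freq * t + phase0) + walk
    return record.copy_with(out)
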