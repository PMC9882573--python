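"""Data-driven Gaussian-process ECG filter in the beat phase domain.

Warping every beat onto a common phase axis with aligned R-peaks turns a
quasi-periodic record into an ensemble of draws from one process; under a
Gaussian assumption the process is fully described by the phase-domain
sample mean and sample covariance, so no kernel family or hyperparameter has
to be chosen by hand.  The measurement model is clean ECG plus white noise
of variance ``v_n``; subtracting the noise contribution from the phase
covariance yields the signal prior, and Gaussian conditioning gives the
per-beat posterior mean — the denoised beat — plus a posterior variance
quantifying the filter's confidence.

Two computational paths are provided:

* the **diagonal** path keeps only the phase variance vector; every beat is
  then filtered with element-wise operations (no matrix inversion), giving
  the per-sample gain form posterior = prior_mean + (k_s / k_x) * (x - prior_mean);
* the **full** path carries the complete phase covariance and solves the
  per-beat linear system of the general Gaussian posterior mean; it is the
  reference implementation, practical for modest beat lengths.

The noise variance is estimated from the isoelectric (PQ) segment before
each R-peak, where the heart is electrically silent and only noise remains,
or supplied directly when known (oracle mode, for simulation studies).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.linalg

from .phase import PhaseMap, backward, build_map, build_map_r_aligned, dense_theta, forward
from .records import EcgRecord
from .rpeaks import BeatSegmentation, detect_rpeaks, segment_beats

__all__ = [
    "PhaseEnsemble",
    "GpModel",
    "FilterResult",
    "build_ensemble",
    "fit",
    "estimate_noise_variance",
    "filter_beat_diag",
    "filter_beat_full",
    "filter_record",
    "auto_phase_length",
]

log = logging.getLogger("gpecg")


@dataclass(frozen=True)
class PhaseEnsemble:
    """Warped measurement beats stacked as a ``(B, T)`` matrix."""

    beats: np.ndarray
    beat_ids: np.ndarray

    def __post_init__(self) -> None:
        if self.beats.ndim != 2 or self.beats.shape[0] < 2:
            raise ValueError("ensemble needs at least 2 beats of equal phase length")
        if not np.isfinite(self.beats).all():
            raise ValueError("ensemble contains non-finite values")

    @property
    def n_beats(self) -> int:
        return self.beats.shape[0]

    @property
    def n_phase(self) -> int:
        return self.beats.shape[1]


@dataclass
class GpModel:
    """Learned phase-domain state: mean, (co)variance and noise variance.

    ``mode`` selects which covariance representation the filter uses:
    ``"diag"`` keeps the phase variance vector ``k_diag``; ``"full"`` keeps
    the complete sample covariance ``K_full`` (whose diagonal is ``k_diag``).
    """

    mu: np.ndarray
    k_diag: np.ndarray
    v_n: float
    mode: str = "diag"
    K_full: np.ndarray | None = None
    n_phase: int = 0
    r_phase: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("diag", "full"):
            raise ValueError(f"mode must be 'diag' or 'full', got {self.mode!r}")
        if np.any(self.k_diag < 0) or self.v_n < 0:
            raise ValueError("variances must be non-negative")
        if self.mode == "full" and self.K_full is None:
            raise ValueError("full mode requires K_full")
        self.n_phase = self.mu.size

    def save(self, path: str | Path) -> None:
        """Serialise the model state (mu, k_diag, v_n, T, r_phase) as JSON."""
        state = {
            "mu": self.mu.tolist(),
            "k_diag": self.k_diag.tolist(),
            "v_n": self.v_n,
            "mode": self.mode,
            "n_phase": self.n_phase,
            "r_phase": self.r_phase,
        }
        Path(path).write_text(json.dumps(state))

    @classmethod
    def load(cls, path: str | Path) -> "GpModel":
        state = json.loads(Path(path).read_text())
        return cls(
            mu=np.array(state["mu"]),
            k_diag=np.array(state["k_diag"]),
            v_n=state["v_n"],
            mode="diag",
            r_phase=state["r_phase"],
        )


@dataclass(frozen=True)
class FilterResult:
    """Prior- and posterior-based denoised signals with posterior variance.

    ``prior`` is the back-warped phase mean per beat (the template), and
    ``posterior`` the Gaussian conditional mean; ``post_var`` holds the
    per-sample posterior variance.  All arrays have the input's
    ``(leads, N)`` shape; ``models`` holds one fitted :class:`GpModel` per
    lead.
    """

    prior: np.ndarray
    posterior: np.ndarray
    post_var: np.ndarray
    models: list[GpModel] = field(default_factory=list)


def auto_phase_length(seg: BeatSegmentation) -> int:
    """Default phase length with 10% headroom.

    Covers the longest pre-R span plus the longest post-R span, so a common
    R-peak knot is always feasible (this is at least the longest beat).
    """
    lengths = seg.beat_lengths()
    span = int(seg.r_offset.max()) + int((lengths - seg.r_offset).max())
    return int(np.ceil(1.1 * span))


def _choose_r_phase(seg: BeatSegmentation, n_phase: int) -> int:
    """Common R-peak phase knot: median relative R position, clamped feasible."""
    lengths = seg.beat_lengths()
    n_pre = seg.r_offset
    n_post = lengths - seg.r_offset
    target = int(round(n_phase * float(np.median(n_pre / lengths))))
    lo = int(n_pre.max())
    hi = int(n_phase - n_post.max())
    if lo > hi:
        raise ValueError(
            f"phase length {n_phase} too short to R-align all beats "
            f"(need >= {n_pre.max() + n_post.max()})"
        )
    return int(np.clip(target, lo, hi))


def build_ensemble(
    x: np.ndarray,
    seg: BeatSegmentation,
    n_phase: int | None = None,
    alignment: str = "r_aligned",
) -> tuple[PhaseEnsemble, list[PhaseMap]]:
    """Warp every beat of one lead into the phase domain.

    ``alignment="r_aligned"`` (default) uses the two-segment map that pins
    each beat's R-peak to a common phase knot; ``"single"`` uses the plain
    equidistant map over the whole beat.

    Raises
    ------
    ValueError
        If any beat is longer than ``n_phase`` (the offending beat is
        named) or fewer than two beats are available.
    """
    x = np.asarray(x, dtype=float)
    if seg.n_beats < 2:
        raise ValueError("ensemble filtering requires at least 2 beats")
    if n_phase is None:
        n_phase = auto_phase_length(seg)
    lengths = seg.beat_lengths()
    too_long = np.flatnonzero(lengths > n_phase)
    if too_long.size:
        i = int(too_long[0])
        raise ValueError(
            f"beat {i} has {lengths[i]} samples > phase length {n_phase}"
        )
    if alignment == "r_aligned":
        r_phase = _choose_r_phase(seg, n_phase)
        maps = [
            build_map_r_aligned(
                int(seg.r_offset[i]),
                int(lengths[i] - seg.r_offset[i]),
                n_phase,
                r_phase,
            )
            for i in range(seg.n_beats)
        ]
    elif alignment == "single":
        maps = [build_map(int(n), n_phase) for n in lengths]
    else:
        raise ValueError(f"unknown alignment mode {alignment!r}")
    rows = np.stack(
        [forward(m, x[s:e]) for m, (s, e) in zip(maps, seg.bounds)]
    )
    return PhaseEnsemble(rows, np.arange(seg.n_beats)), maps


def fit(
    ens: PhaseEnsemble,
    mode: str = "diag",
    v_n: float | None = None,
    ddof: int = 0,
) -> GpModel:
    """Phase-domain sample statistics of the warped beat ensemble.

    The mean is ``mu = B^-1 sum xi_i`` and the covariance the (biased,
    ``ddof=0``) sample covariance ``B^-1 sum (xi_i - mu)(xi_i - mu)^T``;
    ``ddof=1`` switches to the unbiased normalisation.  In diagonal mode only
    the variance vector is retained.  ``v_n`` may be attached now or set
    later (e.g. from :func:`estimate_noise_variance`).
    """
    b = ens.n_beats
    if b - ddof < 1:
        raise ValueError("not enough beats for the requested normalisation")
    mu = ens.beats.mean(axis=0)
    centered = ens.beats - mu
    k_diag = np.einsum("bt,bt->t", centered, centered) / (b - ddof)
    k_full = None
    if mode == "full":
        k_full = centered.T @ centered / (b - ddof)
    r_phase = None
    return GpModel(
        mu=mu,
        k_diag=k_diag,
        v_n=0.0 if v_n is None else float(v_n),
        mode=mode,
        K_full=k_full,
        r_phase=r_phase,
    )


def estimate_noise_variance(
    x: np.ndarray,
    seg: BeatSegmentation,
    fs: float,
    method: str = "baseline",
    window: tuple[float, float] = (0.06, 0.02),
    v_oracle: float | None = None,
) -> float:
    """Noise variance from the isoelectric segment before each R-peak.

    ``method="baseline"``: for every beat, take the window from
    ``window[0]`` to ``window[1]`` seconds before the R-peak (the PQ
    segment, default 60–20 ms).  The across-beat mean window profile is
    subtracted first — any deterministic ECG content reaching into the
    window (Q-wave onset, filter smearing) repeats every beat and would
    otherwise bias the estimate up — then each beat's residual is linearly
    detrended and its unbiased variance averaged over beats.  Beats whose
    window leaves the record (or is shorter than 4 samples) are skipped.
    ``method="oracle"`` returns ``v_oracle`` unchanged.

    Raises
    ------
    ValueError
        If every beat's window is unusable, or oracle mode lacks a value.
    """
    if method == "oracle":
        if v_oracle is None:
            raise ValueError("oracle method requires v_oracle")
        return float(v_oracle)
    if method != "baseline":
        raise ValueError(f"unknown noise-variance method {method!r}")
    x = np.asarray(x, dtype=float)
    w0 = int(round(window[0] * fs))
    w1 = int(round(window[1] * fs))
    if w0 <= w1 or w0 - w1 < 4:
        raise ValueError("window must span >= 4 samples before the R-peak")
    windows = []
    for r in seg.r_peaks:
        lo, hi = r - w0, r - w1
        if lo < 0 or hi > x.size:
            continue
        windows.append(x[lo:hi])
    if not windows:
        raise ValueError("no usable isoelectric window in any beat")
    w = np.stack(windows)
    b, n = w.shape
    dof = n - 2
    if b > 1:
        # per-beat scaled template: beats may carry the window content at
        # slightly different amplitudes (beat-to-beat morphology scaling)
        m = w.mean(axis=0)
        mm = float(m @ m)
        if mm > 0:
            alpha = (w @ m) / mm
            resid = w - alpha[:, None] * m
            dof = n - 3
        else:
            resid = w - m
    else:
        resid = w
    t = np.arange(n, dtype=float)
    coef = np.polynomial.polynomial.polyfit(t, resid.T, 1)
    resid = resid - np.polynomial.polynomial.polyval(t, coef).reshape(resid.shape)
    per_beat = np.einsum("bn,bn->b", resid, resid) / max(dof, 1)
    v = float(per_beat.mean())
    if b > 1:
        v *= b / (b - 1)  # template subtraction removes 1/b of the noise
    return v


def filter_beat_diag(
    x_i: np.ndarray, pmap: PhaseMap, model: GpModel
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Filter one beat with element-wise (diagonal-covariance) operations.

    Back-maps the phase statistics through the beat's warping map —
    ``mu_s = (Theta^T mu) / g``, ``k_x = (Theta^T k_diag) / g^2``,
    ``k_s = (Theta^T (k_diag - v_n)) / g^2`` clamped at zero — and applies
    the scalar-gain posterior mean ``s_hat = mu_s + (k_s / k_x) * (x - mu_s)``.
    Samples with ``k_x == 0`` get gain 0 (prior passthrough).

    Returns ``(s_hat, mu_s, k_post)`` with the per-sample posterior variance
    ``k_post = k_s * (1 - k_s / k_x)``.
    """
    if model.mode != "diag":
        raise ValueError("filter_beat_diag requires a diagonal-mode model")
    x_i = np.asarray(x_i, dtype=float)
    if x_i.size != pmap.n_time:
        raise ValueError("beat length does not match its phase map")
    g = pmap.g.astype(float)
    mu_s = backward(pmap, model.mu)
    k_x = np.bincount(pmap.assign, weights=model.k_diag, minlength=pmap.n_time) / g**2
    k_s = (
        np.bincount(
            pmap.assign, weights=model.k_diag - model.v_n, minlength=pmap.n_time
        )
        / g**2
    )
    k_s = np.maximum(k_s, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        gain = np.where(k_x > 0, k_s / k_x, 0.0)
    if np.any(k_x == 0):
        log.debug("degenerate zero-variance samples: gain set to 0 (prior passthrough)")
    # convex-combination form: exact at both limits (gain 1 -> x, gain 0 -> prior)
    s_hat = gain * x_i + (1.0 - gain) * mu_s
    k_post = k_s * (1.0 - gain)
    return s_hat, mu_s, k_post


def filter_beat_full(
    x_i: np.ndarray, pmap: PhaseMap, model: GpModel, cond_threshold: float = 1e12
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Filter one beat with the full-covariance Gaussian posterior mean.

    Back-maps the full phase covariance (``K_x = Psi K Psi^T``, signal part
    with the warped noise covariance subtracted) and solves the per-beat
    system — never inverting explicitly.  Ill-conditioned systems get an
    escalating ridge jitter (``1e-10 * trace / N`` doubled up to 6 times,
    logged) before failing.

    Returns ``(s_hat, mu_s, k_post)`` where ``k_post`` is the diagonal of
    the posterior covariance, clipped at zero.
    """
    if model.mode != "full" or model.K_full is None:
        raise ValueError("filter_beat_full requires a full-mode model")
    x_i = np.asarray(x_i, dtype=float)
    if x_i.size != pmap.n_time:
        raise ValueError("beat length does not match its phase map")
    theta = dense_theta(pmap)
    psi = theta.T / pmap.g[:, None]
    mu_s = psi @ model.mu
    k_bar = model.K_full
    k_x = psi @ k_bar @ psi.T
    k_s = psi @ (k_bar - model.v_n * (theta @ theta.T)) @ psi.T
    k_x = 0.5 * (k_x + k_x.T)
    base_jitter = 1e-10 * np.trace(k_x) / max(pmap.n_time, 1)
    jitter = 0.0
    resid = x_i - mu_s
    for attempt in range(7):
        try:
            a = k_x + jitter * np.eye(pmap.n_time)
            if np.linalg.cond(a) > cond_threshold:
                raise np.linalg.LinAlgError("condition number above threshold")
            cho = scipy.linalg.cho_factor(a)
            w = scipy.linalg.cho_solve(cho, resid)
            kxinv_ks = scipy.linalg.cho_solve(cho, k_s.T)
            break
        except (np.linalg.LinAlgError, scipy.linalg.LinAlgError):
            jitter = base_jitter * 2**attempt
            log.debug("ill-conditioned beat covariance; jitter raised to %.3e", jitter)
    else:
        raise np.linalg.LinAlgError("beat covariance singular after maximum jitter")
    s_hat = mu_s + k_s @ w
    k_post_mat = k_s - k_s @ kxinv_ks
    k_post = np.clip(np.diag(k_post_mat), 0.0, None)
    return s_hat, mu_s, k_post


def filter_record(
    record: EcgRecord,
    seg: BeatSegmentation | None = None,
    n_phase: int | None = None,
    mode: str = "diag",
    v_n: float | np.ndarray | None = None,
    alignment: str = "r_aligned",
    exclude_edge_beats: bool = False,
) -> FilterResult:
    """Denoise a whole record, lead by lead.

    Per lead: warp all beats into the phase domain, fit the phase statistics,
    estimate the noise variance from the isoelectric segments (unless ``v_n``
    is supplied — a scalar, or one value per lead), filter every beat, and
    concatenate the beats back in order (the midpoint segmentation partitions
    the record, so lengths are preserved exactly).  When ``seg`` is omitted,
    R-peaks are detected on the first lead.

    ``exclude_edge_beats`` drops the (possibly partial) first and last beats
    from the model fit; they are still filtered.
    """
    if seg is None:
        r = detect_rpeaks(record.lead(0), record.fs)
        seg = segment_beats(r, record.n_samples)
    v_per_lead: list[float | None]
    if v_n is None:
        v_per_lead = [None] * record.n_leads
    else:
        v_arr = np.atleast_1d(np.asarray(v_n, dtype=float))
        if v_arr.size == 1:
            v_per_lead = [float(v_arr[0])] * record.n_leads
        elif v_arr.size == record.n_leads:
            v_per_lead = [float(v) for v in v_arr]
        else:
            raise ValueError("v_n must be a scalar or one value per lead")

    prior = np.empty_like(record.samples)
    posterior = np.empty_like(record.samples)
    post_var = np.empty_like(record.samples)
    models: list[GpModel] = []
    for lead in range(record.n_leads):
        x = record.samples[lead]
        try:
            ens, maps = build_ensemble(x, seg, n_phase, alignment)
            fit_ens = ens
            if exclude_edge_beats and ens.n_beats > 3:
                fit_ens = PhaseEnsemble(ens.beats[1:-1], ens.beat_ids[1:-1])
            model = fit(fit_ens, mode=mode)
            model.v_n = (
                estimate_noise_variance(x, seg, record.fs)
                if v_per_lead[lead] is None
                else v_per_lead[lead]
            )
            model.r_phase = maps[0].r_phase
            beat_filter = filter_beat_diag if mode == "diag" else filter_beat_full
            for (s, e), pmap in zip(seg.bounds, maps):
                s_hat, mu_s, k_post = beat_filter(x[s:e], pmap, model)
                posterior[lead, s:e] = s_hat
                prior[lead, s:e] = mu_s
                post_var[lead, s:e] = k_post
        except Exception as err:
            raise type(err)(f"lead {record.lead_names[lead]}: {err}") from err
        models.append(model)
    return FilterResult(prior=prior, posterior=posterior, post_var=post_var, models=models)
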