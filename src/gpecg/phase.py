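"""Per-beat time↔phase warping.

Every heartbeat, of time-domain length ``N``, is mapped onto a fixed phase
length ``T >= N`` by a binary warping matrix ``Theta`` (shape ``T x N``) with
exactly one 1 per row: phase knot ``k`` replicates time sample ``j(k)``, where
the knots are spread equidistantly over the beat,

    j(k) = floor(k * (N - 1) / (T - 1)),          k = 0, ..., T - 1

(0-based here; the field's convention writes the same rule 1-based).  The last
knot is closed onto the last sample so that every time sample receives at
least one knot, which makes the Gramian ``G = Theta^T Theta = diag(g)``
invertible; ``g`` counts knots per sample.  The back-transformation is the
scatter-average ``Psi = G^-1 Theta^T``, so a time→phase→time round trip is
exact: replicated samples are averaged back to themselves.

``Theta`` is never materialised in production paths — the assignment vector
``assign`` carries its full information content.  :func:`dense_theta` builds
the explicit matrix for tests and inspection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PhaseMap",
    "build_map",
    "build_map_r_aligned",
    "forward",
    "backward",
    "dense_theta",
]


@dataclass(frozen=True)
class PhaseMap:
    """A beat's time→phase assignment and its Gramian counts.

    Attributes
    ----------
    n_time : int
        Beat length ``N`` in the time domain.
    n_phase : int
        Fixed phase length ``T``.
    assign : ndarray of int, shape (T,)
        ``assign[k]`` is the 0-based time index replicated at phase knot ``k``;
        non-decreasing and surjective onto ``{0, ..., N-1}``.
    g : ndarray of int, shape (N,)
        Knots per time sample (diagonal of the Gramian); all ``>= 1`` and
        summing to ``T``.
    r_phase : int or None
        Phase knot holding the R-peak, when built R-aligned.
    """

    n_time: int
    n_phase: int
    assign: np.ndarray
    g: np.ndarray
    r_phase: int | None = None

    def __post_init__(self) -> None:
        if self.assign.shape != (self.n_phase,):
            raise ValueError("assign length must equal n_phase")
        if self.g.shape != (self.n_time,):
            raise ValueError("g length must equal n_time")


def _equidistant_assign(n_time: int, n_phase: int) -> np.ndarray:
    k = np.arange(n_phase)
    j = (k * (n_time - 1)) // (n_phase - 1)
    return j.astype(np.intp)


def build_map(n_time: int, n_phase: int) -> PhaseMap:
    """Equidistant-knot warping map for a beat of ``n_time`` samples.

    Requires ``n_phase >= n_time >= 2``; with fewer knots than samples the
    Gramian would lose rank and the back-transformation would not exist.
    """
    if n_time < 2:
        raise ValueError(f"beat must have at least 2 samples, got {n_time}")
    if n_phase < n_time:
        raise ValueError(
            f"phase length {n_phase} < beat length {n_time}: Gramian would be singular"
        )
    assign = _equidistant_assign(n_time, n_phase)
    g = np.bincount(assign, minlength=n_time)
    return PhaseMap(n_time, n_phase, assign, g)


def build_map_r_aligned(
    n_pre: int, n_post: int, n_phase: int, r_phase: int
) -> PhaseMap:
    """Two-segment warping map pinning the R-peak to a fixed phase knot.

    The beat has ``n_pre`` samples strictly before the R-peak and ``n_post``
    samples from the R-peak (inclusive) to the beat end.  The pre-R segment
    (samples ``0..n_pre``, R included as its last sample) is warped onto phase
    knots ``0..r_phase`` and the post-R segment (samples ``n_pre..N-1``) onto
    knots ``r_phase..T-1``, each with the equidistant-knot rule, so the R-peak
    sample lands exactly on knot ``r_phase`` for every beat.

    Parameters use 0-based indices: ``r_phase`` is the 0-based phase knot of
    the R-peak.  Requires ``r_phase + 1 >= n_pre + 1`` and
    ``n_phase - r_phase >= n_post`` (the per-segment knots-vs-samples
    condition).
    """
    n_time = n_pre + n_post
    if n_post < 1:
        raise ValueError("beat must contain its R-peak (n_post >= 1)")
    if n_time < 2:
        raise ValueError(f"beat must have at least 2 samples, got {n_time}")
    t_pre = r_phase + 1  # knots 0..r_phase, R-peak at the last one
    t_post = n_phase - r_phase  # knots r_phase..T-1, R-peak at the first one
    if t_pre < n_pre + 1:
        raise ValueError(
            f"r_phase={r_phase} leaves {t_pre} pre-R knots for {n_pre + 1} samples"
        )
    if t_post < n_post:
        raise ValueError(
            f"r_phase={r_phase} leaves {t_post} post-R knots for {n_post} samples"
        )
    pre = _segment_assign(n_pre + 1, t_pre)  # maps onto samples 0..n_pre
    post = _segment_assign(n_post, t_post) + n_pre  # samples n_pre..N-1
    # both segments place the R-peak at knot r_phase; keep one copy
    assign = np.concatenate([pre[:-1], post])
    g = np.bincount(assign, minlength=n_time)
    return PhaseMap(n_time, n_phase, assign, g, r_phase=r_phase)


def _segment_assign(n_time: int, n_phase: int) -> np.ndarray:
    """Equidistant assignment tolerating degenerate single-sample segments."""
    if n_time == 1:
        return np.zeros(n_phase, dtype=np.intp)
    return _equidistant_assign(n_time, n_phase)


def forward(pmap: PhaseMap, x: np.ndarray) -> np.ndarray:
    """Warp a time-domain beat to the phase domain (gather, ``Theta @ x``).

    Pure sample replication — no interpolation.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (pmap.n_time,):
        raise ValueError(f"expected beat of length {pmap.n_time}, got {x.shape}")
    return x[pmap.assign]


def backward(pmap: PhaseMap, xi: np.ndarray) -> np.ndarray:
    """Warp a phase-domain beat back to time (scatter-average, ``Psi @ xi``).

    ``backward(forward(x)) == x`` exactly: each sample is the mean of its own
    identical replicas.
    """
    xi = np.asarray(xi, dtype=float)
    if xi.shape != (pmap.n_phase,):
        raise ValueError(f"expected phase beat of length {pmap.n_phase}, got {xi.shape}")
    sums = np.bincount(pmap.assign, weights=xi, minlength=pmap.n_time)
    return sums / pmap.g


def dense_theta(pmap: PhaseMap) -> np.ndarray:
    """Explicit dense warping matrix ``Theta`` (shape ``T x N``) — tests only."""
    theta = np.zeros((pmap.n_phase, pmap.n_time))
    theta[np.arange(pmap.n_phase), pmap.assign] = 1.0
    return theta
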