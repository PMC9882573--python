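"""Time↔phase warping: hand-derived maps, matrix identities, round trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gpecg import backward, build_map, build_map_r_aligned, dense_theta, forward


def test_equidistant_map_hand_example():
    m = build_map(3, 5)
    assert m.assign.tolist() == [0, 0, 1, 1, 2]
    assert m.g.tolist() == [2, 2, 1]


def test_identity_map_when_lengths_match():
    m = build_map(7, 7)
    assert m.assign.tolist() == list(range(7))
    assert m.g.tolist() == [1] * 7
    x = np.arange(7.0)
    assert np.array_equal(backward(m, forward(m, x)), x)


def test_forward_gather_examples():
    m = build_map(3, 5)
    assert forward(m, np.array([1.0, 2.0, 3.0])).tolist() == [1, 1, 2, 2, 3]
    assert forward(m, np.array([0.0, 1.0, 0.0])).tolist() == [0, 0, 1, 1, 0]
    assert np.all(forward(m, np.full(3, 4.2)) == 4.2)


def test_backward_scatter_average_example():
    m = build_map(3, 5)
    assert backward(m, np.array([1.0, 3.0, 2.0, 4.0, 5.0])).tolist() == [2, 3, 5]
    assert np.all(backward(m, np.full(5, 1.7)) == 1.7)


def test_r_aligned_hand_example():
    # 2 samples before R, 3 from R on, 7 phase knots, R pinned at knot 2
    m = build_map_r_aligned(2, 3, 7, 2)
    assert m.assign.tolist() == [0, 1, 2, 2, 3, 3, 4]
    assert m.g.tolist() == [1, 1, 2, 2, 1]
    assert m.g.sum() == 7
    assert m.assign[m.r_phase] == 2  # R-peak time index


def test_r_aligned_pins_r_for_varying_beat_lengths():
    r_phase = 10
    for n_pre, n_post in [(3, 5), (6, 8), (9, 11), (10, 10)]:
        m = build_map_r_aligned(n_pre, n_post, 21, r_phase)
        assert m.assign[r_phase] == n_pre
        x = np.zeros(n_pre + n_post)
        x[n_pre] = 5.0
        assert forward(m, x)[r_phase] == 5.0


@pytest.mark.parametrize(
    "n,t",
    [(2, 2), (2, 7), (3, 5), (5, 5), (7, 23), (13, 40), (30, 120), (29, 31)],
)
def test_gramian_identities_against_dense_oracle(n, t):
    """Theta^T Theta diagonal positive; diag(Theta Theta^T) all ones;
    matrix-free forward/backward agree with the dense-matrix oracle."""
    m = build_map(n, t)
    theta = dense_theta(m)
    gram = theta.T @ theta
    assert np.array_equal(gram, np.diag(m.g))
    assert np.all(m.g >= 1)
    assert np.array_equal(np.diag(theta @ theta.T), np.ones(t))
    # assignment is monotone and surjective
    assert np.all(np.diff(m.assign) >= 0)
    assert set(m.assign.tolist()) == set(range(n))

    rng = np.random.default_rng(n * 1000 + t)
    x = rng.normal(size=n)
    assert np.allclose(forward(m, x), theta @ x, rtol=0, atol=0)
    xi = rng.normal(size=t)
    psi = theta.T / m.g[:, None]
    assert np.allclose(backward(m, xi), psi @ xi, rtol=1e-14, atol=1e-14)


@settings(deadline=None, max_examples=60)
@given(
    n=st.integers(2, 25),
    extra=st.integers(0, 60),
    data=st.data(),
)
def test_round_trip_is_exact(n, extra, data):
    """backward(forward(x)) == x bit-exactly for integer-valued beats."""
    m = build_map(n, n + extra)
    x = np.array(data.draw(st.lists(st.integers(-50, 50), min_size=n, max_size=n)), float)
    assert np.array_equal(backward(m, forward(m, x)), x)


def test_invalid_maps_and_length_mismatches():
    with pytest.raises(ValueError):
        build_map(5, 4)  # fewer knots than samples: singular Gramian
    with pytest.raises(ValueError):
        build_map(1, 5)
    with pytest.raises(ValueError):
        build_map_r_aligned(5, 5, 8, 4)  # not enough knots per segment
    m = build_map(3, 5)
    with pytest.raises(ValueError):
        forward(m, np.zeros(4))
    with pytest.raises(ValueError):
        backward(m, np.zeros(4))
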