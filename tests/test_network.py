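import json
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from annl.network import (
    FeatureScale,
    NetworkSpec,
    decode,
    encode,
    forward,
    load_model,
    risk_score,
    save_model,
    sigmoid,
)


@pytest.mark.parametrize("m,h,p", [(3, 3, 13), (4, 2, 11), (6, 2, 15)])
def test_weight_count_formula(m, h, p):
    assert NetworkSpec(m, h).n_weights == p


@pytest.mark.parametrize("m,h", [(3, 3), (4, 2), (6, 2), (1, 1)])
def test_weight_index_map_is_a_bijection(m, h):
    spec = NetworkSpec(m, h)
    indices = [
        spec.hidden_weight_index(i, j)
        for i in range(1, m + 1)
        for j in range(1, h + 1)
    ]
    indices += [spec.output_weight_index(j) for j in range(1, h + 1)]
    indices.append(spec.bias_index)
    assert sorted(indices) == list(range(1, spec.n_weights + 1))


def test_weight_index_map_matches_input_major_layout():
    # 3x3 net: input 2 reaches hidden node 1 through the 4th weight
    spec = NetworkSpec(3, 3)
    assert spec.hidden_weight_index(1, 1) == 1
    assert spec.hidden_weight_index(2, 1) == 4
    assert spec.hidden_weight_index(3, 1) == 7
    assert spec.output_weight_index(1) == 10
    assert spec.bias_index == 13


def test_encode_endpoints_and_midpoint():
    s = FeatureScale("BMI", 10.0, 30.0)
    assert encode(10.0, s) == 0.0
    assert encode(30.0, s) == 1.0
    assert encode(20.0, s) == 0.5
    # out-of-range values clip into [0, 1]
    assert encode(5.0, s) == 0.0
    assert encode(35.0, s) == 1.0


def test_decode_endpoints():
    s = FeatureScale("x", -2.0, 6.0)
    assert decode(0.0, s) == -2.0
    assert decode(1.0, s) == 6.0


def test_degenerate_scale_rejected():
    with pytest.raises(ValueError, match="constant feature"):
        FeatureScale("flat", 3.0, 3.0)


@settings(derandomize=True, max_examples=200)
@given(
    lo=st.floats(-1e3, 1e3),
    width=st.floats(1e-3, 1e3),
    frac=st.floats(0.0, 1.0),
)
def test_coding_roundtrip_identity(lo, width, frac):
    s = FeatureScale("f", lo, lo + width)
    x = lo + frac * width
    # tolerance is relative to the feature scale: a value near zero inside
    # a wide interval cannot round-trip to its own tiny magnitude
    assert decode(encode(x, s), s) == pytest.approx(
        x, rel=1e-12, abs=1e-12 * max(abs(lo), width)
    )
    # the inverse direction is conditioned by |lo| / width
    assert encode(decode(frac, s), s) == pytest.approx(
        frac, rel=1e-12, abs=1e-12 * max(1.0, abs(lo) / width)
    )


def test_sigmoid_values_and_stability():
    assert sigmoid(0.0) == 0.5
    assert sigmoid(3.0) == pytest.approx(0.952574, abs=5e-7)
    assert sigmoid(700.0) == pytest.approx(1.0)
    assert sigmoid(-700.0) == pytest.approx(0.0, abs=1e-300)


@settings(derandomize=True, max_examples=100)
@given(z=st.floats(-500, 500))
def test_sigmoid_symmetry(z):
    assert sigmoid(-z) == pytest.approx(1.0 - sigmoid(z), abs=1e-12)


def test_forward_all_zero_weights_gives_half():
    spec = NetworkSpec(3, 3)
    assert forward(spec, np.zeros(13), np.array([0.3, 0.9, 0.1])) == 0.5


def test_forward_matches_scalar_hand_calculation():
    # independent scalar oracle: hidden = s(1+1+1), out = s(3*hidden + 1)
    def s(z):
        return 1.0 / (1.0 + math.exp(-z))

    expected = s(3 * s(3.0) + 1.0)
    spec = NetworkSpec(3, 3)
    got = forward(spec, np.ones(13), np.ones(3))
    assert got == pytest.approx(expected, abs=1e-12)
    assert got == pytest.approx(0.979321, abs=5e-7)


def test_perturbing_one_hidden_weight_moves_one_hidden_node():
    # weights W1 and W4 both feed hidden node 1 (inputs 1 and 2); a network
    # whose output taps only hidden node 1 must respond, one tapping only
    # hidden node 2 must not.
    spec = NetworkSpec(3, 3)
    x = np.array([1.0, 1.0, 1.0])
    for idx in (spec.hidden_weight_index(1, 1), spec.hidden_weight_index(2, 1)):
        for tapped, expect_change in ((1, True), (2, False)):
            w = np.zeros(13)
            w[spec.output_weight_index(tapped) - 1] = 1.0
            base = forward(spec, w, x)
            w[idx - 1] = 0.7
            changed = forward(spec, w, x) != base
            assert changed is expect_change


def test_forward_monotone_in_bias_weight():
    spec = NetworkSpec(4, 2)
    rng = np.random.default_rng(5)
    w = rng.normal(size=11)
    x = rng.random(4)
    outs = []
    for b in (-1.0, 0.0, 1.0):
        w[-1] = b
        outs.append(forward(spec, w, x))
    assert outs[0] < outs[1] < outs[2]


def test_forward_shape_errors():
    spec = NetworkSpec(3, 3)
    with pytest.raises(ValueError, match="shape error"):
        forward(spec, np.zeros(12), np.zeros(3))
    with pytest.raises(ValueError, match="shape error"):
        forward(spec, np.zeros(13), np.zeros(4))


def test_risk_score():
    assert risk_score([0.2, 0.8]) == 0.5
    assert risk_score([0.37]) == 0.37
    assert risk_score(np.full(10, 0.25)) == 0.25
    with pytest.raises(ValueError, match="no subjects"):
        risk_score([])


def test_model_json_roundtrip(tmp_path):
    spec = NetworkSpec(6, 2)
    w = np.linspace(-1, 1, 15)
    scales = [FeatureScale(f"f{i}", 0.0, float(i + 1)) for i in range(6)]
    path = tmp_path / "model.json"
    save_model(path, spec, w, scales)
    doc = json.loads(path.read_text())
    assert doc["spec"] == {"m": 6, "h": 2}
    spec2, w2, scales2 = load_model(path)
    assert spec2 == spec
    np.testing.assert_allclose(w2, w)
    assert [s.name for s in scales2] == [s.name for s in scales]
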