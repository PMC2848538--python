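import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mbpkit.chains import (
    chain_bounds,
    predict_mbp_length,
    predicted_rank_frequency,
    shortest_addition_chain,
)


@pytest.mark.parametrize("j,elements", [
    (1, 1), (2, 2), (16, 5), (17, 6), (18, 6), (31, 8), (128, 8),
    # classic awkward targets with known optimal operation counts
    (15, 6), (23, 7), (127, 11), (191, 12),
])
def test_shortest_chain_known_lengths(j, elements):
    rec = shortest_addition_chain(j)
    assert rec.n_elements == elements
    assert rec.n_operations == elements - 1
    assert rec.is_valid()


def test_target_128_is_seven_doublings():
    rec = shortest_addition_chain(128)
    assert rec.n_operations == 7
    assert rec.sequence == (1, 2, 4, 8, 16, 32, 64, 128)


def test_guard_range():
    with pytest.raises(ValueError):
        shortest_addition_chain(0)
    with pytest.raises(ValueError):
        shortest_addition_chain(10_001)


@pytest.mark.parametrize("j", list(range(1, 101)) + [113, 127, 128, 191, 255, 256])
def test_bounds_bracket_the_oracle(j):
    rec = shortest_addition_chain(j)
    b = chain_bounds(j)
    assert b["lower_elements"] <= rec.n_elements <= b["upper_elements"]


@pytest.mark.parametrize("k", range(1, 9))
def test_powers_of_two_are_tight(k):
    b = chain_bounds(2**k)
    assert b["lower_elements"] == b["upper_elements"] == k + 1
    assert shortest_addition_chain(2**k).n_elements == k + 1


@pytest.mark.parametrize("j", list(range(1, 65)) + [95, 127])
def test_subtraction_never_lengthens(j):
    plain = shortest_addition_chain(j)
    sub = shortest_addition_chain(j, allow_subtraction=True)
    assert sub.n_elements <= plain.n_elements
    assert sub.is_valid()


def test_subtraction_helps_below_powers_of_two():
    # 127 = 128 - 1: one subtraction beats the long pure-addition route
    assert shortest_addition_chain(127, allow_subtraction=True).n_operations == 8
    assert shortest_addition_chain(127).n_operations == 10


@pytest.mark.parametrize("j", [64, 128, 256])
def test_logarithmic_growth(j):
    rec = shortest_addition_chain(j)
    assert rec.n_operations / math.log2(j) == pytest.approx(1.0, abs=0.15)


@pytest.mark.parametrize("i,j,expected", [
    (9, 7, 5.977), (9, 6, 2.585), (1, 128, 7.0), (5, 5, 0.0), (12, 18, 2.585),
])
def test_predictor_values(i, j, expected):
    assert predict_mbp_length(i, j).predicted == pytest.approx(expected, abs=1e-3)


@given(st.integers(1, 40), st.integers(1, 40), st.integers(1, 6))
@settings(max_examples=60, deadline=None, derandomize=True)
def test_predictor_gcd_invariance(i, j, c):
    base = predict_mbp_length(i, j).predicted
    scaled = predict_mbp_length(c * i, c * j).predicted
    assert scaled == pytest.approx(base, abs=1e-9)


def test_rank_frequency_prediction():
    e = predicted_rank_frequency(2)
    assert e == pytest.approx([2 / 3, 1 / 3])
    e = predicted_rank_frequency(90)
    assert e.sum() == pytest.approx(1.0)
    # exact harmonic decay has log-log slope -1
    from mbpkit.usage import UsageTable, fit_power_law

    fit = fit_power_law(UsageTable("reaction", {k: float(v) for k, v in
                                                enumerate(e)}))
    assert fit.exponent == pytest.approx(-1.0, abs=0.02)
    with pytest.raises(ValueError):
        predicted_rank_frequency(0)
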