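import math

import numpy as np
import pandas as pd
import pytest

from dp4stereo.dp4 import (
    DP4Parameters,
    NucleusTypeParameters,
    TTriplet,
    dp4plus_probability,
    load_parameters,
    nucleus_likelihood,
    rank_by_probability,
    save_parameters,
)
from dp4stereo.scaling import CandidateEvaluation

from conftest import student_t_cdf_quadrature


def _triplet(nu=3.0, mu=0.0, sigma=2.0):
    return TTriplet(nu, mu, sigma)


def test_likelihood_at_center_is_half():
    for nu, sigma in [(3, 2), (10, 0.15), (1.5, 7)]:
        assert nucleus_likelihood(0.7, TTriplet(nu, 0.7, sigma)) == pytest.approx(0.5)


def test_likelihood_tail_decay_and_derived_value():
    assert nucleus_likelihood(100.0, _triplet()) < 1e-3  # t = 50
    # 1 - T_3(2), checked against an independent quadrature oracle
    expected = 1 - student_t_cdf_quadrature(2.0, 3.0)
    assert expected == pytest.approx(0.0697, abs=5e-5)
    assert nucleus_likelihood(4.0, _triplet()) == pytest.approx(expected, abs=1e-10)


def test_likelihood_symmetric_in_error_sign():
    trip = _triplet(mu=0.0)
    assert nucleus_likelihood(-4.0, trip) == pytest.approx(nucleus_likelihood(4.0, trip))
    with pytest.raises(ValueError):
        nucleus_likelihood(float("nan"), trip)


def _eval(cid, errors, hybridizations=None, element="C"):
    n = len(errors)
    hyb = hybridizations or ["sp3"] * n
    table = pd.DataFrame(
        {
            "label": [f"{element}{i}" for i in range(n)],
            "element": [element] * n,
            "hybridization": hyb,
            "delta_exp": np.linspace(10, 100, n),
            "sigma": np.zeros(n),
            "delta_scaled": np.zeros(n),
            "e_scaled": np.asarray(errors, float),
            "delta_unscaled": np.zeros(n),
            "e_unscaled": np.asarray(errors, float),
        }
    )
    return CandidateEvaluation(cid, table, {})


def _params(nu=3.0, sigma=2.0):
    block = NucleusTypeParameters(
        scaled=TTriplet(nu, 0.0, sigma),
        unscaled_sp2=TTriplet(nu, 0.0, sigma),
        unscaled_sp3=TTriplet(nu, 0.0, sigma),
    )
    return DP4Parameters(proton=block, carbon=block)


def test_single_candidate_probability_is_one():
    result = dp4plus_probability([_eval("a", [1.0, 2.0])], _params())
    for ch in result.channels:
        assert result.probabilities[ch]["a"] == pytest.approx(1.0)


def test_identical_candidates_split_uniformly():
    result = dp4plus_probability([_eval("a", [1.0, 2.0]), _eval("b", [1.0, 2.0])], _params())
    for ch in result.channels:
        assert result.probabilities[ch]["a"] == pytest.approx(0.5)


def test_two_candidate_derived_probability():
    """One sp3 carbon, scaled channel, nu=3, sigma=2, errors 1 vs 4.

    Terms 1-T3(0.5) and 1-T3(2) computed by the independent quadrature
    oracle normalize to 0.8238 / 0.1762.
    """
    t1 = 1 - student_t_cdf_quadrature(0.5, 3.0)
    t2 = 1 - student_t_cdf_quadrature(2.0, 3.0)
    expected = t1 / (t1 + t2)
    result = dp4plus_probability(
        [_eval("a", [1.0]), _eval("b", [4.0])], _params(), channels=["13C_scaled"]
    )
    probs = result.probabilities["13C_scaled"]
    assert probs["a"] == pytest.approx(expected, abs=1e-10)
    assert probs["a"] == pytest.approx(0.8238, abs=1e-4)
    assert probs["b"] == pytest.approx(1 - expected, abs=1e-10)


def test_three_candidates_renormalize_with_tie():
    result = dp4plus_probability(
        [_eval("a", [1.0]), _eval("b", [4.0]), _eval("c", [4.0])],
        _params(),
        channels=["13C_scaled"],
    )
    t1 = 1 - student_t_cdf_quadrature(0.5, 3.0)
    t2 = 1 - student_t_cdf_quadrature(2.0, 3.0)
    probs = result.probabilities["13C_scaled"]
    assert probs["a"] == pytest.approx(t1 / (t1 + 2 * t2), abs=1e-10)
    ranked = rank_by_probability(result, "13C_scaled")
    assert [r.candidate_id for r in ranked] == ["a", "b", "c"]
    assert not ranked[0].tied and ranked[1].tied and ranked[2].tied


def test_log_space_matches_direct_product_oracle():
    """Log-space probabilities agree with a direct product of independently
    evaluated Student-t CDF terms to 1e-9 on a 4-candidate, 10-nucleus case."""
    rng = np.random.default_rng(8)
    nu, sigma = 4.0, 1.5
    errors = {cid: rng.normal(0, 2, 10) for cid in "abcd"}
    hyb = list(rng.choice(["sp2", "sp3"], 10))
    evals = [_eval(cid, errors[cid], hyb) for cid in "abcd"]
    params = _params(nu=nu, sigma=sigma)
    result = dp4plus_probability(evals, params, channels=["13C_scaled"])

    direct = {}
    for cid in "abcd":
        prod = 1.0
        for e in errors[cid]:
            prod *= 1 - student_t_cdf_quadrature(abs(e) / sigma, nu)
        direct[cid] = prod
    total = sum(direct.values())
    for cid in "abcd":
        assert result.probabilities["13C_scaled"][cid] == pytest.approx(
            direct[cid] / total, abs=1e-9
        )


def test_probabilities_sum_to_one_and_permutation_invariant():
    rng = np.random.default_rng(9)
    evals = [_eval(cid, rng.normal(0, 2, 6)) for cid in "abc"]
    params = _params()
    r1 = dp4plus_probability(evals, params)
    r2 = dp4plus_probability(evals[::-1], params)
    for ch in r1.channels:
        assert sum(r1.probabilities[ch].values()) == pytest.approx(1.0, abs=1e-9)
        for cid in "abc":
            assert r1.probabilities[ch][cid] == pytest.approx(
                r2.probabilities[ch][cid], abs=1e-12
            )


def test_hopeless_candidate_leaves_odds_ratio_unchanged():
    rng = np.random.default_rng(10)
    a, b = rng.normal(0, 2, 6), rng.normal(0, 2, 6)
    params = _params()
    r2 = dp4plus_probability([_eval("a", a), _eval("b", b)], params, channels=["13C_scaled"])
    r3 = dp4plus_probability(
        [_eval("a", a), _eval("b", b), _eval("z", np.full(6, 40.0))],
        params,
        channels=["13C_scaled"],
    )
    p2, p3 = r2.probabilities["13C_scaled"], r3.probabilities["13C_scaled"]
    assert p3["a"] / p3["b"] == pytest.approx(p2["a"] / p2["b"], rel=1e-9)


def test_inflating_errors_strictly_decreases_probability():
    rng = np.random.default_rng(11)
    a, b = rng.normal(0, 2, 8), rng.normal(0, 2, 8)
    params = _params()
    base = dp4plus_probability([_eval("a", a), _eval("b", b)], params)
    worse = dp4plus_probability([_eval("a", a * 2.5), _eval("b", b)], params)
    for ch in base.channels:
        assert worse.probabilities[ch]["a"] < base.probabilities[ch]["a"]


def test_hybridization_partition_selects_distinct_triplets():
    block = NucleusTypeParameters(
        scaled=TTriplet(3, 0.0, 2.0),
        unscaled_sp2=TTriplet(3, 0.0, 100.0),  # essentially flat for sp2
        unscaled_sp3=TTriplet(3, 0.0, 0.1),
    )
    params = DP4Parameters(proton=block, carbon=block)
    # identical errors, but one candidate's error sits on an sp3 nucleus
    ev_sp2 = _eval("a", [3.0, 0.0], ["sp2", "sp2"])
    ev_sp3 = _eval("b", [3.0, 0.0], ["sp3", "sp2"])
    result = dp4plus_probability([ev_sp2, ev_sp3], params, channels=["13C_unscaled"])
    probs = result.probabilities["13C_unscaled"]
    assert probs["a"] > 0.9  # sp3 triplet is far stricter on a 3 ppm error


def test_channel_omitted_with_warning_when_no_nuclei():
    ev = _eval("a", [1.0], element="C")
    ev2 = _eval("b", [2.0], element="C")
    with pytest.warns(UserWarning, match="1H_scaled"):
        result = dp4plus_probability([ev, ev2], _params())
    assert "1H_scaled" not in result.channels
    assert "13C" in result.channels and "all" in result.channels


def test_mismatched_nucleus_sets_rejected():
    with pytest.raises(ValueError, match="nucleus set"):
        dp4plus_probability([_eval("a", [1.0]), _eval("b", [1.0, 2.0])], _params())


def test_parameter_profile_roundtrip(tmp_path):
    params = _params(nu=5.0, sigma=1.25)
    path = tmp_path / "profile.yaml"
    save_parameters(params, path)
    loaded = load_parameters(path)
    assert loaded == params
    with pytest.raises(ValueError):
        TTriplet(0.0, 0.0, 1.0)
    with pytest.raises(ValueError):
        TTriplet(3.0, 0.0, -1.0)
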