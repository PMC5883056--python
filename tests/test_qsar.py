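import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gxqsar.errors import (
    DegreesOfFreedomError,
    MissingDescriptorError,
    SingularMatrixError,
)
from gxqsar.qsar import (
    AD_UNAVAILABLE,
    LinearQSARModel,
    applicability_flag,
    fit_mlr,
    predict,
    published_model,
    stepwise_forward,
)
from gxqsar.simdata import SimConfig, simulate_descriptor_table

import oracle

PRINTED = {
    "model1": (
        {
            "DeltaEpsilonC": -39.0090,
            "MMFF_29": -0.8078,
            "SssssCcount": -1.0827,
            "T_2_2_1": -0.0483,
            "SdsCHE-index": 0.5053,
        },
        -0.0560,
    ),
    "model2": (
        {
            "SdssCE-index": -0.6407,
            "T_2_2_2": -0.0336,
            "H-AcceptorCount": -0.1278,
            "SdsCHE-index": 0.2226,
            "T_O_O_3": 0.5877,
        },
        0.5940,
    ),
    "model3": (
        {"T_T_N_4": 0.0948, "T_O_O_3": 0.5217, "SssssCE-index": 0.3687},
        1.1313,
    ),
}


def test_fit_mlr_exact_line():
    x = np.arange(10.0)
    m = fit_mlr(x[:, None], 2.0 * x, names=["x"])
    assert m.coefficients["x"] == pytest.approx(2.0, abs=1e-12)
    assert m.intercept == pytest.approx(0.0, abs=1e-12)
    assert m.fit_stats["r2"] == pytest.approx(1.0)


def test_fit_mlr_duplicate_column_singularity():
    rng = np.random.default_rng(0)
    x = rng.normal(size=20)
    X = np.column_stack([x, x])
    with pytest.raises(SingularMatrixError) as exc:
        fit_mlr(X, rng.normal(size=20), names=["a", "b"])
    assert {"a", "b"} & set(exc.value.columns)


def test_fit_mlr_dof_error():
    with pytest.raises(DegreesOfFreedomError):
        fit_mlr(np.ones((3, 2)), np.ones(3))


def test_fit_mlr_matches_normal_equations_oracle():
    rng = np.random.default_rng(42)
    X = rng.uniform(size=(200, 2))
    y = 0.3 + 1.5 * X[:, 0] - 0.7 * X[:, 1] + rng.normal(0, 0.05, 200)
    m = fit_mlr(X, y, names=["a", "b"])
    beta = oracle.normal_equations_fit(X, y)
    assert m.intercept == pytest.approx(beta[0], abs=1e-8)
    assert m.coefficients["a"] == pytest.approx(beta[1], abs=1e-8)
    assert m.coefficients["b"] == pytest.approx(beta[2], abs=1e-8)
    assert m.coefficients["a"] == pytest.approx(1.5, abs=0.05)


def _noise_table(n, names, informative=None, seed=0):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({name: rng.normal(size=n) for name in names})
    y = rng.normal(size=n)
    if informative:
        y = 2.0 * df[informative].to_numpy() + rng.normal(0, 0.2, n)
    df["log_ic50"] = y
    df.insert(0, "compound_id", [f"c{i}" for i in range(n)])
    from gxqsar.dataset import ActivityTable

    return ActivityTable.from_dataframe(df, list(names))


def test_stepwise_selects_the_planted_descriptor():
    names = [f"x{i}" for i in range(10)]
    t = _noise_table(100, names, informative="x4", seed=1)
    m = stepwise_forward(t, f_to_enter=4.0, max_terms=1)
    # oracle: exhaustive size-1 search for the best single descriptor
    best = min(
        names,
        key=lambda n: oracle.explicit_loo_q2(
            t.df[[n]].to_numpy(), t.y().to_numpy()
        )[1],
    )
    assert m.descriptor_names == ["x4"] == [best]


def test_stepwise_pure_noise_rarely_enters():
    hits = 0
    for seed in range(100):
        t = _noise_table(50, ["x0"], seed=seed)
        m = stepwise_forward(t, f_to_enter=4.0)
        if not m.descriptor_names:
            hits += 1
    assert hits >= 90


def test_stepwise_max_terms_zero_gives_intercept_only():
    t = _noise_table(30, ["x0", "x1"], seed=2)
    m = stepwise_forward(t, max_terms=0)
    assert m.descriptor_names == []
    assert m.intercept == pytest.approx(t.y().mean())
    assert "warning" not in m.fit_stats or m.fit_stats["k"] == 0


def test_stepwise_respects_corr_cutoff():
    rng = np.random.default_rng(3)
    n = 80
    x = rng.normal(size=n)
    df = pd.DataFrame(
        {
            "compound_id": [f"c{i}" for i in range(n)],
            "a": x,
            "a_twin": x + rng.normal(0, 0.01, n),
            "log_ic50": x + rng.normal(0, 0.3, n),
        }
    )
    from gxqsar.dataset import ActivityTable

    t = ActivityTable.from_dataframe(df, ["a", "a_twin"])
    m = stepwise_forward(t, corr_cutoff=0.7)
    assert len(m.descriptor_names) == 1


@pytest.mark.parametrize("which", ["model1", "model2", "model3"])
def test_published_models_pin_printed_equations(which):
    m = published_model(which)
    coeffs, intercept = PRINTED[which]
    assert m.coefficients == coeffs
    assert m.intercept == intercept
    assert m.provenance == f"published:{which}"


def test_published_model_unknown_id():
    with pytest.raises(KeyError, match="model1"):
        published_model("model99")


def test_predict_printed_intercepts_and_coefficients():
    zeros = {n: 0.0 for n in published_model("model1").descriptor_names}
    assert predict(published_model("model1"), zeros).log_ic50 == pytest.approx(-0.0560)
    m2 = published_model("model2")
    assert predict(m2, {n: 0.0 for n in m2.descriptor_names}).log_ic50 == pytest.approx(0.5940)
    m3 = published_model("model3")
    z3 = {n: 0.0 for n in m3.descriptor_names}
    assert predict(m3, z3).log_ic50 == pytest.approx(1.1313)
    assert predict(m3, {**z3, "T_O_O_3": 1.0}).log_ic50 - predict(m3, z3).log_ic50 == pytest.approx(0.5217)
    ones = {n: 1.0 for n in m3.descriptor_names}
    assert predict(m3, ones).log_ic50 == pytest.approx(2.1165)


def test_predict_missing_descriptor_raises():
    m3 = published_model("model3")
    with pytest.raises(MissingDescriptorError, match="T_O_O_3"):
        predict(m3, {"T_T_N_4": 1.0, "SssssCE-index": 0.0})


def test_predict_ic50_is_exact_power_of_ten():
    m3 = published_model("model3")
    p = predict(m3, {n: 0.5 for n in m3.descriptor_names})
    assert p.ic50_uM == 10.0**p.log_ic50


@settings(deadline=None, derandomize=True, max_examples=25)
@given(st.integers(0, 2**31 - 1), st.floats(0.0, 1.0))
def test_predict_is_affine(seed, alpha):
    m3 = published_model("model3")
    rng = np.random.default_rng(seed)
    v1 = {n: float(rng.uniform(0, 5)) for n in m3.descriptor_names}
    v2 = {n: float(rng.uniform(0, 5)) for n in m3.descriptor_names}
    mix = {n: alpha * v1[n] + (1 - alpha) * v2[n] for n in m3.descriptor_names}
    expected = alpha * predict(m3, v1).log_ic50 + (1 - alpha) * predict(m3, v2).log_ic50
    assert predict(m3, mix).log_ic50 == pytest.approx(expected, abs=1e-9)


def test_applicability_flag_boundaries():
    cfg = SimConfig(
        n_compounds=30,
        descriptor_names=["a", "b"],
        true_beta={"a": 1.0},
        noise_sd=0.1,
        seed=5,
    )
    t = simulate_descriptor_table(cfg)
    m = fit_mlr(t.X(), t.y(), names=["a", "b"])
    first = t.df.iloc[0][["a", "b"]].to_dict()
    assert applicability_flag(m, first) == 0
    at_max = {"a": m.train_ranges["a"][1], "b": m.train_ranges["b"][0]}
    assert applicability_flag(m, at_max) == 0  # inclusive boundary
    outside = {"a": m.train_ranges["a"][1] + 1e-6, "b": 0.5}
    assert applicability_flag(m, outside) == 1
    assert applicability_flag(published_model("model3"), {"T_T_N_4": 0, "T_O_O_3": 0, "SssssCE-index": 0}) == AD_UNAVAILABLE


def test_model_json_round_trip(tmp_path):
    rng = np.random.default_rng(6)
    X = rng.uniform(size=(40, 2))
    y = X @ np.array([1.0, -2.0]) + 0.3
    m = fit_mlr(X, y, names=["a", "b"], model_name="demo")
    path = tmp_path / "model.json"
    m.save(path)
    m2 = LinearQSARModel.load(path)
    assert m2.coefficients == m.coefficients
    assert m2.intercept == m.intercept
    assert m2.train_ranges == m.train_ranges
    v = {"a": 0.4, "b": 0.6}
    assert predict(m2, v).log_ic50 == predict(m, v).log_ic50
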