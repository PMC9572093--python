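"""Self-consistent regression, RBF refinement and consensus models."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist

from oxiqspr import (
    QsprSimSpec,
    SCRConfig,
    cross_validate_lmo,
    fit_consensus,
    fit_rbf_scr,
    fit_scr,
    generate_qspr_dataset,
    rational_split,
)
from oxiqspr.qspr import ConsensusModel


def _frame(arr):
    return pd.DataFrame(arr, columns=[f"x{k}" for k in range(arr.shape[1])])


def test_scr_recovers_exact_sparse_signal(rng):
    X = _frame(rng.normal(0, 1, (40, 50)))
    w = {"x3": 2.0, "x17": -1.5, "x29": 0.7}
    y = sum(c * X[k] for k, c in w.items()).to_numpy() + 1.0
    pm = fit_scr(X, y)
    assert set(w) <= set(pm.columns)
    assert pm.r2 == pytest.approx(1.0, abs=1e-9)
    assert pm.sd == pytest.approx(0.0, abs=1e-6)
    # parameter recovery on the true support
    coefs = dict(zip(pm.columns, pm.coef))
    for name, true_val in w.items():
        assert coefs[name] == pytest.approx(true_val, abs=1e-6)
    for name, val in coefs.items():
        if name not in w:
            assert val == pytest.approx(0.0, abs=1e-6)


def test_scr_rejects_degenerate_input(rng):
    X = _frame(rng.normal(0, 1, (20, 5)))
    with pytest.raises(ValueError, match="variance"):
        fit_scr(X, np.full(20, 3.0))
    with pytest.raises(ValueError, match="10 rows"):
        fit_scr(X.iloc[:5], np.arange(5.0))


def test_scr_respects_max_vars(rng):
    X = _frame(rng.normal(0, 1, (103, 200)))
    y = X.iloc[:, :40].sum(axis=1).to_numpy() + rng.normal(0, 0.5, 103)
    pm = fit_scr(X, y, SCRConfig(max_vars=30))
    assert 0 < pm.n_vars <= 30


def test_scr_drops_constant_columns(rng):
    X = _frame(rng.normal(0, 1, (30, 10)))
    X["x3"] = 5.0
    y = X["x1"].to_numpy() * 2 + rng.normal(0, 0.01, 30)
    pm = fit_scr(X, y)
    assert "x3" not in pm.columns


def test_rbf_interpolates_residuals(rng):
    X = _frame(rng.normal(0, 1, (20, 6)))
    # nonlinearity lives in the selected subspace, so residuals are learnable
    y = X["x0"].to_numpy() + 0.5 * np.sin(3 * X["x0"].to_numpy())
    base = fit_scr(X, y, SCRConfig(t_threshold=1.0))
    assert "x0" in base.columns
    refined = fit_rbf_scr(X, y, base)
    err_base = np.abs(base.predict(X) - y).max()
    err_rbf = np.abs(refined.predict(X) - y).max()
    assert err_rbf <= err_base + 1e-12
    assert err_rbf < 0.1 * err_base  # near-interpolation of training points


def test_rbf_zero_residuals_gives_zero_correction(rng):
    X = _frame(rng.normal(0, 1, (15, 4)))
    y = 2.0 * X["x2"].to_numpy() + 1.0
    base = fit_scr(X, y)
    refined = fit_rbf_scr(X, y, base)
    assert np.abs(refined.rbf.alpha).max() < 1e-6


def test_rbf_auto_width_is_median_pairwise_distance(rng):
    X = _frame(rng.normal(0, 1, (15, 4)))
    y = X["x1"].to_numpy() + rng.normal(0, 0.3, 15)
    base = fit_scr(X, y, SCRConfig(t_threshold=1.0))
    refined = fit_rbf_scr(X, y, base)
    Z = X[base.columns].to_numpy()
    assert refined.rbf.width == pytest.approx(float(np.median(pdist(Z))))


@pytest.fixture(scope="module")
def synth_split():
    ds = generate_qspr_dataset(QsprSimSpec(n_compounds=90, noise_sd=0.3, seed=11))
    return rational_split(ds.records, step=6, start_offset=1)


@pytest.fixture(scope="module")
def consensus(synth_split):
    return fit_consensus(synth_split.train, preset="mna", n_partials=10, seed=20191)


def test_consensus_equals_mean_of_in_ad_partials(consensus, synth_split):
    """Explicit-loop oracle: mean over the leverage-admissible partials."""
    graphs = [r.structure for r in synth_split.test]
    pred = consensus.predict(graphs)
    mats = consensus._family_matrices(graphs)
    all_preds = np.array([pm.predict(mats[pm.family].values) for pm in consensus.partials])
    all_lev_ok = np.array(
        [pm.leverage(mats[pm.family].values) <= pm.leverage_threshold
         for pm in consensus.partials]
    )
    for j in range(len(graphs)):
        ok = all_lev_ok[:, j]
        expected = all_preds[ok, j].mean() if ok.any() else all_preds[:, j].mean()
        assert pred["logk7_pred"].iloc[j] == pytest.approx(expected, abs=1e-10)


def test_consensus_without_resampling_collapses_to_single_model(synth_split):
    model = fit_consensus(
        synth_split.train, preset="mna", n_partials=3, leave_fraction=0.0, seed=1
    )
    graphs = [r.structure for r in synth_split.test]
    pred = consensus_pred = model.predict(graphs)["logk7_pred"].to_numpy()
    mats = model._family_matrices(graphs)
    single = model.partials[0].predict(mats[0].values)
    assert np.allclose(consensus_pred, single, atol=1e-10)
    assert model.q2_lmo is None


def test_consensus_serialization_roundtrip_and_determinism(synth_split):
    kw = dict(preset="mna", n_partials=4, seed=77)
    m1 = fit_consensus(synth_split.train, **kw)
    m2 = fit_consensus(synth_split.train, **kw)
    assert m1.to_json() == m2.to_json()
    restored = ConsensusModel.from_json(m1.to_json())
    graphs = [r.structure for r in synth_split.test]
    assert np.allclose(
        restored.predict(graphs)["logk7_pred"], m1.predict(graphs)["logk7_pred"]
    )


def test_prediction_invariant_to_compound_order(consensus, synth_split, rng):
    graphs = [r.structure for r in synth_split.test]
    perm = rng.permutation(len(graphs))
    p1 = consensus.predict(graphs).set_index("id")
    p2 = consensus.predict([graphs[i] for i in perm]).set_index("id")
    assert np.allclose(
        p1.loc[p2.index, "logk7_pred"].to_numpy(), p2["logk7_pred"].to_numpy()
    )


def test_training_compounds_are_in_ad(consensus, synth_split):
    pred = consensus.predict([r.structure for r in synth_split.train])
    assert pred["in_ad"].mean() > 0.9


def test_alien_compound_is_out_of_ad(consensus):
    pred = consensus.predict("ClCl weird")
    assert pred["unseen_fraction"].iloc[0] == 1.0
    assert not pred["in_ad"].iloc[0]


def test_prediction_rmse_tracks_generative_noise(consensus, synth_split):
    pred = consensus.predict([r.structure for r in synth_split.test])
    y = np.array([r.logk7 for r in synth_split.test])
    rmse = float(np.sqrt(np.mean((pred["logk7_pred"].to_numpy() - y) ** 2)))
    assert rmse < 2 * 0.3  # twice the generative noise sd


def test_noise_free_consensus_training_r2_is_one():
    ds = generate_qspr_dataset(QsprSimSpec(n_compounds=40, noise_sd=0.0, seed=4))
    # without row resampling the consensus reproduces the exact linear signal
    exact = fit_consensus(
        ds.records, preset="mna", n_partials=2, level=2, leave_fraction=0.0, seed=5
    )
    assert exact.training_r2 > 0.999
    # with 20% holdouts each partial also predicts rows it never saw
    resampled = fit_consensus(ds.records, preset="mna", n_partials=4, level=2, seed=5)
    assert resampled.training_r2 > 0.98


def test_lmo_limits(rng):
    # noise-free linear data -> Q2 ~ 1
    X = _frame(rng.normal(0, 1, (60, 20)))
    y = 2 * X["x4"].to_numpy() - X["x9"].to_numpy()
    assert cross_validate_lmo(X, y, seed=3) > 0.99
    # pure noise -> Q2 <= 0 in expectation
    y_noise = rng.normal(0, 1, 60)
    assert cross_validate_lmo(X, y_noise, n_rounds=20, seed=3) < 0.1


def test_consensus_input_validation(synth_split):
    with pytest.raises(ValueError, match="n_partials"):
        fit_consensus(synth_split.train, n_partials=1)
    with pytest.raises(ValueError, match="30 training records"):
        fit_consensus(synth_split.train[:10])
    with pytest.raises(ValueError, match="preset"):
        fit_consensus(synth_split.train, preset="nope")
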