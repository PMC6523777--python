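import numpy as np
import pytest

from amopls import anova, mbopls, synthdata
from amopls.io import StudyDesign
from amopls.mbopls import BlockSet, build_dummy_response, fit
from amopls.preprocess import resolve_duplicates


def two_level_design(reps=6):
    ids = [f"s{i}" for i in range(2 * reps)]
    return StudyDesign(ids, {"A": ["a"] * reps + ["b"] * reps})


def strong_single_effect(seed=0, reps=6, p=30, amp=3.0):
    rng = np.random.default_rng(seed)
    design = two_level_design(reps)
    pattern = np.where(np.array(design.codes("A")) == 0, -1.0, 1.0)
    X = amp * pattern[:, None] * rng.standard_normal(p)[None, :]
    X += rng.standard_normal((2 * reps, p))
    return X, design


def test_dummy_response_q():
    assert build_dummy_response(two_level_design()).q == 1
    ids = [f"s{i}" for i in range(9)]
    d3 = StudyDesign(ids, {"A": ["a"] * 3 + ["b"] * 3 + ["c"] * 3})
    assert build_dummy_response(d3).q == 2


def test_reference_design_q_is_nine(calibrated_model):
    _, design, _, model = calibrated_model
    assert model.response.q == 9
    assert model.n_pred == 9


def test_kernels_frobenius_normalized(calibrated_model):
    *_, model = calibrated_model
    for K in model.blockset.kernels.values():
        assert np.linalg.norm(K) == pytest.approx(1.0)
        evals = np.linalg.eigvalsh(K)
        assert evals.min() > -1e-8


def test_single_variable_block_kernel_by_hand():
    bs = BlockSet({"z": np.array([[1.0], [-1.0]])})
    expected = np.array([[1.0, -1.0], [-1.0, 1.0]]) / 2.0
    assert np.allclose(bs.kernels["z"], expected)


def test_empty_block_rejected():
    with pytest.raises(ValueError, match="empty"):
        BlockSet({"z": np.zeros((4, 3))})


def test_single_block_salience_is_one():
    X, design = strong_single_effect()
    bs = BlockSet({"only": X - X.mean(axis=0)})
    model = fit(bs, build_dummy_response(design), n_ortho=1)
    assert np.allclose(model.saliences.to_numpy(), 1.0)


def test_score_orthogonality_invariants(calibrated_model):
    *_, model = calibrated_model
    T = model.T_pred
    G = T.T @ T
    off = G - np.diag(np.diag(G))
    assert np.abs(off).max() < 1e-8 * np.abs(np.diag(G)).max()
    # orthogonal scores uncorrelated with every design contrast
    Y = model.response.Y
    for c in range(model.T_ortho.shape[1]):
        t = model.T_ortho[:, c]
        assert np.abs(Y.T @ t).max() < 1e-8 * max(np.linalg.norm(t), 1e-30)
    # salience rows sum to one, entries non-negative
    sal = model.saliences.to_numpy()
    assert np.allclose(sal.sum(axis=1), 1.0)
    assert (sal >= 0).all()


def test_kernel_pls_oracle_single_block():
    rng = np.random.default_rng(2)
    design = two_level_design(reps=5)  # n = 10 <= 12
    X = rng.standard_normal((10, 7))
    Xc = X - X.mean(axis=0)
    bs = BlockSet({"x": Xc})
    Y = build_dummy_response(design)
    model = fit(bs, Y, n_ortho=0)
    K = bs.kernels["x"]
    M = K @ Y.Y @ Y.Y.T @ K
    evals, evecs = np.linalg.eigh(M)
    u = evecs[:, np.argmax(evals)]
    t = model.T_pred[:, 0]
    cos = abs(u @ t) / (np.linalg.norm(u) * np.linalg.norm(t))
    assert cos == pytest.approx(1.0, abs=1e-6)


def test_permutation_equivariance():
    rng = np.random.default_rng(3)
    X, design = strong_single_effect(seed=4)
    d = anova.decompose(X, design)
    bs = mbopls.build_blocks(d)
    Y = build_dummy_response(design)
    model = fit(bs, Y, n_ortho=1)

    pi = rng.permutation(X.shape[0])
    perm_blocks = BlockSet({k: v[pi] for k, v in bs.blocks.items()})
    Yp = mbopls.DummyResponse(Y.Y[pi], Y.term_slices, Y.design)
    model_p = fit(perm_blocks, Yp, n_ortho=1)
    assert np.allclose(model_p.T_pred, model.T_pred[pi], atol=1e-8)


def test_single_nonnull_effect_dominates_first_component():
    for seed in range(3):
        X, design = strong_single_effect(seed=seed)
        d = anova.decompose(X, design)
        model = fit(mbopls.build_blocks(d), build_dummy_response(design), 1)
        assert mbopls.dominant_block(model, "tp1") == "A"


def test_scores_separate_levels_perfectly_for_strong_effect():
    X, design = strong_single_effect(seed=1, amp=5.0)
    d = anova.decompose(X, design)
    model = fit(mbopls.build_blocks(d), build_dummy_response(design), 1)
    df = mbopls.predictive_scores_plot_data(model, "A")
    signs = df.groupby("level")["tp1"].apply(lambda s: set(np.sign(s)))
    assert signs["a"] != signs["b"]
    assert all(len(s) == 1 for s in signs)


def test_concentration_clusters_have_positive_silhouette(calibrated_model):
    from sklearn.metrics import silhouette_score

    *_, model = calibrated_model
    df = mbopls.predictive_scores_plot_data(model, "Concentration")
    comps = [c for c in df.columns if c.startswith("tp")]
    assert len(comps) == 2  # 3-level factor -> two predictive components
    sil = silhouette_score(df[comps].to_numpy(), df["level"])
    assert sil > 0

    # null data: no separation
    spec = synthdata.SyntheticSpec(seed=9, calibrate=False, effect_scale=0.0)
    tables, design = synthdata.generate(spec)
    merged, _ = resolve_duplicates(list(tables.values()))
    X0 = merged.biological().values
    d0 = anova.decompose(X0, design)
    m0 = fit(mbopls.build_blocks(d0), build_dummy_response(design), 1)
    df0 = mbopls.predictive_scores_plot_data(m0, "Concentration")
    comps0 = [c for c in df0.columns if c.startswith("tp")]
    sil0 = silhouette_score(df0[comps0].to_numpy(), df0["level"])
    # supervised scores overfit the labels even on null data, so the null
    # silhouette is positive too; the real effect must still separate better
    assert sil0 < sil


def test_unknown_effect_errors(calibrated_model):
    *_, model = calibrated_model
    with pytest.raises(ValueError, match="unknown effect"):
        mbopls.predictive_scores_plot_data(model, "Nope")


def test_auto_orthogonal_component_count(calibrated_model):
    X, design, d, _ = calibrated_model
    model = fit(mbopls.build_blocks(d), build_dummy_response(design), n_ortho="auto")
    assert model.T_ortho.shape[1] >= 1
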