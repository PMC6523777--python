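import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from amopls import anova, inference, mbopls, synthdata
from amopls.anova import RESIDUAL
from amopls.io import StudyDesign
from amopls.preprocess import resolve_duplicates


def fit_model(X, design, n_ortho=1):
    d = anova.decompose(X, design)
    return mbopls.fit(
        mbopls.build_blocks(d), mbopls.build_dummy_response(design), n_ortho
    )


def test_residual_rsr_is_one_and_paths_agree(calibrated_model):
    X, design, _, model = calibrated_model
    r_model = inference.rsr(model)
    r_fast = inference._decompose_rsr(X, design)
    assert r_model[RESIDUAL] == 1.0
    for k in r_model:
        assert r_model[k] == pytest.approx(r_fast[k], abs=1e-12)


def test_rsr_ordering_tracks_effect_size(calibrated_model):
    X, design, _, model = calibrated_model
    r = inference.rsr(model)
    assert r["Maturation"] > r["Maturation×Concentration"]
    assert r["Maturation"] > r["Exposure"] > r["Concentration"]


def test_pure_noise_rsr_near_one():
    spec = synthdata.SyntheticSpec(seed=21, calibrate=False, effect_scale=0.0)
    tables, design = synthdata.generate(spec)
    merged, _ = resolve_duplicates(list(tables.values()))
    r = inference._decompose_rsr(merged.biological().values, design)
    for label, val in r.items():
        assert 0.85 < val < 1.15, label


def test_rsr_monotone_in_injected_effect():
    """Scaling one effect submatrix up raises its contribution and RSR."""
    spec = synthdata.SyntheticSpec(seed=13, calibrate=False, effect_scale=1.0)
    tables, design = synthdata.generate(spec)
    merged, _ = resolve_duplicates(list(tables.values()))
    X = merged.biological().values
    d = anova.decompose(X, design)
    prev_contrib, prev_rsr = -1.0, -1.0
    for scale in (1.0, 2.0, 4.0):
        X2 = X + (scale - 1.0) * d.effect_matrices["Maturation"]
        d2 = anova.decompose(X2, design)
        c = anova.contributions(d2)["Maturation"]
        r = inference._decompose_rsr(X2, design)["Maturation"]
        assert c > prev_contrib
        assert r > prev_rsr
        prev_contrib, prev_rsr = c, r


def test_component_association(calibrated_model):
    *_, model = calibrated_model
    assoc = inference.associate_components(model)
    assert len(assoc.components["Concentration"]) == 2  # 3 levels -> 2 components
    assert not assoc.fallback
    covered = [c for comps in assoc.components.values() for c in comps]
    assert sorted(covered) == sorted(model.component_names[: model.n_pred])


def test_single_effect_model_components_all_map_to_it():
    rng = np.random.default_rng(5)
    ids = [f"s{i}" for i in range(12)]
    design = StudyDesign(ids, {"A": ["a"] * 4 + ["b"] * 4 + ["c"] * 4})
    codes = np.array(design.codes("A"), dtype=float)
    # rank-2 level structure so both available contrasts carry signal
    X = 3.0 * codes[:, None] * rng.standard_normal(20)[None, :]
    X += 3.0 * (codes == 1.0)[:, None] * rng.standard_normal(20)[None, :]
    X += rng.standard_normal((12, 20))
    model = fit_model(X, design)
    assoc = inference.associate_components(model)
    assert assoc.components["A"] == ["tp1", "tp2"]


def _toy_model(P, saliences, comp_var):
    """Hand-crafted model exposing only the fields VIP² touches."""
    q = P.shape[1]
    return mbopls.AmoplsModel(
        T_pred=np.zeros((4, q)),
        T_ortho=np.zeros((4, 0)),
        P=P,
        saliences=pd.DataFrame(
            saliences, index=[f"tp{i+1}" for i in range(q)], columns=["eff", RESIDUAL]
        ),
        component_variances=np.asarray(comp_var, dtype=float),
        block_names=["eff", RESIDUAL],
        component_names=[f"tp{i+1}" for i in range(q)],
        response=None,
        X=np.zeros((4, P.shape[0])),
        blockset=None,
    )


def test_vip2_uniform_loadings_give_ones():
    p = 5
    model = _toy_model(np.full((p, 1), 0.3), [[0.8, 0.2]], [1.0])
    assert np.allclose(inference.vip2(model, "eff"), 1.0)


def test_vip2_concentrated_loading_gives_p():
    p = 6
    P = np.zeros((p, 1))
    P[2, 0] = 1.0
    model = _toy_model(P, [[0.8, 0.2]], [1.0])
    v = inference.vip2(model, "eff")
    assert v[2] == pytest.approx(p)
    assert np.allclose(np.delete(v, 2), 0.0)


def test_vip2_mean_one_for_every_effect(calibrated_model):
    *_, model = calibrated_model
    vt = inference.vip_table(model)
    assert np.allclose(vt.mean(axis=0), 1.0, atol=1e-8)
    assert (vt.to_numpy() >= 0).all()


def test_vip2_zero_salience_errors():
    model = _toy_model(np.full((4, 1), 0.5), [[0.0, 1.0]], [1.0])
    with pytest.raises(ValueError, match="zero salience"):
        inference.vip2(model, "eff")


def test_select_features_thresholds():
    vt = pd.DataFrame({"eff": [1.0, 1.0, 1.0]}, index=["a", "b", "c"])
    assert inference.select_features(vt, "eff", 1.1) == []
    vt2 = pd.DataFrame({"eff": [0.5, 2.0, 1.2]}, index=["a", "b", "c"])
    assert inference.select_features(vt2, "eff", 0.0000001) == ["b", "c", "a"]
    assert inference.select_features(vt2, "eff", 1.1) == ["b", "c"]


def test_vip2_recovers_injected_concentration_features():
    from sklearn.metrics import roc_auc_score

    aucs, recalls = [], []
    for seed in range(3):
        spec = synthdata.SyntheticSpec(
            seed=seed,
            calibrate=False,
            effect_scale=2.0,
            responsive={
                "Maturation": 60,
                "Exposure": 60,
                "Concentration": 40,
                "Maturation×Exposure": 30,
                "Maturation×Concentration": 20,
                "Exposure×Concentration": 20,
            },
        )
        tables, design, truth = synthdata.generate(spec, return_truth=True)
        merged, _ = resolve_duplicates(list(tables.values()))
        model = fit_model(merged.biological().values, design)
        v = inference.vip2(model, "Concentration")
        labels = np.zeros(merged.n_features, dtype=bool)
        labels[truth["responsive"]["Concentration"]] = True
        aucs.append(roc_auc_score(labels, v))
        vt = pd.DataFrame({"Concentration": v})
        sel = inference.select_features(
            vt, "Concentration", 1.1, feature_ids=list(range(merged.n_features))
        )
        recalls.append(np.mean(labels[sel]) * len(sel) / labels.sum())
    assert np.mean(aucs) > 0.9
    assert np.mean(recalls) > 0.7


def test_permutation_percent_scale_floor_and_determinism(calibrated):
    merged, design = calibrated
    X = merged.biological().values
    p1 = inference.permutation_test(X, design, "Concentration", n_perm=199, seed=11)
    p2 = inference.permutation_test(X, design, "Concentration", n_perm=199, seed=11)
    assert p1 == p2
    assert p1 == pytest.approx(100.0 / 200.0)  # floor: huge effect, r = 0
    p3 = inference.permutation_test(X, design, "Concentration", n_perm=199, seed=12)
    assert p3 == pytest.approx(p1)  # still at the floor with another stream


def test_permutation_null_uniformity():
    """Under a true null, permutation p-values are uniform on (0, 100]."""
    pvals = []
    for seed in range(200):
        spec = synthdata.SyntheticSpec(
            factors={"A": ["a", "b"], "B": ["x", "y"]},
            replicates=3,
            platform_features={"P1": 15},
            effects=[("A",), ("B",), ("A", "B")],
            effect_fractions={},
            calibrate=False,
            effect_scale=0.0,
            n_qc=2,
            seed=seed,
        )
        tables, design = synthdata.generate(spec)
        X = tables["P1"].biological().values
        pvals.append(
            inference.permutation_test(X, design, "A", n_perm=199, seed=seed + 1)
        )
    stat = kstest(np.array(pvals) / 100.0, "uniform")
    assert stat.pvalue > 0.01


def test_small_n_perm_rejected(calibrated):
    merged, design = calibrated
    with pytest.raises(ValueError, match="at least 99"):
        inference.permutation_test(
            merged.biological().values, design, "Concentration", n_perm=10
        )


def test_effect_report_shape(calibrated):
    merged, design = calibrated
    X = merged.biological().values
    rep = inference.effect_report(X, design, n_perm=0)
    assert list(rep.index) == [
        "Maturation",
        "Exposure",
        "Concentration",
        "Maturation×Exposure",
        "Maturation×Concentration",
        "Exposure×Concentration",
        RESIDUAL,
    ]
    assert rep.loc[RESIDUAL, "rsr"] == 1.0
    assert np.isnan(rep.loc[RESIDUAL, "p_value_pct"])
    assert rep["contribution_pct"].sum() == pytest.approx(100.0)
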