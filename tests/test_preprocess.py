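import numpy as np
import pytest

from amopls import synthdata
from amopls.io import FeatureTable
from amopls.preprocess import qc_cv, qc_cv_filter, resolve_duplicates, uv_scale


def table_with_qc(qc_values, n_features=None, platform="RPLC+", annotation=None):
    """2 biological rows + QC rows holding the given per-feature QC intensities."""
    qc_values = np.asarray(qc_values, dtype=float)
    n_qc, p = qc_values.shape
    bio = np.full((2, p), 100.0)
    ann = annotation if annotation is not None else [""] * p
    return FeatureTable(
        ["S1", "S2"] + [f"QC{i}" for i in range(n_qc)],
        [f"f{j}" for j in range(p)],
        np.vstack([bio, qc_values]),
        np.array([platform] * p, dtype=object),
        np.array(ann, dtype=object),
        np.array([False, False] + [True] * n_qc),
    )


@pytest.mark.parametrize(
    "qc_col, kept",
    [
        ([100.0, 100.0, 100.0], True),  # CV 0
        ([100.0, 200.0, 300.0], False),  # CV = 100/200 = 50% (sd with n-1)
    ],
)
def test_cv_filter_formula(qc_col, kept):
    t = table_with_qc(np.array(qc_col)[:, None])
    filtered, report = qc_cv_filter(t, threshold=0.35)
    assert (filtered.n_features == 1) == kept
    assert report.counts_before["RPLC+"] == 1
    assert report.counts_after["RPLC+"] == int(kept)


def test_cv_exactly_at_threshold_is_kept():
    t = table_with_qc(np.array([[80.0], [120.0]]))  # mean 100, sd 28.28 -> cv .2828
    cv = qc_cv(t)[0]
    filtered, _ = qc_cv_filter(t, threshold=float(cv))
    assert filtered.n_features == 1


def test_zero_qc_mean_removed_as_degenerate():
    t = table_with_qc(np.array([[-50.0], [50.0]]))
    filtered, report = qc_cv_filter(t)
    assert filtered.n_features == 0
    assert report.removed["f0"] == "degenerate"


def test_fewer_than_two_qc_rows_errors():
    t = table_with_qc(np.array([[100.0]]))
    with pytest.raises(ValueError, match="2 QC"):
        qc_cv_filter(t)


def test_cv_filter_idempotent():
    t = synthdata.generate_qc_stress_table(n_features=500, seed=4)
    once, _ = qc_cv_filter(t)
    twice, rep = qc_cv_filter(once)
    assert twice.n_features == once.n_features
    assert not rep.removed


def test_stress_table_retains_about_ten_percent():
    for seed in (0, 1, 2):
        t = synthdata.generate_qc_stress_table(n_features=2000, seed=seed)
        filtered, _ = qc_cv_filter(t, threshold=0.35)
        retained = 100.0 * filtered.n_features / t.n_features
        assert 7.0 <= retained <= 13.0


def _two_platform_tables(cv_a, cv_b, median_a=100.0, median_b=100.0):
    """One shared annotation 'm' on two platforms with controlled QC CVs."""
    def tab(cv, med, plat):
        qc = np.array([[med * (1 - cv), med * (1 + cv)]]).T * np.ones((2, 1))
        vals = np.vstack([np.full((2, 1), med), qc])
        return FeatureTable(
            ["S1", "S2", "QC1", "QC2"],
            ["f0"],
            vals,
            np.array([plat], dtype=object),
            np.array(["m"], dtype=object),
            np.array([False, False, True, True]),
        )

    return [tab(cv_a, median_a, "RPLC+"), tab(cv_b, median_b, "HILIC+")]


def test_duplicate_resolution_lowest_cv_wins():
    tables = _two_platform_tables(0.10, 0.20)
    merged, report = resolve_duplicates(tables)
    assert merged.n_features == 1
    assert merged.platform[0] == "RPLC+"
    assert "m" in report.duplicate_log


def test_duplicate_resolution_tie_breaks_on_median():
    tables = _two_platform_tables(0.10, 0.10, median_a=1e4, median_b=1e5)
    merged, _ = resolve_duplicates(tables)
    assert merged.platform[0] == "HILIC+"


def test_single_platform_feature_kept_unchanged():
    t = table_with_qc(np.array([[100.0], [110.0]]), annotation=["m"])
    merged, report = resolve_duplicates([t])
    assert merged.n_features == 1
    assert not report.duplicate_log


def test_no_duplicate_annotations_after_merge(calibrated):
    merged, _ = calibrated
    ann = [a for a in merged.annotation if a]
    assert len(ann) == len(set(ann))


def test_sample_mismatch_errors():
    tables = _two_platform_tables(0.1, 0.2)
    tables[1].sample_ids[0] = "OTHER"
    with pytest.raises(ValueError, match="sample ids"):
        resolve_duplicates(tables)


def test_uv_scale_moments_and_inverse(calibrated):
    merged, _ = calibrated
    scaled, report = uv_scale(merged)
    bio = scaled.values[~scaled.is_qc]
    assert np.abs(bio.mean(axis=0)).max() < 1e-12
    assert np.abs(bio.std(axis=0, ddof=1) - 1).max() < 1e-12
    back = scaled.values * report.scale_sd + report.scale_mean
    assert np.allclose(back, merged.values, rtol=1e-12)


def test_uv_scale_commutes_with_sample_reordering(calibrated):
    merged, design = calibrated
    scaled, _ = uv_scale(merged)
    rev = list(reversed(design.sample_ids))
    scaled_then_reorder = scaled.reorder_samples(rev)
    reorder_then_scaled, _ = uv_scale(merged.reorder_samples(rev))
    assert np.allclose(
        scaled_then_reorder.values, reorder_then_scaled.values, atol=1e-12
    )


def test_constant_column_errors():
    t = table_with_qc(np.array([[100.0], [120.0]]))
    with pytest.raises(ValueError, match="constant feature"):
        uv_scale(t)  # biological rows are both exactly 100
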