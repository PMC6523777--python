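import pytest

from amopls import anova, mbopls, synthdata
from amopls.preprocess import resolve_duplicates, uv_scale


@pytest.fixture(scope="session")
def calibrated():
    """Default calibrated dataset: merged 36×189 table + design (seed 7)."""
    spec = synthdata.SyntheticSpec(seed=7)
    tables, design = synthdata.generate(spec)
    merged, _ = resolve_duplicates(list(tables.values()))
    return merged, design


@pytest.fixture(scope="session")
def calibrated_model(calibrated):
    """UV-scaled matrix, decomposition and fitted model on the default dataset."""
    merged, design = calibrated
    scaled, _ = uv_scale(merged)
    X = scaled.biological().values
    d = anova.decompose(X, design)
    blocks = mbopls.build_blocks(d)
    Y = mbopls.build_dummy_response(design)
    model = mbopls.fit(blocks, Y, n_ortho=1)
    return X, design, d, model
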