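import numpy as np
import pytest

from stockshift.io import SRRDataset, StockAssessmentSeries


@pytest.fixture
def simple_series():
    years = np.arange(2000, 2020)
    rng = np.random.default_rng(0)
    ssb = 1000.0 + rng.normal(0, 30, years.size)
    rec = 500.0 + rng.normal(0, 20, years.size)
    f = 0.3 + 0.02 * rng.standard_normal(years.size)
    return StockAssessmentSeries(
        stock_id="toy", years=years, ssb=ssb, recruitment=rec, fmort=np.abs(f), recruitment_age=1
    )


@pytest.fixture
def ricker_srr():
    rng = np.random.default_rng(1)
    s = rng.uniform(100, 1000, 40)
    r = s * np.exp(1.2 - 0.002 * s) * np.exp(0.2 * rng.standard_normal(40))
    return SRRDataset(spawn_years=np.arange(1960, 2000), s=s, r=r)


def stock_csv(tmp_path, text, name="stock.csv"):
    p = tmp_path / name
    p.write_text(text)
    return p
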