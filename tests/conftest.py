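import numpy as np
import pytest

import ncaabind as nb


@pytest.fixture(scope="session")
def registry():
    """Canonical 20 + 28 sampled NCAAs, the study-scale token registry."""
    return nb.make_registry(28, seed=0)


@pytest.fixture(scope="session")
def small_registry():
    """Canonical 20 + 5 NCAAs, for cheap encoder tests."""
    return nb.make_registry(5, seed=0)


@pytest.fixture(scope="session")
def synthetic_export(tmp_path_factory, registry):
    """A default-scale synthetic export on disk (166 records + 40 distractors)."""
    path = tmp_path_factory.mktemp("data") / "export.csv"
    spec = nb.GenerativeSpec(seed=0)
    rows, truth = nb.generate(spec, registry, out_path=path)
    return path, truth


def make_export_file(path, rows, delimiter=","):
    """Write a minimal export with the five standard columns."""
    cols = ["Name", "Qualitative Measurement", "Quantitative Measurement",
            "Response Measured", "HLA"]
    with open(path, "w") as fh:
        fh.write(delimiter.join(cols) + "\n")
        for row in rows:
            fh.write(delimiter.join(str(row.get(c, "")) for c in cols) + "\n")
    return path


@pytest.fixture
def six_row_export(tmp_path):
    """2 fully valid rows plus one violator of each filter rule."""
    ic50 = "half maximal inhibitory concentration (IC50)"
    rows = [
        {"Name": "GILGFVFTL + OTH(L9)", "Quantitative Measurement": 32.0,
         "Response Measured": ic50, "HLA": "HLA-A*02:01"},
        {"Name": "SIINFEKLM + OTH(M9)", "Quantitative Measurement": 450.0,
         "Response Measured": "IC50", "HLA": "HLA-A*02:01"},
        {"Name": "GILGFVFTL", "Quantitative Measurement": 12.0,
         "Response Measured": ic50, "HLA": "HLA-A*02:01"},          # no NCAA
        {"Name": "GILGFVFTL + OTH(L9)", "Quantitative Measurement": "",
         "Response Measured": ic50, "HLA": "HLA-A*02:01"},          # missing value
        {"Name": "GILGFVFTL + OTH(L9)", "Quantitative Measurement": 100.0,
         "Response Measured": ic50, "HLA": "HLA-B*07:02"},          # wrong allele
        {"Name": "GILGFVFTL + OTH(L9)", "Quantitative Measurement": 100.0,
         "Response Measured": "EC50", "HLA": "HLA-A*02:01"},        # wrong response
    ]
    return make_export_file(tmp_path / "six.csv", rows)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
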