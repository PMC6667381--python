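import pytest

from rostrack import budget, synthetic, titration


@pytest.fixture(scope="session")
def xray_truth():
    return synthetic.xray_truth()


@pytest.fixture(scope="session")
def xray_curve(xray_truth):
    """Noiseless titration curve calibrated to the X-ray worked example."""
    return synthetic.generate_titration(xray_truth)


@pytest.fixture(scope="session")
def xray_estimate(xray_curve):
    return titration.analyze_titration(xray_curve)


@pytest.fixture(scope="session")
def table1():
    return budget.load_table1()


@pytest.fixture
def titration_csv(tmp_path, xray_curve):
    import pandas as pd

    path = tmp_path / "curve.csv"
    pd.DataFrame({"dmpo_mM": xray_curve.dmpo_mM,
                  "dmpoh_uM": xray_curve.dmpoh_uM}).to_csv(path, index=False)
    return path
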