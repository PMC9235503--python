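import numpy as np
import pytest

from fpkit.dbsearch import identification_rate
from fpkit.pipeline import calibrated_train_configs, train_and_evaluate
from fpkit.spectra_data.model import CompoundRecord, Spectrum
from fpkit.synthetic_fixtures import calibrated_fixture_config, generate_benchmark


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_spectrum(rng, n_peaks=8, structure_key="STRUCT", compound_id="c0"):
    mz = np.sort(rng.uniform(50, 450, size=n_peaks))
    intensity = rng.uniform(0.05, 1.0, size=n_peaks)
    return Spectrum(
        peaks=tuple(zip(mz, intensity)),
        precursor_mz=500.0,
        structure_key=structure_key,
        compound_id=compound_id,
    )


@pytest.fixture
def make_spectrum(rng):
    def factory(n_peaks=8, structure_key="STRUCT", compound_id="c0"):
        return random_spectrum(rng, n_peaks, structure_key, compound_id)

    return factory


@pytest.fixture
def random_records(rng):
    return [
        CompoundRecord(
            spectrum=random_spectrum(rng, compound_id=f"c{i}", structure_key=f"s{i}")
        )
        for i in range(10)
    ]


@pytest.fixture(scope="session")
def calibrated_benchmark():
    return generate_benchmark(calibrated_fixture_config(seed=7))


@pytest.fixture(scope="session")
def benchmark_results(calibrated_benchmark):
    """Both heads trained and evaluated once per session; reused by several
    end-to-end tests to keep the suite inside its time budget."""
    cfgs = calibrated_train_configs()
    out = {}
    for head in ("deep_kernel", "nystrom_svm"):
        res = train_and_evaluate(calibrated_benchmark, head, cfgs[head])
        out[head] = {
            "result": res,
            "mcc": res.report.mean_mcc,
            "bm": res.report.mean_bm,
            "id1": identification_rate(res.ranked, 1),
        }
    return out
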