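import pytest
from hypothesis import settings

import wardflow as wf
from wardflow.census import build_census, build_slot_grid
from wardflow.ingest import link, typed_from_sheets
from wardflow.synthetic import make_bundle

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def demo_cfg():
    """Small two-department, three-unit hospital over four weeks."""
    return wf.demo_config(seed=3)


@pytest.fixture(scope="session")
def bundle(demo_cfg):
    return make_bundle(demo_cfg)


@pytest.fixture(scope="session")
def defect_cfg():
    """Same hospital with realistic data-quality defects switched on."""
    return wf.demo_config(seed=11).with_(
        defect_rates=wf.DefectRates(missing_working_hours=0.15, outpatient=0.12, newborn=0.30),
        activity_outpatient_frac=0.05,
    )


@pytest.fixture(scope="session")
def defect_bundle(defect_cfg):
    return make_bundle(defect_cfg)


@pytest.fixture(scope="session")
def linked(bundle, demo_cfg):
    raw = typed_from_sheets(bundle.sheets())
    return link(raw, maternity_department=demo_cfg.maternity_department, keep_map=True)


@pytest.fixture(scope="session")
def grid(demo_cfg):
    return build_slot_grid(demo_cfg.units, demo_cfg.start_date, demo_cfg.end_date, 30)


@pytest.fixture(scope="session")
def census_df(bundle, grid):
    return build_census(bundle.truth.stays, bundle.truth.segments, grid)
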