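"""Shared fixtures: one synthetic world, reused across the suite.

Everything is generated programmatically at test time from fixed seeds; the
expensive artifacts (cross-validated ensemble, full pipeline run) are
session-scoped so the suite pays for them once.
"""

import numpy as np
import pytest
from hypothesis import settings

from mangroveshift import climate_prep, sdm_ensemble, synthetic_data
from mangroveshift.io_formats import RunConfig

settings.register_profile("repro", derandomize=True, database=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def config():
    return RunConfig(seed=1)


@pytest.fixture(scope="session")
def spec(config):
    # static spatial grid; 2 snapshots so interpolation paths stay exercised
    return config.domain_spec(n_hours=2)


@pytest.fixture(scope="session")
def truth():
    return synthetic_data.SyntheticTruth()


@pytest.fixture(scope="session")
def mask(spec):
    return synthetic_data.make_land_mask(spec, synthetic_data.default_coastline_params(spec))


@pytest.fixture(scope="session")
def occurrences(spec, truth, mask):
    return synthetic_data.make_occurrence_dataset(spec, truth, 2000, seed=1, mask=mask)


@pytest.fixture(scope="session")
def raster(spec, truth, mask):
    return synthetic_data.make_climate_raster(spec, truth, mask)


@pytest.fixture(scope="session")
def filled(occurrences, mask, raster):
    wb = climate_prep.WaterbodyConfig.from_mask(mask)
    return climate_prep.resolve_missing_climate(occurrences, wb, raster)


@pytest.fixture(scope="session")
def predictors(filled):
    retained, _ = climate_prep.screen_predictors(filled)
    return retained


@pytest.fixture(scope="session")
def cv_result(filled, predictors):
    return sdm_ensemble.evaluate_families(filled, predictors, reps=10, seed=1)


@pytest.fixture(scope="session")
def ensemble(filled, predictors, cv_result):
    means = cv_result.family_means()
    fitted = {
        fam: sdm_ensemble.fit_learner(sdm_ensemble.LearnerSpec(fam, seed=1), filled, predictors)
        for fam in sdm_ensemble.FAMILIES
    }
    return sdm_ensemble.build_ensemble(fitted, dict(zip(means["family"], means["TSS"])))


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    from mangroveshift import pipeline

    out = tmp_path_factory.mktemp("pipeline") / "run"
    return pipeline.run_all(RunConfig(seed=1), out)


@pytest.fixture(scope="session")
def tracker_run_10k():
    """10,000 particles drifting alongshore with a weak onshore component."""
    from mangroveshift.domain import DomainSpec
    from mangroveshift.lagrangian_tracker import ReleaseSchedule, advect

    spec = DomainSpec(lon_min=-81.0, lon_max=-80.0, lat_min=24.0, lat_max=26.0,
                      resolution=0.05, n_hours=1000)
    mask = synthetic_data.make_land_mask(
        spec, synthetic_data.CoastlineParams(coast_lon=-80.8, ecotone_lat=24.5)
    )
    field = synthetic_data.make_velocity_field(
        "coastal_jet_tidal",
        {"jet_u": -0.02, "jet_v": 0.3, "tidal_amplitude": 0.05, "tidal_period_hours": 12.0},
        spec, mask=mask,
    )
    coastal = np.argwhere(mask.coastal)
    schedule = ReleaseSchedule(spec, coastal, spec.t0, spec.t0 + np.timedelta64(250, "h"))
    assert schedule.n_events == 10000
    trajectories = advect(field, mask, schedule, max_float_months=1, seed=42)
    return spec, mask, trajectories


@pytest.fixture
def equatorial_spec():
    """Near-equatorial grid where the degree metric is nearly isotropic."""
    return synthetic_data.DomainSpec(
        lon_min=0.0, lon_max=2.0, lat_min=0.0, lat_max=1.0,
        resolution=1.0 / 24.0, t0=np.datetime64("2011-08-01T00:00"), n_hours=2,
    )
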