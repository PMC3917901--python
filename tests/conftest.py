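import numpy as np
import pytest
from hypothesis import settings

import platemix as pm

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def small_run():
    """A compact synthetic induction experiment shared across test modules.

    2 media / 2 wild-type / 2 tagged wells, 60 points at 12-min intervals,
    plus the media-corrected dataset, dilution-series calibration and fitted
    autofluorescence-ratio curve.
    """
    sc = pm.SyntheticScenario(seed=7)
    dataset, truth = pm.generate(
        sc, n_media=2, n_wildtype=2, n_tagged=2, n_timepoints=60
    )
    mc = pm.fit_media(dataset, seed=7)
    corrected, qc = pm.apply_media_correction(dataset, mc)
    table = pm.generate_dilution_series(sc.od_map, seed=7)
    cal = pm.fit_od_calibration(
        table["od"].to_numpy(), table["dilution_factor"].to_numpy(), seed=7
    )
    ra = pm.fit_ra(corrected, seed=7)
    return {
        "scenario": sc,
        "dataset": dataset,
        "truth": truth,
        "media": mc,
        "corrected": corrected,
        "qc": qc,
        "cal_table": table,
        "cal": cal,
        "ra": ra,
    }


@pytest.fixture(scope="session")
def full_run():
    """The reference-scale recovery experiment: 3 media / 3 wild-type /
    3 tagged wells, 100 points at 12-min intervals, n_ra=50, n_g=1000.
    """
    sc = pm.SyntheticScenario(seed=1)
    dataset, truth = pm.generate(
        sc, n_media=3, n_wildtype=3, n_tagged=3, n_timepoints=100
    )
    mc = pm.fit_media(dataset, seed=1)
    corrected, _ = pm.apply_media_correction(dataset, mc)
    table = pm.generate_dilution_series(sc.od_map, seed=1)
    cal = pm.fit_od_calibration(
        table["od"].to_numpy(), table["dilution_factor"].to_numpy(), seed=1
    )
    ra = pm.fit_ra(corrected, seed=1)
    bayes = pm.bayes_pipeline(corrected, ra, cal, n_ra=50, n_g=1000, seed=1)
    direct = pm.direct_pipeline(corrected, cal)
    return {
        "scenario": sc,
        "dataset": dataset,
        "truth": truth,
        "corrected": corrected,
        "cal": cal,
        "ra": ra,
        "bayes": bayes,
        "direct": direct,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
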