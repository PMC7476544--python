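import numpy as np
import pytest
from hypothesis import settings

import raytox as rt

settings.register_profile("repeatable", derandomize=True)
settings.load_profile("repeatable")

# Parameter sets mirroring the fitted-model summary of the motivating study:
# AgNO3 (μg/L) and ZnO nanoparticles (mg/L) against Daphnia magna mobility.
AG_PARAMS = dict(u_max=99.12, beta=2.38, ec50=0.91, unit_label="μg/L")
ZNO_PARAMS = dict(u_max=99.12, beta=0.68, ec50=2.21, unit_label="mg/L")


@pytest.fixture
def ag():
    return rt.LogLogisticParams(**AG_PARAMS)


@pytest.fixture
def zno():
    return rt.LogLogisticParams(**ZNO_PARAMS)


def mixture(u_max=99.12, beta1=2.38, ec50_1=0.91, beta2=0.68, ec50_2=2.21,
            deviation=None):
    chem = (rt.LogLogisticParams(u_max, beta1, ec50_1, "μg/L"),
            rt.LogLogisticParams(u_max, beta2, ec50_2, "mg/L"))
    return rt.MixtureParams(u_max, chem, deviation or rt.DeviationSpec())


@pytest.fixture
def ca_reference():
    return mixture()


@pytest.fixture
def ca_dr():
    """CA with a dose-ratio deviation: synergism at ZnO-rich ratios."""
    dev = rt.DeviationSpec(base=rt.Base.CA, kind=rt.DeviationKind.DR,
                           a=-2.39, b_dr=3.74)
    return mixture(u_max=98.05, beta1=2.37, ec50_1=0.91, beta2=0.69,
                   ec50_2=2.60, deviation=dev)


@pytest.fixture
def small_design():
    """Reduced design for fast fitting tests (same structure, fewer wells)."""
    return rt.DesignSpec(n_replicates=4)


def exact_dataset(params, base, design=rt.DEFAULT_DESIGN, n_exposed=10**6):
    """Near-noise-free dataset: huge wells, counts rounded to the prediction.

    Rounding limits percent-mobile error per treatment to 5e-5, so residuals
    at the generating parameters are ~1e-9 on the SS scale.
    """
    ec50s = (params.chem[0].ec50, params.chem[1].ec50)
    obs = []
    for t, concs in enumerate(rt.build_design(design, ec50s)):
        y = rt.predict_mixture(params, concs, base)
        k = round(n_exposed * (1.0 - y / 100.0))
        obs.append(rt.QuantalObservation(
            concentrations=concs, replicate_id="r1", n_exposed=n_exposed,
            n_immobile=k, treatment_id=f"t{t:02d}"))
    units = (params.chem[0].unit_label, params.chem[1].unit_label)
    return rt.Dataset(observations=obs, units=units)
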