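import warnings

import numpy as np
import pytest

from dceqc import ModelAifParams, model_aif
from dceqc.config import PipelineConfig
from dceqc.phantom import generate_phantom, make_category_phantom
from dceqc.pipeline import run_pipeline

warnings.filterwarnings("ignore", category=RuntimeWarning)

SEED = 11


@pytest.fixture(scope="session")
def frame_times():
    return np.arange(0, 543, 3.0)  # 181 frames at 3 s


@pytest.fixture(scope="session")
def default_aif(frame_times):
    return model_aif(ModelAifParams(), dose=0.1, times=frame_times, onset=30.0)


def quadrature_oracle(params, aif, times, nfine=4000):
    """Brute-force fine-grid trapezoidal evaluation of the tissue curve."""
    kep = params.ktrans / params.ve if params.ktrans > 0 else 0.0
    out = np.empty(len(times))
    for i, t in enumerate(times):
        if t == 0:
            out[i] = params.vp * aif.interp(0.0)
            continue
        tf = np.linspace(0.0, t, nfine)
        cpf = aif.interp(tf)
        tmin = tf / 60.0
        out[i] = params.vp * aif.interp(t) + params.ktrans * np.trapezoid(
            cpf * np.exp(-kep * (t / 60.0 - tmin)), tmin)
    return out


@pytest.fixture(scope="session")
def noiseless_phantom():
    return generate_phantom(make_category_phantom(noise_sd=0.0, seed=SEED))


@pytest.fixture(scope="session")
def noisy_phantom():
    return generate_phantom(make_category_phantom(seed=SEED))  # design noise


def _run(data):
    spec = data.spec
    return run_pipeline(data.dynamic, data.times, spec.acq, data.mfa,
                        data.mfa_angles, data.tumour_mask,
                        artery_mask=data.artery_mask, config=PipelineConfig(),
                        aif_override=data.truth.aif)


@pytest.fixture(scope="session")
def noiseless_result(noiseless_phantom):
    return _run(noiseless_phantom)


@pytest.fixture(scope="session")
def noisy_result(noisy_phantom):
    return _run(noisy_phantom)
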