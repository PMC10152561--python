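import numpy as np
import pytest

from csfgrad import gradient as gr
from csfgrad import phantom as ph
from csfgrad.config import PipelineConfig


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Default-geometry phantom with the noise switched off."""
    return ph.make_phantom(ph.PhantomSpec(noise_sd=0.0))


@pytest.fixture(scope="session")
def noiseless_table(noiseless_phantom):
    """Voxel table of the noiseless default phantom under default config."""
    out = noiseless_phantom
    pv = gr.PatientVolumes("p0", out.adc, out.masks.wm, out.masks.irl,
                           out.masks.non_irl, csf_prob=out.prob["CSF"])
    return gr.process_patient(pv, PipelineConfig())


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)
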