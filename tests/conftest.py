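import numpy as np
import pytest

import pwvbold as p
from pwvbold import metrics, signals


@pytest.fixture(scope="session")
def small_cohort():
    """20-subject cohort on a small grid, shared across read-only tests."""
    return p.generate_cohort(n_parent=10, n_offspring=10, dims=(8, 8, 4),
                             n_frames=60, seed=3)


@pytest.fixture(scope="session")
def cohort_maps(small_cohort):
    """Per-subject BOLD/CBF variance stacks for the small cohort."""
    coh = small_cohort
    dens = [signals.separate(s, fwhm=0.0) for s in coh.series]
    bold_var = np.stack(
        [metrics.variance_map(d.bold, coh.atlases["brain"]).values
         for d in dens], axis=-1)
    cbf_var = np.stack(
        [metrics.cbf_variance_map(d.cbf_signal, coh.atlases["gm"]).values
         for d in dens], axis=-1)
    return {"bold_var": bold_var, "cbf_var": cbf_var, "denoised": dens}
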