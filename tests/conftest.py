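import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


def freqs_from_matrix(f, D=50):
    """Long frequency table from a site x host matrix (constant depth)."""
    f = np.asarray(f, dtype=float)
    S, M = f.shape
    return pd.DataFrame(
        {
            "site_id": np.repeat([f"s{i:04d}" for i in range(S)], M),
            "host_id": np.tile([f"h{m:04d}" for m in range(M)], S),
            "f": f.ravel(),
            "D": float(D),
            "depth_ok": True,
        }
    )


@pytest.fixture(scope="session")
def mixed_cohort():
    """A small mixed (strain + evolutionary) cohort with ground truth."""
    import afmacro as am

    spec = am.CohortSpec(n_hosts=100, n_strain_sites=400, n_evo_sites=100)
    counts, truth = am.generate_cohort(spec, seed=123)
    return spec, counts, truth
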