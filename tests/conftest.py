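import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20259)


@pytest.fixture
def small_csv(tmp_path):
    """A 4-row valid ELISA table with one condition alias."""
    path = tmp_path / "assay.csv"
    path.write_text(
        "assay,group,condition,horse,rep,value\n"
        "TNFa_ELISA,adult,Control,A1,1,12.0\n"
        "TNFa_ELISA,adult,LPS,A1,1,812.5\n"
        "TNFa_ELISA,foal,LPS+PCSK,F1,1,93.1\n"
        "TNFa_ELISA,foal,PCSK,F1,2,55.0\n"
    )
    return path
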