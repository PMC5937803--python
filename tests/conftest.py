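import matplotlib
import pytest
from hypothesis import HealthCheck, settings

matplotlib.use("Agg")

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def leydig_graph():
    from steroflow.models import build_rat_leydig

    return build_rat_leydig()


@pytest.fixture(scope="session")
def leydig_net(leydig_graph):
    from steroflow.engine import compile_net

    return compile_net(leydig_graph)


@pytest.fixture(scope="session")
def framework_graph():
    from steroflow.models import build_human_framework

    return build_human_framework()
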