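import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def partition():
    from limerad import default_partition

    return default_partition()


#: one hand-built instance of every example pattern (first 4 accessions =
#: Bhutanese-role cluster, next 2 = subcluster 1, last 2 = subcluster 2)
CATEGORY_EXAMPLES = {
    "A": "MMMM MMMM",
    "B": "AAAA CCCC",
    "C": "MMMM AAAA",
    "D": "AAAA MMMM",
    "E": "MMMM MAMA",
    "F": "MAMA MMMM",
    "G": "AAAA MAMA",
    "H": "MAMA AAAA",
    "I": "MAAA MAAC",
    "J": "AAAA AACC",
    "K": "AACC GGGG",
    "L": "MMMM RRRR",
    "U": "AAAA CCGG",
}


@pytest.fixture(scope="session")
def category_examples():
    return dict(CATEGORY_EXAMPLES)
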