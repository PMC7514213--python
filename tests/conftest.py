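import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from sensegain import demo_model, random_decomposed_model, random_model
from sensegain.models import with_known_initial_environment


@pytest.fixture(scope="session")
def demo():
    """Bundled three-state nutrient model with the pinned decomposition."""
    return demo_model()


@pytest.fixture(scope="session")
def demo_known_y0(demo):
    """The bundled model conditioned on a known initial environment state."""
    return with_known_initial_environment(demo, "s1y")


@pytest.fixture(scope="session")
def small_random_models():
    """A sweep of small random models (some with memory) for property checks."""
    return [
        random_model((2, 2, 2), seed=0),
        random_model((2, 3, 2), seed=1),
        random_model((3, 2, 3), seed=2),
        random_model((2, 2, 3), seed=3, memoryless=False),
        random_model((1, 2, 2), seed=4),
    ]


@pytest.fixture(scope="session")
def small_decomposed_models():
    """Random models with a guaranteed-valid allocation decomposition."""
    return [
        random_decomposed_model((2, 2, 2), seed=10),
        random_decomposed_model((2, 3, 2), seed=11),
        random_decomposed_model((3, 3, 2), seed=12),
    ]
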