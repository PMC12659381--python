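import pytest

from ncd_excess import generate_inputs


@pytest.fixture(scope="session")
def small_bundle():
    """Three-disease bundle (one per model kind) on a short grid."""
    bundle, truth = generate_inputs(1, profile="small")
    return bundle, truth


@pytest.fixture(scope="session")
def paper_like_bundle():
    """Five-disease bundle on the full 2000-2024 monthly grid."""
    bundle, truth = generate_inputs(1, profile="paper_like")
    return bundle, truth
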