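import pytest

from cidscope.synthetic_data import default_model, simulate_strain


@pytest.fixture(scope="session")
def model():
    return default_model(0)


@pytest.fixture(scope="session")
def strain_k3(model):
    return simulate_strain(model, 3, seed=1, strain_id="k3")


@pytest.fixture(scope="session")
def strain_k1(model):
    return simulate_strain(model, 1, seed=1, strain_id="k1")


@pytest.fixture(scope="session")
def strain_rich(model):
    """Six distinct cidA variants and four distinct cidB variants."""
    choices = [
        (("α", "1"), ("a", "1")),
        (("β", "1"), ("a", "2")),
        (("γ", "1"), ("b", "1")),
        (("δ", "1"), ("b", "3")),
        (("α", "2"), ("a", "1")),
        (("δ", "2"), ("a", "2")),
    ]
    return simulate_strain(model, 6, variant_choices=choices, seed=7, strain_id="rich")
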