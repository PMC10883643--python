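import pytest

from dockbench.fixtures import FixtureSpec, generate_toy_case


@pytest.fixture(scope="session")
def unperturbed_toy():
    """Bound complex whose unbound components differ only by a rigid motion."""
    return generate_toy_case(FixtureSpec(seed=11))


@pytest.fixture(scope="session")
def shifted_toy():
    """Case whose interface residues are displaced by exactly 3 A RMS."""
    return generate_toy_case(
        FixtureSpec(perturbation="rigid_shift", magnitude=3.0, seed=12)
    )
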