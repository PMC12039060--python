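import pytest

from tmcsmiles import xyz_to_smiles
from tmcsmiles.fixtures import fixture_suite, make_fixture


@pytest.fixture(scope="session")
def suite_results():
    """Every toy fixture converted once: {name: (spec, ConversionResult)}."""
    out = {}
    for spec in fixture_suite():
        xyz, _ = make_fixture(spec)
        out[spec.name] = (spec, xyz_to_smiles(xyz, spec.overall_charge))
    return out


@pytest.fixture(scope="session")
def successful_results(suite_results):
    return {
        name: (spec, res)
        for name, (spec, res) in suite_results.items()
        if spec.expected.failure_stage is None
    }
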