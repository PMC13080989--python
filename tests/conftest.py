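import numpy as np
import pytest

from fragmops.cbu_assembler import assemble_geometry
from fragmops.cbu_templates import default_templates, expand_orientations
from fragmops.workbench_io import (
    FixtureSpec,
    generate_fixture_library,
    generate_fixture_metals,
)


@pytest.fixture(scope="session")
def library():
    return generate_fixture_library(FixtureSpec(seed=0))


@pytest.fixture(scope="session")
def metals():
    return generate_fixture_metals()


@pytest.fixture(scope="session")
def templates():
    return {t.name: t for t in default_templates()}


@pytest.fixture(scope="session")
def carboxylate(library):
    return library["*C(=O)[O-]"]


@pytest.fixture(scope="session")
def phenylene(library):
    return library["*c1ccc(*)cc1"]


def two_arm_assignment(template, binding_group, linkers):
    """Build a slot assignment for a 2-arm template."""
    positions = [s.position for s in template.slots]
    asg = {positions[0]: binding_group, positions[-1]: binding_group}
    for p, lk in zip(positions[1:-1], linkers):
        asg[p] = lk
    return asg


@pytest.fixture(scope="session")
def terephthalate_cbu(templates, carboxylate, phenylene):
    tmpl = templates["linear-1"]
    asg = two_arm_assignment(tmpl, carboxylate, [phenylene])
    ori = expand_orientations(tmpl, asg, symmetric=True)[0]
    return assemble_geometry(tmpl, asg, ori)


@pytest.fixture(scope="session")
def slim_cbu(templates, library, carboxylate):
    """Narrow CBU (butadienylene linker) that fits the lantern models."""
    tmpl = templates["linear-1"]
    asg = two_arm_assignment(tmpl, carboxylate, [library["*/C=C/C=C/*"]])
    ori = expand_orientations(tmpl, asg, symmetric=True)[0]
    return assemble_geometry(tmpl, asg, ori)
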