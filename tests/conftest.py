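import pytest

from glycotree.linkage import (
    assemble_oligomer,
    man_glcnac_topology,
    nag2man_topology,
    trimannose_topology,
)
from glycotree.templates import build_template
from glycotree.tree import builtin_catalog, enumerate_conformers

TRISACCHARIDE_CATALOGS = (
    "nag2man-trans-trans1",
    "nag2man-trans-cis1",
    "nag2man-cis-cis1",
    "nag2man-cis-trans1",
)
ALL_CATALOGS = TRISACCHARIDE_CATALOGS + (
    "trimannose",
    "pentasaccharide-strategy1",
    "pentasaccharide-strategy2",
    "pentasaccharide-strategy3",
)


@pytest.fixture(scope="session")
def mannose():
    return build_template("alpha-D-Man")


@pytest.fixture(scope="session")
def glcnac():
    return build_template("beta-D-GlcNAc")


@pytest.fixture(scope="session")
def trisaccharide_tt():
    """Manβ(1,4)GlcNAcβ(1,4)GlcNAc skeleton, trans-trans1."""
    return assemble_oligomer(nag2man_topology("trans", "trans"))


@pytest.fixture(scope="session")
def trimannose_cc():
    return assemble_oligomer(trimannose_topology("cis", "cis"))


@pytest.fixture(scope="session")
def disaccharide_trans():
    return assemble_oligomer(man_glcnac_topology("trans"))


@pytest.fixture(scope="session")
def catalogs():
    """All built-in catalogs, materialized once."""
    return {name: builtin_catalog(name) for name in ALL_CATALOGS}


@pytest.fixture(scope="session")
def enumerations(catalogs):
    """Full enumeration results for every built-in catalog."""
    return {name: enumerate_conformers(cat) for name, cat in catalogs.items()}
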