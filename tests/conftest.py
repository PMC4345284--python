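"""Shared fixtures: domain tables, synthetic proteins and scaffolds."""

import numpy as np
import pytest

from crosscoil.structure import AssemblyModel, FragmentModel
from crosscoil.synth import LinkSimSpec, ScaffoldSpec, make_dimer_scaffold, simulate_crosslinks
from crosscoil.xlink import DomainTable, ProteinDef, ProteinRegistry

# d1–d5 boundaries of the chicken condensin SMC proteins (head/coil/hinge
# segmentation used throughout the classification tests)
SMC2_SEGMENTS = [
    ("d1", 1, 167, "head"),
    ("d2", 168, 506, "coil"),
    ("d3", 507, 674, "hinge"),
    ("d4", 675, 1028, "coil"),
    ("d5", 1029, 1189, "head"),
]
SMC4_SEGMENTS = [
    ("d1", 79, 250, "head"),
    ("d2", 251, 591, "coil"),
    ("d3", 592, 766, "hinge"),
    ("d4", 767, 1128, "coil"),
    ("d5", 1129, 1300, "head"),
]


def _synthetic_sequence(length: int) -> str:
    """Deterministic stand-in sequence of the right length (synthetic: the
    real database sequences are not bundled)."""
    alphabet = "ACDEFGHIKLMNPQRSTVWY"
    return "".join(alphabet[i % len(alphabet)] for i in range(length))


@pytest.fixture(scope="session")
def smc_registry() -> ProteinRegistry:
    reg = ProteinRegistry()
    reg.add(ProteinDef("SMC2", _synthetic_sequence(1189)))
    reg.add(ProteinDef("SMC4", _synthetic_sequence(1300)))
    reg.add(ProteinDef("CAP-H", _synthetic_sequence(730)))
    return reg


@pytest.fixture(scope="session")
def smc_domains() -> DomainTable:
    table = DomainTable()
    for name, start, end, kind in SMC2_SEGMENTS:
        table.add("SMC2", name, start, end, kind)
    for name, start, end, kind in SMC4_SEGMENTS:
        table.add("SMC4", name, start, end, kind)
    table.disruptions["SMC4"] = [(1035, 1067, "pro_rich")]
    return table


@pytest.fixture(scope="session")
def scaffold():
    """Default two-coil rod scaffold: (assembly, registry, domains)."""
    return make_dimer_scaffold(ScaffoldSpec(seed=0))


@pytest.fixture(scope="session")
def scaffold_links(scaffold):
    assembly, _, _ = scaffold
    return simulate_crosslinks(assembly, LinkSimSpec(seed=3))


@pytest.fixture()
def three_fragment_scaffold(scaffold):
    """The default scaffold with its second coil split into two fragments."""
    assembly, registry, domains = scaffold
    coil_b = assembly.fragments[1]
    pid = coil_b.segments[0][0]
    upper = {k: r for k, r in coil_b.residues.items() if k[1] <= 35 or k[1] >= 111}
    lower = {k: r for k, r in coil_b.residues.items() if k not in upper}
    f_b1 = FragmentModel(
        "B_upper", [(pid, 1, 35, "+"), (pid, 111, 145, "-")], upper
    )
    f_b2 = FragmentModel(
        "B_lower", [(pid, 36, 70, "+"), (pid, 76, 110, "-")], lower
    )
    return AssemblyModel(
        [assembly.fragments[0].copy(), f_b1.copy(), f_b2.copy()]
    ), registry, domains
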