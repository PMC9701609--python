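import numpy as np
import pytest

from gmma import ProteinVariant, ReferenceTemplate, Substitution
from gmma.pipeline import simulate_dataset
from gmma.simulate import default_template


@pytest.fixture(scope="session")
def tiny_template() -> ReferenceTemplate:
    """Handcrafted 6-codon template: window translates to MKEGCL (residues 48-53),
    10-base flanks, every window base doped."""
    window = "ATG" "AAA" "GAA" "GGT" "TGC" "CTG"
    dna = "ACGTACGTAC" + window + "TGCATGCATG"
    return ReferenceTemplate(
        dna_sequence=dna,
        window=(10, 28),
        doped_positions=frozenset(range(10, 28)),
        protein_offset=48,
        frame=0,
    )


@pytest.fixture(scope="session")
def template() -> ReferenceTemplate:
    return default_template()


@pytest.fixture(scope="session")
def compensation_variants() -> tuple[dict[str, Substitution], list[ProteinVariant]]:
    """Eight variants over four substitutions exhibiting mutual compensation:
    B rescues the inactivation caused by combining A and D, while C
    inactivates on its own."""
    subs = {
        "A": Substitution(48, "A", "V"),
        "B": Substitution(49, "L", "P"),
        "C": Substitution(50, "G", "R"),
        "D": Substitution(51, "K", "E"),
    }

    def make(names: str, active: bool) -> ProteinVariant:
        members = tuple(sorted((subs[n] for n in names), key=lambda s: s.residue))
        return ProteinVariant(substitutions=members, active=active)

    variants = [
        make("A", True),
        make("D", True),
        make("AD", False),
        make("ABD", True),
        make("C", False),
        make("BC", False),
        make("AB", True),
        make("CD", False),
    ]
    return subs, variants


@pytest.fixture(scope="session")
def small_screen():
    """A modest seeded simulate->screen->label run shared across tests."""
    variants, truth, template = simulate_dataset(seed=11, n_transformants=3000)
    return variants, truth, template


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
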