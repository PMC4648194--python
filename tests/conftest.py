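import pytest

from rhizoglob.synthetic_data import (
    GlobinPlanting,
    SyntheticGenomeSpec,
    generate_genome,
)
from rhizoglob.synthetic_references import reference_globins


@pytest.fixture(scope="session")
def refs():
    return reference_globins()


#: the six globin types actually found in rhizobial genomes
RHIZOBIAL_TYPES = ("ref_fhb", "ref_sdgb", "ref_gcs", "ref_thb1", "ref_thb2", "ref_thb3")


@pytest.fixture(scope="session")
def planted_bundle(refs):
    """Two-scaffold genome with planted globins, motifs and neighbors."""
    spec = SyntheticGenomeSpec(
        seed=11,
        n_scaffolds=2,
        scaffold_length=15_000,
        plantings=(
            GlobinPlanting(
                "ref_sdgb",
                0.0,
                0,
                "+",
                3000,
                promoter_plantings=(("-35", -41, 0), ("Fnr", -115, 5), ("SD", -12, 0)),
                neighbor_plantings=(
                    ("chemotaxis protein CheY", 1600, 600),
                    ("hypothetical protein", -900, 450),
                ),
            ),
            GlobinPlanting(
                "ref_thb2",
                0.0,
                1,
                "-",
                5000,
                promoter_plantings=(("-10", -30, 1),),
            ),
        ),
    )
    return spec, generate_genome(spec, refs)
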