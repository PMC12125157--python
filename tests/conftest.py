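import pytest

from fishmet.harmonize import SpeciesCatalogEntry, SpeciesProfile
from fishmet.toxdata import Feeding, Habitat, Metal, default_exposure, load_toxref


@pytest.fixture(scope="session")
def toxref():
    return load_toxref()


@pytest.fixture(scope="session")
def exposure():
    return default_exposure()


@pytest.fixture
def catalog():
    """Catalog naming species the compiled literature covers, including a
    euryhaline/freshwater dual-habitat goby that yields two profiles."""
    return [
        SpeciesCatalogEntry(
            species="Heteropneustes fossilis",
            habitat="freshwater",
            feeding="omnivorous",
            aliases=("stinging catfish",),
        ),
        SpeciesCatalogEntry(
            species="Liza parsia", habitat="euryhaline", feeding="herbivorous"
        ),
        SpeciesCatalogEntry(
            species="Glossogobius giuris", habitat="freshwater", feeding="carnivorous"
        ),
        SpeciesCatalogEntry(
            species="Glossogobius giuris", habitat="euryhaline", feeding="carnivorous"
        ),
        SpeciesCatalogEntry(
            species="Tenualosa ilisha", habitat="saltwater", feeding="omnivorous"
        ),
    ]


def make_profile(species="sp", habitat=Habitat.freshwater, feeding=Feeding.omnivorous,
                 **conc):
    conc_map = {Metal(k): v for k, v in conc.items()}
    return SpeciesProfile(
        species=species,
        habitat=habitat,
        feeding=feeding,
        conc=conc_map,
        support={m: 1 for m in conc_map},
    )
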