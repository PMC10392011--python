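import pytest

from olfrep.annotate import GeneModel, iterate_annotation
from olfrep.simulate import make_references, plant_genome, small_config


def make_model(gid, start, end, scaffold="s", family="OR", strand="+",
               protein="", status="intact"):
    return GeneModel(
        id=gid,
        family=family,
        subtype=None,
        scaffold=scaffold,
        start=start,
        end=end,
        strand=strand,
        exons=((start, end),),
        protein=protein,
        status=status,
    )


@pytest.fixture(scope="session")
def references():
    return make_references(3, seed=1)


@pytest.fixture(scope="session")
def planted(references):
    """A compact planted genome with its truth annotation."""
    genome, truth = plant_genome(small_config(seed=1), references)
    return genome, truth


@pytest.fixture(scope="session")
def annotated(planted, references):
    """Models recovered from the planted genome by the full iteration."""
    genome, _truth = planted
    models, info = iterate_annotation(genome, references)
    return models, info
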