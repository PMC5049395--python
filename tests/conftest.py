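import numpy as np
import pytest
from hypothesis import settings

from poolmap import annotate, simcross, variantio

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_genome():
    """One 200 kb chromosome; enough G/C sites for any test here."""
    return simcross.make_genome(1, [200_000], gc_fraction=0.4, seed=11)


@pytest.fixture(scope="session")
def genic_genome():
    """A 2 x 150 kb genome with 8 planted toy genes, plus the models."""
    base = simcross.make_genome(2, [150_000, 150_000], gc_fraction=0.4,
                                seed=23)
    models, genome = annotate.make_toy_gene_models(base, 8, seed=29,
                                                   n_exons=(2, 3))
    return models, genome


@pytest.fixture(scope="session")
def default_experiment(small_genome):
    """A simulated experiment: variants, F2 population, causal index."""
    variants = simcross.apply_ems(small_genome, 40, seed=5)
    population = simcross.simulate_f2(variants, small_genome, 400, seed=7)
    return {
        "genome": small_genome,
        "variants": variants,
        "population": population,
        "causal_index": simcross.causal_index(variants),
    }


@pytest.fixture()
def simulated_table(default_experiment):
    """Suppressed + control pooled counts as a VariantTable."""
    exp = default_experiment
    supp = simcross.build_pools(exp["population"], 30, simcross.SUPPRESSED,
                                n_misclassified=0, seed=13, label="supp")
    ctrl = simcross.build_pools(exp["population"], 30,
                                simcross.NON_SUPPRESSED,
                                n_misclassified=0, seed=17, label="ctrl")
    counts = {
        "supp": simcross.sequence_pool(supp, 60, 0.0, seed=19),
        "ctrl": simcross.sequence_pool(ctrl, 60, 0.0, seed=21),
    }
    return variantio.from_simulation(exp["variants"], counts, exp["genome"])
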