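import numpy as np
import pandas as pd
import pytest

from castepop import synthetic_data as syn
from castepop.io_formats import VariantTable


def make_variant_table(genotypes, pos=None, species=None, population=None,
                       ref=None, alt=None, contig="chr1"):
    """Small VariantTable from a (sites x samples) dosage list."""
    g = np.asarray(genotypes, dtype=np.int8)
    n_sites, n_samples = g.shape
    pos = np.arange(1, n_sites + 1) if pos is None else np.asarray(pos)
    species = ["spA"] * n_samples if species is None else list(species)
    population = ["pop1"] * n_samples if population is None else list(population)
    return VariantTable(
        contig=np.array([contig] * n_sites, dtype=object),
        pos=pos,
        ref=np.array(["A"] * n_sites, dtype=object) if ref is None else np.asarray(ref, dtype=object),
        alt=np.array(["T"] * n_sites, dtype=object) if alt is None else np.asarray(alt, dtype=object),
        genotypes=g,
        samples=[f"s{i}" for i in range(n_samples)],
        species=np.array(species, dtype=object),
        population=np.array(population, dtype=object),
    )


@pytest.fixture(scope="session")
def small_simulation():
    """A modest two-species simulation shared across tests (default regimes)."""
    cfg = syn.SimulationConfig(
        n_genes_per_class={"queen_biased": 20, "worker_biased": 20, "unbiased": 20},
        seed=7,
    )
    seqs, genes, vt, truth = syn.simulate_genomes(cfg)
    return {"cfg": cfg, "seqs": seqs, "genes": genes, "vt": vt, "truth": truth}
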