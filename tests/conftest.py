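import numpy as np
import pytest

from riboquant.annotation import Genome, Orf, protein_molecular_weight
from riboquant.simulate import SimConfig, simulate_footprints, simulate_genome


def make_orf(locus_tag="g1", chromosome="c1", start=0, end=300, strand="+",
             protein="M" + "A" * 98):
    return Orf(locus_tag=locus_tag, chromosome=chromosome, start=start,
               end=end, strand=strand, protein_sequence=protein,
               mol_weight=protein_molecular_weight(protein))


@pytest.fixture
def write_fasta(tmp_path):
    def _write(records, name="genome.fasta"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for rid, seq in records:
                fh.write(f">{rid}\n{seq}\n")
        return path
    return _write


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated study shared across tests (20 ORFs, 50k reads)."""
    cfg = SimConfig(seed=7, n_orfs=20, n_reads=50_000)
    sim = simulate_genome(cfg)
    reads = simulate_footprints(sim, cfg)
    return cfg, sim, reads


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
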