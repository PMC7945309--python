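import numpy as np
import pytest

from gbsfoil.simulate import (IntrogressionEvent, SimulationConfig,
                              simulate_matrix)

#: canonical five-taxon scan topology: (P1,P2) split 0.3, (P3,P4) split 0.6,
#: joint ancestor 1.0, outgroup 1.5
QUINTET_TREE = "(((P1:0.3,P2:0.3):0.7,(P3:0.6,P4:0.6):0.4):0.5,OUT:1.5);"
QUINTET = ("P1", "P2", "P3", "P4", "OUT")


def quintet_config(events=(), n_loci=400, seed=0, **overrides):
    """Single-individual-per-taxon system on the canonical quintet."""
    kwargs = dict(species_tree=QUINTET_TREE, pops_per_taxon=1, inds_per_pop=1,
                  n_loci=n_loci, seed=seed, dropout=0.0, paralog_rate=0.0,
                  events=list(events))
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


def quintet_supermatrix(config):
    """Taxon-level supermatrix rows for the canonical quintet, ordered
    P1, P2, P3, P4, OUT."""
    from gbsfoil import _seq
    from gbsfoil.datasets import build_dataset, to_sequence_dataset

    matrix, truth = simulate_matrix(config)
    ds = build_dataset(matrix, "taxon", truth.grouping)
    seq = to_sequence_dataset(ds, np.random.default_rng(config.seed))
    return np.stack([_seq.encode(seq.sequences[u]) for u in QUINTET])


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture(scope="session")
def small_system():
    """A 13-taxon no-event system shared by read-only tests."""
    config = SimulationConfig(n_loci=150, seed=11)
    matrix, truth = simulate_matrix(config)
    return config, matrix, truth


@pytest.fixture(scope="session")
def introgressed_system():
    """13-taxon system with one strong donor->recipient event."""
    event = IntrogressionEvent(donor="capillacea_albanian", recipient="langii",
                               gamma=0.5, t_admix=0.05)
    config = SimulationConfig(n_loci=500, seed=5, events=[event])
    matrix, truth = simulate_matrix(config)
    return config, matrix, truth
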