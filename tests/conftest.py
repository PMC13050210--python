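import numpy as np
import pytest

from crossplan import simstudy as ss
from crossplan.popdata import ClassValueMap, GeneticMap, ParentPanel, TraitEffects


@pytest.fixture(scope="session")
def small_map():
    """Two chromosomes x 10 loci, 90 cM each (LD-rich spacing)."""
    return GeneticMap(
        marker=np.array([f"m{i}" for i in range(20)], object),
        chrom=np.array(["c1"] * 10 + ["c2"] * 10, object),
        pos_cm=np.array(list(np.linspace(0, 90, 10)) * 2),
    )


def _markov_haplotypes(n, nl, rng, stay=0.9):
    H = np.zeros((n, nl), dtype=np.int8)
    H[:, 0] = rng.integers(0, 2, n)
    for j in range(1, nl):
        flip = rng.random(n) >= stay
        H[:, j] = np.where(flip, 1 - H[:, j - 1], H[:, j - 1])
    return H


def _phased_panel(ploidy, n_parents, gmap, seed, homozygous=False):
    rng = np.random.default_rng(seed)
    nl = gmap.n_loci
    if homozygous:
        h = _markov_haplotypes(n_parents, nl, rng)
        H = np.repeat(h[:, None, :], ploidy, axis=1)
    else:
        H = _markov_haplotypes(n_parents * ploidy, nl, rng).reshape(n_parents, ploidy, nl)
    return ParentPanel(
        ploidy=ploidy,
        dosages=H.sum(axis=1),
        names=np.array([f"P{i}" for i in range(n_parents)], object),
        gmap=gmap,
        haplotypes=H,
        subpop=np.array(["a"] * (n_parents // 2) + ["b"] * (n_parents - n_parents // 2), object),
    )


@pytest.fixture(scope="session")
def dh_panel(small_map):
    """Eight fully homozygous diploid lines with within-pool LD."""
    return _phased_panel(2, 8, small_map, seed=10, homozygous=True)


@pytest.fixture(scope="session")
def het_panel(small_map):
    """Eight heterozygous phased diploid clones."""
    return _phased_panel(2, 8, small_map, seed=11)


@pytest.fixture(scope="session")
def tetra_panel(small_map):
    """Eight heterozygous phased autotetraploid genotypes."""
    return _phased_panel(4, 8, small_map, seed=12)


@pytest.fixture(scope="session")
def effects20():
    rng = np.random.default_rng(20)
    return TraitEffects(additive=rng.normal(size=20), dominance=rng.normal(size=20) * 0.5)


@pytest.fixture(scope="session")
def additive20():
    rng = np.random.default_rng(21)
    return TraitEffects(additive=rng.normal(size=20), dominance=np.zeros(20))


@pytest.fixture(scope="session")
def cvm2():
    return ClassValueMap.default(2)


@pytest.fixture(scope="session")
def cvm4():
    return ClassValueMap.heterozygosity(4)


@pytest.fixture(scope="session")
def sim_diploid_small():
    """Scaled-down synthetic diploid dataset (200 loci, 4 chromosomes)."""
    cfg = ss.SimConfig(n_loci=200, n_chrom=4)
    return ss.make_diploid_dataset(cfg, seed=101)


@pytest.fixture(scope="session")
def sim_clonal_small():
    cfg = ss.SimConfig(n_loci=200, n_chrom=4)
    return ss.make_diploid_dataset(cfg, seed=102, dh=False)


@pytest.fixture(scope="session")
def sim_tetra_small():
    cfg = ss.SimConfig(n_loci=200, n_chrom=4, ploidy=4)
    return ss.make_tetraploid_dataset(cfg, seed=103)
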