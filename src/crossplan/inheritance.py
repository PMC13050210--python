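"""Per-locus gamete/genotype-class probability engines and a meiosis simulator.

Analytic side: small transition tables over dosage classes give, for any
breeding pipeline (F1, selfing chains, doubled haploids, testcrosses) and
ploidy 2 or 4, the marginal genotype-class distribution of a prospective family
at every locus.  Diploid gametes are Mendelian; autotetraploid gametes follow
random bivalent pairing with polysomic inheritance and no double reduction, so
a parent of dosage m transmits k copies with hypergeometric probability
C(m,k) C(4-m,2-k) / C(4,2).

Simulation side: :func:`simulate_progeny` runs whole-genome meioses with
crossovers from a Poisson process on the genetic map (Haldane model, no
interference), applying the scheme generation by generation.  It is the
independent truth oracle against which the analytic means/variances are tested.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.special import comb

from .popdata import CrossScheme, GeneticMap, PanelValidationError, ParentPanel

__all__ = [
    "gamete_dist",
    "gamete_matrix",
    "f1_locus_dist",
    "f1_table",
    "self_transition",
    "self_locus_dist",
    "dh_locus_dist",
    "testcross_locus_dist",
    "family_locus_dists",
    "simulate_progeny",
    "simulate_gametes",
]

_SUM_TOL = 1e-12


def _check_dist(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if np.any(p < -_SUM_TOL) or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("not a probability distribution")
    return p


# ---------------------------------------------------------------------------
# Class-probability engines
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def gamete_matrix(ploidy: int) -> np.ndarray:
    """G[m, k] = P(gamete carries k effect alleles | parent dosage m).

    Rows m = 0..ploidy, columns k = 0..ploidy/2.
    """
    if ploidy % 2 or ploidy < 2:
        raise PanelValidationError("ploidy must be an even integer >= 2")
    half = ploidy // 2
    m = np.arange(ploidy + 1)[:, None]
    k = np.arange(half + 1)[None, :]
    G = comb(m, k) * comb(ploidy - m, half - k) / comb(ploidy, half)
    return G


def gamete_dist(parent_dosage: int, ploidy: int) -> np.ndarray:
    """Gamete dosage distribution (length ploidy/2 + 1) for one parent dosage."""
    if not 0 <= parent_dosage <= ploidy:
        raise ValueError(f"dosage {parent_dosage} out of range for ploidy {ploidy}")
    return gamete_matrix(ploidy)[int(parent_dosage)]


def f1_locus_dist(gk: np.ndarray, gl: np.ndarray) -> np.ndarray:
    """Genotype-class distribution of the F1: convolution of two gamete dists."""
    return np.convolve(_check_dist(gk), _check_dist(gl))


@lru_cache(maxsize=None)
def f1_table(ploidy: int) -> np.ndarray:
    """T[mk, ml, :] = F1 class distribution for parent dosages (mk, ml)."""
    G = gamete_matrix(ploidy)
    n = ploidy + 1
    T = np.zeros((n, n, n))
    for a in range(n):
        for b in range(n):
            T[a, b] = np.convolve(G[a], G[b])
    return T


@lru_cache(maxsize=None)
def self_transition(ploidy: int) -> np.ndarray:
    """S[m, :] = offspring class distribution when an individual of class m selfs."""
    G = gamete_matrix(ploidy)
    n = ploidy + 1
    S = np.zeros((n, n))
    for m in range(n):
        S[m] = np.convolve(G[m], G[m])
    return S


def self_locus_dist(dist: np.ndarray, t: int, ploidy: int | None = None) -> np.ndarray:
    """Apply t generations of per-class selfing (Markov recursion) to a family
    class distribution: each class selfs through its own gamete distribution and
    the results are mixed by class frequency."""
    if t < 0:
        raise ValueError("selfing generations t must be >= 0")
    dist = _check_dist(dist)
    if ploidy is None:
        ploidy = len(dist) - 1
    S = np.linalg.matrix_power(self_transition(ploidy), t)
    return dist @ S


def dh_locus_dist(f1: np.ndarray) -> np.ndarray:
    """Doubled haploids from a diploid family distribution: mass only on {0, 2}."""
    f1 = _check_dist(f1)
    if len(f1) != 3:
        raise PanelValidationError("doubled haploids are only defined for diploids")
    p = float(f1 @ gamete_matrix(2)[:, 1])  # P(gamete carries the effect allele)
    return np.array([1.0 - p, 0.0, p])


def testcross_locus_dist(family: np.ndarray, tester_dosage: int, ploidy: int | None = None) -> np.ndarray:
    """Hybrid class distribution: family gamete mixture convolved with the
    tester's gamete distribution."""
    family = _check_dist(family)
    if ploidy is None:
        ploidy = len(family) - 1
    gam = family @ gamete_matrix(ploidy)
    return np.convolve(gam, gamete_dist(tester_dosage, ploidy))


def family_locus_dists(
    panel: ParentPanel,
    pair: tuple[int, int],
    scheme: CrossScheme,
    tester: int | None = None,
) -> np.ndarray:
    """Per-locus genotype-class distributions, shape (n_loci, ploidy + 1), for
    the scheme's evaluated generation.  Loci are treated independently (only
    marginals are needed for means and per-locus variances); cross-locus
    structure lives in the LD models and the simulator.

    When the scheme carries testers, ``tester`` selects which tester's hybrid
    distribution to return (per-tester predictions are aggregated upstream).
    """
    k, l = pair
    scheme.validate_for_ploidy(panel.ploidy)
    T = f1_table(panel.ploidy)
    dists = T[panel.dosages[k], panel.dosages[l]]  # (n_loci, ploidy+1)
    if scheme.pipeline == "SELF" and scheme.t > 0:
        S = np.linalg.matrix_power(self_transition(panel.ploidy), scheme.t)
        dists = dists @ S
    elif scheme.pipeline == "DH":
        p = dists @ gamete_matrix(2)[:, 1]
        dists = np.stack([1.0 - p, np.zeros_like(p), p], axis=1)
    if tester is not None:
        G = gamete_matrix(panel.ploidy)
        gam = dists @ G  # (n_loci, ploidy/2 + 1)
        tg = G[panel.dosages[tester]]  # (n_loci, ploidy/2 + 1)
        n = panel.ploidy + 1
        out = np.zeros((panel.n_loci, n))
        half = panel.ploidy // 2
        for a in range(half + 1):
            for b in range(half + 1):
                out[:, a + b] += gam[:, a] * tg[:, b]
        dists = out
    return dists


# ---------------------------------------------------------------------------
# Meiosis simulator
# ---------------------------------------------------------------------------

@dataclass
class _MapLayout:
    """Precomputed chromosome blocks for fast crossover placement."""

    blocks: list[tuple[int, int, np.ndarray, float]]  # (start, stop, rel pos cM, length cM)

    @classmethod
    def from_map(cls, gmap: GeneticMap) -> "_MapLayout":
        blocks = []
        for _, sl in gmap.chromosome_slices():
            pos = gmap.pos_cm[sl.start : sl.stop]
            rel = pos - pos[0]
            length = float(rel[-1]) if len(rel) > 1 else 0.0
            blocks.append((sl.start, sl.stop, rel, length))
        return cls(blocks)


def _crossover_parity(
    rel_pos: np.ndarray, length_cm: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Parity (0/1) of the crossover count left of each locus for n independent
    meioses of one chromosome, crossovers from a Poisson process (Haldane)."""
    nl = len(rel_pos)
    parity = np.zeros((n, nl), dtype=np.int8)
    if length_cm <= 0 or nl == 1:
        return parity
    counts = rng.poisson(length_cm / 100.0, size=n)
    total = int(counts.sum())
    if total == 0:
        return parity
    owner = np.repeat(np.arange(n), counts)
    xpos = rng.uniform(0.0, length_cm, size=total)
    idx = np.searchsorted(rel_pos, xpos, side="left")  # crossover flips loci >= idx
    hits = np.zeros((n, nl + 1), dtype=np.int32)
    np.add.at(hits, (owner, idx), 1)
    np.cumsum(hits[:, :-1], axis=1, out=hits[:, :-1])
    parity = (hits[:, :-1] & 1).astype(np.int8)
    return parity


def _bivalent_products(
    haps: np.ndarray, chrom_pair: np.ndarray, layout: _MapLayout, rng: np.random.Generator
) -> np.ndarray:
    """Meiotic products of one bivalent.

    haps: (n, ploidy, n_loci) parental haplotypes (may be broadcast from one
    parent); chrom_pair: (n, 2) indices of the two homologs forming the
    bivalent.  Returns (n, n_loci) alleles of one recombined product.
    """
    n, _, nl = haps.shape
    sel = np.empty((n, nl), dtype=np.int8)
    for start, stop, rel, length in layout.blocks:
        par = _crossover_parity(rel, length, n, rng)
        par ^= rng.integers(0, 2, size=(n, 1), dtype=np.int8)  # random start homolog
        sel[:, start:stop] = par
    chrom = np.take_along_axis(chrom_pair, sel.astype(np.intp), axis=1)  # (n, nl)
    rows = np.arange(n)[:, None]
    cols = np.arange(nl)[None, :]
    return haps[rows, chrom, cols]


def simulate_gametes(
    haps: np.ndarray, layout: _MapLayout, rng: np.random.Generator
) -> np.ndarray:
    """One gamete per individual.

    haps: (n, ploidy, n_loci).  Diploid: single recombined product.
    Tetraploid: homologs are paired at random into two bivalents; the gamete is
    the sum of one product from each (2 chromosomes, no double reduction).
    Returns gamete haplotype array: (n, ploidy/2, n_loci).
    """
    n, ploidy, nl = haps.shape
    if ploidy == 2:
        pair = np.broadcast_to(np.array([[0, 1]], dtype=np.int8), (n, 2))
        return _bivalent_products(haps, pair, layout, rng)[:, None, :]
    if ploidy == 4:
        perm = np.argsort(rng.random((n, 4)), axis=1).astype(np.int8)
        prod1 = _bivalent_products(haps, perm[:, :2], layout, rng)
        prod2 = _bivalent_products(haps, perm[:, 2:], layout, rng)
        return np.stack([prod1, prod2], axis=1)
    raise PanelValidationError("simulator supports ploidy 2 or 4")


def _parent_haps(panel: ParentPanel, i: int, rng: np.random.Generator) -> np.ndarray:
    return np.asarray(panel.parent_haplotypes(i, rng=rng), dtype=np.int8)


def simulate_progeny(
    panel: ParentPanel,
    pair: tuple[int, int],
    scheme: CrossScheme,
    n_progeny: int,
    seed: int | np.random.Generator,
    return_haplotypes: bool = False,
):
    """Simulate the scheme's evaluated generation for one cross.

    Selfing chains are per-individual (each line descends from a single F1
    plant); DH doubles one sampled F1 gamete; testcross schemes mate each end
    individual to every tester and return one dosage matrix per tester (list),
    otherwise a single (n_progeny, n_loci) dosage matrix.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    scheme.validate_for_ploidy(panel.ploidy)
    layout = _MapLayout.from_map(panel.gmap)
    k, l = pair
    hk = np.broadcast_to(_parent_haps(panel, k, rng), (n_progeny, panel.ploidy, panel.n_loci))
    hl = np.broadcast_to(_parent_haps(panel, l, rng), (n_progeny, panel.ploidy, panel.n_loci))

    gk = simulate_gametes(hk, layout, rng)
    gl = simulate_gametes(hl, layout, rng)
    haps = np.concatenate([gk, gl], axis=1)  # F1 individuals, (n, ploidy, nl)

    if scheme.pipeline == "SELF":
        for _ in range(scheme.t):
            g1 = simulate_gametes(haps, layout, rng)
            g2 = simulate_gametes(haps, layout, rng)
            haps = np.concatenate([g1, g2], axis=1)
    elif scheme.pipeline == "DH":
        g = simulate_gametes(haps, layout, rng)
        haps = np.concatenate([g, g], axis=1)

    if scheme.testers:
        out = []
        for tester in scheme.testers:
            gfam = simulate_gametes(haps, layout, rng)
            ht = np.broadcast_to(
                _parent_haps(panel, tester, rng), (n_progeny, panel.ploidy, panel.n_loci)
            )
            gt = simulate_gametes(ht, layout, rng)
            hyb = np.concatenate([gfam, gt], axis=1)
            out.append(hyb if return_haplotypes else hyb.sum(axis=1, dtype=np.int16))
        return out
    return haps if return_haplotypes else haps.sum(axis=1, dtype=np.int16)
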