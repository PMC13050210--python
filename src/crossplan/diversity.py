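"""Genomic relationships and the proportion of additive SD lost (PropSD).

Additive values of the candidate parents are modelled as u ~ N(0, G sigma*^2)
with G a genomic relationship matrix, so the additive SD of any subset can be
anticipated without marker effects.  The expected *sample* standard deviation
of a correlated Gaussian vector is obtained by moment-matching the sample
variance to a gamma distribution:

    E(s_a) = beta^(1/2) Gamma(alpha + 1/2) / Gamma(alpha),
    alpha  = E(s_a^2)^2 / var(s_a^2),   beta = var(s_a^2) / E(s_a^2),

with E(s_a^2) and var(s_a^2) closed forms in G.  For G = I this reproduces the
classical c4(n) bias constant of the sample SD exactly, which pins down the
moment match.  PropSD of a selected parent multiset is then
1 - E(s_am)/E(s_a), the anticipated proportional loss of additive SD; the
variance-component scale cancels in the ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .popdata import PanelValidationError, ParentPanel, TraitEffects

__all__ = [
    "GRM",
    "SdEstimate",
    "grm",
    "expected_sample_sd",
    "prop_sd",
    "realized_prop_sd",
    "genic_sd",
    "genetic_sd",
]


@dataclass
class GRM:
    """Additive genomic relationship matrix with parent names attached."""

    matrix: np.ndarray
    names: np.ndarray

    def __post_init__(self) -> None:
        G = np.asarray(self.matrix, dtype=float)
        if G.ndim != 2 or G.shape[0] != G.shape[1]:
            raise ValueError("GRM must be square")
        if not np.allclose(G, G.T, atol=1e-8):
            raise ValueError("GRM must be symmetric")
        self.matrix = 0.5 * (G + G.T)
        self.names = np.asarray(self.names, dtype=object)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def submatrix(self, idx) -> np.ndarray:
        idx = np.asarray(idx)
        return self.matrix[np.ix_(idx, idx)]

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.matrix, index=self.names, columns=self.names).to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "GRM":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(matrix=df.to_numpy(float), names=df.index.to_numpy(object))


def grm(panel: ParentPanel) -> GRM:
    """Ploidy-generalized VanRaden relationship matrix.

    Z = M - phi*p (dosages centred by ploidy x pool allele frequency),
    G = Z Z^T / (phi * sum_j p_j (1 - p_j)).
    """
    if panel.n_parents < 2:
        raise PanelValidationError("GRM needs at least 2 parents")
    p = panel.allele_freq()
    if not np.any(np.ptp(panel.dosages, axis=0) > 0):
        raise PanelValidationError("all loci are monomorphic; GRM undefined")
    Z = panel.dosages.astype(float) - panel.ploidy * p
    denom = panel.ploidy * float(np.sum(p * (1.0 - p)))
    return GRM(matrix=(Z @ Z.T) / denom, names=panel.names)


@dataclass
class SdEstimate:
    expected_sd: float
    alpha: float
    beta: float
    mean_s2: float
    var_s2: float
    sem: float
    sigma1: np.ndarray
    sigma2: np.ndarray


def expected_sample_sd(G: GRM | np.ndarray) -> SdEstimate:
    """Expected sample SD of u ~ N(0, G) via the gamma moment match.

    Computes, in order: SEM = (1^T G 1)^(1/2) / n;
    Sigma1[i,j] = G[i,j] + SEM^2 - rowmean_i - rowmean_j;
    Sigma2 = 2 * Sigma1 (elementwise squared);
    E(s^2)  = [tr(G)/n - 1^T G 1 / n^2] * n/(n-1);
    var(s^2) = 1^T Sigma2 1 / (n-1)^2;
    alpha = E(s^2)^2 / var(s^2), beta = var(s^2)/E(s^2);
    E(s) = beta^(1/2) Gamma(alpha + 1/2)/Gamma(alpha).
    """
    M = G.matrix if isinstance(G, GRM) else np.asarray(G, dtype=float)
    n = M.shape[0]
    if n < 2:
        raise ValueError("need n >= 2")
    gsum = float(M.sum())
    sem = np.sqrt(max(gsum, 0.0)) / n
    rowmean = M.mean(axis=1)
    sigma1 = M + sem**2 - rowmean[:, None] - rowmean[None, :]
    sigma2 = 2.0 * sigma1**2
    mean_s2 = (np.trace(M) / n - gsum / n**2) * n / (n - 1)
    var_s2 = float(sigma2.sum()) / (n - 1) ** 2
    mean_s2 = max(mean_s2, 0.0)
    if var_s2 <= 0 or mean_s2 == 0.0:
        # degenerate gamma limit: point mass at E(s^2)
        return SdEstimate(float(np.sqrt(mean_s2)), np.inf, 0.0, mean_s2, var_s2, sem, sigma1, sigma2)
    alpha = mean_s2**2 / var_s2
    beta = var_s2 / mean_s2
    log_e = 0.5 * np.log(beta) + gammaln(alpha + 0.5) - gammaln(alpha)
    return SdEstimate(float(np.exp(log_e)), float(alpha), float(beta), mean_s2, var_s2, sem, sigma1, sigma2)


def prop_sd(G_pool: GRM | np.ndarray, selected) -> float:
    """PropSD = 1 - E(s_am)/E(s_a) for a selected parent multiset.

    ``selected`` may repeat indices (a parent enters once per mating it takes
    part in); the corresponding rows/columns of G are duplicated.  Fewer than
    two selected entries mean complete loss (PropSD = 1).
    """
    M = G_pool.matrix if isinstance(G_pool, GRM) else np.asarray(G_pool, dtype=float)
    sel = np.asarray(list(selected), dtype=int)
    if sel.size == 0:
        raise ValueError("selected multiset is empty")
    if np.any(sel < 0) or np.any(sel >= M.shape[0]):
        raise IndexError("selected index out of range")
    if sel.size < 2:
        return 1.0
    e_pool = expected_sample_sd(M).expected_sd
    e_sel = expected_sample_sd(M[np.ix_(sel, sel)]).expected_sd
    if e_pool == 0.0:
        raise ValueError("pool has zero expected additive SD")
    return 1.0 - e_sel / e_pool


def realized_prop_sd(u_pool: np.ndarray, u_sel: np.ndarray) -> float:
    """Realized loss 1 - sd(u_sel)/sd(u_pool) (sample SDs, ddof 1)."""
    u_pool = np.asarray(u_pool, dtype=float)
    u_sel = np.asarray(u_sel, dtype=float)
    if u_pool.size < 2 or u_sel.size < 2:
        raise ValueError("need at least 2 values in pool and selection")
    sd_pool = u_pool.std(ddof=1)
    if sd_pool == 0:
        raise ValueError("pool additive SD is zero")
    return 1.0 - u_sel.std(ddof=1) / sd_pool


def genic_sd(panel: ParentPanel, effects: TraitEffects, idx=None) -> float:
    """LD-free additive SD: sqrt(sum_j a_j^2 var_j) with per-locus dosage
    variances across the subset (no cross-locus covariances)."""
    M = panel.dosages if idx is None else panel.dosages[np.asarray(idx)]
    if M.shape[0] < 2:
        raise ValueError("need at least 2 individuals")
    v = M.var(axis=0, ddof=1)
    return float(np.sqrt(np.sum(effects.additive**2 * v)))


def genetic_sd(panel: ParentPanel, effects: TraitEffects, idx=None) -> float:
    """Sample SD of per-individual additive values sum_j M[i,j] a_j (includes
    every LD contribution)."""
    M = panel.dosages if idx is None else panel.dosages[np.asarray(idx)]
    if M.shape[0] < 2:
        raise ValueError("need at least 2 individuals")
    u = M.astype(float) @ effects.additive
    return float(u.std(ddof=1))
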