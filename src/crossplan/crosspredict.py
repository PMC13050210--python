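"""Family mean, within-family variance under three LD models, and usefulness.

Means
-----
The family mean is the sum over loci of the class-probability-weighted locus
values  mu_F,j = sum_k P(k) (m(k) a_j + w(k) d_j), valid for any
parameterization, filial generation and ploidy.  The classical Falconer F1
mean is kept only as a comparator (it is restricted to F1 and known to deviate
from the class-frequency expectation).

Variances
---------
The genome-wide within-family variance couples per-locus standard deviations
through a correlation matrix of locus genotypic effects (linkage
disequilibrium):

* ``independent`` - identity correlation: the sum of per-locus variances.
* ``approx`` - parental-LD propagation: the covariance of genotypic effects in
  each parent's source population is propagated to the family through the
  recombination-fraction matrix, without phased data.
* ``full`` - phased haplotypes give each parent's own LD exactly; dominance is
  attached through per-locus additive/dominance decompositions and the
  additive correlation matrix (path rule).

LD transfer through the pipeline
--------------------------------
The cross-locus covariance of the evaluated generation is assembled from two
elementwise coefficient paths derived from two-locus gamete-frequency
recursions (no interference; random bivalent pairing without double reduction
for tetraploids):

* a within-parent path carrying Gamma = gamma_k + gamma_l, the parent-centred
  haplotype covariances, and
* a between-parent path carrying the outer product of the parental
  allele-frequency differences Delta_j = p_kj - p_lj (segregation LD created
  by the cross itself).

Closed forms (q = (1-2c)/2 and rho4 = 5/6 - c are the per-generation selfing
decays of within-individual LD for ploidy 2 and 4) are documented in
docs/methods.md and validated against the meiosis simulator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import inheritance as inh
from .popdata import (
    ClassValueMap,
    CrossScheme,
    PanelValidationError,
    ParentPanel,
    TraitEffects,
    recombination_matrix,
)

__all__ = [
    "LocusSummary",
    "FamilyPrediction",
    "locus_mean",
    "family_mean",
    "falconer_f1_mean",
    "locus_variance",
    "locus_ad_decomposition",
    "variance_independent",
    "variance_approx",
    "variance_full",
    "source_pop_cov",
    "propagate_family_cov",
    "cov_to_corr",
    "phased_additive_cov",
    "usefulness",
    "CrossPredictor",
    "predict_all_crosses",
]

LD_MODELS = ("independent", "approx", "full")


# ---------------------------------------------------------------------------
# Per-locus moments
# ---------------------------------------------------------------------------

@dataclass
class LocusSummary:
    mean: float
    total_var: float
    additive_var: float
    dominance_var: float
    ad_correlation: float


def _value_tables(effects: TraitEffects, cvm: ClassValueMap):
    """(n_loci, ploidy+1) additive and dominance class-value tables."""
    a = effects.additive[:, None] * cvm.additive_score[None, :]
    if np.any(effects.dominance):
        w = cvm.require_dominance()
        d = effects.dominance[:, None] * w[None, :]
    else:
        d = np.zeros_like(a)
    return a, d


def _locus_moments(dists: np.ndarray, Va: np.ndarray, Vd: np.ndarray):
    """Vectorized per-locus moments.  dists: (n_loci, K)."""
    mu_a = np.einsum("jk,jk->j", dists, Va)
    mu_d = np.einsum("jk,jk->j", dists, Vd)
    var_a = np.einsum("jk,jk->j", dists, Va**2) - mu_a**2
    var_d = np.einsum("jk,jk->j", dists, Vd**2) - mu_d**2
    V = Va + Vd
    mu = mu_a + mu_d
    var = np.einsum("jk,jk->j", dists, V**2) - mu**2
    np.clip(var_a, 0.0, None, out=var_a)
    np.clip(var_d, 0.0, None, out=var_d)
    np.clip(var, 0.0, None, out=var)
    cov_ad = 0.5 * (var - var_a - var_d)
    denom = np.sqrt(var_a * var_d)
    rho = np.divide(cov_ad, denom, out=np.zeros_like(cov_ad), where=denom > 0)
    np.clip(rho, -1.0, 1.0, out=rho)
    return mu, var, var_a, var_d, rho


def locus_mean(dist: np.ndarray, a_j: float, d_j: float, cvm: ClassValueMap) -> float:
    """mu_F,j = sum_k P(k) (m(k) a_j + w(k) d_j)."""
    dist = np.asarray(dist, dtype=float)
    v = cvm.additive_score * a_j
    if d_j:
        v = v + cvm.require_dominance() * d_j
    return float(dist @ v)


def locus_variance(
    dist: np.ndarray, a_j: float, d_j: float, cvm: ClassValueMap, component: str = "total"
) -> float:
    """Population variance of class values under the family distribution.

    component "additive_only"/"dominance_only" zeroes the other effect.
    """
    if component == "additive_only":
        d_j = 0.0
    elif component == "dominance_only":
        a_j = 0.0
    elif component != "total":
        raise ValueError(f"unknown component {component!r}")
    dist = np.asarray(dist, dtype=float)
    v = cvm.additive_score * a_j
    if d_j:
        v = v + cvm.require_dominance() * d_j
    mu = dist @ v
    return float(max(dist @ v**2 - mu**2, 0.0))


def locus_ad_decomposition(
    dist: np.ndarray, a_j: float, d_j: float, cvm: ClassValueMap
) -> LocusSummary:
    """Mean, total/additive/dominance variances and the additive-dominance
    correlation at one locus.  rho := 0 when either component variance is 0."""
    mu = locus_mean(dist, a_j, d_j, cvm)
    var = locus_variance(dist, a_j, d_j, cvm, "total")
    va = locus_variance(dist, a_j, d_j, cvm, "additive_only")
    vd = locus_variance(dist, a_j, d_j, cvm, "dominance_only")
    cov = 0.5 * (var - va - vd)
    denom = np.sqrt(va * vd)
    rho = float(cov / denom) if denom > 0 else 0.0
    return LocusSummary(mu, var, va, vd, float(np.clip(rho, -1.0, 1.0)))


def family_mean(
    panel: ParentPanel,
    pair: tuple[int, int],
    scheme: CrossScheme,
    effects: TraitEffects,
    cvm: ClassValueMap | None = None,
) -> float:
    """E(g_F): sum of locus means of the scheme's evaluated generation
    (averaged over testers for testcross schemes)."""
    cvm = cvm or ClassValueMap.default(panel.ploidy)
    Va, Vd = _value_tables(effects, cvm)
    testers = scheme.testers or (None,)
    out = 0.0
    for tester in testers:
        dists = inh.family_locus_dists(panel, pair, scheme, tester=tester)
        out += float(np.einsum("jk,jk->", dists, Va + Vd))
    return out / len(testers)


def falconer_f1_mean(p: float, q: float, y: float, a: float, d: float) -> float:
    """Legacy single-locus F1 mean  a(p - q - y) + d[2pq + y(p - q)].

    Kept strictly as a comparator: it does not reproduce class-frequency
    expectations outside its narrow assumptions and is never used in
    prediction.
    """
    if not (0 <= p <= 1 and 0 <= q <= 1):
        raise ValueError("frequencies must lie in [0, 1]")
    return a * (p - q - y) + d * (2 * p * q + y * (p - q))


# ---------------------------------------------------------------------------
# Genome-wide variance: three LD models
# ---------------------------------------------------------------------------

def variance_independent(total_vars: np.ndarray) -> float:
    """Sum of per-locus variances (identity correlation matrix)."""
    return float(np.sum(total_vars))


def variance_approx(total_vars: np.ndarray, CF: np.ndarray, clip: "ClipCounter | None" = None) -> float:
    """s^T C_F s with s the vector of per-locus *standard deviations*.

    The quadratic form reduces to the independent model when C_F = I; negative
    results (possible with estimated effects) are clipped to 0 and counted.
    """
    s = np.sqrt(np.asarray(total_vars, dtype=float))
    if CF.shape != (len(s), len(s)):
        raise ValueError("correlation matrix does not match the number of loci")
    v = float(s @ CF @ s)
    if v < 0:
        if clip is not None:
            clip.count += 1
        v = 0.0
    return v


def variance_full(
    additive_vars: np.ndarray,
    dominance_vars: np.ndarray,
    rho: np.ndarray,
    CaF: np.ndarray,
    clip: "ClipCounter | None" = None,
) -> float:
    """Path-rule variance with dominance.

    Summing additive x additive, additive x dominance and dominance x dominance
    covariance components with the additive correlation matrix Ca_F and the
    per-locus additive-dominance correlations rho gives

        Var = v^T Ca_F v + sum_j sd_j^2 (1 - rho_j^2),   v = sa + rho * sd,

    which reduces exactly to the single-locus total variance when there is one
    locus (the same-locus dominance term enters without the rho^2 scaling).
    """
    sa = np.sqrt(np.asarray(additive_vars, dtype=float))
    sd = np.sqrt(np.asarray(dominance_vars, dtype=float))
    if CaF.shape != (len(sa), len(sa)):
        raise ValueError("correlation matrix does not match the number of loci")
    v = sa + rho * sd
    out = float(v @ CaF @ v + np.sum(sd**2 * (1.0 - rho**2)))
    if out < 0:
        if clip is not None:
            clip.count += 1
        out = 0.0
    return out


def cov_to_corr(sigma: np.ndarray) -> np.ndarray:
    """Covariance -> correlation; zero-variance loci get zero rows/columns and a
    unit diagonal (they contribute nothing to the quadratic forms)."""
    d = np.sqrt(np.clip(np.diag(sigma), 0.0, None))
    ok = d > 0
    inv = np.zeros_like(d)
    inv[ok] = 1.0 / d[ok]
    C = sigma * inv[:, None] * inv[None, :]
    np.clip(C, -1.0, 1.0, out=C)
    np.fill_diagonal(C, 1.0)
    return C


def source_pop_cov(
    panel: ParentPanel,
    subpop: object,
    effects: TraitEffects,
    cvm: ClassValueMap | None = None,
) -> np.ndarray:
    """Covariance (over individuals, divisor n) of per-locus genotypic effects
    M*[i,j] = m(M[i,j]) a_j + w(M[i,j]) d_j in one source population."""
    cvm = cvm or ClassValueMap.default(panel.ploidy)
    idx = np.nonzero(panel.subpop == subpop)[0]
    if len(idx) < 2:
        raise PanelValidationError(f"source population {subpop!r} has fewer than 2 members")
    Va, Vd = _value_tables(effects, cvm)
    V = Va + Vd  # (n_loci, K)
    M = panel.dosages[idx].astype(np.intp)
    X = V[np.arange(V.shape[0])[None, :], M]  # X[i, j] = V[j, M[i, j]]
    Z = X - X.mean(axis=0)
    return (Z.T @ Z) / len(idx)


def phased_additive_cov(
    Hk: np.ndarray, Hl: np.ndarray, effects: TraitEffects
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-parent haplotype additive covariances with *family* allele
    frequencies p_j (average of the two parents' haplotype means).

    Returns (Sigma_a_k, Sigma_a_l, p).  Centering at the family frequency keeps
    loci that are homozygous-divergent between the parents informative.
    """
    Hk = np.asarray(Hk, dtype=float)
    Hl = np.asarray(Hl, dtype=float)
    if Hk.ndim != 2 or Hk.shape != Hl.shape:
        raise PanelValidationError("phased haplotype matrices must be (ploidy x n_loci) and congruent")
    p = 0.5 * (Hk.mean(axis=0) + Hl.mean(axis=0))
    a = effects.additive

    def _cov(H):
        Z = (H - p) * a
        return (Z.T @ Z) / H.shape[0]

    return _cov(Hk), _cov(Hl), p


# ---------------------------------------------------------------------------
# LD-transfer coefficients
# ---------------------------------------------------------------------------

@dataclass
class _LDState:
    """Elementwise coefficients of the two LD paths.

    E[gamma_gen]   = aD * Gamma + bD * DeltaOuter
    cov(p_ind)_gen = am * Gamma + bm * DeltaOuter

    with Gamma = gamma_k + gamma_l (parent-centred haplotype covariances) and
    DeltaOuter = Delta Delta^T, Delta = p_k - p_l (allele-frequency scale).
    """

    aD: np.ndarray
    bD: np.ndarray
    am: np.ndarray
    bm: np.ndarray


def _f1_state(c: np.ndarray, ploidy: int) -> _LDState:
    one = 1.0 - 2.0 * c
    if ploidy == 2:
        return _LDState(aD=one / 4, bD=np.full_like(c, 0.25), am=one / 4, bm=np.zeros_like(c))
    if ploidy == 4:
        return _LDState(
            aD=5.0 / 12 - c / 2,
            bD=np.full_like(c, 0.25),
            am=one / 12,
            bm=np.zeros_like(c),
        )
    raise PanelValidationError("LD propagation supports ploidy 2 or 4")


def _self_step(st: _LDState, c: np.ndarray, ploidy: int) -> _LDState:
    one = 1.0 - 2.0 * c
    lam = 1.0 if ploidy == 2 else 4.0 / 3.0
    upd = (2.0 * lam / ploidy**2) * one
    decay = 0.5 * one if ploidy == 2 else (5.0 / 6.0 - c)
    return _LDState(
        aD=st.aD * decay,
        bD=st.bD * decay,
        am=st.am + upd * st.aD,
        bm=st.bm + upd * st.bD,
    )


def scheme_ld_coefficients(c: np.ndarray, scheme: CrossScheme, ploidy: int):
    """Elementwise coefficient matrices (A, B) such that the additive dosage
    covariance of the evaluated generation (before any testcross) is
    A * Gamma + B * DeltaOuter; for testcross schemes the family-side *gamete*
    coefficients are returned instead (tester terms are added separately)."""
    st = _f1_state(c, ploidy)
    lam = 1.0 if ploidy == 2 else 4.0 / 3.0
    one = 1.0 - 2.0 * c
    if scheme.pipeline == "SELF":
        for _ in range(scheme.t):
            st = _self_step(st, c, ploidy)
    if scheme.pipeline == "DH":
        A = 4.0 * (one * st.aD + st.am)
        B = 4.0 * (one * st.bD + st.bm)
        if scheme.testers:
            A, B = A / 4.0, B / 4.0  # gamete of a DH line = half its dosage
        return A, B
    if scheme.testers:
        A = lam * one * st.aD + (ploidy**2 / 4.0) * st.am
        B = lam * one * st.bD + (ploidy**2 / 4.0) * st.bm
        return A, B
    return ploidy**2 * st.am, ploidy**2 * st.bm


def tester_gamete_coefficient(c: np.ndarray, ploidy: int) -> np.ndarray:
    """Coefficient on the tester's own gamma for the tester-side gamete LD."""
    lam = 1.0 if ploidy == 2 else 4.0 / 3.0
    return lam * (1.0 - 2.0 * c)


def propagate_family_cov(
    sigma_k: np.ndarray,
    sigma_l: np.ndarray,
    c: np.ndarray,
    scheme: CrossScheme,
    *,
    ploidy: int = 2,
    delta_outer: np.ndarray | None = None,
) -> np.ndarray:
    """Propagate parental LD to the family.

    Without ``delta_outer`` (source-population inputs, the printed F1 rule for
    that case) the parental matrices enter symmetrically:
    F1 gives Sigma_F = 1/2 (1-2c) * sigma_k + 1/2 (1-2c) * sigma_l; other
    pipelines use their scheme coefficient on (sigma_k + sigma_l)/2 per parent.

    With ``delta_outer`` the inputs are parent-centred haplotype covariances
    gamma_k, gamma_l plus the between-parent divergence outer product, and the
    exact two-path decomposition is used.
    """
    if sigma_k.shape != sigma_l.shape or sigma_k.shape != c.shape:
        raise ValueError("parental covariance and recombination matrices must be conformable")
    if delta_outer is not None:
        A, B = scheme_ld_coefficients(c, scheme, ploidy)
        return A * (sigma_k + sigma_l) + B * delta_outer
    A, _ = scheme_ld_coefficients(c, scheme, ploidy)
    if scheme.pipeline == "F1" and not scheme.testers:
        half = 0.5 * (1.0 - 2.0 * c)
        return half * sigma_k + half * sigma_l
    return 0.5 * A * (sigma_k + sigma_l)


# ---------------------------------------------------------------------------
# Usefulness
# ---------------------------------------------------------------------------

def usefulness(
    mean: float, variance: float, i_f: float, r: float, use_sd: bool = True
) -> float:
    """U_F = E(g_F) + i_F * r * sqrt(Var(g_F)).

    ``use_sd=False`` multiplies by the variance instead of the standard
    deviation (literal-variance mode, exposed for comparison only).
    """
    if variance < 0:
        raise ValueError("variance must be non-negative")
    if not 0.0 <= r <= 1.0:
        raise ValueError("accuracy r must lie in [0, 1]")
    spread = np.sqrt(variance) if use_sd else variance
    return float(mean + i_f * r * spread)


# ---------------------------------------------------------------------------
# Predictor
# ---------------------------------------------------------------------------

@dataclass
class ClipCounter:
    count: int = 0


@dataclass
class FamilyPrediction:
    parent1: object
    parent2: object
    mean: float
    variance: float
    sd: float
    usefulness: float
    ld_model: str
    scheme: str


def _pool_inbreeding(panel: ParentPanel, idx: np.ndarray) -> float:
    """1 - observed/expected heterozygosity of a source pool, clipped to [0,1].

    Observed: P(two distinct homologs of a parent differ), computable from
    dosages; expected: the same probability for two random pool gametes.
    """
    M = panel.dosages[idx].astype(float)
    phi = panel.ploidy
    obs = np.mean(2.0 * M * (phi - M) / (phi * (phi - 1)))
    p = M.mean(axis=0) / phi
    exp = np.mean(2.0 * p * (1.0 - p))
    if exp <= 0:
        return 1.0
    return float(np.clip(1.0 - obs / exp, 0.0, 1.0))


class CrossPredictor:
    """Precomputes everything shared across crosses for one (panel, scheme,
    effects, LD model) combination and predicts single pairs or whole tables.

    Negative propagated variances (possible with estimated effects) are clipped
    to zero; ``clip.count`` reports how often.
    """

    def __init__(
        self,
        panel: ParentPanel,
        effects: TraitEffects,
        scheme: CrossScheme,
        ld_model: str = "approx",
        cvm: ClassValueMap | None = None,
        i_f: float = 0.0,
        use_sd: bool = True,
    ):
        if ld_model not in LD_MODELS:
            raise ValueError(f"ld_model must be one of {LD_MODELS}")
        if ld_model == "full" and not panel.is_phased:
            raise PanelValidationError(
                "the full LD model requires phased haplotypes; use the approx model"
            )
        scheme.validate_for_ploidy(panel.ploidy)
        self.panel = panel
        self.effects = effects
        self.scheme = scheme
        self.ld_model = ld_model
        self.cvm = cvm or ClassValueMap.default(panel.ploidy)
        self.i_f = i_f
        self.use_sd = use_sd
        self.clip = ClipCounter()
        self.Va, self.Vd = _value_tables(effects, self.cvm)
        phi = panel.ploidy
        if ld_model != "independent":
            self.c = recombination_matrix(panel.gmap)
            self.A, self.B = scheme_ld_coefficients(self.c, scheme, phi)
            self.aa = np.outer(effects.additive, effects.additive)
            self.Aaa = self.A * self.aa
            self.Baa = self.B * self.aa
            self.tester_coeff = tester_gamete_coefficient(self.c, phi) * self.aa
        if ld_model == "approx":
            # Pool-level LD summaries (unphased).  cov_p is the covariance of
            # parent allele frequencies; the average within-parent haplotype
            # covariance gamma is recovered from it through the pool
            # inbreeding estimate, and its correlation shape Rpool is combined
            # per pair with the parent's own heterozygosity weights
            # w_i = (dos/phi)(1 - dos/phi) (the exact within-parent allele
            # variance), so homozygous parents contribute no within-parent LD.
            self._pool_R: dict = {}
            self._pool_mu: dict = {}
            self._pool_freqcov: dict = {}
            for pop in np.unique(panel.subpop):
                idx = np.nonzero(panel.subpop == pop)[0]
                if len(idx) < 2:
                    continue
                M = panel.dosages[idx].astype(float)
                Zf = (M - M.mean(axis=0)) / phi
                cov_p = (Zf.T @ Zf) / len(idx)
                F = _pool_inbreeding(panel, idx)
                hapcov = cov_p * phi / (1.0 + (phi - 1) * F)
                gamma_pool = hapcov - cov_p  # average within-parent covariance
                if np.all(np.diag(gamma_pool) < 1e-12):
                    self._pool_R[pop] = None  # fully inbred pool: no within-parent LD
                else:
                    R = cov_to_corr(gamma_pool)
                    np.fill_diagonal(R, 1.0)
                    self._pool_R[pop] = R
                self._pool_mu[pop] = M.mean(axis=0) / phi
                self._pool_freqcov[pop] = cov_p

    # -- per-pair pieces -----------------------------------------------------

    def _gamma_exact(self, i: int) -> tuple[np.ndarray | None, np.ndarray]:
        """Parent-centred haplotype covariance; None for homozygous parents
        (identically zero)."""
        H = self.panel.haplotypes[i].astype(float)
        p = H.mean(axis=0)
        if np.all((p == 0.0) | (p == 1.0)):
            return None, p
        Z = H - p
        return (Z.T @ Z) / self.panel.ploidy, p

    def _ld_inputs(self, k: int, l: int, testers: tuple[int, ...]):
        """(Gamma, DeltaOuter, tester gammas) on the allele-frequency scale.

        Entries may be None (identically zero contributions).
        """
        phi = self.panel.ploidy
        if self.ld_model == "full":
            gk, pk = self._gamma_exact(k)
            gl, pl = self._gamma_exact(l)
            delta = pk - pl
            if gk is None:
                Gamma = gl
            elif gl is None:
                Gamma = gk
            else:
                Gamma = gk + gl
            gammas_t = [self._gamma_exact(t)[0] for t in testers]
            return Gamma, np.outer(delta, delta), gammas_t
        # approx: source-population proxies + per-parent heterozygosity weights
        pop_k, pop_l = self.panel.subpop[k], self.panel.subpop[l]
        for pop in (pop_k, pop_l):
            if pop not in self._pool_freqcov:
                raise PanelValidationError(
                    "approx LD model needs a source population of >= 2 parents for every parent"
                )

        def _gamma_proxy(i: int):
            pop = self.panel.subpop[i]
            R = self._pool_R.get(pop)
            if R is None:
                return None
            f = self.panel.dosages[i].astype(float) / phi
            s = np.sqrt(f * (1.0 - f))
            if not np.any(s):
                return None
            return R * np.outer(s, s)

        gk = _gamma_proxy(k)
        gl = _gamma_proxy(l)
        if gk is None:
            Gamma = gl
        elif gl is None:
            Gamma = gk
        else:
            Gamma = gk + gl
        D = self._pool_freqcov[pop_k] + self._pool_freqcov[pop_l]
        if pop_k != pop_l:
            md = self._pool_mu[pop_k] - self._pool_mu[pop_l]
            D = D + np.outer(md, md)
        gammas_t = []
        for t in testers:
            if self.panel.subpop[t] not in self._pool_freqcov:
                raise PanelValidationError("tester has no source population for the approx model")
            gammas_t.append(_gamma_proxy(t))
        return Gamma, D, gammas_t

    def _correlation(self, k: int, l: int, testers: tuple[int, ...]) -> np.ndarray | list[np.ndarray]:
        Gamma, D, gammas_t = self._ld_inputs(k, l, testers)
        base = self.Baa * D if Gamma is None else self.Aaa * Gamma + self.Baa * D
        if not testers:
            return cov_to_corr(base)
        return [
            cov_to_corr(base if gt is None else base + self.tester_coeff * gt)
            for gt in gammas_t
        ]

    def _moments_for(self, k: int, l: int, tester: int | None):
        dists = inh.family_locus_dists(self.panel, (k, l), self.scheme, tester=tester)
        return _locus_moments(dists, self.Va, self.Vd)

    # -- public API ----------------------------------------------------------

    def predict_pair(self, k: int, l: int, testers: tuple[int, ...] | None = None) -> FamilyPrediction:
        """Predict one family; ``testers`` overrides the scheme's tester set
        (e.g. one random tester per validation cross)."""
        sch_testers = self.scheme.testers if testers is None else tuple(testers)
        testers_iter = sch_testers or (None,)
        if self.ld_model != "independent":
            corr = self._correlation(k, l, sch_testers)
            corrs = corr if isinstance(corr, list) else [corr] * len(testers_iter)
        means, variances = [], []
        for t_i, tester in enumerate(testers_iter):
            mu, var, var_a, var_d, rho = self._moments_for(k, l, tester)
            means.append(float(mu.sum()))
            if self.ld_model == "independent":
                variances.append(variance_independent(var))
            elif self.ld_model == "approx":
                variances.append(variance_approx(var, corrs[t_i], self.clip))
            else:
                variances.append(variance_full(var_a, var_d, rho, corrs[t_i], self.clip))
        mean = float(np.mean(means))
        var = float(np.mean(variances))
        u = usefulness(mean, var, self.i_f, self.effects.accuracy, self.use_sd)
        return FamilyPrediction(
            parent1=self.panel.names[k],
            parent2=self.panel.names[l],
            mean=mean,
            variance=var,
            sd=float(np.sqrt(var)),
            usefulness=u,
            ld_model=self.ld_model,
            scheme=self.scheme.label,
        )

    def predict_pairs(self, pairs) -> "pd.DataFrame":
        import pandas as pd

        rows = [self.predict_pair(int(k), int(l)) for k, l in pairs]
        return pd.DataFrame([r.__dict__ for r in rows])

    def predict_all(self, pair_mask: np.ndarray | None = None, include_self: bool = False):
        n = self.panel.n_parents
        pairs = [
            (k, l)
            for k in range(n)
            for l in range(k if include_self else k + 1, n)
            if pair_mask is None or pair_mask[k, l]
        ]
        return self.predict_pairs(pairs)


def predict_all_crosses(
    panel: ParentPanel,
    scheme: CrossScheme,
    effects: TraitEffects,
    ld_model: str = "approx",
    pair_mask: np.ndarray | None = None,
    cvm: ClassValueMap | None = None,
    i_f: float = 0.0,
):
    """Prediction table for every allowed unordered pair (symmetric in parent
    order, consistent with single-pair computation)."""
    if pair_mask is not None:
        pair_mask = np.asarray(pair_mask, dtype=bool)
        if not np.array_equal(pair_mask, pair_mask.T):
            raise ValueError("pair mask must be symmetric")
    pred = CrossPredictor(panel, effects, scheme, ld_model=ld_model, cvm=cvm, i_f=i_f)
    return pred.predict_all(pair_mask=pair_mask)
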