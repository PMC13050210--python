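"""Synthetic datasets, effect calibration and the validation harness.

The generator emulates strongly LD-structured crop panels: 1,000 loci on 8
chromosomes of 150 cM, founder haplotypes drawn as a Markov chain along each
chromosome with a target adjacent-locus correlation of 0.95 (capped at the
Frechet bound implied by the two allele frequencies), and

* a diploid panel of two heterotic pools, each built by simulating 200 founder
  haplotypes, crossing 100 founders at random 50 times and converting the
  progeny to doubled haploids (50 fully homozygous lines per pool); and
* an autotetraploid panel of 100 non-fully-homozygous genotypes from 100
  random crosses among 400 founders.

Marker effects for two correlated traits (YLD, MAT; cross-trait correlation
0.3) are drawn for 250 randomly placed QTL under the genotypic
parameterization.  Effect *calibration* degrades the true effects in the ways
a genomic-prediction pipeline would: QTL_1 redistributes effects within the
QTL while reproducing the parents' genome-wide values exactly; QTL_0.7 and
Markers_0.7 are ridge (SNP-BLUP) fits to noisy parental phenotypes, with the
noise variance bisected until parental accuracy is 0.7 — on the true QTL
columns and on the 750 non-QTL markers respectively.

The validation harness compares predicted family means/SDs against
Monte-Carlo progeny simulated with the true QTL effects, and predicted PropSD
against realized losses of genetic and genic SD under random sampling and
under optimized selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import inheritance as inh
from .crosspredict import CrossPredictor
from .diversity import genetic_sd, genic_sd, grm, prop_sd
from .optimizer import (
    ConstraintSet,
    OptimizerConfig,
    optimize,
)
from .popdata import (
    ClassValueMap,
    CrossScheme,
    GeneticMap,
    ParentPanel,
    TraitEffects,
)

__all__ = [
    "SimConfig",
    "EffectConfig",
    "default_map",
    "simulate_founder_haplotypes",
    "make_diploid_dataset",
    "make_tetraploid_dataset",
    "simulate_effects",
    "calibrate_effects",
    "true_genotypic_values",
    "pearson",
    "nrmse",
    "standard_schemes",
    "run_cross_validation_experiment",
    "run_propsd_random_experiment",
    "run_propsd_selection_experiment",
]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    n_loci: int = 1000
    n_chrom: int = 8
    chrom_length_cm: float = 150.0
    target_autocorr: float = 0.95
    ploidy: int = 2
    freq_range: tuple[float, float] = (0.05, 0.95)
    # diploid: per pool; tetraploid: single pool
    n_founder_haplotypes: int = 200
    n_crosses: int = 50
    n_subpops: int = 2
    tetra_n_founders: int = 400
    tetra_n_crosses: int = 100

    def __post_init__(self) -> None:
        if not 0.0 <= self.target_autocorr < 1.0:
            raise ValueError("target_autocorr must lie in [0, 1)")
        for name in ("n_loci", "n_chrom", "n_founder_haplotypes", "n_crosses"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class EffectConfig:
    n_qtl: int = 250
    traits: tuple[str, ...] = ("YLD", "MAT")
    trait_correlation: float = 0.3
    dominance_scale: float = 0.5
    parameterization: str = "genotypic"
    target_parental_accuracy: float = 0.7

    def __post_init__(self) -> None:
        if not -1.0 < self.trait_correlation < 1.0:
            raise ValueError("trait_correlation must lie in (-1, 1)")


def default_map(cfg: SimConfig) -> GeneticMap:
    """Loci spread evenly over n_chrom chromosomes of chrom_length_cm each."""
    per = np.full(cfg.n_chrom, cfg.n_loci // cfg.n_chrom)
    per[: cfg.n_loci % cfg.n_chrom] += 1
    marker, chrom, pos = [], [], []
    j = 0
    for ci, m in enumerate(per):
        p = np.linspace(0.0, cfg.chrom_length_cm, int(m))
        for x in p:
            marker.append(f"m{j:05d}")
            chrom.append(f"chr{ci + 1}")
            pos.append(float(x))
            j += 1
    return GeneticMap(marker=np.array(marker, object), chrom=np.array(chrom, object), pos_cm=np.array(pos))


# ---------------------------------------------------------------------------
# Founder haplotypes
# ---------------------------------------------------------------------------

def _max_bernoulli_corr(p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
    """Frechet upper bound on the correlation of Bernoulli(p1), Bernoulli(p2)."""
    cov_max = np.minimum(p1, p2) - p1 * p2
    denom = np.sqrt(p1 * (1 - p1) * p2 * (1 - p2))
    return np.where(denom > 0, cov_max / denom, 0.0)


def simulate_founder_haplotypes(
    cfg: SimConfig, n_haplotypes: int, rng: np.random.Generator, gmap: GeneticMap | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Binary founder haplotypes with target adjacent-locus correlation.

    Per chromosome, locus allele frequencies are sampled independently
    (uniform on freq_range) and haplotypes follow a first-order Markov chain
    whose adjacent-locus correlation is min(target, feasible max given the two
    frequencies).  Chromosomes are independent.  Returns (H, freqs).
    """
    gmap = gmap or default_map(cfg)
    nl = gmap.n_loci
    lo, hi = cfg.freq_range
    freqs = rng.uniform(lo, hi, size=nl)
    H = np.zeros((n_haplotypes, nl), dtype=np.int8)
    for _, sl in gmap.chromosome_slices():
        idx = range(sl.start, sl.stop)
        prev = None
        for j in idx:
            p = freqs[j]
            if prev is None:
                H[:, j] = rng.random(n_haplotypes) < p
            else:
                pp = freqs[prev]
                rho = min(cfg.target_autocorr, float(_max_bernoulli_corr(np.array(pp), np.array(p))))
                cov = rho * np.sqrt(pp * (1 - pp) * p * (1 - p))
                cond = p + (H[:, prev] - pp) * cov / (pp * (1 - pp))
                H[:, j] = rng.random(n_haplotypes) < cond
            prev = j
    return H, freqs


def _founder_panel(H: np.ndarray, ploidy: int, gmap: GeneticMap, prefix: str) -> ParentPanel:
    n = H.shape[0] // ploidy
    haps = H[: n * ploidy].reshape(n, ploidy, -1)
    return ParentPanel(
        ploidy=ploidy,
        dosages=haps.sum(axis=1),
        names=np.array([f"{prefix}F{i:03d}" for i in range(n)], object),
        gmap=gmap,
        haplotypes=haps,
    )


def make_diploid_dataset(cfg: SimConfig | None = None, seed: int = 0, dh: bool = True) -> ParentPanel:
    """Two-pool diploid panel.

    Per pool: 200 founder haplotypes -> 100 founders -> 50 random crosses,
    each contributing one progeny line.  ``dh=True`` converts progeny to
    doubled haploids (fully homozygous lines); ``dh=False`` keeps the
    heterozygous F1 clones (used for clonal-crop scenarios, where crosses of
    fully homozygous lines would have zero within-family variance).
    """
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(seed)
    gmap = default_map(cfg)
    scheme = CrossScheme("DH") if dh else CrossScheme("F1")
    panels = []
    for s in range(cfg.n_subpops):
        H, _ = simulate_founder_haplotypes(cfg, cfg.n_founder_haplotypes, rng, gmap)
        founders = _founder_panel(H, 2, gmap, prefix=chr(ord("A") + s))
        lines = np.empty((cfg.n_crosses, 2, gmap.n_loci), dtype=np.int8)
        for i in range(cfg.n_crosses):
            k, l = rng.choice(founders.n_parents, size=2, replace=False)
            lines[i] = inh.simulate_progeny(
                founders, (int(k), int(l)), scheme, 1, rng, return_haplotypes=True
            )[0]
        pool = chr(ord("A") + s)
        panels.append(
            ParentPanel(
                ploidy=2,
                dosages=lines.sum(axis=1),
                names=np.array([f"{pool}{i:03d}" for i in range(cfg.n_crosses)], object),
                gmap=gmap,
                haplotypes=lines,
                subpop=np.array([f"pool{pool}"] * cfg.n_crosses, object),
            )
        )
    return _concat_panels(panels)


def make_tetraploid_dataset(cfg: SimConfig | None = None, seed: int = 0) -> ParentPanel:
    """Single-pool autotetraploid panel: 400 founders, 100 random crosses,
    one non-fully-homozygous genotype per cross."""
    cfg = cfg or SimConfig(ploidy=4)
    rng = np.random.default_rng(seed)
    gmap = default_map(cfg)
    H, _ = simulate_founder_haplotypes(cfg, cfg.tetra_n_founders * 4, rng, gmap)
    founders = _founder_panel(H, 4, gmap, prefix="T")
    scheme = CrossScheme("F1")
    lines = np.empty((cfg.tetra_n_crosses, 4, gmap.n_loci), dtype=np.int8)
    for i in range(cfg.tetra_n_crosses):
        k, l = rng.choice(founders.n_parents, size=2, replace=False)
        lines[i] = inh.simulate_progeny(
            founders, (int(k), int(l)), scheme, 1, rng, return_haplotypes=True
        )[0]
    return ParentPanel(
        ploidy=4,
        dosages=lines.sum(axis=1),
        names=np.array([f"G{i:03d}" for i in range(cfg.tetra_n_crosses)], object),
        gmap=gmap,
        haplotypes=lines,
        subpop=np.array(["pool"] * cfg.tetra_n_crosses, object),
    )


def _concat_panels(panels: list[ParentPanel]) -> ParentPanel:
    return ParentPanel(
        ploidy=panels[0].ploidy,
        dosages=np.concatenate([p.dosages for p in panels]),
        names=np.concatenate([p.names for p in panels]),
        gmap=panels[0].gmap,
        haplotypes=np.concatenate([p.haplotypes for p in panels]),
        subpop=np.concatenate([p.subpop for p in panels]),
    )


# ---------------------------------------------------------------------------
# Effects and calibration
# ---------------------------------------------------------------------------

def simulate_effects(
    panel: ParentPanel, ecfg: EffectConfig | None = None, seed: int = 0, with_dominance: bool = True
) -> tuple[dict[str, TraitEffects], np.ndarray]:
    """QTL effects for the configured traits.

    250 QTL positions are sampled without replacement; per trait, additive
    (and dominance, scaled by dominance_scale) effects are drawn from a
    multivariate normal with the configured cross-trait correlation.  Non-QTL
    loci carry zero effect.  Returns ({trait: TraitEffects}, qtl indices).
    """
    ecfg = ecfg or EffectConfig()
    if ecfg.n_qtl >= panel.n_loci:
        raise ValueError("n_qtl must be smaller than the number of loci")
    rng = np.random.default_rng(seed)
    qtl = np.sort(rng.choice(panel.n_loci, size=ecfg.n_qtl, replace=False))
    nt = len(ecfg.traits)
    C = np.full((nt, nt), ecfg.trait_correlation)
    np.fill_diagonal(C, 1.0)
    L = np.linalg.cholesky(C)
    a = rng.standard_normal((ecfg.n_qtl, nt)) @ L.T
    d = (rng.standard_normal((ecfg.n_qtl, nt)) @ L.T) * ecfg.dominance_scale
    out = {}
    for t_i, trait in enumerate(ecfg.traits):
        av = np.zeros(panel.n_loci)
        dv = np.zeros(panel.n_loci)
        av[qtl] = a[:, t_i]
        if with_dominance:
            dv[qtl] = d[:, t_i]
        out[trait] = TraitEffects(
            additive=av, dominance=dv, parameterization=ecfg.parameterization, name=trait
        )
    return out, qtl


def true_genotypic_values(
    panel: ParentPanel, effects: TraitEffects, cvm: ClassValueMap | None = None
) -> np.ndarray:
    """Per-parent genotypic values sum_j m(M_ij) a_j + w(M_ij) d_j."""
    cvm = cvm or ClassValueMap.default(panel.ploidy)
    M = panel.dosages.astype(np.intp)
    g = cvm.additive_score[M] @ effects.additive
    if np.any(effects.dominance):
        g = g + cvm.require_dominance()[M] @ effects.dominance
    return g


def _design_matrix(panel: ParentPanel, loci: np.ndarray, cvm: ClassValueMap, dominance: bool):
    M = panel.dosages[:, loci].astype(np.intp)
    Xa = cvm.additive_score[M]
    if dominance:
        return np.hstack([Xa, cvm.require_dominance()[M]])
    return Xa


def calibrate_effects(
    mode: str,
    panel: ParentPanel,
    true_effects: TraitEffects,
    qtl: np.ndarray,
    target_r: float = 0.7,
    cvm: ClassValueMap | None = None,
    seed: int = 0,
    tol: float = 0.005,
) -> TraitEffects:
    """Estimated-effect sets reproducing the validation settings.

    QTL_true: identity.  QTL_1: a null-space perturbation of the parental
    QTL design leaves every parent's genome-wide value unchanged while
    per-locus effects differ.  QTL_0.7: Gaussian noise on the QTL effects,
    scaled by bisection until corr(parental GEGV, TGV) = target.  Markers_0.7:
    minimum-norm least squares of the parental TGVs on the non-QTL columns
    (plus the same tuned noise); QTL columns carry zero estimated effect.
    """
    cvm = cvm or ClassValueMap.default(panel.ploidy)
    if mode == "QTL_true":
        return true_effects
    rng = np.random.default_rng(seed)
    tgv = true_genotypic_values(panel, true_effects, cvm)
    has_dom = bool(np.any(true_effects.dominance))

    def _assemble(loci, coefs) -> TraitEffects:
        a = np.zeros(panel.n_loci)
        d = np.zeros(panel.n_loci)
        nq = len(loci)
        a[loci] = coefs[:nq]
        if len(coefs) > nq:
            d[loci] = coefs[nq:]
        return TraitEffects(
            additive=a,
            dominance=d,
            parameterization=true_effects.parameterization,
            accuracy=1.0 if mode == "QTL_1" else target_r,
            name=true_effects.name,
        )

    if mode == "QTL_1":
        from scipy.linalg import null_space

        X = _design_matrix(panel, qtl, cvm, has_dom)
        base = np.concatenate(
            [true_effects.additive[qtl]] + ([true_effects.dominance[qtl]] if has_dom else [])
        )
        N = null_space(X)  # orthonormal kernel basis of the parental design
        if N.shape[1] == 0:
            raise ValueError(
                "parental QTL design has full column rank (no null space); "
                "QTL_1 needs more effect columns than parents"
            )
        v = N @ rng.standard_normal(N.shape[1])
        v *= np.linalg.norm(base) / np.linalg.norm(v)
        return _assemble(qtl, base + v)

    if mode in ("QTL_0.7", "Markers_0.7"):
        # Ridge (SNP-BLUP) effects fitted to noisy parental phenotypes
        # y = TGV + e, with var(e) tuned by bisection until the parental
        # GEGV-TGV correlation hits the target.  QTL_0.7 fits the true QTL
        # columns, Markers_0.7 the 750 non-QTL columns.  Estimating from
        # noisy phenotypes (rather than perturbing effects directly) gives
        # the effect errors realistic LD/relationship structure, the way
        # sub-unit accuracy arises in genomic prediction, and makes the two
        # calibrations behave near-identically downstream.
        loci = qtl if mode == "QTL_0.7" else np.setdiff1d(np.arange(panel.n_loci), qtl)
        X = _design_matrix(panel, loci, cvm, has_dom)
        n = X.shape[0]
        K = X @ X.T
        sb2 = float(np.var(tgv)) / max(np.trace(K) / n, 1e-12)
        z = rng.standard_normal(n) * np.std(tgv)
        eye = np.eye(n)

        def beta_at(se: float) -> np.ndarray:
            lam = se**2 / sb2 + 1e-10
            alpha = np.linalg.solve(K + lam * eye, tgv + se * z)
            return X.T @ alpha

        def corr_at(se: float) -> float:
            return pearson(X @ beta_at(se), tgv)

        se = _bisect_down(corr_at, target_r, tol)
        return _assemble(loci, beta_at(se))

    raise ValueError(f"unknown calibration mode {mode!r}")


def _bisect_down(corr_at, target: float, tol: float) -> float:
    """Find s >= 0 with corr_at(s) = target for a (near) decreasing corr_at."""
    lo, hi = 0.0, 1.0
    while corr_at(hi) > target:
        hi *= 2.0
        if hi > 1e6:
            raise ValueError(f"cannot reach target correlation {target}")
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        c = corr_at(mid)
        if abs(c - target) <= tol:
            return mid
        if c > target:
            lo = mid
        else:
            hi = mid
    mid = 0.5 * (lo + hi)
    if abs(corr_at(mid) - target) > tol:
        raise ValueError(f"bisection failed to reach target correlation {target}")
    return mid


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def pearson(x, y) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    return float(np.corrcoef(x, y)[0, 1])


def nrmse(pred, true) -> float:
    """RMSE divided by the SD of the true values."""
    pred = np.asarray(pred, float)
    true = np.asarray(true, float)
    if len(pred) != len(true) or len(pred) < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    sd = true.std(ddof=1)
    if sd == 0:
        raise ValueError("true values have zero variance")
    return float(np.sqrt(np.mean((pred - true) ** 2)) / sd)


# ---------------------------------------------------------------------------
# Cross-validation harness
# ---------------------------------------------------------------------------

def standard_schemes(ploidy: int) -> dict[str, CrossScheme]:
    """The five benchmark breeding schemes (DH-based ones for diploids only).

    Hybrid entries carry no tester indices; the validation harness assigns
    panel-appropriate testers (names starting with "Hybrid" mark them).
    """
    out = {
        "ILs": CrossScheme("SELF", t=3),
        "Clonal": CrossScheme("F1"),
        "Hybrid_ILs": CrossScheme("SELF", t=3),
    }
    if ploidy == 2:
        out["DH"] = CrossScheme("DH")
        out["Hybrid_DH"] = CrossScheme("DH")
    return out


def _sample_pairs(panel, hybrid, n_pairs, rng):
    """Validation pairs are sampled from the whole panel (random pairs of
    parents, including inter-pool crosses); testcross (hybrid) schemes mate
    within the first pool only, with testers from the opposite pool
    (reciprocal-recurrent layout)."""
    pools = np.unique(panel.subpop)
    idx_all = np.arange(panel.n_parents)
    idx_first = np.nonzero(panel.subpop == pools[0])[0]
    pairs = []
    for _ in range(n_pairs):
        idx = idx_first if hybrid else idx_all
        k, l = rng.choice(idx, size=2, replace=False)
        pairs.append((int(k), int(l)))
    return pairs


def _tester_candidates(panel) -> np.ndarray:
    """Testers come from the second pool when two pools exist (the opposite
    heterotic pool), otherwise from the whole panel."""
    pools = np.unique(panel.subpop)
    if len(pools) > 1:
        return np.nonzero(panel.subpop == pools[1])[0]
    return np.arange(panel.n_parents)


def _simulated_truth(panel, pair, scheme, effects, cvm, n_progeny, rng):
    """Monte-Carlo mean and SD of progeny genotypic values (true effects)."""
    sims = inh.simulate_progeny(panel, pair, scheme, n_progeny, rng)
    if not isinstance(sims, list):
        sims = [sims]
    w = cvm.require_dominance() if np.any(effects.dominance) else None
    mus, sds = [], []
    for S in sims:
        g = cvm.additive_score[S.astype(np.intp)] @ effects.additive
        if w is not None:
            g = g + w[S.astype(np.intp)] @ effects.dominance
        mus.append(g.mean())
        sds.append(g.std(ddof=1))
    return float(np.mean(mus)), float(np.mean(sds))


def run_cross_validation_experiment(
    panel: ParentPanel,
    true_effects: TraitEffects | dict[str, TraitEffects],
    effect_sets: dict[str, TraitEffects] | None = None,
    schemes: dict[str, CrossScheme] | None = None,
    ld_models: tuple[str, ...] = ("independent", "approx", "full"),
    n_crosses: int = 200,
    n_progeny: int = 2000,
    cvm: ClassValueMap | None = None,
    seed: int = 0,
    clonal_panel: ParentPanel | None = None,
    qtl: np.ndarray | None = None,
    calibration_modes: tuple[str, ...] = ("QTL_true",),
) -> pd.DataFrame:
    """Accuracy/NRMSE of predicted family means and SDs against simulation.

    For each scheme, ``n_crosses`` random parent pairs are drawn, the truth is
    the sample mean/SD of ``n_progeny`` simulated progeny under the true
    effects, and every (effect setting x LD model) combination is scored.

    ``true_effects`` may be a single TraitEffects or a dict of trait value
    variants (e.g. ``{"additive": ..., "genotypic": ...}``, the benchmark's
    additive-only and additive+dominance rows); the simulated progeny
    genotypes are shared between variants, only the value maps differ.
    Effect sets are either supplied directly (``effect_sets``) or calibrated
    per (evaluation panel, variant) from ``calibration_modes`` and the QTL
    index set — estimated effects must be fitted in the population they
    predict.  ``clonal_panel`` substitutes a heterozygous panel for the
    Clonal scheme (fully homozygous parents would give zero clonal variance).
    """
    cvm = cvm or ClassValueMap.default(panel.ploidy)
    rng = np.random.default_rng(seed)
    schemes = schemes or standard_schemes(panel.ploidy)
    variants = true_effects if isinstance(true_effects, dict) else {"genotypic": true_effects}
    if effect_sets is None and qtl is None:
        raise ValueError("provide either effect_sets or the qtl index set for calibration")
    set_cache: dict = {}

    def _sets_for(pan: ParentPanel, variant: str) -> dict[str, TraitEffects]:
        if effect_sets is not None:
            return effect_sets
        key = (id(pan), variant)
        if key not in set_cache:
            set_cache[key] = {
                mode: calibrate_effects(
                    mode, pan, variants[variant], qtl, cvm=cvm, seed=seed
                )
                for mode in calibration_modes
            }
        return set_cache[key]

    rows = []
    for sname, scheme in schemes.items():
        pan = clonal_panel if (sname == "Clonal" and clonal_panel is not None) else panel
        hybrid = sname.startswith("Hybrid") or bool(scheme.testers)
        pairs = _sample_pairs(pan, hybrid, n_crosses, rng)
        if hybrid and not scheme.testers:
            # one random opposite-pool tester per validation cross
            cand = _tester_candidates(pan)
            testers = [(int(rng.choice(cand)),) for _ in pairs]
        elif scheme.testers:
            testers = [scheme.testers] * len(pairs)
        else:
            testers = [()] * len(pairs)
        # scheme carrying a tester marks the pipeline as a testcross for the
        # LD-transfer coefficients; the actual tester is supplied per cross
        run_scheme = (
            CrossScheme(scheme.pipeline, t=scheme.t, testers=(int(testers[0][0]),))
            if hybrid
            else scheme
        )
        # simulate once per cross; apply every trait variant to the same
        # progeny genotypes
        truth = {v: ([], []) for v in variants}
        for pr, ts in zip(pairs, testers):
            sch = CrossScheme(scheme.pipeline, t=scheme.t, testers=ts) if ts else scheme
            sims = inh.simulate_progeny(pan, pr, sch, n_progeny, rng)
            sims = sims if isinstance(sims, list) else [sims]
            for v, eff_true in variants.items():
                mus, sds = [], []
                for S in sims:
                    Sx = S.astype(np.intp)
                    g = cvm.additive_score[Sx] @ eff_true.additive
                    if np.any(eff_true.dominance):
                        g = g + cvm.require_dominance()[Sx] @ eff_true.dominance
                    mus.append(g.mean())
                    sds.append(g.std(ddof=1))
                truth[v][0].append(float(np.mean(mus)))
                truth[v][1].append(float(np.mean(sds)))
        for v in variants:
            true_mu = np.array(truth[v][0])
            true_sd = np.array(truth[v][1])
            for setting, eff in _sets_for(pan, v).items():
                for model in ld_models:
                    pred = CrossPredictor(pan, eff, run_scheme, ld_model=model, cvm=cvm)
                    fps = [
                        pred.predict_pair(*pr, testers=ts or None)
                        for pr, ts in zip(pairs, testers)
                    ]
                    mu = np.array([f.mean for f in fps])
                    sd = np.array([f.sd for f in fps])
                    rows.append(
                        {
                            "scheme": sname,
                            "values": v,
                            "setting": setting,
                            "ld_model": model,
                            "n_crosses": len(pairs),
                            "n_progeny": n_progeny,
                            "accuracy_mean": pearson(mu, true_mu),
                            "nrmse_mean": nrmse(mu, true_mu),
                            "accuracy_sd": pearson(sd, true_sd),
                            "nrmse_sd": nrmse(sd, true_sd),
                            "clip_count": pred.clip.count,
                        }
                    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# PropSD experiments
# ---------------------------------------------------------------------------

def run_propsd_random_experiment(
    panel: ParentPanel,
    sizes: tuple[int, ...] = (5, 20, 100, 200),
    reps: int = 20,
    n_effect_draws: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Predicted PropSD vs Monte-Carlo mean realized loss under random
    sampling with replacement.

    Additive values are realized as u = Z b with iid standard-normal marker
    effects b on centred dosages, so cov(u) is proportional to the VanRaden
    relationship matrix without factorizing it.
    """
    rng = np.random.default_rng(seed)
    G = grm(panel)
    Z = panel.dosages.astype(float) - panel.ploidy * panel.allele_freq()
    B = rng.standard_normal((panel.n_loci, n_effect_draws))
    U = Z @ B  # (n_parents, n_draws)
    sd_pool = U.std(axis=0, ddof=1)
    rows = []
    for size in sizes:
        for rep in range(reps):
            sel = rng.integers(0, panel.n_parents, size=size)
            predicted = prop_sd(G, sel)
            realized = 1.0 - U[sel].std(axis=0, ddof=1) / sd_pool
            rows.append(
                {
                    "size": size,
                    "rep": rep,
                    "predicted": predicted,
                    "realized_mc_mean": float(realized.mean()),
                    "realized_mc_sem": float(realized.std(ddof=1) / np.sqrt(n_effect_draws)),
                }
            )
    return pd.DataFrame(rows)


def run_propsd_selection_experiment(
    panel: ParentPanel,
    cutoffs: tuple[float, ...] = (0.001, 0.01, 0.02, 0.03, 0.04, 0.05),
    n_effect_sets: int = 100,
    total_crosses: int = 10,
    scheme: CrossScheme | None = None,
    config: OptimizerConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Predicted PropSD vs realized genetic- and genic-SD losses under
    usefulness-driven selection.

    Per (cutoff, effect set): optimize a mating plan with the PropSD
    constraint, then compute the realized losses over the selected parent
    multiset with the same marker effects.  Selection induces negative LD
    among loci (Bulmer effect), so the genetic loss typically exceeds the
    prediction while the genic loss does not.
    """
    scheme = scheme or CrossScheme("F1" if panel.ploidy != 2 else "DH")
    scheme.validate_for_ploidy(panel.ploidy)
    rng = np.random.default_rng(seed)
    G = grm(panel)
    T = inh.f1_table(panel.ploidy)
    rows = []
    for es in range(n_effect_sets):
        a = rng.standard_normal(panel.n_loci)
        eff = TraitEffects(additive=a, dominance=np.zeros(panel.n_loci))
        # fast mean/SD table over all pairs (independent-loci model)
        preds = _fast_prediction_table(panel, eff, scheme, T)
        for cutoff in cutoffs:
            cons = ConstraintSet(
                total_crosses=total_crosses,
                allow_repeats=False,
                propsd_cutoff=cutoff,
            )
            cfg = config or OptimizerConfig(
                population_size=60, n_elite=8, max_iterations=120, convergence_patience=40
            )
            cfg.seed = int(rng.integers(0, 2**31 - 1))
            plan, rep, _ = optimize(preds, cons, cfg, G_pool=G)
            sel = plan.selected_parents()
            rows.append(
                {
                    "cutoff": cutoff,
                    "effect_set": es,
                    "feasible": rep.feasible,
                    "predicted_propsd": rep.propsd,
                    "realized_genetic_loss": 1.0
                    - genetic_sd(panel, eff, sel) / genetic_sd(panel, eff),
                    "realized_genic_loss": 1.0 - genic_sd(panel, eff, sel) / genic_sd(panel, eff),
                }
            )
    return pd.DataFrame(rows)


def _fast_prediction_table(panel, eff, scheme, T):
    """Vectorized per-pair mean/SD (independent-loci variance) for optimizer
    experiments: per-locus class moments are tabulated once per dosage pair."""
    phi = panel.ploidy
    K = phi + 1
    S = np.eye(K)
    if scheme.pipeline == "SELF" and scheme.t:
        S = np.linalg.matrix_power(inh.self_transition(phi), scheme.t)
    elif scheme.pipeline == "DH":
        g1 = inh.gamete_matrix(2)[:, 1]
        S = np.stack([1 - g1, np.zeros(K), g1], axis=1)
    Tend = np.einsum("abk,km->abm", T, S)  # (K, K, K) end-generation dists
    kvals = np.arange(K, dtype=float)
    m1 = Tend @ kvals
    m2 = Tend @ kvals**2
    v = m2 - m1**2
    Mk = panel.dosages
    n = panel.n_parents
    a = eff.additive
    preds = {}
    for k in range(n):
        mu_tab = m1[Mk[k][None, :].repeat(n - k - 1, 0), Mk[k + 1 :]]  # (n-k-1, nl)
        var_tab = v[Mk[k][None, :].repeat(n - k - 1, 0), Mk[k + 1 :]]
        mus = mu_tab @ a
        sds = np.sqrt(var_tab @ a**2)
        for off, l in enumerate(range(k + 1, n)):
            preds[(k, l)] = (float(mus[off]), float(sds[off]))
    return preds
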