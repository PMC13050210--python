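"""Data model and I/O for parent panels, genetic maps, haplotypes and marker effects.

The central container is :class:`ParentPanel`: an ``n_parents x n_loci`` allele-dosage
matrix (integer 0..ploidy, counting copies of the effect allele), an optional set of
phased haplotypes, a genetic map, and subpopulation labels.  Recombination fractions
between markers are obtained from map distances with the Haldane mapping function
(no crossover interference), which keeps the analytic LD propagation consistent with
the meiosis simulator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GeneticMap",
    "ParentPanel",
    "TraitEffects",
    "ClassValueMap",
    "CrossScheme",
    "PanelDiagnostics",
    "load_panel",
    "save_panel",
    "load_effects",
    "recombination_matrix",
    "haldane",
    "validate_panel",
]


class PanelValidationError(ValueError):
    """Raised when a panel, map or effect table violates a structural invariant."""


# ---------------------------------------------------------------------------
# Genetic map
# ---------------------------------------------------------------------------

@dataclass
class GeneticMap:
    """Marker positions in centimorgans on named chromosomes.

    Markers are identified by id; only cM distances matter (no physical
    coordinates).  Markers are stored sorted by (chromosome, position) and this
    order is the canonical locus order of any panel attached to the map.
    """

    marker: np.ndarray          # object array of marker ids
    chrom: np.ndarray           # object array of chromosome ids
    pos_cm: np.ndarray          # float array, non-negative

    def __post_init__(self) -> None:
        self.marker = np.asarray(self.marker, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos_cm = np.asarray(self.pos_cm, dtype=float)
        if not (len(self.marker) == len(self.chrom) == len(self.pos_cm)):
            raise PanelValidationError("map columns have unequal lengths")
        if len(np.unique(self.marker)) != len(self.marker):
            raise PanelValidationError("duplicate marker ids in genetic map")
        if np.any(self.pos_cm < 0):
            raise PanelValidationError("negative map position")
        order = np.lexsort((self.pos_cm, _sortable(self.chrom)))
        self.marker = self.marker[order]
        self.chrom = self.chrom[order]
        self.pos_cm = self.pos_cm[order]

    @property
    def n_loci(self) -> int:
        return len(self.marker)

    def chromosome_slices(self) -> list[tuple[object, slice]]:
        """Contiguous (chromosome id, slice) blocks in canonical order."""
        out: list[tuple[object, slice]] = []
        start = 0
        for i in range(1, self.n_loci + 1):
            if i == self.n_loci or self.chrom[i] != self.chrom[start]:
                out.append((self.chrom[start], slice(start, i)))
                start = i
        return out

    @classmethod
    def from_tsv(cls, path) -> "GeneticMap":
        df = pd.read_csv(path, sep=None, engine="python")
        cols = {c.lower(): c for c in df.columns}
        try:
            return cls(
                marker=df[cols["marker"]].to_numpy(),
                chrom=df[cols["chrom"]].to_numpy(),
                pos_cm=df[cols["pos_cm"]].to_numpy(),
            )
        except KeyError as e:  # pragma: no cover - message path
            raise PanelValidationError(f"map file missing column {e}") from e

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"marker": self.marker, "chrom": self.chrom, "pos_cm": self.pos_cm}
        ).to_csv(path, sep="\t", index=False)


def _sortable(values: np.ndarray) -> np.ndarray:
    # stable key for heterogeneous chromosome labels
    return np.asarray([str(v) for v in values])


def haldane(d_cm: np.ndarray) -> np.ndarray:
    """Map distance (cM) -> recombination fraction, Haldane (no interference).

    c = 0.5 * (1 - exp(-2 d))  with d in Morgans.
    """
    d = np.asarray(d_cm, dtype=float)
    if np.any(d < 0):
        raise PanelValidationError("negative map distance")
    return 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))


def recombination_matrix(gmap: GeneticMap) -> np.ndarray:
    """Pairwise recombination-fraction matrix c, in [0, 0.5].

    Same marker: 0. Different chromosomes: 0.5 (independent assortment).
    Within a chromosome: Haldane function of the cM distance.
    """
    pos = gmap.pos_cm
    c = np.full((gmap.n_loci, gmap.n_loci), 0.5)
    for _, sl in gmap.chromosome_slices():
        p = pos[sl]
        c[sl, sl] = haldane(np.abs(p[:, None] - p[None, :]))
    return c


# ---------------------------------------------------------------------------
# Parent panel
# ---------------------------------------------------------------------------

@dataclass
class ParentPanel:
    """Dosage matrix plus optional phased haplotypes for a set of candidate parents.

    dosages[i, j] counts copies of the effect allele (0..ploidy) carried by
    parent i at locus j.  haplotypes, when present, is an
    (n_parents, ploidy, n_loci) binary array whose per-parent column sums equal
    the dosage row (1 = effect allele).
    """

    ploidy: int
    dosages: np.ndarray
    names: np.ndarray
    gmap: GeneticMap
    haplotypes: np.ndarray | None = None
    subpop: np.ndarray | None = None
    strict: bool = True  # False keeps inconsistent haplotypes for diagnostics

    def __post_init__(self) -> None:
        if self.ploidy < 2 or self.ploidy % 2:
            raise PanelValidationError("ploidy must be an even integer >= 2")
        self.dosages = np.asarray(self.dosages)
        if self.dosages.ndim != 2:
            raise PanelValidationError("dosages must be 2-D (parents x markers)")
        if not np.issubdtype(self.dosages.dtype, np.integer):
            d = np.asarray(self.dosages, dtype=float)
            if np.any(d != np.round(d)) or np.any(np.isnan(d)):
                raise PanelValidationError(
                    "missing or non-integer dosages are rejected (no imputation)"
                )
            self.dosages = d.astype(np.int16)
        bad = (self.dosages < 0) | (self.dosages > self.ploidy)
        if np.any(bad):
            i, j = np.argwhere(bad)[0]
            raise PanelValidationError(
                f"dosage out of range [0, {self.ploidy}] for parent "
                f"{self.names[i]!r} at marker {self.gmap.marker[j]!r}"
            )
        self.names = np.asarray(self.names, dtype=object)
        if len(self.names) != self.dosages.shape[0]:
            raise PanelValidationError("names length != number of parents")
        if self.dosages.shape[1] != self.gmap.n_loci:
            raise PanelValidationError("dosage columns do not match map markers")
        if self.subpop is None:
            self.subpop = np.asarray(["pop0"] * self.n_parents, dtype=object)
        else:
            self.subpop = np.asarray(self.subpop, dtype=object)
        if self.haplotypes is not None:
            H = np.asarray(self.haplotypes, dtype=np.int8)
            if H.shape != (self.n_parents, self.ploidy, self.n_loci):
                raise PanelValidationError(
                    "haplotypes must have shape (n_parents, ploidy, n_loci)"
                )
            if np.any((H != 0) & (H != 1)):
                raise PanelValidationError("haplotypes must be binary")
            if self.strict and np.any(H.sum(axis=1) != self.dosages):
                raise PanelValidationError(
                    "haplotype column sums do not equal the dosage rows"
                )
            self.haplotypes = H

    @property
    def n_parents(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosages.shape[1]

    @property
    def is_phased(self) -> bool:
        return self.haplotypes is not None

    def allele_freq(self, idx: Sequence[int] | None = None) -> np.ndarray:
        """Per-locus effect-allele frequency over (a subset of) parents."""
        M = self.dosages if idx is None else self.dosages[np.asarray(idx)]
        return M.mean(axis=0) / self.ploidy

    def subset(self, idx: Sequence[int]) -> "ParentPanel":
        idx = np.asarray(idx)
        return ParentPanel(
            ploidy=self.ploidy,
            dosages=self.dosages[idx],
            names=self.names[idx],
            gmap=self.gmap,
            haplotypes=None if self.haplotypes is None else self.haplotypes[idx],
            subpop=self.subpop[idx],
        )

    def parent_haplotypes(self, i: int, rng: np.random.Generator | None = None) -> np.ndarray:
        """Phased haplotypes of parent i; for unphased parents a uniform random
        phase consistent with the dosages is drawn (with a warning)."""
        if self.haplotypes is not None:
            return self.haplotypes[i]
        dos = self.dosages[i]
        H = np.zeros((self.ploidy, self.n_loci), dtype=np.int8)
        het = (dos > 0) & (dos < self.ploidy)
        H[:, dos == self.ploidy] = 1
        if np.any(het):
            if rng is None:
                raise PanelValidationError(
                    f"parent {self.names[i]!r} is heterozygous but unphased; "
                    "provide phased haplotypes or a random generator for the "
                    "random-phase fallback"
                )
            warnings.warn(
                f"parent {self.names[i]!r} is unphased; using a seeded random "
                "phase consistent with its dosages",
                stacklevel=2,
            )
            for j in np.nonzero(het)[0]:
                rows = rng.choice(self.ploidy, size=dos[j], replace=False)
                H[rows, j] = 1
        return H


# ---------------------------------------------------------------------------
# Effects / scores / schemes
# ---------------------------------------------------------------------------

@dataclass
class TraitEffects:
    """Per-locus additive and dominance effects for one trait.

    parameterization is "genotypic" (strictly additive + dominance components,
    not mutually independent) or "breeding" (breeding values + dominance
    deviations).  accuracy is the genomic prediction accuracy r in [0, 1] used
    by the usefulness criterion.
    """

    additive: np.ndarray
    dominance: np.ndarray
    parameterization: str = "genotypic"
    accuracy: float = 1.0
    name: str = "trait"

    def __post_init__(self) -> None:
        self.additive = np.asarray(self.additive, dtype=float)
        self.dominance = np.asarray(self.dominance, dtype=float)
        if self.additive.shape != self.dominance.shape or self.additive.ndim != 1:
            raise PanelValidationError("additive/dominance effect vectors must be 1-D and equal length")
        if self.parameterization not in ("genotypic", "breeding"):
            raise PanelValidationError("parameterization must be 'genotypic' or 'breeding'")
        if not 0.0 <= self.accuracy <= 1.0:
            raise PanelValidationError("accuracy r must lie in [0, 1]")

    @property
    def n_loci(self) -> int:
        return len(self.additive)


@dataclass
class ClassValueMap:
    """Dosage-class scores: m(k) multiplies the additive effect, w(k) the dominance effect.

    Diploid default: m = (0, 1, 2), w = (0, 1, 0) (heterozygosity indicator).
    For higher ploidies no dominance score is assumed: it must be supplied
    explicitly whenever dominance effects are nonzero.
    """

    ploidy: int
    additive_score: np.ndarray | None = None
    dominance_score: np.ndarray | None = None

    def __post_init__(self) -> None:
        k = np.arange(self.ploidy + 1, dtype=float)
        if self.additive_score is None:
            self.additive_score = k
        self.additive_score = np.asarray(self.additive_score, dtype=float)
        if self.dominance_score is None and self.ploidy == 2:
            self.dominance_score = np.array([0.0, 1.0, 0.0])
        if self.dominance_score is not None:
            self.dominance_score = np.asarray(self.dominance_score, dtype=float)
            if len(self.dominance_score) != self.ploidy + 1:
                raise PanelValidationError("dominance_score must cover dosages 0..ploidy")
        if len(self.additive_score) != self.ploidy + 1:
            raise PanelValidationError("additive_score must cover dosages 0..ploidy")

    def require_dominance(self) -> np.ndarray:
        if self.dominance_score is None:
            raise PanelValidationError(
                f"no dominance score defined for ploidy {self.ploidy}; supply one "
                "explicitly (e.g. a heterozygosity indicator)"
            )
        return self.dominance_score

    @classmethod
    def default(cls, ploidy: int) -> "ClassValueMap":
        return cls(ploidy=ploidy)

    @classmethod
    def heterozygosity(cls, ploidy: int) -> "ClassValueMap":
        """m(k) = k and w(k) = 1{0 < k < ploidy}."""
        k = np.arange(ploidy + 1)
        return cls(ploidy=ploidy, dominance_score=((k > 0) & (k < ploidy)).astype(float))


@dataclass
class CrossScheme:
    """Breeding pipeline applied to a cross before its progeny are evaluated.

    pipeline: "F1"/"CLONE" (evaluate the F1 directly), "SELF" (t selfing
    generations after the F1), or "DH" (doubled haploids from F1 gametes,
    diploids only).  testers, when given, testcross the pipeline's end
    generation to each tester parent and evaluate the hybrids.
    """

    pipeline: str = "F1"
    t: int = 0
    testers: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        p = self.pipeline.upper()
        if p == "CLONE":
            p = "F1"
        if p not in ("F1", "SELF", "DH"):
            raise PanelValidationError(f"unknown pipeline {self.pipeline!r}")
        self.pipeline = p
        if self.t < 0 or int(self.t) != self.t:
            raise PanelValidationError("selfing generations t must be a non-negative integer")
        self.t = int(self.t)
        if p != "SELF" and self.t:
            raise PanelValidationError("t is only meaningful for SELF pipelines")
        self.testers = tuple(int(x) for x in self.testers)

    def validate_for_ploidy(self, ploidy: int) -> None:
        if self.pipeline == "DH" and ploidy != 2:
            raise PanelValidationError("doubled haploids are only defined for diploids")

    @property
    def label(self) -> str:
        base = {"F1": "Clonal", "DH": "DH", "SELF": f"ILs(t={self.t})"}[self.pipeline]
        return f"Hybrid_{base}" if self.testers else base


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_effects(path, n_loci: int | None = None, **kwargs) -> TraitEffects:
    """Read a marker-effects table (columns marker, additive, dominance)."""
    df = pd.read_csv(path, sep=None, engine="python")
    cols = {c.lower(): c for c in df.columns}
    eff = TraitEffects(
        additive=df[cols["additive"]].to_numpy(float),
        dominance=df[cols["dominance"]].to_numpy(float)
        if "dominance" in cols
        else np.zeros(len(df)),
        **kwargs,
    )
    if n_loci is not None and eff.n_loci != n_loci:
        raise PanelValidationError(f"effects table has {eff.n_loci} rows, panel has {n_loci} loci")
    return eff


def save_effects(effects: TraitEffects, markers: Sequence, path) -> None:
    pd.DataFrame(
        {"marker": list(markers), "additive": effects.additive, "dominance": effects.dominance}
    ).to_csv(path, sep="\t", index=False)


def load_panel(
    dosage_path,
    map_path,
    phased_path=None,
    ploidy: int = 2,
    subpop: Mapping[str, str] | None = None,
) -> ParentPanel:
    """Load a dosage table (rows = parents, columns = marker ids), a genetic map
    and, optionally, phased genotypes from a VCF with '|'-separated GT fields.

    Dosage columns are aligned to the map's canonical (chromosome, position)
    order; markers present in one file but not the other raise an error listing
    the offending ids.
    """
    gmap = GeneticMap.from_tsv(map_path)
    df = pd.read_csv(dosage_path, sep=None, engine="python", index_col=0)
    missing_in_map = [m for m in df.columns if m not in set(gmap.marker)]
    missing_in_panel = [m for m in gmap.marker if m not in set(df.columns)]
    if missing_in_map or missing_in_panel:
        raise PanelValidationError(
            f"map/panel marker mismatch; absent from map: {missing_in_map[:10]}, "
            f"absent from panel: {missing_in_panel[:10]}"
        )
    df = df[list(gmap.marker)]
    names = df.index.to_numpy(dtype=object)
    hap = None
    if phased_path is not None:
        hap = _load_phased_vcf(phased_path, names, list(gmap.marker), ploidy)
    labels = None
    if subpop is not None:
        labels = np.asarray([subpop.get(str(n), "pop0") for n in names], dtype=object)
    return ParentPanel(
        ploidy=ploidy,
        dosages=df.to_numpy(),
        names=names,
        gmap=gmap,
        haplotypes=hap,
        subpop=labels,
    )


def save_panel(panel: ParentPanel, dosage_path, map_path=None, phased_path=None) -> None:
    pd.DataFrame(panel.dosages, index=panel.names, columns=panel.gmap.marker).to_csv(
        dosage_path, sep="\t"
    )
    if map_path is not None:
        panel.gmap.to_tsv(map_path)
    if phased_path is not None:
        if panel.haplotypes is None:
            raise PanelValidationError("panel carries no haplotypes to write")
        write_phased_vcf(panel, phased_path)


def _load_phased_vcf(path, names, markers, ploidy: int) -> np.ndarray:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_pos = {s: i for i, s in enumerate(vcf.samples)}
    missing = [str(n) for n in names if str(n) not in sample_pos]
    if missing:
        raise PanelValidationError(f"samples absent from VCF: {missing[:10]}")
    marker_pos = {m: j for j, m in enumerate(markers)}
    H = np.full((len(names), ploidy, len(markers)), -1, dtype=np.int8)
    order = [sample_pos[str(n)] for n in names]
    for rec in vcf:
        j = marker_pos.get(rec.ID)
        if j is None:
            continue
        gt = np.asarray(rec.genotype.array())  # (n_samples, ploidy + 1); last col = phased flag
        alleles = gt[:, :ploidy]
        phased = gt[:, ploidy]
        het = (alleles.min(axis=1) != alleles.max(axis=1))
        if np.any(het & (phased == 0)):
            raise PanelValidationError(
                f"unphased heterozygous genotype at marker {rec.ID!r}; phased GT ('|') required"
            )
        H[:, :, j] = alleles[order]
    got = H[0, 0, :] >= 0
    if not np.all(got):
        absent = [markers[j] for j in np.nonzero(~got)[0][:10]]
        raise PanelValidationError(f"markers absent from VCF: {absent}")
    return H


def write_phased_vcf(panel: ParentPanel, path) -> None:
    """Write panel haplotypes as a minimal phased VCF (ALT = effect allele)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        chroms = {c for c, _ in panel.gmap.chromosome_slices()}
        for c in sorted(chroms, key=str):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(n) for n in panel.names)
            + "\n"
        )
        H = panel.haplotypes
        for j in range(panel.n_loci):
            pos = int(round(panel.gmap.pos_cm[j] * 1e4)) + 1  # synthetic bp coordinate
            gts = "\t".join("|".join(str(a) for a in H[i, :, j]) for i in range(panel.n_parents))
            fh.write(
                f"{panel.gmap.chrom[j]}\t{pos}\t{panel.gmap.marker[j]}\tA\tT\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------

@dataclass
class PanelDiagnostics:
    monomorphic_loci: np.ndarray
    heterozygosity: np.ndarray
    phasing_consistent: bool
    inconsistent_parents: np.ndarray = field(default_factory=lambda: np.array([], dtype=object))

    def summary(self) -> str:
        return (
            f"{len(self.monomorphic_loci)} monomorphic loci; mean parent "
            f"heterozygosity {self.heterozygosity.mean():.4f}; phasing "
            f"{'consistent' if self.phasing_consistent else 'INCONSISTENT'}"
        )


def validate_panel(panel: ParentPanel) -> PanelDiagnostics:
    """Report-only diagnostics: monomorphic loci, per-parent heterozygosity and
    haplotype/dosage consistency.  Never mutates the panel."""
    mono = np.nonzero(np.ptp(panel.dosages, axis=0) == 0)[0]
    het = np.mean((panel.dosages > 0) & (panel.dosages < panel.ploidy), axis=1)
    consistent = True
    bad: list = []
    if panel.haplotypes is not None:
        mismatch = np.any(panel.haplotypes.sum(axis=1) != panel.dosages, axis=1)
        consistent = not np.any(mismatch)
        bad = list(panel.names[mismatch])
    return PanelDiagnostics(
        monomorphic_loci=mono,
        heterozygosity=het,
        phasing_consistent=consistent,
        inconsistent_parents=np.asarray(bad, dtype=object),
    )
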