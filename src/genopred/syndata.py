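"""Synthetic pedigree populations with linked SNPs and a known QTL architecture.

Emulates a two-generation full-sib design: a set of founder sires, founder
dams nested within sires, and full-sib families of progeny.  Founder
haplotypes are drawn in linkage equilibrium; progeny haplotypes are produced
by gene dropping with Haldane (no-interference) meiosis, so linkage
disequilibrium among progeny arises from cosegregation alone.  A small number
of QTL — additive, imprinted (parent-of-origin), and additive-by-additive
epistatic — are placed on the SNP map, effects are rescaled so the empirical
additive-genetic variance among progeny equals a requested value exactly, and
phenotypes are recorded for a fixed number of progeny per family, leaving the
rest as a validation set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

UNKNOWN_PARENT = 0

__all__ = [
    "MarkerMap",
    "QTLSpec",
    "TraitParams",
    "SimulatedPopulation",
    "build_pedigree",
    "evenly_spaced_map",
    "simulate_founders",
    "meiosis",
    "drop_genes",
    "assign_architecture",
    "compute_genetic_values",
    "scale_and_phenotype",
    "simulate_population",
    "mendelian_error_count",
    "write_population",
]


class InvalidDesignError(ValueError):
    """Raised when a population design parameter is out of range."""


# ---------------------------------------------------------------------------
# marker map


@dataclass(frozen=True)
class MarkerMap:
    """SNP map: chromosome assignment and within-chromosome position in Morgans.

    Attributes
    ----------
    chromosome : (k,) int array, 1-based chromosome of each SNP.
    position : (k,) float array, position within chromosome in Morgans.
    chrom_length : length of every chromosome in Morgans.
    """

    chromosome: np.ndarray
    position: np.ndarray
    chrom_length: float = 1.0

    def __post_init__(self):
        if len(self.chromosome) != len(self.position):
            raise ValueError("chromosome and position must have equal length")
        for c in self.chromosomes:
            pos = self.position[self.chromosome == c]
            if np.any(np.diff(pos) < 0):
                raise ValueError(f"positions not sorted on chromosome {c}")

    @property
    def n_snps(self) -> int:
        return len(self.chromosome)

    @property
    def chromosomes(self) -> np.ndarray:
        return np.unique(self.chromosome)

    def snps_on(self, chrom: int) -> np.ndarray:
        """0-based global indices of the SNPs on one chromosome, in map order."""
        return np.flatnonzero(self.chromosome == chrom)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp": np.arange(1, self.n_snps + 1),
                "chrom": self.chromosome,
                "position_morgans": self.position,
            }
        )


def evenly_spaced_map(
    n_snps: int = 1998, n_chrom: int = 5, chrom_length: float = 1.0
) -> MarkerMap:
    """Spread ``n_snps`` SNPs uniformly over ``n_chrom`` chromosomes.

    Spacing is uniform genome-wide (``n_chrom * chrom_length / n_snps``), so
    chromosome SNP counts may differ by one when the total does not divide
    evenly.  Defaults give the 5 x 1 Morgan, 1,998-SNP panel used throughout.
    """
    if n_snps < n_chrom or n_chrom < 1:
        raise InvalidDesignError("need at least one SNP per chromosome")
    total = n_chrom * chrom_length
    step = total / n_snps
    global_pos = (np.arange(n_snps) + 0.5) * step
    chrom = np.minimum((global_pos // chrom_length).astype(int), n_chrom - 1) + 1
    pos = global_pos - (chrom - 1) * chrom_length
    return MarkerMap(chromosome=chrom, position=pos, chrom_length=chrom_length)


# ---------------------------------------------------------------------------
# pedigree


def build_pedigree(
    n_sires: int, n_dams_per_sire: int, n_progeny_per_dam: int
) -> pd.DataFrame:
    """Two-generation full-sib pedigree.

    Ids are assigned 1..N in record order: sires first, then dams (nested in
    sires), then progeny family by family.  Founders carry unknown parents
    (coded 0).  Returns a DataFrame with columns id, sire, dam, generation.
    """
    if min(n_sires, n_dams_per_sire, n_progeny_per_dam) < 1:
        raise InvalidDesignError("all design counts must be >= 1")
    sires = np.arange(1, n_sires + 1)
    n_dams = n_sires * n_dams_per_sire
    dams = np.arange(n_sires + 1, n_sires + n_dams + 1)
    dam_sire = np.repeat(sires, n_dams_per_sire)

    prog_start = n_sires + n_dams + 1
    n_prog = n_dams * n_progeny_per_dam
    prog = np.arange(prog_start, prog_start + n_prog)
    prog_dam = np.repeat(dams, n_progeny_per_dam)
    prog_sire = np.repeat(dam_sire, n_progeny_per_dam)

    return pd.DataFrame(
        {
            "id": np.concatenate([sires, dams, prog]),
            "sire": np.concatenate(
                [np.zeros(n_sires + n_dams, dtype=int), prog_sire]
            ),
            "dam": np.concatenate([np.zeros(n_sires + n_dams, dtype=int), prog_dam]),
            "generation": ["founder"] * (n_sires + n_dams) + ["progeny"] * n_prog,
        }
    )


# ---------------------------------------------------------------------------
# founders and gene dropping


def simulate_founders(
    marker_map: MarkerMap,
    maf_low: float,
    maf_high: float,
    n_founders: int,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Founder haplotypes in linkage equilibrium.

    Per-SNP allele frequencies are drawn uniformly in [maf_low, maf_high] and
    alleles are sampled independently for every haplotype (no founder LD).
    Returns a (n_founders, 2, k) uint8 array; axis 1 is (paternal, maternal)
    — arbitrary for founders.
    """
    if not (0 < maf_low <= maf_high <= 0.5):
        raise InvalidDesignError("require 0 < maf_low <= maf_high <= 0.5")
    rng = np.random.default_rng(seed)
    freqs = rng.uniform(maf_low, maf_high, size=marker_map.n_snps)
    haps = (
        rng.random(size=(n_founders, 2, marker_map.n_snps)) < freqs
    ).astype(np.uint8)
    return haps


def meiosis(
    parent_haps: np.ndarray, marker_map: MarkerMap, rng: np.random.Generator
) -> np.ndarray:
    """One gamete from a (2, k) pair of parental haplotypes.

    Haldane model per chromosome: crossover count ~ Poisson(length in
    Morgans), crossover positions uniform, starting strand fair, no
    interference.  A zero-length chromosome is transmitted intact.
    """
    k = marker_map.n_snps
    gamete = np.empty(k, dtype=np.uint8)
    for c in marker_map.chromosomes:
        idx = marker_map.snps_on(c)
        pos = marker_map.position[idx]
        n_cx = rng.poisson(marker_map.chrom_length)
        start = rng.integers(2)
        if n_cx == 0:
            strand = np.full(len(idx), start)
        else:
            cuts = np.sort(rng.uniform(0.0, marker_map.chrom_length, size=n_cx))
            strand = (start + np.searchsorted(cuts, pos)) % 2
        gamete[idx] = parent_haps[strand, idx]
    return gamete


def drop_genes(
    pedigree: pd.DataFrame,
    founder_haps: np.ndarray,
    marker_map: MarkerMap,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Propagate founder haplotypes through the pedigree.

    Founders (in record order) take rows of ``founder_haps``; each progeny
    receives one meiotic gamete from its sire (paternal haplotype, axis-1
    slot 0) and one from its dam (slot 1).  Returns (n, 2, k) uint8.
    """
    rng = np.random.default_rng(seed)
    ids = pedigree["id"].to_numpy()
    row_of = {int(i): r for r, i in enumerate(ids)}
    is_founder = (pedigree["generation"] == "founder").to_numpy()
    n_founders = int(is_founder.sum())
    if founder_haps.shape[0] != n_founders:
        raise ValueError(
            f"founder_haps has {founder_haps.shape[0]} rows, pedigree has "
            f"{n_founders} founders"
        )
    n = len(pedigree)
    haps = np.empty((n, 2, marker_map.n_snps), dtype=np.uint8)
    haps[:n_founders] = founder_haps
    sires = pedigree["sire"].to_numpy()
    dams = pedigree["dam"].to_numpy()
    for r in range(n):
        if is_founder[r]:
            continue
        try:
            sr = row_of[int(sires[r])]
            dr = row_of[int(dams[r])]
        except KeyError as exc:  # pragma: no cover - guarded by pedigree builder
            raise ValueError(f"parent {exc} of individual {ids[r]} not in pedigree")
        if sr >= r or dr >= r:
            raise ValueError("parents must precede progeny in the pedigree")
        haps[r, 0] = meiosis(haps[sr], marker_map, rng)
        haps[r, 1] = meiosis(haps[dr], marker_map, rng)
    return haps


# ---------------------------------------------------------------------------
# QTL architecture


@dataclass(frozen=True)
class QTLSpec:
    """One QTL placed at a map SNP.

    effect: for ``additive`` action, half the difference between homozygotes;
    for ``imprinted``, the value carried by the expressed (parent-of-origin)
    allele coded +/-1; for ``epistatic_pair``, the interaction coefficient of
    the centered-dosage product (stored on both members, identical).
    """

    snp_index: int
    action: str  # additive | imprinted | epistatic_pair
    effect: float
    partner_index: int | None = None
    linkage_phase: str = "n/a"  # coupling | repulsion | n/a
    imprint_origin: str = "paternal"  # expressed parental allele

    def __post_init__(self):
        if self.action not in ("additive", "imprinted", "epistatic_pair"):
            raise ValueError(f"unknown QTL action {self.action!r}")
        if self.action == "epistatic_pair" and self.partner_index is None:
            raise ValueError("epistatic QTL needs a partner_index")
        if self.action != "epistatic_pair" and self.partner_index is not None:
            raise ValueError("partner_index only valid for epistatic pairs")


def _nearest_snp(marker_map: MarkerMap, chrom: int, pos: float) -> int:
    idx = marker_map.snps_on(chrom)
    if len(idx) == 0:
        raise InvalidDesignError(f"no SNPs on chromosome {chrom}")
    return int(idx[np.argmin(np.abs(marker_map.position[idx] - pos))])


def validate_architecture(qtl: list[QTLSpec], n_snps: int) -> None:
    """Check index bounds and that epistatic partnerships are symmetric."""
    by_index = {q.snp_index: q for q in qtl}
    if len(by_index) != len(qtl):
        raise InvalidDesignError("duplicate QTL positions")
    for q in qtl:
        if not (0 <= q.snp_index < n_snps):
            raise InvalidDesignError(f"QTL index {q.snp_index} off the map")
        if q.action == "epistatic_pair":
            partner = by_index.get(q.partner_index)
            if partner is None or partner.partner_index != q.snp_index:
                raise InvalidDesignError(
                    f"epistatic QTL at {q.snp_index} lacks a symmetric partner"
                )


def assign_architecture(
    marker_map: MarkerMap,
    preset: str | list[QTLSpec] = "qtlmas2011",
    seed: int | np.random.Generator = 0,
    minor_effect: float = 1.0,
    major_ratio: float = 4.0,
    pair_spacing: float = 0.1,
) -> list[QTLSpec]:
    """Place the default 8-QTL architecture, or validate a custom one.

    The ``qtlmas2011`` preset mirrors a trait with one major and seven minor
    QTL: a major additive QTL mid-chromosome-1; linked additive pairs on
    chromosomes 2 (coupling: equal signs) and 3 (repulsion: opposite signs)
    ``pair_spacing`` Morgans apart; an imprinted QTL on chromosome 4; and an
    additive-by-additive epistatic pair on chromosome 5.  ``seed`` is accepted
    for interface symmetry; the preset is deterministic.
    """
    if isinstance(preset, list):
        validate_architecture(preset, marker_map.n_snps)
        return list(preset)
    if preset != "qtlmas2011":
        raise InvalidDesignError(f"unknown preset {preset!r}")
    L = marker_map.chrom_length
    mid = 0.5 * L
    half = 0.5 * pair_spacing
    a = minor_effect
    e5a = _nearest_snp(marker_map, 5, 0.25 * L)
    e5b = _nearest_snp(marker_map, 5, 0.75 * L)
    qtl = [
        QTLSpec(_nearest_snp(marker_map, 1, mid), "additive", major_ratio * a),
        QTLSpec(_nearest_snp(marker_map, 2, mid - half), "additive", a,
                linkage_phase="coupling"),
        QTLSpec(_nearest_snp(marker_map, 2, mid + half), "additive", a,
                linkage_phase="coupling"),
        QTLSpec(_nearest_snp(marker_map, 3, mid - half), "additive", a,
                linkage_phase="repulsion"),
        QTLSpec(_nearest_snp(marker_map, 3, mid + half), "additive", -a,
                linkage_phase="repulsion"),
        QTLSpec(_nearest_snp(marker_map, 4, mid), "imprinted", a),
        QTLSpec(e5a, "epistatic_pair", a, partner_index=e5b),
        QTLSpec(e5b, "epistatic_pair", a, partner_index=e5a),
    ]
    validate_architecture(qtl, marker_map.n_snps)
    return qtl


# ---------------------------------------------------------------------------
# genetic values


def compute_genetic_values(
    haplotypes: np.ndarray, qtl: list[QTLSpec]
) -> tuple[np.ndarray, np.ndarray]:
    """True genetic values from haplotypes and a QTL list.

    Per-QTL contributions to the total genotypic value:

    * additive: ``effect * (dosage - 1)`` (centered dosage);
    * imprinted: ``effect * s`` with s = +1 if the expressed parental allele
      is 1, else -1 — only the parent-of-origin allele matters;
    * epistatic pair: ``effect * (dosage_A - 1) * (dosage_B - 1)`` counted
      once per pair.

    ``tbv_additive`` is the breeding-value (dosage-linear) part: additive QTL
    contribute in full; an imprinted locus contributes its average effect
    ``effect * (x - 2p)`` (p the population frequency of the expressed-allele
    count); each member of an epistatic pair contributes the average effect
    ``effect * (2*p_partner - 1) * (x - 2p)``, treating the pair's loci as
    independent at the population frequencies.  Returns
    (tbv_additive, tbv_total).
    """
    n = haplotypes.shape[0]
    tbv_a = np.zeros(n)
    tbv_t = np.zeros(n)
    if not qtl:
        return tbv_a, tbv_t
    validate_architecture(qtl, haplotypes.shape[2])
    dosage = haplotypes.sum(axis=1).astype(float)
    freq = dosage.mean(axis=0) / 2.0
    seen_pairs: set[tuple[int, int]] = set()
    for q in qtl:
        x = dosage[:, q.snp_index]
        p = freq[q.snp_index]
        if q.action == "additive":
            contrib = q.effect * (x - 1.0)
            tbv_t += contrib
            tbv_a += contrib
        elif q.action == "imprinted":
            slot = 0 if q.imprint_origin == "paternal" else 1
            allele = haplotypes[:, slot, q.snp_index].astype(float)
            tbv_t += q.effect * (2.0 * allele - 1.0)
            tbv_a += q.effect * (x - 2.0 * p)
        else:  # epistatic_pair
            key = (min(q.snp_index, q.partner_index), max(q.snp_index, q.partner_index))
            xb = dosage[:, q.partner_index]
            pb = freq[q.partner_index]
            if key not in seen_pairs:
                seen_pairs.add(key)
                tbv_t += q.effect * (x - 1.0) * (xb - 1.0)
            # average effect at this member given the partner's frequency
            tbv_a += q.effect * (2.0 * pb - 1.0) * (x - 2.0 * p)
    return tbv_a, tbv_t


# ---------------------------------------------------------------------------
# trait parameters and the population container


@dataclass(frozen=True)
class TraitParams:
    """Trait mean and variance components used to build phenotypes.

    Defaults: additive variance 26.35, residual 61.49, hence narrow-sense
    heritability 0.3.  If ``h2`` is supplied alongside both variances it must
    agree to 1e-9.
    """

    mu: float = 0.0
    sigma2_a: float = 26.35
    sigma2_e: float = 61.49
    h2: float | None = None

    def __post_init__(self):
        if self.sigma2_a <= 0 or self.sigma2_e < 0:
            raise InvalidDesignError("variances must be positive")
        implied = self.sigma2_a / (self.sigma2_a + self.sigma2_e)
        if self.h2 is None:
            object.__setattr__(self, "h2", implied)
        elif abs(self.h2 - implied) > 1e-9:
            raise InvalidDesignError(
                f"h2={self.h2} inconsistent with variances (implied {implied})"
            )


@dataclass
class SimulatedPopulation:
    """Everything the analyses need, plus the simulation ground truth.

    ``haplotypes`` is (n, 2, k) with axis 1 = (paternal, maternal);
    ``phenotype`` is NaN for unphenotyped (validation) progeny and founders.
    """

    haplotypes: np.ndarray
    pedigree: pd.DataFrame
    marker_map: MarkerMap
    qtl: list[QTLSpec] = field(default_factory=list)
    tbv_additive: np.ndarray | None = None
    tbv_total: np.ndarray | None = None
    phenotype: np.ndarray | None = None
    residual: np.ndarray | None = None
    trait: TraitParams | None = None

    @property
    def n_individuals(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.haplotypes.shape[2]

    @property
    def genotypes(self) -> np.ndarray:
        """Allele-dosage matrix X (n x k, values 0/1/2)."""
        return self.haplotypes.sum(axis=1, dtype=np.int16).astype(np.int8)

    @property
    def heterozygosity(self) -> np.ndarray:
        """Heterozygote indicator W (n x k, 1 iff haplotype alleles differ)."""
        return (self.haplotypes[:, 0] != self.haplotypes[:, 1]).astype(np.int8)

    @property
    def is_progeny(self) -> np.ndarray:
        return (self.pedigree["generation"] == "progeny").to_numpy()

    @property
    def is_phenotyped(self) -> np.ndarray:
        if self.phenotype is None:
            return np.zeros(self.n_individuals, dtype=bool)
        return ~np.isnan(self.phenotype)

    @property
    def is_validation(self) -> np.ndarray:
        """Progeny kept out of the training phenotypes."""
        return self.is_progeny & ~self.is_phenotyped

    @property
    def allele_freq(self) -> np.ndarray:
        return self.genotypes.mean(axis=0) / 2.0


def scale_and_phenotype(
    pop: SimulatedPopulation,
    trait: TraitParams,
    n_phenotyped_per_family: int,
    seed: int | np.random.Generator,
) -> SimulatedPopulation:
    """Calibrate QTL effects to the target additive variance and phenotype.

    All QTL effects are rescaled by one common factor so that the empirical
    variance of ``tbv_additive`` among progeny equals ``trait.sigma2_a``
    exactly (every contribution is linear in the effects, so the rescale is
    exact).  Residuals are i.i.d. N(0, sigma2_e); phenotypes
    ``y = mu + tbv_total + e`` are recorded for a random sample of
    ``n_phenotyped_per_family`` progeny in each full-sib family; the rest of
    the progeny form the validation set.  Modifies ``pop`` in place and
    returns it.
    """
    rng = np.random.default_rng(seed)
    tbv_a, _ = compute_genetic_values(pop.haplotypes, pop.qtl)
    prog = pop.is_progeny
    base_var = float(np.var(tbv_a[prog]))
    if base_var <= 0.0:
        raise InvalidDesignError(
            "architecture yields zero additive variance; cannot calibrate to "
            f"sigma2_a={trait.sigma2_a}"
        )
    scale = np.sqrt(trait.sigma2_a / base_var)
    pop.qtl = [replace(q, effect=q.effect * scale) for q in pop.qtl]
    pop.tbv_additive, pop.tbv_total = compute_genetic_values(pop.haplotypes, pop.qtl)
    pop.trait = trait

    ped = pop.pedigree
    y = np.full(pop.n_individuals, np.nan)
    e = np.full(pop.n_individuals, np.nan)
    prog_rows = np.flatnonzero(prog)
    dams = ped["dam"].to_numpy()[prog_rows]
    for dam in np.unique(dams):
        fam = prog_rows[dams == dam]
        if n_phenotyped_per_family > len(fam):
            raise InvalidDesignError(
                f"family of dam {dam} has {len(fam)} progeny < "
                f"{n_phenotyped_per_family} requested phenotypes"
            )
        chosen = rng.choice(fam, size=n_phenotyped_per_family, replace=False)
        e[chosen] = rng.normal(0.0, np.sqrt(trait.sigma2_e), size=len(chosen))
        y[chosen] = trait.mu + pop.tbv_total[chosen] + e[chosen]
    pop.phenotype = y
    pop.residual = e
    return pop


def simulate_population(
    n_sires: int = 20,
    n_dams_per_sire: int = 10,
    n_progeny_per_dam: int = 15,
    n_snps: int = 1998,
    n_chrom: int = 5,
    chrom_length: float = 1.0,
    maf_low: float = 0.1,
    maf_high: float = 0.5,
    qtl_preset: str | list[QTLSpec] = "qtlmas2011",
    minor_effect: float = 1.0,
    major_ratio: float = 4.0,
    pair_spacing: float = 0.1,
    trait: TraitParams | None = None,
    n_phenotyped_per_family: int = 10,
    seed: int = 0,
) -> SimulatedPopulation:
    """One-call simulation of the full default design.

    Defaults reproduce the study design: 20 sires x 10 dams x 15 progeny
    (3,220 individuals), 5 chromosomes of 1 Morgan with 1,998 evenly spaced
    SNPs, 8 QTL, additive variance 26.35 and residual 61.49 (h2 = 0.3), and
    phenotypes for 10 progeny per family (2,000 training / 1,000 validation).
    """
    trait = trait or TraitParams()
    ss = np.random.SeedSequence(seed)
    s_founder, s_drop, s_phen = [int(s) for s in ss.generate_state(3) % (2**31)]
    marker_map = evenly_spaced_map(n_snps, n_chrom, chrom_length)
    ped = build_pedigree(n_sires, n_dams_per_sire, n_progeny_per_dam)
    n_founders = int((ped["generation"] == "founder").sum())
    founders = simulate_founders(marker_map, maf_low, maf_high, n_founders, s_founder)
    haps = drop_genes(ped, founders, marker_map, s_drop)
    qtl = assign_architecture(
        marker_map,
        qtl_preset,
        minor_effect=minor_effect,
        major_ratio=major_ratio,
        pair_spacing=pair_spacing,
    )
    pop = SimulatedPopulation(
        haplotypes=haps, pedigree=ped, marker_map=marker_map, qtl=qtl
    )
    if qtl:
        scale_and_phenotype(pop, trait, n_phenotyped_per_family, s_phen)
    else:
        pop.tbv_additive = np.zeros(pop.n_individuals)
        pop.tbv_total = np.zeros(pop.n_individuals)
        pop.trait = trait
        warnings.warn("empty architecture: no phenotypes generated")
    return pop


# ---------------------------------------------------------------------------
# audits and writers


def mendelian_error_count(pop: SimulatedPopulation) -> int:
    """Number of progeny-SNP genotypes incompatible with the parents.

    A progeny dosage is compatible iff each of its two alleles can be drawn
    from the corresponding parent (e.g. parents 0 and 0 cannot give dosage 1).
    Gene dropping must always return 0.
    """
    X = pop.genotypes
    ped = pop.pedigree
    row_of = {int(i): r for r, i in enumerate(ped["id"])}
    errors = 0
    prog = np.flatnonzero(pop.is_progeny)
    for r in prog:
        sr = row_of[int(ped["sire"].iloc[r])]
        dr = row_of[int(ped["dam"].iloc[r])]
        for parent_row, hap_slot in ((sr, 0), (dr, 1)):
            allele = pop.haplotypes[r, hap_slot]
            pg = X[parent_row]
            # allele must be producible by the parent: 1 impossible if pg==0,
            # 0 impossible if pg==2
            errors += int(np.sum((allele == 1) & (pg == 0)))
            errors += int(np.sum((allele == 0) & (pg == 2)))
    return errors


def write_population(pop: SimulatedPopulation, out_dir: str | Path,
                     header_lines: list[str] | None = None) -> dict[str, Path]:
    """Write the plain-text dataset files.

    genotypes.txt: one row per individual, id then 0/1/2 dosages,
    whitespace-delimited.  pedigree.csv, phenotypes.csv (NA for missing),
    map.tsv, truth.tsv (QTL table then per-individual TBV).  ``header_lines``
    are prepended as '#'-comments to every file.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    hdr = "".join(f"# {line}\n" for line in (header_lines or []))
    paths: dict[str, Path] = {}

    ids = pop.pedigree["id"].to_numpy()
    X = pop.genotypes

    p = out / "genotypes.txt"
    with open(p, "w") as fh:
        fh.write(hdr)
        for i, row in zip(ids, X):
            fh.write(str(int(i)) + " " + " ".join(map(str, row.tolist())) + "\n")
    paths["genotypes"] = p

    p = out / "pedigree.csv"
    with open(p, "w") as fh:
        fh.write(hdr)
        pop.pedigree.to_csv(fh, index=False)
    paths["pedigree"] = p

    p = out / "phenotypes.csv"
    with open(p, "w") as fh:
        fh.write(hdr)
        fh.write("id,trait\n")
        for i, y in zip(ids, pop.phenotype if pop.phenotype is not None
                        else np.full(len(ids), np.nan)):
            fh.write(f"{int(i)},{'NA' if np.isnan(y) else format(y, '.10g')}\n")
    paths["phenotypes"] = p

    p = out / "map.tsv"
    with open(p, "w") as fh:
        fh.write(hdr)
        pop.marker_map.to_frame().to_csv(fh, sep="\t", index=False,
                                         float_format="%.10g")
    paths["map"] = p

    p = out / "truth.tsv"
    with open(p, "w") as fh:
        fh.write(hdr)
        fh.write("# QTL table (1-based SNP indices)\n")
        fh.write("snp\tchrom\tposition_morgans\taction\teffect\tpartner_snp\t"
                 "linkage_phase\n")
        for q in pop.qtl:
            fh.write(
                f"{q.snp_index + 1}\t{pop.marker_map.chromosome[q.snp_index]}\t"
                f"{pop.marker_map.position[q.snp_index]:.10g}\t{q.action}\t"
                f"{q.effect:.10g}\t"
                f"{'NA' if q.partner_index is None else q.partner_index + 1}\t"
                f"{q.linkage_phase}\n"
            )
        fh.write("# per-individual true genetic values\n")
        fh.write("id\ttbv_additive\ttbv_total\n")
        for i, ta, tt in zip(ids, pop.tbv_additive, pop.tbv_total):
            fh.write(f"{int(i)}\t{ta:.10g}\t{tt:.10g}\n")
    paths["truth"] = p
    return paths
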