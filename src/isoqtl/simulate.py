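"""Simulation of partially isogenic F2:3 families with known QTL architecture.

The generator emulates a sorghum-conversion study design: each family is an
F2:3 population from a cross between a converted line (SC, carrying small
elite-donor introgressions) and its exotic progenitor (EP).  Isogenic
families segregate only inside the introgression segments; families from
related or unrelated parents segregate genome-wide at a configurable
polymorphism density.  Major QTL carry family-specific additive effects
(allelic series), and a dominant photoperiod locus can push flowering past a
censoring bound.

Meiosis follows the Haldane model: crossover counts are Poisson with mean
equal to the chromosome's genetic length in Morgans, breakpoints uniform in
genetic distance, mapped to bp through a (by default linear, optionally
piecewise) genetic map.  Each F2:3 line is represented by its F2 parent's
diplotype, the dosage expectation of the selfed F3 pool, so codes stay in
{0, 1, 2} counting the exotic-progenitor (late/tall) allele at segregating
sites.

Allele bookkeeping: the elite-donor allele is the global reference (coded 0
per copy).  Where a family segregates, the SC parent carries the reference
allele and the EP parent the alternative, so raw allele counts coincide with
EP-allele counts at segregating sites.  Monomorphic background sites share a
randomly drawn allele per family, so a SNP can be fixed at 0 in one family
and at 2 in another.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GenotypeMatrix, SnpMap


class ConfigurationError(ValueError):
    """Inconsistent genome/family/QTL specification."""


def _rng(seed) -> np.random.Generator:
    """Generator from an int seed or an already-spawned SeedSequence."""
    if isinstance(seed, np.random.SeedSequence):
        return np.random.default_rng(seed)
    return np.random.default_rng(np.random.SeedSequence(seed))


def _seedseq(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


# ---------------------------------------------------------------------------
# Specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChromosomeSpec:
    """One chromosome: physical length (bp), genetic length (Morgans).

    ``map_points`` optionally anchors a piecewise-linear genetic map as
    ``((bp, morgan), ...)``; used e.g. to mimic pericentromeric suppression
    of recombination.  Endpoints (0, 0) and (length_bp, length_morgan) are
    implied.
    """

    name: str
    length_bp: int
    length_morgan: float
    map_points: tuple = ()

    def __post_init__(self):
        if self.length_bp <= 0 or self.length_morgan <= 0:
            raise ConfigurationError(f"chromosome {self.name}: lengths must be > 0")

    def _anchors(self):
        pts = sorted(set(self.map_points) | {(0, 0.0), (self.length_bp, self.length_morgan)})
        bp = np.array([p[0] for p in pts], dtype=float)
        gm = np.array([p[1] for p in pts], dtype=float)
        if (np.diff(bp) <= 0).any() or (np.diff(gm) < 0).any():
            raise ConfigurationError(f"chromosome {self.name}: map anchors must be monotone")
        return bp, gm

    def bp_to_morgan(self, bp) -> np.ndarray:
        xs, ys = self._anchors()
        return np.interp(np.asarray(bp, dtype=float), xs, ys)

    def morgan_to_bp(self, morgan) -> np.ndarray:
        xs, ys = self._anchors()
        return np.interp(np.asarray(morgan, dtype=float), ys, xs)


@dataclass(frozen=True)
class GenomeSpec:
    """Chromosome set plus marker positions (1-based bp) per chromosome."""

    chromosomes: tuple
    markers: dict

    def __post_init__(self):
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate chromosome names")
        for c in self.chromosomes:
            pos = np.asarray(self.markers.get(c.name, ()), dtype=np.int64)
            if pos.size and ((np.diff(pos) <= 0).any() or pos[0] < 1 or pos[-1] > c.length_bp):
                raise ConfigurationError(
                    f"marker positions on {c.name} must be strictly increasing within [1, length]"
                )

    def chromosome(self, name) -> ChromosomeSpec:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(name)

    @property
    def snp_map(self) -> SnpMap:
        return SnpMap.from_positions(
            {c.name: np.asarray(self.markers[c.name], dtype=np.int64) for c in self.chromosomes}
        )

    def genetic_distance_cm(self, chrom, bp_a, bp_b) -> float:
        c = self.chromosome(chrom)
        m = c.bp_to_morgan([bp_a, bp_b])
        return float(abs(m[1] - m[0]) * 100.0)


def default_genome(n_chrom: int = 3, length_bp: int = 60_000_000,
                   length_morgan: float = 1.0, n_markers: int = 300) -> GenomeSpec:
    """Desk-scale stand-in for the 10-chromosome sorghum genome."""
    spacing = length_bp // n_markers
    pos = np.arange(1, n_markers + 1, dtype=np.int64) * spacing
    chroms = tuple(
        ChromosomeSpec(str(i + 1), length_bp, length_morgan) for i in range(n_chrom)
    )
    return GenomeSpec(chroms, {c.name: pos.copy() for c in chroms})


ISOGENICITY = ("isogenic", "related", "unrelated")


@dataclass(frozen=True)
class FamilySpec:
    """One SC x EP family.

    ``segments`` are ``(chrom, start_bp, end_bp)`` introgression intervals
    (closed, 1-based) where the SC parent differs from the EP parent; used
    only for isogenic families.  ``density`` is the genome-wide marker
    polymorphism probability for related/unrelated families.
    """

    name: str
    n_lines: int
    isogenicity: str
    segments: tuple = ()
    density: float = 0.0

    def __post_init__(self):
        if self.isogenicity not in ISOGENICITY:
            raise ConfigurationError(f"unknown isogenicity {self.isogenicity!r}")
        if self.n_lines < 1:
            raise ConfigurationError("n_lines must be >= 1")
        if self.isogenicity != "isogenic" and not (0 < self.density <= 1):
            raise ConfigurationError("related/unrelated families need density in (0, 1]")
        by_chrom = {}
        for chrom, a, b in self.segments:
            if b <= a:
                raise ConfigurationError(f"segment ({chrom}, {a}, {b}) is empty")
            by_chrom.setdefault(chrom, []).append((a, b))
        for chrom, segs in by_chrom.items():
            segs.sort()
            for (a1, b1), (a2, b2) in itertools.pairwise(segs):
                if a2 <= b1:
                    raise ConfigurationError(f"overlapping segments on chromosome {chrom}")

    def covers(self, chrom, pos) -> bool:
        return any(c == chrom and a <= pos <= b for c, a, b in self.segments)


@dataclass(frozen=True)
class QtlSpec:
    """A causal locus with per-family additive (a) and dominance (d) effects.

    ``a[fam] = 0`` (or absent) means the family's parents carry functionally
    equivalent alleles there.  ``censor_trigger`` marks the dominant
    photoperiod locus whose carriers may overshoot the flowering censor
    bound in the temperate trait.
    """

    name: str
    chrom: str
    pos_bp: int
    trait: str
    a: dict
    d: dict = field(default_factory=dict)
    censor_trigger: bool = False

    def effect(self, fam):
        return float(self.a.get(fam, 0.0)), float(self.d.get(fam, 0.0))


# ---------------------------------------------------------------------------
# Founders
# ---------------------------------------------------------------------------

@dataclass
class FounderPair:
    """SC-like and EP-like founder haplotypes for one family.

    Alleles are 0 (elite-donor reference) / 1 (alternative) at the union of
    marker and QTL positions, stored per chromosome.
    """

    family: str
    positions: dict          # chrom -> int64 loci positions (markers U QTL)
    sc: dict                 # chrom -> 0/1 alleles
    ep: dict                 # chrom -> 0/1 alleles
    marker_index: dict       # chrom -> indices of marker loci within positions
    qtl_index: dict          # qtl name -> (chrom, locus index)

    def polymorphic(self, chrom) -> np.ndarray:
        return self.sc[chrom] != self.ep[chrom]


def _loci_union(genome: GenomeSpec, qtl) -> tuple:
    positions, marker_index, qtl_index = {}, {}, {}
    for c in genome.chromosomes:
        markers = np.asarray(genome.markers[c.name], dtype=np.int64)
        qpos = np.array([q.pos_bp for q in qtl if q.chrom == c.name], dtype=np.int64)
        loci = np.unique(np.concatenate([markers, qpos]))
        positions[c.name] = loci
        marker_index[c.name] = np.searchsorted(loci, markers)
    for q in qtl:
        loci = positions[q.chrom]
        qtl_index[q.name] = (q.chrom, int(np.searchsorted(loci, q.pos_bp)))
    return positions, marker_index, qtl_index


def make_founders(genome: GenomeSpec, family: FamilySpec, seed,
                  qtl=(), bg_alt_freq: float = 0.3) -> FounderPair:
    """Draw the SC/EP founder haplotype pair for one family.

    Isogenic families differ only inside their introgression segments;
    related/unrelated families differ at each locus independently with
    probability ``family.density``.  Every QTL with a non-zero additive
    effect in this family is forced polymorphic (and must fall inside a
    segment for isogenic families).  Monomorphic sites share a background
    allele drawn Bernoulli(``bg_alt_freq``).
    """
    rng = _rng(seed)
    positions, marker_index, qtl_index = _loci_union(genome, qtl)
    sc, ep = {}, {}
    for c in genome.chromosomes:
        loci = positions[c.name]
        n = loci.size
        background = rng.binomial(1, bg_alt_freq, n).astype(np.int8)
        if family.isogenicity == "isogenic":
            poly = np.zeros(n, dtype=bool)
            for chrom, a, b in family.segments:
                if chrom == c.name:
                    poly |= (loci >= a) & (loci <= b)
        else:
            poly = rng.random(n) < family.density
        sc[c.name] = np.where(poly, 0, background).astype(np.int8)
        ep[c.name] = np.where(poly, 1, background).astype(np.int8)
    for q in qtl:
        a_f, _ = q.effect(family.name)
        chrom, idx = qtl_index[q.name]
        if a_f != 0.0:
            if family.isogenicity == "isogenic" and not family.covers(chrom, q.pos_bp):
                raise ConfigurationError(
                    f"QTL {q.name} has effect {a_f} in isogenic family {family.name} "
                    f"but lies outside every introgression segment"
                )
            sc[chrom][idx] = 0
            ep[chrom][idx] = 1
    return FounderPair(family.name, positions, sc, ep, marker_index, qtl_index)


# ---------------------------------------------------------------------------
# Meiosis and F2:3 genotypes
# ---------------------------------------------------------------------------

def _gamete_parity(rng, gpos_morgan: np.ndarray, length_morgan: float) -> np.ndarray:
    """Which founder haplotype (0=SC, 1=EP) a gamete carries at each locus."""
    k = rng.poisson(length_morgan)
    start = rng.integers(2)
    if k == 0:
        return np.full(gpos_morgan.size, start, dtype=np.int8)
    breaks = np.sort(rng.random(k) * length_morgan)
    return ((start + np.searchsorted(breaks, gpos_morgan, side="right")) % 2).astype(np.int8)


def simulate_f23(founders: FounderPair, n_lines: int, genome: GenomeSpec, seed) -> dict:
    """Simulate F2 diplotypes (representing F2:3 lines) from one F1 selfing.

    Returns ``{chrom: (n_lines, n_loci) int8}`` counting EP-derived
    haplotypes (0/1/2) at every marker and QTL locus.
    """
    if n_lines < 1:
        raise ConfigurationError("n_lines must be >= 1")
    rng = _rng(seed)
    epdose = {}
    for c in genome.chromosomes:
        loci = founders.positions[c.name]
        gpos = c.bp_to_morgan(loci)
        out = np.empty((n_lines, loci.size), dtype=np.int8)
        for i in range(n_lines):
            out[i] = (_gamete_parity(rng, gpos, c.length_morgan)
                      + _gamete_parity(rng, gpos, c.length_morgan))
        epdose[c.name] = out
    return epdose


@dataclass
class TruthSet:
    """Realized simulation ground truth for recovery scoring.

    Holds per-line parent-of-origin dosages at every marker and QTL locus,
    the founder haplotypes, and the full specification; bit-reproducible
    from (specs, seed).
    """

    genome: GenomeSpec
    families: tuple
    qtl: tuple
    founders: dict           # family -> FounderPair
    epdose: dict             # family -> {chrom: (n_lines, n_loci) int8}
    line_ids: dict           # family -> array of line ids
    seed: int

    @property
    def snp_map(self) -> SnpMap:
        return self.genome.snp_map

    def family_spec(self, name) -> FamilySpec:
        for f in self.families:
            if f.name == name:
                return f
        raise KeyError(name)

    def qtl_dosage(self, family: str, qtl_name: str) -> np.ndarray:
        chrom, idx = self.founders[family].qtl_index[qtl_name]
        return self.epdose[family][chrom][:, idx]

    def _marker_codes(self, family: str) -> np.ndarray:
        """Alt-allele counts (0/1/2) at marker loci for one family."""
        fp = self.founders[family]
        cols = []
        for c in self.genome.chromosomes:
            mi = fp.marker_index[c.name]
            dose = self.epdose[family][c.name][:, mi].astype(np.float64)
            sc = fp.sc[c.name][mi].astype(np.float64)
            ep = fp.ep[c.name][mi].astype(np.float64)
            cols.append(dose * ep + (2.0 - dose) * sc)
        return np.concatenate(cols, axis=1)

    def marker_genotypes(self) -> GenotypeMatrix:
        """Stack all families into one raw 0/1/2 genotype matrix."""
        codes = np.concatenate([self._marker_codes(f.name) for f in self.families])
        line_id = np.concatenate([self.line_ids[f.name] for f in self.families])
        family = np.concatenate(
            [np.full(f.n_lines, f.name, dtype=object) for f in self.families]
        )
        return GenotypeMatrix(codes, line_id, family, self.snp_map, "raw")

    def parent_genotypes(self, family: str) -> tuple:
        """(SC, EP) parent 0/2 allele-count vectors at the marker loci."""
        fp = self.founders[family]
        sc = np.concatenate(
            [2.0 * fp.sc[c.name][fp.marker_index[c.name]] for c in self.genome.chromosomes]
        )
        ep = np.concatenate(
            [2.0 * fp.ep[c.name][fp.marker_index[c.name]] for c in self.genome.chromosomes]
        )
        return sc.astype(np.float64), ep.astype(np.float64)

    def true_qtl_table(self, trait=None) -> pd.DataFrame:
        rows = [
            {"qtl": q.name, "chrom": q.chrom, "pos_bp": q.pos_bp, "trait": q.trait,
             **{f"a_{f.name}": q.effect(f.name)[0] for f in self.families}}
            for q in self.qtl if trait is None or q.trait == trait
        ]
        return pd.DataFrame(rows)


def simulate_study(genome: GenomeSpec, families, qtl, seed,
                   bg_alt_freq: float = 0.3) -> TruthSet:
    """Realize founders and F2:3 diplotypes for every family."""
    root = _seedseq(seed)
    children = root.spawn(2 * len(families))
    founders, epdose, line_ids = {}, {}, {}
    for i, fam in enumerate(families):
        fp = make_founders(genome, fam, children[2 * i], qtl, bg_alt_freq)
        founders[fam.name] = fp
        epdose[fam.name] = simulate_f23(fp, fam.n_lines, genome, children[2 * i + 1])
        line_ids[fam.name] = np.array(
            [f"{fam.name}-{j + 1:03d}" for j in range(fam.n_lines)], dtype=object
        )
    return TruthSet(genome, tuple(families), tuple(qtl), founders, epdose, line_ids, seed)


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def simulate_phenotypes(truth: TruthSet, offsets: dict, noise_sd: dict, seed) -> pd.DataFrame:
    """Trait = family offset + sum over QTL of a*(g-1) + d*[g==1] + noise.

    ``g`` counts the late/tall (EP) allele at the QTL.  ``offsets`` maps
    trait -> {family: offset}; ``noise_sd`` maps trait -> residual SD.
    Unknown trait names in either dict raise ``ConfigurationError``.
    """
    traits = list(offsets)
    known = {q.trait for q in truth.qtl} | set(traits)
    for t in list(noise_sd):
        if t not in known:
            raise ConfigurationError(f"unknown trait {t!r} in noise_sd")
    for q in truth.qtl:
        if q.trait not in traits:
            raise ConfigurationError(f"QTL {q.name} affects unknown trait {q.trait!r}")
    rng = _rng(seed)
    frames = []
    for fam in truth.families:
        n = fam.n_lines
        data = {"line_id": truth.line_ids[fam.name],
                "family": np.full(n, fam.name, dtype=object)}
        for t in traits:
            value = np.full(n, float(offsets[t].get(fam.name, 0.0)))
            for q in truth.qtl:
                if q.trait != t:
                    continue
                a_f, d_f = q.effect(fam.name)
                if a_f == 0.0 and d_f == 0.0:
                    continue
                g = truth.qtl_dosage(fam.name, q.name).astype(np.float64)
                value += a_f * (g - 1.0) + d_f * (g == 1.0)
            sd = float(noise_sd.get(t, 0.0))
            if sd > 0:
                value = value + rng.normal(0.0, sd, n)
            data[t] = value
        frames.append(pd.DataFrame(data))
    return pd.concat(frames, ignore_index=True)


def flowering_from_anthesis(d25, d75):
    """Row flowering date as the mean of the 25% and 75% anthesis dates."""
    d25 = np.asarray(d25, dtype=float)
    d75 = np.asarray(d75, dtype=float)
    if np.any(d25 > d75):
        raise ValueError("25% anthesis date must not exceed 75% anthesis date")
    out = (d25 + d75) / 2.0
    return float(out) if out.ndim == 0 else out


def censor_flowering(table: pd.DataFrame, trait: str = "FL",
                     bound_days: float = 138.0) -> pd.DataFrame:
    """Truncate flowering values above the frost bound and flag them censored."""
    if trait not in table.columns:
        raise ConfigurationError(f"trait {trait!r} not present in phenotype table")
    out = table.copy()
    censored = out[trait].to_numpy(dtype=float) > bound_days
    out[trait] = np.where(censored, bound_days, out[trait])
    out[f"{trait}_censored"] = censored
    return out


def apply_gbs_missingness(gm: GenotypeMatrix, rate, seed) -> GenotypeMatrix:
    """Set each (line, SNP) cell missing independently.

    ``rate`` is a scalar or a per-SNP vector in [0, 1), the latter useful to
    create SNPs that fail the downstream 5% missingness filter.
    """
    rate = np.asarray(rate, dtype=float)
    if np.any(rate < 0) or np.any(rate >= 1):
        raise ConfigurationError("missingness rate must be in [0, 1)")
    if rate.ndim == 1 and rate.size != gm.snp_map.n_snps:
        raise ConfigurationError("per-SNP rate vector length mismatch")
    rng = _rng(seed)
    out = gm.copy()
    mask = rng.random(out.codes.shape) < rate
    out.codes[mask] = np.nan
    return out


# ---------------------------------------------------------------------------
# Packaged scenarios
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Scenario:
    """A complete simulation design: genome, families, QTL, phenotype model."""

    genome: GenomeSpec
    families: tuple
    qtl: tuple
    offsets: dict
    noise_sd: dict
    censor_trait: str = ""
    censor_bound: float = 138.0
    gbs_missing_rate: float = 0.0
    n_high_missing_snps: int = 0
    high_missing_rate: float = 0.3
    bg_alt_freq: float = 0.3


def simulate_scenario(scenario: Scenario, seed):
    """Run a scenario end to end: (TruthSet, raw GenotypeMatrix, phenotypes)."""
    root = _seedseq(seed)
    s_truth, s_pheno, s_miss, s_pick = root.spawn(4)
    truth = simulate_study(scenario.genome, scenario.families, scenario.qtl,
                           s_truth, scenario.bg_alt_freq)
    genotypes = truth.marker_genotypes()
    if scenario.gbs_missing_rate > 0 or scenario.n_high_missing_snps > 0:
        rate = np.full(genotypes.snp_map.n_snps, scenario.gbs_missing_rate)
        if scenario.n_high_missing_snps > 0:
            pick = np.random.default_rng(s_pick).choice(
                rate.size, scenario.n_high_missing_snps, replace=False
            )
            rate[pick] = scenario.high_missing_rate
        genotypes = apply_gbs_missingness(genotypes, rate, s_miss)
    phenotypes = simulate_phenotypes(truth, scenario.offsets, scenario.noise_sd, s_pheno)
    if scenario.censor_trait:
        phenotypes = censor_flowering(phenotypes, scenario.censor_trait,
                                      scenario.censor_bound)
    return truth, genotypes, phenotypes


def demo_scenario() -> Scenario:
    """The packaged five-family demonstration study.

    Families A and B are nearly isogenic and carry a small-effect
    early-flowering allele at the major photoperiod locus on chromosome 1
    (a = 5.3 d); families C, D and E carry a large-effect allele
    (a = 19.3 d, dominant), forming an allelic series.  The introgression
    geometry guarantees that no marker segregates in all five families
    around that locus (markers segregating in C never fall inside the A/B
    segments).  A second height locus on chromosome 2 segregates with
    equivalent effects in C and E only (two equivalent knockouts), and a
    linked height locus ~4 Mb distal to the photoperiod locus segregates in
    A and B, mirroring the fusion-prone two-locus geometry on sorghum
    chromosome 6.  Chromosome 1 carries a region of suppressed
    recombination spanning the photoperiod locus.
    """
    length = 60_000_000
    grid = np.arange(1, 301, dtype=np.int64) * 200_000
    chr1 = grid[(grid < 40_000_000) | (grid > 40_600_000)]
    chr1 = np.unique(np.concatenate([chr1, [40_000_000, 40_120_000, 40_240_000, 40_660_000]]))
    genome = GenomeSpec(
        (
            ChromosomeSpec("1", length, 1.0,
                           map_points=((20_000_000, 0.45), (45_000_000, 0.55))),
            ChromosomeSpec("2", length, 1.0),
            ChromosomeSpec("3", length, 1.0),
        ),
        {"1": chr1, "2": grid.copy(), "3": grid.copy()},
    )
    families = (
        FamilySpec("A", 160, "isogenic",
                   segments=(("1", 39_850_000, 40_310_000),
                             ("1", 44_250_000, 44_550_000),
                             ("3", 10_000_000, 12_000_000))),
        FamilySpec("B", 160, "isogenic",
                   segments=(("1", 39_850_000, 40_310_000),
                             ("1", 44_250_000, 44_550_000),
                             ("3", 20_000_000, 23_000_000))),
        FamilySpec("C", 160, "isogenic",
                   segments=(("1", 40_250_000, 43_500_000),
                             ("2", 56_500_000, 59_800_000))),
        FamilySpec("D", 180, "related", density=0.35),
        FamilySpec("E", 180, "unrelated", density=0.8),
    )
    qtl = (
        QtlSpec("ma1_like_fl", "1", 40_270_000, "FL",
                a={"A": 5.3, "B": 5.3, "C": 19.3, "D": 19.3, "E": 19.3},
                d={"C": 19.3, "D": 19.3, "E": 19.3},
                censor_trigger=True),
        QtlSpec("ma1_like_ht", "1", 40_270_000, "HT",
                a={"C": 30.0, "D": 30.0, "E": 30.0},
                d={"C": 30.0, "D": 30.0, "E": 30.0}),
        QtlSpec("dw2_like_ht", "1", 44_400_000, "HT",
                a={"A": 22.0, "B": 22.0}),
        QtlSpec("dw3_like_ht", "2", 58_560_000, "HT",
                a={"C": 45.0, "E": 45.0}),
    )
    offsets = {
        "FL": {"A": 70.0, "B": 72.0, "C": 100.0, "D": 102.0, "E": 98.0},
        "HT": {"A": 250.0, "B": 245.0, "C": 260.0, "D": 255.0, "E": 265.0},
    }
    noise_sd = {"FL": 5.0, "HT": 12.0}
    return Scenario(genome, families, qtl, offsets, noise_sd,
                    censor_trait="FL", censor_bound=138.0,
                    gbs_missing_rate=0.02, n_high_missing_snps=5)


#: seed of the shipped demonstration analysis
DEMO_SEED = 1402


def allelic_series_scenario() -> Scenario:
    """Minimal five-family design with one allelic-series locus.

    Two family groups carry effects of 5.3 vs 19.3 d at the same locus and
    no marker segregates in both groups (families A/B segregate only for
    markers left of the locus, C/D only right of it, E genome-wide), so a
    single-effect model cannot tag the locus with one SNP while the
    family-nested model can.
    """
    grid = np.arange(1, 151, dtype=np.int64) * 200_000          # 30 Mb
    chr1 = grid[(grid < 20_000_000) | (grid > 20_700_000)]
    chr1 = np.unique(np.concatenate(
        [chr1, [20_000_000, 20_120_000, 20_240_000, 20_660_000]]))
    genome = GenomeSpec((ChromosomeSpec("1", 30_000_000, 0.6),),
                        {"1": chr1})
    families = (
        FamilySpec("A", 160, "isogenic", segments=(("1", 19_850_000, 20_310_000),)),
        FamilySpec("B", 160, "isogenic", segments=(("1", 19_850_000, 20_310_000),)),
        FamilySpec("C", 160, "isogenic", segments=(("1", 20_250_000, 23_500_000),)),
        FamilySpec("D", 160, "isogenic", segments=(("1", 20_250_000, 23_500_000),)),
        FamilySpec("E", 180, "unrelated", density=0.8),
    )
    qtl = (QtlSpec("series_locus", "1", 20_270_000, "FL",
                   a={"A": 5.3, "B": 5.3, "C": 19.3, "D": 19.3, "E": 19.3}),)
    offsets = {"FL": {"A": 70.0, "B": 72.0, "C": 78.0, "D": 80.0, "E": 75.0}}
    return Scenario(genome, families, qtl, offsets, {"FL": 4.0})


def null_scenario(n_families: int = 5, n_lines: int = 120,
                  n_snps: int = 1000, density: float = 0.6) -> Scenario:
    """No-QTL scenario for threshold calibration: pure-noise phenotypes."""
    per = [n_snps // 3] * 3
    per[-1] += n_snps - sum(per)
    chroms = tuple(ChromosomeSpec(str(i + 1), 60_000_000, 1.0) for i in range(3))
    markers = {
        c.name: np.unique(np.round(np.linspace(2e5, 6e7, per[i])).astype(np.int64))
        for i, c in enumerate(chroms)
    }
    genome = GenomeSpec(chroms, markers)
    families = tuple(
        FamilySpec(f"F{i + 1}", n_lines, "unrelated", density=density)
        for i in range(n_families)
    )
    offsets = {"Y": {f.name: 0.0 for f in families}}
    return Scenario(genome, families, (), offsets, {"Y": 1.0})
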