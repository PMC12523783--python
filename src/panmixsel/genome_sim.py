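"""Genome maps, allele-frequency sampling, and founder populations with
engineered linkage disequilibrium.

The reference population (generation 0) is built the classical way: two
parental populations in linkage equilibrium but with contrasting allele
frequencies are crossed, and the F1 is randomly mated once more.  Generation 0
is then in Hardy-Weinberg equilibrium and its gametic pool carries LD

    Delta_ab = (1 - 2*theta) / 4 * (p_a1 - p_a2) * (p_b1 - p_b2),

where ``theta`` is the recombination fraction between loci a and b and the
indices 1, 2 refer to the two parental populations.  The LD level is therefore
controlled entirely by the frequency contrast between the parental
populations: equal frequencies give a low-LD population, strongly different
frequencies give a high-LD population with predominantly positive pairwise
LD (all frequency differences share the same sign).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from ._rng import as_rng, spawn

__all__ = [
    "GenomeConfig",
    "GenomeMap",
    "FounderSpec",
    "LocusFrequencies",
    "default_genome_config",
    "build_genome",
    "low_ld_spec",
    "high_ld_spec",
    "sample_allele_frequencies",
    "expected_founder_ld",
    "make_reference_population",
    "export_tped",
    "save_population_h5",
    "load_population_h5",
]


# ---------------------------------------------------------------------------
# genome configuration and map
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeConfig:
    """Per-chromosome lengths (cM) and marker/QTL counts."""

    lengths: tuple[float, ...]
    n_snps: tuple[int, ...]
    n_qtl: tuple[int, ...]

    def __post_init__(self):
        if not (len(self.lengths) == len(self.n_snps) == len(self.n_qtl)):
            raise ValueError("per-chromosome arrays must have equal length")
        if any(l <= 0 for l in self.lengths):
            raise ValueError("chromosome lengths must be positive")
        if any(n < 0 for n in self.n_snps) or any(n < 0 for n in self.n_qtl):
            raise ValueError("locus counts must be non-negative")

    @property
    def n_chromosomes(self) -> int:
        return len(self.lengths)

    @property
    def total_snps(self) -> int:
        return int(sum(self.n_snps))

    @property
    def total_qtl(self) -> int:
        return int(sum(self.n_qtl))


def _interpolated_counts(total: int, first: int, last: int,
                         lengths: np.ndarray) -> tuple[int, ...]:
    """First/last chromosome counts fixed; middle chromosomes get the
    remainder in proportion to map length, rounding fixed on the largest
    middle chromosome so the total is exact."""
    n = len(lengths)
    if n == 1:
        return (total,)
    if n == 2:
        if first + last != total:
            raise ValueError("endpoint counts inconsistent with total")
        return (first, last)
    middle_total = total - first - last
    if middle_total < 0:
        raise ValueError("endpoint counts exceed total")
    mid_len = lengths[1:-1]
    raw = middle_total * mid_len / mid_len.sum()
    counts = np.floor(raw + 0.5).astype(int)
    counts[np.argmax(mid_len)] += middle_total - counts.sum()
    if (counts < 0).any():
        raise ValueError("counts inconsistent with per-chromosome lengths")
    return (first, *counts.tolist(), last)


def default_genome_config(n_chromosomes: int = 10,
                          total_snps: int = 38_500,
                          total_qtl: int = 1_000,
                          first_length: float = 199.4,
                          last_length: float = 25.7,
                          first_snps: int = 10_000,
                          last_snps: int = 1_250,
                          first_qtl: int = 260,
                          last_qtl: int = 30,
                          snp_spacing_cm: float = 0.02) -> GenomeConfig:
    """Default chicken-like genome: 10 chromosomes from 199.4 to 25.7 cM,
    38,500 SNPs (10,000 down to 1,250) and 1,000 QTL (260 down to 30).

    Only the endpoints and totals are fixed a priori; intermediate chromosome
    lengths follow a power-law interpolation whose exponent is solved so the
    total map length matches the stated average SNP spacing (0.02 cM, i.e.
    770 cM overall, which also reproduces the 0.77 cM average QTL spacing).
    """
    total_length = total_snps * snp_spacing_cm
    n = n_chromosomes
    if n == 1:
        lengths = np.array([total_length])
    else:
        frac = (n - 1 - np.arange(n)) / (n - 1)  # 1 .. 0
        span = first_length - last_length
        target = total_length - n * last_length

        def total_at(gamma):
            return span * np.sum(frac ** gamma) - target

        # gamma=1 gives the linear interpolation; solve for the exponent that
        # matches the stated total map length
        lo, hi = 0.05, 50.0
        if total_at(lo) * total_at(hi) > 0:
            raise ValueError("cannot match total map length with endpoints")
        gamma = brentq(total_at, lo, hi)
        lengths = last_length + span * frac ** gamma
    snps = _interpolated_counts(total_snps, first_snps, last_snps, lengths)
    qtl = _interpolated_counts(total_qtl, first_qtl, last_qtl, lengths)
    return GenomeConfig(tuple(float(l) for l in lengths), snps, qtl)


@dataclass
class GenomeMap:
    """Chromosome lengths plus ordered SNP and QTL positions (cM).

    Loci of both kinds are merged into one global, per-chromosome-sorted
    locus table used by the meiosis machinery; ``snp_cols``/``qtl_cols``
    index the global table.
    """

    lengths: np.ndarray
    snp_positions: list[np.ndarray]
    qtl_positions: list[np.ndarray]

    # derived fields
    chrom: np.ndarray = field(init=False, repr=False)
    pos: np.ndarray = field(init=False, repr=False)
    is_qtl: np.ndarray = field(init=False, repr=False)
    snp_cols: np.ndarray = field(init=False, repr=False)
    qtl_cols: np.ndarray = field(init=False, repr=False)
    chrom_slices: list[slice] = field(init=False, repr=False)

    def __post_init__(self):
        self.lengths = np.asarray(self.lengths, dtype=float)
        chroms, poss, isq = [], [], []
        self.chrom_slices = []
        start = 0
        for c, (sp, qp) in enumerate(zip(self.snp_positions, self.qtl_positions)):
            sp = np.asarray(sp, dtype=float)
            qp = np.asarray(qp, dtype=float)
            for arr in (sp, qp):
                if arr.size and (np.any(np.diff(arr) <= 0)):
                    raise ValueError("positions must be strictly ascending")
                if arr.size and (arr.min() < 0 or arr.max() > self.lengths[c]):
                    raise ValueError("positions outside [0, length]")
            if np.intersect1d(sp, qp).size:
                raise ValueError("SNP and QTL positions must be disjoint")
            p = np.concatenate([sp, qp])
            q = np.concatenate([np.zeros(sp.size, bool), np.ones(qp.size, bool)])
            order = np.argsort(p, kind="stable")
            chroms.append(np.full(p.size, c, dtype=np.int16))
            poss.append(p[order])
            isq.append(q[order])
            self.chrom_slices.append(slice(start, start + p.size))
            start += p.size
        self.chrom = np.concatenate(chroms)
        self.pos = np.concatenate(poss)
        self.is_qtl = np.concatenate(isq)
        self.snp_cols = np.flatnonzero(~self.is_qtl)
        self.qtl_cols = np.flatnonzero(self.is_qtl)

    @property
    def n_chromosomes(self) -> int:
        return len(self.lengths)

    @property
    def n_loci(self) -> int:
        return self.pos.size

    @property
    def n_snps(self) -> int:
        return self.snp_cols.size

    @property
    def n_qtl(self) -> int:
        return self.qtl_cols.size

    @property
    def snp_ids(self) -> list[str]:
        return [f"snp{self.chrom[i] + 1}_{i}" for i in self.snp_cols]

    @property
    def qtl_ids(self) -> list[str]:
        return [f"qtl{self.chrom[i] + 1}_{i}" for i in self.qtl_cols]

    def export_map(self, path) -> None:
        """Tab-separated map file: chromosome, id, cM position, SNP/QTL."""
        with open(path, "w") as fh:
            fh.write("chrom\tid\tpos_cM\ttype\n")
            for i in range(self.n_loci):
                kind = "QTL" if self.is_qtl[i] else "SNP"
                fh.write(f"{self.chrom[i] + 1}\t{kind.lower()}{self.chrom[i] + 1}_{i}"
                         f"\t{self.pos[i]:.6f}\t{kind}\n")


def build_genome(config: GenomeConfig, seed=None) -> GenomeMap:
    """Draw SNP and QTL positions uniformly on each chromosome.

    Exact position ties (probability ~0 under continuous uniforms) are
    resolved by resampling, keeping SNP and QTL position sets disjoint.
    """
    rng = as_rng(seed)
    snp_positions, qtl_positions = [], []
    for length, ns, nq in zip(config.lengths, config.n_snps, config.n_qtl):
        while True:
            p = rng.uniform(0.0, length, ns + nq)
            if np.unique(p).size == p.size:
                break
        snp_positions.append(np.sort(p[:ns]))
        qtl_positions.append(np.sort(p[ns:]))
    return GenomeMap(np.asarray(config.lengths, float), snp_positions, qtl_positions)


# ---------------------------------------------------------------------------
# founder allele frequencies
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FounderSpec:
    """Mean allele frequencies of the two parental populations.

    ``snp_freq_means`` are the mean allele-1 frequencies for SNPs (stated as
    MAF targets; for means <= 0.5 the folded and unfolded means agree to the
    sampling tolerance), ``qtl_fav_freq_means`` the mean favorable-allele
    frequencies for QTL.  Per-locus frequencies are drawn from
    Beta(mu*nu, (1-mu)*nu) so ``beta_concentration`` (nu) controls spread.
    """

    snp_freq_means: tuple[float, float]
    qtl_fav_freq_means: tuple[float, float]
    beta_concentration: float = 10.0
    n_founders_per_sex: int = 400

    def __post_init__(self):
        for m in (*self.snp_freq_means, *self.qtl_fav_freq_means):
            if not 0.0 < m < 1.0:
                raise ValueError("frequency means must be in (0, 1)")
        if self.beta_concentration <= 0:
            raise ValueError("beta concentration must be positive")


def low_ld_spec(n_founders_per_sex: int = 400, concentration: float = 10.0) -> FounderSpec:
    """Parental populations with equal means: SNP MAF 0.3/0.3, favorable QTL
    allele 0.6/0.6.  Expected gametic LD is zero at every pair."""
    return FounderSpec((0.3, 0.3), (0.6, 0.6), concentration, n_founders_per_sex)


def high_ld_spec(n_founders_per_sex: int = 400, concentration: float = 10.0) -> FounderSpec:
    """Contrasting parental means: SNP frequencies 0.1/0.5, favorable QTL
    allele 0.3/0.9.  All frequency differences share a sign, so pairwise LD in
    generation 0 is predominantly positive."""
    return FounderSpec((0.1, 0.5), (0.3, 0.9), concentration, n_founders_per_sex)


@dataclass
class LocusFrequencies:
    """Per-locus allele-1 frequency in parental populations 1 and 2, aligned
    with the global locus table of a :class:`GenomeMap`."""

    p1: np.ndarray
    p2: np.ndarray

    def __post_init__(self):
        self.p1 = np.asarray(self.p1, float)
        self.p2 = np.asarray(self.p2, float)
        if self.p1.shape != self.p2.shape:
            raise ValueError("p1 and p2 must have the same shape")
        for p in (self.p1, self.p2):
            if np.any((p < 0) | (p > 1)):
                raise ValueError("frequencies must lie in [0, 1]")


def _beta_draw(rng, mean: float, nu: float, size: int) -> np.ndarray:
    return rng.beta(mean * nu, (1.0 - mean) * nu, size)


def sample_allele_frequencies(spec: FounderSpec, gmap: GenomeMap, seed=None) -> LocusFrequencies:
    """Draw per-locus allele-1 frequencies for both parental populations from
    the beta distribution with the founder specification's means."""
    rng = as_rng(seed)
    nu = spec.beta_concentration
    p1 = np.empty(gmap.n_loci)
    p2 = np.empty(gmap.n_loci)
    p1[gmap.snp_cols] = _beta_draw(rng, spec.snp_freq_means[0], nu, gmap.n_snps)
    p2[gmap.snp_cols] = _beta_draw(rng, spec.snp_freq_means[1], nu, gmap.n_snps)
    p1[gmap.qtl_cols] = _beta_draw(rng, spec.qtl_fav_freq_means[0], nu, gmap.n_qtl)
    p2[gmap.qtl_cols] = _beta_draw(rng, spec.qtl_fav_freq_means[1], nu, gmap.n_qtl)
    return LocusFrequencies(p1, p2)


def expected_founder_ld(theta, p_a1, p_a2, p_b1, p_b2):
    """Closed-form gametic LD produced by the two-population cross:
    (1 - 2*theta)/4 * (p_a1 - p_a2) * (p_b1 - p_b2)."""
    theta = np.asarray(theta, float)
    if np.any((theta < 0) | (theta > 0.5)):
        raise ValueError("recombination fraction must lie in [0, 0.5]")
    return (1.0 - 2.0 * theta) / 4.0 * (np.asarray(p_a1) - p_a2) * (np.asarray(p_b1) - p_b2)


# ---------------------------------------------------------------------------
# reference population
# ---------------------------------------------------------------------------

def make_reference_population(freqs: LocusFrequencies, gmap: GenomeMap,
                              n_per_sex: int, seed=None):
    """Build generation 0: cross two linkage-equilibrium parental populations,
    then randomly mate the F1 once.

    Every generation-0 allele receives a unique founder-origin label
    (2 * individual + haplotype), distinguishing identical-by-state copies, so
    identity by descent can be counted exactly in later generations.
    """
    from .population_engine import Population, _gametes

    if n_per_sex < 1:
        raise ValueError("n_per_sex must be at least 1")
    rng_f1, rng_cross = spawn(seed, 2)
    n = 2 * n_per_sex
    n_loci = gmap.n_loci

    # F1: one linkage-equilibrium gamete from each parental population
    f1_alleles = np.empty((n, 2, n_loci), dtype=np.uint8)
    f1_alleles[:, 0, :] = rng_f1.random((n, n_loci)) < freqs.p1
    f1_alleles[:, 1, :] = rng_f1.random((n, n_loci)) < freqs.p2
    f1 = Population(
        ids=np.arange(n, dtype=np.int64),
        sex=np.zeros(n, dtype=np.int8),
        sire=np.full(n, -1, dtype=np.int64),
        dam=np.full(n, -1, dtype=np.int64),
        alleles=f1_alleles,
        origins=np.zeros((n, 2, n_loci), dtype=np.uint16),
        generation=-1,
    )

    # one round of random crosses among distinct F1 individuals
    mothers = rng_cross.integers(0, n, n)
    fathers = (mothers + rng_cross.integers(1, n, n)) % n
    hap0, _ = _gametes(f1, mothers, gmap, rng_cross)
    hap1, _ = _gametes(f1, fathers, gmap, rng_cross)
    alleles = np.stack([hap0, hap1], axis=1)

    origins = np.empty((n, 2, n_loci), dtype=np.uint16)
    labels = (2 * np.arange(n, dtype=np.uint16))[:, None]
    origins[:, 0, :] = labels
    origins[:, 1, :] = labels + 1

    sex = np.zeros(n, dtype=np.int8)
    sex[n_per_sex:] = 1  # 0 = female, 1 = male
    return Population(
        ids=np.arange(n, dtype=np.int64),
        sex=sex,
        sire=np.full(n, -1, dtype=np.int64),
        dam=np.full(n, -1, dtype=np.int64),
        alleles=alleles,
        origins=origins,
        generation=0,
    )


# ---------------------------------------------------------------------------
# genotype export
# ---------------------------------------------------------------------------

def export_tped(pop, gmap: GenomeMap, prefix, snps_only: bool = True) -> None:
    """PLINK-compatible transposed text export (<prefix>.tped/<prefix>.tfam)
    with the cM position in the position column.  Alleles are coded 1/2."""
    cols = gmap.snp_cols if snps_only else np.arange(gmap.n_loci)
    a = pop.alleles[:, :, cols] + 1  # 1/2 coding
    with open(f"{prefix}.tped", "w") as fh:
        for k, col in enumerate(cols):
            name = ("qtl" if gmap.is_qtl[col] else "snp") + f"{gmap.chrom[col] + 1}_{col}"
            geno = " ".join(f"{a[i, 0, k]} {a[i, 1, k]}" for i in range(pop.n))
            fh.write(f"{gmap.chrom[col] + 1} {name} {gmap.pos[col]:.6f} "
                     f"{gmap.pos[col]:.6f} {geno}\n")
    with open(f"{prefix}.tfam", "w") as fh:
        for i in range(pop.n):
            sex = 2 if pop.sex[i] == 0 else 1  # PLINK: 1=male, 2=female
            fh.write(f"FAM {pop.ids[i]} {max(pop.sire[i], 0)} "
                     f"{max(pop.dam[i], 0)} {sex} -9\n")


def save_population_h5(pop, path) -> None:
    """HDF5 container with allele states and founder-origin labels."""
    import h5py

    with h5py.File(path, "w") as fh:
        for name in ("ids", "sex", "sire", "dam", "alleles", "origins"):
            fh.create_dataset(name, data=getattr(pop, name))
        fh.attrs["generation"] = pop.generation


def load_population_h5(path):
    """Inverse of :func:`save_population_h5`."""
    import h5py

    from .population_engine import Population

    with h5py.File(path, "r") as fh:
        kw = {name: fh[name][...]
              for name in ("ids", "sex", "sire", "dam", "alleles", "origins")}
        return Population(generation=int(fh.attrs["generation"]), **kw)
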