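"""Trait architecture: per-QTL additive/dominance effects, constrained
digenic-epistasis tables, the Kempthorne two-locus variance decomposition,
genotypic values and phenotypes at fixed broad-sense heritability.

Conventions
-----------
The simulated trait is feed conversion ratio (FCR): lower is better, and the
favorable allele at every QTL is the one that lowers it.  Genotypes are coded
by the dosage ``u`` of the unfavorable (FCR-raising) allele, so the
single-locus genotypic values are ``m + a`` (u = 2), ``m + d`` (u = 1) and
``m - a`` (u = 0) with ``a >= 0``.  Dominance is positive (toward the
unfavorable homozygote, ``d = degree * a`` with degree in [0, 1.2]), which
makes the favorable alleles recessive.

For a pair of interacting QTL the two-locus genotypic value is
``G_xy = m_i + m_j + alpha_x + alpha_y + I_xy`` and the nine epistatic effects
``I_xy`` are solved so that G is constant within each phenotypic class of the
chosen classical epistasis type (named by its F2 ratio: complementary 9:7,
duplicate 15:1, dominant 12:3:1, recessive 9:3:4, dominant-and-recessive 13:3,
duplicate-cumulative 9:6:1, plus a four-distinct-class interaction type).
The class containing the double homozygote (2,2) is pinned by a random I22
drawn from N(0, k * (sigma_A^2 + sigma_D^2 + 2*sigma_AD)) computed from the
pair's allele frequencies; every other class is anchored by zeroing the
epistatic effect of its lowest-coded member.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import yaml

from ._rng import as_rng, spawn

__all__ = [
    "EPISTASIS_TYPES",
    "GeneEffects",
    "EpistaticPair",
    "VarianceComponents",
    "TraitArchitecture",
    "derive_gene_effects",
    "assign_epistatic_pairs",
    "sample_I22",
    "pair_variance_terms",
    "solve_epistatic_effects",
    "kempthorne_decompose",
    "genotypic_value",
    "phenotype",
    "build_architecture",
]


# ---------------------------------------------------------------------------
# epistasis class partitions (u-codes: dosage of the dominant/unfavorable
# allele at each locus; "A_" means u >= 1)
# ---------------------------------------------------------------------------

def _cells(pred):
    return tuple(sorted((x, y) for x in (0, 1, 2) for y in (0, 1, 2) if pred(x, y)))


EPISTASIS_TYPES: dict[str, tuple[tuple[tuple[int, int], ...], ...]] = {
    # 9:7 — both dominant alleles needed
    "complementary": (
        _cells(lambda x, y: x >= 1 and y >= 1),
        _cells(lambda x, y: not (x >= 1 and y >= 1)),
    ),
    # 15:1 — either dominant allele suffices
    "duplicate": (
        _cells(lambda x, y: x >= 1 or y >= 1),
        _cells(lambda x, y: x == 0 and y == 0),
    ),
    # 12:3:1 — locus A dominant over locus B
    "dominant": (
        _cells(lambda x, y: x >= 1),
        _cells(lambda x, y: x == 0 and y >= 1),
        _cells(lambda x, y: x == 0 and y == 0),
    ),
    # 9:3:4 — aa masks locus B
    "recessive": (
        _cells(lambda x, y: x >= 1 and y >= 1),
        _cells(lambda x, y: x >= 1 and y == 0),
        _cells(lambda x, y: x == 0),
    ),
    # 13:3
    "dominant_and_recessive": (
        _cells(lambda x, y: (x >= 1 and y >= 1) or x == 0),
        _cells(lambda x, y: x >= 1 and y == 0),
    ),
    # 9:6:1 — duplicate genes with cumulative effects
    "duplicate_cumulative": (
        _cells(lambda x, y: x >= 1 and y >= 1),
        _cells(lambda x, y: (x >= 1) != (y >= 1)),
        _cells(lambda x, y: x == 0 and y == 0),
    ),
    # four distinct phenotypic classes (A_B_ / A_bb / aaB_ / aabb)
    "non_epistatic_interaction": (
        _cells(lambda x, y: x >= 1 and y >= 1),
        _cells(lambda x, y: x >= 1 and y == 0),
        _cells(lambda x, y: x == 0 and y >= 1),
        _cells(lambda x, y: x == 0 and y == 0),
    ),
}

ALL_RANDOM = "all_random"


# ---------------------------------------------------------------------------
# gene effects
# ---------------------------------------------------------------------------

@dataclass
class GeneEffects:
    """Per-QTL midpoint m, half-range a (>= 0), dominance deviation d and
    degree of dominance d/a.  The favorable (FCR-lowering) allele is the one
    stored as allele 1 in the genotype arrays."""

    m: np.ndarray
    a: np.ndarray
    d: np.ndarray
    degree: np.ndarray

    def __post_init__(self):
        for name in ("m", "a", "d", "degree"):
            setattr(self, name, np.asarray(getattr(self, name), float))
        if np.any(self.a < 0):
            raise ValueError("half-range a must be non-negative")

    @property
    def n_qtl(self) -> int:
        return self.m.size

    def value_table(self) -> np.ndarray:
        """(n_qtl, 3) single-locus genotypic values indexed by the dosage u of
        the unfavorable allele."""
        return np.stack([self.m - self.a, self.m + self.d, self.m + self.a], axis=1)


def derive_gene_effects(g_min: float, g_max: float, n_qtl: int,
                        dominance_degrees=None, seed=None,
                        allocation: str = "equal",
                        geometric_ratio: float = 0.98) -> GeneEffects:
    """Compute per-QTL (m, a, d) from the homozygote genotypic bounds.

    The sums satisfy sum(m + a) = g_max and sum(m - a) = g_min exactly.
    Degrees of dominance default to Uniform(0, 1.2) (mean 0.6); d = degree*a.
    ``allocation`` is "equal" (a_i all equal) or "geometric" (a_i decaying by
    ``geometric_ratio``, rescaled to the exact sum).
    """
    if n_qtl < 1:
        raise ValueError("n_qtl must be at least 1")
    if g_max <= g_min:
        raise ValueError("g_max must exceed g_min")
    rng = as_rng(seed)
    sum_m = 0.5 * (g_max + g_min)
    sum_a = 0.5 * (g_max - g_min)
    if allocation == "equal":
        a = np.full(n_qtl, sum_a / n_qtl)
    elif allocation == "geometric":
        w = geometric_ratio ** np.arange(n_qtl)
        a = sum_a * w / w.sum()
    else:
        raise ValueError(f"unknown allocation '{allocation}'")
    m = np.full(n_qtl, sum_m / n_qtl)
    if dominance_degrees is None:
        degree = rng.uniform(0.0, 1.2, n_qtl)
    else:
        degree = np.asarray(dominance_degrees, float)
        if degree.size != n_qtl:
            raise ValueError("need one dominance degree per QTL")
    return GeneEffects(m=m, a=a, d=degree * a, degree=degree)


def assign_epistatic_pairs(qtl_ids, fraction_interacting: float,
                           type_policy: str = ALL_RANDOM,
                           seed=None) -> list[tuple[int, int, str]]:
    """Pair a fraction of the QTL into disjoint interacting pairs and assign
    each pair an epistasis type (a fixed type, or one drawn uniformly from the
    seven under the "all_random" policy)."""
    if not 0.0 <= fraction_interacting <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    if type_policy != ALL_RANDOM and type_policy not in EPISTASIS_TYPES:
        raise ValueError(f"unknown epistasis type '{type_policy}'")
    qtl_ids = np.asarray(qtl_ids)
    rng = as_rng(seed)
    n_inter = int(round(fraction_interacting * qtl_ids.size))
    if n_inter % 2:
        warnings.warn("odd number of interacting genes; dropping one",
                      RuntimeWarning, stacklevel=2)
        n_inter -= 1
    if n_inter == 0:
        return []
    chosen = rng.choice(qtl_ids.size, n_inter, replace=False)
    names = list(EPISTASIS_TYPES)
    pairs = []
    for k in range(0, n_inter, 2):
        t = (rng.choice(names) if type_policy == ALL_RANDOM else type_policy)
        i, j = sorted((int(qtl_ids[chosen[k]]), int(qtl_ids[chosen[k + 1]])))
        pairs.append((i, j, str(t)))
    return pairs


# ---------------------------------------------------------------------------
# epistatic effect tables
# ---------------------------------------------------------------------------

def locus_variances(a: float, d: float, p: float) -> tuple[float, float]:
    """Single-locus additive and dominance variances at HWE.

    ``p`` is the frequency of the unfavorable (u-coded) allele; the average
    effect of substitution is alpha = a + d*(q - p)."""
    q = 1.0 - p
    alpha = a + d * (q - p)
    return 2.0 * p * q * alpha ** 2, (2.0 * p * q * d) ** 2


def pair_variance_terms(effects: GeneEffects, i: int, j: int,
                        p_unfav: np.ndarray) -> tuple[float, float, float]:
    """(sigma_A^2, sigma_D^2, sigma_AD) summed over the two epistatic loci at
    the given unfavorable-allele frequencies.  Under HWE random mating the
    additive-dominance covariance is zero."""
    sa = sd = 0.0
    for q_idx in (i, j):
        va, vd = locus_variances(effects.a[q_idx], effects.d[q_idx], p_unfav[q_idx])
        sa += va
        sd += vd
    return sa, sd, 0.0


def sample_I22(k: float, sigma_a2: float, sigma_d2: float, sigma_ad: float,
               seed=None) -> float:
    """Draw the epistatic effect of the double homozygote:
    I22 ~ N(0, k * (sigma_A^2 + sigma_D^2 + 2*sigma_AD))."""
    if k <= 0:
        raise ValueError("k must be positive")
    var = k * (sigma_a2 + sigma_d2 + 2.0 * sigma_ad)
    if var < 0:
        warnings.warn("negative assembled I22 variance clamped to zero",
                      RuntimeWarning, stacklevel=2)
        var = 0.0
    return float(as_rng(seed).normal(0.0, np.sqrt(var)))


def _base_table(m1, a1, d1, m2, a2, d2) -> np.ndarray:
    """Non-epistatic two-locus values B[x, y] = m1 + m2 + alpha_x + alpha_y."""
    alpha1 = np.array([-a1, d1, a1])
    alpha2 = np.array([-a2, d2, a2])
    return m1 + m2 + alpha1[:, None] + alpha2[None, :]


def solve_epistatic_effects(m1, a1, d1, m2, a2, d2, type_name: str,
                            I22: float) -> np.ndarray:
    """Solve the 3x3 table of epistatic effects I[x, y] for a classical
    digenic epistasis type.

    Within each phenotypic class of the type the genotypic value is constant;
    the class containing (2, 2) takes the value m1+m2+a1+a2+I22 and every
    other class is anchored at the non-epistatic value of its lowest-coded
    member (whose epistatic effect is therefore exactly zero).
    """
    if type_name not in EPISTASIS_TYPES:
        raise ValueError(f"unknown epistasis type '{type_name}'")
    base = _base_table(m1, a1, d1, m2, a2, d2)
    I = np.zeros((3, 3))
    for cls in EPISTASIS_TYPES[type_name]:
        if (2, 2) in cls:
            value = base[2, 2] + I22
        else:
            ax, ay = cls[0]  # cells are sorted: first is the lowest code
            value = base[ax, ay]
        for (x, y) in cls:
            I[x, y] = value - base[x, y]
    return I


@dataclass
class EpistaticPair:
    """An interacting QTL pair with its solved 3x3 epistatic-effect table."""

    i: int
    j: int
    type_name: str
    I: np.ndarray
    k: float = 1.5
    I22: float = 0.0

    def genotypic_table(self, effects: GeneEffects) -> np.ndarray:
        return _base_table(effects.m[self.i], effects.a[self.i], effects.d[self.i],
                           effects.m[self.j], effects.a[self.j], effects.d[self.j]) + self.I


# ---------------------------------------------------------------------------
# Kempthorne decomposition
# ---------------------------------------------------------------------------

@dataclass
class VarianceComponents:
    """Orthogonal two-locus partition under HWE and linkage equilibrium.
    ``axd`` houses AxD + DxA."""

    additive: float
    dominance: float
    add_dom_cov: float
    axa: float
    axd: float
    dxd: float
    total: float


def _locus_basis(p: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """HWE weights and the orthogonal additive/dominance contrasts over
    genotype codes u = 0, 1, 2 (dosage of the allele with frequency p)."""
    q = 1.0 - p
    w = np.array([q * q, 2 * p * q, p * p])
    u = np.arange(3.0)
    fa = u - 2 * p
    fd = np.array([-2 * p * p, 2 * p * q, -2 * q * q])
    if p <= 0.0 or p >= 1.0:
        fa = np.zeros(3)
        fd = np.zeros(3)
    return w, fa, fd


def kempthorne_decompose(G_table: np.ndarray, p_i: float, p_j: float
                         ) -> tuple[VarianceComponents, dict[str, np.ndarray]]:
    """Partition a 3x3 table of two-locus genotypic values (indexed by the
    allele-dosage codes of each locus) into additive, dominance, AxA, AxD,
    DxA and DxD genetic values and variances, under HWE genotype frequencies
    at frequencies ``p_i``, ``p_j`` and linkage equilibrium.

    Returns the variance components and per-genotype effect tables.  At a
    fixed locus (p in {0, 1}) all terms involving that locus are zero.
    """
    G = np.asarray(G_table, float)
    if G.shape != (3, 3):
        raise ValueError("G_table must be 3x3")
    wi, fai, fdi = _locus_basis(p_i)
    wj, faj, fdj = _locus_basis(p_j)
    W = wi[:, None] * wj[None, :]

    def proj(f):
        """Weighted projection coefficient and squared norm of basis f."""
        nrm = float(np.sum(W * f * f))
        if nrm <= 0.0:
            return 0.0, 0.0
        return float(np.sum(W * G * f)) / nrm, nrm

    ones = np.ones((3, 3))
    bases = {
        "additive_i": fai[:, None] * ones,
        "additive_j": faj[None, :] * ones,
        "dominance_i": fdi[:, None] * ones,
        "dominance_j": fdj[None, :] * ones,
        "axa": fai[:, None] * faj[None, :],
        "axd": fai[:, None] * fdj[None, :],
        "dxa": fdi[:, None] * faj[None, :],
        "dxd": fdi[:, None] * fdj[None, :],
    }
    coeffs, norms, tables = {}, {}, {}
    for name, f in bases.items():
        c, nrm = proj(f)
        coeffs[name], norms[name] = c, nrm
        tables[name] = c * f
    tables["additive"] = tables.pop("additive_i") + tables.pop("additive_j")
    tables["dominance"] = tables.pop("dominance_i") + tables.pop("dominance_j")
    var = {k: float(np.sum(W * t * t)) for k, t in tables.items()}
    mu = float(np.sum(W * G))
    total = float(np.sum(W * (G - mu) ** 2))
    comps = VarianceComponents(
        additive=var["additive"],
        dominance=var["dominance"],
        add_dom_cov=0.0,
        axa=var["axa"],
        axd=var["axd"] + var["dxa"],
        dxd=var["dxd"],
        total=total,
    )
    tables["axd"] = tables["axd"] + tables.pop("dxa")
    tables["mean"] = np.full((3, 3), mu)
    return comps, tables


# ---------------------------------------------------------------------------
# architecture, genotypic values, phenotypes
# ---------------------------------------------------------------------------

@dataclass
class TraitArchitecture:
    """Everything needed to map QTL genotypes to genotypic values."""

    effects: GeneEffects
    pairs: list[EpistaticPair]
    g_min: float
    g_max: float
    y_min: float
    y_max: float
    h2: float

    def __post_init__(self):
        if not 0.0 < self.h2 < 1.0:
            raise ValueError("broad-sense heritability must lie in (0, 1)")
        smax = float(np.sum(self.effects.m + self.effects.a))
        smin = float(np.sum(self.effects.m - self.effects.a))
        if not (np.isclose(smax, self.g_max) and np.isclose(smin, self.g_min)):
            raise ValueError("effects do not reproduce the genotypic bounds")

    @property
    def n_qtl(self) -> int:
        return self.effects.n_qtl

    def to_yaml(self, path) -> None:
        data = {
            "g_min": self.g_min, "g_max": self.g_max,
            "y_min": self.y_min, "y_max": self.y_max, "h2": self.h2,
            "m": self.effects.m.tolist(), "a": self.effects.a.tolist(),
            "d": self.effects.d.tolist(), "degree": self.effects.degree.tolist(),
            "pairs": [
                {"i": p.i, "j": p.j, "type": p.type_name, "k": p.k,
                 "I22": p.I22, "I": p.I.tolist()}
                for p in self.pairs
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh)

    @classmethod
    def from_yaml(cls, path) -> "TraitArchitecture":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        eff = GeneEffects(m=np.array(data["m"]), a=np.array(data["a"]),
                          d=np.array(data["d"]), degree=np.array(data["degree"]))
        pairs = [EpistaticPair(p["i"], p["j"], p["type"], np.array(p["I"]),
                               p["k"], p["I22"]) for p in data["pairs"]]
        return cls(eff, pairs, data["g_min"], data["g_max"],
                   data["y_min"], data["y_max"], data["h2"])


def genotypic_value(fav_dosage: np.ndarray, arch: TraitArchitecture) -> np.ndarray:
    """True genotypic values from the (n, n_qtl) favorable-allele dosage
    matrix: single-locus values summed over all QTL plus the epistatic effect
    of each interacting pair."""
    U = (2 - np.asarray(fav_dosage, np.int64))  # unfavorable-allele dosage
    vt = arch.effects.value_table()  # (n_qtl, 3)
    g = vt[np.arange(arch.n_qtl)[None, :], U].sum(axis=1)
    for pair in arch.pairs:
        g = g + pair.I[U[:, pair.i], U[:, pair.j]]
    return g


def phenotype(g: np.ndarray, h2: float, y_min: float, y_max: float,
              seed=None, fallback_error_var: float | None = None
              ) -> tuple[np.ndarray, float]:
    """Phenotypes at fixed broad-sense heritability.

    The error variance is set from the realized genotypic variance of the
    cohort, sigma_e^2 = sigma_G^2 * (1 - H2) / H2, so H2 holds in every
    generation; values are truncated into [y_min, y_max] to avoid outliers.
    Returns (phenotypes, error variance used).  If the cohort's genotypic
    variance is zero the caller-provided fallback is used (with a warning).
    """
    if not 0.0 < h2 <= 1.0:
        raise ValueError("h2 must lie in (0, 1]")
    g = np.asarray(g, float)
    var_g = float(g.var())
    if var_g <= 0.0:
        if fallback_error_var is None:
            raise ValueError("zero genotypic variance and no fallback error variance")
        warnings.warn("zero genotypic variance; reusing last error variance",
                      RuntimeWarning, stacklevel=2)
        var_e = fallback_error_var
    else:
        var_e = var_g * (1.0 - h2) / h2
    y = g + as_rng(seed).normal(0.0, np.sqrt(var_e), g.size)
    clipped = np.count_nonzero((y < y_min) | (y > y_max))
    if clipped > 0.01 * g.size:
        warnings.warn(f"phenotype truncation affected {clipped / g.size:.1%} of records",
                      RuntimeWarning, stacklevel=2)
    return np.clip(y, y_min, y_max), var_e


def build_architecture(n_qtl: int, gen0_fav_freq: np.ndarray | None = None,
                       g_min: float = 1.1, g_max: float = 2.9,
                       y_min: float = 1.0, y_max: float = 3.5,
                       h2: float = 0.30,
                       epistasis_fraction: float = 0.0,
                       epistasis_type: str = ALL_RANDOM,
                       k: float = 1.5, seed=None,
                       allocation: str = "equal",
                       pairs: list[tuple[int, int, str]] | None = None
                       ) -> TraitArchitecture:
    """Assemble a full trait architecture.

    Epistatic-effect tables are solved once, at the generation-0 favorable
    allele frequencies supplied (the I tables are properties of genotypes and
    stay fixed thereafter).  Passing ``pairs`` reuses a pairing across
    scenarios that differ only in the epistasis type.
    """
    rng_eff, rng_pairs, rng_i22 = spawn(seed, 3)
    effects = derive_gene_effects(g_min, g_max, n_qtl, seed=rng_eff,
                                  allocation=allocation)
    pair_objs: list[EpistaticPair] = []
    if epistasis_fraction > 0.0 or pairs is not None:
        if pairs is None:
            pairs = assign_epistatic_pairs(np.arange(n_qtl), epistasis_fraction,
                                           epistasis_type, seed=rng_pairs)
        if gen0_fav_freq is None:
            raise ValueError("epistasis requires generation-0 QTL frequencies")
        p_unfav = 1.0 - np.asarray(gen0_fav_freq, float)
        for (i, j, tname) in pairs:
            sa, sd, sad = pair_variance_terms(effects, i, j, p_unfav)
            i22 = sample_I22(k, sa, sd, sad, seed=rng_i22)
            I = solve_epistatic_effects(
                effects.m[i], effects.a[i], effects.d[i],
                effects.m[j], effects.a[j], effects.d[j], tname, i22)
            pair_objs.append(EpistaticPair(i, j, tname, I, k, i22))
    return TraitArchitecture(effects, pair_objs, g_min, g_max, y_min, y_max, h2)
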