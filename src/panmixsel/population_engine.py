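"""Meiosis with founder-allele tracking, mating, pedigree bookkeeping and the
three flavours of inbreeding accounting that depend on it.

Recombination uses the Haldane map function (no interference): the crossover
count on a chromosome of length L cM is Poisson(L/100) and crossover positions
are uniform.  Allele states and founder-origin labels travel together through
meiosis, so identity by descent relative to generation 0 can be read off the
labels at any later generation.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np

from ._rng import as_rng

if TYPE_CHECKING:  # pragma: no cover
    from .genome_sim import GenomeMap

__all__ = [
    "Population",
    "Pedigree",
    "MatingPlan",
    "meiosis",
    "make_generation",
    "allocate_mates",
    "pedigree_inbreeding",
    "realized_inbreeding",
]


@dataclass
class Population:
    """A cohort of individuals from one (non-overlapping) generation.

    ``alleles`` has shape (n, 2, n_loci) with 0/1 allele states;
    ``origins`` carries the founder-origin label of every allele copy.
    Sex is coded 0 = female, 1 = male.  ``sire``/``dam`` are -1 for
    generation-0 individuals.
    """

    ids: np.ndarray
    sex: np.ndarray
    sire: np.ndarray
    dam: np.ndarray
    alleles: np.ndarray
    origins: np.ndarray
    generation: int

    @property
    def n(self) -> int:
        return self.ids.size

    def dosage(self, cols=None) -> np.ndarray:
        """Allele-1 dosage matrix (n, n_loci) or a column subset of it."""
        d = self.alleles.sum(axis=1, dtype=np.int8)
        return d if cols is None else d[:, cols]

    def females(self) -> np.ndarray:
        return self.ids[self.sex == 0]

    def males(self) -> np.ndarray:
        return self.ids[self.sex == 1]

    def index_of(self, ids) -> np.ndarray:
        order = np.argsort(self.ids)
        pos = np.searchsorted(self.ids, ids, sorter=order)
        idx = order[np.clip(pos, 0, self.n - 1)]
        if not np.array_equal(self.ids[idx], np.asarray(ids)):
            raise KeyError("some ids are not in this population")
        return idx


@dataclass
class Pedigree:
    """Flat pedigree records: id, sire, dam, generation, sex (parents -1 for
    founders).  Generations are non-overlapping: every parent belongs to the
    generation immediately before its offspring."""

    ids: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    sire: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    dam: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    generation: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    sex: np.ndarray = field(default_factory=lambda: np.empty(0, np.int8))

    @classmethod
    def from_population(cls, pop: Population) -> "Pedigree":
        ped = cls()
        ped.append(pop.ids, pop.sire, pop.dam, pop.generation, pop.sex)
        return ped

    def append(self, ids, sire, dam, generation, sex) -> None:
        n = np.asarray(ids).size
        gen = np.full(n, generation) if np.isscalar(generation) else np.asarray(generation)
        self.ids = np.concatenate([self.ids, np.asarray(ids, np.int64)])
        self.sire = np.concatenate([self.sire, np.asarray(sire, np.int64)])
        self.dam = np.concatenate([self.dam, np.asarray(dam, np.int64)])
        self.generation = np.concatenate([self.generation, gen.astype(np.int64)])
        self.sex = np.concatenate([self.sex, np.asarray(sex, np.int8)])

    @property
    def n(self) -> int:
        return self.ids.size

    def parents_of(self, ids) -> tuple[np.ndarray, np.ndarray]:
        idx = self._index_of(ids)
        return self.sire[idx], self.dam[idx]

    def _index_of(self, ids) -> np.ndarray:
        order = np.argsort(self.ids)
        pos = np.searchsorted(self.ids, ids, sorter=order)
        idx = order[np.clip(pos, 0, self.n - 1)]
        if not np.array_equal(self.ids[idx], np.asarray(ids)):
            raise KeyError("unknown ids in pedigree lookup")
        return idx

    def export_csv(self, path) -> None:
        """4-column CSV (id, sire, dam, generation) for standard tooling."""
        import pandas as pd

        pd.DataFrame({
            "id": self.ids, "sire": self.sire,
            "dam": self.dam, "generation": self.generation,
        }).to_csv(path, index=False)


@dataclass
class MatingPlan:
    """One row per mating: sire id, dam id, number of offspring."""

    sire_ids: np.ndarray
    dam_ids: np.ndarray
    n_offspring: int

    def __post_init__(self):
        self.sire_ids = np.asarray(self.sire_ids, np.int64)
        self.dam_ids = np.asarray(self.dam_ids, np.int64)
        if self.sire_ids.shape != self.dam_ids.shape:
            raise ValueError("sire and dam arrays must align")

    @property
    def n_matings(self) -> int:
        return self.dam_ids.size


# ---------------------------------------------------------------------------
# meiosis
# ---------------------------------------------------------------------------

def _gametes(pop: Population, parent_idx: np.ndarray, gmap: "GenomeMap",
             rng) -> tuple[np.ndarray, np.ndarray]:
    """Produce one gamete per entry of ``parent_idx`` (positions into pop).

    Returns (alleles, origins), each (n_gametes, n_loci).  Vectorised over
    gametes; loops only over chromosomes.
    """
    n_g = parent_idx.size
    out_a = np.empty((n_g, gmap.n_loci), dtype=pop.alleles.dtype)
    out_o = np.empty((n_g, gmap.n_loci), dtype=pop.origins.dtype)
    for c in range(gmap.n_chromosomes):
        sl = gmap.chrom_slices[c]
        loci = gmap.pos[sl]
        length = gmap.lengths[c]
        n_xo = rng.poisson(length / 100.0, n_g)
        start = rng.integers(0, 2, n_g)
        kmax = int(n_xo.max()) if n_g else 0
        if kmax == 0 or loci.size == 0:
            hap = np.broadcast_to(start[:, None], (n_g, loci.size))
        else:
            xo = rng.uniform(0.0, length, (n_g, kmax))
            xo[np.arange(kmax)[None, :] >= n_xo[:, None]] = np.inf
            xo.sort(axis=1)
            # crossovers before each locus flip the source haplotype
            n_before = (xo[:, :, None] <= loci[None, None, :]).sum(axis=1)
            hap = (start[:, None] + n_before) % 2
        hap3 = hap[:, None, :]
        src_a = pop.alleles[parent_idx][:, :, sl]
        src_o = pop.origins[parent_idx][:, :, sl]
        out_a[:, sl] = np.take_along_axis(src_a, hap3, axis=1)[:, 0, :]
        out_o[:, sl] = np.take_along_axis(src_o, hap3, axis=1)[:, 0, :]
    return out_a, out_o


def meiosis(pop: Population, parent_id: int, gmap: "GenomeMap", seed=None):
    """Single gamete from one parent; returns (alleles, origins) vectors."""
    rng = as_rng(seed)
    idx = pop.index_of(np.asarray([parent_id]))
    a, o = _gametes(pop, idx, gmap, rng)
    return a[0], o[0]


# ---------------------------------------------------------------------------
# generation advance
# ---------------------------------------------------------------------------

def make_generation(pop: Population, plan: MatingPlan, gmap: "GenomeMap",
                    seed=None, id_start: int | None = None) -> Population:
    """Create ``plan.n_offspring`` offspring per mating.

    Sexes are Bernoulli(1/2); ids are sequential from ``id_start`` (default:
    max parent id + 1).
    """
    rng = as_rng(seed)
    if plan.n_matings == 0:
        n_loci = gmap.n_loci
        e = np.empty((0, 2, n_loci))
        return Population(np.empty(0, np.int64), np.empty(0, np.int8),
                          np.empty(0, np.int64), np.empty(0, np.int64),
                          e.astype(np.uint8), e.astype(np.uint16),
                          pop.generation + 1)
    sire_idx = pop.index_of(plan.sire_ids)
    dam_idx = pop.index_of(plan.dam_ids)
    k = plan.n_offspring
    sire_rep = np.repeat(sire_idx, k)
    dam_rep = np.repeat(dam_idx, k)
    pa, po = _gametes(pop, sire_rep, gmap, rng)
    ma, mo = _gametes(pop, dam_rep, gmap, rng)
    n_off = sire_rep.size
    alleles = np.stack([ma, pa], axis=1)
    origins = np.stack([mo, po], axis=1)
    if id_start is None:
        id_start = int(pop.ids.max()) + 1
    return Population(
        ids=np.arange(id_start, id_start + n_off, dtype=np.int64),
        sex=rng.integers(0, 2, n_off).astype(np.int8),
        sire=np.repeat(plan.sire_ids, k),
        dam=np.repeat(plan.dam_ids, k),
        alleles=alleles,
        origins=origins,
        generation=pop.generation + 1,
    )


# ---------------------------------------------------------------------------
# mate allocation with sib avoidance
# ---------------------------------------------------------------------------

def _share_parent(s_sire, s_dam, d_sire, d_dam, rule: str) -> np.ndarray:
    known = (s_sire >= 0) & (d_sire >= 0)
    if rule == "full-sib":
        bad = (s_sire == d_sire) & (s_dam == d_dam)
    else:  # "sib": forbid sharing either parent (full or half sibs)
        bad = (s_sire == d_sire) | (s_dam == d_dam)
    return bad & known


def allocate_mates(sire_ids, dam_ids, ped: Pedigree, dams_per_sire: int = 5,
                   avoidance: str = "sib", seed=None, max_retries: int = 200,
                   n_offspring: int = 10) -> MatingPlan:
    """Randomly allocate ``dams_per_sire`` dams to each sire, avoiding sib
    matings.

    ``avoidance``: "sib" forbids both full- and half-sib pairs, "full-sib"
    only full sibs, "none" disables the check.  If no valid allocation is
    found after ``max_retries`` reshuffles the rule is relaxed one level with
    a warning.
    """
    sire_ids = np.asarray(sire_ids, np.int64)
    dam_ids = np.asarray(dam_ids, np.int64)
    if dam_ids.size != dams_per_sire * sire_ids.size:
        raise ValueError("need dams_per_sire dams per sire")
    rng = as_rng(seed)
    s_sire, s_dam = ped.parents_of(sire_ids)
    d_sire, d_dam = ped.parents_of(dam_ids)
    sire_col = np.repeat(sire_ids, dams_per_sire)

    rules = {"sib": ["sib", "full-sib", "none"],
             "full-sib": ["full-sib", "none"],
             "none": ["none"]}[avoidance]
    for level, rule in enumerate(rules):
        if rule == "none":
            perm = rng.permutation(dam_ids.size)
            return MatingPlan(sire_col, dam_ids[perm], n_offspring)
        ss = np.repeat(s_sire, dams_per_sire)
        sd = np.repeat(s_dam, dams_per_sire)
        for _ in range(max_retries):
            perm = rng.permutation(dam_ids.size)
            bad = _share_parent(ss, sd, d_sire[perm], d_dam[perm], rule)
            if not bad.any():
                return MatingPlan(sire_col, dam_ids[perm], n_offspring)
            # targeted repair: swap offending dams with random others
            for _ in range(20):
                bad_pos = np.flatnonzero(bad)
                if bad_pos.size == 0:
                    break
                swap_with = rng.integers(0, dam_ids.size, bad_pos.size)
                for i, j in zip(bad_pos, swap_with):
                    if _share_parent(ss[i], sd[i], d_sire[perm[j]], d_dam[perm[j]], rule) \
                            or _share_parent(ss[j], sd[j], d_sire[perm[i]], d_dam[perm[i]], rule):
                        continue
                    perm[i], perm[j] = perm[j], perm[i]
                bad = _share_parent(ss, sd, d_sire[perm], d_dam[perm], rule)
            if not bad.any():
                return MatingPlan(sire_col, dam_ids[perm], n_offspring)
        if level + 1 < len(rules):
            warnings.warn(
                f"no {rule}-free allocation found after {max_retries} tries; "
                f"relaxing the avoidance rule to '{rules[level + 1]}'",
                RuntimeWarning, stacklevel=2)
    raise RuntimeError("unreachable")  # pragma: no cover


# ---------------------------------------------------------------------------
# inbreeding
# ---------------------------------------------------------------------------

def pedigree_inbreeding(ped: Pedigree) -> np.ndarray:
    """Inbreeding coefficient of every pedigree member (aligned with ped.ids).

    Generation-layered kinship recursion: the kinship matrix is carried only
    over individuals that actually appear as parents, so the cost is bounded
    by the selected-parent counts rather than by cohort sizes.  Equivalent to
    the numerator-relationship (Meuwissen-Luo) result for non-overlapping
    generations.
    """
    F = np.zeros(ped.n)
    gens = np.unique(ped.generation)
    prev_ids = None  # parent set of the previous layer
    prev_K = None
    for gi, g in enumerate(gens):
        members = np.flatnonzero(ped.generation == g)
        sires, dams = ped.sire[members], ped.dam[members]
        founders = sires < 0
        if founders.all():
            parents = np.empty(0, np.int64)
        elif founders.any():
            raise ValueError("mixed founder/non-founder generation")
        else:
            parents = np.unique(np.concatenate([sires, dams]))
        if parents.size:
            if prev_ids is None:
                raise ValueError("parents referenced before any founder layer")
            lookup = {int(i): k for k, i in enumerate(prev_ids)}
            try:
                si = np.array([lookup[int(i)] for i in sires])
                di = np.array([lookup[int(i)] for i in dams])
            except KeyError as err:
                raise ValueError("parent not in previous generation") from err
            F[members] = prev_K[si, di]
        # kinship among this layer's future parents (all members, restricted
        # lazily: keep only individuals that are parents of the next layer)
        if gi + 1 < len(gens):
            nxt = np.flatnonzero(ped.generation == gens[gi + 1])
            used = np.unique(np.concatenate([ped.sire[nxt], ped.dam[nxt]]))
            used = used[used >= 0]
            uidx = ped._index_of(used)
            if not np.all(ped.generation[uidx] == g):
                raise ValueError("overlapping generations are not supported")
            if parents.size == 0:  # this layer is founders
                K = np.eye(used.size) * 0.5
            else:
                lookup = {int(i): k for k, i in enumerate(prev_ids)}
                us = np.array([lookup[int(s)] for s in ped.sire[uidx]])
                ud = np.array([lookup[int(d)] for d in ped.dam[uidx]])
                K = 0.25 * (prev_K[np.ix_(us, us)] + prev_K[np.ix_(us, ud)]
                            + prev_K[np.ix_(ud, us)] + prev_K[np.ix_(ud, ud)])
                K[np.diag_indices_from(K)] = 0.5 * (1.0 + prev_K[us, ud])
            prev_ids, prev_K = used, K
    return F


def realized_inbreeding(pop: Population, cols=None) -> np.ndarray:
    """Realized F: per individual, the fraction of loci at which the two
    carried alleles descend from the same generation-0 allele copy
    (founder-origin labels equal).  ``cols`` restricts the count to a locus
    subset (typically the SNP columns)."""
    o = pop.origins if cols is None else pop.origins[:, :, cols]
    return (o[:, 0, :] == o[:, 1, :]).mean(axis=1)
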