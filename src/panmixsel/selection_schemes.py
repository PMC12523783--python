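"""The eight recurrent-selection schemes and the cycle loop.

Schemes (names follow the study design they implement):

========  ==========================  ==============================
name      selection criterion         training / phenotyping policy
========  ==========================  ==============================
GS        GBLUP additive value        founders + 20%% of each generation
GS1       GBLUP additive value        founders only (no model updating)
GS2       GBLUP additive value        founders + 10%% of each generation
GS3       GBLUP additive value        as GS, half the parents, double progeny
GV        true genotypic value        none
pbB       pedigree BLUP               every individual phenotyped
pbB1      pedigree BLUP               founders + 20%% of each generation
NS        random (no selection)       none
========  ==========================  ==============================

Every cycle: phenotype the new cohort, extend the training set per policy,
fit the evaluation model, predict all candidates through the joint MME,
truncation-select the best (lowest FCR) females and males within sex,
allocate five dams per sire avoiding sib matings, and advance one generation.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._rng import as_rng, spawn
from .evaluation import (epistatic_kernels, genomic_F_from_dosage, pedigree_A,
                         reml_fit, su_D_from_gram, vanraden_G_from_gram)
from .metrics import (GenerationRecord, allele_frequency_summary,
                      count_selected_progenies, prediction_accuracy)
from .population_engine import (Pedigree, Population, allocate_mates,
                                make_generation, pedigree_inbreeding,
                                realized_inbreeding)
from .trait_model import TraitArchitecture, genotypic_value, phenotype

__all__ = [
    "SCHEME_NAMES",
    "SchemeConfig",
    "SchemeResult",
    "scheme_config",
    "build_training_set",
    "select_parents",
    "run_scheme",
    "run_pedigree_only",
]

SCHEME_NAMES = ("GS", "GS1", "GS2", "GS3", "GV", "pbB", "pbB1", "NS")


@dataclass(frozen=True)
class SchemeConfig:
    """Parameters of one scheme run (counts refer to one selection cycle)."""

    name: str
    criterion: str              # "gblup" | "pblup" | "true" | "random"
    training_policy: str        # "cumulative" | "founders" | "all" | "none"
    training_fraction: float
    n_dams: int
    n_sires: int
    progeny_size: int
    dams_per_sire: int = 5
    n_cycles: int = 7
    model: str = "additive_dominance"   # or "additive_dominance_epistasis"
    sib_avoidance: str = "sib"          # bar full and half sibs; "full-sib" relaxes
    reml_max_n: int = 1500              # REML variance components estimated on a
    #                                     random training subset of this size;
    #                                     BLUP always uses the full data

    def __post_init__(self):
        if self.n_dams != self.dams_per_sire * self.n_sires:
            raise ValueError("n_dams must equal dams_per_sire * n_sires")
        if not 0.0 <= self.training_fraction <= 1.0:
            raise ValueError("training fraction must lie in [0, 1]")


def scheme_config(name: str, n_dams: int = 400, n_sires: int = 80,
                  progeny_size: int = 10, training_fraction: float = 0.20,
                  n_cycles: int = 7, dams_per_sire: int = 5,
                  model: str = "additive_dominance") -> SchemeConfig:
    """Build the standard configuration of one of the eight schemes, scaled
    from the reference parent counts (GS3 halves the parents and doubles the
    progeny size; GS2 halves the training fraction)."""
    if name not in SCHEME_NAMES:
        raise ValueError(f"unknown scheme '{name}'")
    kw = dict(name=name, n_dams=n_dams, n_sires=n_sires,
              progeny_size=progeny_size, dams_per_sire=dams_per_sire,
              n_cycles=n_cycles, model=model,
              training_fraction=training_fraction)
    if name == "GS":
        kw.update(criterion="gblup", training_policy="cumulative")
    elif name == "GS1":
        kw.update(criterion="gblup", training_policy="founders")
    elif name == "GS2":
        kw.update(criterion="gblup", training_policy="cumulative",
                  training_fraction=training_fraction / 2.0)
    elif name == "GS3":
        kw.update(criterion="gblup", training_policy="cumulative",
                  n_dams=n_dams // 2, n_sires=n_sires // 2,
                  progeny_size=progeny_size * 2)
    elif name == "GV":
        kw.update(criterion="true", training_policy="none", training_fraction=0.0)
    elif name == "pbB":
        kw.update(criterion="pblup", training_policy="all", training_fraction=1.0)
    elif name == "pbB1":
        kw.update(criterion="pblup", training_policy="cumulative")
    else:  # NS
        kw.update(criterion="random", training_policy="none", training_fraction=0.0)
    return SchemeConfig(**kw)


# ---------------------------------------------------------------------------
# training set
# ---------------------------------------------------------------------------

def build_training_set(policy: str, generations: dict[int, np.ndarray],
                       fraction: float, seed=None) -> np.ndarray:
    """Ids of the phenotyped training set.

    Founders (generation 0) are always included; under the "cumulative"
    policy a simple random sample of ``fraction`` of every later generation is
    appended, under "all" every individual, under "founders" none.
    """
    if fraction > 1.0:
        raise ValueError("training fraction cannot exceed 1")
    rng = as_rng(seed)
    out = [np.asarray(generations.get(0, []), np.int64)]
    if policy not in ("cumulative", "founders", "all"):
        raise ValueError(f"unknown training policy '{policy}'")
    for g in sorted(k for k in generations if k > 0):
        ids = np.asarray(generations[g], np.int64)
        if policy == "all":
            out.append(ids)
        elif policy == "cumulative" and fraction > 0:
            k = int(round(fraction * ids.size))
            out.append(np.sort(rng.choice(ids, k, replace=False)))
    return np.concatenate(out)


class _TrainingStore:
    """Phenotyped individuals accumulated across cycles.

    Keeps ids, phenotypes and SNP dosage rows, plus the running Gram matrices
    M M' (dosages) and B B' (heterozygosity indicators) over the training
    rows.  The genomic kernels are centered at the *current* reference
    frequencies every cycle, but centering is a rank-one correction of the
    frequency-independent Grams, so only the rows added since the last cycle
    cost a matrix product.
    """

    def __init__(self):
        self.ids = np.empty(0, np.int64)
        self.y = np.empty(0, float)
        self.M = None       # float64 dosage rows (n_t, m)
        self.B = None       # float64 het-indicator rows
        self.MM = None      # running Gram M M'
        self.BB = None      # running Gram B B'

    def add(self, ids, y, dosage):
        R = np.asarray(dosage, np.float64)
        Rb = (R == 1.0).astype(np.float64)
        self.ids = np.concatenate([self.ids, np.asarray(ids, np.int64)])
        self.y = np.concatenate([self.y, np.asarray(y, float)])
        if self.M is None:
            self.M, self.B = R, Rb
            self.MM, self.BB = R @ R.T, Rb @ Rb.T
            return
        cm, cb = R @ self.M.T, Rb @ self.B.T
        self.MM = np.block([[self.MM, cm.T], [cm, R @ R.T]])
        self.BB = np.block([[self.BB, cb.T], [cb, Rb @ Rb.T]])
        self.M = np.vstack([self.M, R])
        self.B = np.vstack([self.B, Rb])

    @property
    def n(self):
        return self.ids.size


# ---------------------------------------------------------------------------
# selection
# ---------------------------------------------------------------------------

def select_parents(ids, sex, criterion, n_females: int, n_males: int,
                   randomize: bool = False, seed=None
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Within-sex truncation selection minimizing the criterion (FCR scale:
    lower is better); ties broken by id.  With ``randomize`` the criterion is
    replaced by a random permutation (the no-selection scheme)."""
    ids = np.asarray(ids, np.int64)
    sex = np.asarray(sex)
    crit = np.asarray(criterion, float)
    if randomize:
        crit = as_rng(seed).permutation(ids.size).astype(float)
    elif crit.size != ids.size or np.any(~np.isfinite(crit)):
        raise ValueError("criterion must be finite and defined for all candidates")
    out = []
    for s, k in ((0, n_females), (1, n_males)):
        mask = sex == s
        if np.count_nonzero(mask) < k:
            raise ValueError(f"not enough candidates of sex {s}: "
                             f"{np.count_nonzero(mask)} < {k}")
        order = np.lexsort((ids[mask], crit[mask]))
        out.append(np.sort(ids[mask][order[:k]]))
    return out[0], out[1]


# ---------------------------------------------------------------------------
# the scheme loop
# ---------------------------------------------------------------------------

@dataclass
class SchemeResult:
    records: list[GenerationRecord]
    pedigree: Pedigree
    final_population: Population | None = None
    varcomp_by_generation: dict = field(default_factory=dict)


def _fit_and_predict(scheme, train, cand_ids, cand_dosage, ped, warm, rng=None):
    """Fit the evaluation model on the phenotyped set and predict additive
    values for training plus candidates through the joint system.

    When the training set exceeds ``scheme.reml_max_n`` the variance
    components are estimated on a random subset of it (they are population
    parameters, so a subset estimates them consistently); the BLUP step always
    uses every phenotyped record.
    """
    tr_ids, tr_y = train.ids, train.y
    all_ids = np.concatenate([tr_ids, cand_ids])
    uniq, first = np.unique(all_ids, return_index=True)
    phen_pos = np.searchsorted(uniq, tr_ids)
    cand_pos = np.searchsorted(uniq, cand_ids)

    if scheme.criterion == "gblup":
        Mc = np.asarray(cand_dosage, np.float64)
        Bc = (Mc == 1.0).astype(np.float64)
        sel = np.ix_(first, first)
        cm, cb = train.M @ Mc.T, train.B @ Bc.T
        MM = np.block([[train.MM, cm], [cm.T, Mc @ Mc.T]])[sel]
        BB = np.block([[train.BB, cb], [cb.T, Bc @ Bc.T]])[sel]
        M_uniq = np.vstack([train.M, Mc])[first]
        p = M_uniq.mean(axis=0) / 2.0
        c = 2.0 * p * (1.0 - p)
        G = vanraden_G_from_gram(MM, M_uniq @ p, p)
        D = su_D_from_gram(BB, (M_uniq == 1.0) @ c, p)
        kernels = {"additive": G, "dominance": D}
        if scheme.model == "additive_dominance_epistasis":
            aa, ad, dd = epistatic_kernels(G, D)
            kernels.update(axa=aa, axd=ad, dxd=dd)
    elif scheme.criterion == "pblup":
        A, ids_A = pedigree_A(ped, uniq)
        pos = np.searchsorted(ids_A, uniq, sorter=np.argsort(ids_A))
        pos = np.argsort(ids_A)[pos]
        kernels = {"additive": A[np.ix_(pos, pos)]}
    else:  # pragma: no cover
        raise ValueError(scheme.criterion)

    X = np.ones((tr_y.size, 1))
    components = None
    if scheme.reml_max_n and tr_y.size > scheme.reml_max_n:
        sub = as_rng(rng).choice(tr_y.size, scheme.reml_max_n, replace=False)
        sub.sort()
        sub_fit = reml_fit(tr_y[sub], X[sub], kernels, phen_pos[sub],
                           var_init=warm)
        components = sub_fit.varcomp
    fit = reml_fit(tr_y, X, kernels, phen_pos, var_init=warm,
                   var_components=components)
    if components is not None:
        fit.n_iter = sub_fit.n_iter
        fit.converged = sub_fit.converged
    return fit, fit.predictions["additive"][cand_pos]


def run_scheme(scheme: SchemeConfig, gmap, arch: TraitArchitecture,
               founders: Population, seed=None, shared_seed=None,
               replicate: int = 0, keep_final: bool = False) -> SchemeResult:
    """Run one scheme for ``scheme.n_cycles`` selection cycles.

    Generation 1 is produced by 1:1 random pairing of the founders; its
    randomness (and the founder phenotypes) can be pinned across schemes with
    ``shared_seed`` so that schemes are compared on identical material and
    differ only in selection decisions.
    """
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    rng_shared = spawn(shared_seed if shared_seed is not None else ss, 2)
    rng_gen1, rng_pheno0 = rng_shared
    cycle_rngs = spawn(ss, 4 * (scheme.n_cycles + 1))

    needs_model = scheme.criterion in ("gblup", "pblup")
    records: list[GenerationRecord] = []
    varcomps: dict[int, dict] = {}
    ped = Pedigree.from_population(founders)
    train = _TrainingStore()
    last_var_e = None

    def record(pop: Population) -> GenerationRecord:
        g = genotypic_value(pop.dosage(gmap.qtl_cols), arch)
        rec = GenerationRecord(
            scheme=scheme.name, replicate=replicate, generation=pop.generation,
            mean_fcr=float(g.mean()), genotypic_variance=float(g.var()),
            genomic_f=float(genomic_F_from_dosage(pop.dosage(gmap.snp_cols)).mean()),
            realized_f=float(realized_inbreeding(pop, gmap.snp_cols).mean()),
            **allele_frequency_summary(pop.dosage(gmap.qtl_cols)),
        )
        records.append(rec)
        return rec

    # generation 0: founders (phenotyped whenever a model will need them)
    record(founders)
    g0 = genotypic_value(founders.dosage(gmap.qtl_cols), arch)
    if needs_model:
        y0, last_var_e = phenotype(g0, arch.h2, arch.y_min, arch.y_max, rng_pheno0)
        train.add(founders.ids, y0, founders.dosage(gmap.snp_cols))

    # generation 1: same hierarchical mating design as every later cycle
    # (all n_dams founder females, a random draw of n_sires founder males)
    dams0, sires0 = select_parents(founders.ids, founders.sex,
                                   np.zeros(founders.n), scheme.n_dams,
                                   scheme.n_sires, randomize=True,
                                   seed=rng_gen1)
    plan = allocate_mates(sires0, dams0, ped, scheme.dams_per_sire,
                          scheme.sib_avoidance, seed=rng_gen1,
                          n_offspring=scheme.progeny_size)
    pop = make_generation(founders, plan, gmap, rng_gen1)
    ped.append(pop.ids, pop.sire, pop.dam, pop.generation, pop.sex)
    record(pop)

    for cycle in range(1, scheme.n_cycles + 1):
        rng_ph, rng_tr, rng_sel, rng_mate = cycle_rngs[4 * cycle:4 * cycle + 4]
        g_true = genotypic_value(pop.dosage(gmap.qtl_cols), arch)

        # phenotype the cohort and extend the training set
        if scheme.training_policy in ("cumulative", "all") and scheme.training_fraction > 0:
            y, last_var_e = phenotype(g_true, arch.h2, arch.y_min, arch.y_max,
                                      rng_ph, fallback_error_var=last_var_e)
            if scheme.training_policy == "all":
                chosen = np.arange(pop.n)
            else:
                k = int(round(scheme.training_fraction * pop.n))
                chosen = rng_tr.choice(pop.n, k, replace=False)
            train.add(pop.ids[chosen], y[chosen], pop.dosage(gmap.snp_cols)[chosen])

        # criterion
        accuracy = np.nan
        if needs_model:
            warm = varcomps.get(pop.generation - 1)  # previous cycle's REML solution
            fit, pred = _fit_and_predict(scheme, train, pop.ids,
                                         pop.dosage(gmap.snp_cols), ped, warm,
                                         rng=rng_sel)
            varcomps[pop.generation] = fit.varcomp
            criterion = pred
            accuracy = prediction_accuracy(pred, g_true)
        elif scheme.criterion == "true":
            criterion = g_true
        else:
            criterion = np.zeros(pop.n)

        dams, sires = select_parents(pop.ids, pop.sex, criterion,
                                     scheme.n_dams, scheme.n_sires,
                                     randomize=(scheme.criterion == "random"),
                                     seed=rng_sel)
        sel_idx = pop.index_of(np.concatenate([dams, sires]))
        rec = records[-1]
        rec.accuracy = float(accuracy)
        rec.n_selected_families = count_selected_progenies(
            pop.sire[sel_idx], pop.dam[sel_idx])

        plan = allocate_mates(sires, dams, ped, scheme.dams_per_sire,
                              scheme.sib_avoidance, seed=rng_mate,
                              n_offspring=scheme.progeny_size)
        pop = make_generation(pop, plan, gmap, rng_mate,
                              id_start=int(ped.ids.max()) + 1)
        ped.append(pop.ids, pop.sire, pop.dam, pop.generation, pop.sex)
        record(pop)

    # pedigree F, one layered pass over the whole pedigree
    F = pedigree_inbreeding(ped)
    mean_by_gen = {int(g): float(F[ped.generation == g].mean())
                   for g in np.unique(ped.generation)}
    for rec in records:
        rec.pedigree_f = mean_by_gen.get(rec.generation, np.nan)
    return SchemeResult(records, ped, pop if keep_final else None, varcomps)


# ---------------------------------------------------------------------------
# pedigree-only no-selection design
# ---------------------------------------------------------------------------

def run_pedigree_only(n_founders_per_sex: int = 400, n_dams: int = 400,
                      n_sires: int = 80, dams_per_sire: int = 5,
                      progeny_size: int = 10, n_cycles: int = 7,
                      seed=None) -> tuple[dict[int, float], Pedigree]:
    """Simulate the mating design without genotypes: random parent
    replacement with sib-mating avoidance, tracking only the pedigree.

    Returns (mean pedigree F per generation, pedigree).  This is the fast
    path for studying inbreeding accumulation under no selection at full
    population size.
    """
    rng = as_rng(seed)
    n0 = 2 * n_founders_per_sex
    ped = Pedigree()
    sex0 = np.zeros(n0, np.int8)
    sex0[n_founders_per_sex:] = 1
    ped.append(np.arange(n0), np.full(n0, -1), np.full(n0, -1), 0, sex0)

    ids = np.arange(n0)
    sex = sex0
    next_id = n0
    # generation 1: same hierarchical design as the cycles
    dams, sires = select_parents(ids, sex, np.zeros(n0), n_dams, n_sires,
                                 randomize=True, seed=rng)
    plan = allocate_mates(sires, dams, ped, dams_per_sire, "sib",
                          seed=rng, n_offspring=progeny_size)
    cur_sire = np.repeat(plan.sire_ids, progeny_size)
    cur_dam = np.repeat(plan.dam_ids, progeny_size)
    for cycle in range(n_cycles + 1):
        n_off = cur_sire.size
        ids = np.arange(next_id, next_id + n_off)
        next_id += n_off
        sex = rng.integers(0, 2, n_off).astype(np.int8)
        ped.append(ids, cur_sire, cur_dam, cycle + 1, sex)
        if cycle == n_cycles:
            break
        dams, sires = select_parents(ids, sex, np.zeros(n_off), n_dams,
                                     n_sires, randomize=True, seed=rng)
        plan = allocate_mates(sires, dams, ped, dams_per_sire, "sib",
                              seed=rng, n_offspring=progeny_size)
        cur_sire = np.repeat(plan.sire_ids, progeny_size)
        cur_dam = np.repeat(plan.dam_ids, progeny_size)
    F = pedigree_inbreeding(ped)
    means = {int(g): float(F[ped.generation == g].mean())
             for g in np.unique(ped.generation)}
    return means, ped
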