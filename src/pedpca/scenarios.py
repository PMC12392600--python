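"""Synthetic breeding-programme scenarios for validating pedigree PCA.

Two forward-in-time designs produce pedigrees with population/generation
metadata plus genotype dosages:

* ``2pop`` — two populations of 50 founders diverged by allele-frequency
  drift, each selected for one of two negatively correlated traits (top ten
  by phenotype, 50 offspring per generation, 20 generations), with a
  hybrid/crossbred population created at generation 10 and propagated in
  parallel.  2,650 individuals in total.
* ``4pop`` — one panmictic population of 200 propagated for 10 generations,
  then split into four isolated populations of 50 propagated for nine more,
  without selection.  4,000 individuals in total.

Founder genomes are drawn from population-specific allele frequencies
obtained by Wright-Fisher drift from shared ancestral frequencies, and
genotypes descend through the pedigree by gene dropping: each meiosis
transmits one recombinant haplotype per parent under a Haldane map with one
Morgan per chromosome.  This drift emulation reproduces the divergence and
family structure the designs call for, not any particular coalescent
genealogy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .operators import ImplicitOperator, TraceEstimate
from .pca import PCAResult
from .pedigree import Pedigree, PedigreeError

__all__ = [
    "ScenarioConfig",
    "ScenarioOutput",
    "simulate_founders",
    "gene_drop",
    "run_2pop",
    "run_4pop",
    "run_scenario",
    "random_pedigree",
    "layered_pedigree",
    "genotype_pca_reference",
    "realised_relationship",
]

MORGANS_PER_CHROM = 1.0


@dataclass
class ScenarioConfig:
    """Which scenario to run, its seed, and optional design overrides.

    With no overrides the designs produce their canonical sizes (2pop: 2,650
    individuals, 11,000 loci on 10 chromosomes; 4pop: 4,000 individuals).
    Overrides (e.g. ``{"size_per_pop": 10, "nloci": 500}``) scale the designs
    down while keeping their structure.
    """

    scenario: str = "2pop"
    seed: int = 0
    overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.scenario not in {"2pop", "4pop"}:
            raise ValueError(f"unknown scenario {self.scenario!r}")


@dataclass
class ScenarioOutput:
    """Simulated pedigree plus per-individual metadata and genomes."""

    ped: Pedigree                      # sorted, generations assigned
    dosages: np.ndarray                # n x nloci uint8 in {0, 1, 2}
    locus_map: pd.DataFrame            # columns chrom (1-based), pos (Morgans)
    base_freq: np.ndarray              # ancestral allele frequencies per locus
    trait_values: np.ndarray | None = None  # n x 2 true genetic values

    def write(self, prefix: str | Path) -> None:
        """Write pedigree (CSV), dosages (TSV) and locus map (TSV) to
        ``<prefix>.ped.csv`` / ``.dosages.tsv`` / ``.map.tsv``."""
        from .pedigree import write_pedigree

        prefix = str(prefix)
        write_pedigree(self.ped, prefix + ".ped.csv")
        pd.DataFrame(self.dosages, index=self.ped.labels).to_csv(
            prefix + ".dosages.tsv", sep="\t", header=False
        )
        self.locus_map.to_csv(prefix + ".map.tsv", sep="\t", index=False)


def default_map(nloci: int, nchrom: int) -> pd.DataFrame:
    """Evenly spaced loci, ``nloci // nchrom`` per chromosome of one Morgan."""
    per = nloci // nchrom
    if per * nchrom != nloci:
        raise ValueError("nloci must be divisible by nchrom")
    chrom = np.repeat(np.arange(1, nchrom + 1), per)
    pos = np.tile(np.linspace(0.0, MORGANS_PER_CHROM, per, endpoint=False), nchrom)
    return pd.DataFrame({"chrom": chrom, "pos": pos})


def simulate_founders(
    npop: int,
    size_per_pop: int,
    nloci: int = 11_000,
    divergence_generations: int = 100,
    seed: int = 0,
    nchrom: int = 10,
    drift_pop_size: int = 100,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, pd.DataFrame]:
    """Founder haplotypes for ``npop`` diverged populations.

    Ancestral allele frequencies are Uniform(0.05, 0.95); each population's
    frequencies then drift independently for ``divergence_generations``
    Wright-Fisher generations of ``drift_pop_size`` diploids.  Loci that end
    up fixed (0 or 1) in every population are redrawn so all returned loci
    segregate.  Haplotypes are Bernoulli draws from the population
    frequencies (founders in linkage equilibrium).

    Returns ``(haplotypes, pop_freq, base_freq, locus_map)`` with haplotypes
    of shape (npop * size_per_pop, 2, nloci).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xF0]))
    locus_map = default_map(nloci, nchrom)

    def drift(p0: np.ndarray) -> np.ndarray:
        p = np.repeat(p0[None, :], npop, axis=0)
        for _ in range(divergence_generations):
            p = rng.binomial(2 * drift_pop_size, p) / (2 * drift_pop_size)
        return p

    base = rng.uniform(0.05, 0.95, size=nloci)
    freq = drift(base)
    for _ in range(200):  # redraw loci fixed in all populations
        fixed = np.all((freq == 0.0) | (freq == 1.0), axis=0)
        if not fixed.any():
            break
        base[fixed] = rng.uniform(0.05, 0.95, size=int(fixed.sum()))
        freq[:, fixed] = drift(base[fixed])[:, :]
    haps = (
        rng.random((npop, size_per_pop, 2, nloci)) < freq[:, None, None, :]
    ).astype(np.uint8)
    return haps.reshape(npop * size_per_pop, 2, nloci), freq, base, locus_map


def _meiosis(parent_haps: np.ndarray, chrom_slices, pos_by_chrom, rng) -> np.ndarray:
    """One gamete from a (2, nloci) parent: per chromosome, a random starting
    haplotype and Poisson(length)-many crossovers at uniform positions
    (Haldane model, no interference)."""
    choice = np.empty(parent_haps.shape[1], dtype=np.int64)
    for sl, pos in zip(chrom_slices, pos_by_chrom):
        length = pos[-1] if len(pos) else 0.0
        start = rng.integers(0, 2)
        k = rng.poisson(length)
        if k == 0:
            choice[sl] = start
        else:
            bp = np.sort(rng.uniform(0.0, length, size=k))
            choice[sl] = (start + np.searchsorted(bp, pos)) % 2
    return parent_haps[choice, np.arange(parent_haps.shape[1])]


def _chrom_layout(locus_map: pd.DataFrame):
    chrom = locus_map["chrom"].to_numpy()
    pos = locus_map["pos"].to_numpy(dtype=float)
    slices, pos_by = [], []
    for c in np.unique(chrom):
        idx = np.nonzero(chrom == c)[0]
        slices.append(slice(idx[0], idx[-1] + 1))
        pos_by.append(pos[idx])
    return slices, pos_by


def gene_drop(
    ped: Pedigree,
    founder_haplotypes: np.ndarray,
    locus_map: pd.DataFrame,
    seed: int = 0,
    return_haplotypes: bool = False,
) -> np.ndarray:
    """Drop founder genomes through a sorted pedigree.

    ``founder_haplotypes`` has shape (n_founders, 2, nloci), ordered as the
    founders appear in the pedigree.  Each non-founder receives one
    recombinant gamete from each parent.  Returns the (n, nloci) dosage
    matrix (values 0/1/2).
    """
    ped.require_sorted("gene_drop")
    rng = np.random.default_rng(seed)
    sire, dam = ped.sire, ped.dam
    founder_rows = np.nonzero((sire == 0) & (dam == 0))[0]
    if founder_haplotypes.shape[0] != len(founder_rows):
        raise PedigreeError(
            f"pedigree has {len(founder_rows)} founders but "
            f"{founder_haplotypes.shape[0]} founder haplotype pairs were given"
        )
    nloci = founder_haplotypes.shape[2]
    slices, pos_by = _chrom_layout(locus_map)
    H = np.zeros((ped.n, 2, nloci), dtype=np.uint8)
    H[founder_rows] = founder_haplotypes
    for i in range(ped.n):
        s, d = sire[i], dam[i]
        if s == 0 and d == 0:
            continue
        if s == 0 or d == 0:
            raise PedigreeError(
                "gene_drop needs both parents known or both unknown "
                f"(individual {ped.labels[i]})"
            )
        H[i, 0] = _meiosis(H[s - 1], slices, pos_by, rng)
        H[i, 1] = _meiosis(H[d - 1], slices, pos_by, rng)
    dos = H.sum(axis=1, dtype=np.uint8)
    return (dos, H) if return_haplotypes else dos


# ---------------------------------------------------------------------------
# forward breeding simulations


class _Recorder:
    """Accumulates pedigree rows in parents-first order during a forward
    simulation, so the resulting Pedigree is sorted by construction."""

    def __init__(self, n_total: int, nloci: int, with_traits: bool):
        self.sire = np.zeros(n_total, dtype=np.int64)
        self.dam = np.zeros(n_total, dtype=np.int64)
        self.pop: list[str] = []
        self.gen = np.zeros(n_total, dtype=np.int64)
        self.H = np.zeros((n_total, 2, nloci), dtype=np.uint8)
        self.tgv = np.zeros((n_total, 2)) if with_traits else None
        self.next = 0

    def add_founders(self, haps: np.ndarray, pop: str) -> np.ndarray:
        k = haps.shape[0]
        rows = np.arange(self.next, self.next + k)
        self.H[rows] = haps
        self.gen[rows] = 1
        self.pop.extend([pop] * k)
        self.next += k
        return rows

    def add_offspring(self, sires, dams, gen, pop, layout, rng) -> np.ndarray:
        k = len(sires)
        rows = np.arange(self.next, self.next + k)
        slices, pos_by = layout
        for r, s, d in zip(rows, sires, dams):
            self.sire[r] = s + 1
            self.dam[r] = d + 1
            self.H[r, 0] = _meiosis(self.H[s], slices, pos_by, rng)
            self.H[r, 1] = _meiosis(self.H[d], slices, pos_by, rng)
        self.gen[rows] = gen
        self.pop.extend([pop] * k)
        self.next += k
        return rows

    def finish(self, label_prefix: str = "I") -> Pedigree:
        n = self.next
        assert n == len(self.sire)
        labels = np.asarray([f"{label_prefix}{i + 1}" for i in range(n)], dtype=object)
        sire_lab = np.asarray(
            [labels[s - 1] if s else None for s in self.sire], dtype=object
        )
        dam_lab = np.asarray(
            [labels[d - 1] if d else None for d in self.dam], dtype=object
        )
        meta = pd.DataFrame({"population": self.pop})
        ped = Pedigree(
            labels, sire_lab, dam_lab, generation=self.gen.copy(),
            metadata=meta, sorted=True, perm_to_input=np.arange(n),
        )
        ped._sire_idx = self.sire.copy()
        ped._dam_idx = self.dam.copy()
        return ped


def _draw_pairs(parents: np.ndarray, n_off: int, rng) -> tuple[np.ndarray, np.ndarray]:
    """Uniform sire/dam pairs from a parent pool, sire != dam per offspring."""
    if len(parents) < 2:
        raise PedigreeError("need at least two parents to produce offspring")
    s = rng.integers(0, len(parents), size=n_off)
    d = rng.integers(0, len(parents) - 1, size=n_off)
    d = np.where(d >= s, d + 1, d)  # skip the sire's slot
    return parents[s], parents[d]


def _top(rows: np.ndarray, score: np.ndarray, k: int) -> np.ndarray:
    if len(rows) < k:
        raise PedigreeError(
            f"selection of top {k} infeasible with only {len(rows)} candidates"
        )
    return rows[np.argsort(score[rows])[::-1][:k]]


def run_2pop(cfg: ScenarioConfig | None = None) -> ScenarioOutput:
    """Two-population selection scenario with a hybrid population.

    Defaults: 50 founders per population (diverged 100 generations), two
    traits with genetic variance 1.0, genetic correlation -0.3 and
    environmental variance 2.0 (100 causal loci per chromosome); 20
    generations of truncation selection on phenotype (top ten, trait 1 in
    population 1, trait 2 in population 2, 50 offspring each); a hybrid
    population of 50 founded at generation 10 from both lines and propagated
    alongside (parents per cohort: two from each pure line and six hybrids,
    ranked on an equal-weight phenotype index).  Total 2,650 individuals.
    """
    cfg = cfg or ScenarioConfig("2pop")
    o = cfg.overrides
    size = int(o.get("size_per_pop", 50))
    n_cycles = int(o.get("n_generations", 20))
    n_sel = int(o.get("n_select", 10))
    nloci = int(o.get("nloci", 11_000))
    nchrom = int(o.get("nchrom", 10))
    qtl_per_chrom = int(o.get("qtl_per_chrom", min(100, nloci // nchrom)))
    divergence = int(o.get("divergence_generations", 100))
    hybrid_at = int(o.get("hybrid_at", min(10, n_cycles)))
    var_e = float(o.get("env_variance", 2.0))
    ss = np.random.SeedSequence([cfg.seed, 0x2B0B])
    r_founder, r_qtl, r_mate, r_env = [np.random.default_rng(s) for s in ss.spawn(4)]

    haps, _, base, locus_map = simulate_founders(
        2, size, nloci=nloci, divergence_generations=divergence,
        seed=cfg.seed, nchrom=nchrom,
    )
    layout = _chrom_layout(locus_map)

    # additive bivariate trait architecture, rescaled to unit founder variance
    per = nloci // nchrom
    qtl = np.concatenate(
        [c * per + r_qtl.choice(per, size=qtl_per_chrom, replace=False)
         for c in range(nchrom)]
    )
    cov = np.array([[1.0, -0.3], [-0.3, 1.0]])
    eff = r_qtl.multivariate_normal(np.zeros(2), cov, size=len(qtl))
    founder_dos = haps.sum(axis=1)[:, qtl].astype(float)
    sd = (founder_dos @ eff).std(axis=0, ddof=1)
    eff /= sd  # founder genetic variance exactly 1 per trait

    n_hyb_cohorts = n_cycles - hybrid_at + 1
    n_total = 2 * size * (n_cycles + 1) + size * n_hyb_cohorts
    rec = _Recorder(n_total, nloci, with_traits=True)
    cur = {
        "1": rec.add_founders(haps[:size], "1"),
        "2": rec.add_founders(haps[size:], "2"),
    }

    def tgv_of(rows):
        rec.tgv[rows] = rec.H[rows].sum(axis=1)[:, qtl].astype(float) @ eff

    phen = np.zeros((n_total, 2))

    def phenotype(rows):
        tgv_of(rows)
        phen[rows] = rec.tgv[rows] + r_env.normal(0.0, np.sqrt(var_e), size=(len(rows), 2))

    phenotype(cur["1"])
    phenotype(cur["2"])
    index = phen.sum(axis=1)  # equal-weight selection index

    for g in range(1, n_cycles + 1):
        sel1 = _top(cur["1"], phen[:, 0], n_sel)
        sel2 = _top(cur["2"], phen[:, 1], n_sel)
        new = {}
        for pop, sel in (("1", sel1), ("2", sel2)):
            s, d = _draw_pairs(sel, size, r_mate)
            new[pop] = rec.add_offspring(s, d, g + 1, pop, layout, r_mate)
        if g == hybrid_at:
            # crossbred founding cohort: strict population-1 x population-2 crosses
            half = max(1, n_sel // 2)
            p1 = _top(cur["1"], index, half)
            p2 = _top(cur["2"], index, half)
            s = p1[r_mate.integers(0, len(p1), size=size)]
            d = p2[r_mate.integers(0, len(p2), size=size)]
            new["hybrid"] = rec.add_offspring(s, d, g + 1, "hybrid", layout, r_mate)
        elif g > hybrid_at:
            pool = np.concatenate([
                _top(cur["1"], index, 2),
                _top(cur["2"], index, 2),
                _top(cur["hybrid"], index, max(2, n_sel - 4)),
            ])
            s, d = _draw_pairs(pool, size, r_mate)
            new["hybrid"] = rec.add_offspring(s, d, g + 1, "hybrid", layout, r_mate)
        cur = new
        for rows in cur.values():
            phenotype(rows)
        index = phen.sum(axis=1)

    ped = rec.finish("S")
    dos = rec.H.sum(axis=1, dtype=np.uint8)
    return ScenarioOutput(ped, dos, locus_map, base, trait_values=rec.tgv.copy())


def run_4pop(cfg: ScenarioConfig | None = None) -> ScenarioOutput:
    """Four-population split scenario without selection.

    One panmictic population of 200 random-mates for 10 generations; its
    final generation is then split into four groups of 50 that found four
    isolated populations, each propagated for nine generations at constant
    size 50.  All 200 + 10*200 + 4*50*9 = 4,000 individuals are recorded.
    """
    cfg = cfg or ScenarioConfig("4pop")
    o = cfg.overrides
    anc_size = int(o.get("ancestral_size", 200))
    anc_gens = int(o.get("ancestral_generations", 10))
    npop = int(o.get("npop", 4))
    size = int(o.get("size_per_pop", 50))
    split_gens = int(o.get("split_generations", 9))
    nloci = int(o.get("nloci", 11_000))
    nchrom = int(o.get("nchrom", 10))
    if npop * size > anc_size:
        raise PedigreeError("cannot split the ancestral population into groups "
                            f"of {size}: {npop * size} > {anc_size}")
    ss = np.random.SeedSequence([cfg.seed, 0x4B0B])
    r_mate = np.random.default_rng(ss.spawn(1)[0])

    haps, _, base, locus_map = simulate_founders(
        1, anc_size, nloci=nloci, divergence_generations=0,
        seed=cfg.seed, nchrom=nchrom,
    )
    layout = _chrom_layout(locus_map)
    n_total = anc_size * (anc_gens + 1) + npop * size * split_gens
    rec = _Recorder(n_total, nloci, with_traits=False)
    cur = rec.add_founders(haps, "ancestral")
    for g in range(1, anc_gens + 1):
        s, d = _draw_pairs(cur, anc_size, r_mate)
        cur = rec.add_offspring(s, d, g + 1, "ancestral", layout, r_mate)
    groups = [cur[p * size:(p + 1) * size] for p in range(npop)]
    for g in range(1, split_gens + 1):
        new = []
        for p in range(npop):  # no gene flow: parents only from own group
            s, d = _draw_pairs(groups[p], size, r_mate)
            new.append(rec.add_offspring(s, d, anc_gens + g + 1, str(p + 1), layout, r_mate))
        groups = new
    ped = rec.finish("S")
    return ScenarioOutput(ped, rec.H.sum(axis=1, dtype=np.uint8), locus_map, base)


def run_scenario(cfg: ScenarioConfig) -> ScenarioOutput:
    return run_2pop(cfg) if cfg.scenario == "2pop" else run_4pop(cfg)


# ---------------------------------------------------------------------------
# small random pedigrees (tests) and large layered pedigrees (scale runs)


def random_pedigree(
    n: int,
    seed: int = 0,
    p_missing: float = 0.2,
    n_founders: int | None = None,
) -> Pedigree:
    """A random sorted pedigree with a mix of unknown parents.

    Individual i (after an initial founder block) independently has its sire
    and/or dam unknown with probability ``p_missing`` each; known parents are
    uniform among earlier individuals, sire and dam always distinct (no
    selfing).  Useful for property tests against the dense oracle.
    """
    rng = np.random.default_rng(seed)
    n_founders = n_founders or max(2, n // 10)
    sire = np.zeros(n, dtype=np.int64)
    dam = np.zeros(n, dtype=np.int64)
    for i in range(n_founders, n):
        if rng.random() > p_missing:
            sire[i] = rng.integers(1, i + 1)
        if rng.random() > p_missing:
            d = rng.integers(1, i + 1)
            if d == sire[i]:  # no selfing: shift to a different candidate
                d = d % i + 1 if i > 1 else 0
            dam[i] = d
    labels = np.asarray([f"R{i + 1}" for i in range(n)], dtype=object)
    return Pedigree.from_indices(sire, dam, labels, perm_to_input=np.arange(n))


def layered_pedigree(cohort_size: int, n_cohorts: int, seed: int = 0) -> Pedigree:
    """A large discrete-generation pedigree: ``n_cohorts`` cohorts of
    ``cohort_size``, parents drawn uniformly from the previous cohort.
    Shallow by design so it scales to millions of records."""
    rng = np.random.default_rng(seed)
    n = cohort_size * n_cohorts
    sire = np.zeros(n, dtype=np.int64)
    dam = np.zeros(n, dtype=np.int64)
    for c in range(1, n_cohorts):
        lo, hi = c * cohort_size, (c + 1) * cohort_size
        prev_lo = (c - 1) * cohort_size
        sire[lo:hi] = rng.integers(prev_lo + 1, lo + 1, size=cohort_size)
        dam[lo:hi] = rng.integers(prev_lo + 1, lo + 1, size=cohort_size)
    labels = np.asarray([f"L{i + 1}" for i in range(n)], dtype=object)
    return Pedigree.from_indices(sire, dam, labels, perm_to_input=np.arange(n))


# ---------------------------------------------------------------------------
# genotype-side references


def genotype_pca_reference(dosages: np.ndarray, k: int = 10) -> PCAResult:
    """Standard centred genotype PCA for side-by-side comparison.

    Column-centres the dosage matrix and eigendecomposes the individuals'
    Gram matrix; scores follow the data-matrix convention U d, with variance
    proportions d_i^2 / sum d^2.
    """
    X = np.asarray(dosages, dtype=float)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need at least 2 individuals and 2 loci")
    X = X - X.mean(axis=0, keepdims=True)
    G = X @ X.T
    lam, W = np.linalg.eigh(G)
    lam = np.clip(lam[::-1], 0.0, None)
    W = W[:, ::-1]
    total = TraceEstimate(float(lam.sum()), exact=True)
    k = min(k, X.shape[0])
    d = np.sqrt(lam[:k])
    return PCAResult(
        scores=W[:, :k] * d,
        sdev=d,
        centred=True,
        method="genotype",
        total_variance=total,
    )


def realised_relationship(dosages: np.ndarray, base_freq: np.ndarray) -> np.ndarray:
    """Realised (genomic) relationship matrix G = Pn X X^T Pn / sum 2p(1-p),
    with p the known base allele frequencies; its pedigree expectation over
    the meiotic process is the centred relationship matrix Pn A Pn."""
    X = np.asarray(dosages, dtype=float)
    X = X - X.mean(axis=0, keepdims=True)
    denom = float(np.sum(2.0 * base_freq * (1.0 - base_freq)))
    return (X @ X.T) / denom
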