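"""Simulation of a pedigreed, partially genotyped livestock population.

The generator emulates the data structure of a pig breeding program: discrete
generations, a limited number of sires mated to many dams, full-sib litters,
sex-biased genotyping that intensifies in recent generations, and phenotypes
with a litter (common environment) random effect.  Genotypes are produced by
gene dropping: founder haplotypes are drawn from per-SNP allele frequencies
and transmitted through the pedigree with recombination under the Haldane
map function (crossovers form a Poisson process, so recombination events in
disjoint marker intervals are independent).

Phenotypes follow a single-trait animal model

    y = mu + sex + litter + (pen) + u + e,

where the true breeding value u is a linear combination of centred SNP
dosages (all SNPs act as QTL with Gaussian effects), rescaled so that the
realized additive variance equals ``h2`` on a unit phenotypic-variance scale.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "SimulatedStudy",
    "simulate_pedigree",
    "drop_genes",
    "simulate_phenotypes",
    "simulate_study",
    "write_pedigree_csv",
    "read_pedigree_csv",
    "write_genotypes_raw",
    "read_genotypes_raw",
    "write_phenotypes_csv",
]

PEDIGREE_COLUMNS = [
    "animal", "sire", "dam", "sex", "cohort", "litter", "pen",
    "genotyped", "phenotyped",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the simulated breeding program.

    Defaults are the study conditions used throughout the package: a
    five-generation population with ~2,500 genotyped animals and 3,000 SNPs,
    an effective dimensionality (4*Ne*L) of roughly 400 independent
    chromosome segments, and heritability 0.20.
    """

    n_generations: int = 5
    n_sires_per_gen: int = 8
    n_dams_per_gen: int = 90
    progeny_per_litter: int = 12
    n_snps_per_chrom: int = 1000
    n_chroms: int = 3
    chrom_length_morgans: float = 0.25
    founder_maf_low: float = 0.05
    founder_maf_high: float = 0.95
    h2: float = 0.20
    litter_var_frac: float = 0.10
    pen_var_frac: float = 0.0
    sex_effect: float = 0.25
    litters_per_pen: int = 4
    genotyping_fraction_by_gen: tuple[float, ...] = (0.1, 0.4, 0.6, 0.8, 0.95)
    female_genotyping_factor: float = 0.85
    phenotyping_fraction: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_generations < 1:
            raise ValueError("n_generations must be >= 1")
        for name in ("n_sires_per_gen", "n_dams_per_gen", "progeny_per_litter",
                     "n_snps_per_chrom", "n_chroms"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError("h2 must be in [0, 1]")
        for name in ("litter_var_frac", "pen_var_frac", "phenotyping_fraction",
                     "female_genotyping_factor"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.h2 + self.litter_var_frac + self.pen_var_frac > 1.0:
            raise ValueError(
                "h2 + litter_var_frac + pen_var_frac must not exceed 1")
        if not 0.0 < self.founder_maf_low <= self.founder_maf_high <= 1.0:
            raise ValueError("founder frequency bounds must satisfy "
                             "0 < low <= high <= 1")
        if len(self.genotyping_fraction_by_gen) < self.n_generations:
            raise ValueError("genotyping_fraction_by_gen must provide one "
                             "fraction per generation")
        if any(not 0.0 <= f <= 1.0 for f in self.genotyping_fraction_by_gen):
            raise ValueError("genotyping fractions must be in [0, 1]")

    @property
    def n_snps(self) -> int:
        return self.n_snps_per_chrom * self.n_chroms

    @property
    def genome_length_morgans(self) -> float:
        return self.n_chroms * self.chrom_length_morgans

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)

    def _seed_streams(self):
        ss = np.random.SeedSequence(self.seed)
        return [np.random.default_rng(s) for s in ss.spawn(3)]


@dataclass
class GenotypeMatrix:
    """SNP dosages (0/1/2) for an ordered set of animals.

    ``p`` is the counted-allele frequency of each SNP computed from the
    stored animals unless frequencies were supplied externally.
    """

    ids: np.ndarray
    snp_names: list[str]
    chrom: np.ndarray
    pos: np.ndarray          # map position in Morgans within chromosome
    dosage: np.ndarray       # (n_animals, n_snps) int8
    p: np.ndarray

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.dosage = np.asarray(self.dosage)
        if self.dosage.shape != (len(self.ids), len(self.snp_names)):
            raise ValueError("dosage dimensions inconsistent with ids/snps")

    @classmethod
    def from_dosage(cls, ids, dosage, snp_names=None, chrom=None, pos=None,
                    p=None) -> "GenotypeMatrix":
        dosage = np.asarray(dosage)
        n, m = dosage.shape
        if snp_names is None:
            snp_names = [f"snp{j + 1}" for j in range(m)]
        if chrom is None:
            chrom = np.ones(m, dtype=int)
        if pos is None:
            pos = np.arange(m, dtype=float)
        if p is None:
            p = dosage.mean(axis=0) / 2.0
        return cls(np.asarray(ids), list(snp_names), np.asarray(chrom),
                   np.asarray(pos), dosage, np.asarray(p, dtype=float))

    @property
    def n_animals(self) -> int:
        return len(self.ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_names)

    def centered(self) -> np.ndarray:
        """Dosages centred by twice the counted-allele frequency."""
        return self.dosage.astype(float) - 2.0 * self.p

    def minor_allele_freq(self) -> np.ndarray:
        return np.minimum(self.p, 1.0 - self.p)

    def subset_animals(self, ids) -> "GenotypeMatrix":
        """Restrict to ``ids`` (frequencies recomputed from the subset)."""
        ids = np.asarray(ids)
        pos_map = {a: i for i, a in enumerate(self.ids)}
        missing = [a for a in ids if a not in pos_map]
        if missing:
            raise KeyError(f"animals not in genotype matrix: {missing[:5]}")
        idx = np.array([pos_map[a] for a in ids])
        dos = self.dosage[idx]
        return GenotypeMatrix(ids, self.snp_names, self.chrom, self.pos,
                              dos, dos.mean(axis=0) / 2.0)

    def drop_monomorphic(self) -> "GenotypeMatrix":
        keep = (self.p > 0.0) & (self.p < 1.0)
        return GenotypeMatrix(self.ids,
                              [s for s, k in zip(self.snp_names, keep) if k],
                              self.chrom[keep], self.pos[keep],
                              self.dosage[:, keep], self.p[keep])


@dataclass
class SimulatedStudy:
    """A complete simulated dataset: pedigree, genotypes, truth, records."""

    config: SimulationConfig
    pedigree: pd.DataFrame
    genotypes: GenotypeMatrix            # genotyped animals only
    true_bv: pd.Series                   # all pedigree animals
    phenotypes: pd.DataFrame             # animal, y, sex, cohort, litter, pen
    qtl_effects: np.ndarray
    realized: dict = field(default_factory=dict)

    @property
    def genotyped_ids(self) -> np.ndarray:
        return self.pedigree.loc[self.pedigree["genotyped"], "animal"].to_numpy()

    def validation_ids(self) -> np.ndarray:
        """Youngest cohort with both genotypes and records."""
        ped = self.pedigree
        recorded = set(self.phenotypes["animal"])
        mask = ped["genotyped"] & ped["animal"].isin(recorded)
        if not mask.any():
            raise ValueError("no genotyped animal has a phenotype record")
        last = ped.loc[mask, "cohort"].max()
        return ped.loc[mask & (ped["cohort"] == last), "animal"].to_numpy()


def simulate_pedigree(config: SimulationConfig) -> pd.DataFrame:
    """Discrete-generation pedigree with full-sib litters.

    Generation 0 founders have unknown parents (coded 0).  In each later
    generation, ``n_dams_per_gen`` dams from the previous generation are
    each mated to one randomly drawn sire and produce a full-sib litter.
    Animal ids are 1..N in topological (birth) order.
    """
    rng_ped, _, _ = config._seed_streams()
    n_founders = config.n_sires_per_gen + config.n_dams_per_gen
    if n_founders == 0:
        raise ValueError("configuration produces zero founders")

    rows = []
    litter_counter = 0
    # founders: singleton litters (no shared maternal environment)
    for i in range(n_founders):
        litter_counter += 1
        sex = "M" if i < config.n_sires_per_gen else "F"
        rows.append((i + 1, 0, 0, sex, 0, litter_counter))
    prev_males = np.arange(1, config.n_sires_per_gen + 1)
    prev_females = np.arange(config.n_sires_per_gen + 1, n_founders + 1)

    next_id = n_founders + 1
    for g in range(1, config.n_generations):
        if (len(prev_males) < config.n_sires_per_gen
                or len(prev_females) < config.n_dams_per_gen):
            raise ValueError(
                f"generation {g - 1} too small to supply "
                f"{config.n_sires_per_gen} sires and "
                f"{config.n_dams_per_gen} dams")
        sires = rng_ped.choice(prev_males, config.n_sires_per_gen,
                               replace=False)
        dams = rng_ped.choice(prev_females, config.n_dams_per_gen,
                              replace=False)
        males, females = [], []
        for dam in dams:
            sire = sires[rng_ped.integers(len(sires))]
            litter_counter += 1
            sexes = rng_ped.integers(0, 2, size=config.progeny_per_litter)
            for s in sexes:
                sex = "M" if s == 0 else "F"
                rows.append((next_id, int(sire), int(dam), sex, g,
                             litter_counter))
                (males if sex == "M" else females).append(next_id)
                next_id += 1
        prev_males = np.array(males, dtype=int)
        prev_females = np.array(females, dtype=int)

    ped = pd.DataFrame(rows, columns=["animal", "sire", "dam", "sex",
                                      "cohort", "litter"])
    if ped["litter"].nunique() == 0:
        raise ValueError("configuration produces zero litters")
    # pens: blocks of consecutive litters within a cohort
    ped["pen"] = (ped["litter"] - 1) // config.litters_per_pen + 1

    # genotyping flags: per-generation fraction, female-biased downward
    prob = np.array([config.genotyping_fraction_by_gen[c]
                     for c in ped["cohort"]])
    prob = np.where(ped["sex"].to_numpy() == "F",
                    prob * config.female_genotyping_factor, prob)
    ped["genotyped"] = rng_ped.random(len(ped)) < prob
    ped["phenotyped"] = rng_ped.random(len(ped)) < config.phenotyping_fraction
    return ped


def _recomb_prob_vector(config: SimulationConfig) -> np.ndarray:
    """Recombination fraction between consecutive SNPs (0.5 across
    chromosome boundaries), Haldane: c = (1 - exp(-2d)) / 2."""
    m_per = config.n_snps_per_chrom
    if m_per > 1:
        d = config.chrom_length_morgans / (m_per - 1)
    else:
        d = 0.0
    c_within = 0.5 * (1.0 - np.exp(-2.0 * d))
    c = np.full(config.n_snps - 1, c_within)
    for k in range(1, config.n_chroms):
        c[k * m_per - 1] = 0.5
    return c


def _snp_map(config: SimulationConfig):
    m_per = config.n_snps_per_chrom
    chrom = np.repeat(np.arange(1, config.n_chroms + 1), m_per)
    if m_per > 1:
        within = np.linspace(0.0, config.chrom_length_morgans, m_per)
    else:
        within = np.zeros(1)
    pos = np.tile(within, config.n_chroms)
    names = [f"c{c}_s{i + 1}" for c in range(1, config.n_chroms + 1)
             for i in range(m_per)]
    return names, chrom, pos


def _make_gametes(parent_haplos: np.ndarray, rng: np.random.Generator,
                  recomb_prob: np.ndarray) -> np.ndarray:
    """One gamete per row of ``parent_haplos`` (shape (k, 2, n_snps)).

    The phase along the chromosome is a Markov chain that switches between
    the two parental haplotypes with the per-interval recombination
    fraction; the starting haplotype is chosen at random.
    """
    k, _, m = parent_haplos.shape
    start = rng.integers(0, 2, size=k)
    switches = rng.random((k, m - 1)) < recomb_prob
    phase = np.empty((k, m), dtype=np.int8)
    phase[:, 0] = start
    phase[:, 1:] = (start[:, None] + np.cumsum(switches, axis=1)) % 2
    rows = np.arange(k)[:, None]
    cols = np.arange(m)[None, :]
    return parent_haplos[rows, phase, cols]


def _drop_all_haplotypes(pedigree: pd.DataFrame,
                         config: SimulationConfig,
                         rng: np.random.Generator) -> np.ndarray:
    """Haplotypes (n_animals, 2, n_snps) for every animal in the pedigree."""
    if config.n_snps == 0:
        raise ValueError("SNP count must be positive")
    n = len(pedigree)
    m = config.n_snps
    founder_p = rng.uniform(config.founder_maf_low, config.founder_maf_high,
                            size=m)
    haplos = np.zeros((n, 2, m), dtype=np.int8)
    sire = pedigree["sire"].to_numpy()
    dam = pedigree["dam"].to_numpy()
    cohort = pedigree["cohort"].to_numpy()
    recomb = _recomb_prob_vector(config)

    founders = np.flatnonzero((sire == 0) & (dam == 0))
    haplos[founders] = (rng.random((len(founders), 2, m)) < founder_p
                        ).astype(np.int8)
    for g in sorted(set(cohort) - {0}):
        idx = np.flatnonzero(cohort == g)
        if len(idx) == 0:
            continue
        s_idx = sire[idx] - 1  # ids are 1-based positions
        d_idx = dam[idx] - 1
        pat = _make_gametes(haplos[s_idx], rng, recomb)
        mat = _make_gametes(haplos[d_idx], rng, recomb)
        haplos[idx, 0] = pat
        haplos[idx, 1] = mat
    return haplos


def drop_genes(pedigree: pd.DataFrame, config: SimulationConfig,
               *, keep_monomorphic: bool = False) -> GenotypeMatrix:
    """Gene-drop genotypes; return dosages of the genotyped animals only.

    SNPs that are monomorphic among the genotyped animals are removed
    (mimicking routine quality control) unless ``keep_monomorphic``.
    """
    _, rng_geno, _ = config._seed_streams()
    haplos = _drop_all_haplotypes(pedigree, config, rng_geno)
    dosage = haplos.sum(axis=1, dtype=np.int8)
    gids = pedigree.loc[pedigree["genotyped"], "animal"].to_numpy()
    names, chrom, pos = _snp_map(config)
    gm = GenotypeMatrix(gids, names, chrom, pos, dosage[gids - 1],
                        dosage[gids - 1].mean(axis=0) / 2.0)
    return gm if keep_monomorphic else gm.drop_monomorphic()


def simulate_phenotypes(pedigree: pd.DataFrame, full_dosage: np.ndarray,
                        config: SimulationConfig) -> SimulatedStudy:
    """True breeding values and phenotype records for the whole pedigree.

    ``full_dosage`` must hold dosages for *every* pedigree animal in id
    order (the genotyped flag only controls what is exported downstream).
    Phenotypic variance is 1 by construction of the variance fractions.
    """
    _, _, rng_ph = config._seed_streams()
    n = len(pedigree)
    if full_dosage.shape[0] != n:
        raise ValueError("full_dosage must cover every pedigree animal")
    m = full_dosage.shape[1]

    raw_effects = rng_ph.normal(size=m)
    zc = full_dosage.astype(float) - full_dosage.mean(axis=0)
    u_raw = zc @ raw_effects
    sd = u_raw.std()
    if sd == 0:
        scale = 0.0
    else:
        scale = np.sqrt(config.h2) / sd
    true_bv = u_raw * scale
    qtl_effects = raw_effects * scale

    sigma_l = np.sqrt(config.litter_var_frac)
    sigma_pen = np.sqrt(config.pen_var_frac)
    sigma_e = np.sqrt(max(0.0,
                          1.0 - config.h2 - config.litter_var_frac
                          - config.pen_var_frac))

    litters = pedigree["litter"].to_numpy()
    pens = pedigree["pen"].to_numpy()
    litter_codes, litter_idx = np.unique(litters, return_inverse=True)
    pen_codes, pen_idx = np.unique(pens, return_inverse=True)
    litter_eff = rng_ph.normal(0.0, sigma_l, size=len(litter_codes))
    pen_eff = rng_ph.normal(0.0, sigma_pen, size=len(pen_codes))
    resid = rng_ph.normal(0.0, sigma_e, size=n)

    is_male = (pedigree["sex"].to_numpy() == "M").astype(float)
    y = (config.sex_effect * is_male + litter_eff[litter_idx]
         + pen_eff[pen_idx] + true_bv + resid)

    recorded = pedigree["phenotyped"].to_numpy()
    phen = pd.DataFrame({
        "animal": pedigree.loc[recorded, "animal"].to_numpy(),
        "y": y[recorded],
        "sex": pedigree.loc[recorded, "sex"].to_numpy(),
        "cohort": pedigree.loc[recorded, "cohort"].to_numpy(),
        "litter": pedigree.loc[recorded, "litter"].to_numpy(),
        "pen": pedigree.loc[recorded, "pen"].to_numpy(),
    })

    var_y = y.var()
    realized = {
        "var_bv": float(true_bv.var()),
        "var_litter": float(litter_eff[litter_idx].var()),
        "var_pen": float(pen_eff[pen_idx].var()),
        "var_resid": float(resid.var()),
        "var_y": float(var_y),
        "h2_realized": float(true_bv.var()
                             / (true_bv.var() + litter_eff[litter_idx].var()
                                + pen_eff[pen_idx].var() + resid.var())),
    }
    return SimulatedStudy(
        config=config, pedigree=pedigree, genotypes=None,  # filled by caller
        true_bv=pd.Series(true_bv, index=pedigree["animal"].to_numpy()),
        phenotypes=phen, qtl_effects=qtl_effects, realized=realized)


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Full deterministic simulation: pedigree, genotypes, phenotypes."""
    pedigree = simulate_pedigree(config)
    _, rng_geno, _ = config._seed_streams()
    haplos = _drop_all_haplotypes(pedigree, config, rng_geno)
    full_dosage = haplos.sum(axis=1, dtype=np.int8)
    study = simulate_phenotypes(pedigree, full_dosage, config)

    gids = pedigree.loc[pedigree["genotyped"], "animal"].to_numpy()
    if len(gids) == 0:
        raise ValueError("no animal was flagged genotyped")
    names, chrom, pos = _snp_map(config)
    gm = GenotypeMatrix(gids, names, chrom, pos, full_dosage[gids - 1],
                        full_dosage[gids - 1].mean(axis=0) / 2.0)
    study.genotypes = gm.drop_monomorphic()
    return study


# ---------------------------------------------------------------------------
# flat-file interfaces (pedigree CSV, PLINK RAW-style genotypes)

def write_pedigree_csv(pedigree: pd.DataFrame, path) -> None:
    pedigree.to_csv(path, index=False)


def read_pedigree_csv(path) -> pd.DataFrame:
    ped = pd.read_csv(path)
    missing = [c for c in ["animal", "sire", "dam", "sex"] if c not in ped]
    if missing:
        raise ValueError(f"pedigree file lacks columns: {missing}")
    return ped


def write_genotypes_raw(gm: GenotypeMatrix, path) -> None:
    """PLINK RAW-style dialect: header of SNP names, one row per animal
    (id followed by 0/1/2 dosages, whitespace separated)."""
    with open(path, "w") as fh:
        fh.write("IID " + " ".join(gm.snp_names) + "\n")
        for i, a in enumerate(gm.ids):
            fh.write(str(a) + " "
                     + " ".join(map(str, gm.dosage[i].tolist())) + "\n")


def read_genotypes_raw(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep=r"\s+")
    ids = df.iloc[:, 0].to_numpy()
    snp_names = list(df.columns[1:])
    dosage = df.iloc[:, 1:].to_numpy(dtype=np.int8)
    return GenotypeMatrix.from_dosage(ids, dosage, snp_names=snp_names)


def write_phenotypes_csv(phenotypes: pd.DataFrame, path) -> None:
    phenotypes.to_csv(path, index=False)


def save_study(study: SimulatedStudy, directory) -> None:
    """Write pedigree, genotype, and phenotype flat files for a study."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_pedigree_csv(study.pedigree, directory / "pedigree.csv")
    write_genotypes_raw(study.genotypes, directory / "genotypes.raw")
    write_phenotypes_csv(study.phenotypes, directory / "phenotypes.csv")
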