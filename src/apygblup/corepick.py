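"""Core-subset selection strategies for the APY inverse.

Each strategy maps (study data, target size, seed) to a partition of the
genotyped animals into a core (whose genomic relationship block is inverted
directly) and a noncore (whose breeding values are conditioned on the core):

* ``MPA``   most popular animals — ranked by progeny count, both parents
            known, with own records;
* ``Rnd``   uniform random sample of genotyped animals;
* ``Ped``   animals uniformly spread over the pedigree in genealogical order;
* ``Fam``   one random progeny per full-sib family;
* ``Unrel`` greedily chosen animals whose pairwise genomic relationship
            stays below a threshold (auto-calibrated by bisection);
* ``LPM``/``LPF``  least popular males/females — both parents known, no
            progeny, no own records;
* ``QR``    animals indexing the largest pivoted-QR diagonal of the centred
            gene-content matrix;
* ``FULL``  every genotyped animal (regular ssGBLUP baseline).

All strategies are deterministic given their inputs and seed, break ties by
smaller animal id, and report a shortfall when the eligible pool cannot
reach the requested size rather than failing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg

from .relmat import RelationshipMatrix
from .synthpop import GenotypeMatrix

__all__ = [
    "CoreSpec",
    "CorePartition",
    "select_mpa",
    "select_random",
    "select_ped_spread",
    "select_family",
    "select_unrelated",
    "select_least_popular",
    "select_qr",
    "make_full_core",
    "select_core",
    "DEFINITIONS",
]

DEFINITIONS = ("MPA", "Rnd", "Ped", "Fam", "Unrel", "LPM", "LPF", "QR")


@dataclass(frozen=True)
class CoreSpec:
    definition: str
    target_size: int = 0
    seed: int = 0
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.definition not in DEFINITIONS + ("FULL",):
            raise ValueError(f"unknown core definition {self.definition!r}")


@dataclass
class CorePartition:
    """Ordered core/noncore split of the genotyped animals."""

    core: np.ndarray
    noncore: np.ndarray
    target_size: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.core = np.asarray(self.core)
        self.noncore = np.asarray(self.noncore)
        if np.intersect1d(self.core, self.noncore).size:
            raise ValueError("core and noncore overlap")

    @property
    def achieved_size(self) -> int:
        return len(self.core)

    @property
    def shortfall(self) -> int:
        return max(0, self.target_size - self.achieved_size)

    @property
    def genotyped_ids(self) -> np.ndarray:
        return np.concatenate([self.core, self.noncore])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "animal": np.concatenate([self.core, self.noncore]),
            "role": ["core"] * len(self.core)
                    + ["noncore"] * len(self.noncore),
        })


def _finish(genotyped_ids, core_ids, target, **meta) -> CorePartition:
    genotyped_ids = np.asarray(genotyped_ids)
    core = np.sort(np.asarray(core_ids))
    noncore = np.setdiff1d(genotyped_ids, core)
    return CorePartition(core, noncore, target, meta=dict(meta))


def _progeny_counts(ped: pd.DataFrame) -> pd.Series:
    counts = pd.concat([ped["sire"], ped["dam"]]).value_counts()
    counts = counts.drop(index=0, errors="ignore")
    return counts.reindex(ped["animal"], fill_value=0)


def _recorded_ids(ped: pd.DataFrame, phenotypes: pd.DataFrame | None) -> set:
    if phenotypes is not None:
        return set(phenotypes["animal"])
    return set(ped.loc[ped["phenotyped"], "animal"])


def select_mpa(ped: pd.DataFrame, phenotypes: pd.DataFrame | None,
               target: int, seed: int = 0) -> CorePartition:
    """Most popular animals: ranked by progeny count (descending, ties to
    the smaller id) among genotyped animals with both parents known and at
    least one own record."""
    recorded = _recorded_ids(ped, phenotypes)
    counts = _progeny_counts(ped)
    elig = ped[(ped["genotyped"]) & (ped["sire"] != 0) & (ped["dam"] != 0)
               & (ped["animal"].isin(recorded))]
    if elig.empty:
        raise ValueError("MPA pool empty: no genotyped animal has both "
                         "parents known and an own record")
    order = elig.assign(progeny=counts.loc[elig["animal"]].to_numpy()) \
        .sort_values(["progeny", "animal"], ascending=[False, True])
    core = order["animal"].to_numpy()[:target]
    gids = ped.loc[ped["genotyped"], "animal"].to_numpy()
    return _finish(gids, core, target)


def select_random(genotyped_ids, target: int, seed: int = 0) -> CorePartition:
    genotyped_ids = np.asarray(genotyped_ids)
    if target > len(genotyped_ids):
        raise ValueError("target exceeds number of genotyped animals")
    rng = np.random.default_rng(seed)
    core = rng.choice(genotyped_ids, size=target, replace=False)
    return _finish(genotyped_ids, core, target)


def select_ped_spread(ped: pd.DataFrame, genotyped_ids,
                      target: int) -> CorePartition:
    """Genotyped animals in genealogical (topological id) order, sampled at
    uniformly spaced ranks floor((i + 0.5) * n / target)."""
    genotyped_ids = np.sort(np.asarray(genotyped_ids))
    n = len(genotyped_ids)
    if target > n:
        raise ValueError("target exceeds number of genotyped animals")
    idx = np.floor((np.arange(target) + 0.5) * n / target).astype(int)
    return _finish(genotyped_ids, genotyped_ids[idx], target)


def select_family(ped: pd.DataFrame, genotyped_ids, target: int,
                  seed: int = 0) -> CorePartition:
    """One random genotyped progeny per full-sib family.

    Families are groups of genotyped animals sharing both (known) parents;
    an animal with an unknown parent forms its own family.  If there are
    more families than the target, a random subset of families is used; if
    fewer, the representatives are topped up at random from the remaining
    genotyped animals (the shortfall-free rule used when family count is
    the limit).
    """
    genotyped_ids = np.asarray(genotyped_ids)
    rng = np.random.default_rng(seed)
    sub = ped[ped["animal"].isin(genotyped_ids)]
    fam_key = [
        (s, d) if (s != 0 and d != 0) else ("solo", a)
        for a, s, d in zip(sub["animal"], sub["sire"], sub["dam"])
    ]
    groups: dict = {}
    for a, k in zip(sub["animal"], fam_key):
        groups.setdefault(k, []).append(a)
    reps = np.array(sorted(
        members[rng.integers(len(members))] for members in groups.values()))
    if len(reps) > target:
        reps = rng.choice(reps, size=target, replace=False)
        core = reps
    else:
        remaining = np.setdiff1d(genotyped_ids, reps)
        extra = min(target - len(reps), len(remaining))
        top_up = rng.choice(remaining, size=extra, replace=False) \
            if extra else np.empty(0, dtype=reps.dtype)
        core = np.concatenate([reps, top_up])
    return _finish(genotyped_ids, core, target,
                   n_families=len(groups))


def _greedy_unrelated(values: np.ndarray, order: np.ndarray,
                      threshold: float) -> np.ndarray:
    """Scan candidates in ``order``; keep one iff its relationship with every
    kept animal is <= threshold.  Returns kept positions."""
    kept: list[int] = []
    for cand in order:
        if not kept or values[cand, kept].max() <= threshold:
            kept.append(int(cand))
    return np.array(kept, dtype=int)


def select_unrelated(G: RelationshipMatrix, target: int, seed: int = 0,
                     threshold: float | None = None) -> CorePartition:
    """Greedy maximal set of pairwise weakly related genotyped animals.

    With an explicit relationship ``threshold`` the greedy scan (in a
    seed-shuffled candidate order) keeps each candidate whose genomic
    relationship with all previously kept animals does not exceed it; the
    kept set is randomly trimmed if larger than the target.  Without a
    threshold, the threshold is bisected until the kept set lands in
    [target, 1.02 * target], then trimmed to the target.
    """
    values = G.values
    n = G.n
    if target > n:
        raise ValueError("target exceeds number of genotyped animals")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    off = values[~np.eye(n, dtype=bool)]
    lo, hi = float(off.min()), float(off.max())

    def kept_for(t):
        return _greedy_unrelated(values, order, t)

    if threshold is not None:
        kept = kept_for(threshold)
        final_t = threshold
    else:
        kept = kept_for(hi)
        final_t = hi
        if len(kept) >= target:
            t_lo, t_hi = lo, hi
            best, best_t = kept, hi
            for _ in range(50):
                mid = 0.5 * (t_lo + t_hi)
                k = kept_for(mid)
                if len(k) < target:
                    t_lo = mid
                else:
                    best, best_t = k, mid
                    t_hi = mid
                    if len(k) <= int(np.ceil(1.02 * target)):
                        break
            kept, final_t = best, best_t
    if len(kept) > target:
        kept = rng.choice(kept, size=target, replace=False)
    core = np.sort(G.ids[np.asarray(kept, dtype=int)])
    return _finish(G.ids, core, target, threshold=final_t)


def select_least_popular(ped: pd.DataFrame, phenotypes: pd.DataFrame | None,
                         sex: str, target: int, seed: int = 0) -> CorePartition:
    """Least popular animals of one sex: genotyped, both parents known, no
    progeny, and no own performance records.  A pool smaller than the
    target is returned whole with the shortfall recorded."""
    if sex not in ("M", "F"):
        raise ValueError("sex must be 'M' or 'F'")
    recorded = _recorded_ids(ped, phenotypes)
    counts = _progeny_counts(ped)
    pool = ped[(ped["genotyped"]) & (ped["sex"] == sex)
               & (ped["sire"] != 0) & (ped["dam"] != 0)
               & (~ped["animal"].isin(recorded))
               & (counts.loc[ped["animal"]].to_numpy() == 0)]
    if pool.empty:
        raise ValueError(f"least-popular pool empty for sex {sex!r}")
    rng = np.random.default_rng(seed)
    pool_ids = pool["animal"].to_numpy()
    if len(pool_ids) <= target:
        core = pool_ids
    else:
        core = rng.choice(pool_ids, size=target, replace=False)
    gids = ped.loc[ped["genotyped"], "animal"].to_numpy()
    return _finish(gids, core, target, pool_size=len(pool_ids))


def select_qr(genotypes: GenotypeMatrix, target: int) -> CorePartition:
    """Column-pivoted QR of the SNP-by-animal centred gene-content matrix.

    Pivot columns index animals; the first ``target`` pivots (largest
    |diag(R)| in pivot order) form the core.  If the target exceeds the
    numerical rank, later pivots are appended with a warning.
    """
    Z = genotypes.centered().T  # SNPs x animals so pivots index animals
    n = genotypes.n_animals
    if target > n:
        raise ValueError("target exceeds number of genotyped animals")
    R, piv = scipy.linalg.qr(Z, mode="r", pivoting=True)
    rdiag = np.abs(np.diag(R))
    rank = int((rdiag > rdiag[0] * max(Z.shape) * np.finfo(float).eps).sum()) \
        if rdiag.size and rdiag[0] > 0 else 0
    if target > rank:
        warnings.warn(
            f"QR core target {target} exceeds numerical rank {rank}; "
            "appending remaining pivots in pivot order")
    core = genotypes.ids[piv[:target]]
    return _finish(genotypes.ids, core, target,
                   rdiag=rdiag[:min(target, len(rdiag))], rank=rank)


def make_full_core(genotyped_ids) -> CorePartition:
    """Regular ssGBLUP: every genotyped animal in the core."""
    genotyped_ids = np.sort(np.asarray(genotyped_ids))
    return CorePartition(genotyped_ids, np.empty(0, dtype=genotyped_ids.dtype),
                         target_size=len(genotyped_ids))


def select_core(spec: CoreSpec, *, ped=None, phenotypes=None,
                genotypes=None, G=None, genotyped_ids=None) -> CorePartition:
    """Dispatch a :class:`CoreSpec` to the matching strategy."""
    d, t, s = spec.definition, spec.target_size, spec.seed
    if genotyped_ids is None and ped is not None:
        genotyped_ids = ped.loc[ped["genotyped"], "animal"].to_numpy()
    if d == "FULL":
        return make_full_core(genotyped_ids)
    if d == "MPA":
        return select_mpa(ped, phenotypes, t, s)
    if d == "Rnd":
        return select_random(genotyped_ids, t, s)
    if d == "Ped":
        return select_ped_spread(ped, genotyped_ids, t)
    if d == "Fam":
        return select_family(ped, genotyped_ids, t, s)
    if d == "Unrel":
        return select_unrelated(G, t, s, spec.params.get("threshold"))
    if d == "LPM":
        return select_least_popular(ped, phenotypes, "M", t, s)
    if d == "LPF":
        return select_least_popular(ped, phenotypes, "F", t, s)
    if d == "QR":
        return select_qr(genotypes, t)
    raise ValueError(f"unknown definition {d!r}")
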