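"""Comparison metrics for APY ssGBLUP scenarios.

Implements the evaluation layer of the study: validation-cohort prediction
accuracy corr(y_adj, u_hat)/h and MSE, correlations between GEBV of
scenarios, hierarchical (Ward) clustering of scenario GEBV vectors,
minor-allele-frequency spectrum overlap between core and all genotyped
animals, and row sums of |G_cn| (core-noncore connectivity).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .corepick import CorePartition
from .mme import ModelSpec, Solutions
from .relmat import RelationshipMatrix
from .synthpop import GenotypeMatrix

__all__ = [
    "ValidationSet",
    "MAFBinning",
    "Linkage",
    "adjusted_phenotypes",
    "prediction_accuracy",
    "prediction_mse",
    "gebv_correlation",
    "maf_overlap",
    "gcn_row_sums",
    "ward_linkage",
]

MAF_BIN_EDGES = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5)


@dataclass
class ValidationSet:
    """Validation animals with phenotypes adjusted for non-genetic effects."""

    ids: np.ndarray
    y_adj: pd.Series
    h: float

    def __post_init__(self):
        self.ids = np.asarray(self.ids)
        if len(self.ids) == 0:
            raise ValueError("validation set is empty")
        if not 0.0 < self.h <= 1.0:
            raise ValueError("h (sqrt of heritability) must be in (0, 1]")


def adjusted_phenotypes(solutions: Solutions, phenotypes: pd.DataFrame,
                        model: ModelSpec) -> pd.Series:
    """y adjusted for all non-genetic effects of a full-data baseline run.

    y_adj = y - X b_hat - sum_k W_k u_hat_k over the model's non-additive
    random effects; the additive solution is *not* subtracted, so y_adj
    retains the genetic signal plus residual noise.
    """
    y_adj = phenotypes.set_index("animal")["y"].astype(float).copy()
    df = phenotypes.set_index("animal")

    b = solutions.block("fixed")
    if "intercept" in b.index:
        y_adj -= b["intercept"]
    for eff in model.fixed_effects:
        prefix = f"{eff}:"
        lut = {lab[len(prefix):]: val for lab, val in b.items()
               if lab.startswith(prefix)}
        if lut:
            y_adj -= df[eff].astype(str).map(
                {str(k): v for k, v in lut.items()}).fillna(0.0)
    for cov in model.covariates:
        if cov in b.index:
            y_adj -= b[cov] * df[cov]
    for reff in model.random_effects:
        if reff.name not in solutions.block_index:
            raise KeyError(f"missing solution block {reff.name!r}")
        u = solutions.block(reff.name)
        y_adj -= df[reff.column].map(u).fillna(0.0)
    return y_adj


def prediction_accuracy(val: ValidationSet, u_hat: pd.Series) -> float:
    """acc = corr(y_adj, u_hat) / h over the validation animals."""
    if len(val.ids) < 3:
        raise ValueError("need at least 3 validation animals")
    a = val.y_adj.loc[val.ids].to_numpy(dtype=float)
    b = u_hat.loc[val.ids].to_numpy(dtype=float)
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance in y_adj or GEBV; accuracy undefined")
    return float(np.corrcoef(a, b)[0, 1] / val.h)


def prediction_mse(val: ValidationSet, u_hat: pd.Series) -> float:
    """Mean squared difference between adjusted phenotypes and GEBV."""
    a = val.y_adj.loc[val.ids].to_numpy(dtype=float)
    b = u_hat.loc[val.ids].to_numpy(dtype=float)
    return float(np.mean((a - b) ** 2))


def gebv_correlation(u_hat_a: pd.Series, u_hat_b: pd.Series,
                     ids) -> float:
    """Pearson correlation of two GEBV vectors over a named id set."""
    ids = np.asarray(ids)
    for u in (u_hat_a, u_hat_b):
        missing = np.setdiff1d(ids, u.index.to_numpy())
        if missing.size:
            raise KeyError(f"ids missing from GEBV vector: {missing[:5]}")
    a = u_hat_a.loc[ids].to_numpy(dtype=float)
    b = u_hat_b.loc[ids].to_numpy(dtype=float)
    return float(np.corrcoef(a, b)[0, 1])


@dataclass
class MAFBinning:
    """Per-SNP MAF bins from all genotyped animals (B) vs a core set (C)."""

    edges: tuple
    all_bins: np.ndarray
    core_bins: np.ndarray
    overlap: float

    @property
    def n_snps(self) -> int:
        return len(self.all_bins)


def _maf_bins(maf: np.ndarray) -> np.ndarray:
    """Labels 1..5 for bins [0,.1), [.1,.2), [.2,.3), [.3,.4), [.4,.5]."""
    return np.digitize(maf, MAF_BIN_EDGES[1:-1], right=False) + 1


def maf_overlap(genotypes: GenotypeMatrix,
                partition: CorePartition) -> MAFBinning:
    """Fraction of SNPs whose MAF bin agrees between core and all animals.

    A SNP monomorphic within the core falls in the first bin (MAF 0); it is
    not an error.
    """
    all_bins = _maf_bins(genotypes.minor_allele_freq())
    core_gm = genotypes.subset_animals(partition.core)
    core_bins = _maf_bins(core_gm.minor_allele_freq())
    overlap = float(np.mean(all_bins == core_bins))
    return MAFBinning(MAF_BIN_EDGES, all_bins, core_bins, overlap)


def gcn_row_sums(G: RelationshipMatrix,
                 partition: CorePartition) -> pd.DataFrame:
    """Row sums of |G_cn|: per-core-animal total absolute relationship with
    the noncore.  The summary (mean, sd, min, max) is in ``df.attrs``."""
    ci = G.positions(partition.core)
    ni = G.positions(partition.noncore)
    sums = np.abs(G.values[np.ix_(ci, ni)]).sum(axis=1)
    df = pd.DataFrame({"animal": partition.core, "abs_row_sum": sums})
    df.attrs["summary"] = {
        "mean": float(sums.mean()) if sums.size else 0.0,
        "sd": float(sums.std()) if sums.size else 0.0,
        "min": float(sums.min()) if sums.size else 0.0,
        "max": float(sums.max()) if sums.size else 0.0,
    }
    return df


@dataclass
class Linkage:
    """Agglomerative merge sequence under Ward's criterion (D2 form)."""

    labels: list
    merges: list = field(default_factory=list)  # (a, b, height, size)

    def heights(self) -> np.ndarray:
        return np.array([h for _, _, h, _ in self.merges])

    def to_merge_table(self) -> pd.DataFrame:
        return pd.DataFrame(self.merges,
                            columns=["cluster_a", "cluster_b", "height",
                                     "size"])

    def to_newick(self) -> str:
        n = len(self.labels)
        nodes = {i: f"{self.labels[i]}" for i in range(n)}
        heights = {i: 0.0 for i in range(n)}
        for k, (a, b, h, _) in enumerate(self.merges):
            la = max(h - heights[a], 0.0)
            lb = max(h - heights[b], 0.0)
            nodes[n + k] = f"({nodes[a]}:{la:.6g},{nodes[b]}:{lb:.6g})"
            heights[n + k] = h
        root = n + len(self.merges) - 1 if self.merges else 0
        return nodes[root] + ";"


def ward_linkage(gebv_by_scenario: dict[str, pd.Series]) -> Linkage:
    """Ward (D2) hierarchical clustering of scenario GEBV vectors.

    Distances are Euclidean norms between aligned GEBV vectors; merges use
    the Lance–Williams update for Ward's criterion on squared distances.
    Cluster indices follow the scipy convention: originals 0..k-1, the i-th
    merge creates cluster k+i.  Ties break toward the lexicographically
    smallest index pair.
    """
    names = list(gebv_by_scenario)
    if len(names) < 2:
        raise ValueError("need at least two scenarios to cluster")
    ref_index = gebv_by_scenario[names[0]].index
    mat = np.empty((len(names), len(ref_index)))
    for i, name in enumerate(names):
        s = gebv_by_scenario[name]
        if not s.index.equals(ref_index):
            if set(s.index) != set(ref_index):
                raise ValueError(f"scenario {name!r} has misaligned ids")
            s = s.loc[ref_index]
        mat[i] = s.to_numpy(dtype=float)

    k = len(names)
    d2 = np.sum((mat[:, None, :] - mat[None, :, :]) ** 2, axis=2)
    sizes = {i: 1 for i in range(k)}
    merges = []
    next_cluster = k
    # squared distances keyed by cluster-id pairs; grows as clusters merge
    d2map = {(i, j): float(d2[i, j])
             for i in range(k) for j in range(i + 1, k)}
    clusters = set(range(k))
    while len(clusters) > 1:
        best = min(
            ((d2map[(min(a, b), max(a, b))], (min(a, b), max(a, b)))
             for a in clusters for b in clusters if a < b))
        dij2, (i, j) = best
        h = float(np.sqrt(dij2))
        ni, nj = sizes[i], sizes[j]
        new = next_cluster
        next_cluster += 1
        merges.append((i, j, h, ni + nj))
        clusters.discard(i)
        clusters.discard(j)
        for m in clusters:
            nm = sizes[m]
            dim2 = d2map[(min(i, m), max(i, m))]
            djm2 = d2map[(min(j, m), max(j, m))]
            dnew2 = ((ni + nm) * dim2 + (nj + nm) * djm2 - nm * dij2) \
                / (ni + nj + nm)
            d2map[(min(new, m), max(new, m))] = dnew2
        clusters.add(new)
        sizes[new] = ni + nj
    return Linkage(labels=names, merges=merges)
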