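"""Orchestration of the full core-definition x core-size factorial study.

`prepare_study` simulates (or loads) the data and precomputes everything
shared by scenarios: relationship matrices and inverses, the blended G, the
eigen-spectrum core sizes, and the regular-ssGBLUP baselines (a full-data
run per trait from which adjusted phenotypes are derived, and a truncated
run giving the baseline GEBV and accuracy).  `run_scenario` then evaluates
one (trait, definition, size) cell: select the core, build the APY inverse
and H^-1, solve the truncated MME, and score the scenario against the
baseline.  `run_study` loops the factorial and collects a tidy report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import apycore, corepick, evalsuite, mme, relmat
from .synthpop import (GenotypeMatrix, SimulatedStudy, SimulationConfig,
                       _drop_all_haplotypes, _snp_map, simulate_pedigree,
                       simulate_phenotypes)

__all__ = [
    "TraitSpec",
    "RunConfig",
    "StudyContext",
    "StudyReport",
    "prepare_study",
    "run_scenario",
    "run_study",
    "make_report",
    "scenario_seed",
]

DEFAULT_THRESHOLDS = (0.50, 0.80, 0.90, 0.95, 0.99)

_STAGE_CODES = {"simulation": 0, "selection": 1, "trait": 2}


def scenario_seed(master: int, stage: str, def_idx: int = 0,
                  size_idx: int = 0) -> int:
    """Deterministic sub-seed: master + fixed offsets per (stage,
    definition, size), kept below 2**31."""
    return (int(master) + 100_003 * _STAGE_CODES[stage]
            + 1_009 * def_idx + 101 * size_idx) % (2 ** 31)


@dataclass(frozen=True)
class TraitSpec:
    """A single-trait model layer over the shared pedigree + genotypes."""

    name: str = "trait1"
    h2: float = 0.20
    litter_var_frac: float = 0.10
    pen_var_frac: float = 0.0


@dataclass(frozen=True)
class RunConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    traits: tuple = (TraitSpec(),)
    thresholds: tuple = DEFAULT_THRESHOLDS
    oversize: int | None = None          # absolute core size beyond eigen99
    definitions: tuple = corepick.DEFINITIONS
    master_seed: int = 0
    blend_weight: float = 0.95
    solver_tol: float = 1e-12
    solver_max_iter: int = 5000
    output_dir: str = "apygblup_out"

    def __post_init__(self):
        th = tuple(self.thresholds)
        if any(not 0 < t <= 1 for t in th) or list(th) != sorted(set(th)):
            raise ValueError("thresholds must be strictly increasing in "
                             "(0, 1]")
        bad = set(self.definitions) - set(corepick.DEFINITIONS)
        if bad:
            raise ValueError(f"unknown definitions: {sorted(bad)}")


@dataclass
class TraitContext:
    spec: TraitSpec
    study: SimulatedStudy
    model: mme.ModelSpec
    training_mask: np.ndarray
    validation: evalsuite.ValidationSet
    baseline_full: mme.Solutions        # all records (source of y_adj)
    baseline_trunc: mme.Solutions       # validation records removed
    baseline_accuracy: float
    baseline_mse: float


@dataclass
class StudyContext:
    config: RunConfig
    pedigree: pd.DataFrame
    genotypes: GenotypeMatrix
    A_inv: relmat.RelationshipMatrix
    A22: relmat.RelationshipMatrix
    A22_inv: relmat.RelationshipMatrix
    G_raw: relmat.RelationshipMatrix
    G_blend: relmat.RelationshipMatrix
    sizing: relmat.EigenSizing
    sizes: dict                          # size label -> core count
    traits: dict                         # trait name -> TraitContext

    @property
    def genotyped_ids(self) -> np.ndarray:
        return self.genotypes.ids


@dataclass
class StudyReport:
    config: RunConfig
    metrics: pd.DataFrame
    sizing: relmat.EigenSizing
    sizes: dict
    linkages: dict
    diagnostics: dict
    failures: list


def _training_mask(study: SimulatedStudy, validation_ids) -> np.ndarray:
    return ~study.phenotypes["animal"].isin(validation_ids).to_numpy()


def prepare_study(config: RunConfig) -> StudyContext:
    """Simulate the population and precompute scenario-shared state."""
    sim = config.simulation.replace(seed=scenario_seed(
        config.master_seed, "simulation"))

    # shared pedigree + a single gene drop; trait layers reuse the dosages
    pedigree = simulate_pedigree(sim)
    _, rng_geno, _ = sim._seed_streams()
    full_dosage = _drop_all_haplotypes(pedigree, sim, rng_geno) \
        .sum(axis=1, dtype=np.int8)
    gids_all = pedigree.loc[pedigree["genotyped"], "animal"].to_numpy()
    if len(gids_all) == 0:
        raise ValueError("no animal was flagged genotyped")
    names, chrom, pos = _snp_map(sim)
    genotypes = GenotypeMatrix(gids_all, names, chrom, pos,
                               full_dosage[gids_all - 1],
                               full_dosage[gids_all - 1].mean(axis=0) / 2.0
                               ).drop_monomorphic()

    A = relmat.build_A(pedigree)
    F = np.diag(A.values) - 1.0
    A_inv = relmat.build_A_inverse(pedigree, F)
    gids = genotypes.ids
    idx = gids - 1
    A22 = relmat.RelationshipMatrix(gids, A.values[np.ix_(idx, idx)],
                                    kind="A22")
    A22_inv = relmat.RelationshipMatrix(
        gids, np.linalg.inv(A22.values), kind="A22_inv")
    G_raw = relmat.build_G(genotypes)
    G_blend = relmat.blend_G(G_raw, A22, w=config.blend_weight)
    sizing = relmat.eigen_core_sizes(G_raw, config.thresholds)
    sizes = {f"eigen{int(round(t * 100))}": sizing.sizes[t]
             for t in config.thresholds}
    if config.oversize:
        sizes["oversize"] = min(int(config.oversize), len(gids))

    G_inv_full = apycore.full_g_inverse(G_blend)
    h_inv_full = apycore.build_h_inverse(A_inv, A22_inv, G_inv_full, gids)

    traits = {}
    for t_idx, tspec in enumerate(config.traits):
        t_sim = sim.replace(h2=tspec.h2, litter_var_frac=tspec.litter_var_frac,
                            pen_var_frac=tspec.pen_var_frac,
                            seed=scenario_seed(config.master_seed, "trait",
                                               t_idx))
        study = simulate_phenotypes(pedigree, full_dosage, t_sim)
        study.genotypes = genotypes
        model = mme.ModelSpec.from_simulation(t_sim)
        val_ids = study.validation_ids()
        mask = _training_mask(study, val_ids)

        sol_full = mme.solve_ssgblup(
            study.phenotypes, model, h_inv_full,
            tol=config.solver_tol, max_iter=config.solver_max_iter,
            meta={"definition": "FULL", "run": "full-data"})
        y_adj = evalsuite.adjusted_phenotypes(sol_full, study.phenotypes,
                                              model)
        validation = evalsuite.ValidationSet(val_ids, y_adj,
                                             h=np.sqrt(tspec.h2))
        sol_trunc = mme.solve_ssgblup(
            study.phenotypes, model, h_inv_full, training_mask=mask,
            tol=config.solver_tol, max_iter=config.solver_max_iter,
            meta={"definition": "FULL", "run": "truncated"})
        traits[tspec.name] = TraitContext(
            spec=tspec, study=study, model=model, training_mask=mask,
            validation=validation, baseline_full=sol_full,
            baseline_trunc=sol_trunc,
            baseline_accuracy=evalsuite.prediction_accuracy(
                validation, sol_trunc.u_hat),
            baseline_mse=evalsuite.prediction_mse(
                validation, sol_trunc.u_hat))

    return StudyContext(config=config, pedigree=pedigree,
                        genotypes=genotypes, A_inv=A_inv, A22=A22,
                        A22_inv=A22_inv, G_raw=G_raw, G_blend=G_blend,
                        sizing=sizing, sizes=sizes, traits=traits)


def select_partition(ctx: StudyContext, definition: str, size: int,
                     seed: int) -> corepick.CorePartition:
    spec = corepick.CoreSpec(definition, target_size=size, seed=seed)
    return corepick.select_core(
        spec, ped=ctx.pedigree, phenotypes=None, genotypes=ctx.genotypes,
        G=ctx.G_blend, genotyped_ids=ctx.genotyped_ids)


def run_scenario(ctx: StudyContext, trait: str, definition: str,
                 size_label: str,
                 partition: corepick.CorePartition | None = None) -> dict:
    """Evaluate one (trait, definition, size) cell against the baseline."""
    tctx = ctx.traits[trait]
    cfg = ctx.config
    def_idx = list(corepick.DEFINITIONS).index(definition) \
        if definition in corepick.DEFINITIONS else len(corepick.DEFINITIONS)
    size_idx = list(ctx.sizes).index(size_label) if size_label in ctx.sizes \
        else 0
    if partition is None:
        size = ctx.sizes[size_label]
        seed = scenario_seed(cfg.master_seed, "selection", def_idx, size_idx)
        partition = select_partition(ctx, definition, size, seed)

    apy = apycore.apy_g_inverse(ctx.G_blend, partition)
    h_inv = apycore.build_h_inverse(ctx.A_inv, ctx.A22_inv, apy,
                                    ctx.genotyped_ids)
    sol = mme.solve_ssgblup(
        tctx.study.phenotypes, tctx.model, h_inv,
        training_mask=tctx.training_mask,
        tol=cfg.solver_tol, max_iter=cfg.solver_max_iter,
        meta={"definition": definition, "size_label": size_label,
              "achieved_size": partition.achieved_size})

    acc = evalsuite.prediction_accuracy(tctx.validation, sol.u_hat)
    msev = evalsuite.prediction_mse(tctx.validation, sol.u_hat)
    corr = evalsuite.gebv_correlation(tctx.baseline_trunc.u_hat, sol.u_hat,
                                      ctx.genotyped_ids)
    overlap = evalsuite.maf_overlap(ctx.genotypes, partition).overlap
    gcn = evalsuite.gcn_row_sums(ctx.G_blend, partition)
    return {
        "trait": trait, "definition": definition, "size_label": size_label,
        "target_size": partition.target_size,
        "achieved_size": partition.achieved_size,
        "shortfall": partition.shortfall,
        "accuracy": acc, "mse": msev,
        "gebv_corr_vs_full": corr,
        "maf_overlap": overlap,
        "accuracy_full": tctx.baseline_accuracy,
        "mse_full": tctx.baseline_mse,
        "accuracy_diff": acc - tctx.baseline_accuracy,
        "n_iter": sol.n_iter, "converged": sol.converged,
        "min_mendelian": float(apy.m.min()) if apy.m.size else np.nan,
        "gcn_mean": gcn.attrs["summary"]["mean"],
        "gcn_sd": gcn.attrs["summary"]["sd"],
        "u_hat": sol.u_hat,
    }


def pedigree_baseline(ctx: StudyContext, trait: str) -> dict:
    """Pedigree-only BLUP (H = A) on the same truncated training data,
    scored on the same validation cohort — the no-genomics reference."""
    tctx = ctx.traits[trait]
    h_inv = apycore.pedigree_h_inverse(ctx.A_inv)
    sol = mme.solve_ssgblup(
        tctx.study.phenotypes, tctx.model, h_inv,
        training_mask=tctx.training_mask,
        tol=ctx.config.solver_tol, max_iter=ctx.config.solver_max_iter,
        meta={"definition": "PED_BLUP", "run": "truncated"})
    return {
        "accuracy": evalsuite.prediction_accuracy(tctx.validation, sol.u_hat),
        "mse": evalsuite.prediction_mse(tctx.validation, sol.u_hat),
        "n_iter": sol.n_iter,
        "u_hat": sol.u_hat,
    }


def run_study(config: RunConfig) -> StudyReport:
    """Full factorial: definitions x sizes x traits, plus baseline rows."""
    ctx = prepare_study(config)
    rows = []
    failures = []
    gebv_store: dict = {t: {} for t in ctx.traits}

    for trait, tctx in ctx.traits.items():
        rows.append({
            "trait": trait, "definition": "FULL", "size_label": "full",
            "target_size": len(ctx.genotyped_ids),
            "achieved_size": len(ctx.genotyped_ids), "shortfall": 0,
            "accuracy": tctx.baseline_accuracy, "mse": tctx.baseline_mse,
            "gebv_corr_vs_full": 1.0, "maf_overlap": 1.0,
            "accuracy_full": tctx.baseline_accuracy,
            "mse_full": tctx.baseline_mse, "accuracy_diff": 0.0,
            "n_iter": tctx.baseline_trunc.n_iter,
            "converged": tctx.baseline_trunc.converged,
        })
        gebv_store[trait]["FULL"] = \
            tctx.baseline_trunc.u_hat.loc[ctx.genotyped_ids]

    largest = list(ctx.sizes)[-1] if ctx.sizes else None
    for trait in ctx.traits:
        for definition in config.definitions:
            for size_label in ctx.sizes:
                try:
                    res = run_scenario(ctx, trait, definition, size_label)
                except Exception as exc:  # record, keep factorial intact
                    failures.append({"trait": trait, "definition": definition,
                                     "size_label": size_label,
                                     "error": str(exc)})
                    continue
                u_hat = res.pop("u_hat")
                if size_label == largest:
                    gebv_store[trait][definition] = \
                        u_hat.loc[ctx.genotyped_ids]
                rows.append(res)

    linkages = {}
    for trait, store in gebv_store.items():
        if len(store) >= 2:
            linkages[trait] = evalsuite.ward_linkage(store)

    metrics = pd.DataFrame(rows)
    diagnostics = {
        "n_genotyped": int(len(ctx.genotyped_ids)),
        "n_animals": int(len(ctx.pedigree)),
        "sizes": dict(ctx.sizes),
        "spectrum_trace": float(ctx.sizing.spectrum.sum()),
    }
    return StudyReport(config=config, metrics=metrics, sizing=ctx.sizing,
                       sizes=ctx.sizes, linkages=linkages,
                       diagnostics=diagnostics, failures=failures)


def make_report(report: StudyReport, output_dir=None) -> dict:
    """Write tidy CSV/JSON/Newick outputs; returns the written paths."""
    outdir = Path(output_dir or report.config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    metrics_path = outdir / "metrics.csv"
    report.metrics.to_csv(metrics_path, index=False)
    paths["metrics"] = metrics_path

    tidy = report.metrics.melt(
        id_vars=[c for c in ("trait", "definition", "size_label")
                 if c in report.metrics.columns],
        value_vars=[c for c in ("accuracy", "mse", "gebv_corr_vs_full",
                                "maf_overlap") if c in report.metrics.columns],
        var_name="metric", value_name="value")
    tidy_path = outdir / "metrics_tidy.csv"
    tidy.to_csv(tidy_path, index=False)
    paths["metrics_tidy"] = tidy_path

    meta = {
        "sizes": {k: int(v) for k, v in report.sizes.items()},
        "diagnostics": report.diagnostics,
        "failures": report.failures,
        "master_seed": report.config.master_seed,
        "definitions": list(report.config.definitions),
        "thresholds": list(report.config.thresholds),
        "solver": {"tol": report.config.solver_tol,
                   "max_iter": report.config.solver_max_iter},
    }
    meta_path = outdir / "run_metadata.json"
    meta_path.write_text(json.dumps(meta, indent=2, default=str))
    paths["metadata"] = meta_path

    for trait, linkage in report.linkages.items():
        nwk = outdir / f"dendrogram_{trait}.nwk"
        nwk.write_text(linkage.to_newick() + "\n")
        mt = outdir / f"linkage_{trait}.csv"
        linkage.to_merge_table().to_csv(mt, index=False)
        paths[f"linkage_{trait}"] = mt
        paths[f"newick_{trait}"] = nwk

    if not report.metrics.empty and "accuracy" in report.metrics:
        summary = report.metrics.pivot_table(
            index="definition", columns="size_label", values="accuracy",
            aggfunc="mean")
        print("Prediction accuracy by core definition and size:")
        print(summary.round(3).to_string())
    return paths
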