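"""End-to-end experiment runners chaining the simulators and tests.

Each experiment reproduces one of the package's standard in-silico
studies on purely synthetic data, deterministically per seed.  Results are
returned as plain DataFrames/dicts and, when an output directory is
given, written as TSV/JSON next to the config that produced them (so any
bundle can be reproduced exactly from its own ``config.yaml``).

Available experiments
---------------------
admixture_validation
    Replicated admixed populations; true vs inferred homoplasy.
neutral_vs_observed
    Shared/multiple counts of an admixed population vs the neutral
    tree-placement expectation.
balancing_sweep
    Inferred apparent multiple emergence across a grid of balancing
    fraction and minor-allele frequency.
niche_enrichment
    Same-niche sharing of 2-/3-occurrence variants vs the neutral null.
directional_null
    Coherence test on simulated QTL architectures (null and coherent).
mapping_demo
    Simulated inbred cross: forward selection, fine mapping, permutation
    FDR.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .emergence import compare_true_vs_inferred, genome_scan, neutral_expectation
from .phylo import WindowSpec, neighbor_joining, snp_distance_matrix
from .qtl import (
    append_pseudo_genotypes,
    fine_map_qtn,
    forward_select,
    normalize_phenotypes,
    permutation_fdr,
    PhenotypePanel,
)
from .selection import coherence_vs_distance, niche_null_distribution, niche_sharing_fraction
from .simulate import (
    AdmixtureParams,
    BalancingParams,
    CrossSimParams,
    GenomeModel,
    build_admixed_population,
    overlay_balanced_polymorphisms,
    simulate_f6_cross,
)

__all__ = ["RunConfig", "run_experiment", "EXPERIMENTS"]

DEFAULT_F_GRID = (1e-5, 1e-4, 1e-3, 1e-2, 1e-1)
DEFAULT_MAF_GRID = (2**-5, 2**-4, 2**-3, 2**-2, 2**-1)


@dataclass
class RunConfig:
    """Configuration shared by all experiments.

    ``scale`` multiplies the genome and per-lineage mutation counts by a
    single factor (1.0 = the full study conditions); ``n_reps`` overrides
    each experiment's default replicate count; ``options`` carries
    experiment-specific knobs.  Every stochastic run records its seed.
    """

    seed: int = 0
    window: int = 500
    scale: float = 1.0
    n_reps: int | None = None
    outdir: str | None = None
    options: dict = field(default_factory=dict)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _scaled_setup(cfg: RunConfig) -> tuple[GenomeModel, AdmixtureParams]:
    s = cfg.scale
    genome = GenomeModel.yeast(s)
    ap = AdmixtureParams(
        muts_per_founder=max(1, int(round(30_000 * s))),
        muts_per_strain_post=max(1, int(round(10_000 * s))),
    )
    return genome, ap


def _spawn(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _write(outdir: str | None, name: str, tables: dict, summary: dict, cfg: RunConfig):
    if not outdir:
        return
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.yaml")
    for key, df in tables.items():
        df.to_csv(out / f"{name}_{key}.tsv", sep="\t", index=False, float_format="%.6g")
    with open(out / f"{name}_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)


def admixture_validation(cfg: RunConfig) -> dict:
    n_reps = cfg.n_reps or 25
    genome, ap = _scaled_setup(cfg)
    rows = []
    for rep, rng in enumerate(_spawn(cfg.seed, n_reps)):
        pop = build_admixed_population(ap, genome, rng=rng)
        true, inferred = compare_true_vs_inferred(pop, WindowSpec(cfg.window))
        rows.append({"replicate": rep, "true_homoplasy": true, "inferred_multiple": inferred})
    df = pd.DataFrame(rows)
    summary = {
        "n_reps": n_reps,
        "mean_true": float(df["true_homoplasy"].mean()),
        "mean_inferred": float(df["inferred_multiple"].mean()),
        "inferred_le_true": bool(
            df["inferred_multiple"].mean() <= df["true_homoplasy"].mean()
        ),
    }
    _write(cfg.outdir, "admixture_validation", {"replicates": df}, summary, cfg)
    return {"replicates": df, "summary": summary}


def neutral_vs_observed(cfg: RunConfig) -> dict:
    n_reps = cfg.n_reps or 10
    genome, ap = _scaled_setup(cfg)
    rng_pop, rng_neutral = _spawn(cfg.seed, 2)
    pop = build_admixed_population(ap, genome, rng=rng_pop)
    obs = genome_scan(pop.matrix, WindowSpec(cfg.window))
    tree = neighbor_joining(snp_distance_matrix(pop.matrix))
    neutral = neutral_expectation(
        tree, pop.matrix.n_loci, n_reps, WindowSpec(cfg.window), rng_neutral, genome
    )
    summary = {
        "observed_shared": obs.summary.n_shared,
        "observed_multiple": obs.summary.n_multiple,
        "neutral_shared_mean": neutral.mean_shared,
        "neutral_shared_sd": neutral.sd_shared,
        "neutral_multiple_mean": neutral.mean_multiple,
        "neutral_multiple_sd": neutral.sd_multiple,
    }
    _write(
        cfg.outdir,
        "neutral_vs_observed",
        {"neutral_replicates": neutral.replicates},
        summary,
        cfg,
    )
    return {"neutral": neutral, "observed": obs.summary, "summary": summary}


def balancing_sweep(cfg: RunConfig) -> dict:
    n_reps = cfg.n_reps or 5
    f_grid = tuple(cfg.options.get("f_ancestral", DEFAULT_F_GRID))
    maf_grid = tuple(cfg.options.get("maf_balanced", DEFAULT_MAF_GRID))
    genome, ap = _scaled_setup(cfg)
    rows = []
    for rep, rng in enumerate(_spawn(cfg.seed, n_reps)):
        base = build_admixed_population(ap, genome, rng=rng)
        true_h = base.true_homoplasy_count()
        for f in f_grid:
            for maf in maf_grid:
                pop = overlay_balanced_polymorphisms(
                    base, BalancingParams(f, maf), genome, rng
                )
                res = genome_scan(pop.matrix, WindowSpec(cfg.window))
                rows.append(
                    {
                        "f_ancestral": f,
                        "maf_balanced": maf,
                        "replicate": rep,
                        "n_balanced": int(pop.balanced.sum()),
                        "true_homoplasy": true_h,
                        "inferred_multiple": res.summary.n_multiple,
                        "n_shared": res.summary.n_shared,
                    }
                )
    df = pd.DataFrame(rows)
    agg = (
        df.groupby(["f_ancestral", "maf_balanced"])["inferred_multiple"]
        .agg(["mean", "std"])
        .reset_index()
    )
    summary = {"n_reps": n_reps, "f_grid": list(f_grid), "maf_grid": list(maf_grid)}
    _write(cfg.outdir, "balancing_sweep", {"replicates": df, "mean": agg}, summary, cfg)
    return {"replicates": df, "mean": agg, "summary": summary}


def niche_enrichment(cfg: RunConfig) -> dict:
    n_reps = cfg.n_reps or 50
    n_niches = int(cfg.options.get("n_niches", 4))
    genome, ap = _scaled_setup(cfg)
    rng_pop, rng_lbl, rng_null = _spawn(cfg.seed, 3)
    pop = build_admixed_population(ap, genome, rng=rng_pop)
    strains = pop.matrix.strains
    labels = {
        s: f"niche{rng_lbl.integers(n_niches) + 1}" for s in strains
    }
    tree = neighbor_joining(snp_distance_matrix(pop.matrix))
    observed = {}
    for k in (2, 3):
        observed[k] = niche_sharing_fraction(pop.matrix, labels, k).fraction
    null = niche_null_distribution(
        tree,
        labels,
        n_variants=pop.matrix.n_loci,
        n_reps=n_reps,
        rng=rng_null,
        observed=observed,
    )
    summary = {
        "observed": observed,
        "null_means": null.null_means,
        "p_values": null.p_values,
        "niche_labels": labels,
    }
    _write(cfg.outdir, "niche_enrichment", {"null": null.replicates}, summary, cfg)
    return {"null": null, "summary": summary}


def directional_null(cfg: RunConfig) -> dict:
    n_traits = int(cfg.options.get("n_traits", 7))
    qtls_per_trait = int(cfg.options.get("qtls_per_trait", 28))
    n_markers = int(cfg.options.get("n_markers", 12_054))
    p_same = float(cfg.options.get("p_coherent", 0.8))
    rng_null, rng_coh = _spawn(cfg.seed, 2)

    def architecture(rng, coherent: bool) -> pd.DataFrame:
        rows = []
        for t in range(n_traits):
            idx = np.sort(rng.choice(n_markers, size=qtls_per_trait, replace=False))
            chrom = idx * 16 // n_markers  # markers spread over 16 chromosomes
            if coherent:
                trait_parent = rng.integers(2)
                par = np.where(
                    rng.random(qtls_per_trait) < p_same, trait_parent, 1 - trait_parent
                )
            else:
                par = rng.integers(2, size=qtls_per_trait)
            for i, c, p in zip(idx, chrom, par):
                rows.append(
                    {
                        "trait": f"trait{t + 1}",
                        "chrom": int(c),
                        "marker_index": int(i),
                        "high_parent": "A" if p == 0 else "B",
                    }
                )
        return pd.DataFrame(rows)

    res_null = coherence_vs_distance(architecture(rng_null, False))
    res_coh = coherence_vs_distance(architecture(rng_coh, True))
    summary = {
        "null_pooled_fraction": res_null.pooled_fraction,
        "null_pooled_p": res_null.pooled_p,
        "coherent_pooled_fraction": res_coh.pooled_fraction,
        "coherent_pooled_p": res_coh.pooled_p,
    }
    _write(
        cfg.outdir,
        "directional_null",
        {"null_bins": res_null.per_bin, "coherent_bins": res_coh.per_bin},
        summary,
        cfg,
    )
    return {"null": res_null, "coherent": res_coh, "summary": summary}


def mapping_demo(cfg: RunConfig) -> dict:
    n_perms = int(cfg.options.get("n_perms", 20))
    cp = CrossSimParams(
        n_progeny=int(cfg.options.get("n_progeny", 1125)),
        n_markers=int(cfg.options.get("n_markers", 12_054)),
    )
    rng_sim, rng_perm = _spawn(cfg.seed, 2)
    genome = GenomeModel.yeast()
    matrix, phenotypes, truth = simulate_f6_cross(cp, genome, rng_sim)
    panel = PhenotypePanel(phenotypes)
    y = normalize_phenotypes(panel).reindex(matrix.strains).to_numpy()
    design = append_pseudo_genotypes(matrix, panel)
    model = forward_select(design, y)
    profiles = []
    for mk in model.genetic_terms["marker_index"]:
        prof = fine_map_qtn(model, int(mk), matrix, y, design)
        profiles.append(
            {
                "qtl_marker": int(mk),
                "resolved": prof.resolved,
                "best_marker": prof.best_marker,
                "n_candidates": len(prof.candidates),
                "resolution_width_bp": prof.resolution_width_bp,
            }
        )
    fdr = permutation_fdr(design, y, n_perms=n_perms, rng=rng_perm)
    summary = {
        "planted": truth["qtns"],
        "n_qtls": model.n_qtls,
        "fdr": fdr.fdr,
        "fdr_degenerate": fdr.degenerate,
    }
    tables = {
        "qtls": model.terms,
        "fine_mapping": pd.DataFrame(profiles),
    }
    _write(cfg.outdir, "mapping_demo", tables, summary, cfg)
    return {"model": model, "fine_mapping": pd.DataFrame(profiles), "fdr": fdr, "summary": summary}


EXPERIMENTS = {
    "admixture_validation": admixture_validation,
    "neutral_vs_observed": neutral_vs_observed,
    "balancing_sweep": balancing_sweep,
    "niche_enrichment": niche_enrichment,
    "directional_null": directional_null,
    "mapping_demo": mapping_demo,
}


def run_experiment(name: str, cfg: RunConfig | None = None) -> dict:
    """Run a named experiment; unknown names raise with the option list."""
    if name not in EXPERIMENTS:
        raise ValueError(
            f"unknown experiment {name!r}; options: {', '.join(sorted(EXPERIMENTS))}"
        )
    return EXPERIMENTS[name](cfg or RunConfig())
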