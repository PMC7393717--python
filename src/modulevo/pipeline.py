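"""Configuration-driven orchestration of the full study workflow.

Two analysis tracks mirror the study design:

* ``natural`` — OTU-structured data with a tree ensemble: GPA, allometry
  correction, OTU means, PCA, then any of EMMLi-over-trees, stochastic
  character mapping of the habitat character, PGLS-residual disparity,
  Brownian rate comparisons, and phylogenetic MANOVA.
* ``experimental`` — a single population under two treatments, no phylogeny:
  GPA, allometry correction, PCA, EMMLi on specimen deviations, ordinary
  disparity and MANOVA.

Every output table is plain delimited text with a provenance comment line;
the run manifest records inputs, settings, and the per-stage seeds derived
from the master seed (via ``numpy.random.SeedSequence(master, spawn_key)``),
so identical config + seed reproduces identical bytes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import emmli as emmli_mod
from . import evodyn, morpho, phylo, synthgen

__all__ = ["StudyConfig", "run_study", "make_report", "stage_seed"]

_STAGES = ["simulate", "align", "allometry", "emmli", "simmap",
           "disparity", "rates", "manova", "subsample"]


def stage_seed(master: int, stage: str) -> np.random.SeedSequence:
    """Deterministic per-stage seed: SeedSequence(master, spawn_key=(i,))."""
    return np.random.SeedSequence(master, spawn_key=(_STAGES.index(stage),))


@dataclass
class StudyConfig:
    """Inputs, toggles, and numeric settings of one study run.

    Either ``simulation`` (a SimulationConfig or its field dict) or the
    dataset paths must be supplied.  ``mode`` "natural" requires trees;
    "experimental" forbids the phylogenetic analyses.
    """

    seed: int
    mode: str = "natural"
    landmarks: str | None = None
    landmarks_format: str = "long-table"
    trees: str | None = None
    partitions: list = field(default_factory=list)     # partition file paths
    simulation: object = None
    analyses: dict = field(default_factory=lambda: {
        "emmli": True, "simmap": True, "disparity": True,
        "rates": True, "manova": True, "subsample": False})
    n_perm: int = 1000
    n_sims: int = 1000
    maps_per_tree: int = 1
    mk_structure: str = "ER"
    pcs_for_manova: int = 5
    subsample_target: int | None = None
    subsample_reps: int = 100
    log_size: bool = False

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.mode not in ("natural", "experimental"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if isinstance(self.simulation, dict):
            self.simulation = synthgen.SimulationConfig(**self.simulation)
        phylo_analyses = [a for a in ("simmap", "rates") if self.analyses.get(a)]
        if self.mode == "experimental":
            if self.trees is not None:
                raise ValueError("experimental mode forbids phylogenetic input: "
                                 "remove the trees path")
            if phylo_analyses:
                raise ValueError(
                    f"experimental mode forbids phylogenetic analyses: {phylo_analyses}")
        else:
            if self.trees is None and self.simulation is None:
                raise ValueError("natural mode requires trees (or a simulation)")
        if self.landmarks is None and self.simulation is None:
            raise ValueError("either landmark data or a simulation is required")

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def _provenance(stage: str, cfg: StudyConfig, extra: str = "") -> str:
    return (f"# modulevo {__version__} | stage={stage} | seed={cfg.seed} | "
            f"mode={cfg.mode}{' | ' + extra if extra else ''}\n")


def _write_table(df: pd.DataFrame, path: Path, stage: str, cfg: StudyConfig,
                 extra: str = "") -> None:
    with open(path, "w") as fh:
        fh.write(_provenance(stage, cfg, extra))
        df.to_csv(fh, index=False, float_format="%.12g")


def _partitions_for(cfg: StudyConfig, k: int) -> list:
    """Partition hypotheses: user files if given, otherwise the generating
    partition of the simulation plus a two-module split and the null."""
    if cfg.partitions:
        return [emmli_mod.read_partition(p) for p in cfg.partitions]
    if cfg.simulation is not None and cfg.simulation.n_landmarks == k:
        assign = synthgen.generating_partition(cfg.simulation)
        functional = emmli_mod.PartitionHypothesis(
            name="generating", assignment=tuple(f"M{m + 1}" for m in assign))
    else:
        m = max(2, min(6, k // 8))
        sizes = [k // m] * (m - 1) + [k - (k // m) * (m - 1)]
        functional = emmli_mod.PartitionHypothesis(
            name="blocks", assignment=tuple(np.repeat(
                [f"M{i + 1}" for i in range(m)], sizes)))
    ap = emmli_mod.PartitionHypothesis(
        name="two_block",
        assignment=tuple(["anterior"] * (k // 2) + ["posterior"] * (k - k // 2)))
    null = emmli_mod.PartitionHypothesis(name="null", assignment=tuple(["all"] * k))
    return [functional, ap, null]


def run_study(config: StudyConfig, out_dir) -> dict:
    """Execute the configured workflow and write all result tables.

    Returns a results dict (also the input of :func:`make_report`).  Any
    stage failure aborts with the stage name; the manifest marks the run
    incomplete until the final write succeeds.
    """
    cfg = config
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    manifest = {"version": __version__, "seed": cfg.seed, "mode": cfg.mode,
                "settings": {k: v for k, v in asdict(cfg).items()
                             if k not in ("simulation",)},
                "stage_seeds": {}, "outputs": [], "complete": False}
    if cfg.simulation is not None:
        manifest["settings"]["simulation"] = asdict(cfg.simulation)

    def note_seed(stage):
        ss = stage_seed(cfg.seed, stage)
        manifest["stage_seeds"][stage] = int(ss.generate_state(1)[0] % (2 ** 31))
        return ss

    def emit(df, name, stage, extra=""):
        _write_table(df, out / name, stage, cfg, extra)
        manifest["outputs"].append(name)

    def fail(stage, exc):
        manifest["complete"] = False
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True, default=str))
        raise RuntimeError(f"stage {stage!r} failed on {exc}") from exc

    # ---- inputs -----------------------------------------------------------
    trees = None
    try:
        if cfg.simulation is not None:
            rng = np.random.default_rng(note_seed("simulate"))
            sim = cfg.simulation
            tree = synthgen.simulate_tree(sim, rng=rng)
            dataset = synthgen.simulate_shapes(tree, sim, rng=rng)
            if cfg.mode == "natural":
                trees = synthgen.simulate_tree_sample(tree, sim, rng=rng)
                phylo.write_trees(trees, out / "trees.nwk")
                manifest["outputs"].append("trees.nwk")
            morpho.write_landmarks(dataset, out / "landmarks.csv")
            manifest["outputs"].append("landmarks.csv")
        else:
            dataset = morpho.read_landmarks(cfg.landmarks, cfg.landmarks_format)
            if cfg.trees:
                trees = phylo.read_trees(cfg.trees)
    except Exception as exc:                                # pragma: no cover
        fail("simulate", exc)

    # ---- align + allometry + means + PCA ---------------------------------
    try:
        alignment = morpho.gpa(dataset)
        ss = note_seed("allometry")
        allom = morpho.allometry_anova(alignment, n_perm=cfg.n_perm,
                                       seed=ss, log_size=cfg.log_size)
        emit(pd.DataFrame({"r_squared": [allom.r_squared],
                           "p_value": [allom.p_value],
                           "n_perm": [cfg.n_perm]}),
             "allometry.csv", "allometry")
        residual = allom.residual_dataset
        results["allometry"] = allom
    except Exception as exc:
        fail("allometry", exc)

    pca_res = morpho.pca(residual)
    emit(pd.DataFrame({"component": np.arange(1, len(pca_res.eigenvalues) + 1),
                       "eigenvalue": pca_res.eigenvalues,
                       "percent_variance": pca_res.percent_variance}),
         "pca_variance.csv", "align")
    results["pca"] = pca_res

    # the experimental track analyses individuals; OTU aggregation is the
    # natural track's concern
    has_otus = (cfg.mode == "natural" and dataset.otu is not None
                and len(set(dataset.otu)) > 1)
    if has_otus:
        means = morpho.otu_means(residual)
        means_allom = morpho.otu_means(alignment.dataset)   # retains allometry
        otu_groups = means.habitat
        tip_states = dict(zip(dataset.otu, dataset.habitat))
        scores_by_spec = dict(zip(dataset.specimen_ids,
                                  pca_res.scores[:, :cfg.pcs_for_manova]))
        otu_scores = np.stack([
            np.mean([scores_by_spec[sid]
                     for sid, o in zip(dataset.specimen_ids, dataset.otu)
                     if o == otu], axis=0)
            for otu in means.specimen_ids])
    else:
        means = residual
        otu_groups = dataset.habitat
        otu_scores = pca_res.scores[:, :cfg.pcs_for_manova]

    if trees is not None and has_otus:
        trees = phylo.prune_to(trees, list(means.specimen_ids))
    primary_tree = trees[0] if trees else None
    partitions = _partitions_for(cfg, dataset.n_landmarks)

    # ---- analyses ---------------------------------------------------------
    if cfg.analyses.get("emmli"):
        try:
            if cfg.mode == "natural":
                ens = emmli_mod.emmli_over_trees(means, trees, partitions)
            else:
                ens = emmli_mod.emmli_over_trees(
                    means, [None], partitions, use_pic=False)
            emit(ens.frequency_table(), "emmli_frequencies.csv", "emmli")
            rho_rows = [(pool, i, v) for pool, vs in ens.rho_distributions.items()
                        for i, v in enumerate(vs)]
            emit(pd.DataFrame(rho_rows, columns=["pool", "run", "rho"]),
                 "emmli_rho.csv", "emmli")
            results["emmli"] = ens
        except Exception as exc:
            fail("emmli", exc)

    if cfg.analyses.get("subsample") and cfg.mode == "natural":
        try:
            ss = note_seed("subsample")
            counts = {g: int((otu_groups == g).sum()) for g in set(otu_groups)}
            big = max(counts, key=counts.get)
            # contrasts need >= 4 observations, hence >= 5 OTUs per subset
            target = min(max(cfg.subsample_target or min(counts.values()), 5),
                         counts[big])
            sens = emmli_mod.subsample_sensitivity(
                means, otu_groups, big, target, cfg.subsample_reps,
                trees, partitions, seed=ss)
            emit(sens.frequency_table(), "subsample_frequencies.csv", "subsample")
            results["subsample"] = sens
        except Exception as exc:
            fail("subsample", exc)

    if cfg.analyses.get("simmap") and trees is not None:
        try:
            ss = note_seed("simmap")
            summary = phylo.average_transitions(
                trees, tip_states, n_maps_per_tree=cfg.maps_per_tree,
                structure=cfg.mk_structure, seed=ss)
            emit(pd.DataFrame([summary]), "simmap_transitions.csv", "simmap")
            results["simmap"] = summary
        except Exception as exc:
            fail("simmap", exc)

    if cfg.analyses.get("disparity"):
        try:
            ss = note_seed("disparity")
            if cfg.mode == "natural" and primary_tree is not None:
                disp = evodyn.pgls_residual_disparity(
                    means_allom, means_allom.centroid_sizes, primary_tree,
                    otu_groups, n_perm=cfg.n_perm, seed=ss)
            else:
                disp = evodyn.procrustes_variance(
                    residual, dataset.habitat, n_perm=cfg.n_perm, seed=ss)
            rows = [{"group": g, "pv": v} for g, v in disp.pv.items()]
            emit(pd.DataFrame(rows), "disparity.csv", "disparity")
            pw = [{"group_a": a, "group_b": b, "abs_diff": d,
                   "p_value": disp.p_values[(a, b)]}
                  for (a, b), d in disp.pairwise_diff.items()]
            emit(pd.DataFrame(pw), "disparity_pairwise.csv", "disparity")
            results["disparity"] = disp
        except Exception as exc:
            fail("disparity", exc)

    if cfg.analyses.get("rates") and primary_tree is not None:
        try:
            ss = note_seed("rates")
            rng_seeds = ss.spawn(2)
            rg = evodyn.sigma2_mult_groups(
                primary_tree, means, otu_groups, n_sims=cfg.n_sims,
                seed=rng_seeds[0], tree_sample=trees)
            emit(pd.DataFrame([{"group": g, "sigma2": v,
                                "ci_lo": rg.intervals.get(g, (np.nan, np.nan))[0],
                                "ci_hi": rg.intervals.get(g, (np.nan, np.nan))[1]}
                               for g, v in rg.sigma2.items()]),
                 "rates_groups.csv", "rates",
                 extra=f"ratio={rg.ratio:.6g} p={rg.p_value:.6g}")
            rm = evodyn.sigma2_mult_modules(
                primary_tree, means, partitions[0], n_sims=cfg.n_sims,
                seed=rng_seeds[1], tree_sample=trees)
            emit(pd.DataFrame([{"module": m, "sigma2": v,
                                "ci_lo": rm.intervals.get(m, (np.nan, np.nan))[0],
                                "ci_hi": rm.intervals.get(m, (np.nan, np.nan))[1]}
                               for m, v in rm.sigma2.items()]),
                 "rates_modules.csv", "rates",
                 extra=f"ratio={rm.ratio:.6g} p={rm.p_value:.6g}")
            results["rates_groups"] = rg
            results["rates_modules"] = rm
        except Exception as exc:
            fail("rates", exc)

    if cfg.analyses.get("manova"):
        try:
            ss = note_seed("manova")
            if cfg.mode == "natural" and primary_tree is not None:
                man = evodyn.pmanova(primary_tree, otu_scores, otu_groups,
                                     n_sims=cfg.n_sims, seed=ss,
                                     taxa_order=list(means.specimen_ids))
            else:
                man = evodyn.manova_plain(otu_scores, dataset.habitat)
            emit(pd.DataFrame([{"wilks_lambda": man.wilks_lambda, "F": man.F,
                                "df1": man.df1, "df2": man.df2,
                                "p_value": man.p_value, "mode": man.mode}]),
                 "manova.csv", "manova")
            results["manova"] = man
        except Exception as exc:
            fail("manova", exc)

    report = make_report(results)
    (out / "report.txt").write_text(report)
    manifest["outputs"].append("report.txt")
    manifest["complete"] = True
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True, default=str))
    results["manifest"] = manifest
    return results


def make_report(results: dict) -> str:
    """Human-readable text summary of completed analyses (pure formatting:
    regenerating from the same results is idempotent)."""
    sections = []
    if not any(k in results for k in ("allometry", "emmli", "simmap",
                                      "disparity", "rates_groups",
                                      "rates_modules", "manova")):
        raise ValueError("no completed analyses to report")
    if "allometry" in results:
        a = results["allometry"]
        sections.append("Allometry (shape ~ centroid size)\n"
                        f"  r^2 = {a.r_squared:.4f}   permutation p = {a.p_value:.4g}")
    if "pca" in results:
        pct = results["pca"].percent_variance[:5]
        sections.append("PCA\n  first PCs explain (%): "
                        + ", ".join(f"{v:.2f}" for v in pct))
    if "emmli" in results:
        ens = results["emmli"]
        lines = ["EMMLi model selection (frequency over runs)"]
        for name, fr in sorted(ens.selection_frequency.items(),
                               key=lambda kv: -kv[1]):
            lines.append(f"  {name}: {fr:.2f}")
        comp_counts: dict = {}
        for comps in ens.competitors_within_2:
            for nm in comps:
                comp_counts[nm] = comp_counts.get(nm, 0) + 1
        if comp_counts:
            lines.append("  competitors within 2 AICc of the best model:")
            for nm, c in sorted(comp_counts.items(), key=lambda kv: -kv[1]):
                lines.append(f"    {nm} (in {c}/{len(ens.competitors_within_2)} runs)")
        sections.append("\n".join(lines))
    if "subsample" in results:
        ens = results["subsample"]
        lines = ["Subsampling sensitivity (selection frequency)"]
        for name, fr in sorted(ens.selection_frequency.items(),
                               key=lambda kv: -kv[1]):
            lines.append(f"  {name}: {fr:.2f}")
        sections.append("\n".join(lines))
    if "simmap" in results:
        s = results["simmap"]
        sections.append(
            "Habitat transitions (stochastic character maps)\n"
            f"  mean total = {s['mean_total']:.1f} "
            f"(shallow->deep {s['mean_shallow_to_deep']:.1f}, "
            f"deep->shallow {s['mean_deep_to_shallow']:.1f})")
    if "disparity" in results:
        d = results["disparity"]
        lines = ["Disparity (Procrustes variance)"]
        for g, v in d.pv.items():
            lines.append(f"  {g}: PV = {v:.3e}")
        for (a, b), p in d.p_values.items():
            lines.append(f"  {a} vs {b}: |dPV| = {d.pairwise_diff[(a, b)]:.3e}, "
                         f"p = {p:.3f}")
        sections.append("\n".join(lines))
    for key, label in (("rates_groups", "between habitats"),
                       ("rates_modules", "among modules")):
        if key in results:
            r = results[key]
            lines = [f"Brownian rates {label}"]
            for g, v in r.sigma2.items():
                ci = r.intervals.get(g)
                ci_s = f" (95% CI {ci[0]:.3e}, {ci[1]:.3e})" if ci else ""
                lines.append(f"  {g}: sigma^2 = {v:.3e}{ci_s}")
            lines.append(f"  ratio = {r.ratio:.2f}, p = {r.p_value:.3f}")
            sections.append("\n".join(lines))
    if "manova" in results:
        m = results["manova"]
        sections.append(f"MANOVA ({m.mode})\n"
                        f"  Wilks lambda = {m.wilks_lambda:.4f}, F = {m.F:.2f}, "
                        f"p = {m.p_value:.4g}")
    return "\n\n".join(sections) + "\n"
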