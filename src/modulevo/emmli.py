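"""Maximum-likelihood modularity model selection on landmark correlation
matrices (the EMMLi framework).

Each landmark is one trait: the correlation between two landmarks is the
congruence coefficient of their 3D deviation vectors across observations
(specimens or phylogenetic contrasts), taken in absolute value, so the
correlation matrix carries a single number per landmark pair.  A modularity
model pools the off-diagonal correlations (within modules, between modules,
separately or shared) and scores each pool with a Gaussian likelihood on
Fisher-z-transformed correlations with standard error 1/sqrt(n_obs - 3),
maximizing the pooled correlation rho over the grid {0, 0.01, ..., 0.99}.
Models are compared by AICc with K = (#rho pools) + 1; "model likelihood" is
exp(-dAICc/2) and the "posterior probability" is the Akaike weight.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phylo import pic

__all__ = [
    "PartitionHypothesis",
    "ModelVariant",
    "CorrelationMatrix",
    "EMMLiFit",
    "EnsembleResult",
    "read_partition",
    "write_partition",
    "model_variants",
    "landmark_correlation",
    "count_rho_parameters",
    "fit_emmli",
    "emmli_over_trees",
    "subsample_sensitivity",
    "example_partitions",
]

RHO_GRID = np.round(np.arange(0.0, 1.0, 0.01), 2)      # {0, 0.01, ..., 0.99}


# ---------------------------------------------------------------------------
# model structures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PartitionHypothesis:
    """Named landmark -> module assignment."""

    name: str
    assignment: tuple            # length k, hashable module labels

    def __post_init__(self):
        if len(self.assignment) == 0:
            raise ValueError("empty partition")
        object.__setattr__(self, "assignment", tuple(self.assignment))

    @property
    def modules(self) -> list:
        return list(dict.fromkeys(self.assignment))

    @property
    def n_modules(self) -> int:
        return len(set(self.assignment))

    @property
    def n_landmarks(self) -> int:
        return len(self.assignment)


@dataclass(frozen=True)
class ModelVariant:
    """A partition plus its rho-pooling mode: within/between x sep/same."""

    partition: PartitionHypothesis
    within_mode: str = "sep"     # "sep" | "same"
    between_mode: str = "same"   # "sep" | "same"

    def __post_init__(self):
        for mode in (self.within_mode, self.between_mode):
            if mode not in ("sep", "same"):
                raise ValueError(f"pooling mode must be 'sep' or 'same', got {mode!r}")

    @property
    def name(self) -> str:
        if self.partition.n_modules == 1:
            return f"{self.partition.name}.single.rho"
        return (f"{self.partition.name}.{self.within_mode}.Mod+"
                f"{self.between_mode}.between")


def model_variants(partition: PartitionHypothesis) -> list[ModelVariant]:
    """All pooling variants of a partition (the single-rho null for m = 1)."""
    if partition.n_modules == 1:
        return [ModelVariant(partition, "same", "same")]
    return [ModelVariant(partition, w, b)
            for w in ("sep", "same") for b in ("sep", "same")]


def read_partition(path) -> PartitionHypothesis:
    """Read a delimited partition file (landmark_id, module_label); the
    hypothesis name comes from a leading ``# name: ...`` comment or the stem."""
    name = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") and "name:" in line:
                name = line.split("name:", 1)[1].strip()
                break
            if not line.startswith("#"):
                break
    df = pd.read_csv(path, comment="#")
    df = df.sort_values("landmark_id")
    if not np.array_equal(df["landmark_id"].to_numpy(), np.arange(len(df))):
        raise ValueError("partition file must cover landmark_ids 0..k-1 exactly once")
    from pathlib import Path
    return PartitionHypothesis(name=name or Path(path).stem,
                               assignment=tuple(df["module_label"]))


def write_partition(partition: PartitionHypothesis, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# name: {partition.name}\n")
        fh.write("landmark_id,module_label\n")
        for i, m in enumerate(partition.assignment):
            fh.write(f"{i},{m}\n")


def example_partitions(bone: str = "mandible") -> list[PartitionHypothesis]:
    """Illustrative partition hypotheses for the two bones the pipeline is
    aimed at: a 6-module functional partition of a 109-landmark mandible-like
    configuration, and a 5-module partition of a 45-landmark pharyngeal-jaw-
    like configuration, each with a simple anterior/posterior alternative and
    the no-modularity null.  Module membership uses contiguous landmark
    blocks and is illustrative, not a digitization-scheme replica.
    """
    if bone == "mandible":
        k = 109
        labels = ["tooth_bearing", "lateral_line_canal", "quadrate_articular",
                  "articular_excurvation", "ascending_arm", "retro_articular"]
        sizes = [25, 18, 15, 17, 20, 14]
    elif bone == "pharyngeal":
        k = 45
        labels = ["tooth_plate", "wings", "pci_attachment", "pce_attachment",
                  "ph_attachment"]
        sizes = [14, 11, 7, 7, 6]
    else:
        raise ValueError(f"unknown bone {bone!r}")
    assert sum(sizes) == k
    functional = PartitionHypothesis(
        name=f"{bone}_functional_{len(sizes)}mod",
        assignment=tuple(np.repeat(labels, sizes)))
    ap = PartitionHypothesis(
        name=f"{bone}_anterior_posterior",
        assignment=tuple(["anterior"] * (k // 2) + ["posterior"] * (k - k // 2)))
    null = PartitionHypothesis(name=f"{bone}_null", assignment=tuple(["all"] * k))
    return [functional, ap, null]


# ---------------------------------------------------------------------------
# correlation matrix
# ---------------------------------------------------------------------------

@dataclass
class CorrelationMatrix:
    matrix: np.ndarray        # (k, k), |r| in [0, 1], unit diagonal
    n_obs: int                # observations behind each correlation

    @property
    def n_landmarks(self) -> int:
        return self.matrix.shape[0]


def landmark_correlation(observations: np.ndarray) -> CorrelationMatrix:
    """Congruence-coefficient correlation matrix across observations.

    ``observations`` has shape (n_obs, k, 3): mean-centered deviations
    (contrasts are inherently mean-zero).  The correlation between landmarks
    i and j is |sum_s <u_is, u_js>| / sqrt(sum_s ||u_is||^2 sum_s ||u_js||^2).
    """
    U = np.asarray(observations, dtype=float)
    if U.ndim != 3 or U.shape[2] != 3:
        raise ValueError("observations must have shape (n_obs, k, 3)")
    n_obs, k, _ = U.shape
    if n_obs < 4:
        raise ValueError("need n_obs >= 4 (Fisher-z variance requires n_obs > 3)")
    # gram over observations and axes: V is k x (3 n_obs)
    V = U.transpose(1, 0, 2).reshape(k, -1)
    G = V @ V.T
    norms = np.sqrt(np.diag(G))
    zero = np.flatnonzero(norms == 0)
    if zero.size:
        raise ValueError(f"landmark(s) with zero total deviation: {zero.tolist()}")
    R = np.abs(G) / np.outer(norms, norms)
    np.clip(R, 0.0, 1.0, out=R)
    np.fill_diagonal(R, 1.0)
    return CorrelationMatrix(matrix=R, n_obs=n_obs)


# ---------------------------------------------------------------------------
# likelihood fitting
# ---------------------------------------------------------------------------

@dataclass
class EMMLiFit:
    model: ModelVariant
    rho: dict                    # pool label -> rho-hat
    log_likelihood: float
    K: int
    AICc: float
    dAICc: float = np.nan
    model_likelihood: float = np.nan
    akaike_weight: float = np.nan

    @property
    def name(self) -> str:
        return self.model.name


def count_rho_parameters(model: ModelVariant) -> int:
    """K for AICc: (#rho pools) + 1.

    Pools: m within-module pools if within_mode is "sep" else 1; m(m-1)/2
    between-module pools if between_mode is "sep" else 1.  A one-module
    partition has the single pooled rho (K = 2).
    """
    m = model.partition.n_modules
    if m == 1:
        return 2
    n_within = m if model.within_mode == "sep" else 1
    n_between = m * (m - 1) // 2 if model.between_mode == "sep" else 1
    return n_within + n_between + 1


def _pool_labels(model: ModelVariant) -> tuple[np.ndarray, list]:
    """Pool index for every off-diagonal pair (i < j) plus pool names."""
    assign = np.asarray(model.partition.assignment, dtype=object)
    modules = model.partition.modules
    mod_idx = {m: i for i, m in enumerate(modules)}
    k = len(assign)
    iu, ju = np.triu_indices(k, 1)
    mi = np.array([mod_idx[a] for a in assign])[iu]
    mj = np.array([mod_idx[a] for a in assign])[ju]
    m = len(modules)
    names: list = []
    ids = np.empty(len(iu), dtype=int)
    same = mi == mj
    if model.partition.n_modules == 1:
        names = ["all"]
        ids[:] = 0
        return ids, names
    if model.within_mode == "sep":
        within_id = {w: len(names) + w for w in range(m)}
        names += [f"within.{modules[w]}" for w in range(m)]
    else:
        wid = len(names)
        within_id = {w: wid for w in range(m)}
        names.append("within")
    if model.between_mode == "sep":
        between_id = {}
        for a in range(m):
            for b in range(a + 1, m):
                between_id[(a, b)] = len(names)
                names.append(f"between.{modules[a]}.{modules[b]}")
    else:
        bid = len(names)
        between_id = {(a, b): bid for a in range(m) for b in range(a + 1, m)}
        names.append("between")
    for w, pid in within_id.items():
        ids[same & (mi == w)] = pid
    lo = np.minimum(mi, mj)
    hi = np.maximum(mi, mj)
    for (a, b), pid in between_id.items():
        ids[~same & (lo == a) & (hi == b)] = pid
    return ids, names


def _pool_ml(z_sum, z_sq, counts, se):
    """Exact grid ML per pool from sufficient statistics.

    For pool with Fisher-z values z_i, the Gaussian log-likelihood at pooled
    value zr is -n log(se sqrt(2 pi)) - (sum z^2 - 2 zr sum z + n zr^2)/(2 se^2);
    maximize over the rho grid.
    """
    zgrid = np.arctanh(RHO_GRID)                       # (G,)
    n = counts[:, None]
    const = -counts * np.log(se * np.sqrt(2 * np.pi))
    quad = (z_sq[:, None] - 2 * zgrid[None, :] * z_sum[:, None]
            + n * zgrid[None, :] ** 2) / (2 * se * se)
    ll = const[:, None] - quad                         # (pools, G)
    best = np.argmax(ll, axis=1)
    return RHO_GRID[best], ll[np.arange(len(best)), best]


def fit_emmli(corr: CorrelationMatrix, models: list[ModelVariant]) -> list[EMMLiFit]:
    """Fit every model variant to one correlation matrix and rank by AICc.

    Models with too few unique correlations to support their parameter count
    (n_c <= K + 1) are excluded with a warning.  AICc ties are broken toward
    the smaller K.
    """
    k = corr.n_landmarks
    n_obs = corr.n_obs
    if n_obs <= 3:
        raise ValueError("n_obs must exceed 3")
    se = 1.0 / np.sqrt(n_obs - 3)
    iu, ju = np.triu_indices(k, 1)
    r = corr.matrix[iu, ju]
    z = np.arctanh(np.clip(r, 0.0, 1.0 - 1e-15))
    n_c = len(r)

    fits = []
    for model in models:
        if model.partition.n_landmarks != k:
            raise ValueError(
                f"model {model.name!r} covers {model.partition.n_landmarks} "
                f"landmarks, data has {k}")
        K = count_rho_parameters(model)
        if n_c <= K + 1:
            warnings.warn(f"model {model.name!r} unfittable: "
                          f"n_c={n_c} <= K+1={K + 1}; excluded", stacklevel=2)
            continue
        ids, names = _pool_labels(model)
        npool = len(names)
        counts = np.bincount(ids, minlength=npool).astype(float)
        z_sum = np.bincount(ids, weights=z, minlength=npool)
        z_sq = np.bincount(ids, weights=z * z, minlength=npool)
        occupied = counts > 0
        rho = np.zeros(npool)
        ll_pool = np.zeros(npool)
        rho[occupied], ll_pool[occupied] = _pool_ml(
            z_sum[occupied], z_sq[occupied], counts[occupied], se)
        logL = float(ll_pool.sum())
        aicc = -2 * logL + 2 * K + 2 * K * (K + 1) / (n_c - K - 1)
        fits.append(EMMLiFit(model=model,
                             rho={nm: float(rh) for nm, rh, occ
                                  in zip(names, rho, occupied) if occ},
                             log_likelihood=logL, K=K, AICc=aicc))
    if not fits:
        raise ValueError("no fittable models")
    best_aicc = min(f.AICc for f in fits)
    ties = [f for f in fits if abs(f.AICc - best_aicc) < 1e-12]
    best = min(ties, key=lambda f: f.K)
    for f in fits:
        f.dAICc = f.AICc - best.AICc
    wsum = sum(np.exp(-f.dAICc / 2) for f in fits)
    for f in fits:
        f.model_likelihood = float(np.exp(-f.dAICc / 2))
        f.akaike_weight = f.model_likelihood / wsum
    fits.sort(key=lambda f: (f.AICc, f.K))
    return fits


def fits_table(fits: list[EMMLiFit]) -> pd.DataFrame:
    return pd.DataFrame({
        "model": [f.name for f in fits],
        "K": [f.K for f in fits],
        "logL": [f.log_likelihood for f in fits],
        "AICc": [f.AICc for f in fits],
        "dAICc": [f.dAICc for f in fits],
        "model_likelihood": [f.model_likelihood for f in fits],
        "posterior_probability": [f.akaike_weight for f in fits],
    })


# ---------------------------------------------------------------------------
# ensemble / subsampling analyses
# ---------------------------------------------------------------------------

@dataclass
class EnsembleResult:
    """Aggregated model selection over many runs (trees or subsamples)."""

    selection_frequency: dict          # model name -> fraction of runs best
    rho_distributions: dict            # pool label -> list of rho-hats (best model per run)
    competitors_within_2: list         # per run: names within 2 AICc of best (excl. best)
    best_models: list = field(default_factory=list)   # best model name per run

    @property
    def modal_model(self) -> str:
        return max(self.selection_frequency.items(), key=lambda kv: kv[1])[0]

    def frequency_table(self) -> pd.DataFrame:
        items = sorted(self.selection_frequency.items(),
                       key=lambda kv: -kv[1])
        return pd.DataFrame(items, columns=["model", "frequency"])


def _aggregate(run_fits: list[list[EMMLiFit]]) -> EnsembleResult:
    best_names, comp, rho_dist = [], [], {}
    for fits in run_fits:
        best = fits[0]
        best_names.append(best.name)
        comp.append([f.name for f in fits[1:] if f.dAICc <= 2.0])
        for pool, rho in best.rho.items():
            rho_dist.setdefault(pool, []).append(rho)
    n = len(run_fits)
    freq = {}
    for nm in best_names:
        freq[nm] = freq.get(nm, 0) + 1
    freq = {nm: c / n for nm, c in freq.items()}
    return EnsembleResult(selection_frequency=freq, rho_distributions=rho_dist,
                          competitors_within_2=comp, best_models=best_names)


def _contrast_deviations(otu_shapes, tree) -> np.ndarray:
    """PIC of flattened OTU shapes, reshaped to (n_tips-1, k, 3) deviations."""
    Y = otu_shapes.flat()
    cs = pic(tree, Y, labels=list(otu_shapes.specimen_ids))
    return cs.contrasts.reshape(-1, otu_shapes.n_landmarks, 3)


def emmli_over_trees(otu_shapes, tree_sample, partitions,
                     use_pic: bool = True) -> EnsembleResult:
    """Run EMMLi once per tree on phylogenetic contrasts of the OTU mean
    shapes and aggregate best-model frequencies, within-2-AICc co-selections,
    and pooled-rho distributions.

    With ``use_pic=False`` the OTU shapes are mean-centered and used directly
    (one run per tree is still performed, but the correlation matrix is then
    tree-independent).
    """
    models = []
    for p in partitions:
        models.extend(model_variants(p))
    run_fits = []
    for tree in tree_sample:
        if use_pic:
            U = _contrast_deviations(otu_shapes, tree)
        else:
            X = otu_shapes.coords
            U = X - X.mean(axis=0)
        corr = landmark_correlation(U)
        run_fits.append(fit_emmli(corr, models))
    return _aggregate(run_fits)


def subsample_sensitivity(otu_shapes, group_labels, group, target_n: int,
                          n_reps: int, tree_sample, partitions,
                          seed: int = 0, use_pic: bool = True) -> EnsembleResult:
    """Sensitivity of model selection to sample size: OTUs of ``group`` are
    subsampled without replacement to ``target_n``, ``n_reps`` times, EMMLi
    re-run per subset on a tree cycled from the ensemble (pruned to the
    subset).
    """
    if target_n < 4:
        raise ValueError("target_n must be >= 4 (correlation SE undefined below)")
    labels = np.asarray(group_labels)
    members = [sid for sid, g in zip(otu_shapes.specimen_ids, labels) if g == group]
    if target_n > len(members):
        raise ValueError(f"target_n={target_n} exceeds group size {len(members)}")
    from .phylo import prune_to
    models = []
    for p in partitions:
        models.extend(model_variants(p))
    rng = np.random.default_rng(seed)
    run_fits = []
    sid_index = {sid: i for i, sid in enumerate(otu_shapes.specimen_ids)}
    for rep in range(n_reps):
        chosen = sorted(rng.choice(members, size=target_n, replace=False).tolist())
        tree = tree_sample[rep % len(tree_sample)]
        sub_idx = [sid_index[s] for s in chosen]
        sub = otu_shapes.copy()
        sub.coords = otu_shapes.coords[sub_idx]
        sub.specimen_ids = chosen
        if sub.otu is not None:
            sub.otu = otu_shapes.otu[sub_idx]
        if sub.habitat is not None:
            sub.habitat = otu_shapes.habitat[sub_idx]
        if sub.centroid_sizes is not None:
            sub.centroid_sizes = otu_shapes.centroid_sizes[sub_idx]
        if use_pic:
            ptree = prune_to(tree, chosen)
            U = _contrast_deviations(sub, ptree)
        else:
            U = sub.coords - sub.coords.mean(axis=0)
        corr = landmark_correlation(U)
        run_fits.append(fit_emmli(corr, models))
    return _aggregate(run_fits)
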