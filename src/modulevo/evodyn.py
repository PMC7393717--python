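"""Disparity, multivariate Brownian rate comparison, and (phylogenetic)
MANOVA.

Disparity is Procrustes variance (PV): the mean squared Procrustes distance
of group members from their group mean (denominator n, matching the usual
morphometric convention; ``ddof=1`` is available).  Group differences are
tested by permutation of group labels on |PV_a - PV_b| with the
(b+1)/(m+1) p-value convention.

The multivariate Brownian rate sigma^2_mult of a group is the mean squared
phylogenetically transformed deviation per trait:  residuals from the GLS
ancestral mean are premultiplied by C^{-1/2} and sigma^2_g =
sum_{i in g} ||row_i||^2 / (n_g p).  Rate differences are tested against
parametric-bootstrap nulls that simulate tip data under a single common rate
while preserving the observed among-trait covariance (for the among-module
test, trait variances are equalized to the pooled rate so only the
correlation structure is retained).

The phylogenetic MANOVA computes Wilks' Lambda and Rao's F on PC scores and
draws its null from Brownian simulations with the evolutionary rate matrix
estimated from phylogenetic contrasts of the observed scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .phylo import gls_mean, inv_sqrt_psd, phylo_covariance, pic

__all__ = [
    "DisparityResult",
    "RateResult",
    "ManovaResult",
    "procrustes_variance",
    "pgls_fit",
    "pgls_residual_disparity",
    "sigma2_mult_groups",
    "sigma2_mult_modules",
    "pmanova",
    "manova_plain",
]


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

@dataclass
class DisparityResult:
    pv: dict                      # group -> Procrustes variance
    pairwise_diff: dict           # (a, b) -> |PV_a - PV_b|
    p_values: dict                # (a, b) -> permutation p
    n_permutations: int = 0


@dataclass
class RateResult:
    sigma2: dict                  # group or module -> rate
    ratio: float                  # max/min observed rate ratio
    p_value: float
    pairwise: dict = field(default_factory=dict)    # (a, b) -> (ratio, p)
    intervals: dict = field(default_factory=dict)   # group -> (lo, hi) over ensemble
    interval_method: str = "ensemble percentiles (2.5, 97.5) over the tree sample"


@dataclass
class ManovaResult:
    wilks_lambda: float
    F: float
    df1: float
    df2: float
    p_value: float
    mode: str = "ordinary"        # "ordinary" | "phylogenetic"
    n_sims: int = 0


# ---------------------------------------------------------------------------
# disparity
# ---------------------------------------------------------------------------

def _group_pv(flat: np.ndarray, labels: np.ndarray, groups, ddof: int = 0) -> dict:
    pv = {}
    for g in groups:
        sub = flat[labels == g]
        dev = sub - sub.mean(axis=0)
        denom = len(sub) - ddof
        pv[g] = float((dev ** 2).sum() / denom) if denom > 0 else 0.0
    return pv


def procrustes_variance(shapes, groups, n_perm: int = 1000, seed: int = 0,
                        ddof: int = 0) -> DisparityResult:
    """Per-group Procrustes variance with pairwise permutation tests.

    ``shapes`` is a ShapeDataset or an (n, p) flat matrix; ``groups`` a label
    per specimen.  PV_g = sum_i d^2(x_i, mean_g)/n_g.
    """
    flat = shapes if isinstance(shapes, np.ndarray) else shapes.flat()
    labels = np.asarray(groups)
    if len(labels) != len(flat):
        raise ValueError("groups length does not match specimens")
    uniq = list(dict.fromkeys(labels))
    for g in uniq:
        if (labels == g).sum() < 1:
            raise ValueError(f"empty group {g!r}")
    pv = _group_pv(flat, labels, uniq, ddof)
    pairs = [(a, b) for i, a in enumerate(uniq) for b in uniq[i + 1:]]
    diffs = {(a, b): abs(pv[a] - pv[b]) for a, b in pairs}
    rng = np.random.default_rng(seed)
    counts = {pair: 0 for pair in pairs}
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        pv_p = _group_pv(flat, perm, uniq, ddof)
        for a, b in pairs:
            if abs(pv_p[a] - pv_p[b]) >= diffs[(a, b)] - 1e-15:
                counts[(a, b)] += 1
    pvals = {pair: (c + 1) / (n_perm + 1) for pair, c in counts.items()}
    return DisparityResult(pv=pv, pairwise_diff=diffs, p_values=pvals,
                           n_permutations=n_perm)


def pgls_fit(C: np.ndarray, X: np.ndarray, Y: np.ndarray):
    """GLS coefficients B = (X'C^-1 X)^-1 X'C^-1 Y and residuals Y - XB."""
    Ci_X = np.linalg.solve(C, X)
    XtCiX = X.T @ Ci_X
    if np.linalg.matrix_rank(XtCiX) < XtCiX.shape[0]:
        raise ValueError("singular design in PGLS fit")
    B = np.linalg.solve(XtCiX, Ci_X.T @ Y)
    return B, Y - X @ B


def pgls_residual_disparity(shapes, centroid_sizes, tree, groups,
                            n_perm: int = 1000, seed: int = 0,
                            taxa_order=None) -> DisparityResult:
    """Disparity on residuals of a phylogenetic regression of shape on
    centroid size (shapes here retain their allometric component; size enters
    the model as a covariate, phylogeny as the GLS error covariance).
    """
    flat = shapes if isinstance(shapes, np.ndarray) else shapes.flat()
    ids = taxa_order if taxa_order is not None else (
        list(range(len(flat))) if isinstance(shapes, np.ndarray)
        else list(shapes.specimen_ids))
    C, order = phylo_covariance(tree, taxa_order=ids)
    sizes = np.asarray(centroid_sizes, dtype=float)
    X = np.column_stack([np.ones(len(flat)), sizes])
    _, resid = pgls_fit(C, X, flat)
    return procrustes_variance(resid, groups, n_perm=n_perm, seed=seed)


# ---------------------------------------------------------------------------
# multivariate Brownian rates
# ---------------------------------------------------------------------------

def _phylo_transform(C: np.ndarray):
    """Projector U = C^{-1/2} (I - 1 (1'C^-1 1)^-1 1' C^-1): residuals from
    the GLS mean, whitened by the tree."""
    n = C.shape[0]
    one = np.ones((n, 1))
    Ci1 = np.linalg.solve(C, one)
    P = np.eye(n) - one @ (Ci1.T / (one.T @ Ci1).item())
    return inv_sqrt_psd(C) @ P


def _sim_transformed(P: np.ndarray, Lc: np.ndarray, B: np.ndarray,
                     n_sims: int, rng) -> np.ndarray:
    """n_sims whitened-residual matrices under BM with trait cov B B'."""
    n, p = Lc.shape[0], B.shape[0]
    Z = rng.standard_normal((n_sims, n, B.shape[1]))
    # tip data Lc Z B', then whiten: P (Lc Z B')
    PL = P @ Lc
    return np.einsum("ij,sjk,lk->sil", PL, Z, B)


def _trait_basis(U: np.ndarray, equalize: bool = False,
                 pooled_sigma2: float | None = None) -> np.ndarray:
    """Factor B with B B' = estimated trait covariance of the whitened data.

    ``equalize=True`` rescales every trait variance to ``pooled_sigma2`` so
    the null preserves only the among-trait correlation structure.
    """
    n = U.shape[0]
    S = U.T @ U / n
    if equalize:
        d = np.sqrt(np.diag(S))
        d[d == 0] = 1.0
        corr = S / np.outer(d, d)
        S = pooled_sigma2 * corr
    vals, vecs = np.linalg.eigh(S)
    return vecs * np.sqrt(np.clip(vals, 0.0, None))


def sigma2_mult_groups(tree, otu_shapes, groups, n_sims: int = 1000,
                       seed: int = 0, tree_sample=None,
                       taxa_order=None) -> RateResult:
    """Compare the multivariate Brownian rate between groups of OTUs.

    The null distribution of the max/min rate ratio comes from simulating tip
    data under a common pooled rate with the trait covariance estimated from
    the pooled whitened residuals.  If ``tree_sample`` is given, per-group
    2.5/97.5 rate percentiles across the ensemble are reported.
    """
    flat = otu_shapes if isinstance(otu_shapes, np.ndarray) else otu_shapes.flat()
    ids = taxa_order if taxa_order is not None else (
        list(range(len(flat))) if isinstance(otu_shapes, np.ndarray)
        else list(otu_shapes.specimen_ids))
    labels = np.asarray(groups)
    uniq = list(dict.fromkeys(labels))
    for g in uniq:
        if (labels == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 OTUs")
    C, _ = phylo_covariance(tree, taxa_order=ids)
    P = _phylo_transform(C)
    U = P @ flat
    p = flat.shape[1]
    masks = {g: labels == g for g in uniq}

    def rates_of(Umat):
        return {g: float((Umat[masks[g]] ** 2).sum() / (masks[g].sum() * p))
                for g in uniq}

    sig = rates_of(U)
    vals = np.array(list(sig.values()))
    ratio = float(vals.max() / vals.min())

    # Under the common-rate null the whitened residual rows are iid, so
    # permuting group labels across rows gives an exactly calibrated test
    # whatever the trait dimension.  The ratio depends on rows only through
    # their squared norms, so permutation is O(n) per draw.
    rng = np.random.default_rng(seed)
    row_ss = (U ** 2).sum(axis=1)
    sizes = np.array([masks[g].sum() for g in uniq])
    perm_idx = np.stack([rng.permutation(len(row_ss)) for _ in range(n_sims)])
    perm_ss = row_ss[perm_idx]                               # (n_sims, n)
    bounds = np.cumsum(sizes)[:-1]
    group_rates = np.stack([chunk.sum(axis=1) / (sz * p) for chunk, sz in
                            zip(np.split(perm_ss, bounds, axis=1), sizes)])
    sim_ratio = group_rates.max(axis=0) / group_rates.min(axis=0)
    p_value = float((np.sum(sim_ratio >= ratio - 1e-15) + 1) / (n_sims + 1))

    intervals = {}
    if tree_sample is not None:
        per_tree = {g: [] for g in uniq}
        for t in tree_sample:
            Ct, _ = phylo_covariance(t, taxa_order=ids)
            Ut = _phylo_transform(Ct) @ flat
            for g, v in rates_of(Ut).items():
                per_tree[g].append(v)
        intervals = {g: (float(np.percentile(v, 2.5)),
                         float(np.percentile(v, 97.5)))
                     for g, v in per_tree.items()}
    return RateResult(sigma2=sig, ratio=ratio, p_value=p_value,
                      intervals=intervals)


def sigma2_mult_modules(tree, otu_shapes, partition, n_sims: int = 1000,
                        seed: int = 0, tree_sample=None,
                        taxa_order=None) -> RateResult:
    """Compare the Brownian rate among landmark modules of one bone.

    ``partition`` maps each landmark to a module (array of labels or a
    PartitionHypothesis).  The null simulates all traits under a common rate
    while preserving the observed among-trait correlation structure.
    """
    if hasattr(partition, "assignment"):
        assign = np.asarray(partition.assignment, dtype=object)
    else:
        assign = np.asarray(partition, dtype=object)
    flat = otu_shapes if isinstance(otu_shapes, np.ndarray) else otu_shapes.flat()
    ids = taxa_order if taxa_order is not None else (
        list(range(len(flat))) if isinstance(otu_shapes, np.ndarray)
        else list(otu_shapes.specimen_ids))
    k = len(assign)
    if flat.shape[1] != 3 * k:
        raise ValueError("partition does not cover all landmarks")
    col_mod = np.repeat(assign, 3)
    modules = list(dict.fromkeys(assign))
    C, _ = phylo_covariance(tree, taxa_order=ids)
    P = _phylo_transform(C)
    U = P @ flat
    n = U.shape[0]

    def rates_of(Umat):
        out = {}
        for m in modules:
            cols = col_mod == m
            out[m] = float((Umat[:, cols] ** 2).sum() / (n * cols.sum()))
        return out

    sig = rates_of(U)
    tiny = max(sig.values()) * 1e-12
    active = {m: v for m, v in sig.items() if v > tiny}
    if len(active) < len(sig):
        import warnings
        dead = sorted(set(sig) - set(active))
        warnings.warn(f"modules with zero variance excluded from ratios: {dead}",
                      stacklevel=2)
    vals = np.array(list(active.values()))
    ratio = float(vals.max() / vals.min())

    pooled = float((U ** 2).sum() / (n * flat.shape[1]))
    rng = np.random.default_rng(seed)
    B = _trait_basis(U, equalize=True, pooled_sigma2=pooled)
    Lc = np.linalg.cholesky(C)
    Usim = _sim_transformed(P, Lc, B, n_sims, rng)
    mod_rates = {}
    for m in active:
        cols = col_mod == m
        mod_rates[m] = (Usim[:, :, cols] ** 2).sum(axis=(1, 2)) / (n * cols.sum())
    sim_mat = np.stack(list(mod_rates.values()))    # (M, n_sims)
    sim_ratio = sim_mat.max(axis=0) / sim_mat.min(axis=0)
    p_value = float((np.sum(sim_ratio >= ratio - 1e-15) + 1) / (n_sims + 1))

    pairwise = {}
    mods = list(active)
    for i, a in enumerate(mods):
        for b in mods[i + 1:]:
            obs = max(sig[a], sig[b]) / min(sig[a], sig[b])
            sim_pair = np.maximum(mod_rates[a], mod_rates[b]) / \
                np.minimum(mod_rates[a], mod_rates[b])
            pw_p = float((np.sum(sim_pair >= obs - 1e-15) + 1) / (n_sims + 1))
            pairwise[(a, b)] = (float(obs), pw_p)

    intervals = {}
    if tree_sample is not None:
        per_tree = {m: [] for m in modules}
        for t in tree_sample:
            Ct, _ = phylo_covariance(t, taxa_order=ids)
            Ut = _phylo_transform(Ct) @ flat
            for m, v in rates_of(Ut).items():
                per_tree[m].append(v)
        intervals = {m: (float(np.percentile(v, 2.5)),
                         float(np.percentile(v, 97.5)))
                     for m, v in per_tree.items()}
    return RateResult(sigma2=sig, ratio=ratio, p_value=p_value,
                      pairwise=pairwise, intervals=intervals)


# ---------------------------------------------------------------------------
# MANOVA
# ---------------------------------------------------------------------------

def _wilks_F(X: np.ndarray, labels: np.ndarray):
    """Wilks' Lambda and Rao's F approximation for a one-way design."""
    uniq = list(dict.fromkeys(labels))
    g = len(uniq)
    n, p = X.shape
    if g < 2:
        raise ValueError("need at least 2 groups")
    if g >= n:
        raise ValueError("group count must be smaller than the sample size")
    Xc = X - X.mean(axis=0)
    T = Xc.T @ Xc
    W = np.zeros((p, p))
    for grp in uniq:
        sub = X[labels == grp]
        d = sub - sub.mean(axis=0)
        W += d.T @ d
    sign_w, logdet_w = np.linalg.slogdet(W)
    sign_t, logdet_t = np.linalg.slogdet(T)
    if sign_w <= 0 or sign_t <= 0:
        raise ValueError("singular within-group cross-products: reduce the "
                         "number of variables or add observations")
    lam = float(np.exp(logdet_w - logdet_t))
    q = g - 1
    t = np.sqrt((p * p * q * q - 4) / (p * p + q * q - 5)) \
        if p * p + q * q - 5 > 0 else 1.0
    w = n - g - (p - q + 1) / 2
    df1 = p * q
    df2 = w * t - (p * q - 2) / 2
    lam_t = lam ** (1 / t)
    F = (1 - lam_t) / lam_t * df2 / df1
    return lam, float(F), float(df1), float(df2)


def _batched_wilks_F(X: np.ndarray, labels: np.ndarray):
    """Vectorized Wilks/F over a stack of datasets X (s, n, p)."""
    uniq = list(dict.fromkeys(labels))
    g, (s, n, p) = len(uniq), X.shape
    Xc = X - X.mean(axis=1, keepdims=True)
    T = np.einsum("sni,snj->sij", Xc, Xc)
    W = np.zeros((s, p, p))
    for grp in uniq:
        sub = X[:, labels == grp, :]
        d = sub - sub.mean(axis=1, keepdims=True)
        W += np.einsum("sni,snj->sij", d, d)
    sw, lw = np.linalg.slogdet(W)
    st, lt = np.linalg.slogdet(T)
    lam = np.where((sw > 0) & (st > 0), np.exp(lw - lt), np.nan)
    q = g - 1
    t = np.sqrt((p * p * q * q - 4) / (p * p + q * q - 5)) \
        if p * p + q * q - 5 > 0 else 1.0
    w = n - g - (p - q + 1) / 2
    df1 = p * q
    df2 = w * t - (p * q - 2) / 2
    lam_t = lam ** (1 / t)
    return (1 - lam_t) / lam_t * df2 / df1


def manova_plain(scores: np.ndarray, groups, permute: int = 0,
                 seed: int = 0) -> ManovaResult:
    """Ordinary one-way MANOVA: Wilks' Lambda, Rao's F, p from the F
    distribution (or label permutation when ``permute`` > 0)."""
    X = np.asarray(scores, dtype=float)
    labels = np.asarray(groups)
    uniq = list(dict.fromkeys(labels))
    for grp in uniq:
        if (labels == grp).sum() < 2:
            raise ValueError(f"group {grp!r} has fewer than 2 members")
    lam, F, df1, df2 = _wilks_F(X, labels)
    if permute:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(permute):
            _, Fp, _, _ = _wilks_F(X, rng.permutation(labels))
            if Fp >= F - 1e-15:
                count += 1
        p = (count + 1) / (permute + 1)
    else:
        p = float(stats.f.sf(F, df1, df2))
    return ManovaResult(wilks_lambda=lam, F=F, df1=df1, df2=df2, p_value=p,
                        mode="ordinary", n_sims=permute)


def pmanova(tree, scores: np.ndarray, groups, n_sims: int = 1000,
            seed: int = 0, taxa_order=None) -> ManovaResult:
    """Phylogenetic MANOVA on PC scores.

    The observed Wilks/F statistic is the ordinary one; its null distribution
    is built by simulating ``n_sims`` Brownian datasets on the tree with the
    evolutionary rate matrix estimated from phylogenetic contrasts of the
    observed scores, keeping the group labels fixed.
    """
    X = np.asarray(scores, dtype=float)
    labels = np.asarray(groups)
    if taxa_order is None:
        raise ValueError("taxa_order (row labels of scores) is required")
    lam, F, df1, df2 = _wilks_F(X, labels)
    cs = pic(tree, X, labels=list(taxa_order))
    n_tips = X.shape[0]
    R = cs.contrasts.T @ cs.contrasts / (n_tips - 1)
    C, _ = phylo_covariance(tree, taxa_order=list(taxa_order))
    rng = np.random.default_rng(seed)
    Lc = np.linalg.cholesky(C)
    vals, vecs = np.linalg.eigh(R)
    B = vecs * np.sqrt(np.clip(vals, 0.0, None))
    Z = rng.standard_normal((n_sims, n_tips, X.shape[1]))
    Xsim = np.einsum("ij,sjk,lk->sil", Lc, Z, B)
    Fsim = _batched_wilks_F(Xsim, labels)
    p = float((np.sum(Fsim >= F - 1e-15) + 1) / (n_sims + 1))
    return ManovaResult(wilks_lambda=lam, F=F, df1=df1, df2=df2, p_value=p,
                        mode="phylogenetic", n_sims=n_sims)
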