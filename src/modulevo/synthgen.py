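"""Synthetic data with the statistical structure the downstream analyses
assume: Yule trees, posterior-like tree ensembles, a binary habitat character
evolving under a two-state Markov model, and modular landmark datasets
evolving under block-structured multivariate Brownian motion with allometry
and individual noise.

The defaults emulate the study conditions the pipeline is designed for: 22
OTUs in two habitat classes with 3 individuals each, a 1000-tree ensemble, a
binary habitat character with roughly 11 expected transitions across the
tree, and a 109-landmark configuration (14 fixed + 95 semilandmarks on
curves) partitioned into six modules.

All generators are pure functions of (inputs, seed); one seeded
:class:`numpy.random.Generator` is threaded explicitly through every stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .morpho import ShapeDataset
from .phylo import (STATES, CharacterHistory, TreeTable, tree_table,
                    phylo_covariance, _simulate_path, _segments_from_events)

__all__ = [
    "SimulationConfig",
    "simulate_tree",
    "simulate_tree_sample",
    "simulate_habitat",
    "simulate_shapes",
    "template_configuration",
    "generating_partition",
]


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study.

    Module sizes must sum to the landmark count implied by ``curve_spec``;
    all correlations live in [0, 1); ``sigma2`` is the Brownian rate in
    squared shape units per unit branch length.
    """

    seed: int = 0
    n_otus: int = 22
    birth_rate: float = 1.0
    tree_depth_target: float = 1.0
    n_trees: int = 1000
    branch_jitter_sd: float = 0.1
    # (shallow->deep, deep->shallow) per unit branch length; the default pair
    # yields ~11 expected transition events on the default 22-tip tree
    mk_rates: tuple = (1.35, 1.35)
    module_sizes: tuple = (25, 18, 15, 17, 20, 14)     # sums to 109
    rho_within: tuple = (0.7, 0.7, 0.7, 0.7, 0.7, 0.7)
    rho_between: float = 0.2
    sigma2: float = 1e-4
    allometry_slope: float = 0.15
    n_individuals_per_otu: int = 3
    noise_sd: float = 0.002
    size_log_sd: float = 0.1
    # semilandmark curves: list of (n_semilandmarks_per_curve); fixed
    # landmarks are the curve junctions (one per curve on a closed outline)
    curve_spec: tuple = (7, 7, 7, 7, 7, 7, 7, 7, 7, 7, 7, 6, 6, 6)

    def __post_init__(self):
        if self.n_otus < 3:
            raise ValueError("n_otus must be >= 3")
        if self.birth_rate <= 0:
            raise ValueError("birth_rate must be positive")
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be non-negative")
        if not all(0 <= r < 1 for r in self.rho_within) or not 0 <= self.rho_between < 1:
            raise ValueError("all correlations must lie in [0, 1)")
        if len(self.rho_within) != len(self.module_sizes):
            raise ValueError("rho_within must match module_sizes in length")
        if sum(self.module_sizes) != self.n_landmarks:
            raise ValueError(
                f"module_sizes sum to {sum(self.module_sizes)} but the curve "
                f"spec implies {self.n_landmarks} landmarks")

    @property
    def n_fixed(self) -> int:
        return len(self.curve_spec)

    @property
    def n_landmarks(self) -> int:
        return self.n_fixed + sum(self.curve_spec)


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

def simulate_tree(config: SimulationConfig, rng=None) -> dendropy.Tree:
    """Pure-birth (Yule) tree conditioned on ``n_otus`` tips, rescaled so the
    root-to-tip depth equals ``tree_depth_target``.  Tips are labeled
    OTU_1..OTU_n in random order.
    """
    if config.n_otus < 2:
        raise ValueError("need at least 2 tips")
    if config.birth_rate <= 0:
        raise ValueError("birth_rate must be positive")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_otus
    lam = config.birth_rate
    # forward simulation: waiting time with k lineages ~ Exp(k * lambda);
    # a lineage splits at most once (it is then replaced by its two children)
    split_time: dict[int, float] = {}
    children: dict[int, list] = {0: []}
    created = {0: 0.0}
    active = [0]
    next_id = 1
    now = 0.0
    while len(active) < n:
        k = len(active)
        now += rng.exponential(1.0 / (k * lam))
        parent = active.pop(int(rng.integers(k)))
        split_time[parent] = now
        for _ in range(2):
            created[next_id] = now
            children[next_id] = []
            children[parent].append(next_id)
            active.append(next_id)
            next_id += 1
    now += rng.exponential(1.0 / (n * lam))   # extend tips past the last split

    # node time: split time for internals, `now` for leaves; root at its split
    def node_time(v):
        return split_time[v] if children[v] else now

    root_time = node_time(0)
    scale = config.tree_depth_target / (now - root_time)
    labels = [f"OTU_{i + 1}" for i in range(n)]
    rng.shuffle(labels)
    label_iter = iter(labels)

    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)

    def build(v, dd_node):
        if not children[v]:
            dd_node.taxon = taxa.new_taxon(next(label_iter))
        for c in children[v]:
            ch = dendropy.Node()
            dd_node.add_child(ch)
            ch.edge.length = (node_time(c) - node_time(v)) * scale
            build(c, ch)

    build(0, tree.seed_node)
    tree.seed_node.edge.length = None
    return tree


def simulate_tree_sample(tree: dendropy.Tree, config: SimulationConfig,
                         rng=None) -> list[dendropy.Tree]:
    """Posterior-like ensemble: branch lengths jittered by independent
    mean-one lognormal factors, then re-ultrametricized by proportional
    tip-path rescaling back to the input depth.  ``branch_jitter_sd = 0``
    returns exact copies.
    """
    sd = config.branch_jitter_sd
    if sd < 0:
        raise ValueError("branch_jitter_sd must be >= 0")
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    depth_target = max(lf.distance_from_root() for lf in tree.leaf_node_iter())
    out = []
    for _ in range(config.n_trees):
        t2 = tree.clone(depth=1)
        if sd > 0:
            for edge in t2.preorder_edge_iter():
                if edge.length is not None:
                    edge.length *= float(rng.lognormal(-sd * sd / 2, sd))
            _rescale_tip_paths(t2, depth_target)
        out.append(t2)
    return out


def _rescale_tip_paths(tree: dendropy.Tree, target: float) -> None:
    """Proportional tip-path rescaling: every node depth becomes
    target * depth / (max leaf depth below it), restoring ultrametricity
    while preserving relative node heights along every path."""
    depth = {tree.seed_node: 0.0}
    for nd in tree.preorder_node_iter():
        if nd.parent_node is not None:
            depth[nd] = depth[nd.parent_node] + (nd.edge.length or 0.0)
    max_below = {}
    for nd in tree.postorder_node_iter():
        max_below[nd] = depth[nd] if nd.is_leaf() else \
            max(max_below[c] for c in nd.child_nodes())
    for nd in tree.preorder_node_iter():
        par = nd.parent_node
        if par is None:
            continue
        d_new = target * depth[nd] / max_below[nd]
        p_new = 0.0 if par is tree.seed_node else target * depth[par] / max_below[par]
        nd.edge.length = d_new - p_new


# ---------------------------------------------------------------------------
# habitat character
# ---------------------------------------------------------------------------

def simulate_habitat(tree: dendropy.Tree, config: SimulationConfig, rng=None,
                     root_state: str | int | None = None
                     ) -> tuple[dict, CharacterHistory]:
    """Two-state CTMC simulation of the habitat character down the tree.

    The root state is drawn from the stationary distribution unless
    ``root_state`` is given.  Returns (tip states as label -> "shallow"/"deep",
    exact branch-segment history).
    """
    q01, q10 = config.mk_rates
    if q01 < 0 or q10 < 0 or (q01 == 0 and q10 == 0 and root_state is None):
        raise ValueError("mk_rates must be non-negative and not both zero")
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    tt = tree_table(tree)
    if root_state is None:
        s = q01 + q10
        p_deep = q01 / s if s > 0 else 0.5
        root = int(rng.random() < p_deep)
    else:
        root = STATES.index(root_state) if isinstance(root_state, str) else int(root_state)
    state = np.zeros(tt.n_nodes, dtype=int)
    state[tt.root] = root
    segments = {}
    for i in range(tt.n_nodes - 1, -1, -1):           # preorder
        for c in tt.children[i]:
            t = tt.edge_length[c]
            events = _simulate_path(state[i], t, q01, q10, rng)
            state[c] = events[-1][1] if events else state[i]
            segments[c] = _segments_from_events(state[i], t, events)
    hist = CharacterHistory(segments=segments, tree_table=tt)
    tips = {lab: STATES[state[i]]
            for i, lab in zip(tt.leaf_ids, tt.leaf_labels)}
    return tips, hist


# ---------------------------------------------------------------------------
# landmark template and shapes
# ---------------------------------------------------------------------------

def template_configuration(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Smooth template: fixed landmarks on a closed 3D outline, semilandmarks
    equally spaced on the polyline curve between consecutive fixed landmarks.

    Returns (coords (k, 3), landmark_types, curve_ids).  Landmark order is
    curve-major: fixed landmark of curve c, then its semilandmarks.
    """
    nf = config.n_fixed
    theta = 2 * np.pi * np.arange(nf) / nf
    fixed = np.column_stack([np.cos(theta),
                             0.6 * np.sin(theta),
                             0.25 * np.sin(2 * theta)])
    coords, types, curves = [], [], []
    for c in range(nf):
        a, b = fixed[c], fixed[(c + 1) % nf]
        coords.append(a)
        types.append("fixed")
        curves.append(-1)
        ns = config.curve_spec[c]
        # semilandmarks on a slightly bowed polyline between the fixed pair
        for m in range(1, ns + 1):
            f = m / (ns + 1)
            mid = a + f * (b - a)
            bow = 0.08 * np.sin(np.pi * f)
            normal = np.array([-(b - a)[1], (b - a)[0], 0.3 * (b - a)[2]])
            nn = np.linalg.norm(normal)
            if nn > 0:
                mid = mid + bow * normal / nn
            coords.append(mid)
            types.append("semi")
            curves.append(c)
    coords = np.array(coords)
    coords -= coords.mean(axis=0)
    coords /= np.sqrt((coords ** 2).sum())          # unit centroid size
    return coords, np.array(types), np.array(curves, dtype=int)


def generating_partition(config: SimulationConfig) -> np.ndarray:
    """Landmark -> module assignment (contiguous blocks in landmark order)."""
    return np.repeat(np.arange(len(config.module_sizes)),
                     config.module_sizes)


def _correlation_matrix(config: SimulationConfig) -> np.ndarray:
    """Block landmark correlation matrix: rho_within on the diagonal blocks,
    rho_between elsewhere, unit diagonal.  Positive definiteness is verified
    before any Cholesky use."""
    assign = generating_partition(config)
    k = len(assign)
    R = np.full((k, k), config.rho_between)
    for m, rho in enumerate(config.rho_within):
        idx = assign == m
        R[np.ix_(idx, idx)] = rho
    np.fill_diagonal(R, 1.0)
    try:
        np.linalg.cholesky(R)
    except np.linalg.LinAlgError:
        raise ValueError(
            "landmark correlation matrix is not positive definite for "
            f"rho_within={config.rho_within}, rho_between={config.rho_between}")
    return R


def simulate_shapes(tree: dendropy.Tree, config: SimulationConfig,
                    rng=None) -> ShapeDataset:
    """Modular landmark dataset on a tree.

    OTU mean displacements evolve under multivariate Brownian motion with
    covariance ``sigma2 * (C (x) R)`` applied independently and identically to
    each coordinate axis, where R is the block landmark correlation matrix.
    Individuals add isotropic noise (sd ``noise_sd``) and an allometric
    displacement ``allometry_slope * (log centroid size deviation)`` along a
    fixed unit shape vector.  Habitat labels are attached from a habitat
    simulation on the same tree (same rng stream).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 3)
    template, lm_types, curve_ids = template_configuration(config)
    k = config.n_landmarks
    R = _correlation_matrix(config)
    C, taxa = phylo_covariance(tree)
    n = len(taxa)
    Lc = np.linalg.cholesky(C)
    Lr = np.linalg.cholesky(R)
    sd_scale = np.sqrt(config.sigma2)
    # per-axis matrix-normal draws: n_otus x k displacements
    disp = np.empty((n, k, 3))
    for ax in range(3):
        Z = rng.standard_normal((n, k))
        disp[:, :, ax] = sd_scale * (Lc @ Z @ Lr.T)
    otu_mean = template[None, :, :] + disp

    tips, _ = simulate_habitat(tree, config, rng=rng)

    # fixed allometric shape vector (unit norm in flattened space)
    u = rng.standard_normal(3 * k)
    u /= np.linalg.norm(u)
    u = u.reshape(k, 3)

    n_ind = config.n_individuals_per_otu
    log_sizes = rng.normal(0.0, config.size_log_sd, size=(n, n_ind))
    log_dev = log_sizes - log_sizes.mean()
    coords, ids, otus, habs, sizes = [], [], [], [], []
    for i, otu in enumerate(taxa):
        for j in range(n_ind):
            cfg = (otu_mean[i]
                   + config.allometry_slope * log_dev[i, j] * u
                   + rng.normal(0.0, config.noise_sd, size=(k, 3)))
            coords.append(cfg)
            ids.append(f"{otu}_ind{j + 1}")
            otus.append(otu)
            habs.append(tips[otu])
            sizes.append(float(np.exp(log_sizes[i, j])))
    return ShapeDataset(coords=np.array(coords), specimen_ids=ids,
                        otu=np.array(otus), habitat=np.array(habs),
                        landmark_types=lm_types, curve_ids=curve_ids,
                        centroid_sizes=np.array(sizes))
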