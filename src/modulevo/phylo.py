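"""Phylogenetic machinery: tree I/O and pruning (via dendropy), independent
contrasts, the two-state Mk model, stochastic character mapping, and Brownian
tip simulation.

State convention for the binary habitat character: index 0 = "shallow",
index 1 = "deep".  ``rate_sd`` is the shallow-to-deep transition rate and
``rate_ds`` the deep-to-shallow rate, both per unit branch length.

Trees are consumed, never inferred.  Non-ultrametric input is refused by the
operations that require an ultrametric tree; a proportional rescaler is
available behind an explicit ``approximate=True`` flag for users who accept
the distortion (proper penalized-likelihood dating is out of scope here).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy import optimize

__all__ = [
    "read_trees",
    "write_trees",
    "prune_to",
    "tip_labels",
    "tree_depth",
    "is_ultrametric",
    "make_ultrametric",
    "TreeTable",
    "tree_table",
    "pic",
    "ContrastSet",
    "phylo_covariance",
    "gls_mean",
    "inv_sqrt_psd",
    "MkModel",
    "mk2_loglik",
    "fit_mk2",
    "CharacterHistory",
    "simmap_sample",
    "fitch_parsimony_length",
    "average_transitions",
    "sim_bm_tips",
    "simmap_newick",
]

STATES = ("shallow", "deep")
_RATE_LO, _RATE_HI = 1e-8, 1e3


# ---------------------------------------------------------------------------
# tree I/O (dendropy-backed)
# ---------------------------------------------------------------------------

def read_trees(path, schema: str | None = None) -> list[dendropy.Tree]:
    """Read one or more trees from Newick or NEXUS; schema sniffed if omitted."""
    if schema is None:
        with open(path) as fh:
            head = fh.read(200).lstrip()
        schema = "nexus" if head.upper().startswith("#NEXUS") else "newick"
    tl = dendropy.TreeList.get(path=str(path), schema=schema)
    return list(tl)


def write_trees(trees, path, schema: str = "newick") -> None:
    if isinstance(trees, dendropy.Tree):
        trees = [trees]
    tl = dendropy.TreeList(trees, taxon_namespace=trees[0].taxon_namespace)
    tl.write(path=str(path), schema=schema,
             suppress_rooting=(schema == "newick"))


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


def prune_to(trees, taxa) -> list[dendropy.Tree]:
    """Prune each tree to the given taxa, suppressing the resulting degree-2
    nodes (their branch lengths are summed).  Unknown taxa raise."""
    single = isinstance(trees, dendropy.Tree)
    if single:
        trees = [trees]
    taxa = list(taxa)
    out = []
    for tree in trees:
        have = set(tip_labels(tree))
        missing = [t for t in taxa if t not in have]
        if missing:
            raise ValueError(f"taxa not present in tree: {missing}")
        t2 = tree.clone(depth=1)
        t2.retain_taxa_with_labels(taxa)
        out.append(t2)
    return out[0] if single else out


def tree_depth(tree: dendropy.Tree) -> float:
    return max(lf.distance_from_root() for lf in tree.leaf_node_iter())


def is_ultrametric(tree: dendropy.Tree, rtol: float = 1e-9) -> bool:
    depths = [lf.distance_from_root() for lf in tree.leaf_node_iter()]
    d = max(depths)
    return d > 0 and (d - min(depths)) <= rtol * d


def make_ultrametric(tree: dendropy.Tree, approximate: bool = False) -> dendropy.Tree:
    """Return an ultrametric copy of ``tree``.

    Refuses non-ultrametric input unless ``approximate=True``, in which case
    node depths are rescaled proportionally so every tip sits at the original
    maximum depth.  This is a crude stand-in; proper rate-smoothed dating of
    substitution trees is out of scope.
    """
    t2 = tree.clone(depth=1)
    if is_ultrametric(t2):
        return t2
    if not approximate:
        raise ValueError(
            "tree is not ultrametric; proper dating is out of scope here — "
            "pass approximate=True for a proportional rescaling")
    depth = {t2.seed_node: 0.0}
    for nd in t2.preorder_node_iter():
        if nd.parent_node is not None:
            depth[nd] = depth[nd.parent_node] + (nd.edge.length or 0.0)
    target = max(depth[lf] for lf in t2.leaf_node_iter())
    max_below = {}
    for nd in t2.postorder_node_iter():
        if nd.is_leaf():
            max_below[nd] = depth[nd]
        else:
            max_below[nd] = max(max_below[c] for c in nd.child_nodes())
    newdepth = {nd: (target * depth[nd] / max_below[nd] if max_below[nd] > 0 else 0.0)
                for nd in t2.preorder_node_iter()}
    for nd in t2.preorder_node_iter():
        if nd.parent_node is not None:
            nd.edge.length = newdepth[nd] - newdepth[nd.parent_node]
    return t2


# ---------------------------------------------------------------------------
# flat tree table (fast repeated traversal)
# ---------------------------------------------------------------------------

@dataclass
class TreeTable:
    """Array representation of a rooted tree for fast repeated traversal.

    Nodes are indexed 0..n_nodes-1 in postorder (root last); leaves carry
    taxon labels.  ``children[i]`` lists child indices, ``edge_length[i]`` is
    the branch above node i (0 for the root).
    """

    children: list
    edge_length: np.ndarray
    parent: np.ndarray
    leaf_ids: np.ndarray
    leaf_labels: list
    postorder: np.ndarray
    root: int

    @property
    def n_nodes(self) -> int:
        return len(self.children)

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)


def tree_table(tree: dendropy.Tree) -> TreeTable:
    nodes = list(tree.postorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(nodes)}
    children, parent, lengths = [], [], []
    leaf_ids, leaf_labels = [], []
    for i, nd in enumerate(nodes):
        children.append([index[id(c)] for c in nd.child_nodes()])
        parent.append(index[id(nd.parent_node)] if nd.parent_node is not None else -1)
        lengths.append(nd.edge.length if (nd.parent_node is not None and nd.edge.length) else 0.0)
        if nd.is_leaf():
            leaf_ids.append(i)
            leaf_labels.append(nd.taxon.label)
    return TreeTable(children=children,
                     edge_length=np.array(lengths, dtype=float),
                     parent=np.array(parent, dtype=int),
                     leaf_ids=np.array(leaf_ids, dtype=int),
                     leaf_labels=leaf_labels,
                     postorder=np.arange(len(nodes)),
                     root=len(nodes) - 1)


# ---------------------------------------------------------------------------
# phylogenetic independent contrasts
# ---------------------------------------------------------------------------

@dataclass
class ContrastSet:
    contrasts: np.ndarray          # (n_tips - 1, p) standardized contrasts
    expected_variances: np.ndarray  # (n_tips - 1,)
    node_values: np.ndarray = field(repr=False, default=None)


def pic(tree: dendropy.Tree, traits, labels=None) -> ContrastSet:
    """Felsenstein's phylogenetic independent contrasts.

    ``traits`` is an (n_tips, p) matrix; ``labels`` gives its row order
    (defaults to sorted tip labels).  The tree must be strictly bifurcating.
    Each internal node contributes one standardized contrast
    ``(x_a - x_b) / sqrt(v_a + v_b)`` with the usual branch-length extension
    of ancestral values.
    """
    tt = tree_table(tree)
    X = np.atleast_2d(np.asarray(traits, dtype=float))
    if X.shape[0] == 1 and X.shape[1] == tt.n_leaves and X.shape[0] != tt.n_leaves:
        X = X.T
    if labels is None:
        labels = sorted(tt.leaf_labels)
    row = {lab: i for i, lab in enumerate(labels)}
    missing = [l for l in tt.leaf_labels if l not in row]
    if missing:
        raise ValueError(f"traits missing for tips: {missing}")

    p = X.shape[1]
    val = np.zeros((tt.n_nodes, p))
    var = np.zeros(tt.n_nodes)
    contrasts, variances = [], []
    for i in range(tt.n_nodes):
        ch = tt.children[i]
        if not ch:
            leaf_pos = tt.leaf_ids.tolist().index(i)
            val[i] = X[row[tt.leaf_labels[leaf_pos]]]
            var[i] = tt.edge_length[i]
        else:
            if len(ch) != 2:
                raise ValueError("pic requires a strictly bifurcating tree")
            a, b = ch
            va, vb = var[a], var[b]
            if va + vb <= 0:
                raise ValueError("zero-length terminal pair: contrast undefined")
            contrasts.append((val[a] - val[b]) / np.sqrt(va + vb))
            variances.append(va + vb)
            val[i] = (val[a] / va + val[b] / vb) / (1 / va + 1 / vb) \
                if va > 0 and vb > 0 else (val[a] if vb > 0 else val[b])
            var[i] = tt.edge_length[i] + va * vb / (va + vb)
    return ContrastSet(contrasts=np.array(contrasts),
                       expected_variances=np.array(variances),
                       node_values=val)


# ---------------------------------------------------------------------------
# phylogenetic covariance utilities
# ---------------------------------------------------------------------------

def phylo_covariance(tree: dendropy.Tree, taxa_order=None) -> tuple[np.ndarray, list]:
    """Shared-path-length matrix C (Brownian covariance up to sigma^2).

    Returns (C, taxa_order); ``C[i, j]`` is the root-to-MRCA path length of
    tips i and j, ``C[i, i]`` the root-to-tip depth.
    """
    tt = tree_table(tree)
    if taxa_order is None:
        taxa_order = sorted(tt.leaf_labels)
    pos = {lab: i for i, lab in enumerate(taxa_order)}
    missing = [l for l in tt.leaf_labels if l not in pos]
    if missing:
        raise ValueError(f"taxa_order missing tips: {missing}")
    n = len(taxa_order)
    depth = np.zeros(tt.n_nodes)
    for i in range(tt.n_nodes - 1, -1, -1):
        par = tt.parent[i]
        depth[i] = (depth[par] if par >= 0 else 0.0) + tt.edge_length[i]
    C = np.zeros((n, n))
    below: dict[int, list] = {}
    for i in range(tt.n_nodes):
        ch = tt.children[i]
        if not ch:
            leaf_pos = tt.leaf_ids.tolist().index(i)
            below[i] = [pos[tt.leaf_labels[leaf_pos]]]
            C[below[i][0], below[i][0]] = depth[i]
        else:
            sets = [below.pop(c) for c in ch]
            for a in range(len(sets)):
                for b in range(a + 1, len(sets)):
                    for u in sets[a]:
                        for v in sets[b]:
                            C[u, v] = C[v, u] = depth[i]
            below[i] = [x for s in sets for x in s]
    # PD check: duplicate zero-length tips make C singular
    sign, _ = np.linalg.slogdet(C)
    if sign <= 0:
        raise ValueError("phylogenetic covariance is not positive definite "
                         "(duplicate or zero-length tips?)")
    return C, list(taxa_order)


def gls_mean(C: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """GLS ancestral mean a = (1' C^-1 1)^-1 1' C^-1 Y (row vector, length p)."""
    one = np.ones(C.shape[0])
    w = np.linalg.solve(C, one)
    return (w @ np.atleast_2d(Y.T).T) / (one @ w)


def inv_sqrt_psd(C: np.ndarray) -> np.ndarray:
    """Symmetric inverse square root of a positive-definite matrix."""
    vals, vecs = np.linalg.eigh(C)
    if vals.min() <= 0:
        raise ValueError("matrix is not positive definite")
    return (vecs / np.sqrt(vals)) @ vecs.T


# ---------------------------------------------------------------------------
# two-state Mk model
# ---------------------------------------------------------------------------

@dataclass
class MkModel:
    """Binary-habitat continuous-time Markov model.

    ``rate_sd`` : shallow -> deep rate; ``rate_ds`` : deep -> shallow rate.
    ``structure`` is "ER" (rates constrained equal) or "ARD".
    ``root_prior`` is "stationary", "equal", or a probability pair.
    """

    rate_sd: float
    rate_ds: float
    structure: str = "ER"
    root_prior: object = "stationary"
    log_likelihood: float | None = None
    states: tuple = STATES

    def root_probs(self) -> np.ndarray:
        if isinstance(self.root_prior, str):
            if self.root_prior == "equal":
                return np.array([0.5, 0.5])
            if self.root_prior == "stationary":
                s = self.rate_sd + self.rate_ds
                if s <= 0:
                    return np.array([0.5, 0.5])
                return np.array([self.rate_ds / s, self.rate_sd / s])
            raise ValueError(f"unknown root prior {self.root_prior!r}")
        pr = np.asarray(self.root_prior, dtype=float)
        if pr.shape != (2,) or not np.isclose(pr.sum(), 1.0):
            raise ValueError("root prior must be a probability pair")
        return pr


def _pmat(a: float, b: float, t: float) -> np.ndarray:
    """Transition probabilities for the 2-state chain (closed form)."""
    s = a + b
    if s <= 0 or t <= 0:
        return np.eye(2)
    pi1 = a / s
    pi0 = b / s
    e = np.exp(-s * t)
    return np.array([[pi0 + pi1 * e, pi1 * (1 - e)],
                     [pi0 * (1 - e), pi1 + pi0 * e]])


def _state_indices(tip_states: dict) -> dict:
    out = {}
    for k, v in tip_states.items():
        if isinstance(v, str):
            out[k] = STATES.index(v)
        else:
            out[k] = int(v)
    return out


def _partials(tt: TreeTable, states_idx: dict, a: float, b: float) -> np.ndarray:
    """Postorder conditional likelihoods L[node, state] (tips as indicators)."""
    L = np.ones((tt.n_nodes, 2))
    leaf_set = dict(zip(tt.leaf_ids.tolist(), tt.leaf_labels))
    for i in range(tt.n_nodes):
        ch = tt.children[i]
        if not ch:
            s = states_idx[leaf_set[i]]
            L[i] = 0.0
            L[i, s] = 1.0
        else:
            prod = np.ones(2)
            for c in ch:
                P = _pmat(a, b, tt.edge_length[c])
                prod *= P @ L[c]
            L[i] = prod
    return L


def mk2_loglik(tree, tip_states: dict, rate_sd: float, rate_ds: float,
               root_prior="stationary") -> float:
    """Pruning-algorithm log-likelihood of binary tip states."""
    tt = tree if isinstance(tree, TreeTable) else tree_table(tree)
    L = _partials(tt, _state_indices(tip_states), rate_sd, rate_ds)
    model = MkModel(rate_sd, rate_ds, root_prior=root_prior)
    lik = float(model.root_probs() @ L[tt.root])
    return np.log(lik) if lik > 0 else -np.inf


def fit_mk2(tree, tip_states: dict, structure: str = "ER",
            root_prior="stationary") -> MkModel:
    """Maximum-likelihood Mk rates by bounded optimization of the pruning
    likelihood.  Monomorphic tip states push the rate to the lower bound;
    this is reported with a warning rather than an error.
    """
    tt = tree if isinstance(tree, TreeTable) else tree_table(tree)
    idx = _state_indices(tip_states)
    missing = [l for l in tt.leaf_labels if l not in idx]
    if missing:
        raise ValueError(f"tip states missing for: {missing}")

    def nll_er(logq):
        q = np.exp(logq)
        return -mk2_loglik(tt, idx, q, q, root_prior)

    lo, hi = np.log(_RATE_LO), np.log(_RATE_HI)
    res = optimize.minimize_scalar(nll_er, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-8})
    q_er = float(np.exp(res.x))
    if structure == "ER":
        model = MkModel(q_er, q_er, structure="ER", root_prior=root_prior,
                        log_likelihood=-float(res.fun))
    elif structure == "ARD":
        def nll_ard(v):
            return -mk2_loglik(tt, idx, np.exp(v[0]), np.exp(v[1]), root_prior)

        best = None
        for x0 in ([np.log(q_er)] * 2, [np.log(q_er) - 1, np.log(q_er) + 1]):
            r = optimize.minimize(nll_ard, x0=np.asarray(x0), method="L-BFGS-B",
                                  bounds=[(lo, hi), (lo, hi)])
            if best is None or r.fun < best.fun:
                best = r
        model = MkModel(float(np.exp(best.x[0])), float(np.exp(best.x[1])),
                        structure="ARD", root_prior=root_prior,
                        log_likelihood=-float(best.fun))
    else:
        raise ValueError(f"unknown Mk structure {structure!r}")

    if len(set(idx.values())) == 1 and max(model.rate_sd, model.rate_ds) < 10 * _RATE_LO:
        warnings.warn("monomorphic tip states: rate estimated at the lower bound",
                      stacklevel=2)
    return model


# ---------------------------------------------------------------------------
# stochastic character mapping
# ---------------------------------------------------------------------------

@dataclass
class CharacterHistory:
    """Piecewise-constant state history along every branch.

    ``segments[node_id]`` is the ordered list of ``(t_start, t_end, state)``
    segments of the branch above node ``node_id`` (times measured from the
    parent end).  Segments tile the branch; state changes between adjacent
    segments are the transition events.
    """

    segments: dict
    tree_table: TreeTable = field(repr=False, default=None)
    states: tuple = STATES

    def transition_counts(self) -> tuple[int, int]:
        """(n shallow->deep, n deep->shallow) over the whole tree."""
        n01 = n10 = 0
        for segs in self.segments.values():
            for (_, _, s0), (_, _, s1) in zip(segs, segs[1:]):
                if s0 == 0 and s1 == 1:
                    n01 += 1
                elif s0 == 1 and s1 == 0:
                    n10 += 1
        return n01, n10

    @property
    def n_transitions(self) -> int:
        a, b = self.transition_counts()
        return a + b

    def tip_states(self) -> dict:
        tt = self.tree_table
        out = {}
        for leaf_pos, i in enumerate(tt.leaf_ids):
            segs = self.segments.get(int(i))
            out[tt.leaf_labels[leaf_pos]] = segs[-1][2] if segs else None
        return out


def _simulate_path(start: int, t: float, a: float, b: float, rng) -> list:
    """Unconditioned CTMC path from ``start`` over time t: [(time, new_state)]."""
    events = []
    state = start
    now = 0.0
    rates = (a, b)
    while True:
        r = rates[state]
        if r <= 0:
            break
        now += rng.exponential(1.0 / r)
        if now >= t:
            break
        state = 1 - state
        events.append((now, state))
    return events


def _uniformization_path(i: int, j: int, t: float, a: float, b: float, rng,
                         nmax: int = 500) -> list:
    """Endpoint-conditioned CTMC path via uniformization."""
    s = a + b
    if s <= 0:
        return []
    omega = max(a, b) * 1.05
    Q = np.array([[-a, a], [b, -b]])
    R = np.eye(2) + Q / omega
    # p(n) ∝ Poisson(n; omega t) R^n[i, j]
    Rpow = [np.eye(2)]
    logpois = -omega * t
    weights = [np.exp(logpois) * Rpow[0][i, j]]
    for n in range(1, nmax + 1):
        Rpow.append(Rpow[-1] @ R)
        logpois += np.log(omega * t) - np.log(n)
        weights.append(np.exp(logpois) * Rpow[n][i, j])
        if n > omega * t + 10 and weights[-1] < 1e-14 * sum(weights):
            break
    w = np.array(weights)
    total = w.sum()
    if total <= 0:
        raise RuntimeError("uniformization failed: endpoint pair has zero probability")
    n = int(rng.choice(len(w), p=w / total))
    if n == 0:
        return []
    # sample the uniformized chain states given N = n and endpoints
    chain = [i]
    for m in range(1, n):
        prev = chain[-1]
        probs = np.array([R[prev, x] * Rpow[n - m][x, j] for x in (0, 1)])
        chain.append(int(rng.choice(2, p=probs / probs.sum())))
    chain.append(j)
    times = np.sort(rng.uniform(0.0, t, size=n))
    events = []
    for m in range(1, n + 1):
        if chain[m] != chain[m - 1]:
            events.append((float(times[m - 1]), chain[m]))
    return events


def _sample_branch_path(i: int, j: int, t: float, a: float, b: float, rng,
                        max_attempts: int = 1000) -> list:
    """Endpoint-conditioned path: rejection sampling, uniformization fallback."""
    if t <= 0:
        if i != j:
            raise RuntimeError("zero-length branch cannot change state")
        return []
    for _ in range(max_attempts):
        events = _simulate_path(i, t, a, b, rng)
        end = events[-1][1] if events else i
        if end == j:
            return events
    return _uniformization_path(i, j, t, a, b, rng)


def _segments_from_events(start_state: int, t: float, events: list) -> list:
    segs = []
    prev_t, prev_s = 0.0, start_state
    for ev_t, ev_s in events:
        segs.append((prev_t, ev_t, prev_s))
        prev_t, prev_s = ev_t, ev_s
    segs.append((prev_t, t, prev_s))
    return segs


def simmap_sample(tree, tip_states: dict, model: MkModel, n_maps: int = 1,
                  seed=None, rng=None) -> list[CharacterHistory]:
    """Sample stochastic character maps consistent with the tip states.

    Node states are drawn from their joint conditional distribution given the
    tips (backward sampling from the pruning partials); each branch is then
    filled with an endpoint-conditioned CTMC path.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    tt = tree if isinstance(tree, TreeTable) else tree_table(tree)
    idx = _state_indices(tip_states)
    a, b = model.rate_sd, model.rate_ds
    L = _partials(tt, idx, a, b)
    root_pr = model.root_probs()
    maps = []
    for _ in range(n_maps):
        state = np.zeros(tt.n_nodes, dtype=int)
        w = root_pr * L[tt.root]
        if w.sum() <= 0:
            raise ValueError("tip states have zero likelihood under the model")
        state[tt.root] = rng.choice(2, p=w / w.sum())
        segments = {}
        for i in range(tt.n_nodes - 1, -1, -1):   # preorder (root last in postorder)
            for c in tt.children[i]:
                P = _pmat(a, b, tt.edge_length[c])
                wc = P[state[i]] * L[c]
                state[c] = rng.choice(2, p=wc / wc.sum())
                events = _sample_branch_path(state[i], state[c],
                                             tt.edge_length[c], a, b, rng)
                segments[c] = _segments_from_events(state[i], tt.edge_length[c],
                                                    events)
        maps.append(CharacterHistory(segments=segments, tree_table=tt))
    return maps


def fitch_parsimony_length(tree, tip_states: dict) -> int:
    """Fitch parsimony minimum number of changes for binary tip states."""
    tt = tree if isinstance(tree, TreeTable) else tree_table(tree)
    idx = _state_indices(tip_states)
    leaf_set = dict(zip(tt.leaf_ids.tolist(), tt.leaf_labels))
    sets = [None] * tt.n_nodes
    changes = 0
    for i in range(tt.n_nodes):
        ch = tt.children[i]
        if not ch:
            sets[i] = {idx[leaf_set[i]]}
        else:
            inter = set.intersection(*(sets[c] for c in ch))
            if inter:
                sets[i] = inter
            else:
                sets[i] = set.union(*(sets[c] for c in ch))
                changes += 1
    return changes


def average_transitions(trees, tip_states: dict, n_maps_per_tree: int = 1,
                        structure: str = "ER", root_prior="stationary",
                        seed=None) -> dict:
    """Fit an Mk model per tree, sample maps, and average directional counts.

    Returns mean total / shallow-to-deep / deep-to-shallow transition counts
    over all maps and trees, plus 2.5/50/97.5 percentiles of the totals.
    """
    if isinstance(trees, dendropy.Tree):
        trees = [trees]
    rng = np.random.default_rng(seed)
    n01s, n10s = [], []
    for tree in trees:
        tt = tree_table(tree)
        model = fit_mk2(tt, tip_states, structure=structure, root_prior=root_prior)
        for hist in simmap_sample(tt, tip_states, model,
                                  n_maps=n_maps_per_tree, rng=rng):
            a, b = hist.transition_counts()
            n01s.append(a)
            n10s.append(b)
    n01s, n10s = np.array(n01s), np.array(n10s)
    totals = n01s + n10s
    return {
        "mean_total": float(totals.mean()),
        "mean_shallow_to_deep": float(n01s.mean()),
        "mean_deep_to_shallow": float(n10s.mean()),
        "quantiles_total": [float(q) for q in
                            np.percentile(totals, [2.5, 50, 97.5])],
        "n_maps": int(len(totals)),
    }


def simmap_newick(tree: dendropy.Tree, history: CharacterHistory) -> str:
    """Newick string with SIMMAP-style {state,time:state,time} branch comments."""
    tt = history.tree_table

    def annot(node_id):
        segs = history.segments.get(node_id, [])
        parts = [f"{STATES[s]},{t1 - t0:g}" for (t0, t1, s) in segs]
        return "{" + ":".join(parts) + "}" if parts else ""

    nodes = list(tree.postorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(nodes)}

    def render(nd):
        i = index[id(nd)]
        if nd.is_leaf():
            core = nd.taxon.label.replace(" ", "_")
        else:
            core = "(" + ",".join(render(c) for c in nd.child_nodes()) + ")"
        if nd.parent_node is None:
            return core
        return f"{core}:{nd.edge.length or 0.0:g}{annot(i)}"

    return render(tree.seed_node) + ";"


# ---------------------------------------------------------------------------
# Brownian tip simulation
# ---------------------------------------------------------------------------

def sim_bm_tips(tree_or_C, rate_matrix: np.ndarray, n_sims: int = 1,
                seed=None, rng=None, taxa_order=None,
                root: np.ndarray | None = None) -> np.ndarray:
    """Simulate tip trait matrices under multivariate Brownian motion.

    Draws from the matrix normal with row covariance C (shared path lengths)
    and column covariance ``rate_matrix`` (symmetric PSD).  Returns an array
    of shape ``(n_sims, n_tips, p)``.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if isinstance(tree_or_C, dendropy.Tree):
        C, taxa_order = phylo_covariance(tree_or_C, taxa_order)
    else:
        C = np.asarray(tree_or_C, dtype=float)
    R = np.atleast_2d(np.asarray(rate_matrix, dtype=float))
    if not np.allclose(R, R.T, atol=1e-10):
        raise ValueError("rate matrix must be symmetric")
    n, p = C.shape[0], R.shape[0]
    Lc = np.linalg.cholesky(C)
    vals, vecs = np.linalg.eigh(R)
    if vals.min() < -1e-10 * max(vals.max(), 1.0):
        raise ValueError("rate matrix must be positive semi-definite")
    B = vecs * np.sqrt(np.clip(vals, 0.0, None))      # R = B B'
    Z = rng.standard_normal((n_sims, n, p))
    X = np.einsum("ij,sjk,lk->sil", Lc, Z, B)
    if root is not None:
        X = X + np.asarray(root, dtype=float)
    return X
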