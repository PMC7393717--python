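"""Geometric morphometrics: landmark I/O, semilandmark resampling, generalized
Procrustes analysis, allometry correction, OTU means, and PCA.

The shape container is a :class:`ShapeDataset` — an ``(n_specimens, k, 3)``
coordinate block plus per-specimen metadata (OTU, habitat, centroid size) and
per-landmark metadata (fixed/semi flag, curve membership).  Landmark order is
fixed across a dataset; every operation preserves it.

Conventions
-----------
* GPA scales every configuration to unit centroid size (full Procrustes);
  rotations exclude reflections (the SVD rotation is forced to determinant +1).
* Semilandmarks are resampled equidistantly along their polyline curve and
  thereafter treated as fixed points — no bending-energy sliding is performed.
* The allometry regression uses raw centroid size by default (``log_size=True``
  switches to log size); permutation p-values follow the (b+1)/(m+1) convention.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ShapeDataset",
    "AlignmentResult",
    "AllometryResult",
    "PCAResult",
    "read_landmarks",
    "write_landmarks",
    "resample_curve",
    "centroid_size",
    "gpa",
    "procrustes_distance",
    "allometry_anova",
    "otu_means",
    "pca",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ShapeDataset:
    """Specimens x landmarks x 3 coordinates with specimen and landmark metadata.

    Attributes
    ----------
    coords : ndarray, shape (n, k, 3)
    specimen_ids : list of str
    otu : ndarray of str or None
        OTU label per specimen.
    habitat : ndarray of str or None
        Habitat / treatment label per specimen.
    landmark_types : ndarray of str, shape (k,)
        ``"fixed"`` or ``"semi"`` per landmark.
    curve_ids : ndarray of int, shape (k,)
        Curve membership for semilandmarks, ``-1`` for fixed landmarks.
    centroid_sizes : ndarray or None
        Original centroid sizes (populated by :func:`gpa`).
    aligned : bool
        Whether coordinates are Procrustes-aligned.
    """

    coords: np.ndarray
    specimen_ids: list
    otu: np.ndarray | None = None
    habitat: np.ndarray | None = None
    landmark_types: np.ndarray = None
    curve_ids: np.ndarray = None
    centroid_sizes: np.ndarray | None = None
    aligned: bool = False

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_specimens, k, 3)")
        n, k, _ = self.coords.shape
        if len(self.specimen_ids) != n:
            raise ValueError("specimen_ids length does not match coords")
        if self.landmark_types is None:
            self.landmark_types = np.array(["fixed"] * k)
        else:
            self.landmark_types = np.asarray(self.landmark_types)
        if self.curve_ids is None:
            self.curve_ids = np.full(k, -1, dtype=int)
        else:
            self.curve_ids = np.asarray(self.curve_ids, dtype=int)
        if self.otu is not None:
            self.otu = np.asarray(self.otu)
        if self.habitat is not None:
            self.habitat = np.asarray(self.habitat)
        if self.centroid_sizes is not None:
            self.centroid_sizes = np.asarray(self.centroid_sizes, dtype=float)

    @property
    def n_specimens(self) -> int:
        return self.coords.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.coords.shape[1]

    def flat(self) -> np.ndarray:
        """Coordinates flattened to (n, 3k), landmark-major (x1 y1 z1 x2 ...)."""
        n = self.n_specimens
        return self.coords.reshape(n, -1)

    def copy(self) -> "ShapeDataset":
        return replace(
            self,
            coords=self.coords.copy(),
            specimen_ids=list(self.specimen_ids),
            otu=None if self.otu is None else self.otu.copy(),
            habitat=None if self.habitat is None else self.habitat.copy(),
            landmark_types=self.landmark_types.copy(),
            curve_ids=self.curve_ids.copy(),
            centroid_sizes=None if self.centroid_sizes is None else self.centroid_sizes.copy(),
        )


@dataclass
class AlignmentResult:
    """Output of generalized Procrustes analysis."""

    dataset: ShapeDataset          # aligned copy (coords at unit centroid size)
    consensus: np.ndarray          # (k, 3) mean shape, unit centroid size
    centroid_sizes: np.ndarray     # (n,) original centroid sizes
    converged: bool
    iterations: int

    @property
    def aligned(self) -> np.ndarray:
        return self.dataset.coords


@dataclass
class AllometryResult:
    """Shape-on-size regression: r^2, permutation p, and residual shapes."""

    r_squared: float
    p_value: float
    residual_dataset: ShapeDataset
    coefficients: np.ndarray = field(repr=False, default=None)
    n_permutations: int = 0


@dataclass
class PCAResult:
    scores: np.ndarray           # (n, n_components)
    eigenvalues: np.ndarray      # descending, length n_components
    percent_variance: np.ndarray
    loadings: np.ndarray         # (n_components, 3k)
    mean: np.ndarray             # (3k,)


# ---------------------------------------------------------------------------
# I/O: long-table and TPS dialect
# ---------------------------------------------------------------------------

_LONG_COLUMNS = ["specimen_id", "otu", "habitat", "landmark_id",
                 "type", "curve_id", "x", "y", "z"]


def write_landmarks(dataset: ShapeDataset, path, format: str = "long-table") -> None:
    """Write a dataset as long-format delimited text or a TPS dialect."""
    if format == "long-table":
        _write_long(dataset, path)
    elif format == "TPS":
        _write_tps(dataset, path)
    else:
        raise ValueError(f"unknown landmark format: {format!r}")


def read_landmarks(path, format: str = "long-table") -> ShapeDataset:
    """Read a dataset written by :func:`write_landmarks`.

    The long-table reader canonicalizes row order (specimens by first
    appearance, landmarks by landmark_id), so shuffled rows round-trip to the
    same dataset.
    """
    if format == "long-table":
        return _read_long(path)
    if format == "TPS":
        return _read_tps(path)
    raise ValueError(f"unknown landmark format: {format!r}")


def _write_long(dataset: ShapeDataset, path) -> None:
    n, k, _ = dataset.coords.shape
    otu = dataset.otu if dataset.otu is not None else np.array([""] * n)
    hab = dataset.habitat if dataset.habitat is not None else np.array([""] * n)
    rows = {
        "specimen_id": np.repeat(dataset.specimen_ids, k),
        "otu": np.repeat(otu, k),
        "habitat": np.repeat(hab, k),
        "landmark_id": np.tile(np.arange(k), n),
        "type": np.tile(dataset.landmark_types, n),
        "curve_id": np.tile(dataset.curve_ids, n),
        "x": dataset.coords[:, :, 0].ravel(),
        "y": dataset.coords[:, :, 1].ravel(),
        "z": dataset.coords[:, :, 2].ravel(),
    }
    pd.DataFrame(rows, columns=_LONG_COLUMNS).to_csv(path, index=False,
                                                     float_format="%.17g")


def _read_long(path) -> ShapeDataset:
    df = pd.read_csv(path, comment="#",
                     dtype={"specimen_id": str, "otu": str, "habitat": str})
    missing = set(_LONG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"long-table file missing columns: {sorted(missing)}")
    # canonical order: specimens by first appearance, landmarks by id
    spec_order = list(dict.fromkeys(df["specimen_id"]))
    df = df.sort_values("landmark_id", kind="stable")
    groups = dict(list(df.groupby("specimen_id", sort=False)))
    k_ref = None
    coords, otus, habs = [], [], []
    for sid in spec_order:
        g = groups[sid]
        if k_ref is None:
            k_ref = len(g)
            lm_types = g["type"].to_numpy()
            curve_ids = g["curve_id"].to_numpy(dtype=int)
        elif len(g) != k_ref:
            raise ValueError(
                f"specimen {sid!r} has {len(g)} landmarks, expected {k_ref}")
        coords.append(g[["x", "y", "z"]].to_numpy())
        otus.append("" if pd.isna(g["otu"].iloc[0]) else g["otu"].iloc[0])
        habs.append("" if pd.isna(g["habitat"].iloc[0]) else g["habitat"].iloc[0])
    return ShapeDataset(
        coords=np.stack(coords),
        specimen_ids=spec_order,
        otu=np.array(otus),
        habitat=np.array(habs),
        landmark_types=lm_types,
        curve_ids=curve_ids,
    )


def _write_tps(dataset: ShapeDataset, path) -> None:
    buf = io.StringIO()
    k = dataset.n_landmarks
    for i, sid in enumerate(dataset.specimen_ids):
        buf.write(f"LM3={k}\n")
        for x, y, z in dataset.coords[i]:
            buf.write(f"{x:.17g} {y:.17g} {z:.17g}\n")
        buf.write(f"ID={sid}\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def _read_tps(path) -> ShapeDataset:
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    coords, ids = [], []
    i = 0
    while i < len(lines):
        if not lines[i].upper().startswith("LM3="):
            raise ValueError(f"expected LM3= record at line {i + 1}")
        k = int(lines[i].split("=", 1)[1])
        block = []
        i += 1
        while i < len(lines) and not lines[i].upper().startswith(("LM3=", "ID=")):
            block.append([float(v) for v in lines[i].split()])
            i += 1
        rec_id = f"record_{len(ids) + 1}"
        if i < len(lines) and lines[i].upper().startswith("ID="):
            rec_id = lines[i].split("=", 1)[1]
            i += 1
        if len(block) != k:
            raise ValueError(
                f"TPS record {rec_id!r}: LM3={k} but {len(block)} coordinate rows")
        coords.append(np.array(block))
        ids.append(rec_id)
    if not coords:
        raise ValueError("empty TPS file")
    ks = {c.shape[0] for c in coords}
    if len(ks) > 1:
        raise ValueError(f"inconsistent landmark counts across TPS records: {sorted(ks)}")
    return ShapeDataset(coords=np.stack(coords), specimen_ids=ids)


# ---------------------------------------------------------------------------
# semilandmark resampling
# ---------------------------------------------------------------------------

def resample_curve(points: np.ndarray, k: int) -> np.ndarray:
    """Resample a 3D polyline into ``k`` points equidistant in arc length.

    Endpoints are preserved exactly; interior points lie on the polyline and
    are separated by equal arc-length steps of ``total_length / (k - 1)``.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or len(pts) < 2:
        raise ValueError("polyline must contain at least 2 points")
    if k < 2:
        raise ValueError("k must be at least 2")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    total = seg.sum()
    if total <= 0:
        raise ValueError("zero-length curve cannot be resampled")
    s = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, total, k)
    out = np.column_stack([np.interp(targets, s, pts[:, d]) for d in range(pts.shape[1])])
    out[0] = pts[0]
    out[-1] = pts[-1]
    return out


# ---------------------------------------------------------------------------
# Procrustes
# ---------------------------------------------------------------------------

def centroid_size(config: np.ndarray) -> float:
    """sqrt of summed squared distances of landmarks from their centroid."""
    c = np.asarray(config, dtype=float)
    dev = c - c.mean(axis=0)
    return float(np.sqrt((dev ** 2).sum()))


def _optimal_rotation(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rotation R (det +1) minimizing ||source @ R - target||_F."""
    u, _, vt = np.linalg.svd(source.T @ target)
    d = np.sign(np.linalg.det(u @ vt))
    s = np.ones(u.shape[1])
    s[-1] = d
    return (u * s) @ vt


def gpa(dataset: ShapeDataset, tol: float = 1e-10, max_iter: int = 100) -> AlignmentResult:
    """Generalized Procrustes analysis: center, scale to unit centroid size,
    iteratively rotate to the evolving consensus.

    Raises on degenerate configurations (all landmarks coincident).
    """
    X = dataset.coords
    n, k, _ = X.shape
    if n < 2:
        raise ValueError("GPA requires at least 2 specimens")
    if k < 3:
        raise ValueError("GPA requires at least 3 landmarks")
    centered = X - X.mean(axis=1, keepdims=True)
    sizes = np.sqrt((centered ** 2).sum(axis=(1, 2)))
    if np.any(sizes <= 0):
        bad = dataset.specimen_ids[int(np.argmin(sizes))]
        raise ValueError(f"degenerate configuration (zero centroid size): {bad!r}")
    shapes = centered / sizes[:, None, None]

    consensus = shapes[0].copy()
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        for i in range(n):
            shapes[i] = shapes[i] @ _optimal_rotation(shapes[i], consensus)
        new_consensus = shapes.mean(axis=0)
        new_consensus -= new_consensus.mean(axis=0)
        cs = np.sqrt((new_consensus ** 2).sum())
        new_consensus /= cs
        if np.sqrt(((new_consensus - consensus) ** 2).sum()) < tol:
            consensus = new_consensus
            converged = True
            break
        consensus = new_consensus

    out = dataset.copy()
    out.coords = shapes
    out.centroid_sizes = sizes
    out.aligned = True
    return AlignmentResult(dataset=out, consensus=consensus,
                           centroid_sizes=sizes, converged=converged,
                           iterations=iterations)


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Partial Procrustes distance between two configurations: each is
    centered and scaled to unit centroid size, b is optimally rotated onto a.
    """
    a = np.asarray(a, float) - np.asarray(a, float).mean(axis=0)
    b = np.asarray(b, float) - np.asarray(b, float).mean(axis=0)
    a = a / np.sqrt((a ** 2).sum())
    b = b / np.sqrt((b ** 2).sum())
    b = b @ _optimal_rotation(b, a)
    return float(np.sqrt(((a - b) ** 2).sum()))


# ---------------------------------------------------------------------------
# allometry
# ---------------------------------------------------------------------------

def allometry_anova(alignment, centroid_sizes=None, n_perm: int = 1000,
                    seed: int = 0, log_size: bool = False) -> AllometryResult:
    """Multivariate regression of aligned shape on centroid size.

    r^2 = SS_model / SS_total over all flattened coordinates; the p-value
    permutes the size vector (``(b+1)/(m+1)`` convention).  The residual
    dataset is residuals + consensus, i.e. allometry-corrected shapes.
    """
    if isinstance(alignment, AlignmentResult):
        dataset = alignment.dataset
        if centroid_sizes is None:
            centroid_sizes = alignment.centroid_sizes
    else:
        dataset = alignment
    if centroid_sizes is None:
        centroid_sizes = dataset.centroid_sizes
    if centroid_sizes is None:
        raise ValueError("centroid sizes are required for the allometry regression")
    sizes = np.asarray(centroid_sizes, dtype=float)
    if np.any(sizes <= 0):
        raise ValueError("centroid sizes must be strictly positive")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    s = np.log(sizes) if log_size else sizes
    if np.allclose(s, s[0]):
        raise ValueError("size vector is constant: allometry r^2 undefined")

    Y = dataset.flat()
    Yc = Y - Y.mean(axis=0)
    sc = s - s.mean()
    ss_s = float(sc @ sc)
    beta = (sc @ Yc) / ss_s                       # (3k,)
    fitted = np.outer(sc, beta)
    ss_total = float((Yc ** 2).sum())
    ss_model = float((fitted ** 2).sum())
    r2 = ss_model / ss_total

    rng = np.random.default_rng(seed)
    # r^2 under a permuted size vector: ||Yc^T s_pi||^2 / (||s_pi||^2 SS_tot)
    count = 0
    for _ in range(n_perm):
        sp = rng.permutation(sc)
        ss_m = float(((sp @ Yc) ** 2).sum()) / ss_s
        if ss_m / ss_total >= r2 - 1e-15:
            count += 1
    p = (count + 1) / (n_perm + 1)

    resid = Yc - fitted
    consensus = Y.mean(axis=0)
    out = dataset.copy()
    out.coords = (resid + consensus).reshape(dataset.coords.shape)
    out.centroid_sizes = sizes
    return AllometryResult(r_squared=r2, p_value=p, residual_dataset=out,
                           coefficients=beta, n_permutations=n_perm)


# ---------------------------------------------------------------------------
# OTU means and PCA
# ---------------------------------------------------------------------------

def otu_means(dataset: ShapeDataset, otu_map: dict | None = None) -> ShapeDataset:
    """Coordinate-wise mean configuration per OTU.

    OTUs are ordered by first appearance in the dataset (the canonical
    ordering used throughout).  Habitat labels are carried over when they are
    constant within an OTU.
    """
    if otu_map is not None:
        labels = np.array([otu_map[sid] for sid in dataset.specimen_ids])
    elif dataset.otu is not None:
        labels = dataset.otu
    else:
        raise ValueError("no OTU labels: supply otu_map or dataset.otu")
    if any(l == "" for l in labels):
        bad = [sid for sid, l in zip(dataset.specimen_ids, labels) if l == ""]
        raise ValueError(f"specimens without OTU assignment: {bad}")
    order = list(dict.fromkeys(labels))
    coords, habs, sizes = [], [], []
    have_sizes = dataset.centroid_sizes is not None
    for otu in order:
        mask = labels == otu
        if not mask.any():
            raise ValueError(f"OTU {otu!r} has no specimens")
        coords.append(dataset.coords[mask].mean(axis=0))
        if dataset.habitat is not None:
            h = set(dataset.habitat[mask])
            habs.append(h.pop() if len(h) == 1 else "")
        if have_sizes:
            sizes.append(dataset.centroid_sizes[mask].mean())
    return ShapeDataset(
        coords=np.stack(coords),
        specimen_ids=order,
        otu=np.array(order),
        habitat=np.array(habs) if dataset.habitat is not None else None,
        landmark_types=dataset.landmark_types.copy(),
        curve_ids=dataset.curve_ids.copy(),
        centroid_sizes=np.array(sizes) if have_sizes else None,
        aligned=dataset.aligned,
    )


def pca(dataset: ShapeDataset) -> PCAResult:
    """PCA of flattened coordinates via SVD of the centered data matrix."""
    Y = dataset.flat()
    n = Y.shape[0]
    if n < 2:
        raise ValueError("PCA requires at least 2 specimens")
    mean = Y.mean(axis=0)
    Yc = Y - mean
    u, s, vt = np.linalg.svd(Yc, full_matrices=False)
    eigvals = s ** 2 / (n - 1)
    keep = s > s[0] * 1e-12 if s[0] > 0 else slice(0, 1)
    u, s, vt, eigvals = u[:, keep], s[keep], vt[keep], eigvals[keep]
    total = eigvals.sum()
    pct = eigvals / total * 100.0 if total > 0 else np.zeros_like(eigvals)
    return PCAResult(scores=u * s, eigenvalues=eigvals, percent_variance=pct,
                     loadings=vt, mean=mean)
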