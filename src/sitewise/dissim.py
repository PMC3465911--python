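"""Dissimilarity-space representation.

Arbitrary objects are embedded into R^p by their distances to p fixed
*prototypes* (landmarks) drawn from the dataset:

    phi(X) = [d(X, P_1), ..., d(X, P_p)]

where d is any symmetric distance with d(X, X) = 0 — it need not satisfy
the triangle inequality.  Prototypes are selected by farthest-first
traversal (FFT), and the faithfulness of the embedding is measured by the
Pearson correlation between original distances d(X, X') and Euclidean
distances between the projected vectors over object pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "correlation_distance",
    "euclidean_distance",
    "get_distance",
    "PrototypeSet",
    "DissimilarityMap",
    "fft_select",
    "project",
    "projected_distance",
    "ProjectionQuality",
    "projection_quality",
    "select_num_prototypes",
]


def correlation_distance(a, b) -> float:
    """1 − Pearson r, in [0, 2]; 0 iff perfectly positively correlated."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.size < 2:
        raise ValueError("need vectors of length >= 2")
    da = a - a.mean()
    db = b - b.mean()
    na = np.sqrt((da * da).sum())
    nb = np.sqrt((db * db).sum())
    if na == 0 or nb == 0:
        raise ValueError("correlation distance undefined for constant vectors")
    r = float(np.clip((da * db).sum() / (na * nb), -1.0, 1.0))
    return 1.0 - r


def euclidean_distance(a, b) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    return float(np.linalg.norm(a - b))


_DISTANCES = {
    "correlation": correlation_distance,
    "euclidean": euclidean_distance,
}


def get_distance(name: str):
    """Look up a registered distance function by name."""
    try:
        return _DISTANCES[name]
    except KeyError:
        raise ValueError(f"unknown distance {name!r}; known: {sorted(_DISTANCES)}") from None


@dataclass
class PrototypeSet:
    """Ordered prototype indices into the originating dataset."""

    indices: list
    distance: str
    seed: int
    criterion: str = "sum"

    def __len__(self) -> int:
        return len(self.indices)


@dataclass
class DissimilarityMap:
    """The projection phi and its projected-space Euclidean distance."""

    prototypes: list  # the prototype objects themselves
    distance: object  # callable or registered name
    prototype_set: PrototypeSet | None = None
    _d: object = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._d = get_distance(self.distance) if isinstance(self.distance, str) else self.distance

    @property
    def p(self) -> int:
        return len(self.prototypes)


def fft_select(objects, d, p: int, seed: int, criterion: str = "sum") -> PrototypeSet:
    """Farthest-first traversal prototype selection.

    The first prototype is drawn uniformly at random (seeded).  Each further
    prototype is the unselected object maximizing, over the already selected
    prototypes, the *sum* of distances (``criterion="sum"``) or, for the
    classical k-center variant, the *minimum* distance
    (``criterion="maxmin"``).  Ties resolve to the lowest dataset index, so
    the selection is bit-reproducible given (dataset order, seed).
    """
    n = len(objects)
    if n == 0:
        raise ValueError("empty dataset")
    if not 1 <= p <= n:
        raise ValueError(f"p must be in 1..{n}, got {p}")
    if criterion not in ("sum", "maxmin"):
        raise ValueError("criterion must be 'sum' or 'maxmin'")
    if isinstance(d, str):
        d = get_distance(d)
    rng = np.random.default_rng(seed)
    first = int(rng.integers(n))
    selected = [first]
    # score[i]: sum (or min) of distances from object i to selected prototypes
    score = np.array([d(objects[i], objects[first]) for i in range(n)], dtype=float)
    mask = np.zeros(n, dtype=bool)
    mask[first] = True
    while len(selected) < p:
        cand = np.where(~mask, score, -np.inf)
        nxt = int(np.argmax(cand))  # argmax takes the first (lowest-index) max
        selected.append(nxt)
        mask[nxt] = True
        new_d = np.array([d(objects[i], objects[nxt]) for i in range(n)], dtype=float)
        score = score + new_d if criterion == "sum" else np.minimum(score, new_d)
    name = d.__name__ if hasattr(d, "__name__") else "custom"
    return PrototypeSet(indices=selected, distance=name, seed=seed, criterion=criterion)


def project(X, dmap: DissimilarityMap) -> np.ndarray:
    """phi(X): the vector of distances from X to each prototype."""
    out = np.empty(dmap.p, dtype=float)
    for i, proto in enumerate(dmap.prototypes):
        try:
            out[i] = dmap._d(X, proto)
        except Exception as exc:
            raise ValueError(f"distance evaluation failed at prototype {i}: {exc}") from exc
    return out


def project_all(objects, dmap: DissimilarityMap) -> np.ndarray:
    """Project a whole dataset; rows follow the input order."""
    return np.vstack([project(x, dmap) for x in objects])


def projected_distance(X, Xp, dmap: DissimilarityMap) -> float:
    """Euclidean distance between phi(X) and phi(X')."""
    return float(np.linalg.norm(project(X, dmap) - project(Xp, dmap)))


@dataclass
class ProjectionQuality:
    r: float
    n_pairs: int


def projection_quality(
    objects, dmap: DissimilarityMap, pair_cap: int = 50000, seed: int = 0
) -> ProjectionQuality:
    """Pearson correlation between original and projected distances.

    Computed over all unordered object pairs; beyond ``pair_cap`` pairs a
    seeded uniform subsample is used.
    """
    n = len(objects)
    if n < 3:
        raise ValueError("need at least 3 objects (3 pairs)")
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    if len(pairs) > pair_cap:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(pairs), size=pair_cap, replace=False)
        pairs = [pairs[k] for k in idx]
    phi = project_all(objects, dmap)
    orig = np.array([dmap._d(objects[i], objects[j]) for i, j in pairs])
    proj = np.array([np.linalg.norm(phi[i] - phi[j]) for i, j in pairs])
    if orig.std() == 0 or proj.std() == 0:
        raise ValueError("distance set is constant over pairs; correlation undefined")
    r = float(np.corrcoef(orig, proj)[0, 1])
    return ProjectionQuality(r=r, n_pairs=len(pairs))


def select_num_prototypes(
    objects,
    d,
    p_grid,
    threshold: float = 0.85,
    seed: int = 0,
    criterion: str = "sum",
):
    """Smallest p in the grid reaching projection quality r >= threshold.

    If no grid value reaches the threshold, the p maximizing r is returned.
    Returns ``(p, curve)`` where curve is the list of (p, r) pairs evaluated.
    """
    p_grid = list(p_grid)
    if not p_grid:
        raise ValueError("empty prototype grid")
    if isinstance(d, str):
        d = get_distance(d)
    curve = []
    for p in p_grid:
        ps = fft_select(objects, d, p, seed=seed, criterion=criterion)
        dmap = DissimilarityMap(
            prototypes=[objects[i] for i in ps.indices], distance=d, prototype_set=ps
        )
        curve.append((p, projection_quality(objects, dmap, seed=seed).r))
    for p, r in curve:
        if r >= threshold:
            return p, curve
    best = max(curve, key=lambda pr: pr[1])
    return best[0], curve
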