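"""Structural connectome construction, transformation, and graph metrics.

The structural connectome (SC) is a weighted, possibly directed graph of
anatomical connection strengths between brain regions.  Weights follow the
tract-tracing convention used throughout this package: ``weights[b, a]`` is
the strength of the projection *from* region ``b`` *to* region ``a``
(row = source, column = target).

A whole-brain SC is built from single-hemisphere ipsilateral and
contralateral blocks under an assumption of bilateral symmetry, then
normalized so the strongest edge has weight 1 and self-connections are 0.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import dijkstra


class ConnectomeError(ValueError):
    """Raised for structurally invalid connectome operations."""


@dataclass(frozen=True)
class StructuralConnectome:
    """Nonnegative weighted region-by-region structural network.

    Parameters
    ----------
    weights
        Square nonnegative matrix; ``weights[b, a]`` is the connection
        directed from region ``b`` to region ``a``.
    regions
        Ordered unique region labels, one per node.
    hemisphere
        Per-region hemisphere tag, each ``"A"`` or ``"B"``.  Hemisphere A
        occupies the leading block of a bilaterally mirrored connectome and
        is the "first hemisphere" targeted by unilateral injury.
    directed
        Whether the matrix is interpreted as directed.  Undirected
        connectomes must be symmetric.
    """

    weights: np.ndarray
    regions: tuple[str, ...]
    hemisphere: tuple[str, ...]
    directed: bool
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "regions", tuple(self.regions))
        object.__setattr__(self, "hemisphere", tuple(self.hemisphere))
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ConnectomeError(f"weights must be square, got shape {w.shape}")
        if len(self.regions) != w.shape[0]:
            raise ConnectomeError("number of region labels must match matrix size")
        if len(set(self.regions)) != len(self.regions):
            raise ConnectomeError("region labels must be unique")
        if len(self.hemisphere) != w.shape[0]:
            raise ConnectomeError("hemisphere tags must match matrix size")
        if any(h not in ("A", "B") for h in self.hemisphere):
            raise ConnectomeError("hemisphere tags must be 'A' or 'B'")
        if not np.all(np.isfinite(w)):
            raise ConnectomeError("weights must be finite")
        if np.any(w < 0):
            raise ConnectomeError("weights must be nonnegative")
        if not self.directed and not np.allclose(w, w.T):
            raise ConnectomeError("undirected connectome must be symmetric")

    @property
    def n(self) -> int:
        return self.weights.shape[0]

    def index_of(self, labels: Sequence[str]) -> np.ndarray:
        """Node indices for ``labels`` (order preserved); unknown labels raise."""
        lookup = {r: i for i, r in enumerate(self.regions)}
        try:
            return np.array([lookup[lab] for lab in labels], dtype=int)
        except KeyError as exc:
            raise ConnectomeError(f"unknown region label: {exc.args[0]!r}") from None


def mirror_bilateral(
    ipsi: np.ndarray, contra: np.ndarray, labels: Sequence[str]
) -> StructuralConnectome:
    """Mirror single-hemisphere blocks into a bilaterally symmetric SC.

    Given the within-hemisphere (``ipsi``) and between-hemisphere
    (``contra``) projection blocks measured from one hemisphere, build the
    ``2h``-node whole-brain network under bilateral symmetry::

        [[ipsi,   contra],
         [contra, ipsi  ]]

    Node order is hemisphere A first (labels suffixed ``-A``), then
    hemisphere B, so homologous pairs sit ``h`` indices apart.
    """
    ipsi = np.asarray(ipsi, dtype=float)
    contra = np.asarray(contra, dtype=float)
    h = len(labels)
    if ipsi.shape != (h, h) or contra.shape != (h, h):
        raise ConnectomeError(
            f"ipsi/contra must both be {h}x{h}; got {ipsi.shape} and {contra.shape}"
        )
    if np.any(ipsi < 0) or np.any(contra < 0):
        raise ConnectomeError("hemisphere blocks must be nonnegative")
    w = np.block([[ipsi, contra], [contra, ipsi]])
    regions = tuple(f"{lab}-A" for lab in labels) + tuple(f"{lab}-B" for lab in labels)
    hemis = ("A",) * h + ("B",) * h
    return StructuralConnectome(w, regions, hemis, directed=True)


def to_undirected(sc: StructuralConnectome) -> StructuralConnectome:
    """Collapse a directed SC by summing the two directions of every pair."""
    if not sc.directed:
        raise ConnectomeError("connectome is already undirected")
    return replace(sc, weights=sc.weights + sc.weights.T, directed=False)


def normalize(sc: StructuralConnectome) -> StructuralConnectome:
    """Zero the diagonal, then rescale so the maximum edge weight is 1."""
    w = sc.weights.copy()
    np.fill_diagonal(w, 0.0)
    mx = w.max()
    if mx == 0:
        warnings.warn("all-zero connectome; normalize returns it unchanged")
        return replace(sc, weights=w)
    meta = dict(sc.meta)
    meta["normalized"] = True
    return replace(sc, weights=w / mx, meta=meta)


def reduce_to_regions(
    sc: StructuralConnectome, keep: Sequence[str]
) -> StructuralConnectome:
    """Submatrix on ``keep`` in the connectome's own region order.

    Weights are deliberately not re-normalized, so a reduced network shares
    the edge scale of the full network it came from.
    """
    keep_set = set(keep)
    unknown = keep_set - set(sc.regions)
    if unknown:
        raise ConnectomeError(f"unknown region labels: {sorted(unknown)}")
    idx = np.array([i for i, r in enumerate(sc.regions) if r in keep_set], dtype=int)
    return StructuralConnectome(
        sc.weights[np.ix_(idx, idx)],
        tuple(sc.regions[i] for i in idx),
        tuple(sc.hemisphere[i] for i in idx),
        directed=sc.directed,
        meta=dict(sc.meta),
    )


def randomize_directed(
    sc: StructuralConnectome, swaps_per_edge: int = 20, seed: int = 0
) -> StructuralConnectome:
    """Degree-preserving rewiring of a directed weighted network.

    Pairs of directed edges ``(b1->a1), (b2->a2)`` are rewired to
    ``(b1->a2), (b2->a1)`` (weights travel with their source stub) whenever
    the swap creates no self-loop and no duplicate edge.  Each edge is
    swapped ``swaps_per_edge`` times on average, so in- and out-degree
    sequences and the global multiset of edge weights are conserved exactly,
    while in/out *strength* sequences are preserved only distributionally.
    """
    if not sc.directed:
        raise ConnectomeError("randomize_directed requires a directed connectome")
    if swaps_per_edge < 1:
        raise ConnectomeError("swaps_per_edge must be >= 1")
    w = sc.weights.copy()
    sources, targets = np.nonzero(w)
    m = len(sources)
    if m < 2:
        raise ConnectomeError("too few edges to swap")
    values = w[sources, targets].copy()
    present = set(zip(sources.tolist(), targets.tolist()))
    rng = np.random.default_rng(seed)
    attempts = 0
    successes = 0
    goal = swaps_per_edge * m
    max_attempts = 100 * goal
    while successes < goal and attempts < max_attempts:
        attempts += 1
        e1, e2 = rng.integers(0, m, size=2)
        if e1 == e2:
            continue
        b1, a1 = sources[e1], targets[e1]
        b2, a2 = sources[e2], targets[e2]
        if b1 == b2 or a1 == a2:
            continue
        if b1 == a2 or b2 == a1:  # would create a self-loop
            continue
        if (b1, a2) in present or (b2, a1) in present:
            continue
        present.discard((b1, a1))
        present.discard((b2, a2))
        present.add((b1, a2))
        present.add((b2, a1))
        targets[e1], targets[e2] = a2, a1
        successes += 1
    out = np.zeros_like(w)
    out[sources, targets] = values
    meta = dict(sc.meta)
    meta["randomized"] = {"swaps_per_edge": swaps_per_edge, "seed": int(seed),
                          "swaps_done": successes}
    return replace(sc, weights=out, meta=meta)


def global_efficiency(sc: StructuralConnectome) -> float:
    """Mean inverse weighted shortest-path length over ordered node pairs.

    Edge length is the inverse of connection strength, so strong edges are
    short.  Unreachable pairs contribute zero.  An empty or single-node
    network has efficiency 0.
    """
    w = sc.weights
    n = w.shape[0]
    if n < 2:
        return 0.0
    with np.errstate(divide="ignore", over="ignore"):
        lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), np.inf)
    np.fill_diagonal(lengths, 0.0)
    d = dijkstra(lengths, directed=sc.directed)
    off = ~np.eye(n, dtype=bool)
    inv = np.zeros_like(d)
    finite = np.isfinite(d) & (d > 0)
    inv[finite] = 1.0 / d[finite]
    return float(inv[off].mean())


# ---------------------------------------------------------------------------
# I/O

def save_connectome(sc: StructuralConnectome, matrix_path: str | Path,
                    labels_path: str | Path | None = None) -> None:
    """Write the SC as a labeled CSV matrix plus a label/hemisphere table."""
    matrix_path = Path(matrix_path)
    df = pd.DataFrame(sc.weights, index=list(sc.regions), columns=list(sc.regions))
    df.to_csv(matrix_path)
    if labels_path is None:
        labels_path = matrix_path.with_suffix(".labels.csv")
    pd.DataFrame({"label": list(sc.regions), "hemisphere": list(sc.hemisphere)}).to_csv(
        labels_path, index=False
    )
    meta = {"directed": sc.directed, **{k: v for k, v in sc.meta.items()}}
    Path(matrix_path).with_suffix(".meta.json").write_text(json.dumps(meta, indent=1))


def load_connectome(matrix_path: str | Path,
                    labels_path: str | Path | None = None,
                    directed: bool | None = None) -> StructuralConnectome:
    """Read a labeled CSV matrix (and optional label table) back into an SC."""
    matrix_path = Path(matrix_path)
    df = pd.read_csv(matrix_path, index_col=0)
    regions = tuple(str(c) for c in df.columns)
    meta_path = matrix_path.with_suffix(".meta.json")
    meta: dict = {}
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
    if directed is None:
        directed = bool(meta.pop("directed", True))
    else:
        meta.pop("directed", None)
    if labels_path is None:
        default = matrix_path.with_suffix(".labels.csv")
        labels_path = default if default.exists() else None
    if labels_path is not None:
        lab = pd.read_csv(labels_path)
        hemi_map = dict(zip(lab["label"].astype(str), lab["hemisphere"].astype(str)))
        hemis = tuple(hemi_map.get(r, "A") for r in regions)
    else:
        hemis = tuple("B" if r.endswith("-B") else "A" for r in regions)
    return StructuralConnectome(df.to_numpy(dtype=float), regions, hemis,
                                directed=directed, meta=meta)
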