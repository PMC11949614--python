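"""Functional connectivity from region-level BOLD series, and FC comparison.

Empirical functional connectivity (FC) is the matrix of pairwise Pearson
correlations between regional BOLD time series that survive quality
control.  Quality control applies three sequential filters to each
recording: match to the structural atlas, above-median voxel count, and a
variance floor that removes unreliable signals.

FC networks — empirical, simulated, or averaged — are compared through the
Pearson correlation of their upper-triangle edge strengths over shared
regions; applied to a (simulated, empirical) pair this is the model's
*predictive power*.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class BoldRecording:
    """Region-level BOLD time series for one subject."""

    series: np.ndarray              # (time, regions), arbitrary units
    regions: tuple[str, ...]
    voxel_count: tuple[int, ...]
    subject_id: str = ""

    def __post_init__(self) -> None:
        s = np.asarray(self.series, dtype=float)
        object.__setattr__(self, "series", s)
        object.__setattr__(self, "regions", tuple(self.regions))
        object.__setattr__(self, "voxel_count", tuple(int(v) for v in self.voxel_count))
        if s.ndim != 2 or s.shape[1] != len(self.regions):
            raise ValueError("series must be time-by-region matching labels")
        if len(self.voxel_count) != len(self.regions):
            raise ValueError("one voxel count per region required")
        if any(v < 1 for v in self.voxel_count):
            raise ValueError("voxel counts must be >= 1")


@dataclass(frozen=True)
class FCNetwork:
    """Symmetric correlation matrix over labeled regions."""

    matrix: np.ndarray
    regions: tuple[str, ...]
    source: str = "empirical"       # empirical | simulated | average
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "regions", tuple(self.regions))
        if m.ndim != 2 or m.shape[0] != m.shape[1] or m.shape[0] != len(self.regions):
            raise ValueError("matrix must be square and match region labels")
        if not np.allclose(m, m.T, atol=1e-8):
            raise ValueError("FC matrix must be symmetric")
        if not np.allclose(np.diag(m), 1.0, atol=1e-8):
            raise ValueError("FC diagonal must be 1")
        if np.nanmax(np.abs(m)) > 1 + 1e-8:
            raise ValueError("FC entries must lie in [-1, 1]")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def submatrix(self, labels: Sequence[str]) -> np.ndarray:
        lookup = {r: i for i, r in enumerate(self.regions)}
        idx = np.array([lookup[lab] for lab in labels], dtype=int)
        return self.matrix[np.ix_(idx, idx)]

    def upper_edges(self, labels: Sequence[str] | None = None) -> np.ndarray:
        """Strictly-upper-triangle edge strengths, optionally on a subset."""
        m = self.matrix if labels is None else self.submatrix(labels)
        iu = np.triu_indices(m.shape[0], k=1)
        return m[iu]


def region_filter(
    rec: BoldRecording,
    sc_regions: Sequence[str],
    variance_floor: float = 1e-6,
) -> BoldRecording:
    """Quality-control a recording with three sequential filters.

    1. keep regions whose labels exactly match the structural connectome;
    2. keep regions with voxel count strictly above the median voxel count
       of the regions surviving step 1 (median ties are excluded);
    3. drop regions whose time-series variance is below ``variance_floor``.
    """
    if not rec.regions:
        raise ValueError("recording has no regions")
    sc_set = set(sc_regions)
    keep = [i for i, r in enumerate(rec.regions) if r in sc_set]
    if keep:
        counts = np.array([rec.voxel_count[i] for i in keep], dtype=float)
        med = float(np.median(counts))
        keep = [i for i, c in zip(keep, counts) if c > med]
    if keep:
        var = rec.series[:, keep].var(axis=0, ddof=0)
        keep = [i for i, v in zip(keep, var) if v >= variance_floor]
    if not keep:
        raise ValueError(f"all regions removed by quality control ({rec.subject_id})")
    return BoldRecording(
        series=rec.series[:, keep],
        regions=tuple(rec.regions[i] for i in keep),
        voxel_count=tuple(rec.voxel_count[i] for i in keep),
        subject_id=rec.subject_id,
    )


def compute_fc(rec: BoldRecording) -> FCNetwork:
    """Pairwise Pearson FC of a quality-controlled recording."""
    if rec.series.shape[0] < 3:
        raise ValueError("need at least 3 time points")
    if rec.series.shape[1] < 2:
        raise ValueError("need at least 2 regions")
    if np.any(rec.series.var(axis=0, ddof=0) == 0):
        raise ValueError("zero-variance column; run region_filter first")
    fc = np.corrcoef(rec.series, rowvar=False)
    np.fill_diagonal(fc, 1.0)
    return FCNetwork(fc, rec.regions, source="empirical",
                     meta={"subject_id": rec.subject_id})


def common_regions(fcs: Sequence[FCNetwork]) -> tuple[str, ...]:
    """Region labels present in every network, ordered by the first one."""
    if not fcs:
        raise ValueError("no networks given")
    shared = set(fcs[0].regions)
    for fc in fcs[1:]:
        shared &= set(fc.regions)
    if not shared:
        raise ValueError("networks share no regions")
    return tuple(r for r in fcs[0].regions if r in shared)


def average_fc(fcs: Sequence[FCNetwork]) -> FCNetwork:
    """Elementwise mean FC over the regions common to all networks."""
    labels = common_regions(fcs)
    stack = np.stack([fc.submatrix(labels) for fc in fcs])
    mean = stack.mean(axis=0)
    mean = 0.5 * (mean + mean.T)
    np.fill_diagonal(mean, 1.0)
    return FCNetwork(mean, labels, source="average", meta={"n_networks": len(fcs)})


def fc_similarity(fc1: FCNetwork, fc2: FCNetwork) -> float:
    """Pearson r between upper-triangle edges over shared regions.

    With ``fc1`` simulated and ``fc2`` empirical this is the simulation's
    predictive power.
    """
    labels = common_regions([fc1, fc2])
    if len(labels) < 3:
        raise ValueError("need at least 3 shared regions")
    e1 = fc1.upper_edges(labels)
    e2 = fc2.upper_edges(labels)
    if e1.std() == 0 or e2.std() == 0:
        raise ValueError("zero variance of edge strengths")
    return float(stats.pearsonr(e1, e2).statistic)


def fc_mse(fc_sim: FCNetwork, fc_emp: FCNetwork) -> float:
    """Mean squared difference over shared upper-triangle edges."""
    labels = common_regions([fc_sim, fc_emp])
    d = fc_sim.upper_edges(labels) - fc_emp.upper_edges(labels)
    return float(np.mean(d * d))


# ---------------------------------------------------------------------------
# I/O

def save_fc(fc: FCNetwork, path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame(fc.matrix, index=list(fc.regions), columns=list(fc.regions)).to_csv(path)
    meta = {"source": fc.source, **fc.meta}
    path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=1))


def load_fc(path: str | Path) -> FCNetwork:
    path = Path(path)
    df = pd.read_csv(path, index_col=0)
    meta_path = path.with_suffix(".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    source = meta.pop("source", "empirical")
    m = df.to_numpy(dtype=float)
    m = 0.5 * (m + m.T)
    np.fill_diagonal(m, 1.0)
    return FCNetwork(m, tuple(str(c) for c in df.columns), source=source, meta=meta)


def load_bold(series_path: str | Path, sidecar_path: str | Path) -> BoldRecording:
    """Read a time-by-region CSV plus JSON sidecar (labels, voxel counts, id)."""
    series = pd.read_csv(series_path).to_numpy(dtype=float)
    side = json.loads(Path(sidecar_path).read_text())
    return BoldRecording(
        series=series,
        regions=tuple(side["regions"]),
        voxel_count=tuple(side["voxel_count"]),
        subject_id=str(side.get("subject_id", "")),
    )


def save_bold(rec: BoldRecording, series_path: str | Path,
              sidecar_path: str | Path) -> None:
    pd.DataFrame(rec.series, columns=list(rec.regions)).to_csv(series_path, index=False)
    Path(sidecar_path).write_text(json.dumps({
        "regions": list(rec.regions),
        "voxel_count": list(rec.voxel_count),
        "subject_id": rec.subject_id,
    }, indent=1))
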