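"""Synthetic connectomes, target FC networks, and BOLD-like recordings.

Desk-scale stand-ins for the external inputs the analysis was designed
around: a bilaterally mirrored, heavy-tailed, directionally biased
tract-tracing connectome, per-subject target FC matrices with controllable
mean and spread of edge strength and region dropout, and Gaussian BOLD-like
time series realizing a given FC (with deliberately unreliable regions to
exercise quality control).

Every generator is seeded and reproducible, and every generated object
validates against the invariants of the module that consumes it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from statsmodels.stats.correlation_tools import corr_clipped, corr_nearest

from . import kuramoto
from .connectome import StructuralConnectome, mirror_bilateral, normalize, reduce_to_regions
from .empirical_fc import BoldRecording, FCNetwork


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings emulating the study-scale data properties.

    Defaults mirror the empirical regime the pipeline targets: 178
    candidate regions (89 per hemisphere), per-subject FC networks of
    115-146 regions after dropout, 58 subjects, heavy-tailed (log-normal)
    connection weights with a strong directional bias, and FC edge
    strengths centred near 0.2.
    """

    regions_per_hemisphere: int = 89
    density: float = 0.3
    weight_law: tuple[float, float] = (0.0, 2.0)   # log-normal (location, scale)
    direction_bias: float = 0.7
    fc_mean: float = 0.2
    fc_sd: float = 0.15
    dropout_range: tuple[int, int] = (115, 146)
    n_subjects: int = 58
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.density <= 1):
            raise ValueError("density must lie in (0, 1]")
        if not (0 <= self.direction_bias <= 1):
            raise ValueError("direction_bias must lie in [0, 1]")
        lo, hi = self.dropout_range
        if not (1 <= lo <= hi <= 2 * self.regions_per_hemisphere):
            raise ValueError("dropout bounds must fit the available regions")


def _pair_block(
    h: int,
    density: float,
    bias: float,
    weight_law: tuple[float, float],
    rng: np.random.Generator,
    include_diagonal: bool,
) -> np.ndarray:
    """One hemisphere block with the requested directed-edge density.

    Unordered pairs are connected with probability q; a connected pair
    carries both directions with probability (1 - bias) and a single
    dominant direction otherwise, so the expected fraction of nonzero
    directed cells equals ``density``.
    """
    q = 2 * density / (2 - bias)
    if q > 1:
        raise ValueError(
            f"density {density} unreachable at direction bias {bias} (needs q={q:.2f})"
        )
    mu, sigma = weight_law
    w = np.zeros((h, h))
    for i in range(h):
        for j in range(i if include_diagonal else i + 1, h):
            if i == j:
                if rng.random() < density:   # homotopic contralateral edge
                    w[i, i] = rng.lognormal(mu, sigma)
                continue
            if rng.random() >= q:
                continue
            if rng.random() < bias:
                if rng.random() < 0.5:
                    w[i, j] = rng.lognormal(mu, sigma)
                else:
                    w[j, i] = rng.lognormal(mu, sigma)
            else:
                w[i, j] = rng.lognormal(mu, sigma)
                w[j, i] = rng.lognormal(mu, sigma)
    return w


def synth_connectome(cfg: SynthConfig) -> StructuralConnectome:
    """Bilaterally mirrored, normalized, directed synthetic connectome."""
    rng = np.random.default_rng(cfg.seed)
    h = cfg.regions_per_hemisphere
    ipsi = _pair_block(h, cfg.density, cfg.direction_bias, cfg.weight_law, rng,
                       include_diagonal=False)
    contra = _pair_block(h, cfg.density, cfg.direction_bias, cfg.weight_law, rng,
                         include_diagonal=True)
    labels = [f"R{i:03d}" for i in range(h)]
    sc = normalize(mirror_bilateral(ipsi, contra, labels))
    meta = dict(sc.meta)
    meta["synthetic"] = {"seed": cfg.seed, "density": cfg.density,
                         "direction_bias": cfg.direction_bias}
    return StructuralConnectome(sc.weights, sc.regions, sc.hemisphere,
                                directed=True, meta=meta)


def _dropout(sc: StructuralConnectome, cfg: SynthConfig,
             rng: np.random.Generator) -> list[str]:
    lo, hi = cfg.dropout_range
    n_keep = int(rng.integers(lo, hi + 1))
    keep_idx = np.sort(rng.choice(sc.n, size=n_keep, replace=False))
    return [sc.regions[i] for i in keep_idx]


def synth_target_fc(
    sc: StructuralConnectome,
    mode: str,
    cfg: SynthConfig,
    seed: int,
    g: float = 3.5,
    n_factors: int = 5,
    duration_s: float = 200.0,
) -> tuple[FCNetwork, np.ndarray | None]:
    """Per-subject target FC with region dropout.

    ``self_consistent`` simulates the Kuramoto model on the dropout-reduced
    connectome with known frequencies and returns its simulated FC together
    with those ground-truth frequencies — the target is then exactly
    reachable by the optimizer.  ``noisy`` builds a factor-model correlation
    matrix steered toward ``cfg.fc_mean``/``cfg.fc_sd`` and projected to the
    nearest valid correlation matrix; no ground truth exists.
    """
    rng = np.random.default_rng(seed)
    keep = _dropout(sc, cfg, rng)
    if mode == "self_consistent":
        sub = reduce_to_regions(sc, keep)
        omega_true = kuramoto.draw_frequencies(sub.n, seed + 11)
        cfg_run = kuramoto.OscillatorConfig(
            omega=omega_true,
            theta0=kuramoto.draw_phases(sub.n, seed + 13),
            g=g, duration_s=duration_s, transient_s=0.2 * duration_s,
        )
        run = kuramoto.simulate(sub, cfg_run)
        fc = kuramoto.simulated_fc(run, sub.regions)
        return FCNetwork(fc.matrix, fc.regions, source="simulated",
                         meta={"mode": mode, "seed": seed}), omega_true
    if mode != "noisy":
        raise ValueError(f"unknown mode {mode!r}")

    if abs(cfg.fc_mean) + 3 * cfg.fc_sd > 0.98:
        warnings.warn(
            f"fc_mean={cfg.fc_mean} with fc_sd={cfg.fc_sd} is near the "
            "correlation bound; the projected matrix may miss the targets"
        )
    m = len(keep)
    loadings = rng.normal(0.0, 1.0, size=(m, n_factors)) / np.sqrt(n_factors)
    cov = loadings @ loadings.T + 0.5 * np.eye(m)
    d = np.sqrt(np.diag(cov))
    base = cov / np.outer(d, d)
    iu = np.triu_indices(m, k=1)
    edges = base[iu]
    scaled = cfg.fc_mean + cfg.fc_sd * (edges - edges.mean()) / edges.std()
    scaled = np.clip(scaled, -0.99, 0.99)
    raw = np.eye(m)
    raw[iu] = scaled
    raw = raw + raw.T - np.eye(m)
    mat = corr_nearest(raw, threshold=1e-7, n_fact=200)
    mat = 0.5 * (mat + mat.T)
    np.fill_diagonal(mat, 1.0)
    return FCNetwork(np.clip(mat, -1, 1), tuple(keep), source="empirical",
                     meta={"mode": mode, "seed": seed}), None


def synth_bold(
    fc_target: FCNetwork,
    n_timepoints: int,
    variance_floor_violators: int = 0,
    seed: int = 0,
    subject_id: str = "synth",
) -> BoldRecording:
    """Gaussian BOLD-like series whose population correlation is the target.

    ``variance_floor_violators`` regions are overwritten with near-constant
    signal (variance below 1e-6) so the quality-control variance filter has
    known casualties, and voxel counts are assigned so that exactly half of
    the regions sit strictly above the median (violators always do, so they
    reach the variance filter rather than being removed earlier).
    """
    rng = np.random.default_rng(seed)
    n = fc_target.n
    if variance_floor_violators > n // 2:
        raise ValueError("more violators than above-median slots")
    pd_matrix = corr_clipped(fc_target.matrix, threshold=1e-7)
    chol = np.linalg.cholesky(pd_matrix + 1e-10 * np.eye(n))
    series = rng.standard_normal((n_timepoints, n)) @ chol.T

    violators = rng.choice(n, size=variance_floor_violators, replace=False)
    for v in violators:
        series[:, v] = 1.0 + rng.normal(0.0, 1e-5, size=n_timepoints)

    # distinct voxel counts 100..100+n-1; top half is strictly above the median
    counts = np.empty(n, dtype=int)
    values = 100 + np.arange(n)
    top = list(values[n - n // 2:])
    rest = list(values[: n - n // 2])
    rng.shuffle(top)
    rng.shuffle(rest)
    others = [i for i in range(n) if i not in set(violators.tolist())]
    rng.shuffle(others)
    for v in violators:
        counts[v] = top.pop()
    for i in others:
        counts[i] = top.pop() if top else rest.pop()

    return BoldRecording(
        series=series,
        regions=fc_target.regions,
        voxel_count=tuple(int(c) for c in counts),
        subject_id=subject_id,
    )
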