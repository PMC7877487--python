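"""Individual-level morphological covariance brain networks.

For one subject, the gray-matter voxel values inside each atlas region are
treated as a sample from that region's GM-value distribution.  A Gaussian
kernel density estimate of each region's distribution is evaluated on one
grid shared by all regions of the subject and renormalized to a discrete
probability vector P.  The edge between regions with densities P and Q is the
KL-divergence-based similarity

    KLS(P, Q) = exp(-D(P, Q)),
    D(P, Q)   = sum_g [ P_g ln(P_g / Q_g) + Q_g ln(Q_g / P_g) ],

i.e. the symmetrized Kullback-Leibler divergence mapped to (0, 1].  With the
116-region parcellation and the default exclusion of the eight cerebellar
vermis labels (109-116), each subject yields a symmetric 108 x 108 similarity
matrix with unit diagonal — the input image for the downstream classifier.
"""

from __future__ import annotations

import json
import math
import os
import warnings
from dataclasses import dataclass, field

import numpy as np

from .synthetic import GMVolumeMap, ParcellationAtlas

DEFAULT_EXCLUDED = frozenset(range(109, 117))  # cerebellar vermis


@dataclass(frozen=True)
class NetworkConfig:
    """Parameters of the network construction.

    bandwidth_rule is either the string ``"silverman"`` (per-region Silverman
    bandwidth) or a fixed positive float used for every region.  ``prob_floor``
    is added to the discretized density before normalization so that the
    KL logs stay finite on grid points where a kernel sum underflows.
    """

    excluded_labels: frozenset[int] = DEFAULT_EXCLUDED
    grid_size: int = 128
    bandwidth_rule: str | float = "silverman"
    prob_floor: float = 1e-10
    grid_pad_bandwidths: float = 3.0

    def __post_init__(self) -> None:
        if self.grid_size < 16:
            raise ValueError("grid_size must be >= 16")
        if not (0 < self.prob_floor < 1.0 / self.grid_size):
            raise ValueError("prob_floor must be in (0, 1/grid_size)")
        if isinstance(self.bandwidth_rule, str):
            if self.bandwidth_rule != "silverman":
                raise ValueError("bandwidth_rule must be 'silverman' or a float")
        elif self.bandwidth_rule <= 0:
            raise ValueError("fixed bandwidth must be > 0")


@dataclass
class DensityProfile:
    """A region's discretized GM-value distribution on a shared grid."""

    grid: np.ndarray
    probs: np.ndarray

    def __post_init__(self) -> None:
        if self.grid.shape != self.probs.shape:
            raise ValueError("grid and probs must have equal length")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if abs(float(self.probs.sum()) - 1.0) > 1e-9:
            raise ValueError("probs must sum to 1 within 1e-9")


@dataclass
class MorphNetwork:
    """Symmetric KLS similarity matrix over the retained regions."""

    region_labels: list[int]
    matrix: np.ndarray
    subject_id: str = ""
    config: NetworkConfig = field(default_factory=NetworkConfig)

    @property
    def n_regions(self) -> int:
        return len(self.region_labels)

    def flatten(self) -> np.ndarray:
        """Row-major flattening used as the baseline feature vector."""
        return self.matrix.reshape(-1)


def extract_region_values(
    gm: GMVolumeMap, atlas: ParcellationAtlas, config: NetworkConfig | None = None
) -> dict[int, np.ndarray]:
    """Collect GM voxel values per retained region, ordered by ascending label."""
    config = config or NetworkConfig()
    if gm.values.shape != atlas.label_volume.shape:
        raise ValueError(
            f"GM map shape {gm.values.shape} does not match atlas "
            f"{atlas.label_volume.shape}"
        )
    expected = (
        sorted(int(k) for k in atlas.label_names)
        if atlas.label_names
        else sorted(int(x) for x in atlas.labels)
    )
    out: dict[int, np.ndarray] = {}
    for lab in expected:
        if lab in config.excluded_labels:
            continue
        vals = gm.values[atlas.label_volume == lab]
        if vals.size == 0:
            raise ValueError(f"retained region {lab} has no voxels")
        out[lab] = np.asarray(vals, dtype=np.float64)
    return out


def silverman_bandwidth(values: np.ndarray) -> float:
    """Silverman's rule of thumb, 0.9 * min(sd, IQR/1.34) * n^(-1/5)."""
    n = values.size
    sd = float(np.std(values, ddof=1)) if n > 1 else 0.0
    q75, q25 = np.percentile(values, [75, 25])
    iqr = float(q75 - q25)
    spread = min(x for x in (sd, iqr / 1.34) if x > 0) if (sd > 0 or iqr > 0) else 0.0
    return 0.9 * spread * n ** (-0.2)


def _bandwidth(values: np.ndarray, config: NetworkConfig) -> float:
    if isinstance(config.bandwidth_rule, str):
        h = silverman_bandwidth(values)
        if h <= 0:
            scale = max(abs(float(values[0])), 1.0)
            h = 1e-3 * scale
            warnings.warn(
                "zero-variance sample: falling back to fixed minimal bandwidth",
                RuntimeWarning,
                stacklevel=2,
            )
        return h
    return float(config.bandwidth_rule)


def make_shared_grid(
    region_values: dict[int, np.ndarray], config: NetworkConfig | None = None
) -> np.ndarray:
    """Equally spaced grid spanning the pooled value range of all regions,
    padded by ``grid_pad_bandwidths`` times the largest region bandwidth."""
    config = config or NetworkConfig()
    lo = min(float(v.min()) for v in region_values.values())
    hi = max(float(v.max()) for v in region_values.values())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        hmax = max(_bandwidth(v, config) for v in region_values.values())
    pad = config.grid_pad_bandwidths * hmax
    if hi - lo + 2 * pad <= 0:
        pad = max(pad, 0.5)  # degenerate all-constant subject
    return np.linspace(lo - pad, hi + pad, config.grid_size)


def estimate_density(
    values: np.ndarray | list[float],
    config: NetworkConfig | None = None,
    grid: np.ndarray | None = None,
) -> DensityProfile:
    """Gaussian-KDE density of one region, discretized and normalized to sum 1.

    The kernel sum (1/nh) sum_j K((g - v_j)/h) is evaluated at every grid
    point, floored at ``prob_floor`` and renormalized; the floor keeps the
    divergence logs finite where the kernels carry no mass.
    """
    config = config or NetworkConfig()
    values = np.asarray(values, dtype=np.float64).ravel()
    if values.size == 0 or not np.all(np.isfinite(values)):
        raise ValueError("values must be non-empty and finite")
    h = _bandwidth(values, config)
    if grid is None:
        grid = make_shared_grid({0: values}, config)
    z = (grid[:, None] - values[None, :]) / h
    dens = np.exp(-0.5 * z * z).sum(axis=1) / (values.size * h * math.sqrt(2 * math.pi))
    dens = dens + config.prob_floor
    return DensityProfile(grid=np.asarray(grid, float), probs=dens / dens.sum())


def symmetric_kl(p: DensityProfile, q: DensityProfile) -> float:
    """Symmetrized KL divergence sum_g [P ln(P/Q) + Q ln(Q/P)] >= 0."""
    if p.grid.shape != q.grid.shape or not np.allclose(p.grid, q.grid, rtol=0, atol=0):
        raise ValueError("densities must live on identical grids")
    lp, lq = np.log(p.probs), np.log(q.probs)
    return float(np.sum(p.probs * (lp - lq) + q.probs * (lq - lp)))


def kls(p: DensityProfile, q: DensityProfile) -> float:
    """KL-divergence-based similarity exp(-D(P,Q)), in (0, 1]."""
    return math.exp(-symmetric_kl(p, q))


def build_network(
    gm: GMVolumeMap, atlas: ParcellationAtlas, config: NetworkConfig | None = None
) -> MorphNetwork:
    """Construct the subject's KLS similarity matrix over retained regions."""
    config = config or NetworkConfig()
    region_values = extract_region_values(gm, atlas, config)
    labels = list(region_values.keys())
    grid = make_shared_grid(region_values, config)
    probs = np.stack(
        [estimate_density(region_values[lab], config, grid).probs for lab in labels]
    )
    # D_ab = sum_g (P_a - P_b)(ln P_a - ln P_b) = A_aa + A_bb - A_ab - A_ba
    # with A = P @ (ln P)^T; exponentiate to similarity.
    logp = np.log(probs)
    a = probs @ logp.T
    d = np.diag(a)[:, None] + np.diag(a)[None, :] - a - a.T
    mat = np.exp(-np.maximum(0.5 * (d + d.T), 0.0))
    np.fill_diagonal(mat, 1.0)
    return MorphNetwork(
        region_labels=labels, matrix=mat, subject_id=gm.subject_id, config=config
    )


# ---------------------------------------------------------------------------
# TSV I/O


def save_network(net: MorphNetwork, path: str, sidecar: bool = True) -> None:
    """Dense TSV with a header row of region labels + JSON config sidecar."""
    header = "\t".join(str(lab) for lab in net.region_labels)
    np.savetxt(path, net.matrix, delimiter="\t", header=header, comments="")
    if sidecar:
        cfg = net.config
        meta = {
            "subject_id": net.subject_id,
            "excluded_labels": sorted(cfg.excluded_labels),
            "grid_size": cfg.grid_size,
            "bandwidth_rule": cfg.bandwidth_rule,
            "prob_floor": cfg.prob_floor,
        }
        with open(os.path.splitext(path)[0] + ".json", "w") as fh:
            json.dump(meta, fh, indent=2)


def load_network(path: str, subject_id: str = "") -> MorphNetwork:
    with open(path) as fh:
        labels = [int(x) for x in fh.readline().split()]
    mat = np.loadtxt(path, delimiter="\t", skiprows=1)
    return MorphNetwork(
        region_labels=labels,
        matrix=mat,
        subject_id=subject_id or os.path.splitext(os.path.basename(path))[0],
    )
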