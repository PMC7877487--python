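"""Synthetic stand-in for a preprocessed multisite structural-MRI cohort.

Real inputs to the pipeline are per-subject gray-matter (GM) volume maps in a
common template space plus an integer-labeled parcellation atlas.  This module
generates both: a compact 116-region parcellation grown from seeded centroids
inside an ellipsoidal brain mask, and cohorts of GM maps whose within-region
voxel-value distributions optionally differ between the two diagnostic groups
(ASD vs. typical controls, TC) in a configurable set of regions.

Regional voxel values are drawn from Gamma distributions (positive, skewed —
qualitatively like GM density maps).  The group effect is a multiplicative
shift of the Gamma scale parameter in the affected regions, so the *whole*
value distribution changes, which is exactly what the KL-similarity edges
downstream are sensitive to.  Multisite heterogeneity is emulated by a small
additive per-site offset on the scale parameter of every region.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .atlas_names import AAL116_NAMES, VERMIS_LABELS

MIN_REGION_VOXELS = 30


@dataclass
class ParcellationAtlas:
    """Integer-labeled 3D parcellation (0 = background, 1..n = regions)."""

    label_volume: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    label_names: dict[int, str] = field(default_factory=dict)

    @property
    def labels(self) -> np.ndarray:
        labs = np.unique(self.label_volume)
        return labs[labs > 0]

    def region_size(self, label: int) -> int:
        return int(np.count_nonzero(self.label_volume == label))


@dataclass
class GMVolumeMap:
    """Per-subject gray-matter volume map aligned to the atlas grid."""

    subject_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("GM map must be finite and non-negative")


@dataclass
class SiteSpec:
    name: str
    scale_offset: float = 0.0


@dataclass
class EffectConfig:
    """Controls the planted ASD-vs-TC group difference and site effects.

    ``shift_magnitude`` is the relative change of the Gamma scale parameter in
    the member regions of ``affected_region_pairs`` for the ASD group;
    0 means the two groups are identically distributed.  ``noise_sd`` is
    additive voxel-level Gaussian noise (clipped at 0).  ``subject_sd`` is the
    log-normal sd of the per-subject, per-region scale jitter that creates
    within-group variability between subjects.
    """

    affected_region_pairs: list[tuple[int, int]] = field(default_factory=list)
    shift_magnitude: float = 0.0
    noise_sd: float = 0.02
    subject_sd: float = 0.05
    sites: list[SiteSpec] = field(
        default_factory=lambda: [
            SiteSpec("SITE_A", 0.0),
            SiteSpec("SITE_B", 0.008),
            SiteSpec("SITE_C", -0.008),
        ]
    )

    def __post_init__(self) -> None:
        if self.shift_magnitude < 0:
            raise ValueError("shift_magnitude must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.shift_magnitude > 0 and not self.affected_region_pairs:
            raise ValueError(
                "shift_magnitude > 0 requires a non-empty affected_region_pairs"
            )

    @property
    def affected_regions(self) -> set[int]:
        out: set[int] = set()
        for a, b in self.affected_region_pairs:
            out.update((int(a), int(b)))
        return out


DEFAULT_AFFECTED_PAIRS: list[tuple[int, int]] = [
    # precentral / superior-frontal / orbital-superior-frontal vs cerebellum
    # 8-10, mirroring where the discriminative covariance is planted
    (1, 103), (2, 104), (3, 105), (4, 106), (5, 107), (6, 108),
]


def default_effect(shift_magnitude: float = 0.5, n_regions: int = 116) -> EffectConfig:
    """Study-condition default: signal planted in 6 frontal-cerebellar pairs.

    For reduced parcellations (< 108 regions) the six pairs link the first
    six regions to the last six so the planted signal always exists.
    """
    if shift_magnitude == 0:
        pairs: list[tuple[int, int]] = []
    elif n_regions >= 108:
        pairs = DEFAULT_AFFECTED_PAIRS
    else:
        pairs = [(i, n_regions - 6 + i) for i in range(1, 7)]
    return EffectConfig(affected_region_pairs=pairs, shift_magnitude=shift_magnitude)


def _brain_mask(grid_shape: tuple[int, int, int]) -> np.ndarray:
    # ellipsoid with semi-axes at 45% of each dimension
    axes = [np.linspace(-1, 1, s) for s in grid_shape]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    return (xx / 0.9) ** 2 + (yy / 0.9) ** 2 + (zz / 0.9) ** 2 <= 1.0


def generate_atlas(
    grid_shape: tuple[int, int, int] = (48, 48, 48),
    n_regions: int = 116,
    seed: int = 0,
) -> ParcellationAtlas:
    """Grow a compact ``n_regions``-label parcellation inside a brain mask.

    Random centroids are seeded in the mask and voxels assigned to the nearest
    centroid; a few Lloyd relaxation steps balance region sizes.  Deterministic
    for a fixed seed.  Raises ``ValueError`` if the grid cannot host
    ``n_regions`` regions of at least 30 voxels each.
    """
    if n_regions < 2:
        raise ValueError("n_regions must be >= 2")
    mask = _brain_mask(tuple(grid_shape))
    coords = np.argwhere(mask).astype(np.float64)
    if coords.shape[0] < MIN_REGION_VOXELS * n_regions:
        raise ValueError(
            f"grid {tuple(grid_shape)} too small: {coords.shape[0]} brain voxels "
            f"cannot host {n_regions} regions of >= {MIN_REGION_VOXELS} voxels"
        )
    rng = np.random.default_rng(seed)
    centroids = coords[rng.choice(coords.shape[0], size=n_regions, replace=False)]
    assign = np.empty(coords.shape[0], dtype=np.int32)
    for _ in range(4):  # Lloyd steps: nearest-centroid assign, recenter
        d = cdist(coords, centroids)
        assign = np.argmin(d, axis=1).astype(np.int32)
        for r in range(n_regions):
            sel = assign == r
            if np.any(sel):
                centroids[r] = coords[sel].mean(axis=0)
    label_volume = np.zeros(tuple(grid_shape), dtype=np.int32)
    label_volume[mask] = assign + 1
    sizes = np.bincount(assign, minlength=n_regions)
    if np.any(sizes < MIN_REGION_VOXELS):
        bad = np.nonzero(sizes < MIN_REGION_VOXELS)[0] + 1
        raise ValueError(f"regions {bad.tolist()} smaller than {MIN_REGION_VOXELS} voxels")
    names = (
        dict(AAL116_NAMES)
        if n_regions == 116
        else {r: f"Region_{r:03d}" for r in range(1, n_regions + 1)}
    )
    return ParcellationAtlas(label_volume=label_volume, label_names=names)


def _region_base_params(
    n_regions: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Fixed per-region Gamma(shape, scale) baselines shared by both groups."""
    rng = np.random.default_rng([seed, 0xA71A5])
    shape = rng.uniform(3.0, 6.0, size=n_regions)
    scale = rng.uniform(0.08, 0.15, size=n_regions)
    return shape, scale


def simulate_cohort(
    atlas: ParcellationAtlas,
    n_asd: int,
    n_tc: int,
    effect: EffectConfig | None = None,
    seed: int = 0,
) -> tuple[list[GMVolumeMap], pd.DataFrame]:
    """Simulate GM maps and a phenotype table for ``n_asd`` + ``n_tc`` subjects.

    Voxel values in region ``r`` follow Gamma(k_r, theta_r) where theta_r gets
    (i) a per-site additive offset, (ii) a per-subject log-normal jitter, and
    (iii) for ASD subjects in affected regions a ``(1 + shift_magnitude)``
    multiplier.  Per-subject random streams are derived from the master seed,
    so any cohort is bit-reproducible.
    """
    if n_asd < 1 or n_tc < 1:
        raise ValueError("n_asd and n_tc must be >= 1")
    effect = effect if effect is not None else EffectConfig()
    labels = atlas.labels
    n_regions = labels.size
    shape_r, scale_r = _region_base_params(n_regions, seed)
    affected = effect.affected_regions
    affected_idx = np.array(
        [i for i, lab in enumerate(labels) if int(lab) in affected], dtype=int
    )

    rng_pheno = np.random.default_rng([seed, 0xBEEF])
    diagnoses = ["ASD"] * n_asd + ["TC"] * n_tc
    n_total = n_asd + n_tc
    site_names = [s.name for s in effect.sites]
    site_offsets = {s.name: s.scale_offset for s in effect.sites}
    sites = [site_names[i % len(site_names)] for i in range(n_total)]
    rng_pheno.shuffle(sites)
    ages = rng_pheno.uniform(8.0, 30.0, size=n_total)
    sexes = np.where(rng_pheno.random(n_total) < 0.8, "M", "F")

    region_voxels = [np.nonzero(atlas.label_volume == lab) for lab in labels]
    gm_maps: list[GMVolumeMap] = []
    rows = []
    for i in range(n_total):
        dx = diagnoses[i]
        sid = f"sub-{i:04d}"
        rng = np.random.default_rng([seed, 1, i])  # per-subject stream
        theta = scale_r + site_offsets[sites[i]]
        theta = theta * rng.lognormal(0.0, effect.subject_sd, size=n_regions)
        if dx == "ASD" and affected_idx.size and effect.shift_magnitude > 0:
            theta = theta.copy()
            theta[affected_idx] *= 1.0 + effect.shift_magnitude
        vol = np.zeros(atlas.label_volume.shape, dtype=np.float64)
        for r, vox in enumerate(region_voxels):
            n_vox = vox[0].size
            vals = rng.gamma(shape_r[r], theta[r], size=n_vox)
            vals += rng.normal(0.0, effect.noise_sd, size=n_vox)
            vol[vox] = np.clip(vals, 0.0, None)
        gm_maps.append(GMVolumeMap(subject_id=sid, values=vol))
        rows.append((sid, dx, sites[i], round(float(ages[i]), 1), str(sexes[i])))

    phenotypes = pd.DataFrame(
        rows, columns=["subject_id", "dx", "site", "age", "sex"]
    )
    return gm_maps, phenotypes


# ---------------------------------------------------------------------------
# NIfTI / CSV I/O


def _affine(voxel_size_mm: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size_mm
    return aff


def save_atlas(atlas: ParcellationAtlas, path: str) -> None:
    img = nib.Nifti1Image(atlas.label_volume.astype(np.int16), _affine(atlas.voxel_size_mm))
    nib.save(img, path)


def load_atlas(path: str, label_names: dict[int, str] | None = None) -> ParcellationAtlas:
    img = nib.load(path)
    vol = np.asarray(img.dataobj).astype(np.int32)
    vox = tuple(float(z) for z in img.header.get_zooms()[:3])
    names = label_names or {
        int(lab): AAL116_NAMES.get(int(lab), f"Region_{int(lab):03d}")
        for lab in np.unique(vol)
        if lab > 0
    }
    return ParcellationAtlas(label_volume=vol, voxel_size_mm=vox, label_names=names)


def save_gm_map(gm: GMVolumeMap, path: str) -> None:
    img = nib.Nifti1Image(gm.values.astype(np.float32), _affine((1.0, 1.0, 1.0)))
    nib.save(img, path)


def load_gm_map(path: str, subject_id: str | None = None) -> GMVolumeMap:
    img = nib.load(path)
    sid = subject_id or os.path.basename(path).split(".")[0]
    return GMVolumeMap(subject_id=sid, values=np.asarray(img.dataobj, dtype=np.float64))


def save_cohort(
    gm_maps: list[GMVolumeMap],
    phenotypes: pd.DataFrame,
    atlas: ParcellationAtlas,
    out_dir: str,
) -> dict[str, str]:
    """Write atlas, GM maps (.nii.gz) and phenotype CSV; return path map."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {"atlas": os.path.join(out_dir, "atlas.nii.gz")}
    save_atlas(atlas, paths["atlas"])
    for gm in gm_maps:
        p = os.path.join(out_dir, f"{gm.subject_id}_gm.nii.gz")
        save_gm_map(gm, p)
        paths[gm.subject_id] = p
    paths["phenotypes"] = os.path.join(out_dir, "phenotypes.csv")
    phenotypes.to_csv(paths["phenotypes"], index=False)
    return paths
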