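"""Gradient-weighted class activation mapping for the residual classifier.

For a target class c, the gradient of the class score with respect to the
activations A^k of the last convolutional stage is spatially averaged into
channel importance weights

    alpha_k = (1/Z) sum_i sum_j  d y_c / d A^k_ij ,

and the map ReLU(sum_k alpha_k A^k), computed at the last stage's coarse
resolution, is bilinearly upsampled to the 108 x 108 input resolution.  Maps
of correctly classified ASD test subjects are fused by element-wise
averaging; after symmetrization, edges whose fused weight exceeds
mean + k*SD (k = 3) of the upper-triangle entries are reported as the
connectivities driving the classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .classifier import TrainedModel
from .network import MorphNetwork
from .nn import ResNetClassifier


@dataclass
class ImportanceMap:
    matrix: np.ndarray
    source: str = "single"  # "single" or "fused"
    subject_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if np.any(self.matrix < 0):
            raise ValueError("importance maps are non-negative by construction")


@dataclass
class ConnectivitySelection:
    edges: list[tuple[int, int, float]]  # (label_a, label_b, weight), a < b
    threshold: float
    region_set: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.region_set = sorted({lab for a, b, _ in self.edges for lab in (a, b)})


def _class_score_grad(target_class: int) -> float:
    # single-logit head: score of class 1 is the logit, of class 0 its negation
    if target_class not in (0, 1):
        raise ValueError("target_class must be 0 or 1")
    return 1.0 if target_class == 1 else -1.0


def _unwrap(model: TrainedModel | ResNetClassifier) -> ResNetClassifier:
    return model.model if isinstance(model, TrainedModel) else model


def neuron_weights(
    model: TrainedModel | ResNetClassifier,
    network: MorphNetwork | np.ndarray,
    target_class: int = 1,
) -> np.ndarray:
    """Channel importance weights alpha_k at the last convolutional stage."""
    _, grads = _activations_and_gradients(model, network, target_class)
    return grads.mean(axis=(1, 2))


def _activations_and_gradients(
    model: TrainedModel | ResNetClassifier,
    network: MorphNetwork | np.ndarray,
    target_class: int,
) -> tuple[np.ndarray, np.ndarray]:
    net = _unwrap(model)
    mat = network.matrix if isinstance(network, MorphNetwork) else np.asarray(network)
    x = mat.astype(np.float32)[None, None]
    net.forward_logits(x, training=False)
    acts = net.stage_activations[-1][0]
    sign = _class_score_grad(target_class)
    grads = net.backward_from_logits(
        np.array([sign], dtype=np.float32), to_stage=len(net.stages) - 1
    )[0]
    return acts.astype(np.float64), grads.astype(np.float64)


def combine_cam(alpha: np.ndarray, activations: np.ndarray) -> np.ndarray:
    """ReLU(sum_k alpha_k A^k): the rectified weighted activation map."""
    return np.maximum(np.tensordot(alpha, activations, axes=([0], [0])), 0.0)


def gradcam_map(
    model: TrainedModel | ResNetClassifier,
    network: MorphNetwork | np.ndarray,
    target_class: int = 1,
    upsample_to: int | None = None,
) -> ImportanceMap:
    """ReLU-rectified weighted activation map, upsampled to input resolution."""
    acts, grads = _activations_and_gradients(model, network, target_class)
    alpha = grads.mean(axis=(1, 2))
    coarse = combine_cam(alpha, acts)
    size = upsample_to or (
        network.matrix.shape[0]
        if isinstance(network, MorphNetwork)
        else np.asarray(network).shape[0]
    )
    up = _bilinear_resize(coarse, size)
    sid = network.subject_id if isinstance(network, MorphNetwork) else ""
    return ImportanceMap(matrix=up, source="single", subject_ids=[sid] if sid else [])


def _bilinear_resize(m: np.ndarray, size: int) -> np.ndarray:
    if m.shape == (size, size):
        return m
    zoom = (size / m.shape[0], size / m.shape[1])
    out = ndimage.zoom(m, zoom, order=1, grid_mode=True, mode="nearest")
    return np.maximum(out, 0.0)


def fuse_maps(maps: list[ImportanceMap]) -> ImportanceMap:
    """Element-wise mean of per-subject maps, then symmetrized."""
    if not maps:
        raise ValueError("need at least one importance map to fuse")
    shape = maps[0].matrix.shape
    if any(m.matrix.shape != shape for m in maps):
        raise ValueError("all maps must share one shape")
    fused = np.mean([m.matrix for m in maps], axis=0)
    fused = 0.5 * (fused + fused.T)
    sids = [s for m in maps for s in m.subject_ids]
    return ImportanceMap(matrix=fused, source="fused", subject_ids=sids)


def select_connectivities(
    fused: ImportanceMap,
    region_labels: list[int],
    k_sd: float = 3.0,
) -> ConnectivitySelection:
    """Edges whose fused weight strictly exceeds mean + k_sd * SD.

    Statistics are computed over the strict upper triangle (self-similarity
    is not a connectivity); edges are returned with label_a < label_b sorted
    by descending weight.
    """
    m = fused.matrix
    n = m.shape[0]
    if len(region_labels) != n:
        raise ValueError("region_labels must match map size")
    iu, ju = np.triu_indices(n, k=1)
    vals = m[iu, ju]
    threshold = float(vals.mean() + k_sd * vals.std())
    keep = vals > threshold
    edges = [
        (int(region_labels[i]), int(region_labels[j]), float(w))
        for i, j, w in zip(iu[keep], ju[keep], vals[keep])
    ]
    edges.sort(key=lambda e: -e[2])
    return ConnectivitySelection(edges=edges, threshold=threshold)


def rank_edges(
    fused: ImportanceMap, region_labels: list[int]
) -> list[tuple[int, int, float]]:
    """All upper-triangle edges sorted by descending fused weight.

    The mean + 3SD selection can legitimately be empty on smooth fused maps
    (upsampled from a coarse grid they have no extreme tail); the full
    ranking still orders connectivities by their contribution and is what
    localization analyses should use in that regime.
    """
    m = fused.matrix
    n = m.shape[0]
    if len(region_labels) != n:
        raise ValueError("region_labels must match map size")
    iu, ju = np.triu_indices(n, k=1)
    order = np.argsort(m[iu, ju])[::-1]
    return [
        (int(region_labels[iu[k]]), int(region_labels[ju[k]]), float(m[iu[k], ju[k]]))
        for k in order
    ]


def fuse_and_select(
    maps: list[ImportanceMap],
    region_labels: list[int],
    k_sd: float = 3.0,
) -> ConnectivitySelection:
    return select_connectivities(fuse_maps(maps), region_labels, k_sd)


def save_heatmap_png(fused: ImportanceMap, path: str, title: str = "fused Grad-CAM") -> None:
    """Optional figure: the fused importance map as a heat map."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(fused.matrix, cmap="hot", interpolation="nearest")
    ax.set_xlabel("region index")
    ax.set_ylabel("region index")
    ax.set_title(title)
    fig.colorbar(im, ax=ax, label="importance")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def maps_for_correct_asd(
    models: dict[int, TrainedModel],
    networks: list[MorphNetwork],
    fold_results,
) -> list[ImportanceMap]:
    """Grad-CAM maps for every correctly classified ASD test subject."""
    by_id = {net.subject_id: net for net in networks}
    maps: list[ImportanceMap] = []
    hits = fold_results[(fold_results["label"] == 1) & (fold_results["pred"] == 1)]
    for _, row in hits.iterrows():
        net = by_id.get(row["subject_id"])
        if net is None:
            continue
        maps.append(gradcam_map(models[int(row["repeat"])], net, target_class=1))
    return maps
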