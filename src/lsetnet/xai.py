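"""Explainability: Grad-CAM, LIME surrogates, embedding projection and
failure panels.

Grad-CAM weights each channel of a convolutional feature map by the
spatial mean of the gradient of the (pre-softmax) class logit with
respect to that map, sums, rectifies, and max-normalizes:

    alpha_k = (1/Z) sum_ij  d y_c / d A_k(i, j),     Z = H * W
    L_c     = ReLU( sum_k alpha_k A_k ) / max

The LIME surrogate fits a weighted ridge regression of the black box's
class probability on binary superpixel masks; perturbed images replace
masked-out segments by the segment's mean color, and perturbations are
weighted by an exponential kernel on the cosine distance to the full
mask.

The t-SNE projection itself delegates to scikit-learn; this module owns
feature extraction (the GAP embedding feeding the dense head), the
per-class centroid/spread summary and silhouette scoring of the 2-D
coordinates, and the KL objective bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.segmentation import slic
from skimage.transform import resize as sk_resize

from .architecture import LSeTNet
from .nn.layers import softmax

F32 = np.float32


# ---------------------------------------------------------------------------
# Grad-CAM
# ---------------------------------------------------------------------------

@dataclass
class ExplanationMap:
    map: np.ndarray            # (H, W) in [0, 1]
    target_class: int
    mean_intensity: float
    top5_mean: float
    overlay: np.ndarray | None = None  # upsampled to image resolution


def heatmap_stats(norm_map: np.ndarray) -> tuple[float, float]:
    """(mean intensity, mean of the top ceil(5%) pixels) of a normalized map."""
    flat = np.asarray(norm_map, dtype=np.float64).ravel()
    mean = float(flat.mean())
    k = int(np.ceil(0.05 * flat.size))
    top = np.sort(flat)[-k:]
    return mean, float(top.mean())


def grad_cam(model: LSeTNet, image: np.ndarray, target_class: int,
             target_layer: str = "extra_conv", upsample_to: int | None = None) -> ExplanationMap:
    """Class-discriminative attribution at a named convolutional stage.

    Uses the pre-softmax logit as the class score; the map is rectified
    and normalized by its max (an all-zero map stays zero).
    """
    x = np.asarray(image, dtype=F32)
    if x.ndim == 3:
        x = x[None]
    logits = model.forward(x, training=False)
    if target_layer not in model.activations:
        raise KeyError(f"unknown stage {target_layer!r}")
    acts = model.activations[target_layer]
    if acts.ndim != 4:
        raise ValueError(f"stage {target_layer!r} has no spatial extent")
    seed = np.zeros_like(logits)
    seed[:, target_class] = 1.0
    model.backward(seed)
    grads = model.grad_activations[target_layer]

    a = acts[0].astype(np.float64)          # (H, W, K)
    g = grads[0].astype(np.float64)
    alpha = g.mean(axis=(0, 1))             # (K,): 1/Z sum_ij dy/dA
    cam = np.maximum((a * alpha).sum(axis=-1), 0.0)
    peak = cam.max()
    if peak > 0:
        cam = cam / peak
    mean, top5 = heatmap_stats(cam)
    overlay = None
    if upsample_to is not None:
        overlay = sk_resize(cam, (upsample_to, upsample_to), order=1,
                            mode="edge", anti_aliasing=False, preserve_range=True)
    return ExplanationMap(map=cam, target_class=target_class,
                          mean_intensity=mean, top5_mean=top5, overlay=overlay)


# ---------------------------------------------------------------------------
# LIME
# ---------------------------------------------------------------------------

@dataclass
class SurrogateExplanation:
    segments: np.ndarray              # (H, W) superpixel id per pixel
    intercept: float
    weights: np.ndarray               # (M,) per-segment weights
    top_segments: list[tuple[int, float]]  # 5 largest-weight segments
    fidelity: float                   # weighted R^2 of the surrogate
    target_class: int


def _cosine_distance_to_full(masks: np.ndarray) -> np.ndarray:
    """Cosine distance between each binary mask and the all-ones mask."""
    m = masks.astype(np.float64)
    ones = np.ones(m.shape[1])
    num = m @ ones
    denom = np.linalg.norm(m, axis=1) * np.linalg.norm(ones)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos = np.where(denom > 0, num / np.maximum(denom, 1e-300), 0.0)
    return 1.0 - cos


def lime_explain(predict_fn, image: np.ndarray, n_segments: int = 100,
                 n_samples: int = 1000, kernel_width: float = 0.25,
                 ridge: float = 1.0, seed: int = 0,
                 target_class: int | None = None,
                 segments: np.ndarray | None = None,
                 enumerate_all: bool = False) -> SurrogateExplanation:
    """Local surrogate explanation of ``predict_fn`` at ``image``.

    Superpixels come from SLIC unless an explicit segment map is given.
    ``enumerate_all`` replaces sampling by full enumeration of the 2^M
    masks (only sensible for small M); with ``ridge=0`` and enumeration
    the surrogate recovers a mask-linear black box exactly.
    """
    if n_segments < 2:
        raise ValueError("need at least 2 segments")
    image = np.asarray(image)
    if segments is None:
        segments = slic(image, n_segments=n_segments, compactness=10.0, start_label=0)
    seg_ids = np.unique(segments)
    m = len(seg_ids)
    rng = np.random.default_rng(seed)

    if enumerate_all:
        masks = ((np.arange(2 ** m)[:, None] >> np.arange(m)) & 1).astype(np.float64)
    else:
        masks = (rng.random((n_samples, m)) < 0.5).astype(np.float64)
        masks[0] = 1.0  # always include the undisturbed instance

    # per-segment mean color fill
    fill = np.zeros_like(image, dtype=np.float64)
    for si in seg_ids:
        sel = segments == si
        fill[sel] = image[sel].reshape(-1, image.shape[-1]).mean(axis=0)

    preds = np.empty(len(masks))
    probe = predict_fn(image)
    k_classes = np.asarray(probe).ravel().shape[0]
    if target_class is None:
        target_class = int(np.asarray(probe).ravel().argmax())
    for i, z in enumerate(masks):
        pert = image.astype(np.float64).copy()
        off = ~np.isin(segments, seg_ids[z.astype(bool)])
        pert[off] = fill[off]
        out = np.asarray(predict_fn(pert.astype(image.dtype))).ravel()
        preds[i] = out[target_class] if out.shape[0] == k_classes else float(out)

    d = _cosine_distance_to_full(masks)
    pi = np.exp(-(d ** 2) / (kernel_width ** 2))

    # weighted ridge with unpenalized intercept
    xc = masks - np.average(masks, axis=0, weights=pi)
    yc = preds - np.average(preds, weights=pi)
    a = (xc * pi[:, None]).T @ xc + ridge * np.eye(m)
    b = (xc * pi[:, None]).T @ yc
    w = np.linalg.solve(a, b)
    intercept = np.average(preds, weights=pi) - float(np.average(masks, axis=0, weights=pi) @ w)

    fitted = masks @ w + intercept
    ss_res = float(np.sum(pi * (preds - fitted) ** 2))
    ss_tot = float(np.sum(pi * (preds - np.average(preds, weights=pi)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0

    order = np.argsort(-np.abs(w))[:5]
    top = [(int(seg_ids[i]), float(w[i])) for i in order]
    return SurrogateExplanation(segments=segments, intercept=float(intercept),
                                weights=w, top_segments=top, fidelity=r2,
                                target_class=int(target_class))


# ---------------------------------------------------------------------------
# embeddings, t-SNE, silhouettes
# ---------------------------------------------------------------------------

def extract_embeddings(model: LSeTNet, images: np.ndarray, batch_size: int = 64) -> np.ndarray:
    """GAP-layer embedding (the vector feeding the dense head) per image."""
    images = np.asarray(images, dtype=F32)
    if images.ndim == 3:
        images = images[None]
    feats = []
    for i in range(0, len(images), batch_size):
        model.forward(images[i:i + batch_size], training=False)
        feats.append(model.activations["gap"].copy())
    return np.concatenate(feats, axis=0)


def kl_divergence(p: np.ndarray, q: np.ndarray, eps: float = 1e-300) -> float:
    """KL(P || Q) = sum_ij p_ij log(p_ij / q_ij) over matched distributions."""
    p = np.asarray(p, dtype=np.float64)
    q = np.asarray(q, dtype=np.float64)
    mask = p > 0
    return float(np.sum(p[mask] * np.log(p[mask] / np.maximum(q[mask], eps))))


@dataclass
class ProjectionResult:
    coords: np.ndarray                     # (N, 2)
    labels: np.ndarray
    centroids: dict = field(default_factory=dict)  # label -> (x, y)
    spreads: dict = field(default_factory=dict)    # label -> (std_x, std_y)
    silhouette: float = 0.0
    objective: float = np.nan              # final KL(P || Q)


def project_tsne(features: np.ndarray, labels, perplexity: float = 30.0,
                 seed: int = 0, n_iter: int = 1000) -> ProjectionResult:
    """2-D t-SNE of feature vectors plus per-class cluster statistics.

    Requires at least 3 * perplexity samples.  Silhouette is computed
    with Euclidean distance on the projected coordinates.
    """
    from sklearn.manifold import TSNE
    from sklearn.metrics import silhouette_score

    features = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels)
    n = len(features)
    if n < 3 * perplexity:
        raise ValueError(f"need >= {int(3 * perplexity)} samples for perplexity {perplexity}")
    tsne = TSNE(n_components=2, perplexity=perplexity, random_state=seed,
                max_iter=n_iter, init="pca")
    coords = tsne.fit_transform(features)
    result = ProjectionResult(coords=coords, labels=labels,
                              objective=float(tsne.kl_divergence_))
    for lab in np.unique(labels):
        sel = labels == lab
        result.centroids[lab] = tuple(coords[sel].mean(axis=0))
        result.spreads[lab] = tuple(coords[sel].std(axis=0))
    if len(np.unique(labels)) > 1:
        result.silhouette = float(silhouette_score(coords, labels))
    return result


# ---------------------------------------------------------------------------
# failure panel
# ---------------------------------------------------------------------------

@dataclass
class FailureCase:
    image_index: int
    true_label: str
    predicted_label: str
    predicted_probability: float
    class_probabilities: np.ndarray
    explanation: ExplanationMap | None


def failure_panel(model: LSeTNet, images: np.ndarray, y_true, classes: list[str],
                  explain: bool = True, target_layer: str = "extra_conv") -> list[FailureCase]:
    """One panel entry per misclassified image: labels, confidence,
    Grad-CAM map and the full class-probability vector.  A perfect model
    yields an empty panel."""
    probs = model.predict_proba(images)
    preds = probs.argmax(axis=1)
    y_true = np.asarray(y_true)
    panel = []
    for i in np.flatnonzero(preds != y_true):
        exp = None
        if explain:
            exp = grad_cam(model, images[i], int(preds[i]), target_layer=target_layer)
        panel.append(FailureCase(
            image_index=int(i),
            true_label=classes[int(y_true[i])],
            predicted_label=classes[int(preds[i])],
            predicted_probability=float(probs[i, preds[i]]),
            class_probabilities=probs[i],
            explanation=exp,
        ))
    return panel
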