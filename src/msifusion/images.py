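"""Microscope-image path: foreground extraction, black-background
compositing, and model-input normalization.

Foreground segmentation follows the GrabCut scheme: Gaussian-mixture color
models for foreground and background are refitted alternately with a
minimum s-t cut on an 8-connected pixel graph whose n-link weights decay
with local color contrast.  Pixels outside the initialization rectangle are
held as definite background; pixels inside start as probable foreground and
are relabeled by each cut.
"""

from __future__ import annotations

import numpy as np
from skimage.transform import resize
from sklearn.mixture import GaussianMixture

__all__ = [
    "grabcut_foreground", "composite_black", "prepare_model_input",
    "IMAGENET_MEAN", "IMAGENET_STD",
]

IMAGENET_MEAN = (0.485, 0.456, 0.406)
IMAGENET_STD = (0.229, 0.224, 0.225)


def _default_rect(shape):
    """Image bounds shrunk 5% per side."""
    H, W = shape[:2]
    my, mx = max(1, int(round(0.05 * H))), max(1, int(round(0.05 * W)))
    return (my, mx, H - my, W - mx)  # (y0, x0, y1, x1), half-open


def _fit_gmm(pixels, n_components, seed):
    n_components = min(n_components, len(pixels))
    gm = GaussianMixture(n_components=n_components, covariance_type="full",
                         reg_covar=1e-3, random_state=seed, max_iter=50)
    gm.fit(pixels)
    return gm


def grabcut_foreground(image, init_rect=None, iterations=5, n_components=5,
                       gamma=50.0, seed=0):
    """Binary foreground mask via iterated GMM + graph min-cut.

    ``init_rect`` is ``(y0, x0, y1, x1)`` (half-open), strictly inside the
    image and covering the grain; by default the image bounds shrunk 5% per
    side.  The algorithm is deterministic given the image and rectangle.
    """
    import igraph

    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an H x W x 3 RGB image")
    H, W, _ = img.shape
    if init_rect is None:
        init_rect = _default_rect(img.shape)
    y0, x0, y1, x1 = init_rect
    if y1 <= y0 or x1 <= x0:
        raise ValueError("degenerate init_rect: zero area")
    if y0 < 0 or x0 < 0 or y1 > H or x1 > W or (y0 == 0 and x0 == 0
                                                and y1 == H and x1 == W):
        raise ValueError("init_rect must lie strictly inside the image")

    z = img.reshape(-1, 3).astype(np.float64)
    inside = np.zeros((H, W), bool)
    inside[y0:y1, x0:x1] = True
    inside_flat = inside.ravel()
    alpha = inside_flat.copy()                    # current foreground guess

    # n-links: 8-neighborhood, contrast-sensitive weights
    idx = np.arange(H * W).reshape(H, W)
    pairs, dists = [], []
    for dy, dx in ((0, 1), (1, 0), (1, 1), (1, -1)):
        if dx >= 0:
            a, b = idx[:H - dy, :W - dx], idx[dy:, dx:]
        else:
            a, b = idx[:H - dy, -dx:], idx[dy:, :dx]
        pairs.append(np.stack([a.ravel(), b.ravel()], axis=1))
        dists.append(np.full(a.size, np.hypot(dy, dx)))
    pairs = np.concatenate(pairs)
    dists = np.concatenate(dists)
    diff2 = ((z[pairs[:, 0]] - z[pairs[:, 1]]) ** 2).sum(axis=1)
    beta = 1.0 / max(2.0 * diff2.mean(), 1e-12)
    nweights = gamma * np.exp(-beta * diff2) / dists

    S, T = H * W, H * W + 1                       # source=fg, sink=bg
    big = float(nweights.sum() + 1e6)
    bg_fixed = np.flatnonzero(~inside_flat)
    free = np.flatnonzero(inside_flat)

    for _ in range(int(iterations)):
        fg_px = z[alpha]
        bg_px = z[~alpha]
        if len(fg_px) == 0:
            break
        gm_fg = _fit_gmm(fg_px, n_components, seed)
        gm_bg = _fit_gmm(bg_px, n_components, seed)
        d_fg = -gm_fg.score_samples(z[free])      # cost of labeling fg
        d_bg = -gm_bg.score_samples(z[free])

        edges = [(int(u), int(v)) for u, v in pairs]
        caps = list(nweights)
        # t-links: source capacity = bg cost (cut -> bg), sink = fg cost
        edges += [(S, int(p)) for p in free]
        caps += list(d_bg)
        edges += [(int(p), T) for p in free]
        caps += list(d_fg)
        edges += [(int(p), T) for p in bg_fixed]
        caps += [big] * len(bg_fixed)

        g = igraph.Graph(n=H * W + 2, edges=edges, directed=False)
        cut = g.st_mincut(S, T, capacity=caps)
        source_side = np.zeros(H * W + 2, bool)
        source_side[cut.partition[0]] = True
        if not source_side[S]:
            source_side = ~source_side
        new_alpha = alpha.copy()
        new_alpha[free] = source_side[free]
        new_alpha[bg_fixed] = False
        if (new_alpha == alpha).all():
            alpha = new_alpha
            break
        alpha = new_alpha

    mask = alpha.reshape(H, W)
    if not mask.any():
        raise ValueError("GrabCut found no foreground; enlarge or re-center "
                         "the initialization rectangle")
    return mask


def composite_black(image, mask):
    """Keep masked pixels, zero the rest (idempotent)."""
    img = np.asarray(image)
    mask = np.asarray(mask, bool)
    if mask.shape != img.shape[:2]:
        raise ValueError(f"mask shape {mask.shape} does not match image "
                         f"{img.shape[:2]}")
    out = np.zeros_like(img)
    out[mask] = img[mask]
    return out


def prepare_model_input(image, training=False, flip_probability=0.5,
                        mean=IMAGENET_MEAN, std=IMAGENET_STD, size=224,
                        rng=None):
    """Resize to ``size`` x ``size``, optionally flip, scale to [0,1] and
    standardize per channel; returns a float32 array of shape (3, size, size).

    With ``training=False`` the transform is a pure function of the input.
    """
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an H x W x 3 RGB image")
    out = resize(img.astype(np.float64) / 255.0, (size, size, 3),
                 anti_aliasing=True, mode="reflect")
    if training:
        rng = np.random.default_rng() if rng is None else rng
        if rng.random() < flip_probability:
            out = out[:, ::-1, :]
    mean = np.asarray(mean).reshape(1, 1, 3)
    std = np.asarray(std).reshape(1, 1, 3)
    out = (out - mean) / std
    return np.ascontiguousarray(out.transpose(2, 0, 1), dtype=np.float32)
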