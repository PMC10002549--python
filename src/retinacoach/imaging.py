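"""Fundus-image preprocessing, training augmentations, and a synthetic
fundus renderer.

Preprocessing follows the standard fundus pipeline: near-black borders are
trimmed, the circular eye area is located with a circular Hough transform,
the image is cropped to the circle's bounding square, contrast is enhanced
with CLAHE (contrast-limited adaptive histogram equalisation, applied on the
lightness channel of Lab space so colors are preserved), and the result is
resized to the network input size (224 by default).

Augmentations are restricted to label-preserving geometry — scale in
[0.9, 1.1], horizontal/vertical flips, free rotation — plus an occasional
grayscale conversion, because retinal biomarkers can appear anywhere on the
fundus and more invasive transforms risk destroying them.

The synthetic renderer draws fundus-like images (dark background, retinal
disc, optic disc, vessels) with small per-class biomarkers, so that the
whole classification stack is trainable and testable at desk scale without
real photographs.  All randomness is seeded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Tuple

import numpy as np
from skimage import color, draw, exposure, feature, transform

__all__ = [
    "EyeCircle",
    "detect_eye_circle",
    "crop_borders",
    "apply_clahe",
    "preprocess",
    "augment",
    "synth_fundus",
]

log = logging.getLogger(__name__)

BORDER_THRESHOLD = 10.0 / 255.0  # row/col mean below this counts as border


@dataclass(frozen=True)
class EyeCircle:
    cx: float
    cy: float
    r: float


def _as_float(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an H x W x 3 image")
    if min(img.shape[:2]) < 32:
        raise ValueError("image sides must be >= 32 px")
    if img.dtype == np.uint8:
        return img.astype(float) / 255.0
    return np.clip(img.astype(float), 0.0, 1.0)


def crop_borders(image: np.ndarray,
                 threshold: float = BORDER_THRESHOLD) -> np.ndarray:
    """Trim leading/trailing rows and columns whose mean intensity is
    near black."""
    img = _as_float(image)
    gray = img.mean(axis=2)
    rows = np.where(gray.mean(axis=1) >= threshold)[0]
    cols = np.where(gray.mean(axis=0) >= threshold)[0]
    if rows.size == 0 or cols.size == 0:
        return img  # fully dark image: nothing sensible to trim
    out = img[rows[0]:rows[-1] + 1, cols[0]:cols[-1] + 1]
    if min(out.shape[:2]) < 32:  # refuse to trim into a sliver
        return img
    return out


def detect_eye_circle(image: np.ndarray,
                      n_radii: int = 24) -> Optional[EyeCircle]:
    """Locate the circular eye area with a circular Hough transform.

    Radii between a quarter and half of the short side are scanned.
    Returns ``None`` when no convincing circle exists (e.g., blank input).
    """
    img = _as_float(image)
    gray = img.mean(axis=2)
    edges = feature.canny(gray, sigma=2.0)
    if not edges.any():
        return None
    short = min(gray.shape)
    radii = np.unique(np.linspace(short // 4, short // 2, n_radii).astype(int))
    radii = radii[radii > 0]
    h = transform.hough_circle(edges, radii)
    accums, cxs, cys, rs = transform.hough_circle_peaks(h, radii,
                                                        total_num_peaks=1)
    if len(accums) == 0 or accums[0] < 0.2:
        return None
    return EyeCircle(cx=float(cxs[0]), cy=float(cys[0]), r=float(rs[0]))


def apply_clahe(image: np.ndarray, clip_limit: float = 0.02,
                tiles: int = 8) -> np.ndarray:
    """CLAHE on the L channel of Lab space (colors untouched)."""
    img = _as_float(image)
    lab = color.rgb2lab(img)
    L = lab[..., 0] / 100.0
    lab[..., 0] = exposure.equalize_adapthist(
        L, kernel_size=max(8, min(img.shape[:2]) // tiles),
        clip_limit=clip_limit) * 100.0
    return np.clip(color.lab2rgb(lab), 0.0, 1.0)


def preprocess(image: np.ndarray, target_size: int = 224,
               border_threshold: float = BORDER_THRESHOLD,
               clahe: bool = True) -> np.ndarray:
    """Full preprocessing chain: border crop, Hough-circle crop, CLAHE,
    resize.

    Output is a float ``target_size x target_size x 3`` array in [0, 1].
    When no circle is found the center square is cropped instead (logged).
    """
    img = crop_borders(image, threshold=border_threshold)
    circle = detect_eye_circle(img)
    h, w = img.shape[:2]
    if circle is not None:
        r = circle.r
        y0 = int(max(0, round(circle.cy - r)))
        y1 = int(min(h, round(circle.cy + r)))
        x0 = int(max(0, round(circle.cx - r)))
        x1 = int(min(w, round(circle.cx + r)))
        img = img[y0:y1, x0:x1]
    else:
        log.warning("no eye circle detected; falling back to center crop")
        side = min(h, w)
        y0 = (h - side) // 2
        x0 = (w - side) // 2
        img = img[y0:y0 + side, x0:x0 + side]
    if clahe:
        img = apply_clahe(img)
    out = transform.resize(img, (target_size, target_size, 3),
                           anti_aliasing=True)
    return np.clip(out, 0.0, 1.0)


def augment(image: np.ndarray, seed: int,
            scale_range: Tuple[float, float] = (0.9, 1.1),
            p_hflip: float = 0.5, p_vflip: float = 0.5,
            rotation_range: Tuple[float, float] = (-180.0, 180.0),
            p_gray: float = 0.2) -> np.ndarray:
    """Random label-preserving augmentation; identity when every knob is off.

    Deterministic given the seed; output shape equals input shape.
    """
    img = _as_float(image)
    rng = np.random.default_rng(seed)
    h, w = img.shape[:2]
    scale = float(rng.uniform(*scale_range))
    if scale != 1.0:
        scaled = transform.rescale(img, scale, channel_axis=2,
                                   anti_aliasing=True)
        sh, sw = scaled.shape[:2]
        if scale > 1.0:  # center crop back
            y0, x0 = (sh - h) // 2, (sw - w) // 2
            img = scaled[y0:y0 + h, x0:x0 + w]
        else:  # pad back with black
            out = np.zeros_like(img)
            y0, x0 = (h - sh) // 2, (w - sw) // 2
            out[y0:y0 + sh, x0:x0 + sw] = scaled
            img = out
    if rng.random() < p_hflip:
        img = img[:, ::-1]
    if rng.random() < p_vflip:
        img = img[::-1, :]
    angle = float(rng.uniform(*rotation_range))
    if angle != 0.0:
        img = transform.rotate(img, angle, mode="constant", cval=0.0)
    if rng.random() < p_gray:
        g = color.rgb2gray(img)
        img = np.stack([g, g, g], axis=2)
    return np.clip(np.ascontiguousarray(img), 0.0, 1.0)


# ---------------------------------------------------------------------------
# synthetic fundus renderer

# biomarker recipe per fine class; classes absent here render as plain fundus
_BIOMARKERS = {
    "C1": ("bright_dots", 12, 2.5),      # drusen-like deposits (AMD)
    "C14": ("bright_dots", 20, 1.5),     # discrete hard drusen
    "C2": ("dark_dots", 6, 1.5),         # scattered microaneurysms
    "C3": ("dark_dots", 16, 2.0),
    "C4": ("dark_dots", 30, 2.5),
    "C5": ("dark_dots", 45, 3.0),        # proliferative: dense hemorrhages
    "C6": ("big_cup", None, None),       # enlarged optic cup
    "C13": ("big_cup", None, None),
    "C7": ("thin_vessels", None, None),  # arteriolar narrowing
    "C8": ("crescent", None, None),      # peripapillary myopic crescent
    "C9": ("tessellation", None, None),
    "C10": ("floaters", 8, 4.0),
    "C11": ("wedge", 90.0, None),        # sectoral hemorrhage (branch RVO)
    "C32": ("wedge", 360.0, None),       # four-quadrant hemorrhage (CRVO)
    "C15": ("sheen", None, None),
    "C18": ("blurred_disc", None, None),
    "C19": ("feather", None, None),
    "C22": ("fold", None, None),
    "C25": ("haze", None, None),
    "C27": ("dome", None, None),
    "C29": ("ring_dots", 24, 2.0),       # photocoagulation scars
}


def synth_fundus(labels: Iterable[str], size: int = 128,
                 seed: int = 0) -> np.ndarray:
    """Render a deterministic synthetic fundus-like image.

    The base image is a dark square with a reddish-orange circular fundus,
    a bright optic disc, and a few dark vessel tracks; each requested class
    adds its biomarker from a small recipe table.  ``C0`` (normal) adds
    nothing.
    """
    labels = sorted(set(labels), key=lambda c: (len(c), c))
    rng = np.random.default_rng(seed)
    img = np.zeros((size, size, 3), dtype=float)
    cy = cx = size / 2.0
    R = size * 0.46

    yy, xx = np.mgrid[0:size, 0:size]
    fundus = (yy - cy) ** 2 + (xx - cx) ** 2 <= R ** 2
    base = np.array([0.72, 0.35, 0.18]) * (0.9 + 0.2 * rng.random())
    img[fundus] = base
    # mild radial shading
    rad = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2) / R
    shade = np.clip(1.0 - 0.25 * rad ** 2, 0.0, 1.0)
    img *= shade[..., None]

    # optic disc: bright blob offset toward one side
    disc_x = cx + R * 0.45 * (1 if rng.random() < 0.5 else -1)
    disc_y = cy + R * 0.1 * rng.standard_normal()
    disc_r = size * 0.07
    rr, cc = draw.disk((disc_y, disc_x), disc_r, shape=(size, size))
    img[rr, cc] = [0.95, 0.82, 0.55]

    vessel_width = 1 if ("C7" in labels) else 2
    for _ in range(5):  # vessels: dark random walks from the disc
        y, x = disc_y, disc_x
        ang = rng.uniform(0, 2 * np.pi)
        for _ in range(size):
            ang += rng.normal(0, 0.25)
            y2, x2 = y + 2.0 * np.sin(ang), x + 2.0 * np.cos(ang)
            if not (0 <= y2 < size and 0 <= x2 < size):
                break
            rr, cc = draw.disk((y2, x2), vessel_width, shape=(size, size))
            inside = fundus[rr, cc]
            img[rr[inside], cc[inside]] *= 0.55
            y, x = y2, x2

    def random_point(max_frac=0.85):
        ang = rng.uniform(0, 2 * np.pi)
        d = R * max_frac * np.sqrt(rng.random())
        return cy + d * np.sin(ang), cx + d * np.cos(ang)

    for label in labels:
        recipe = _BIOMARKERS.get(label)
        if recipe is None:
            continue
        kind, count, radius = recipe
        if kind == "bright_dots":
            for _ in range(count):
                rr, cc = draw.disk(random_point(), radius, shape=(size, size))
                img[rr, cc] = [0.98, 0.95, 0.55]
        elif kind == "dark_dots":
            for _ in range(count):
                rr, cc = draw.disk(random_point(), radius, shape=(size, size))
                img[rr, cc] = [0.25, 0.02, 0.02]
        elif kind == "ring_dots":
            for i in range(count):
                ang = 2 * np.pi * i / count
                y = cy + R * 0.6 * np.sin(ang)
                x = cx + R * 0.6 * np.cos(ang)
                rr, cc = draw.disk((y, x), radius, shape=(size, size))
                img[rr, cc] = [0.9, 0.9, 0.8]
        elif kind == "big_cup":
            rr, cc = draw.disk((disc_y, disc_x), disc_r * 0.7,
                               shape=(size, size))
            img[rr, cc] = [1.0, 0.97, 0.85]
        elif kind == "crescent":
            rr, cc = draw.disk((disc_y, disc_x), disc_r * 1.6,
                               shape=(size, size))
            keep = cc >= disc_x  # half-moon on the temporal side
            img[rr[keep], cc[keep]] = [0.93, 0.88, 0.75]
            rr, cc = draw.disk((disc_y, disc_x), disc_r, shape=(size, size))
            img[rr, cc] = [0.95, 0.82, 0.55]
        elif kind == "tessellation":
            tile = ((yy // max(4, size // 16) + xx // max(4, size // 16)) % 2
                    ).astype(float)
            img[fundus] *= (0.8 + 0.3 * tile[fundus])[..., None]
        elif kind == "floaters":
            for _ in range(count):
                rr, cc = draw.disk(random_point(), radius, shape=(size, size))
                img[rr, cc] = img[rr, cc] * 0.5 + 0.25
        elif kind == "wedge":
            span = np.deg2rad(count)
            start = rng.uniform(0, 2 * np.pi)
            theta = np.arctan2(yy - cy, xx - cx) - start
            theta = np.mod(theta, 2 * np.pi)
            sector = fundus & (theta <= span) & (rad > 0.15)
            img[sector] *= np.array([0.45, 0.15, 0.15])
        elif kind == "sheen":
            rr, cc = draw.disk((cy, cx), R * 0.25, shape=(size, size))
            img[rr, cc] = img[rr, cc] * 0.7 + 0.25
        elif kind == "blurred_disc":
            rr, cc = draw.disk((disc_y, disc_x), disc_r * 1.8,
                               shape=(size, size))
            img[rr, cc] = img[rr, cc] * 0.4 + np.array([0.55, 0.45, 0.3])
        elif kind == "feather":
            rr, cc = draw.disk((disc_y, disc_x - disc_r), disc_r * 1.4,
                               shape=(size, size))
            keep = rng.random(rr.size) < 0.6
            img[rr[keep], cc[keep]] = [0.92, 0.92, 0.9]
        elif kind == "fold":
            band = fundus & (np.abs((yy - cy) - 0.3 * (xx - cx)) < size * 0.06)
            img[band] = img[band] * 0.4 + np.array([0.35, 0.35, 0.4])
        elif kind == "haze":
            img[fundus] = img[fundus] * 0.55 + 0.3
        elif kind == "dome":
            rr, cc = draw.disk((cy, cx), R * 0.3, shape=(size, size))
            img[rr, cc] *= 0.65
        elif kind == "thin_vessels":
            pass  # handled above via vessel width
    noise = rng.normal(0, 0.015, img.shape)
    img = np.clip(img + noise * fundus[..., None], 0.0, 1.0)
    return img
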