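"""2D similarity registration from reference-point pairs.

Tomograms of the same anatomy taken months apart differ by patient pose:
a displacement, an in-plane rotation, and a uniform scale.  Given matched
reference points the least-squares similarity transform is closed-form
(centroid alignment plus the rotation from the SVD of the cross-covariance,
the classic orthogonal-Procrustes solution), which is all that 2D
superposition of exported tomogram bitmaps needs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .imaging_io import GrayscaleImage, LandmarkSet

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimilarityTransform:
    """x' = s * R(theta) @ x + t, coordinates as (x, y) column pairs."""

    scale: float
    rotation: float
    translation: tuple[float, float]

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    @property
    def matrix(self) -> np.ndarray:
        """Homogeneous 3x3 matrix acting on (x, y, 1) columns."""
        c, s = math.cos(self.rotation), math.sin(self.rotation)
        tx, ty = self.translation
        return np.array([
            [self.scale * c, -self.scale * s, tx],
            [self.scale * s, self.scale * c, ty],
            [0.0, 0.0, 1.0],
        ])

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        lin = self.matrix[:2, :2]
        return pts @ lin.T + np.asarray(self.translation)

    def inverse(self) -> "SimilarityTransform":
        c, s = math.cos(-self.rotation), math.sin(-self.rotation)
        tx, ty = self.translation
        inv_s = 1.0 / self.scale
        return SimilarityTransform(
            inv_s, -self.rotation,
            (inv_s * (-c * tx + s * ty), inv_s * (-s * tx - c * ty)),
        )


def estimate_similarity(landmarks: LandmarkSet) -> SimilarityTransform:
    """Least-squares similarity minimizing sum ||T(src) - dst||^2.

    Closed form: center both point sets, take the rotation angle from the
    2D cross-covariance, the scale from the projection onto that rotation,
    and the translation from the centroids.
    """
    src, dst = landmarks.src, landmarks.dst
    mu_s = src.mean(axis=0)
    mu_d = dst.mean(axis=0)
    ps = src - mu_s
    pd = dst - mu_d
    var_s = float((ps ** 2).sum())
    if var_s == 0.0:
        raise ValueError("all source landmarks coincide")
    # cross-covariance terms; the optimal 2D rotation is atan2 of the
    # antisymmetric vs symmetric parts
    a = float((ps * pd).sum())                         # cos component
    b = float((ps[:, 0] * pd[:, 1] - ps[:, 1] * pd[:, 0]).sum())  # sin
    theta = math.atan2(b, a)
    scale = math.hypot(a, b) / var_s
    if scale == 0.0:
        raise ValueError("degenerate landmark configuration (zero scale)")
    c, s = math.cos(theta), math.sin(theta)
    rot = np.array([[c, -s], [s, c]])
    t = mu_d - scale * rot @ mu_s
    return SimilarityTransform(scale, theta, (float(t[0]), float(t[1])))


def residual_rms(t: SimilarityTransform, landmarks: LandmarkSet) -> float:
    """Root-mean-square landmark misfit after applying the transform."""
    r = t.apply(landmarks.src) - landmarks.dst
    return float(np.sqrt((r ** 2).sum(axis=1).mean()))


def apply_transform(image: GrayscaleImage, t: SimilarityTransform,
                    interpolation: str = "nearest") -> GrayscaleImage:
    """Resample the image under the transform (inverse mapping; samples
    falling outside the frame take background value 0).

    ``nearest`` preserves the brightness value set exactly and is the
    pipeline default; ``bilinear`` invents intermediate brightness values
    and therefore perturbs the histogram, which is logged.
    """
    orders = {"nearest": 0, "bilinear": 1}
    if interpolation not in orders:
        raise ValueError(f"unknown interpolation: {interpolation!r}")
    if interpolation == "bilinear":
        log.warning("bilinear resampling invents intermediate brightness "
                    "values; the histogram of the output is perturbed")
    inv = t.inverse()
    lin_xy = inv.matrix[:2, :2]
    # scipy's affine_transform works in (row, col) = (y, x) order
    matrix_rc = np.array([[lin_xy[1, 1], lin_xy[1, 0]],
                          [lin_xy[0, 1], lin_xy[0, 0]]])
    offset_rc = np.array([inv.translation[1], inv.translation[0]])
    out = ndimage.affine_transform(
        image.pixels.astype(float), matrix_rc, offset=offset_rc,
        order=orders[interpolation], mode="constant", cval=0.0)
    out = np.clip(np.rint(out), 0, image.levels - 1).astype(np.int64)
    return GrayscaleImage(out, image.bit_depth)


def transform_to_text(t: SimilarityTransform, path=None) -> str:
    text = (f"scale: {t.scale!r}\nrotation: {t.rotation!r}\n"
            f"tx: {t.translation[0]!r}\nty: {t.translation[1]!r}\n")
    if path is not None:
        Path(path).write_text(text)
    return text


def transform_from_text(path) -> SimilarityTransform:
    fields = {}
    for line in Path(path).read_text().splitlines():
        if ":" in line:
            k, v = line.split(":", 1)
            fields[k.strip()] = float(v)
    return SimilarityTransform(fields["scale"], fields["rotation"],
                               (fields["tx"], fields["ty"]))
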