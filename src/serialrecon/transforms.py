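"""Spatial transform hierarchy: rigid, affine, B-spline free-form deformation.

Every transform maps point arrays of shape (N, ndim) in world millimetres.
By convention a transform used for resampling maps *fixed* (output) coordinates
into *moving* (input) coordinates — the inverse-mapping convention — so a
single direction rule holds across the whole package.

2D alignment operations (marker alignment, COG, rotation search, landmark and
feature fits) return *forward* transforms, i.e. the motion that carries the
section onto its reference; resampling the section then uses ``.inverse()``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np
from scipy.ndimage import map_coordinates

__all__ = [
    "Rigid2D",
    "Affine3D",
    "BSplineField",
    "ComposedTransform",
    "IdentityTransform",
    "transform_to_dict",
    "transform_from_dict",
    "save_transforms",
    "load_transforms",
]


def _pts(points: np.ndarray, ndim: int) -> np.ndarray:
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[1] != ndim:
        raise ValueError(f"expected points of dimension {ndim}, got {pts.shape[1]}")
    return pts


@dataclass(frozen=True)
class Rigid2D:
    """2D rotation (counterclockwise positive) about ``center`` plus translation.

    ``apply(p) = R(p - c) + c + t`` with all quantities in mm.
    """

    theta: float = 0.0
    t: Tuple[float, float] = (0.0, 0.0)
    center: Tuple[float, float] = (0.0, 0.0)

    @property
    def ndim(self) -> int:
        return 2

    def matrix(self) -> np.ndarray:
        """Homogeneous 3x3 matrix form."""
        c, s = np.cos(self.theta), np.sin(self.theta)
        R = np.array([[c, -s], [s, c]])
        cen = np.asarray(self.center, dtype=float)
        t = cen + np.asarray(self.t, dtype=float) - R @ cen
        H = np.eye(3)
        H[:2, :2] = R
        H[:2, 2] = t
        return H

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = _pts(points, 2)
        H = self.matrix()
        return pts @ H[:2, :2].T + H[:2, 2]

    def inverse(self) -> "Rigid2D":
        H = np.linalg.inv(self.matrix())
        theta = float(np.arctan2(H[1, 0], H[0, 0]))
        return Rigid2D(theta=theta, t=tuple(H[:2, 2]), center=(0.0, 0.0))

    def compose(self, other: "Rigid2D") -> "Rigid2D":
        """``self ∘ other``: apply ``other`` first, then ``self``."""
        H = self.matrix() @ other.matrix()
        theta = float(np.arctan2(H[1, 0], H[0, 0]))
        return Rigid2D(theta=theta, t=tuple(H[:2, 2]), center=(0.0, 0.0))

    @property
    def is_identity(self) -> bool:
        H = self.matrix()
        return bool(np.allclose(H, np.eye(3), atol=1e-12))


@dataclass(frozen=True)
class Affine3D:
    """3D affine map ``apply(p) = M p + t`` (mm); det(M) must be nonzero."""

    M: np.ndarray = field(default_factory=lambda: np.eye(3))
    t: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        M = np.asarray(self.M, dtype=float).reshape(3, 3)
        object.__setattr__(self, "M", M)
        if abs(np.linalg.det(M)) < 1e-12:
            raise ValueError("affine matrix must be invertible")

    @property
    def ndim(self) -> int:
        return 3

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = _pts(points, 3)
        return pts @ self.M.T + np.asarray(self.t)

    def inverse(self) -> "Affine3D":
        Minv = np.linalg.inv(self.M)
        return Affine3D(M=Minv, t=tuple(-Minv @ np.asarray(self.t)))

    def compose(self, other: "Affine3D") -> "Affine3D":
        """``self ∘ other``: apply ``other`` first, then ``self``."""
        return Affine3D(M=self.M @ other.M, t=tuple(self.M @ np.asarray(other.t) + np.asarray(self.t)))

    @classmethod
    def from_params(
        cls,
        scales: Sequence[float] = (1, 1, 1),
        rotations_deg: Sequence[float] = (0, 0, 0),
        translation: Sequence[float] = (0, 0, 0),
        center: Sequence[float] = (0, 0, 0),
    ) -> "Affine3D":
        """Rotations (x, y, z, degrees) about ``center``, then scale, then translate."""
        rx, ry, rz = np.deg2rad(rotations_deg)
        Rx = np.array([[1, 0, 0], [0, np.cos(rx), -np.sin(rx)], [0, np.sin(rx), np.cos(rx)]])
        Ry = np.array([[np.cos(ry), 0, np.sin(ry)], [0, 1, 0], [-np.sin(ry), 0, np.cos(ry)]])
        Rz = np.array([[np.cos(rz), -np.sin(rz), 0], [np.sin(rz), np.cos(rz), 0], [0, 0, 1]])
        M = np.diag(scales) @ Rz @ Ry @ Rx
        c = np.asarray(center, dtype=float)
        t = c + np.asarray(translation, dtype=float) - M @ c
        return cls(M=M, t=tuple(t))


@dataclass
class BSplineField:
    """Cubic B-spline free-form deformation, 2D or 3D.

    ``coefficients`` holds displacement vectors (mm) at the control points with
    shape ``(gx, gy[, gz], ndim)``; node ``i`` sits at
    ``grid_origin + i * grid_spacing`` (world mm), matching the ITK layout where
    the grid covers the image domain plus one cubic-margin node on each side.
    The displacement is evaluated as a tensor-product cubic B-spline of the
    coefficients; points outside the covered domain get zero displacement.
    """

    grid_origin: np.ndarray
    grid_spacing: np.ndarray
    coefficients: np.ndarray
    order: int = 3

    def __post_init__(self):
        self.grid_origin = np.asarray(self.grid_origin, dtype=float)
        self.grid_spacing = np.asarray(self.grid_spacing, dtype=float)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        ndim = self.coefficients.shape[-1]
        if self.coefficients.ndim != ndim + 1:
            raise ValueError("coefficients must have shape (g1, .., g_ndim, ndim)")
        if np.any(self.grid_spacing <= 0):
            raise ValueError("grid spacing must be strictly positive")
        if self.order != 3:
            raise ValueError("only cubic (order 3) B-splines are supported")

    @property
    def ndim(self) -> int:
        return self.coefficients.shape[-1]

    @property
    def grid_shape(self) -> tuple:
        return self.coefficients.shape[:-1]

    def displacement(self, points: np.ndarray) -> np.ndarray:
        pts = _pts(points, self.ndim)
        u = (pts - self.grid_origin) / self.grid_spacing  # continuous node coords
        # Cubic support needs nodes floor(u)-1 .. floor(u)+2; the valid domain
        # therefore is [1, g-2] in node coordinates.  Outside: zero displacement.
        g = np.asarray(self.grid_shape)
        inside = np.all((u >= 1.0 - 1e-9) & (u <= g - 2.0 + 1e-9), axis=1)
        disp = np.zeros_like(pts)
        if np.any(inside):
            coords = u[inside].T  # (ndim, N) in coefficient-array index order
            for d in range(self.ndim):
                disp[inside, d] = map_coordinates(
                    self.coefficients[..., d], coords, order=3, prefilter=False, mode="constant"
                )
        return disp

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = _pts(points, self.ndim)
        return pts + self.displacement(pts)

    def max_displacement(self) -> float:
        return float(np.linalg.norm(self.coefficients, axis=-1).max())

    @classmethod
    def zero(cls, domain_size_mm: Sequence[float], spacing_mm: Sequence[float]) -> "BSplineField":
        """Zero field whose grid covers ``[0, domain]`` plus the cubic margin."""
        size = np.asarray(domain_size_mm, dtype=float)
        spacing = np.asarray(spacing_mm, dtype=float)
        n_inner = np.maximum(1, np.ceil(size / spacing).astype(int))
        grid_shape = tuple(n_inner + 3)  # +3 = cubic margin (ITK convention)
        origin = -spacing
        coeff = np.zeros(grid_shape + (len(size),))
        return cls(grid_origin=origin, grid_spacing=spacing, coefficients=coeff)


class IdentityTransform:
    """Identity map of any dimension."""

    def __init__(self, ndim: int = 3):
        self.ndim = ndim

    def apply(self, points: np.ndarray) -> np.ndarray:
        return _pts(points, self.ndim).copy()

    def inverse(self) -> "IdentityTransform":
        return self


class ComposedTransform:
    """Function composition: ``apply(p) = stages[0](stages[1](... p))``.

    The list is given outermost first, i.e. the *last* element is applied
    first — matching mathematical ``f ∘ g`` order.
    """

    def __init__(self, stages: List):
        if not stages:
            raise ValueError("composition needs at least one transform")
        self.stages = list(stages)
        self.ndim = stages[0].ndim

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = _pts(points, self.ndim)
        for tr in reversed(self.stages):
            pts = tr.apply(pts)
        return pts

    def inverse(self) -> "ComposedTransform":
        return ComposedTransform([s.inverse() for s in reversed(self.stages)])


class FixedPointInverse:
    """Approximate inverse of a smooth displacement-style transform.

    Solves ``T(q) = p`` for ``q`` by fixed-point iteration
    ``q <- q - (T(q) - p)``; accurate for small, smooth displacement fields
    (contraction when the field's Jacobian is < 1).
    """

    def __init__(self, transform, n_iter: int = 10):
        self.transform = transform
        self.ndim = transform.ndim
        self.n_iter = n_iter

    def apply(self, points: np.ndarray) -> np.ndarray:
        p = _pts(points, self.ndim)
        q = p.copy()
        for _ in range(self.n_iter):
            q = q - (self.transform.apply(q) - p)
        return q

    def inverse(self):
        return self.transform


# ---------------------------------------------------------------------------
# JSON serialization (type tag + parameters)
# ---------------------------------------------------------------------------

def transform_to_dict(tr) -> dict:
    if isinstance(tr, Rigid2D):
        return {"type": "rigid2d", "theta": tr.theta, "t": list(tr.t), "center": list(tr.center)}
    if isinstance(tr, Affine3D):
        return {"type": "affine3d", "M": tr.M.tolist(), "t": list(tr.t)}
    if isinstance(tr, BSplineField):
        return {
            "type": "bspline",
            "grid_origin": tr.grid_origin.tolist(),
            "grid_spacing": tr.grid_spacing.tolist(),
            "grid_shape": list(tr.grid_shape),
            "coefficients": tr.coefficients.ravel().tolist(),
        }
    if isinstance(tr, IdentityTransform):
        return {"type": "identity", "ndim": tr.ndim}
    if isinstance(tr, ComposedTransform):
        return {"type": "composed", "stages": [transform_to_dict(s) for s in tr.stages]}
    raise TypeError(f"cannot serialize transform of type {type(tr).__name__}")


def transform_from_dict(d: dict):
    kind = d["type"]
    if kind == "rigid2d":
        return Rigid2D(theta=d["theta"], t=tuple(d["t"]), center=tuple(d["center"]))
    if kind == "affine3d":
        return Affine3D(M=np.array(d["M"]), t=tuple(d["t"]))
    if kind == "bspline":
        shape = tuple(d["grid_shape"])
        ndim = len(shape)
        coeff = np.array(d["coefficients"]).reshape(shape + (ndim,))
        return BSplineField(
            grid_origin=np.array(d["grid_origin"]),
            grid_spacing=np.array(d["grid_spacing"]),
            coefficients=coeff,
        )
    if kind == "identity":
        return IdentityTransform(ndim=d["ndim"])
    if kind == "composed":
        return ComposedTransform([transform_from_dict(s) for s in d["stages"]])
    raise ValueError(f"unknown transform type tag {kind!r}")


def save_transforms(transforms, path) -> None:
    payload = [transform_to_dict(t) for t in transforms]
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_transforms(path) -> list:
    with open(path) as fh:
        payload = json.load(fh)
    return [transform_from_dict(d) for d in payload]
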