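"""Affine and displacement-field transforms between atlas and sample space.

The package consumes transforms computed elsewhere (e.g. by a registration
suite); it never estimates them.  A chain of components maps points in one
direction; labels are always warped by inverse-mapping each output voxel
center and looking the label up with nearest-neighbour (floor-voxel)
semantics, so integer parcellation values are never interpolated.

Two equivalent quantification routes follow from this: warp the whole
parcellation into sample space once, or map the resampled neurite points
atlas-ward with the inverse chain and query the unwarped parcellation.
Both are provided; they agree up to nearest-neighbour ties at voxel
boundaries, and point-mapping is the cheaper default.

Native on-disk format: a ``transform.json`` listing the components, with
any displacement field stored as a vector-valued NRRD next to it.  A
minimal import shim for Elastix-style affine parameter text files is
included.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

from .atlas import ParcellationVolume

__all__ = [
    "AffineTransform",
    "DisplacementField",
    "TransformChain",
    "downsample_volume",
    "apply_to_points",
    "apply_to_labels",
    "invert",
    "save_chain",
    "load_chain",
    "load_elastix_affine",
]


@dataclass
class AffineTransform:
    """Homogeneous 4x4 affine in um units."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (4, 4):
            raise ValueError("affine matrix must be 4x4")
        if not np.allclose(self.matrix[3], (0, 0, 0, 1)):
            raise ValueError("last row must be (0, 0, 0, 1)")
        if abs(np.linalg.det(self.matrix[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.matrix[:3, :3].T + self.matrix[:3, 3]

    def inverse(self) -> "AffineTransform":
        return AffineTransform(np.linalg.inv(self.matrix))

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(4))

    @classmethod
    def translation(cls, offset: Sequence[float]) -> "AffineTransform":
        m = np.eye(4)
        m[:3, 3] = offset
        return cls(m)


class FieldInversionError(RuntimeError):
    pass


@dataclass
class DisplacementField:
    """Dense vector field d on its own grid: p' = p + d(p), d interpolated
    trilinearly; points outside the grid support get zero offset (flagged
    via :meth:`support_mask`)."""

    offsets: np.ndarray                       # (nx, ny, nz, 3) um
    voxel_size: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, dtype=float)
        if self.offsets.ndim != 4 or self.offsets.shape[-1] != 3:
            raise ValueError("offsets must be (nx, ny, nz, 3)")
        if not np.all(np.isfinite(self.offsets)):
            raise ValueError("offsets must be finite")

    def _grid_coords(self, points: np.ndarray) -> np.ndarray:
        # sample at voxel centers: grid index i holds d at origin+(i+0.5)*v
        return ((points - np.asarray(self.origin))
                / np.asarray(self.voxel_size) - 0.5).T

    def support_mask(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        g = self._grid_coords(pts).T
        hi = np.asarray(self.offsets.shape[:3]) - 1
        return np.all((g >= 0) & (g <= hi), axis=1)

    def displacement_at(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        g = self._grid_coords(pts)
        out = np.empty((len(pts), 3))
        for c in range(3):
            out[:, c] = ndimage.map_coordinates(
                self.offsets[..., c], g, order=1, mode="constant", cval=0.0)
        out[~self.support_mask(pts)] = 0.0
        return out

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts + self.displacement_at(pts)


class _InverseField:
    """Lazy inverse of a displacement field: solves x + d(x) = y per point
    by fixed-point iteration x <- y - d(x)."""

    def __init__(self, forward: DisplacementField,
                 tol: float = 0.01, max_iter: int = 50):
        self.forward = forward
        self.tol = tol
        self.max_iter = max_iter

    def apply(self, points: np.ndarray) -> np.ndarray:
        y = np.atleast_2d(np.asarray(points, dtype=float))
        x = y.copy()
        for _ in range(self.max_iter):
            x_new = y - self.forward.displacement_at(x)
            resid = np.max(np.linalg.norm(x_new - x, axis=1), initial=0.0)
            x = x_new
            if resid < self.tol:
                return x
        raise FieldInversionError(
            f"field inversion did not converge below {self.tol} um in "
            f"{self.max_iter} iterations (residual {resid:.4g} um)")


@dataclass
class TransformChain:
    """Ordered transform components applied left to right to points.

    ``direction`` is bookkeeping ("atlas_to_sample" or "sample_to_atlas");
    inverting the chain flips it.  An empty chain is the identity.
    """

    components: list = None  # type: ignore[assignment]
    direction: str = "atlas_to_sample"

    def __post_init__(self) -> None:
        if self.components is None:
            self.components = []

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        for comp in self.components:
            pts = comp.apply(pts)
        return pts

    def inverse(self, tol: float = 0.01, max_iter: int = 50) -> "TransformChain":
        inv_dir = ("sample_to_atlas" if self.direction == "atlas_to_sample"
                   else "atlas_to_sample")
        inv_components = []
        for comp in reversed(self.components):
            if isinstance(comp, AffineTransform):
                inv_components.append(comp.inverse())
            elif isinstance(comp, DisplacementField):
                inv_components.append(_InverseField(comp, tol, max_iter))
            elif isinstance(comp, _InverseField):
                inv_components.append(comp.forward)
            else:
                raise TypeError(f"cannot invert component {type(comp)!r}")
        return TransformChain(inv_components, inv_dir)

    @classmethod
    def identity(cls, direction: str = "atlas_to_sample") -> "TransformChain":
        return cls([], direction)


def apply_to_points(chain: TransformChain, points: np.ndarray) -> np.ndarray:
    """Map um points through the chain (affine: M.p; field: p + d(p))."""
    return chain.apply(points)


def invert(chain: TransformChain, tol: float = 0.01,
           max_iter: int = 50) -> TransformChain:
    """Chain inverse; displacement fields invert by fixed-point iteration
    to ``tol`` um (default 0.01, max 50 iterations)."""
    return chain.inverse(tol, max_iter)


# --------------------------------------------------------------------------
# downsampling
# --------------------------------------------------------------------------

def downsample_volume(
    stack: np.ndarray,
    voxel_size: Sequence[float],
    target_voxel: float | Sequence[float],
    kind: str = "mean",
) -> np.ndarray:
    """Block-reduce a stack from its native voxel size to a coarser one.

    Every input voxel is assigned to the output voxel containing its
    center, which accommodates anisotropic non-integer ratios (e.g. a
    0.8 x 0.8 x 5 um stack onto a 25 um grid).  Intensity stacks use the
    block mean (``kind="mean"``); label stacks use the block mode
    (``kind="mode"``), which never invents labels (ties break to the
    smallest label).  Output dimensions are ceil(input_extent /
    target_voxel); edge blocks reduce over the voxels they actually
    contain.  A target finer than the input voxel is an error.
    """
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError("stack must be 3D")
    voxel_size = np.asarray(voxel_size, dtype=float)
    target = np.asarray(
        [target_voxel] * 3 if np.isscalar(target_voxel) else target_voxel,
        dtype=float)
    ratio = target / voxel_size
    if np.any(ratio < 1 - 1e-9):
        raise ValueError(
            f"target voxel {target.tolist()} is finer than the input voxel "
            f"{voxel_size.tolist()} (ratios {ratio.tolist()})")
    extent = np.asarray(stack.shape) * voxel_size
    out_shape = tuple(int(np.ceil(e / t - 1e-9)) for e, t in zip(extent, target))
    # output bin of each input index, per axis (by input-voxel center)
    bins = [np.minimum(((np.arange(s) + 0.5) * v / t).astype(int), o - 1)
            for s, v, t, o in zip(stack.shape, voxel_size, target, out_shape)]
    # contiguous runs per axis -> reduceat boundaries
    bounds = [np.flatnonzero(np.diff(b, prepend=-1)) for b in bins]

    if kind == "mean":
        acc = stack.astype(float)
        cnt = np.ones(stack.shape)
        for ax in range(3):
            acc = np.add.reduceat(acc, bounds[ax], axis=ax)
            cnt = np.add.reduceat(cnt, bounds[ax], axis=ax)
        return acc / cnt
    if kind == "mode":
        if not np.issubdtype(stack.dtype, np.integer):
            raise TypeError("mode downsampling expects integer labels")
        out = np.empty(out_shape, dtype=stack.dtype)
        edges = [np.append(b, s) for b, s in zip(bounds, stack.shape)]
        for i in range(out_shape[0]):
            for j in range(out_shape[1]):
                for k in range(out_shape[2]):
                    block = stack[edges[0][i]:edges[0][i + 1],
                                  edges[1][j]:edges[1][j + 1],
                                  edges[2][k]:edges[2][k + 1]]
                    vals, counts = np.unique(block, return_counts=True)
                    out[i, j, k] = vals[np.argmax(counts)]
        return out
    raise ValueError(f"unknown downsampling kind {kind!r}")


# --------------------------------------------------------------------------
# label warping
# --------------------------------------------------------------------------

def apply_to_labels(
    chain: TransformChain,
    vol: ParcellationVolume,
    out_frame: ParcellationVolume | tuple | None = None,
) -> ParcellationVolume:
    """Warp a label volume through the chain by inverse-mapping.

    Every output voxel center is mapped back through the chain inverse and
    the source label is read with the same half-open floor convention as
    point queries (nearest-neighbour; labels are never interpolated).
    ``out_frame`` gives the output grid (a ParcellationVolume to copy the
    frame from, or a (shape, voxel_size, origin) tuple); by default the
    input frame is reused.
    """
    if out_frame is None:
        shape, vsize, origin = vol.shape, vol.voxel_size, vol.origin
        axis_order = vol.axis_order
    elif isinstance(out_frame, ParcellationVolume):
        shape, vsize, origin = out_frame.shape, out_frame.voxel_size, out_frame.origin
        axis_order = out_frame.axis_order
    else:
        shape, vsize, origin = out_frame
        axis_order = "xyz"
    inv = chain.inverse()
    out = ParcellationVolume(np.zeros(shape, dtype=vol.labels.dtype),
                             vsize, origin, axis_order)
    centers = out.voxel_centers()
    src_pts = inv.apply(centers)
    labels = vol.lookup(src_pts)
    perm = out._grid_permutation()
    # centers were produced in grid raveling order, so reshape directly
    out.labels = labels.reshape(shape)
    return out


# --------------------------------------------------------------------------
# on-disk format + Elastix shim
# --------------------------------------------------------------------------

def save_chain(chain: TransformChain, path: str | Path) -> None:
    """Write transform.json (+ sidecar NRRD per displacement field)."""
    path = Path(path)
    doc = {"direction": chain.direction, "components": []}
    for i, comp in enumerate(chain.components):
        if isinstance(comp, AffineTransform):
            doc["components"].append(
                {"type": "affine", "matrix": comp.matrix.tolist()})
        elif isinstance(comp, DisplacementField):
            fname = f"{path.stem}_field{i}.nrrd"
            arr = np.transpose(comp.offsets, (3, 0, 1, 2))  # vector-first
            import SimpleITK as sitk
            img = sitk.GetImageFromArray(
                np.ascontiguousarray(np.transpose(comp.offsets, (2, 1, 0, 3))),
                isVector=True)
            img.SetSpacing(tuple(float(v) for v in comp.voxel_size))
            img.SetOrigin(tuple(float(o) for o in comp.origin))
            sitk.WriteImage(img, str(path.parent / fname))
            doc["components"].append({"type": "displacement_field",
                                      "nrrd": fname})
        else:
            raise TypeError(f"cannot serialize component {type(comp)!r}")
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def load_chain(path: str | Path) -> TransformChain:
    import SimpleITK as sitk

    path = Path(path)
    with open(path) as fh:
        doc = json.load(fh)
    components = []
    for comp in doc["components"]:
        if comp["type"] == "affine":
            components.append(AffineTransform(np.array(comp["matrix"])))
        elif comp["type"] == "displacement_field":
            img = sitk.ReadImage(str(path.parent / comp["nrrd"]))
            arr = sitk.GetArrayFromImage(img)          # (z, y, x, 3)
            offsets = np.transpose(arr, (2, 1, 0, 3))
            components.append(DisplacementField(
                offsets, tuple(img.GetSpacing()), tuple(img.GetOrigin())))
        else:
            raise ValueError(f"unknown component type {comp['type']!r}")
    return TransformChain(components, doc.get("direction", "atlas_to_sample"))


def load_elastix_affine(path: str | Path) -> AffineTransform:
    """Minimal import of an Elastix AffineTransform parameter text file.

    Reads ``(TransformParameters a11 ... a33 tx ty tz)`` and
    ``(CenterOfRotationPoint cx cy cz)``; the stored mapping is
    p' = A (p - c) + t + c.
    """
    text = Path(path).read_text()

    def _params(key: str, default=None):
        m = re.search(rf"\({key}\s+([^)]*)\)", text)
        if not m:
            if default is not None:
                return default
            raise ValueError(f"missing ({key} ...) in {path}")
        return [float(tok) for tok in m.group(1).split()]

    p = _params("TransformParameters")
    if len(p) != 12:
        raise ValueError("expected 12 affine parameters")
    a = np.array(p[:9]).reshape(3, 3)
    t = np.array(p[9:])
    c = np.array(_params("CenterOfRotationPoint", default=[0.0, 0.0, 0.0]))
    m = np.eye(4)
    m[:3, :3] = a
    m[:3, 3] = t + c - a @ c
    return AffineTransform(m)
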