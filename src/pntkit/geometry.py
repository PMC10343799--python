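"""Axis fitting, radial statistics, pairwise superposition, cylindrical maps."""

from __future__ import annotations

import dataclasses

import numpy as np

from .structures import Assembly


class GeometryError(ValueError):
    pass


@dataclasses.dataclass
class AxisFit:
    point: np.ndarray       # a point on the axis (centroid)
    direction: np.ndarray   # unit vector
    method: str = "principal_component"


@dataclasses.dataclass
class RadialReport:
    mean_radius: float
    min_radius: float
    max_radius: float
    layer_thickness: float
    radii: np.ndarray


def _coords_of(obj) -> np.ndarray:
    if isinstance(obj, Assembly):
        return obj.coords
    return np.asarray(obj, dtype=float)


def fit_axis(assembly) -> AxisFit:
    """Dominant principal direction of the coordinate covariance.

    The direction sign is canonicalized (largest-magnitude component
    positive) so repeated fits are deterministic.
    """
    coords = _coords_of(assembly)
    if len(coords) < 3:
        raise GeometryError("need >= 3 atoms to fit an axis")
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    if not np.any(np.linalg.norm(centered, axis=1) > 1e-12):
        raise GeometryError("degenerate geometry: all atoms coincide")
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    direction = vt[0]
    pivot = np.argmax(np.abs(direction))
    if direction[pivot] < 0:
        direction = -direction
    return AxisFit(point=centroid, direction=direction)


def radial_stats(assembly, axis: AxisFit) -> RadialReport:
    """Perpendicular distance of every atom to the axis line."""
    coords = _coords_of(assembly)
    d = coords - axis.point
    u = axis.direction / np.linalg.norm(axis.direction)
    perp = d - np.outer(d @ u, u)
    radii = np.linalg.norm(perp, axis=1)
    return RadialReport(
        mean_radius=float(radii.mean()),
        min_radius=float(radii.min()),
        max_radius=float(radii.max()),
        layer_thickness=float(radii.max() - radii.min()),
        radii=radii,
    )


def pair_fit(mobile: Assembly, reference: Assembly,
             atom_pairs) -> tuple[float, Assembly]:
    """Least-squares rigid superposition over explicit atom pairs.

    ``atom_pairs`` is a sequence of (mobile_index, reference_index) 1-based
    ordinals.  The rotation is constrained to det = +1 -- reflections are
    forbidden so the superposition can never silently invert handedness.
    Returns the RMSD over the paired atoms and the transformed mobile copy.
    """
    pairs = np.asarray(list(atom_pairs), dtype=int)
    if pairs.ndim != 2 or pairs.shape[1] != 2 or len(pairs) < 3:
        raise GeometryError("need >= 3 atom pairs")
    mi, ri = pairs[:, 0] - 1, pairs[:, 1] - 1
    p = mobile.coords[mi]
    q = reference.coords[ri]
    pc, qc = p.mean(axis=0), q.mean(axis=0)
    h = (p - pc).T @ (q - qc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    if np.linalg.det(rot) < 0:
        raise GeometryError("superposition produced a reflection")
    transformed = mobile.copy(
        coords=(mobile.coords - pc) @ rot.T + qc
    )
    delta = transformed.coords[mi] - q
    rmsd = float(np.sqrt((delta ** 2).sum(axis=1).mean()))
    return rmsd, transformed


def cylindrical_map(assembly, axis: AxisFit | None = None,
                    n_angular: int = 30, n_axial: int = 15):
    """Unwrapped (angle, z) grids of outer and inner surface radii.

    For every bin the outer surface is the maximum atom radius and the inner
    surface the minimum; empty bins are NaN.  The angular origin is the
    projection of the first Calpha atom (first atom if none), so maps from
    different runs are comparable.

    Returns ``(outer, inner, angle_edges, z_edges)`` with grids shaped
    ``(n_angular, n_axial)``.
    """
    coords = _coords_of(assembly)
    if axis is None:
        axis = fit_axis(coords)
    u = axis.direction / np.linalg.norm(axis.direction)
    d = coords - axis.point
    z = d @ u
    perp = d - np.outer(z, u)
    radii = np.linalg.norm(perp, axis=1)

    # reference direction in the plane perpendicular to the axis
    if isinstance(assembly, Assembly):
        ca = assembly.calpha_indices()
        ref_i = int(ca[0]) if len(ca) else 0
    else:
        ref_i = 0
    ref = perp[ref_i]
    if np.linalg.norm(ref) < 1e-9:
        ref = np.array([1.0, 0.0, 0.0])
        ref = ref - np.dot(ref, u) * u
    e1 = ref / np.linalg.norm(ref)
    e2 = np.cross(u, e1)
    theta = np.arctan2(perp @ e2, perp @ e1)  # [-pi, pi)

    angle_edges = np.linspace(-np.pi, np.pi, n_angular + 1)
    z_edges = np.linspace(z.min(), z.max() + 1e-9, n_axial + 1)
    ai = np.clip(np.digitize(theta, angle_edges) - 1, 0, n_angular - 1)
    zi = np.clip(np.digitize(z, z_edges) - 1, 0, n_axial - 1)

    outer = np.full((n_angular, n_axial), np.nan)
    inner = np.full((n_angular, n_axial), np.nan)
    for a, k, r in zip(ai, zi, radii):
        if np.isnan(outer[a, k]) or r > outer[a, k]:
            outer[a, k] = r
        if np.isnan(inner[a, k]) or r < inner[a, k]:
            inner[a, k] = r
    return outer, inner, angle_edges, z_edges
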