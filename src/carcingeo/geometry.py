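"""Landmark construction and attachment-angle statistics.

This module implements the 3-D landmark scheme used to quantify where, and
facing which way, a carcinoecium-forming sea anemone sits on its host
gastropod shell.  The inputs per specimen are a triangulated shell surface,
the aperture rim (or outer-lip/carcinoecium-edge points), a point cloud
segmented around the anemone's siphonoglyphs, and the two operator landmarks
C (upper tip of the outer lip) and D (lower tip).

Landmarks
---------
A   midpoint between the two "upper tips" of the siphonoglyph cloud
B   closest point on the shell surface from A
C,D upper / lower tip of the outer lip (inputs)
E   intersection of the siphonoglyph approximation plane with line CD
F   intersection of line AB with the aperture approximation plane G

Angle 1 is the signed angle ∠CBE: 0° when the directive axis points exactly
at the upper lip tip C, positive toward the aperture (E on the D side of C),
negative toward the apex.  Angle 2 is the elevation-complement ∠AFG of the
anemone's axis over the aperture plane: <90° means the animal faces the
dorsal side of the hermit crab, >90° the substrate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh

from .errors import (
    DegenerateGeometryError,
    OrientationError,
    UndefinedLandmarkError,
)
from .stats import sample_summary

__all__ = [
    "FittedPlane",
    "LandmarkSet",
    "AttachmentAngles",
    "fit_plane",
    "closest_point_on_mesh",
    "line_plane_intersection",
    "derive_landmarks",
    "angle1",
    "angle2",
    "measure_attachment",
    "summarize_angles",
]

_EPS = 1e-12


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < _EPS:
        raise DegenerateGeometryError("zero-length direction vector")
    return v / n


@dataclass(frozen=True)
class FittedPlane:
    """A plane fitted to points: anchor point, unit normal, RMS residual."""

    point: np.ndarray
    normal: np.ndarray
    rms_residual: float

    def signed_distance(self, p) -> np.ndarray:
        return np.dot(np.atleast_2d(p) - self.point, self.normal)


def fit_plane(points) -> FittedPlane:
    """Total-least-squares plane through a point cloud.

    The normal is the eigenvector of the 3x3 scatter matrix with the
    smallest eigenvalue (orthogonal regression), anchored at the centroid.
    The normal's sign is canonicalised so its largest-magnitude component is
    positive; callers needing an oriented normal (e.g. the dorsal side)
    re-orient it against a reference vector.

    Raises
    ------
    DegenerateGeometryError
        Fewer than 3 points, or all points collinear.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 3:
        raise DegenerateGeometryError("plane fit needs >= 3 points in 3-D")
    centroid = pts.mean(axis=0)
    centred = pts - centroid
    # eigh on the symmetric scatter matrix: ascending eigenvalues
    evals, evecs = np.linalg.eigh(centred.T @ centred)
    scale = float(np.abs(centred).max())
    if scale == 0.0 or evals[1] <= 1e-10 * max(evals[2], _EPS):
        raise DegenerateGeometryError("points are collinear; plane is undefined")
    normal = evecs[:, 0]
    k = int(np.argmax(np.abs(normal)))
    if normal[k] < 0:
        normal = -normal
    rms = float(np.sqrt(max(evals[0], 0.0) / pts.shape[0]))
    return FittedPlane(point=centroid, normal=normal / np.linalg.norm(normal), rms_residual=rms)


def _closest_on_triangles(p: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Exact closest point to ``p`` on each triangle of ``tri`` (n,3,3).

    Vectorised version of the classical barycentric region walk
    (Ericson, *Real-Time Collision Detection*, §5.1.5); faces, edges and
    vertices are all candidate regions.
    """
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab, ac, ap = b - a, c - a, p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    out = np.empty_like(a)
    done = np.zeros(len(tri), dtype=bool)

    def settle(mask, value):
        m = mask & ~done
        out[m] = value[m] if value.ndim == 2 else value
        done[m] = True

    settle((d1 <= 0) & (d2 <= 0), a)  # vertex A
    settle((d3 >= 0) & (d4 <= d3), b)  # vertex B
    settle((d6 >= 0) & (d5 <= d6), c)  # vertex C

    vc = d1 * d4 - d3 * d2
    with np.errstate(divide="ignore", invalid="ignore"):
        v_ab = np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0)
    settle((vc <= 0) & (d1 >= 0) & (d3 <= 0), a + v_ab[:, None] * ab)  # edge AB

    vb = d5 * d2 - d1 * d6
    with np.errstate(divide="ignore", invalid="ignore"):
        w_ac = np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0)
    settle((vb <= 0) & (d2 >= 0) & (d6 <= 0), a + w_ac[:, None] * ac)  # edge AC

    va = d3 * d6 - d5 * d4
    den_bc = (d4 - d3) + (d5 - d6)
    with np.errstate(divide="ignore", invalid="ignore"):
        w_bc = np.where(den_bc != 0, (d4 - d3) / den_bc, 0.0)
    settle((va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0), b + w_bc[:, None] * (c - b))

    # interior region
    denom = va + vb + vc
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(denom != 0, vb / denom, 0.0)
        w = np.where(denom != 0, vc / denom, 0.0)
    settle(~done, a + v[:, None] * ab + w[:, None] * ac)
    return out


def closest_point_on_mesh(point, mesh: trimesh.Trimesh) -> np.ndarray:
    """Closest point on a triangulated surface from an arbitrary 3-D point.

    Every face is an exact candidate (interior, edges, vertices), so the
    result is the global minimiser over the whole surface.

    Raises
    ------
    DegenerateGeometryError
        Empty mesh.
    """
    p = np.asarray(point, dtype=float)
    if mesh is None or len(mesh.faces) == 0:
        raise DegenerateGeometryError("closest-point query on an empty mesh")
    cand = _closest_on_triangles(p, mesh.triangles)
    d2 = np.einsum("ij,ij->i", cand - p, cand - p)
    return cand[int(np.argmin(d2))]


def line_plane_intersection(p1, p2, plane: FittedPlane) -> np.ndarray:
    """Intersection of the infinite line through ``p1``/``p2`` with a plane.

    Raises
    ------
    UndefinedLandmarkError
        Line (anti)parallel to the plane — no unique intersection.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    d = p2 - p1
    nd = float(np.dot(d, plane.normal))
    if abs(nd) <= 1e-9 * np.linalg.norm(d):
        raise UndefinedLandmarkError("line is parallel to the plane")
    t = float(np.dot(plane.point - p1, plane.normal)) / nd
    return p1 + t * d


def siphonoglyph_tips(siphonoglyph_points, plane: FittedPlane | None = None):
    """The two cloud points extremal along the in-plane major axis.

    These stand in for the manually picked "upper tips" of the siphonoglyph:
    the groove is an elongated structure, and its two ends are the extremes
    of the cloud along the principal in-plane direction.
    """
    pts = np.asarray(siphonoglyph_points, dtype=float)
    if plane is None:
        plane = fit_plane(pts)
    centred = pts - plane.point
    in_plane = centred - np.outer(centred @ plane.normal, plane.normal)
    evals, evecs = np.linalg.eigh(in_plane.T @ in_plane)
    major = evecs[:, -1]
    s = in_plane @ major
    return pts[int(np.argmax(s))], pts[int(np.argmin(s))]


@dataclass
class LandmarkSet:
    """The full per-specimen landmark configuration A–F plus fitted planes."""

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    D: np.ndarray
    E: np.ndarray
    F: np.ndarray
    siph_plane: FittedPlane
    aperture_plane: FittedPlane
    specimen_id: str = ""


@dataclass(frozen=True)
class AttachmentAngles:
    """Signed Angle 1 and oriented Angle 2 for one specimen (degrees)."""

    angle1: float
    angle2: float
    specimen_id: str = ""


def derive_landmarks(
    siphonoglyph_points,
    mesh: trimesh.Trimesh,
    rim_points,
    C,
    D,
    *,
    tips=None,
    specimen_id: str = "",
) -> LandmarkSet:
    """Construct landmarks A, B, E, F from the raw per-specimen inputs.

    Parameters
    ----------
    siphonoglyph_points : (n,3) array-like
        Segmented siphonoglyph region cloud (n >= 3, non-collinear).
    mesh : trimesh.Trimesh
        Shell (or carcinoecium) surface.
    rim_points : (m,3) array-like
        Aperture rim / outer-lip points defining plane G.
    C, D : 3-vectors
        Upper and lower tip of the outer lip.
    tips : optional pair of 3-vectors
        Operator-supplied siphonoglyph tips; overrides the automatic
        extremal-point rule for A.
    """
    C = np.asarray(C, dtype=float)
    D = np.asarray(D, dtype=float)
    if np.linalg.norm(C - D) < _EPS:
        raise DegenerateGeometryError("landmarks C and D coincide")
    siph_plane = fit_plane(siphonoglyph_points)
    if tips is None:
        tips = siphonoglyph_tips(siphonoglyph_points, siph_plane)
    A = 0.5 * (np.asarray(tips[0], dtype=float) + np.asarray(tips[1], dtype=float))
    aperture_plane = fit_plane(rim_points)
    B = closest_point_on_mesh(A, mesh)
    if np.linalg.norm(A - B) < _EPS:
        raise DegenerateGeometryError("A lies on the shell surface; line AB undefined")
    E = line_plane_intersection(C, D, siph_plane)
    F = line_plane_intersection(A, B, aperture_plane)
    return LandmarkSet(A=A, B=B, C=C, D=D, E=E, F=F,
                       siph_plane=siph_plane, aperture_plane=aperture_plane,
                       specimen_id=specimen_id)


def angle1(lm: LandmarkSet) -> float:
    """Signed ∠CBE in degrees, in (-180, 180].

    Magnitude: angle at vertex B between rays B→C and B→E.  Sign: positive
    when E lies on the D side of C along line CD (directive axis toward the
    shell aperture), negative when E lies beyond C away from D (toward the
    apex).  E == C gives exactly 0°.
    """
    u = lm.C - lm.B
    w = lm.E - lm.B
    nu, nw = np.linalg.norm(u), np.linalg.norm(w)
    if nu < _EPS or nw < _EPS:
        raise DegenerateGeometryError("B coincides with C or E; angle undefined")
    mag = np.degrees(np.arctan2(np.linalg.norm(np.cross(u, w)), float(np.dot(u, w))))
    cd = lm.D - lm.C
    t = float(np.dot(lm.E - lm.C, cd)) / float(np.dot(cd, cd))
    if mag == 0.0 or t == 0.0:
        return 0.0 if t == 0.0 else float(mag)
    return float(np.sign(t) * mag)


def angle2(lm: LandmarkSet, dorsal_reference) -> float:
    """Oriented ∠AFG in degrees, in [0, 180).

    Let ``n`` be the aperture-plane normal oriented toward the dorsal
    reference and ``θ`` the signed elevation of ray F→A over plane G
    (positive toward ``n``).  Angle 2 is ``90° − θ``: an axis pointing
    straight dorsal gives 0°, one lying in the aperture plane 90°, one
    pointing at the substrate >90°.
    """
    dorsal = _unit(np.asarray(dorsal_reference, dtype=float))
    n = lm.aperture_plane.normal
    nd = float(np.dot(n, dorsal))
    if abs(nd) < 1e-9:
        raise OrientationError("dorsal reference is perpendicular to the aperture plane normal")
    if nd < 0:
        n = -n
    v = lm.A - lm.F
    nv = np.linalg.norm(v)
    if nv < _EPS:
        raise DegenerateGeometryError("A coincides with F; Angle 2 undefined")
    s = np.clip(float(np.dot(v, n)) / nv, -1.0, 1.0)
    theta = np.degrees(np.arcsin(s))
    return float(90.0 - theta)


def measure_attachment(lm: LandmarkSet, dorsal_reference) -> AttachmentAngles:
    """Angles 1 and 2 from a landmark set (degrees)."""
    return AttachmentAngles(
        angle1=angle1(lm), angle2=angle2(lm, dorsal_reference),
        specimen_id=lm.specimen_id,
    )


def summarize_angles(angles) -> dict:
    """Cohort summary (mean, s.d., min, max, n) for Angles 1 and 2.

    ``angles`` is an iterable of :class:`AttachmentAngles`; entries that are
    ``None`` (flagged specimens) are excluded and counted.
    """
    kept = [a for a in angles if a is not None]
    flagged = sum(1 for a in angles if a is None)
    if not kept:
        raise DegenerateGeometryError("no measurable specimens in cohort")
    out = {"n": len(kept), "n_flagged": flagged}
    for key in ("angle1", "angle2"):
        vals = [getattr(a, key) for a in kept]
        s = sample_summary(vals)
        out[key] = {k: s[k] for k in ("mean", "sd", "min", "max")}
    return out
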