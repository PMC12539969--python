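"""Synthetic logarithmically coiled gastropod shells.

Spiral gastropod shells grow by forward elongation at the aperture with a
constant-angle growth-rate gradient, which makes every linear dimension
scale exponentially with the rotation angle (Raup-type isometric coiling).
The generator sweeps a circular generating curve (the aperture) around a
vertical coiling axis:

    r(θ) = r0 · W^(θ/2π)                aperture radius
    d(θ) = k · r(θ)                     distance of aperture centre to axis
    z(θ) = −T · (W^(θ/2π) − 1)/(W − 1)  axial drop (T over the first whorl)

with expansion ratio W > 1 per revolution.  The generating circle lies in
the plane spanned by the radial direction and a "tilted vertical"
u = cos β ẑ + sin β e_t, where β is the aperture inclination against the
coiling axis (real gastropod apertures are inclined, and the inclination
couples the lip-tip landmarks to the surface normal field).  The rim at the
final θ is an exact analytic circle stored alongside the triangulated
surface.  The umbilicus D-parameter of the full Raup model is folded into
the fixed centre-offset ratio k; k large enough for open coiling keeps the
surface free of self-contact, so every surface point is exposed for
closest-point and voxelisation queries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh

from .errors import ParameterError

__all__ = ["ShellModel", "ShellGeometry", "generate_shell"]

_TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class ShellModel:
    """Parameters of a logarithmically coiled shell surface.

    Attributes
    ----------
    whorl_expansion : float
        Raup's W, linear expansion per revolution; must exceed 1.
    translation_rate : float
        Axial drop (length units) accumulated over the first revolution;
        later whorls drop proportionally more, keeping the coil self-similar.
    aperture_radius0 : float
        Generating-curve radius at θ = 0.
    n_revolutions : float
        Number of revolutions swept.
    points_per_revolution : int
        Sweep samples per revolution (>= 16).
    aperture_points : int
        Samples around the generating circle (>= 8).
    center_offset_ratio : float
        k = d/r, distance of the aperture centre from the coiling axis in
        units of the aperture radius; k > 1 keeps the tube off the axis and
        the default leaves a gap between successive whorls (open coiling).
    aperture_tilt_deg : float
        Inclination β of the generating circle against the coiling axis,
        degrees in [0, 75].
    seed : int
        Carried for API uniformity; the surface itself is deterministic.
    """

    whorl_expansion: float = 2.0
    translation_rate: float = 1.6
    aperture_radius0: float = 1.0
    n_revolutions: float = 3.25
    points_per_revolution: int = 96
    aperture_points: int = 40
    center_offset_ratio: float = 3.5
    aperture_tilt_deg: float = 45.0
    seed: int = 0

    def __post_init__(self):
        if not np.isfinite(self.whorl_expansion) or self.whorl_expansion <= 1.0:
            raise ParameterError(
                f"whorl_expansion must be > 1, got {self.whorl_expansion}"
            )
        if self.aperture_radius0 <= 0:
            raise ParameterError("aperture_radius0 must be positive")
        if self.n_revolutions <= 0:
            raise ParameterError("n_revolutions must be positive")
        if self.translation_rate < 0:
            raise ParameterError("translation_rate must be non-negative")
        if self.points_per_revolution < 16:
            raise ParameterError("points_per_revolution must be >= 16")
        if self.aperture_points < 8:
            raise ParameterError("aperture_points must be >= 8")
        if self.center_offset_ratio <= 1.0:
            raise ParameterError("center_offset_ratio must exceed 1")
        if not (-75.0 <= self.aperture_tilt_deg <= 75.0):
            raise ParameterError("aperture_tilt_deg must lie in [-75, 75]")


@dataclass
class ShellGeometry:
    """A generated shell: mesh, analytic rim, axes and the source model."""

    mesh: trimesh.Trimesh
    rim: np.ndarray              # (aperture_points, 3) closed rim polyline
    apex: np.ndarray             # (3,) point at the small end of the coil
    axis: np.ndarray             # (3,) unit coiling axis, pointing apex-ward
    aperture_center: np.ndarray  # (3,) centre of the final generating circle
    aperture_normal: np.ndarray  # (3,) unit growth direction at the aperture
    model: ShellModel

    @property
    def dorsal_reference(self) -> np.ndarray:
        """Orientation reference for Angle 2 in the synthetic convention:
        the outward growth direction at the aperture (the direction the
        shell opening faces)."""
        return self.aperture_normal

    # -- analytic surface -------------------------------------------------
    def _frames(self, theta):
        theta = np.asarray(theta, dtype=float)
        m = self.model
        w = m.whorl_expansion ** (theta / _TWO_PI)
        r = m.aperture_radius0 * w
        d = m.center_offset_ratio * r
        z = -m.translation_rate * (w - 1.0) / (m.whorl_expansion - 1.0)
        e_r = np.stack([np.cos(theta), np.sin(theta), np.zeros_like(theta)], axis=-1)
        e_t = np.stack([-np.sin(theta), np.cos(theta), np.zeros_like(theta)], axis=-1)
        beta = np.radians(m.aperture_tilt_deg)
        up = np.zeros_like(e_r)
        up[..., 2] = 1.0
        u = np.cos(beta) * up + np.sin(beta) * e_t
        center = d[..., None] * e_r
        center[..., 2] = z
        return center, e_r, u, r

    def surface_point(self, theta, phi) -> np.ndarray:
        """Analytic surface point at sweep angle θ and circle angle φ."""
        center, e_r, u, r = self._frames(theta)
        return center + r[..., None] * (
            np.cos(phi)[..., None] * e_r + np.sin(phi)[..., None] * u
        )

    def surface_normal(self, theta, phi, h: float = 1e-5) -> np.ndarray:
        """Outward unit normal of the analytic surface (central differences)."""
        t = np.asarray(theta, dtype=float)
        p = np.asarray(phi, dtype=float)
        dt = self.surface_point(t + h, p) - self.surface_point(t - h, p)
        dp = self.surface_point(t, p + h) - self.surface_point(t, p - h)
        n = np.cross(dt, dp)
        n /= np.linalg.norm(n, axis=-1, keepdims=True)
        # orient outward: away from the generating-circle centre
        center, _, _, _ = self._frames(t)
        outward = self.surface_point(t, p) - center
        flip = np.sum(n * outward, axis=-1) < 0
        n[flip] *= -1.0
        return n


def generate_shell(model: ShellModel) -> ShellGeometry:
    """Sweep the generating curve into a triangulated shell surface.

    The returned mesh is a capped tube along the coiling spiral; the final
    aperture rim is kept as an explicit closed polyline whose vertices lie
    exactly on the analytic generating circle.  Deterministic for a given
    model.
    """
    m = model
    n_theta = int(round(m.points_per_revolution * m.n_revolutions)) + 1
    theta = np.linspace(0.0, _TWO_PI * m.n_revolutions, n_theta)
    phi = np.linspace(0.0, _TWO_PI, m.aperture_points, endpoint=False)

    geom = ShellGeometry(
        mesh=None, rim=None, apex=None, axis=np.array([0.0, 0.0, 1.0]),
        aperture_center=None, aperture_normal=None, model=m,
    )
    tt, pp = np.meshgrid(theta, phi, indexing="ij")
    verts = geom.surface_point(tt, pp).reshape(-1, 3)

    nt, nphi = n_theta, m.aperture_points
    idx = np.arange(nt * nphi).reshape(nt, nphi)
    i0 = idx[:-1]
    i1 = idx[1:]
    j1 = np.roll(np.arange(nphi), -1)
    quad_a = np.stack([i0, i1, i0[:, j1]], axis=-1).reshape(-1, 3)
    quad_b = np.stack([i1, i1[:, j1], i0[:, j1]], axis=-1).reshape(-1, 3)
    faces = [quad_a, quad_b]

    # end caps: triangle fans around the two generating-circle centres
    centers, _, _, _ = geom._frames(np.array([theta[0], theta[-1]]))
    cap0 = len(verts)
    cap1 = len(verts) + 1
    verts = np.vstack([verts, centers])
    ring0, ring1 = idx[0], idx[-1]
    fan0 = np.stack(
        [np.full(nphi, cap0), ring0[j1], ring0], axis=-1)
    fan1 = np.stack(
        [np.full(nphi, cap1), ring1, ring1[j1]], axis=-1)
    faces.extend([fan0, fan1])

    mesh = trimesh.Trimesh(
        vertices=verts, faces=np.vstack(faces), process=False)

    rim = geom.surface_point(np.full(nphi, theta[-1]), phi)
    center_end, e_r_end, u_end, _ = geom._frames(theta[-1])
    growth = np.cross(e_r_end, u_end)
    growth /= np.linalg.norm(growth)
    e_t_end = np.array([-np.sin(theta[-1]), np.cos(theta[-1]), 0.0])
    if np.dot(growth, e_t_end) < 0:
        growth = -growth

    geom.mesh = mesh
    geom.rim = rim
    geom.apex = centers[0]
    geom.aperture_center = center_end
    geom.aperture_normal = growth
    return geom
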