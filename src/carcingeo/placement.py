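"""Synthetic anemone placement with known ground-truth attachment angles.

Given a generated shell, :func:`place_anemone` constructs the raw inputs of
the landmark pipeline (siphonoglyph point cloud, lip tips C and D) such
that measuring the configuration returns a *requested* Angle 1 / Angle 2
pair.  The construction inverts the measurement:

* Angle 2 fixes the elevation of the anemone's axis over the aperture
  plane, and that axis is the surface normal at the pedal-disc footprint;
  so the footprint is searched on the analytic surface for a point whose
  outward normal makes the requested angle with the (dorsal-oriented)
  aperture-plane normal.
* Angle 1 then fixes where the siphonoglyph plane must cross line CD: the
  crossing point E is solved on the C→D ray (or its apex-ward extension)
  so that ∠CBE equals the request, and the synthetic siphonoglyph cloud is
  laid out as a flat ellipse whose plane contains both the oral point A and
  that E, with its two major-axis extremes straddling A ("upper tips").

With zero cloud noise the measurement module recovers the requested angles
up to mesh discretisation (about a degree at default resolution).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .errors import InfeasiblePlacementError, ParameterError
from .geometry import derive_landmarks, fit_plane, closest_point_on_mesh, measure_attachment
from .shells import ShellGeometry

__all__ = ["AnemonePlacement", "place_anemone", "rim_tips", "measure_placement"]


@dataclass
class AnemonePlacement:
    """Ground truth and raw landmark inputs for one synthetic specimen."""

    footprint_center: np.ndarray      # pedal-disc centre on the shell surface
    directive_axis: np.ndarray        # unit oral–aboral axis (surface normal)
    siphonoglyph_points: np.ndarray   # (n,3) cloud around the siphonoglyphs
    C: np.ndarray                     # upper tip of the outer lip (rim vertex)
    D: np.ndarray                     # lower tip of the outer lip (rim vertex)
    true_angle1: float                # requested signed Angle 1 (degrees)
    true_angle2: float                # requested Angle 2 (degrees)
    noise_sd: float                   # isotropic jitter applied to the cloud
    specimen_id: str = ""

    def landmark_inputs(self) -> dict:
        """JSON-ready raw inputs consumed by the geometry pipeline."""
        return {
            "C": self.C.tolist(),
            "D": self.D.tolist(),
            "siphonoglyph_points": self.siphonoglyph_points.tolist(),
        }


def rim_tips(shell: ShellGeometry) -> tuple[np.ndarray, np.ndarray]:
    """Upper (C) and lower (D) tips of the outer lip.

    Defined as the rim vertices extremal along the coiling axis projected
    into the aperture plane — a reproducible surrogate for the manual
    landmark choice on scanned shells.
    """
    n = shell.aperture_normal
    proj = shell.axis - np.dot(shell.axis, n) * n
    norm = np.linalg.norm(proj)
    if norm < 1e-12:
        raise InfeasiblePlacementError("coiling axis is normal to the aperture plane")
    proj = proj / norm
    s = shell.rim @ proj
    return shell.rim[int(np.argmax(s))].copy(), shell.rim[int(np.argmin(s))].copy()


def _angle_deg(u, v) -> float:
    u = np.asarray(u, float)
    v = np.asarray(v, float)
    return float(np.degrees(np.arctan2(np.linalg.norm(np.cross(u, v)), float(np.dot(u, v)))))


def _solve_E(B: np.ndarray, C: np.ndarray, D: np.ndarray, target: float) -> np.ndarray:
    """Point E on line CD with ∠CBE equal to ``target`` (signed degrees).

    E = C + t (D - C); positive targets put E on the D side (t > 0),
    negative ones beyond C toward the apex (t < 0).  The angle grows
    monotonically with |t|, so a bracketed root solve is exact.
    """
    if target == 0.0:
        return C.copy()
    u = (D - C) * (1.0 if target > 0 else -1.0)
    goal = abs(target)
    sup = _angle_deg(C - B, u)
    if goal >= sup - 1e-6:
        raise InfeasiblePlacementError(
            f"requested Angle 1 = {target:.2f} exceeds the geometric bound {sup:.2f}"
        )

    def f(t):
        return _angle_deg(C - B, C + t * u - B) - goal

    t_hi = 1.0
    while f(t_hi) < 0:
        t_hi *= 2.0
        if t_hi > 1e9:  # pragma: no cover - guarded by the sup check
            raise InfeasiblePlacementError("Angle 1 root bracketing failed")
    t = brentq(f, 0.0, t_hi, xtol=1e-12, rtol=1e-14)
    return C + t * u


def _rim_edge_candidates(shell, C, D, n_g, requested_angle1, requested_angle2,
                         margin_deg):
    """Footprints on the aperture rim edge for dorsal-facing placements.

    On the rim the surface has a crease between the swept tube and the
    aperture cap, so the closest-point direction cone spans from the tube
    normal (in plane G) to the cap normal n_G.  An oral point A placed at
    inclination ψ = 90° − Angle 2 inside that cone measures exactly the
    requested Angle 2, while the position along the rim arc sets the
    reachable ∠CBE range.  Yields (B0, direction, h) triples, best first.
    """
    c_e = shell.aperture_center
    psi = np.radians(90.0 - requested_angle2)
    # actual rim mesh vertices: at a vertex of the rim polygon the
    # closest-point cone strictly contains any direction perpendicular to
    # the local rim tangent, so A = B + h·dir projects back exactly onto B
    B = shell.rim
    rad = B - c_e
    r_e = np.linalg.norm(rad, axis=1)
    rad = rad / r_e[:, None]
    r_e = float(r_e.mean())
    ucd = (D - C) / np.linalg.norm(D - C)
    CB = C - B
    gamma = np.degrees(np.arctan2(
        np.linalg.norm(np.cross(CB, ucd), axis=-1), CB @ ucd))
    if requested_angle1 > 0:
        feasible = (gamma >= requested_angle1 + margin_deg) & (gamma <= 175.0)
        target = min(requested_angle1 + 30.0, 165.0)
    elif requested_angle1 < 0:
        feasible = ((180.0 - gamma) >= -requested_angle1 + margin_deg) & (gamma >= 5.0)
        target = max(150.0 + requested_angle1, 15.0)
    else:
        feasible = (gamma >= 5.0) & (gamma <= 175.0)
        target = 90.0
    if not feasible.any():
        return
    for idx in np.argsort(np.where(feasible, np.abs(gamma - target), np.inf)):
        if not feasible[idx]:
            break
        direction = np.cos(psi) * rad[idx] + np.sin(psi) * n_g
        yield B[idx], direction / np.linalg.norm(direction), 0.35 * r_e


def place_anemone(
    shell: ShellGeometry,
    requested_angle1: float,
    requested_angle2: float,
    noise_sd: float = 0.0,
    *,
    n_cloud_points: int = 36,
    seed: int = 0,
    specimen_id: str = "",
    _margin_deg: float = 3.0,
) -> AnemonePlacement:
    """Place a synthetic anemone realising the requested attachment angles.

    Parameters
    ----------
    requested_angle1 : float
        Signed Angle 1 in degrees, within the reachable range of the shell
        (|value| < 180; extreme values may be geometrically infeasible).
    requested_angle2 : float
        Angle 2 in degrees, strictly inside (0, 180).
    noise_sd : float
        Isotropic Gaussian jitter (length units) added to the siphonoglyph
        cloud only; the mesh stays exact.
    n_cloud_points : int
        Even number of points on the synthetic siphonoglyph ellipse.

    Raises
    ------
    ParameterError, InfeasiblePlacementError
    """
    if requested_angle2 in (0.0, 180.0):
        raise InfeasiblePlacementError(
            "Angle 2 of exactly 0 or 180 needs the directive axis parallel "
            "to the aperture-plane normal at the rim; not representable")
    if not (0.0 < requested_angle2 < 180.0):
        raise ParameterError("requested_angle2 must lie strictly in (0, 180)")
    if not (-180.0 < requested_angle1 <= 180.0):
        raise ParameterError("requested_angle1 must lie in (-180, 180]")
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    if n_cloud_points < 8 or n_cloud_points % 2:
        raise ParameterError("n_cloud_points must be an even number >= 8")

    C, D = rim_tips(shell)
    g_plane = fit_plane(shell.rim)
    n_g = g_plane.normal
    if np.dot(n_g, shell.dorsal_reference) < 0:
        n_g = -n_g

    # --- candidate footprint search on the analytic surface --------------
    m = shell.model
    theta_end = 2.0 * np.pi * m.n_revolutions
    theta = np.linspace(
        0.20 * 2 * np.pi, theta_end - 0.08 * 2 * np.pi,
        max(240, int(180 * m.n_revolutions)))
    phi = np.linspace(0.0, 2 * np.pi, 180, endpoint=False)
    tt, pp = np.meshgrid(theta, phi, indexing="ij")
    P = shell.surface_point(tt, pp)
    N = shell.surface_normal(tt, pp)
    r_grid = m.aperture_radius0 * m.whorl_expansion ** (tt / (2 * np.pi))
    h_grid = 0.35 * r_grid
    # Angle 2 as the pipeline will measure it: the ray F→A points from
    # plane G toward A, so its elevation sign is the side of G that
    # A = P + h·n̂ lies on; the magnitude is set by angle(n̂, n_G).
    cosang = np.clip(np.einsum("ijk,k->ij", N, n_g), -1.0, 1.0)
    alpha = np.degrees(np.arccos(cosang))
    d_a = np.einsum("ijk,k->ij", P + h_grid[..., None] * N - g_plane.point, n_g)
    predicted2 = 90.0 - np.sign(d_a) * np.abs(90.0 - alpha)
    err2 = np.abs(predicted2 - requested_angle2)
    # Angle 1 feasibility at each candidate
    gamma = np.degrees(
        np.arctan2(
            np.linalg.norm(np.cross(C - P, (D - C) / np.linalg.norm(D - C)), axis=-1),
            np.einsum("ijk,k->ij", C - P, (D - C) / np.linalg.norm(D - C)),
        )
    )
    if requested_angle1 > 0:
        feasible = gamma >= requested_angle1 + _margin_deg
    elif requested_angle1 < 0:
        feasible = (180.0 - gamma) >= -requested_angle1 + _margin_deg
    else:
        feasible = np.ones_like(gamma, dtype=bool)
    # keep A clearly off plane G so the elevation sign is stable
    ok = (err2 < 0.5) & feasible & (np.abs(d_a) > 0.1 * h_grid)

    def _candidates():
        # primary: smooth tube-surface footprints, best Angle 2 match first
        order = np.argsort(np.where(ok, err2, np.inf), axis=None)
        for flat in order[: min(int(ok.sum()), 40)]:
            i, j = np.unravel_index(flat, err2.shape)
            th, ph = float(tt[i, j]), float(pp[i, j])
            B0 = shell.surface_point(np.array(th), np.array(ph))
            nrm = shell.surface_normal(np.array(th), np.array(ph))
            r_local = m.aperture_radius0 * m.whorl_expansion ** (th / (2 * np.pi))
            yield B0, nrm, 0.35 * r_local
        # fallback: rim-edge footprints (dorsal-facing axes, Angle 2 < 90)
        if requested_angle2 < 90.0:
            count = 0
            for cand in _rim_edge_candidates(
                    shell, C, D, n_g, requested_angle1, requested_angle2,
                    _margin_deg):
                yield cand
                count += 1
                if count >= 40:
                    break

    rng = np.random.default_rng(seed)
    last_reason = (
        f"no surface point realises Angle 1 = {requested_angle1:.2f}, "
        f"Angle 2 = {requested_angle2:.2f} on this shell"
    )
    for B0, nrm, h in _candidates():
        A = B0 + h * nrm
        # verify the mesh path: A's closest surface point must be the
        # footprint itself, not another whorl or a cap
        B_mesh = closest_point_on_mesh(A, shell.mesh)
        if np.linalg.norm(B_mesh - B0) > 0.05 * h:
            last_reason = "footprint shadowed by another part of the surface"
            continue
        try:
            E = _solve_E(B0, C, D, requested_angle1)
        except InfeasiblePlacementError as exc:
            last_reason = str(exc)
            continue
        # siphonoglyph plane through A and E, cloud ellipse centred on A
        u_ae = E - A
        u_ae = u_ae / np.linalg.norm(u_ae)
        w = D - C
        n_s = w - np.dot(w, u_ae) * u_ae
        if np.linalg.norm(n_s) < 1e-9:
            n_s = np.cross(u_ae, shell.axis)
        n_s = n_s / np.linalg.norm(n_s)
        v1 = u_ae                      # in-plane major axis, toward E
        v2 = np.cross(n_s, v1)
        a_len = 0.30 * h
        b_len = a_len / 4.0
        psi = np.linspace(0.0, 2 * np.pi, n_cloud_points, endpoint=False)
        cloud = (A[None, :]
                 + a_len * np.cos(psi)[:, None] * v1[None, :]
                 + b_len * np.sin(psi)[:, None] * v2[None, :])
        placement = AnemonePlacement(
            footprint_center=B0,
            directive_axis=nrm,
            siphonoglyph_points=cloud,
            C=C, D=D,
            true_angle1=float(requested_angle1),
            true_angle2=float(requested_angle2),
            noise_sd=float(noise_sd),
            specimen_id=specimen_id,
        )
        # self-check before adding noise: the mesh-path measurement of the
        # exact configuration must reproduce the request within the
        # discretisation tolerance the generator promises
        got = measure_placement(shell, placement)
        if (abs(got.angle1 - requested_angle1) > 0.75
                or abs(got.angle2 - requested_angle2) > 0.75):
            last_reason = (
                f"candidate measured ({got.angle1:.2f}, {got.angle2:.2f}) "
                f"vs requested ({requested_angle1:.2f}, {requested_angle2:.2f})"
            )
            continue
        if noise_sd > 0:
            placement.siphonoglyph_points = cloud + rng.normal(
                0.0, noise_sd, size=cloud.shape)
        return placement
    raise InfeasiblePlacementError(last_reason)


def measure_placement(shell: ShellGeometry, placement: AnemonePlacement,
                      mesh=None):
    """Run the landmark pipeline on a synthetic placement.

    ``mesh`` overrides the shell's own mesh (e.g. a voxel-path
    re-extraction); rim, C, D and the dorsal reference stay the shell's.
    """
    lm = derive_landmarks(
        placement.siphonoglyph_points,
        shell.mesh if mesh is None else mesh,
        shell.rim,
        placement.C,
        placement.D,
        specimen_id=placement.specimen_id,
    )
    return measure_attachment(lm, shell.dorsal_reference)
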