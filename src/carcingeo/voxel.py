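"""Mock CT path: solid voxelisation and isosurface re-extraction.

The study's scans pass through a tomographic reconstruction before any
landmarks are set.  This module emulates the geometric part of that path:
a surface mesh is rasterised into a binary occupancy volume (no attenuation
physics — the analysis consumes segmented surfaces) and a surface is
re-extracted with marching cubes, after a one-voxel Gaussian smoothing of
the occupancy grid that suppresses the staircase bias of binary volumes.
Running the landmark pipeline on the re-extracted mesh quantifies how much
the rasterisation degrades the attachment angles.
"""

from __future__ import annotations

import numpy as np
import trimesh
from scipy import ndimage
from skimage import measure

from .errors import ExtractionError, ParameterError, ResolutionError

__all__ = ["voxelize_mesh", "extract_surface", "voxelize_and_extract"]

#: minimum number of voxels across the smallest aperture for a usable scan
MIN_VOXELS_ACROSS = 10


def voxelize_mesh(mesh: trimesh.Trimesh, voxel_size: float,
                  min_feature: float | None = None):
    """Rasterise a closed mesh into a filled uint8 occupancy volume.

    Parameters
    ----------
    voxel_size : float
        Edge length of the cubic voxels, in mesh length units.
    min_feature : float, optional
        Diameter of the smallest structure that must stay resolved
        (defaults to nothing); if given, ``voxel_size`` must fit at least
        ``MIN_VOXELS_ACROSS`` voxels across it.

    Returns
    -------
    volume : (nx, ny, nz) uint8 array with values {0, 255}
    origin : (3,) world coordinates of voxel index (0, 0, 0)
    """
    if voxel_size <= 0:
        raise ParameterError("voxel_size must be positive")
    if min_feature is not None and voxel_size > min_feature / MIN_VOXELS_ACROSS:
        raise ResolutionError(
            f"voxel_size {voxel_size:g} too coarse: fewer than "
            f"{MIN_VOXELS_ACROSS} voxels across the smallest feature "
            f"({min_feature:g})"
        )
    grid = mesh.voxelized(pitch=voxel_size).fill()
    volume = (grid.matrix.astype(np.uint8)) * np.uint8(255)
    origin = np.asarray(grid.transform[:3, 3], dtype=float)
    return volume, origin


def extract_surface(volume: np.ndarray, voxel_size: float,
                    origin=(0.0, 0.0, 0.0), smooth_sigma: float = 1.0
                    ) -> trimesh.Trimesh:
    """Marching-cubes isosurface of a binary occupancy volume.

    The volume is smoothed with a Gaussian of ``smooth_sigma`` voxels
    before contouring at level 0.5, which recovers sub-voxel surface
    placement from the binary grid.

    Raises
    ------
    ExtractionError
        Empty volume, or no surface crosses the iso-level.
    """
    vol = np.asarray(volume)
    if vol.size == 0 or not (vol > 0).any():
        raise ExtractionError("occupancy volume is empty; no surface to extract")
    field = vol.astype(np.float64) / float(vol.max())
    if smooth_sigma > 0:
        field = ndimage.gaussian_filter(field, sigma=smooth_sigma, mode="constant")
    try:
        verts, faces, _, _ = measure.marching_cubes(field, level=0.5)
    except (ValueError, RuntimeError) as exc:
        raise ExtractionError(f"isosurface extraction failed: {exc}") from exc
    verts = verts * voxel_size + np.asarray(origin, dtype=float)
    return trimesh.Trimesh(vertices=verts, faces=faces, process=False)


def voxelize_and_extract(mesh: trimesh.Trimesh, voxel_size: float,
                         min_feature: float | None = None,
                         smooth_sigma: float = 1.0):
    """Round-trip a mesh through the mock CT path.

    Returns ``(volume, origin, remesh)`` where ``remesh`` is the
    marching-cubes surface in the original world coordinates.  Siphonoglyph
    clouds and rim landmarks are separate inputs of the landmark pipeline
    (in the study they were exported as separate region-of-interest files)
    and pass through unchanged; only the shell surface is rasterised.
    """
    volume, origin = voxelize_mesh(mesh, voxel_size, min_feature=min_feature)
    remesh = extract_surface(volume, voxel_size, origin, smooth_sigma=smooth_sigma)
    return volume, origin, remesh
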