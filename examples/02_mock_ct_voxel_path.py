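"""Push a shell through the mock CT path and compare angle recovery.

The study's landmarks were set on surfaces reconstructed from micro-CT
volumes.  This example rasterises a synthetic shell into a binary
occupancy volume, re-extracts the surface with marching cubes, and shows
how little the attachment angles degrade.
"""

from carcingeo import (
    ShellModel, generate_shell, place_anemone, measure_placement,
    voxelize_and_extract,
)

shell = generate_shell(ShellModel(
    n_revolutions=1.75, points_per_revolution=72, aperture_points=32))
placement = place_anemone(shell, 30.0, 70.0, noise_sd=0.0, seed=5)

r0 = shell.model.aperture_radius0
volume, origin, remesh = voxelize_and_extract(
    shell.mesh, voxel_size=2 * r0 / 12, min_feature=2 * r0)
print(f"volume {volume.shape}, re-extracted surface "
      f"{len(remesh.faces)} faces")

mesh_path = measure_placement(shell, placement)
voxel_path = measure_placement(shell, placement, mesh=remesh)
print(f"mesh path  : Angle 1 = {mesh_path.angle1:6.2f}, "
      f"Angle 2 = {mesh_path.angle2:6.2f}")
print(f"voxel path : Angle 1 = {voxel_path.angle1:6.2f}, "
      f"Angle 2 = {voxel_path.angle2:6.2f}")
print("Differences stay within a few degrees at 12 voxels per aperture;")
print("the rasterisation is not the accuracy bottleneck of the method.")
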