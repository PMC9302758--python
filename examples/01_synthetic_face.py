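"""Generate a synthetic face shell and inspect its geometry.

The generator emulates a template-registered 3D face scan: an open
elliptical dome with a Gaussian nose ridge and chin bump, facing +Z, with
anthropometric landmarks placed at extrema of the generating height field.
"""

from maskfit import SyntheticFaceSpec, generate_synthetic_face, save_obj

spec = SyntheticFaceSpec(target_vertex_count=2000, seed=1)
mesh = generate_synthetic_face(spec)

print(f"vertices:  {mesh.n_vertices} (target {spec.target_vertex_count})")
print(f"triangles: {mesh.n_triangles}")
print(f"open-boundary vertices (clamped in the FE model): {len(mesh.boundary_vertices)}")
for name, idx in mesh.landmarks.items():
    x, y, z = mesh.vertices[idx]
    print(f"landmark {name:12s} -> vertex {idx:5d} at ({x:7.1f}, {y:7.1f}, {z:6.1f}) mm")

save_obj(mesh, "synthetic_face.obj")
print("wrote synthetic_face.obj (mm units)")
# The vertex count lands within 2% of the target; the landmark heights show
# the nose (pronasale) as the most protruded point, as on a real face.
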