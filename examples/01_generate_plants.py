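"""Generate synthetic weeds of both morphotypes and inspect their traits.

The generators construct plants whose height and one-sided leaf area are
known in closed form, which is what makes every downstream estimator
testable without field data.
"""

from weedphenom import generate_dicot, generate_monocot, mesh_surface_area

dicot = generate_dicot(height_cm=12.0, n_leaves=6, seed=7)
monocot = generate_monocot(height_cm=20.0, n_leaves=5, seed=3)

for plant in (dicot, monocot):
    mesh_total = mesh_surface_area(plant.mesh)
    print(f"{plant.morphotype}:")
    print(f"  truth height      {plant.truth_height_cm:.2f} cm")
    print(f"  truth leaf area   {plant.truth_leaf_area_cm2:.2f} cm^2 "
          f"({plant.n_leaves} leaves)")
    print(f"  mesh triangle sum {mesh_total:.2f} cm^2 "
          f"(= leaf area + stem tube {plant.stem_area_cm2:.2f} cm^2)")

# The mesh triangle sum exceeds the leaf-area truth by exactly the stem
# tube's lateral surface; leaves are open single sheets, so each
# triangle counts its one-sided area once.
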