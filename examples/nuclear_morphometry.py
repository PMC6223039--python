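"""Nuclear volume, shape factor and invagination scoring.

Generates a spherical nucleus and an invaginated one (two pocket-like
indentations), and compares voxel-coverage volume, the nuclear shape
factor (sphericity: 1 for a perfect sphere) and solidity (volume over
convex-hull volume; below 0.92 classifies the nucleus as invaginated).
"""

from nucarch import (
    GridSpec,
    NucleusShapeParams,
    classify_invaginated,
    make_nucleus_mask,
    nuclear_shape_factor,
    nuclear_volume,
    solidity,
)

grid = GridSpec((52, 52, 52), (0.125, 0.125, 0.125))

smooth = NucleusShapeParams(radius=3.0)
pocketed = NucleusShapeParams(
    radius=3.0,
    invagination_count=2,
    invagination_depth=1.5,
    invagination_radius=1.0,
)

for label, params in (("smooth sphere", smooth), ("invaginated", pocketed)):
    mask = make_nucleus_mask(params, grid, seed=2)
    s = solidity(mask)
    print(
        f"{label:>13}: V = {nuclear_volume(mask):6.1f} um3, "
        f"NSF = {nuclear_shape_factor(mask):.3f}, "
        f"solidity = {s:.3f}, invaginated = {classify_invaginated(s)}"
    )
# The sphere scores NSF ~1.00 and solidity ~1.00; carving pockets lowers
# both, and the solidity cutoff turns the visual invagination call into a
# reproducible classification.
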