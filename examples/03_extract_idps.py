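"""Extract muscle volume/mass phenotypes from ground-truth phantom labels.

The abdominal cavity slab runs from the most inferior lung slice to the
inferior aspect of L5 (both included); per-class volume is voxel counting
times voxel volume, and mass applies the 1.06 g/mL muscle density.
"""

from muscleidp.classes import MUSCLE_GROUPS
from muscleidp.idp import extract_idp, idp_table
from muscleidp.phantom import PhantomSpec, generate_phantom

vol, labels, lm = generate_phantom(PhantomSpec(seed=3))
idp = extract_idp("sub000", labels, lm, vol.spacing_mm)

print(f"cavity slab: slices {lm.lung_inferior_slice}..{lm.l5_inferior_slice} inclusive")
print(f"voxel volume: {vol.voxel_volume_ml*1000:.0f} mm³\n")
for group in MUSCLE_GROUPS:
    print(f"  {group:22s} {idp.group_mass_g(group):8.1f} g")
print(f"  {'total':22s} {idp.total_mass_g:8.1f} g "
      f"({idp.total_volume_ml:.1f} mL x 1.06 g/mL)")

df = idp_table([idp])
print("\nIDP table columns:", ", ".join(df.columns[:4]), "...")
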