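"""Project a protein environment's Coulomb field onto a reaction axis.

Builds a toy active site with a Ser/His/Asp-style triad, assigns partial
charges from a table, excludes the triad from the environment (the triad
belongs to the reacting system, not to the scaffold whose field we probe),
and prints the axial internal electric field in MV/cm.
"""

import tempfile

from fieldpmf.efield import axial_field
from fieldpmf.structures_io import Selection, read_structure
from fieldpmf.synthetic_data import GeneratorSpec, gen_toy_active_site

site = gen_toy_active_site(GeneratorSpec(seed=0))
with tempfile.NamedTemporaryFile("w", suffix=".pdb") as fh:
    fh.write(site.pdb_text)
    fh.flush()
    frame = read_structure(fh.name, site.charge_table)

environment = Selection(member_keys=set(site.triad_ids), mode="exclude")
sample = axial_field(frame, site.axis, environment)

print(f"axis: {site.axis.label}")
print(f"field vector (MV/cm): {sample.field_vector.round(2)}")
print(f"axial component (MV/cm): {sample.axial_component:.2f}")
print("A negative axial value means the scaffold field opposes the "
      "tail->head direction of the axis.")
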