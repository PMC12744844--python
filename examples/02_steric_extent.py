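"""Steric extent of each 2'-ribose chemistry.

Measures the C2'-to-farthest-substituent-atom distance on the package's
synthetic idealized nucleotide geometries, for all seven chemistries.
"""

from sirmsd.simulate import make_nucleotide
from sirmsd.sterics import modification_extent, substituent_atoms

print(f"{'chemistry':10s} {'extent_A':>8s}  {'farthest':8s} {'substituent atoms'}")
for chem in ("DNA", "FLUORO", "RNA", "OME", "FA", "MOE", "MTMM"):
    residue, _ = make_nucleotide("U", chem, guide_position=2)
    extent = modification_extent(residue)
    atoms = [a.name for a in substituent_atoms(residue).atoms]
    print(f"{chem:10s} {extent.extent:8.3f}  {extent.farthest_atom:8s} {atoms}")
# The extent orders the chemistries by bulk: 2'-deoxy (a lone hydrogen) is
# smallest, the 2'-MTMM thioacetal chain is largest.  Bulkier 2' groups at
# seed positions 2-5 are the ones that distort the guide on AGO2.
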