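"""Compute signed dihedral features from a multi-model PDB.

Builds a small synthetic peptide with prescribed backbone dihedrals,
writes it as a multi-model PDB, and featurizes it back; the recovered
phi/psi match the prescription.  The same call featurizes a real
channel trajectory given the selectivity-filter ResidueSpec.
"""

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

import clcgating as cg
from clcgating.geometry import build_chain

# helical backbone: phi = -57, psi = -47 for the middle residue
phi_psi = [(0.0, -47.0), (-57.0, -47.0), (-139.0, 0.0)]
internal = []
for i, (phi, psi) in enumerate(phi_psi):
    if i == 0:
        internal += [(1.46, 0, 0), (1.52, 111.0, 0.0), (1.33, 116.0, psi)]
    else:
        internal += [(1.46, 122.0, 179.9), (1.52, 111.0, phi),
                     (1.33, 116.0, psi)]
chain = build_chain(internal)

atoms = struc.AtomArray(9)
atoms.coord = chain[:9].astype(np.float32)  # N, CA, C of the 3 residues
atoms.res_id = np.repeat([1, 2, 3], 3)
atoms.res_name = np.repeat(["ALA", "GLU", "GLY"], 3)
atoms.atom_name = np.tile(["N", "CA", "C"], 3)
atoms.element = np.tile(["N", "C", "C"], 3)
atoms.chain_id = np.array(["A"] * 9)
pdb = PDBFile()
pdb.set_structure(atoms)
pdb.write("scratch_peptide.pdb")

fm = cg.featurize_trajectory("scratch_peptide.pdb",
                             cg.ResidueSpec(residues=(2,),
                                            kinds=("phi", "psi")))
print("columns:", fm.names)
print("angles :", np.round(fm.values[0], 2), "degrees")
print("prescribed phi/psi of residue 2: -57.0 / -47.0")
# Backbone feature names span the two residues of the dihedral
# ("phi:E2-A1" is phi of E2, reaching back to A1's carbonyl), the
# convention used throughout the selectivity-filter feature set.

import os
os.remove("scratch_peptide.pdb")
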