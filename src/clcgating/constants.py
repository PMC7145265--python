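"""Physical constants and the selectivity-filter residue set.

All free energies are in kcal/mol, angles in degrees, distances in
angstrom. Times are expressed in frames unless a frame time is declared;
the default frame time makes the production MSM lag of 28.8 ns an integer
number of frames.
"""

#: Boltzmann constant in kcal/mol/K.
KB_KCAL = 1.9872e-3

#: kT at 300 K in kcal/mol (0.5962 to the printed precision).
KT_300K = KB_KCAL * 300.0

#: Default physical time per trajectory frame, in nanoseconds.
FRAME_TIME_NS = 9.6

#: Default MSM lag time in nanoseconds (an integer multiple of FRAME_TIME_NS).
MSM_LAG_NS = 28.8

#: Selectivity-filter residues of rCLC-2, primary-sequence numbering.
SF_RESIDUES = (167, 168, 169, 170, 171, 209, 210, 211, 212, 213,
               463, 464, 465, 466, 467, 468, 559)

#: One-letter residue identities used to name synthetic dihedral features.
#: The mechanistically annotated positions (G167, S168, G169, I170, E211,
#: Y559) are fixed; the remainder is a plausible default and configurable.
SF_RESIDUE_NAMES = {
    167: "G", 168: "S", 169: "G", 170: "I", 171: "F",
    209: "F", 210: "G", 211: "E", 212: "L", 213: "P",
    463: "G", 464: "I", 465: "F", 466: "Q", 467: "S", 468: "P",
    559: "Y",
}

#: Canonical macrostate labels: closed (both gates), inner-gate open,
#: putative open, and the protonation-only occluded state.
MACROSTATE_LABELS = ("C_oi", "C_o", "O", "U")
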