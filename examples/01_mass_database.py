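"""Build the theoretical N-glycan mass database and inspect a few ions.

Prints the singly-sodiated m/z of landmark compositions (a biantennary
complex glycan, a high-mannose glycan, and its sialylated, derivatized
relatives), the composition-independent Endo F3 release shift, and the
size of the default enumerated database.
"""

from glycoims import (
    ChemistryConfig, GlycanComposition, build_database, endof3_mz, mz_for_key,
    theoretical_mz,
)

for key in ["Hex5HexNAc4", "Hex9HexNAc2", "Hex5dHex1HexNAc4", "Hex5dHex1HexNAc4NeuAc1"]:
    print(f"{key:28s} [M+Na]+ = {mz_for_key(key):.4f}")

# amidation-amidation derivatization makes sialic-acid linkage isomers
# mass-resolvable: alpha-2,3 -> amide (-0.9840 Da), alpha-2,6 ->
# dimethylamide (+27.0473 Da)
chem = ChemistryConfig(sialic_mode="amidation_amidation")
for key in ["Hex5dHex1HexNAc4NeuAc1(2,3)", "Hex5dHex2HexNAc5NeuAc1(2,6)"]:
    c = GlycanComposition.from_key(key)
    print(f"{key:28s} [M+Na]+ = {theoretical_mz(c, chem):.4f}")

# Endo F3 releases core-fucosylated glycans minus one GlcNAc + one fucose
c = GlycanComposition.from_key("Hex5dHex1HexNAc4")
plain = ChemistryConfig()
print(f"Endo F3 shift: {endof3_mz(c, plain) - theoretical_mz(c, plain):+.4f} Da")

db = build_database()
print(f"default database: {len(db)} entries, "
      f"m/z {db[0].theoretical_mz:.1f} .. {db[-1].theoretical_mz:.1f}")
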