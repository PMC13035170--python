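"""Compute neutral monoisotopic masses of reported O-GlcNAc glycopeptides.

Each peptide's mass is the residue-mass sum plus one water plus 203.079373 Da
per HexNAc; the printed values match engine-reported Mr(calc) at 2 dp.
"""

from oglyco import HEXNAC, Peptide, mz_from_mass, peptide_neutral_mass

GLYCOPEPTIDES = [
    ("PNSRHDNVSPSK", (9, 11)),
    ("LLVADILACNDDTPASAMMAGNGPVATMSLQVK", (29,)),
    ("HGGTTRTADAIRYATK", (4, 15)),
    ("VGLIAARRTGR", (9,)),
    ("DELPAIRLISLEEDMTK", (10, 16)),
    ("TFDFRADKILESLTNSLK", (14,)),
]

for sequence, sites in GLYCOPEPTIDES:
    p = Peptide(sequence, tuple((k, HEXNAC) for k in sites))
    mass = peptide_neutral_mass(p)
    print(
        f"{sequence:35s} {len(sites)} HexNAc  Mr(calc) {mass:9.2f} Da  "
        f"[M+2H]2+ {mz_from_mass(mass, 2):9.4f} m/z"
    )

print("\nMr(calc) is the neutral mass; the 2+ m/z column is what the "
      "instrument would select for a doubly protonated precursor.")
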