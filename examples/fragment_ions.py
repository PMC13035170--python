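"""Theoretical fragment and diagnostic ions for one glycopeptide.

Generates the b/y ladder with ammonia/water/HexNAc-loss derivatives for
PNSRHDNVSPSK carrying HexNAc at S9, and shows the intact/loss ion pairs
whose 203.0794 Da spacing is the neutral-loss fingerprint of O-GlcNAc.
"""

from oglyco import HEXNAC, Peptide, generate_fragments, hexnac_loss_pairs, oxonium_targets
from oglyco.fragment_model import fragments_to_frame

p = Peptide("PNSRHDNVSPSK", ((9, HEXNAC),))
frags = generate_fragments(p, max_charge=2)
table = fragments_to_frame(frags)
print(f"{len(frags)} theoretical ions for {p.sequence} (HexNAc@S9)")
print(table.head(10).to_string(index=False))

pairs = hexnac_loss_pairs(frags)
print(f"\n{len(pairs)} intact/HexNAc-loss pairs; first three:")
for intact, lost in pairs[:3]:
    print(
        f"  {intact.label:10s} {intact.mz:9.4f} -> {lost.label:14s} {lost.mz:9.4f}"
        f"   delta(neutral) = {intact.neutral_mass - lost.neutral_mass:.4f} Da"
    )

ox = oxonium_targets()
print(f"\noxonium diagnostics: primary {ox.primary} m/z, secondary {ox.secondary}")
print("A spectrum supporting O-GlcNAc shows the primary plus at least one "
      "secondary ion and a 203.0794 Da loss at precursor or fragment level.")
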