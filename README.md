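# oglyco

Evidence validation for O-GlcNAc glycopeptide identifications from
tandem mass spectrometry, with the downstream annotation stages of a
typical glycoproteomics campaign.

O-GlcNAc is a single β-linked N-acetylglucosamine (HexNAc) on Ser/Thr
hydroxyls of intracellular proteins. Search engines readily *propose*
HexNAc-modified peptide-spectrum matches (PSMs); accepting one as real
O-GlcNAc evidence requires spectrum-level corroboration. This package
implements that decision procedure as a deterministic, auditable battery:

- **Mass arithmetic** — neutral monoisotopic peptide masses
  (`Mr = Σ residues + H₂O + Σ mod deltas`, HexNAc = +203.079373 Da),
  m/z conversion and signed ppm errors.
- **Fragment model** — theoretical b/y ladders with −NH₃/−H₂O
  derivatives, HexNAc intact/loss ion pairs (Δ = 203.0794 Da), and the
  oxonium diagnostics (m/z 204.0867 primary; 138.055/144.066 secondary).
- **Spectral matching** — MGF/PSM-table I/O and nearest-peak matching
  within Da or ppm windows (defaults 0.05 Da fragments, 0.08 Da precursor).
- **Tiered classification** — with expectation value < 0.05:
  score ≤ 20 → *rejected*; 20 < score < 30 → *candidate*; score ≥ 30 with
  all diagnostics passing (oxonium primary + a secondary, a 203.0794 Da
  neutral loss at precursor or fragment level, b/y flanking support for a
  modified site, |precursor error| ≤ 10 ppm) → *high*; score ≥ 40 →
  *very high*. Failed diagnostics demote to candidate with the failing
  rules recorded.
- **Summaries** — mass/score/length distributions and tier-by-strain tables.
- **Annotation** — hypergeometric over-representation with BH-FDR and the
  <0.01 / <0.001 / <1e-4 reporting bins; two-source ortholog agreement.
- **Synthetic data** — a seeded generator of tryptic-like glycopeptides,
  EThcD-like spectra and PSM tables with known ground truth, so the whole
  chain is testable offline.

## Worked example

```python
from oglyco import HEXNAC, Peptide, peptide_neutral_mass

p = Peptide("PNSRHDNVSPSK", ((9, HEXNAC), (11, HEXNAC)))
print(f"{peptide_neutral_mass(p):.2f}")   # 1742.81
```

Running `python examples/validate_synthetic.py` simulates 200 peptides
(half glycosylated) and validates every PSM:

```
tier      candidate  high  rejected  very_high
is_glyco
False             0     0        89        0
True              8    91         0       12
```

Every PSM confirmed at high/very high is a planted glycopeptide; decoys
never pass because they lack oxonium ions, the 203.08 Da loss and a
HexNAc site to support. The eight glyco candidates are those whose
synthetic engine score fell below 30 — the score gate, not the
diagnostics, holds them back.

The other scripts in `examples/` each exercise one capability: reported
glycopeptide masses, fragment/diagnostic ion tables, enrichment binning,
and ortholog agreement.

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the pipeline from scratch: it generates a seeded synthetic
dataset, validates all PSMs, summarizes tiers by strain, runs an
enrichment query against a synthetic term collection and computes the
two-source ortholog agreement, then writes the results JSON.
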