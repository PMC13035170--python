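"""Simulate a ground-truth glycoproteome and validate it end to end.

Builds 200 tryptic-like peptides (half glycosylated), renders EThcD-like
spectra with 2 ppm jitter and noise peaks, assigns synthetic engine
scores, then runs every PSM through the diagnostic battery and prints the
confusion between planted truth and assigned tier.
"""

import pandas as pd

from oglyco import SimulationConfig, generate_dataset, reports_to_frame, validate_dataset

cfg = SimulationConfig(seed=42, n_peptides=200)
ds = generate_dataset(cfg)
reports = validate_dataset(ds.psms, ds.spectra)

df = reports_to_frame(reports)
df["is_glyco"] = [t.is_glyco for t in ds.truth]
print(pd.crosstab(df["is_glyco"], df["tier"]))

confirmed = df[df["tier"].isin(["high", "very_high"])]
print(f"\n{len(confirmed)} PSMs confirmed at high/very_high; all are planted "
      f"glycopeptides: {bool(confirmed['is_glyco'].all())}")
print("\nOne audited report:")
print(confirmed.iloc[0][["sequence", "ion_score", "tier", "reasons",
                          "neutral_loss_fragments", "precursor_ppm"]].to_string())
print("\nDecoys can never reach 'high': they lack oxonium ions, the 203.08 Da "
      "loss and a HexNAc site to support, so the diagnostics demote them.")
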