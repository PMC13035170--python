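# Methods

## The decision procedure

A search engine assigns a HexNAc-modified peptide to a spectrum and
reports an ion score and an expectation value. Neither is spectrum-level
proof of O-GlcNAc: the score measures backbone sequence match quality and
can be earned without any glycan-specific signal. The validator therefore
re-derives, from the peptide and the raw peak list, four independent
lines of evidence and combines them with the engine's statistics:

1. **Oxonium ions.** The HexNAc oxonium cation (C₈H₁₄NO₅⁺, m/z
   204.0867) and its secondary fragments at 138.055 and 144.066 appear
   whenever a HexNAc-bearing precursor is fragmented with
   collision-activated methods. The rule is conjunctive on the primary
   and disjunctive over the secondaries: 204.0867 must be present plus at
   least one of the two. A config switch relaxes to primary-only.
2. **203.0794 Da neutral loss.** The O-glycosidic bond is labile, so both
   the precursor and glycan-bearing fragments shed the intact sugar.
   Because it is unstated whether the published procedure assessed this on
   the precursor, on fragments, or both, both are computed and recorded
   separately, and either satisfies the rule: a peak at the
   (M − 203.0794) ion for the precursor charge z or z−1 (charge reduction
   is routine under electron-transfer activation), or at least one
   intact/loss fragment pair with both members matched.
3. **Site-flanking b/y support.** A site at position k (of n) is
   b-supported when a matched b-ion spans it (index ≥ k, mass includes
   the sugar) and another matched b-ion stops before it (index < k);
   y-support is the mirror image (index > n−k and index ≤ n−k). Terminal
   sites have no flanking ion on one side, so for k = 1 a matched
   sugar-carrying b1 — whose span is the single residue — counts alone
   (symmetrically y1 for k = n). One supported site in either series
   satisfies the rule; this is flanking-ion evidence only, not a
   site-localization probability.
4. **Precursor mass error.** The observed precursor must sit within
   ±10 ppm of theory. The published wording "between 5–10 ppm" is read as
   an acceptance band of |ppm| ≤ 10 — a literal *minimum* error of 5 ppm
   would be physically nonsensical — with |ppm| ≤ 5 reported as a quality
   grade in the tier's reason string.

Tiers, with expectation value < 0.05 required throughout: score ≤ 20
rejected (the ">20" bound is strict), 20–30 candidate, ≥ 30 high and
≥ 40 very high provided **all** enabled diagnostics pass (the conjunctive
reading; per-rule toggles exist because the original criteria do not
state whether any subset suffices). A score-eligible PSM failing a
diagnostic is demoted to candidate and every failed rule is recorded, so
no tier below the score-implied maximum is ever unexplained. PSMs
without any HexNAc cannot pass the glycan diagnostics and thus cap at
candidate by construction. Classification is deterministic and monotone
in score at fixed diagnostics.

## Mass and fragment conventions

Residue masses are standard monoisotopic values at six decimals; I/L are
distinct letters with identical mass. Mr(calc) is the neutral mass
(residues + water + modification deltas); rounding — half away from
zero, two decimals — is applied only when comparing to printed tables.
Carbamidomethyl and oxidation are per-PSM annotations, not unconditional
additions: one published peptide mass is only consistent with an
unmodified cysteine despite carbamidomethylation being nominally fixed.

Fragments are b/y with −NH₃/−H₂O on all ions (no residue-content
restriction by default; a config option adds one) and HexNAc loss only on
sugar-carrying ions. Although electron-transfer methods also produce c/z
ions, validation uses b/y as published; c/z stays disabled by default.
Doubly charged fragments are emitted only for neutral masses ≥ 800 Da
(configurable) to bound the match space — the published procedure
evaluated 1+/2+ but gave no rule. Peak matching is nearest-peak within
±0.05 Da by default with a ppm-window alternative; equidistant ties break
to the higher-intensity peak (signal over noise, deterministic), and each
observed peak may serve several fragments (no bipartite assignment), as
in manual annotation.

## Enrichment and orthologs

Over-representation uses the hypergeometric upper tail
P(X ≥ k | N, K, n) with Benjamini–Hochberg adjustment across all tested
terms and the reporting bins <0.01, <0.001, <1e-4. This is a
self-contained stand-in for network-based enrichment services: the
background defaults to the union of the annotation collection, term sets
are intersected with the background before testing, and terms without
background overlap are skipped. Network construction, edge evidence and
shell expansion are out of scope. Ortholog agreement treats sources as
arbitrary labelled tables; absence must be encoded explicitly (a row
with an empty ortholog) so silent coverage gaps cannot masquerade as
negative results.

## The synthetic world

The generator emulates the statistical shape of a lectin-enriched tryptic
glycopeptide population, not any real proteome:

- **Peptides**: residues sampled from nematode-like amino-acid
  frequencies; C-terminal K/R with at most two missed cleavages
  (weights 0.6/0.3/0.1 for 0/1/2); lengths from a discretized gamma
  (shape 16, scale 1.1, clipped to 7–45) whose width-5 histogram mode
  falls in 15–19, matching the reported length distribution; half the
  peptides carry 1–2 HexNAc on uniformly chosen S/T.
- **Spectra**: the full b/y/loss ladder (per-cut-site completeness
  parameter, default 1.0), oxonium triplet and precursor-loss peak for
  glycopeptides, Gaussian m/z jitter (default σ = 2 ppm,
  instrument-grade), and Poisson(30) uniform noise peaks. Noise is
  excluded from ±0.1 Da windows around the three oxonium targets, and
  decoy backbone ions that coincide with those windows by mass accident
  (e.g. the His b1 ion at 138.066) are suppressed and counted, so a
  non-glyco spectrum is oxonium-free *by construction* — the decoy
  specificity a test then measures is structural, not luck.
- **Scores**: shifted gamma per class (glycopeptides 20 + Γ(13, 1.2),
  mass ≈ 25–45; decoys 5 + Γ(9, 1.0), mass < 20) with log-uniform
  expectation values. These are explicitly synthetic; no engine's score
  law is claimed.

Planted peak positions reuse the same fragment-generation code the
validator uses, so zero-noise recovery is exact by construction — the
suite verifies this rather than assuming it. Consequently a green
end-to-end test establishes internal consistency of the pipeline and
correct wiring of every diagnostic, **not** performance on real spectra:
the generator has no intensity model, isotope clusters, chimeric spectra
or co-eluting interferences, and its score distributions are invented.

## Numerical choices

- Null-calibration of the enrichment test uses background 500, term 50,
  query 50: the discrete hypergeometric critical tail at α = 0.05 is
  0.0483, the attainable rate nearest 0.05, and the simulation test
  compares the empirical rejection rate to that exact value (±3 binomial
  SE) rather than to α itself — the test is conservative by discreteness.
- b/y complementarity is enforced to 1e-9 Da; intact/loss pair spacing to
  4 dp; printed masses to 2 dp after half-away-from-zero rounding.
- One reported sequence (RARDSASSSSSHSK, printed 2477.10) computes to
  2477.0889 with five HexNAc under every consistent modification layout;
  it is recorded as-is and excluded from the mass checks.
- All randomness flows from a single mandatory seed through
  `numpy.random.default_rng`; regenerating a dataset with the same
  configuration is byte-identical.

## Known limitations

Engine scores and expectation values are consumed, never recomputed;
there is no target-decoy FDR estimation, no site-localization
probabilities beyond flanking flags, no profile-data centroiding, and no
glycan ladders beyond the single-HexNAc loss. mzML ingestion is not
implemented; MGF is the interchange format.
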