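"""Per-PSM diagnostic checks and tiered O-GlcNAc confidence classification.

A search engine's glycopeptide assignment is accepted as O-GlcNAc evidence
only after a battery of spectrum-level checks: the HexNAc oxonium ions
(m/z 204.0867 plus at least one of 138.055 / 144.066), a 203.0794 Da
neutral loss at precursor or fragment level, backbone b/y support flanking
the modified residue, and a precursor mass error within the ppm band.
The engine's ion score and expectation value gate the tier:

    rejected    p_expect >= 0.05 or score <= 20
    candidate   20 < score < 30, or score >= 30 with failing diagnostics
    high        score >= 30 and all enabled diagnostics pass
    very_high   score >= 40 and all enabled diagnostics pass

"Manual inspection" is replaced by this deterministic battery; every
sub-check outcome is preserved in the report so a human can audit the call.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .fragment_model import (
    DEFAULT_OXONIUM,
    HEXNAC_NEUTRAL_LOSS,
    Loss,
    OxoniumSet,
    generate_fragments,
    hexnac_loss_pairs,
)
from .mass_chem import Peptide, mz_from_mass, peptide_neutral_mass, ppm_error
from .spectra_io import PSMRecord, PeakMatch, Spectrum, match_peaks

__all__ = [
    "Tier",
    "ValidationConfig",
    "DiagnosticOutcome",
    "ConfidenceTier",
    "EvidenceReport",
    "scan_oxonium",
    "detect_neutral_loss",
    "site_support",
    "classify",
    "validate_psm",
    "validate_dataset",
    "reports_to_frame",
]


class Tier(str, Enum):
    REJECTED = "rejected"
    CANDIDATE = "candidate"
    HIGH = "high"
    VERY_HIGH = "very_high"

    @property
    def rank(self) -> int:
        return {"rejected": 0, "candidate": 1, "high": 2, "very_high": 3}[self.value]


@dataclass(frozen=True)
class ValidationConfig:
    """Tolerances, thresholds and rule toggles; defaults follow the
    published search settings (0.05 Da fragments, 0.08 Da precursor,
    10 ppm band, score tiers 20/30/40, expect < 0.05)."""

    fragment_tol_da: float = 0.05
    precursor_tol_da: float = 0.08
    ppm_band: float = 10.0
    ppm_quality: float = 5.0
    expect_max: float = 0.05
    score_min: float = 20.0
    score_high: float = 30.0
    score_very_high: float = 40.0
    oxonium: OxoniumSet = DEFAULT_OXONIUM
    require_oxonium_secondary: bool = True
    require_neutral_loss: bool = True
    require_site_support: bool = True
    require_ppm_band: bool = True
    losses_enabled: tuple[str, ...] = ("NH3", "H2O", "HexNAc")
    max_fragment_charge: int = 2
    doubly_charged_min_mass: float = 800.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ValidationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "oxonium" in raw:
            ox = raw.pop("oxonium")
            raw["oxonium"] = OxoniumSet(
                primary=float(ox.get("primary", 204.0867)),
                secondary=tuple(float(s) for s in ox.get("secondary", (138.055, 144.066))),
            )
        if "losses_enabled" in raw:
            raw["losses_enabled"] = tuple(raw["losses_enabled"])
        return cls(**raw)


@dataclass(frozen=True)
class DiagnosticOutcome:
    """Outcome of every spectrum-level check for one PSM."""

    oxonium_primary_found: bool
    oxonium_secondary_found: bool
    neutral_loss_precursor: bool
    neutral_loss_fragment_count: int
    site_flanking_b: bool
    site_flanking_y: bool
    precursor_ppm: float
    matched_fraction: float

    def __post_init__(self) -> None:
        if self.neutral_loss_fragment_count < 0:
            raise ValueError("fragment neutral-loss count must be non-negative")
        if not 0.0 <= self.matched_fraction <= 1.0:
            raise ValueError("matched_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class ConfidenceTier:
    tier: Tier
    reasons: tuple[str, ...]


@dataclass(frozen=True)
class EvidenceReport:
    """Self-contained, serializable record of one validated PSM."""

    psm: PSMRecord
    diagnostics: DiagnosticOutcome
    tier: ConfidenceTier
    mr_calc: float
    matches: tuple[PeakMatch, ...]

    @property
    def peptide_length(self) -> int:
        return len(self.psm.peptide)


def scan_oxonium(
    s: Spectrum,
    ox: OxoniumSet = DEFAULT_OXONIUM,
    tol_da: float = 0.05,
    tol_ppm: float | None = None,
) -> tuple[bool, bool]:
    """Look for the HexNAc oxonium ions in the low-mass region.

    Returns (primary_found, secondary_found): primary is a peak within
    tolerance of 204.0867; secondary is a peak near any configured
    secondary target ("and/or" semantics — one suffices).  When
    ``tol_ppm`` is given, the window for each target is relative
    (target * tol_ppm * 1e-6) instead of the fixed Da window.
    """
    if tol_da <= 0:
        raise ValueError("tol_da must be positive")

    def window(target: float) -> float:
        return target * tol_ppm * 1e-6 if tol_ppm is not None else tol_da

    primary = s.has_peak_near(ox.primary, window(ox.primary))
    secondary = any(s.has_peak_near(t, window(t)) for t in ox.secondary)
    return primary, secondary


def detect_neutral_loss(
    s: Spectrum,
    p: Peptide,
    tol_da: float = 0.05,
    matches: Sequence[PeakMatch] | None = None,
    max_fragment_charge: int = 2,
    doubly_charged_min_mass: float = 800.0,
) -> tuple[bool, int]:
    """Detect the 203.0794 Da HexNAc neutral loss, precursor- and fragment-level.

    Precursor level: a peak within +/- tol_da of the (M - 203.0794) ion at
    the spectrum's precursor charge z or at z-1 (charge reduction during
    electron-transfer activation is common).  Fragment level: the count of
    intact/loss fragment pairs for which BOTH members match an observed
    peak.  Undefined for peptides without HexNAc.
    """
    if not p.hexnac_sites:
        raise ValueError("neutral-loss check is undefined for peptides without HexNAc")
    neutral = peptide_neutral_mass(p) - HEXNAC_NEUTRAL_LOSS
    z0 = s.precursor_charge or 2
    charges = {z for z in (z0, z0 - 1) if z >= 1}
    precursor_flag = any(
        s.has_peak_near(mz_from_mass(neutral, z), tol_da) for z in sorted(charges)
    )

    if matches is None:
        frags = generate_fragments(
            p,
            max_charge=max_fragment_charge,
            losses_enabled=(Loss.NH3, Loss.H2O, Loss.HEXNAC),
            doubly_charged_min_mass=doubly_charged_min_mass,
        )
        matches = match_peaks(s, frags, tol_da)
    matched_keys = {
        (m.fragment.series, m.fragment.index, m.fragment.charge, m.fragment.loss)
        for m in matches
    }
    pairs = hexnac_loss_pairs([m.fragment for m in matches])
    count = sum(
        1
        for intact, loss in pairs
        if (intact.series, intact.index, intact.charge, Loss.NONE) in matched_keys
        and (loss.series, loss.index, loss.charge, Loss.HEXNAC) in matched_keys
    )
    return precursor_flag, count


def site_support(
    matches: Sequence[PeakMatch], p: Peptide
) -> dict[int, tuple[bool, bool]]:
    """Flanking b/y ion support per HexNAc site.

    A site at 1-based position k is b-supported when some matched b-ion
    spans the site (index >= k, so its mass includes the sugar) and some
    matched b-ion stops before it (index < k) — the pair brackets the
    residue from the N-terminal side.  y-support is the mirror image from
    the C-terminal side: a matched y-ion with index > n-k (spans the site)
    plus one with index <= n-k (stops before it).

    Terminal sites have no flanking ion on one side: for k=1 a matched,
    sugar-carrying b1 localizes the site by itself (its span is the single
    residue), so the N-terminal bracket is waived there; symmetrically for
    k=n and y1.
    """
    n = len(p)
    b_idx = {m.fragment.index for m in matches if m.fragment.series == "b"}
    y_idx = {m.fragment.index for m in matches if m.fragment.series == "y"}
    out: dict[int, tuple[bool, bool]] = {}
    for k in p.hexnac_sites:
        b_ok = any(i >= k for i in b_idx) and (k == 1 or any(i < k for i in b_idx))
        # y_j covers residues n-j+1..n; it includes site k iff j > n-k
        y_ok = any(j > n - k for j in y_idx) and (
            k == n or any(j <= n - k for j in y_idx)
        )
        out[k] = (b_ok, y_ok)
    return out


def classify(
    psm: PSMRecord, d: DiagnosticOutcome, cfg: ValidationConfig = ValidationConfig()
) -> ConfidenceTier:
    """Assign the confidence tier from score/expect gates and diagnostics.

    Score boundaries are deliberate: "more than 20" is strict (a score of
    exactly 20 is rejected) while 30 and 40 are inclusive.  A score-
    eligible PSM failing any enabled diagnostic is demoted to candidate
    with the failing rules recorded.
    """
    reasons: list[str] = []
    if psm.p_expect >= cfg.expect_max:
        return ConfidenceTier(Tier.REJECTED, (f"p_expect {psm.p_expect:g} >= {cfg.expect_max:g}",))
    if psm.ion_score <= cfg.score_min:
        return ConfidenceTier(Tier.REJECTED, (f"ion_score {psm.ion_score:g} <= {cfg.score_min:g}",))
    if psm.ion_score < cfg.score_high:
        return ConfidenceTier(
            Tier.CANDIDATE,
            (f"ion_score {psm.ion_score:g} in candidate band "
             f"({cfg.score_min:g}, {cfg.score_high:g})",),
        )

    if not d.oxonium_primary_found:
        reasons.append("oxonium: primary 204.0867 not observed")
    if cfg.require_oxonium_secondary and not d.oxonium_secondary_found:
        reasons.append("oxonium: no secondary ion (138.055/144.066) observed")
    if cfg.require_neutral_loss and not (
        d.neutral_loss_precursor or d.neutral_loss_fragment_count > 0
    ):
        reasons.append("neutral loss: 203.0794 Da not observed at precursor or fragment level")
    if cfg.require_site_support and not (d.site_flanking_b or d.site_flanking_y):
        reasons.append("site support: no modified site flanked by b or y ions")
    if cfg.require_ppm_band and abs(d.precursor_ppm) > cfg.ppm_band:
        reasons.append(
            f"precursor mass error {d.precursor_ppm:+.1f} ppm outside +/-{cfg.ppm_band:g} ppm"
        )

    if reasons:
        return ConfidenceTier(Tier.CANDIDATE, tuple(reasons))
    tier = Tier.VERY_HIGH if psm.ion_score >= cfg.score_very_high else Tier.HIGH
    grade = "<=5 ppm" if abs(d.precursor_ppm) <= cfg.ppm_quality else "<=10 ppm"
    return ConfidenceTier(
        tier,
        (f"ion_score {psm.ion_score:g} with all diagnostics passing "
         f"(precursor {grade})",),
    )


def validate_psm(
    psm: PSMRecord, s: Spectrum, cfg: ValidationConfig = ValidationConfig()
) -> EvidenceReport:
    """Run the full evidence battery for one PSM against its spectrum."""
    if psm.spectrum_id != s.identifier:
        raise ValueError(
            f"spectrum id mismatch: PSM refers to {psm.spectrum_id!r}, "
            f"got spectrum {s.identifier!r}"
        )
    p = psm.peptide
    frags = generate_fragments(
        p,
        max_charge=cfg.max_fragment_charge,
        losses_enabled=[Loss(l) for l in cfg.losses_enabled],
        doubly_charged_min_mass=cfg.doubly_charged_min_mass,
    )
    matches = match_peaks(s, frags, cfg.fragment_tol_da)
    mr = peptide_neutral_mass(p)

    ox_primary, ox_secondary = scan_oxonium(s, cfg.oxonium, cfg.fragment_tol_da)
    if p.hexnac_sites:
        nl_prec, nl_frag = detect_neutral_loss(
            s, p, cfg.fragment_tol_da, matches=matches,
            max_fragment_charge=cfg.max_fragment_charge,
            doubly_charged_min_mass=cfg.doubly_charged_min_mass,
        )
        support = site_support(matches, p)
        b_ok = any(b for b, _ in support.values())
        y_ok = any(y for _, y in support.values())
    else:
        nl_prec, nl_frag = False, 0
        b_ok = y_ok = False

    theo_mz = mz_from_mass(mr, psm.charge)
    prec_ppm = ppm_error(psm.precursor_mz_observed, theo_mz)
    plain = [f for f in frags if f.loss is Loss.NONE and f.charge == 1]
    matched_plain = {
        (m.fragment.series, m.fragment.index)
        for m in matches
        if m.fragment.loss is Loss.NONE and m.fragment.charge == 1
    }
    fraction = len(matched_plain) / len(plain) if plain else 0.0

    diag = DiagnosticOutcome(
        oxonium_primary_found=ox_primary,
        oxonium_secondary_found=ox_secondary,
        neutral_loss_precursor=nl_prec,
        neutral_loss_fragment_count=nl_frag,
        site_flanking_b=b_ok,
        site_flanking_y=y_ok,
        precursor_ppm=prec_ppm,
        matched_fraction=fraction,
    )
    return EvidenceReport(
        psm=psm,
        diagnostics=diag,
        tier=classify(psm, diag, cfg),
        mr_calc=mr,
        matches=tuple(matches),
    )


def validate_dataset(
    psms: Sequence[PSMRecord],
    spectra: Sequence[Spectrum] | Mapping[str, Spectrum],
    cfg: ValidationConfig = ValidationConfig(),
) -> list[EvidenceReport]:
    """Validate every PSM, resolving spectra by identifier."""
    if not isinstance(spectra, Mapping):
        spectra = {s.identifier: s for s in spectra}
    missing = [p.spectrum_id for p in psms if p.spectrum_id not in spectra]
    if missing:
        raise KeyError(f"unresolvable spectrum ids: {sorted(set(missing))}")
    return [validate_psm(p, spectra[p.spectrum_id], cfg) for p in psms]


def reports_to_frame(reports: Sequence[EvidenceReport]) -> pd.DataFrame:
    """Flatten evidence reports to a table (one row per PSM)."""
    rows = []
    for r in reports:
        d = r.diagnostics
        rows.append(
            {
                "spectrum_id": r.psm.spectrum_id,
                "sequence": r.psm.peptide.sequence,
                "n_hexnac": len(r.psm.peptide.hexnac_sites),
                "ion_score": r.psm.ion_score,
                "p_expect": r.psm.p_expect,
                "source_strain": r.psm.source_strain,
                "mr_calc": r.mr_calc,
                "peptide_length": r.peptide_length,
                "tier": r.tier.tier.value,
                "reasons": " | ".join(r.tier.reasons),
                "oxonium_primary": d.oxonium_primary_found,
                "oxonium_secondary": d.oxonium_secondary_found,
                "neutral_loss_precursor": d.neutral_loss_precursor,
                "neutral_loss_fragments": d.neutral_loss_fragment_count,
                "site_flanking_b": d.site_flanking_b,
                "site_flanking_y": d.site_flanking_y,
                "precursor_ppm": d.precursor_ppm,
                "matched_fraction": d.matched_fraction,
            }
        )
    return pd.DataFrame(rows)
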