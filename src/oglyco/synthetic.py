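"""Ground-truth glycoproteome, spectrum and PSM simulation.

Generates tryptic-like peptides (C-terminal K/R, bounded missed
cleavages, length mode in the 15-19 bin), stochastically O-GlcNAcylates
S/T positions, and renders each peptide into an EThcD-like centroided
spectrum: b/y ladder with ammonia/water-loss derivatives, HexNAc
intact/loss pairs and oxonium ions for glycopeptides, an optional
precursor-minus-203.0794 peak, Gaussian ppm jitter, and uniform noise
peaks.  Planted peaks come from the same fragment arithmetic the
validator uses, so zero-noise recovery is exact by construction — a fact
the test suite verifies rather than assumes.

Every spectrum is paired with a ground-truth record of what was planted
and the tier the peptide should earn at zero noise, so sensitivity and
specificity of the whole pipeline are measurable without any external
download.  PSM engine scores are explicitly synthetic (shifted-gamma per
class); no claim is made that they follow any real engine's score law.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .fragment_model import (
    DEFAULT_OXONIUM,
    HEXNAC_NEUTRAL_LOSS,
    Loss,
    generate_fragments,
)
from .mass_chem import (
    HEXNAC,
    Peptide,
    format_mod_string,
    mz_from_mass,
    peptide_neutral_mass,
)
from .spectra_io import PSMRecord, Spectrum, write_mgf, write_psm_table
from .validator import Tier

__all__ = [
    "SimulationConfig",
    "ScoreModel",
    "GroundTruthEntry",
    "SyntheticDataset",
    "generate_peptides",
    "simulate_spectrum",
    "generate_dataset",
    "emit_dataset",
]

#: Amino-acid sampling frequencies, roughly those of a nematode proteome.
#: K/R are excluded here because cleavage-site placement handles them.
RESIDUE_FREQUENCIES = {
    "A": 0.063, "C": 0.020, "D": 0.053, "E": 0.065, "F": 0.048,
    "G": 0.054, "H": 0.023, "I": 0.061, "L": 0.086, "M": 0.026,
    "N": 0.049, "P": 0.049, "Q": 0.041, "S": 0.081, "T": 0.059,
    "V": 0.062, "W": 0.011, "Y": 0.031,
}


@dataclass(frozen=True)
class ScoreModel:
    """Shifted-gamma engine-score model plus a log-uniform expect model."""

    loc: float
    shape: float
    scale: float
    log10_expect_range: tuple[float, float]

    def draw(self, rng: np.random.Generator) -> tuple[float, float]:
        score = self.loc + rng.gamma(self.shape, self.scale)
        lo, hi = self.log10_expect_range
        expect = 10.0 ** (-rng.uniform(lo, hi))
        return float(round(score, 1)), float(expect)


@dataclass(frozen=True)
class SimulationConfig:
    """The stated world of the simulation.

    Defaults: peptide lengths drawn from a discretized gamma with mode
    ~16-17 (so the width-5 histogram mode lands in 15-19), up to two
    missed cleavages, half the peptides glycosylated with 1-2 HexNAc,
    2 ppm m/z jitter (instrument-grade accuracy), 30 uniform noise peaks,
    glycopeptide scores centred in the 25-45 band and decoy scores below
    20.  The seed is mandatory.
    """

    seed: int
    n_peptides: int = 200
    glyco_fraction: float = 0.5
    length_gamma_shape: float = 16.0
    length_gamma_scale: float = 1.1
    length_min: int = 7
    length_max: int = 45
    missed_cleavage_max: int = 2
    missed_cleavage_weights: tuple[float, ...] = (0.6, 0.3, 0.1)
    max_hexnac_per_peptide: int = 2
    mz_jitter_ppm: float = 2.0
    noise_peaks_per_spectrum: float = 30.0
    ladder_completeness: float = 1.0
    emit_precursor_loss: bool = True
    emit_oxonium: bool = True
    glyco_scores: ScoreModel = ScoreModel(
        loc=20.0, shape=13.0, scale=1.2, log10_expect_range=(1.5, 3.5)
    )
    decoy_scores: ScoreModel = ScoreModel(
        loc=5.0, shape=9.0, scale=1.0, log10_expect_range=(0.8, 2.0)
    )

    def __post_init__(self) -> None:
        if not 0.0 <= self.glyco_fraction <= 1.0:
            raise ValueError("glyco_fraction must lie in [0, 1]")
        if not 0.0 <= self.ladder_completeness <= 1.0:
            raise ValueError("ladder_completeness must lie in [0, 1]")
        if self.missed_cleavage_max + 1 != len(self.missed_cleavage_weights):
            raise ValueError("need one missed-cleavage weight per count 0..max")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass(frozen=True)
class GroundTruthEntry:
    """Links a generated spectrum to its true peptide, sites and class."""

    peptide: Peptide
    is_glyco: bool
    spectrum_id: str
    planted_diagnostics: dict
    true_class: Tier


@dataclass(frozen=True)
class SyntheticDataset:
    spectra: tuple[Spectrum, ...]
    psms: tuple[PSMRecord, ...]
    truth: tuple[GroundTruthEntry, ...]


def _draw_length(cfg: SimulationConfig, rng: np.random.Generator) -> int:
    raw = rng.gamma(cfg.length_gamma_shape, cfg.length_gamma_scale)
    return int(np.clip(round(raw), cfg.length_min, cfg.length_max))


def _draw_sequence(length: int, n_internal_kr: int, rng: np.random.Generator) -> str:
    letters = np.array(list(RESIDUE_FREQUENCIES))
    probs = np.array(list(RESIDUE_FREQUENCIES.values()))
    probs = probs / probs.sum()
    body = rng.choice(letters, size=length - 1, p=probs)
    if n_internal_kr:
        # missed-cleavage K/R sites anywhere but the last internal position
        # (a K/R immediately before the C-terminal one would be fine too,
        # but keeping them interior makes the count unambiguous)
        positions = rng.choice(length - 1, size=n_internal_kr, replace=False)
        body[positions] = rng.choice(["K", "R"], size=n_internal_kr)
    terminal = rng.choice(["K", "R"])
    return "".join(body) + terminal


def generate_peptides(cfg: SimulationConfig) -> list[Peptide]:
    """Sample tryptic-like peptides with stochastic HexNAc occupancy.

    Peptides end in K or R and contain at most ``missed_cleavage_max``
    internal K/R.  A ``glyco_fraction`` share receives 1-2 HexNAc on
    uniformly chosen S/T positions; sequences drawn without any S/T are
    re-drawn when they were destined to be glycosylated, so peptides
    without acceptor sites are never glyco.
    """
    if cfg.glyco_fraction > 0 and not {"S", "T"} & set(RESIDUE_FREQUENCIES):
        raise ValueError("glyco_fraction > 0 requires S/T in the alphabet")
    rng = np.random.default_rng(cfg.seed)
    peptides: list[Peptide] = []
    weights = np.asarray(cfg.missed_cleavage_weights, dtype=float)
    weights = weights / weights.sum()
    for _ in range(cfg.n_peptides):
        glyco = rng.random() < cfg.glyco_fraction
        n_mc = int(rng.choice(cfg.missed_cleavage_max + 1, p=weights))
        while True:
            seq = _draw_sequence(_draw_length(cfg, rng), n_mc, rng)
            st_sites = [i + 1 for i, aa in enumerate(seq) if aa in "ST"]
            if not glyco or st_sites:
                break
        mods = ()
        if glyco:
            n_sites = int(rng.integers(1, cfg.max_hexnac_per_peptide + 1))
            n_sites = min(n_sites, len(st_sites))
            chosen = rng.choice(st_sites, size=n_sites, replace=False)
            mods = tuple((int(k), HEXNAC) for k in sorted(chosen))
        peptides.append(Peptide(seq, mods))
    return peptides


def _jitter(mz: float, sigma_ppm: float, rng: np.random.Generator) -> float:
    if sigma_ppm <= 0:
        return mz
    return mz * (1.0 + rng.normal(0.0, sigma_ppm * 1e-6))


# noise peaks are kept out of these windows so a decoy spectrum can never
# fake an oxonium by accident (the validator is tested against structure,
# not against lucky noise)
_NOISE_EXCLUSION_DA = 0.1


def simulate_spectrum(
    p: Peptide,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
    spectrum_id: str = "scan=1",
) -> tuple[Spectrum, GroundTruthEntry]:
    """Render one peptide into an EThcD-like centroided spectrum.

    Planted peak positions reuse :func:`generate_fragments`, so the
    simulation and the validator share one mass code path.  The returned
    ground-truth entry records exactly which diagnostics were emitted;
    ``true_class`` is filled with CANDIDATE and overwritten once a score
    is drawn at dataset level.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    mass = peptide_neutral_mass(p)
    charge = 2 if mass < 1800 else 3
    is_glyco = bool(p.hexnac_sites)

    frags = generate_fragments(
        p, max_charge=2, losses_enabled=(Loss.NH3, Loss.H2O, Loss.HEXNAC)
    )
    # per-cut-site retention so a dropped site removes its whole ion family
    n = len(p)
    kept_cuts = {
        i for i in range(1, n) if rng.random() < cfg.ladder_completeness
    }
    guarded = (DEFAULT_OXONIUM.primary, *DEFAULT_OXONIUM.secondary)
    peaks: list[tuple[float, float]] = []
    planted_fragments = 0
    suppressed_fragments = 0
    for f in frags:
        cut = f.index if f.series == "b" else n - f.index
        if cut not in kept_cuts:
            continue
        # a decoy backbone ion can coincide with a diagnostic window by
        # mass accident (e.g. His b1 at 138.066); suppress those so a
        # non-glyco spectrum is guaranteed oxonium-free by construction
        if not is_glyco and any(
            abs(f.mz - g) < _NOISE_EXCLUSION_DA for g in guarded
        ):
            suppressed_fragments += 1
            continue
        peaks.append((_jitter(f.mz, cfg.mz_jitter_ppm, rng), float(rng.uniform(50, 150))))
        planted_fragments += 1

    planted_oxonium = False
    planted_precursor_loss = False
    if is_glyco and cfg.emit_oxonium:
        for target in (DEFAULT_OXONIUM.primary, *DEFAULT_OXONIUM.secondary):
            peaks.append((_jitter(target, cfg.mz_jitter_ppm, rng), float(rng.uniform(150, 300))))
        planted_oxonium = True
    if is_glyco and cfg.emit_precursor_loss:
        loss_mz = mz_from_mass(mass - HEXNAC_NEUTRAL_LOSS, charge)
        peaks.append((_jitter(loss_mz, cfg.mz_jitter_ppm, rng), float(rng.uniform(50, 150))))
        planted_precursor_loss = True

    n_noise = int(rng.poisson(cfg.noise_peaks_per_spectrum))
    mz_hi = mz_from_mass(mass, 1)
    added = 0
    while added < n_noise:
        mz = float(rng.uniform(100.0, mz_hi))
        if any(abs(mz - g) < _NOISE_EXCLUSION_DA for g in guarded):
            continue
        peaks.append((mz, float(rng.uniform(1, 20))))
        added += 1

    precursor_mz = _jitter(mz_from_mass(mass, charge), cfg.mz_jitter_ppm, rng)
    spectrum = Spectrum(
        identifier=spectrum_id,
        precursor_mz=precursor_mz,
        precursor_charge=charge,
        peaks=tuple(peaks),
    )
    truth = GroundTruthEntry(
        peptide=p,
        is_glyco=is_glyco,
        spectrum_id=spectrum_id,
        planted_diagnostics={
            "oxonium": planted_oxonium,
            "precursor_loss": planted_precursor_loss,
            "fragments_planted": planted_fragments,
            "fragments_suppressed": suppressed_fragments,
            "cut_sites_kept": len(kept_cuts),
        },
        true_class=Tier.CANDIDATE,
    )
    return spectrum, truth


def _intended_tier(is_glyco: bool, score: float, expect: float) -> Tier:
    if expect >= 0.05 or score <= 20:
        return Tier.REJECTED
    if not is_glyco or score < 30:
        return Tier.CANDIDATE
    return Tier.VERY_HIGH if score >= 40 else Tier.HIGH


def generate_dataset(cfg: SimulationConfig) -> SyntheticDataset:
    """Peptides -> spectra -> PSMs, all from one seeded generator."""
    peptides = generate_peptides(cfg)
    rng = np.random.default_rng(cfg.seed + 1_000_003)
    spectra: list[Spectrum] = []
    psms: list[PSMRecord] = []
    truth: list[GroundTruthEntry] = []
    strains = ("WT-N2-L1", "WT-N2-adult", "Tau-L1", "Tau-adult")
    for i, p in enumerate(peptides):
        sid = f"scan={i + 1}"
        spectrum, entry = simulate_spectrum(p, cfg, rng, spectrum_id=sid)
        model = cfg.glyco_scores if entry.is_glyco else cfg.decoy_scores
        score, expect = model.draw(rng)
        entry = replace(entry, true_class=_intended_tier(entry.is_glyco, score, expect))
        psms.append(
            PSMRecord(
                spectrum_id=sid,
                peptide=p,
                ion_score=score,
                p_expect=expect,
                precursor_mz_observed=spectrum.precursor_mz,
                charge=spectrum.precursor_charge or 2,
                source_strain=strains[int(rng.integers(len(strains)))],
            )
        )
        spectra.append(spectrum)
        truth.append(entry)
    return SyntheticDataset(tuple(spectra), tuple(psms), tuple(truth))


def truth_to_frame(truth: Sequence[GroundTruthEntry]) -> pd.DataFrame:
    rows = []
    for t in truth:
        rows.append(
            {
                "spectrum_id": t.spectrum_id,
                "sequence": t.peptide.sequence,
                "mods": format_mod_string(t.peptide.mods, t.peptide.sequence),
                "is_glyco": t.is_glyco,
                "true_class": t.true_class.value,
                "planted_oxonium": t.planted_diagnostics["oxonium"],
                "planted_precursor_loss": t.planted_diagnostics["precursor_loss"],
                "fragments_planted": t.planted_diagnostics["fragments_planted"],
            }
        )
    return pd.DataFrame(rows)


def emit_dataset(cfg: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Write the dataset as MGF + PSM CSV + ground-truth CSV.

    Files cross-reference by spectrum_id; regenerating with the same
    config is byte-identical.  A spectrum-id collision (impossible with
    the internal labelling, but possible with adversarial configs) raises.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds = generate_dataset(cfg)
    ids = [s.identifier for s in ds.spectra]
    if len(ids) != len(set(ids)):
        raise ValueError("spectrum id collision in generated dataset")
    paths = {
        "mgf": outdir / "spectra.mgf",
        "psms": outdir / "psms.csv",
        "truth": outdir / "ground_truth.csv",
    }
    write_mgf(ds.spectra, paths["mgf"])
    write_psm_table(ds.psms, paths["psms"])
    truth_to_frame(ds.truth).to_csv(paths["truth"], index=False)
    return paths
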