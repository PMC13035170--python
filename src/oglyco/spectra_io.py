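"""Peak-list and PSM-table I/O, and tolerance-based peak matching.

MGF (Mascot generic format) is the canonical interchange format here: a
plain-text stream of BEGIN IONS/END IONS blocks each carrying TITLE,
PEPMASS, CHARGE headers and one ``mz intensity`` pair per line.  PSM
tables are CSV with one row per peptide-spectrum match; modification
assignments use the ``HexNAc@S9; Oxidation@M18`` syntax.

Matching is nearest-peak within a Da window: each theoretical fragment
maps to at most one observed peak, while an observed peak may satisfy
several fragments (mirrors manual spectrum annotation, and keeps matching
linear after a sort).
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .fragment_model import FragmentIon
from .mass_chem import (
    BUILTIN_MODIFICATIONS,
    Modification,
    Peptide,
    PeptideError,
    parse_mod_string,
    format_mod_string,
    ppm_error,
)

__all__ = [
    "Spectrum",
    "PSMRecord",
    "PeakMatch",
    "MGFError",
    "read_mgf",
    "write_mgf",
    "read_psm_table",
    "write_psm_table",
    "match_peaks",
]

PSM_COLUMNS = (
    "spectrum_id",
    "sequence",
    "mods",
    "ion_score",
    "p_expect",
    "precursor_mz",
    "charge",
    "source_strain",
)


class MGFError(ValueError):
    """Malformed MGF input; message names the offending block ordinal."""


@dataclass(frozen=True)
class Spectrum:
    """A centroided peak list with precursor m/z and charge.

    Peaks are stored sorted ascending by m/z; construction sorts them.
    """

    identifier: str
    precursor_mz: float
    precursor_charge: int | None
    peaks: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        pk = tuple(sorted((float(m), float(i)) for m, i in self.peaks))
        for mz, inten in pk:
            if mz <= 0:
                raise ValueError(f"{self.identifier}: non-positive peak m/z {mz}")
            if inten < 0:
                raise ValueError(f"{self.identifier}: negative intensity {inten}")
        object.__setattr__(self, "peaks", pk)
        if self.precursor_charge is not None and not 1 <= self.precursor_charge <= 7:
            raise ValueError(
                f"{self.identifier}: precursor charge {self.precursor_charge} outside 1..7"
            )

    @property
    def mz_array(self) -> list[float]:
        return [m for m, _ in self.peaks]

    def has_peak_near(self, target: float, tol_da: float) -> bool:
        """Any observed peak within +/- tol_da of target m/z?"""
        return nearest_peak(self.peaks, target, tol_da) is not None


@dataclass(frozen=True)
class PSMRecord:
    """One peptide-spectrum match as exported by a search engine."""

    spectrum_id: str
    peptide: Peptide
    ion_score: float
    p_expect: float
    precursor_mz_observed: float
    charge: int
    source_strain: str = ""

    def __post_init__(self) -> None:
        if not self.p_expect > 0:
            raise ValueError(f"{self.spectrum_id}: p_expect must be positive")
        if not 1 <= self.charge <= 7:
            raise ValueError(f"{self.spectrum_id}: charge {self.charge} outside 1..7")


@dataclass(frozen=True)
class PeakMatch:
    """A theoretical fragment paired with the nearest observed peak."""

    fragment: FragmentIon
    observed_mz: float
    observed_intensity: float
    error_da: float
    error_ppm: float


# ---------------------------------------------------------------------------
# MGF


def read_mgf(path: str | Path) -> list[Spectrum]:
    """Parse an MGF file into spectra; peaks are sorted on load.

    Blocks with no peaks are preserved as empty spectra.  A block missing
    PEPMASS, or with an unparseable peak line, raises :class:`MGFError`
    naming the block ordinal.  An unparseable CHARGE is recorded as missing
    (``precursor_charge=None``).
    """
    spectra: list[Spectrum] = []
    in_block = False
    ordinal = 0
    title = ""
    pepmass: float | None = None
    charge: int | None = None
    peaks: list[tuple[float, float]] = []

    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line == "BEGIN IONS":
                if in_block:
                    raise MGFError(f"block {ordinal + 1}: nested BEGIN IONS")
                in_block = True
                ordinal += 1
                title, pepmass, charge, peaks = f"scan={ordinal}", None, None, []
            elif line == "END IONS":
                if not in_block:
                    raise MGFError(f"block {ordinal}: END IONS without BEGIN IONS")
                if pepmass is None:
                    raise MGFError(f"block {ordinal}: missing PEPMASS")
                spectra.append(
                    Spectrum(
                        identifier=title,
                        precursor_mz=pepmass,
                        precursor_charge=charge,
                        peaks=tuple(peaks),
                    )
                )
                in_block = False
            elif not in_block:
                continue
            elif "=" in line:
                key, _, value = line.partition("=")
                key = key.upper()
                if key == "TITLE":
                    title = value.strip()
                elif key == "PEPMASS":
                    pepmass = float(value.split()[0])
                elif key == "CHARGE":
                    v = value.strip().rstrip("+")
                    charge = int(v) if v.lstrip("-").isdigit() and int(v) > 0 else None
            else:
                parts = line.split()
                try:
                    peaks.append((float(parts[0]), float(parts[1])))
                except (IndexError, ValueError) as exc:
                    raise MGFError(
                        f"block {ordinal}: unparseable peak line {line!r}"
                    ) from exc
    if in_block:
        raise MGFError(f"block {ordinal}: unterminated (missing END IONS)")
    return spectra


def write_mgf(spectra: Iterable[Spectrum], path: str | Path) -> None:
    """Write spectra as MGF; m/z at 6 dp so a round-trip is lossless to 6 dp."""
    with open(path, "w") as fh:
        for s in spectra:
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={s.identifier}\n")
            fh.write(f"PEPMASS={s.precursor_mz:.6f}\n")
            if s.precursor_charge is not None:
                fh.write(f"CHARGE={s.precursor_charge}+\n")
            for mz, inten in s.peaks:
                fh.write(f"{mz:.6f} {inten:.4f}\n")
            fh.write("END IONS\n")


# ---------------------------------------------------------------------------
# PSM tables


def read_psm_table(
    path: str | Path,
    modifications: Mapping[str, Modification] | None = None,
) -> tuple[list[PSMRecord], pd.DataFrame]:
    """Read a PSM CSV; invalid rows are quarantined, not silently dropped.

    Returns ``(records, rejects)`` where ``rejects`` is a DataFrame of the
    offending rows with a ``reject_reason`` column.  A missing mandatory
    column raises immediately, naming it.
    """
    modifications = modifications or BUILTIN_MODIFICATIONS
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in PSM_COLUMNS[:-1]:  # source_strain optional
        if col not in df.columns:
            raise ValueError(f"PSM table missing mandatory column {col!r}")
    records: list[PSMRecord] = []
    reject_rows: list[dict] = []
    for _, row in df.iterrows():
        try:
            mods = parse_mod_string(row["mods"], modifications)
            peptide = Peptide(row["sequence"].strip().upper(), mods)
            records.append(
                PSMRecord(
                    spectrum_id=row["spectrum_id"],
                    peptide=peptide,
                    ion_score=float(row["ion_score"]),
                    p_expect=float(row["p_expect"]),
                    precursor_mz_observed=float(row["precursor_mz"]),
                    charge=int(row["charge"]),
                    source_strain=str(row.get("source_strain", "")),
                )
            )
        except (PeptideError, ValueError) as exc:
            rec = dict(row)
            rec["reject_reason"] = str(exc)
            reject_rows.append(rec)
    return records, pd.DataFrame(reject_rows)


def write_psm_table(records: Sequence[PSMRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "spectrum_id": r.spectrum_id,
                "sequence": r.peptide.sequence,
                "mods": format_mod_string(r.peptide.mods, r.peptide.sequence),
                "ion_score": r.ion_score,
                "p_expect": r.p_expect,
                "precursor_mz": r.precursor_mz_observed,
                "charge": r.charge,
                "source_strain": r.source_strain,
            }
        )
    pd.DataFrame(rows, columns=list(PSM_COLUMNS)).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Peak matching


def nearest_peak(
    peaks: Sequence[tuple[float, float]], target: float, tol_da: float
) -> tuple[float, float] | None:
    """Nearest peak to target within +/- tol_da, or None.

    Equidistant candidates break ties toward higher intensity (then lower
    m/z, for full determinism).
    """
    if not peaks:
        return None
    mzs = [m for m, _ in peaks]
    i = bisect.bisect_left(mzs, target)
    candidates = [peaks[j] for j in (i - 1, i) if 0 <= j < len(peaks)]
    best = None
    for mz, inten in candidates:
        err = abs(mz - target)
        if err > tol_da:
            continue
        if best is None:
            best = (mz, inten)
            continue
        berr = abs(best[0] - target)
        if err < berr or (err == berr and (inten, -mz) > (best[1], -best[0])):
            best = (mz, inten)
    return best


def match_peaks(
    s: Spectrum,
    frags: Sequence[FragmentIon],
    tol_da: float = 0.05,
    tol_ppm: float | None = None,
) -> list[PeakMatch]:
    """Match each theoretical fragment to its nearest observed peak.

    At most one match per fragment; fragments with no peak within the
    window are absent from the output.  Both Da and ppm errors are
    recorded so either gate can be applied downstream.  When ``tol_ppm``
    is given the window scales with each fragment's m/z instead of the
    fixed Da window.
    """
    if tol_da <= 0:
        raise ValueError(f"tol_da must be positive, got {tol_da}")
    out: list[PeakMatch] = []
    for f in frags:
        tol = f.mz * tol_ppm * 1e-6 if tol_ppm is not None else tol_da
        hit = nearest_peak(s.peaks, f.mz, tol)
        if hit is None:
            continue
        mz, inten = hit
        out.append(
            PeakMatch(
                fragment=f,
                observed_mz=mz,
                observed_intensity=inten,
                error_da=mz - f.mz,
                error_ppm=ppm_error(mz, f.mz),
            )
        )
    return out
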