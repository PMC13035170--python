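"""Monoisotopic mass arithmetic for peptides and their modifications.

Every downstream stage — theoretical fragments, diagnostic-ion windows,
precursor ppm checks — reduces to sums over this table, so the residue
masses are kept at full published precision and rounding happens only at
report time.

The neutral (uncharged) peptide mass is the residue-mass sum plus one
water, plus the mass shifts of any positioned modifications; ``Mr(calc)``
values printed by search engines follow the same convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from types import MappingProxyType
from typing import Iterable, Mapping, Sequence

import yaml

__all__ = [
    "WATER",
    "PROTON",
    "AMMONIA",
    "MONOISOTOPIC_RESIDUE_MASSES",
    "Modification",
    "HEXNAC",
    "CARBAMIDOMETHYL",
    "OXIDATION",
    "BUILTIN_MODIFICATIONS",
    "load_modifications",
    "Peptide",
    "PeptideError",
    "peptide_neutral_mass",
    "mz_from_mass",
    "ppm_error",
    "round_half_away",
]

# Monoisotopic constants, Da.
WATER = 18.010565
PROTON = 1.007276
AMMONIA = 17.026549

#: Monoisotopic residue (i.e. dehydrated amino acid) masses, Da.
#: I and L are distinct keys with identical mass; no collapsing.
MONOISOTOPIC_RESIDUE_MASSES: Mapping[str, float] = MappingProxyType(
    {
        "G": 57.021464,
        "A": 71.037114,
        "S": 87.032028,
        "P": 97.052764,
        "V": 99.068414,
        "T": 101.047679,
        "C": 103.009185,
        "L": 113.084064,
        "I": 113.084064,
        "N": 114.042927,
        "D": 115.026943,
        "Q": 128.058578,
        "K": 128.094963,
        "E": 129.042593,
        "M": 131.040485,
        "H": 137.058912,
        "F": 147.068414,
        "R": 156.101111,
        "Y": 163.063329,
        "W": 186.079313,
    }
)


class PeptideError(ValueError):
    """Raised when a sequence or modification layout violates an invariant."""


@dataclass(frozen=True)
class Modification:
    """A named monoisotopic mass shift restricted to particular residues.

    ``allowed_targets`` holds single-letter residue codes; the special
    tokens ``"N-term"`` / ``"C-term"`` mark terminal modifications.
    """

    name: str
    delta: float
    allowed_targets: frozenset[str]

    def permits(self, residue: str) -> bool:
        return residue in self.allowed_targets


HEXNAC = Modification("HexNAc", 203.079373, frozenset({"S", "T"}))
CARBAMIDOMETHYL = Modification("Carbamidomethyl", 57.021464, frozenset({"C"}))
OXIDATION = Modification("Oxidation", 15.994915, frozenset({"M"}))

BUILTIN_MODIFICATIONS: Mapping[str, Modification] = MappingProxyType(
    {m.name: m for m in (HEXNAC, CARBAMIDOMETHYL, OXIDATION)}
)


def load_modifications(path: str | Path) -> dict[str, Modification]:
    """Load modification definitions from a YAML config.

    The file maps names to ``{delta: <Da>, targets: [<letters>]}``.
    Built-in definitions are included and may be overridden by the file.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    mods = dict(BUILTIN_MODIFICATIONS)
    for name, entry in raw.items():
        mods[name] = Modification(
            name=name,
            delta=float(entry["delta"]),
            allowed_targets=frozenset(entry["targets"]),
        )
    return mods


@dataclass(frozen=True)
class Peptide:
    """A residue sequence with positioned modifications (1-based sites)."""

    sequence: str
    mods: tuple[tuple[int, Modification], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise PeptideError("empty peptide sequence")
        for i, aa in enumerate(self.sequence, start=1):
            if aa not in MONOISOTOPIC_RESIDUE_MASSES:
                raise PeptideError(f"unknown residue {aa!r} at position {i}")
        object.__setattr__(self, "mods", tuple(self.mods))
        seen: set[int] = set()
        for pos, mod in self.mods:
            if not 1 <= pos <= len(self.sequence):
                raise PeptideError(
                    f"modification {mod.name} position {pos} outside 1..{len(self.sequence)}"
                )
            residue = self.sequence[pos - 1]
            if not mod.permits(residue):
                raise PeptideError(
                    f"{mod.name} not permitted on residue {residue} at position {pos}"
                )
            if pos in seen:
                raise PeptideError(f"two modifications share position {pos}")
            seen.add(pos)

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def hexnac_sites(self) -> tuple[int, ...]:
        """1-based positions carrying a HexNAc (by modification name)."""
        return tuple(sorted(p for p, m in self.mods if m.name == HEXNAC.name))

    def mod_delta_in_span(self, start: int, stop: int) -> float:
        """Sum of modification deltas whose site lies in [start, stop] (1-based, inclusive)."""
        return sum(m.delta for p, m in self.mods if start <= p <= stop)

    def with_mods(self, mods: Iterable[tuple[int, Modification]]) -> "Peptide":
        return Peptide(self.sequence, tuple(mods))


def peptide_neutral_mass(p: Peptide) -> float:
    """Neutral monoisotopic mass of a (modified) peptide, Da.

    Residue-mass sum + one water + all modification deltas, at full
    precision.  This is the quantity search engines print as Mr(calc).
    """
    residues = sum(MONOISOTOPIC_RESIDUE_MASSES[aa] for aa in p.sequence)
    return residues + WATER + sum(m.delta for _, m in p.mods)


def mz_from_mass(neutral_mass: float, charge: int) -> float:
    """m/z of a neutral mass at a given positive charge state."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return (neutral_mass + charge * PROTON) / charge


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass deviation in parts per million."""
    if theoretical <= 0:
        raise ValueError(f"theoretical m/z must be positive, got {theoretical}")
    return 1e6 * (observed - theoretical) / theoretical


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero — the convention used for printed Mr(calc).

    Python's built-in ``round`` is banker's rounding; printed mass tables
    round 0.005 upward, so comparisons at 2 dp must too.
    """
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def parse_mod_string(
    spec: str,
    modifications: Mapping[str, Modification] | None = None,
) -> tuple[tuple[int, Modification], ...]:
    """Parse ``"HexNAc@S9; Oxidation@M18"`` into positioned modifications.

    Each token is ``Name@<residue letter><1-based position>``; the residue
    letter is advisory and checked against the sequence later by the
    Peptide invariants.  Empty string means no modifications.
    """
    modifications = modifications or BUILTIN_MODIFICATIONS
    out: list[tuple[int, Modification]] = []
    for token in filter(None, (t.strip() for t in spec.split(";"))):
        name, _, site = token.partition("@")
        name = name.strip()
        if name not in modifications:
            raise PeptideError(f"unknown modification {name!r} in {spec!r}")
        site = site.strip()
        if not site or not site[1:].isdigit():
            raise PeptideError(f"malformed modification site {token!r}")
        out.append((int(site[1:]), modifications[name]))
    return tuple(out)


def format_mod_string(mods: Sequence[tuple[int, Modification]], sequence: str) -> str:
    """Inverse of :func:`parse_mod_string` for a known sequence."""
    return "; ".join(
        f"{m.name}@{sequence[p - 1]}{p}" for p, m in sorted(mods, key=lambda t: t[0])
    )
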