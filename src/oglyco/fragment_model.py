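"""Theoretical fragment and diagnostic ions for (glyco)peptides.

Generates the b/y backbone series with ammonia-, water- and HexNAc-loss
derivatives at charge 1-2, plus the low-mass oxonium ions that flag the
presence of a HexNAc-bearing precursor.  The HexNAc oxonium at m/z
204.0867 is the glycan fragment cation itself; 138.055 and 144.066 are its
secondary fragments.  Loss of the intact sugar (203.0794 Da neutral)
produces the characteristic intact/loss ion pairs used as evidence.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import pandas as pd

from .mass_chem import (
    AMMONIA,
    HEXNAC,
    MONOISOTOPIC_RESIDUE_MASSES,
    WATER,
    Peptide,
    mz_from_mass,
    peptide_neutral_mass,
)

__all__ = [
    "Loss",
    "FragmentIon",
    "OxoniumSet",
    "DEFAULT_OXONIUM",
    "HEXNAC_NEUTRAL_LOSS",
    "generate_fragments",
    "oxonium_targets",
    "hexnac_loss_pairs",
    "fragments_to_frame",
]

#: Neutral loss of an intact HexNAc from a glycosylated ion, Da.  Numerically
#: this equals the HexNAc residue delta; kept as its own name because the two
#: play different roles (addition on the peptide vs subtraction on an ion).
HEXNAC_NEUTRAL_LOSS = 203.0794

LOSS_MASSES = {
    "none": 0.0,
    "NH3": AMMONIA,
    "H2O": WATER,
    "HexNAc": HEXNAC.delta,
}


class Loss(str, Enum):
    NONE = "none"
    NH3 = "NH3"
    H2O = "H2O"
    HEXNAC = "HexNAc"


@dataclass(frozen=True)
class FragmentIon:
    """One theoretical backbone fragment ion.

    ``index`` counts residues from the N-terminus for b ions and from the
    C-terminus for y ions; ``carries_mod`` is true when the residue span
    includes at least one HexNAc site.
    """

    series: str  # "b" or "y"
    index: int
    charge: int
    loss: Loss
    mz: float
    neutral_mass: float
    carries_mod: bool

    @property
    def label(self) -> str:
        suffix = {"none": "", "NH3": "*", "H2O": "o", "HexNAc": "-HexNAc"}[self.loss.value]
        z = "" if self.charge == 1 else f"^{self.charge}+"
        return f"{self.series}{self.index}{suffix}{z}"


@dataclass(frozen=True)
class OxoniumSet:
    """Diagnostic oxonium m/z targets: one primary, any number of secondary."""

    primary: float = 204.0867
    secondary: tuple[float, ...] = (138.055, 144.066)

    def __post_init__(self) -> None:
        if self.primary <= 0 or any(s <= 0 for s in self.secondary):
            raise ValueError("oxonium targets must be positive m/z values")


DEFAULT_OXONIUM = OxoniumSet()


def oxonium_targets() -> OxoniumSet:
    """The default HexNAc oxonium diagnostic set (204.0867; 138.055, 144.066)."""
    return DEFAULT_OXONIUM


def generate_fragments(
    p: Peptide,
    max_charge: int = 2,
    losses_enabled: Iterable[Loss | str] = (Loss.NH3, Loss.H2O, Loss.HEXNAC),
    doubly_charged_min_mass: float = 800.0,
) -> list[FragmentIon]:
    """Theoretical b/y ions for a peptide, with enabled loss derivatives.

    For each cut site i in 1..N-1 the b_i ion covers residues 1..i and the
    y_{N-i} ion covers residues i+1..N plus one water; their neutral masses
    sum to the peptide neutral mass.  HexNAc loss is only emitted on
    fragments whose span carries a HexNAc.  Doubly charged variants are
    emitted only for neutral masses >= ``doubly_charged_min_mass`` (the
    match space is otherwise dominated by implausible low-mass 2+ ions).

    A length-1 peptide has no cut site and yields an empty list.
    """
    if max_charge not in (1, 2):
        raise ValueError(f"max_charge must be 1 or 2, got {max_charge}")
    losses = {Loss(l) for l in losses_enabled} - {Loss.NONE}
    n = len(p)
    hexnac_sites = set(p.hexnac_sites)
    out: list[FragmentIon] = []

    prefix = 0.0
    masses = [MONOISOTOPIC_RESIDUE_MASSES[aa] for aa in p.sequence]
    total = peptide_neutral_mass(p)
    for i in range(1, n):
        prefix += masses[i - 1] + sum(
            m.delta for pos, m in p.mods if pos == i
        )
        b_neutral = prefix
        y_neutral = total - prefix
        b_mod = any(s <= i for s in hexnac_sites)
        y_mod = any(s > i for s in hexnac_sites)
        for series, index, neutral, carries in (
            ("b", i, b_neutral, b_mod),
            ("y", n - i, y_neutral, y_mod),
        ):
            variants = [Loss.NONE] + sorted(losses, key=lambda l: l.value)
            for loss in variants:
                if loss is Loss.HEXNAC and not carries:
                    continue
                lneutral = neutral - LOSS_MASSES[loss.value]
                if lneutral <= 0:
                    continue
                for z in range(1, max_charge + 1):
                    if z == 2 and neutral < doubly_charged_min_mass:
                        continue
                    out.append(
                        FragmentIon(
                            series=series,
                            index=index,
                            charge=z,
                            loss=loss,
                            mz=mz_from_mass(lneutral, z),
                            neutral_mass=lneutral,
                            carries_mod=carries,
                        )
                    )
    return out


def hexnac_loss_pairs(
    fragments: Sequence[FragmentIon],
) -> list[tuple[FragmentIon, FragmentIon]]:
    """Pair each HexNAc-carrying fragment with its sugar-loss counterpart.

    Returns (intact, loss) pairs at matched series/index/charge; the
    neutral-mass difference of every pair is the HexNAc delta.
    """
    by_key = {
        (f.series, f.index, f.charge): f
        for f in fragments
        if f.loss is Loss.HEXNAC
    }
    pairs = []
    for f in fragments:
        if f.loss is Loss.NONE and f.carries_mod:
            partner = by_key.get((f.series, f.index, f.charge))
            if partner is not None:
                pairs.append((f, partner))
    return pairs


def fragments_to_frame(fragments: Sequence[FragmentIon]) -> pd.DataFrame:
    """Fragment table as a DataFrame (CSV-exportable)."""
    return pd.DataFrame(
        {
            "series": [f.series for f in fragments],
            "index": [f.index for f in fragments],
            "charge": [f.charge for f in fragments],
            "loss": [f.loss.value for f in fragments],
            "mz": [f.mz for f in fragments],
            "neutral_mass": [f.neutral_mass for f in fragments],
            "carries_mod": [f.carries_mod for f in fragments],
        }
    )
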