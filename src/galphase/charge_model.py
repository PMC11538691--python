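"""pH-dependent net charge of a sequence by Henderson-Hasselbalch titration.

Each ionizable side chain contributes its expected (population-averaged)
charge at a given pH: an acidic group D/E (and optionally C, Y) carries
-1/(1 + 10^(pKa - pH)); a basic group H/K/R carries +1/(1 + 10^(pH - pKa)).
Summing over a region gives a net-charge-versus-pH curve that is monotone
non-increasing in pH.  This quantifies how acidification partially
protonates the aspartates of an IDR like galectin-3's N-terminal domain
(which has only Asp-3 and Asp-9 as charged residues), weakening
electrostatic repulsion between chains.

The model is sequence-only: no environment-dependent pKa shifts.  The pKa
table is fully configurable and is echoed into every report.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

#: Consensus intrinsic side-chain pKa values (Grimsley-style averages).
DEFAULT_PKAS: dict[str, float] = {
    "D": 3.9,
    "E": 4.3,
    "H": 6.5,
    "K": 10.4,
    "R": 12.3,
}
ACIDIC = frozenset("DECY")
BASIC = frozenset("HKR")
DEFAULT_NTERM_PKA = 8.0
DEFAULT_CTERM_PKA = 3.7


@dataclass(frozen=True)
class PKaTable:
    """Ionizable-residue pKa values and terminal-group handling.

    ``pkas`` maps residue letter to its intrinsic pKa; only letters in
    the table ionize (C and Y are excluded by default).  Termini are off
    by default — the charge argument of interest concerns side chains.
    """

    pkas: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_PKAS))
    include_termini: bool = False
    nterm_pka: float = DEFAULT_NTERM_PKA
    cterm_pka: float = DEFAULT_CTERM_PKA

    def __post_init__(self) -> None:
        for letter, pka in self.pkas.items():
            if letter not in ACIDIC | BASIC:
                raise ValueError(f"{letter!r} is not an ionizable residue")
            if not (0.0 < pka < 14.0):
                raise ValueError(f"pKa {pka} for {letter!r} outside (0, 14)")

    def is_ionizable(self, letter: str) -> bool:
        return letter in self.pkas


@dataclass(frozen=True)
class ChargeCurve:
    """Net charge evaluated on an ordered pH grid."""

    ph_grid: tuple[float, ...]
    net_charge: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.ph_grid) != len(self.net_charge):
            raise ValueError("grid and charge lists differ in length")


def residue_charge(letter: str, ph: float,
                   table: PKaTable = PKaTable()) -> float:
    """Expected charge of one ionizable side chain at ``ph``.

    Acidic groups titrate from 0 to -1 with increasing pH, basic groups
    from +1 to 0; at pH = pKa the group is half-titrated (-0.5 or +0.5).
    """
    if not table.is_ionizable(letter):
        raise ValueError(f"{letter!r} is not ionizable under the given table")
    pka = table.pkas[letter]
    if letter in ACIDIC:
        return -1.0 / (1.0 + 10.0 ** (pka - ph))
    return 1.0 / (1.0 + 10.0 ** (ph - pka))


def net_charge_at_ph(seq: str, ph: float, table: PKaTable = PKaTable()) -> float:
    """Sum of expected side-chain (and optional terminal) charges."""
    if not seq:
        raise ValueError("empty sequence")
    total = sum(residue_charge(a, ph, table) for a in seq if table.is_ionizable(a))
    if table.include_termini:
        total += 1.0 / (1.0 + 10.0 ** (ph - table.nterm_pka))
        total += -1.0 / (1.0 + 10.0 ** (table.cterm_pka - ph))
    return total


def net_charge_vs_ph(seq: str, ph_grid: Sequence[float],
                     table: PKaTable = PKaTable()) -> ChargeCurve:
    """Net charge over a monotone pH grid; curve is non-increasing in pH."""
    if len(ph_grid) == 0:
        raise ValueError("empty pH grid")
    grid = np.asarray(ph_grid, dtype=float)
    if not (np.all(np.diff(grid) >= 0) or np.all(np.diff(grid) <= 0)):
        raise ValueError("pH grid must be monotone")
    charges = tuple(net_charge_at_ph(seq, ph, table) for ph in grid)
    return ChargeCurve(ph_grid=tuple(grid.tolist()), net_charge=charges)


def charge_ratio(seq: str, ph_a: float, ph_b: float,
                 table: PKaTable = PKaTable()) -> float:
    """|net charge at ph_a| / |net charge at ph_b|.

    Quantifies charge attenuation between two conditions, e.g. how much
    of an acidic IDR's charge survives a drop from pH 7 to pH 4.  A zero
    denominator is a domain error.
    """
    num = abs(net_charge_at_ph(seq, ph_a, table))
    den = abs(net_charge_at_ph(seq, ph_b, table))
    if den == 0.0:
        raise ValueError(f"net charge at pH {ph_b} is zero; ratio undefined")
    return num / den


def table_to_dict(table: PKaTable) -> dict:
    """Serializable echo of the pKa configuration for reports."""
    return {
        "pkas": dict(table.pkas),
        "include_termini": table.include_termini,
        "nterm_pka": table.nterm_pka,
        "cterm_pka": table.cterm_pka,
    }
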