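"""Monoisotopic mass and m/z computation for light and heavy-labelled peptides.

Masses are additive over residues: the neutral monoisotopic mass of a
peptide is the sum of its residue masses plus one water, plus any
modification deltas, plus the isotope-label delta on each labelled residue.
Residue masses come from :mod:`pyteomics` (``std_aa_mass``).  The stable
isotope label supported by default is the SILS chemistry used for arginine
internal standards: every ``R`` carries six 13C and four 15N substitutions
(+10.0083 Da).  Carbamidomethylation of cysteine (+57.02146 Da) is the
usual fixed modification from iodoacetamide alkylation and can be applied
as a residue rule.

Fragment ions follow the y/b backbone series: a y_i ion is the C-terminal
``i`` residues plus water, a b_i ion the N-terminal ``i`` residues without
water; both are protonated with 1.00728 Da per charge.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

import pandas as pd
from pyteomics import mass as _ptmass

RESIDUE_MASS: dict[str, float] = dict(_ptmass.std_aa_mass)
"""Monoisotopic residue (amino-acid minus water) masses, Da."""

WATER = 18.0105646863
PROTON = 1.00728
CARBAMIDOMETHYL = 57.02146

# monoisotopic mass differences for single-nucleon isotope substitutions
_DELTA_13C = 1.0033548  # 13C - 12C
_DELTA_15N = 0.9970349  # 15N - 14N

_STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


class Label(str, Enum):
    """Isotope-label state of a peptide."""

    LIGHT = "light"
    HEAVY = "heavy"


def label_delta(n_13c: int = 0, n_15n: int = 0) -> float:
    """Mass shift (Da) for a 12C→13C / 14N→15N substitution pattern.

    Parameters
    ----------
    n_13c, n_15n
        Number of carbon and nitrogen atoms substituted by their heavy
        isotope.  The arginine SILS label is ``label_delta(6, 4)`` =
        10.0083 Da.
    """
    if n_13c < 0 or n_15n < 0:
        raise ValueError("isotope substitution counts must be non-negative")
    return n_13c * _DELTA_13C + n_15n * _DELTA_15N


ARG_LABEL_DELTA = label_delta(6, 4)
"""The 13C6,15N4 arginine label shift, Da."""


@dataclass(frozen=True)
class Peptide:
    """A peptide sequence with modifications and an isotope-label state.

    Parameters
    ----------
    sequence
        One-letter amino-acid string (standard 20 codes).
    modifications
        List of ``(position_or_residue, delta_mass_da)``.  A position is a
        0-based integer index into the sequence; a residue rule is a
        one-letter string and applies the delta at every occurrence of that
        residue (matching zero positions is allowed).
    label
        ``Label.LIGHT`` or ``Label.HEAVY``.  A heavy peptide carries the
        13C6,15N4 label on every arginine.
    """

    sequence: str
    modifications: tuple[tuple[int | str, float], ...] = ()
    label: Label = Label.LIGHT

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("peptide sequence must be non-empty")
        for ch in self.sequence:
            if ch not in _STANDARD_AA:
                raise ValueError(
                    f"unknown residue code {ch!r} in sequence {self.sequence!r}"
                )
        object.__setattr__(self, "modifications", tuple(self.modifications))
        object.__setattr__(self, "label", Label(self.label))
        for pos, _delta in self.modifications:
            if isinstance(pos, str):
                if len(pos) != 1 or pos not in _STANDARD_AA:
                    raise ValueError(f"invalid residue rule {pos!r}")
            elif not 0 <= pos < len(self.sequence):
                raise ValueError(
                    f"modification position {pos} outside sequence of length "
                    f"{len(self.sequence)}"
                )

    # -- per-residue mass deltas -------------------------------------------

    def _position_deltas(self) -> list[float]:
        """Modification + label delta applied at each sequence position."""
        deltas = [0.0] * len(self.sequence)
        for pos, delta in self.modifications:
            if isinstance(pos, str):
                for i, ch in enumerate(self.sequence):
                    if ch == pos:
                        deltas[i] += delta
            else:
                deltas[pos] += delta
        if self.label is Label.HEAVY:
            for i, ch in enumerate(self.sequence):
                if ch == "R":
                    deltas[i] += ARG_LABEL_DELTA
        return deltas

    def neutral_mass(self) -> float:
        """Neutral monoisotopic mass in Da."""
        deltas = self._position_deltas()
        return (
            sum(RESIDUE_MASS[ch] for ch in self.sequence) + WATER + sum(deltas)
        )

    def with_label(self, label: Label | str) -> "Peptide":
        """A copy of this peptide in the given label state."""
        return replace(self, label=Label(label))


def peptide_neutral_mass(peptide: Peptide) -> float:
    """Neutral monoisotopic mass of ``peptide`` in Da."""
    return peptide.neutral_mass()


def precursor_mz(peptide: Peptide, charge: int) -> float:
    """m/z of the ``charge``-protonated precursor."""
    if charge < 1:
        raise ValueError("precursor charge must be >= 1")
    return (peptide.neutral_mass() + charge * PROTON) / charge


def fragment_mz(
    peptide: Peptide, fragment_type: str, index: int, charge: int
) -> float:
    """m/z of the y- or b-series fragment ion.

    ``index`` counts residues from the C terminus for y ions and from the
    N terminus for b ions and must be strictly less than the peptide
    length (the full-length y ion coincides with the precursor and is
    permitted at ``index == len(sequence)`` for the identity check).
    """
    if fragment_type not in ("y", "b"):
        raise ValueError(f"unsupported fragment type {fragment_type!r}")
    if charge < 1:
        raise ValueError("fragment charge must be >= 1")
    n = len(peptide.sequence)
    if not 1 <= index <= n:
        raise ValueError(f"fragment index {index} out of range for length {n}")
    deltas = peptide._position_deltas()
    if fragment_type == "y":
        positions = range(n - index, n)
        neutral = WATER
    else:
        positions = range(index)
        neutral = 0.0
    for i in positions:
        neutral += RESIDUE_MASS[peptide.sequence[i]] + deltas[i]
    return (neutral + charge * PROTON) / charge


@dataclass(frozen=True)
class Transition:
    """One precursor→product ion pair monitored for a peptide.

    Light and heavy m/z are computed from the peptide in both label
    states; collision energy and retention time are instrument settings
    carried through verbatim.
    """

    peptide: Peptide
    precursor_charge: int
    fragment_type: str
    fragment_index: int
    fragment_charge: int
    collision_energy: float | None = None
    retention_time: float | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.fragment_index < len(self.peptide.sequence):
            raise ValueError(
                f"fragment index {self.fragment_index} must be < sequence "
                f"length {len(self.peptide.sequence)}"
            )

    def _mz(self, label: Label) -> tuple[float, float]:
        pep = self.peptide.with_label(label)
        return (
            precursor_mz(pep, self.precursor_charge),
            fragment_mz(
                pep, self.fragment_type, self.fragment_index, self.fragment_charge
            ),
        )

    @property
    def precursor_mz_light(self) -> float:
        return self._mz(Label.LIGHT)[0]

    @property
    def precursor_mz_heavy(self) -> float:
        return self._mz(Label.HEAVY)[0]

    @property
    def product_mz_light(self) -> float:
        return self._mz(Label.LIGHT)[1]

    @property
    def product_mz_heavy(self) -> float:
        return self._mz(Label.HEAVY)[1]


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero, as printed transition lists do."""
    scale = 10**ndigits
    eps = 1e-9  # absorb binary representation error at the .5 boundary
    return int(abs(x) * scale + 0.5 + eps) / scale * (1 if x >= 0 else -1)


def build_transition_table(
    peptides: Sequence[Peptide],
    fragments: Sequence[Iterable[tuple[str, int, int]]],
    precursor_charges: Sequence[int],
    collision_energies: Sequence[Sequence[float | None]] | None = None,
    retention_times: Sequence[float | None] | None = None,
) -> pd.DataFrame:
    """Build a light/heavy transition table, one row per (peptide, fragment).

    Parameters
    ----------
    peptides
        Light-state peptides (label state is recomputed for both channels).
    fragments
        Per peptide, an iterable of ``(fragment_type, index, charge)``.
    precursor_charges
        Per-peptide precursor charge.
    collision_energies, retention_times
        Optional per-fragment collision energies (eV) and per-peptide
        retention times (min), carried through verbatim.

    Returns
    -------
    DataFrame with exact m/z columns and display columns rounded half-up
    to one decimal.
    """
    if not (len(peptides) == len(fragments) == len(precursor_charges)):
        raise ValueError("peptides, fragments and charges must align")
    rows = []
    for i, (pep, frags, z) in enumerate(zip(peptides, fragments, precursor_charges)):
        rt = retention_times[i] if retention_times is not None else None
        for j, (ftype, idx, fz) in enumerate(frags):
            ce = (
                collision_energies[i][j]
                if collision_energies is not None
                else None
            )
            tr = Transition(pep, z, ftype, idx, fz, ce, rt)
            rows.append(
                {
                    "sequence": pep.sequence,
                    "modifications": _format_mods(pep.modifications),
                    "precursor_charge": z,
                    "precursor_mz_light": tr.precursor_mz_light,
                    "precursor_mz_heavy": tr.precursor_mz_heavy,
                    "fragment": f"{ftype}{idx}",
                    "fragment_charge": fz,
                    "product_mz_light": tr.product_mz_light,
                    "product_mz_heavy": tr.product_mz_heavy,
                    "collision_energy": ce,
                    "retention_time": rt,
                }
            )
    table = pd.DataFrame(
        rows,
        columns=[
            "sequence",
            "modifications",
            "precursor_charge",
            "precursor_mz_light",
            "precursor_mz_heavy",
            "fragment",
            "fragment_charge",
            "product_mz_light",
            "product_mz_heavy",
            "collision_energy",
            "retention_time",
        ],
    )
    for col in (
        "precursor_mz_light",
        "precursor_mz_heavy",
        "product_mz_light",
        "product_mz_heavy",
    ):
        table[col.replace("_mz_", "_display_")] = table[col].map(
            lambda v: round_half_up(v, 1) if pd.notna(v) else v
        )
    return table


def _format_mods(mods: tuple[tuple[int | str, float], ...]) -> str:
    return ";".join(f"{pos}:{delta:+.5f}" for pos, delta in mods)


def _parse_mods(spec: str) -> tuple[tuple[int | str, float], ...]:
    if not spec or pd.isna(spec):
        return ()
    out = []
    for part in str(spec).split(";"):
        pos_s, delta_s = part.split(":")
        pos: int | str = int(pos_s) if pos_s.lstrip("-").isdigit() else pos_s
        out.append((pos, float(delta_s)))
    return tuple(out)


def write_transition_table(table: pd.DataFrame, path_or_buf, sep: str = ",") -> None:
    """Write a transition table as delimited text."""
    table.to_csv(path_or_buf, sep=sep, index=False)


def read_transition_table(path_or_buf, sep: str = ",") -> pd.DataFrame:
    """Read a transition table written by :func:`write_transition_table`."""
    if isinstance(path_or_buf, str) and "\n" in path_or_buf:
        path_or_buf = io.StringIO(path_or_buf)
    table = pd.read_csv(path_or_buf, sep=sep)
    table["modifications"] = table["modifications"].fillna("")
    return table


def svep1_transition_table() -> pd.DataFrame:
    """The murine SVEP1 MRM assay transition list.

    Two proteotypic peptides, three y-ion transitions each, with the
    optimised collision energies (eV) and retention times (min) of the
    published assay.
    """
    gaf = Peptide("GAFQQAAQILR")
    ltc = Peptide("LTCQGNAQWDGPEPR", modifications=(("C", CARBAMIDOMETHYL),))
    return build_transition_table(
        peptides=[gaf, ltc],
        fragments=[
            [("y", 7, 1), ("y", 6, 1), ("y", 3, 1)],
            [("y", 6, 1), ("y", 5, 1), ("y", 4, 1)],
        ],
        precursor_charges=[2, 3],
        collision_energies=[[21, 21, 19], [15, 21, 17]],
        retention_times=[1.2, 1.6],
    )
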