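"""Exact-mass arithmetic for CHNO small molecules.

Monoisotopic masses, protonation/deprotonation adducts, ppm mass error,
ring-and-double-bond equivalents (RDBE), and bounded exhaustive CHNO
formula decomposition under a ppm tolerance window.

All masses are monoisotopic and expressed in daltons (Da); m/z values for
singly charged ions are numerically equal to the ion mass and expressed in
thomsons (Th).  The constants live in a machine-readable table shipped with
the package (``data/element_masses.tsv``) so they can be audited without
reading source code.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from typing import Dict, Iterator, List, Mapping, Tuple

__all__ = [
    "ELEMENT_MASSES",
    "PROTON_MASS",
    "Formula",
    "Adduct",
    "ADDUCTS",
    "FormulaCandidate",
    "monoisotopic_mass",
    "ion_mz",
    "ppm_error",
    "rdbe",
    "decompose_mass",
]


def _load_element_masses() -> Dict[str, float]:
    table = {}
    text = (
        resources.files("msescreen")
        .joinpath("data/element_masses.tsv")
        .read_text(encoding="utf-8")
    )
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("symbol"):
            continue
        symbol, mass = line.split("\t")
        table[symbol] = float(mass)
    return table


#: Monoisotopic atomic masses (Da), CODATA/IUPAC values; C is exactly 12 by
#: definition of the unified atomic mass unit.
ELEMENT_MASSES: Dict[str, float] = _load_element_masses()

#: Mass of the proton (Da).  Protonation/deprotonation deltas use the proton
#: mass directly; the electron mass is folded into this convention.
PROTON_MASS: float = 1.00727646688


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class Formula(Mapping[str, int]):
    """An element -> count map with monoisotopic-mass semantics.

    Immutable and hashable.  Parse with :meth:`parse` ("C18H33NO") or build
    from keyword counts: ``Formula(C=18, H=33, N=1, O=1)``.
    """

    __slots__ = ("_counts",)

    def __init__(self, **counts: int) -> None:
        bad = {e: n for e, n in counts.items() if n < 0}
        if bad:
            raise ValueError(f"negative element counts: {bad}")
        self._counts: Dict[str, int] = {e: int(n) for e, n in counts.items() if n}

    @classmethod
    def parse(cls, text: str) -> "Formula":
        """Parse a Hill-style formula string such as ``C9H16O4``."""
        text = text.strip()
        if not text:
            return cls()
        counts: Dict[str, int] = {}
        pos = 0
        for match in _FORMULA_TOKEN.finditer(text):
            if not match.group(0):
                continue
            if match.start() != pos:
                raise ValueError(f"cannot parse formula {text!r}")
            pos = match.end()
            counts[match.group(1)] = counts.get(match.group(1), 0) + int(
                match.group(2) or 1
            )
        if pos != len(text):
            raise ValueError(f"cannot parse formula {text!r}")
        return cls(**counts)

    # Mapping protocol -----------------------------------------------------
    def __getitem__(self, element: str) -> int:
        return self._counts[element]

    def __iter__(self) -> Iterator[str]:
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def get(self, element: str, default: int = 0) -> int:  # type: ignore[override]
        return self._counts.get(element, default)

    def __hash__(self) -> int:
        return hash(frozenset(self._counts.items()))

    def __eq__(self, other: object) -> bool:
        if isinstance(other, Formula):
            return self._counts == other._counts
        return NotImplemented

    def __add__(self, other: "Formula") -> "Formula":
        counts = dict(self._counts)
        for e, n in other.items():
            counts[e] = counts.get(e, 0) + n
        return Formula(**counts)

    @property
    def atom_count(self) -> int:
        return sum(self._counts.values())

    def hill(self) -> str:
        """Hill-notation string: C first, H second, then alphabetical."""
        order = [e for e in ("C", "H") if e in self._counts]
        order += sorted(e for e in self._counts if e not in ("C", "H"))
        return "".join(
            f"{e}{self._counts[e]}" if self._counts[e] != 1 else e for e in order
        )

    def __repr__(self) -> str:
        return f"Formula({self.hill() or 'empty'})"


@dataclass(frozen=True)
class Adduct:
    """A singly charged protonation-type adduct ([M+H]+ or [M-H]-)."""

    name: str
    charge: int
    mass_delta: float  # Da, signed; sign matches the charge

    def __post_init__(self) -> None:
        if abs(self.charge) != 1:
            raise ValueError("only singly charged adducts are supported")
        if (self.mass_delta > 0) != (self.charge > 0):
            raise ValueError("sign of mass_delta must equal sign of charge")


ADDUCTS: Dict[str, Adduct] = {
    "[M+H]+": Adduct("[M+H]+", +1, +PROTON_MASS),
    "[M-H]-": Adduct("[M-H]-", -1, -PROTON_MASS),
}


def get_adduct(name: str) -> Adduct:
    """Resolve an adduct by name, normalizing unicode minus/dash variants."""
    canon = (
        name.replace("−", "-")
        .replace("–", "-")
        .replace("—", "-")
        .replace(" ", "")
        .replace("^", "")
    )
    try:
        return ADDUCTS[canon]
    except KeyError:
        raise ValueError(
            f"unsupported adduct {name!r}; supported: {sorted(ADDUCTS)}"
        ) from None


def monoisotopic_mass(formula: Mapping[str, int]) -> float:
    """Monoisotopic mass (Da) of a neutral formula: sum of count * mass."""
    mass = 0.0
    for element, count in formula.items():
        try:
            mass += count * ELEMENT_MASSES[element]
        except KeyError:
            raise ValueError(f"unknown element {element!r} in formula") from None
    return mass


def ion_mz(formula: Mapping[str, int], adduct: Adduct | str) -> float:
    """m/z (Th) of the singly charged adduct ion of a neutral molecule."""
    if isinstance(adduct, str):
        adduct = get_adduct(adduct)
    return monoisotopic_mass(formula) + adduct.mass_delta


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass error in parts per million.

    Convention: ``1e6 * (observed - theoretical) / theoretical``, so a
    positive value means the observation is heavier than theory.
    """
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return 1e6 * (observed - theoretical) / theoretical


def rdbe(formula: Mapping[str, int]) -> float:
    """Ring-and-double-bond equivalents of a neutral CHNO formula.

    RDBE = C - H/2 + N/2 + 1.  A saturated acyclic monocarboxylic acid or
    primary fatty amide has RDBE 1 (the carbonyl).  May be negative or
    half-integral for formulas that cannot be an even-electron neutral;
    such values are filtered downstream, not raised here.
    """
    return (
        formula.get("C", 0)
        - formula.get("H", 0) / 2.0
        + formula.get("N", 0) / 2.0
        + 1.0
    )


@dataclass(frozen=True)
class FormulaCandidate:
    """A neutral CHNO formula explaining an observed ion m/z."""

    formula: Formula
    theoretical_mz: float
    ppm_error: float
    rdbe: float


#: Default element bounds for decomposition.  N <= 1 because the compound
#: classes of interest carry at most a single amide nitrogen.
DEFAULT_BOUNDS: Dict[str, int] = {"C": 40, "H": 80, "N": 1, "O": 8}

#: Default RDBE acceptance interval; 12 covers fused aromatics with margin.
DEFAULT_DBE_RANGE: Tuple[float, float] = (0.0, 12.0)


def decompose_mass(
    observed_mz: float,
    adduct: Adduct | str,
    tolerance_ppm: float = 7.0,
    bounds: Mapping[str, int] | None = None,
    dbe_range: Tuple[float, float] = DEFAULT_DBE_RANGE,
) -> List[FormulaCandidate]:
    """Enumerate all neutral CHNO formulas whose ion lies within tolerance.

    Exhaustive bounded search: for every (C, N, O) the admissible hydrogen
    counts form a contiguous interval solved directly from the mass window,
    so the search is provably complete over the bounds.  Candidates with
    negative or non-integer RDBE (impossible even-electron CHNO neutrals)
    are removed.  Sorted by \\|ppm error\\| ascending; ties broken by fewer
    heteroatoms, then fewer atoms.

    An empty list is a valid result, not an error.
    """
    if tolerance_ppm <= 0:
        raise ValueError("tolerance_ppm must be positive")
    if isinstance(adduct, str):
        adduct = get_adduct(adduct)
    if bounds is None:
        bounds = DEFAULT_BOUNDS
    neutral = observed_mz - adduct.mass_delta
    half_width = neutral * tolerance_ppm * 1e-6
    lo, hi = neutral - half_width, neutral + half_width

    m_c = ELEMENT_MASSES["C"]
    m_h = ELEMENT_MASSES["H"]
    m_n = ELEMENT_MASSES["N"]
    m_o = ELEMENT_MASSES["O"]

    out: List[FormulaCandidate] = []
    for c in range(bounds.get("C", 0) + 1):
        for n in range(bounds.get("N", 0) + 1):
            for o in range(bounds.get("O", 0) + 1):
                base = c * m_c + n * m_n + o * m_o
                if base > hi:
                    break
                h_lo = max(0, -int(-(lo - base) // m_h))  # ceil
                h_hi = min(bounds.get("H", 0), int((hi - base) // m_h))
                for h in range(h_lo, h_hi + 1):
                    mass = base + h * m_h
                    if not (lo <= mass <= hi):
                        continue
                    dbe = c - h / 2.0 + n / 2.0 + 1.0
                    if dbe != int(dbe):
                        continue
                    if not (dbe_range[0] <= dbe <= dbe_range[1]):
                        continue
                    if c + h + n + o == 0:
                        continue
                    formula = Formula(C=c, H=h, N=n, O=o)
                    theo = mass + adduct.mass_delta
                    out.append(
                        FormulaCandidate(
                            formula=formula,
                            theoretical_mz=theo,
                            ppm_error=ppm_error(observed_mz, theo),
                            rdbe=dbe,
                        )
                    )
    out.sort(
        key=lambda cand: (
            abs(cand.ppm_error),
            cand.formula.get("N", 0) + cand.formula.get("O", 0),
            cand.formula.atom_count,
        )
    )
    return out
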