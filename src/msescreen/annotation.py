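"""Class-diagnostic fragmentation rules and RDBE-based classification.

Encodes the fragmentation chemistry that separates the four compound
classes screened by the pipeline:

* monocarboxylic fatty acids (MFA) and dicarboxylic fatty acids (DFA)
  lose water, CO2, formic acid, or water+CO2 from the deprotonated
  molecule in the high-collision-energy channel;
* fatty acid amides (FAA) cleave the acyl chain and retain a protonated
  amide head group, giving a CH2-spaced ion series
  [C3H8NO]+ / [C4H10NO]+ / [C5H12NO]+ / [C6H14NO]+;
* cinnamic acid derivatives (CAD) are C6-C3 aromatics recognized by high
  RDBE at small carbon count (plus CO2/CO losses for the acids).

Classification is a pure function of (formula, fragments, hint): an
elemental composition fixes nitrogen/oxygen counts and RDBE, and the
decision rules partition compositions into the four classes, with the
oxygenated-DFA vs polyhydroxy-MFA boundary — the only genuinely
ambiguous one — resolved by fragment evidence or a library hint.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from msescreen.chem_core import (
    Adduct,
    Formula,
    FormulaCandidate,
    decompose_mass,
    get_adduct,
    ion_mz,
    monoisotopic_mass,
    rdbe,
)

__all__ = [
    "NeutralLossRule",
    "NEUTRAL_LOSS_RULES",
    "HEADGROUP_SERIES",
    "ClassAssignment",
    "match_neutral_losses",
    "match_headgroup",
    "classify_compound",
    "annotate_entry",
    "count_by_class",
]

#: Default absolute tolerance (Da) for fragment matching.  Printed
#: high-energy fragment masses drift far more than precursor masses do
#: (tens of ppm), so an absolute window is used instead of a ppm one.
DEFAULT_FRAGMENT_TOL = 0.01


@dataclass(frozen=True)
class NeutralLossRule:
    """A diagnostic neutral loss from the quasimolecular ion."""

    loss_name: str
    loss_formula: Formula
    loss_mass: float  # Da
    applicable_classes: Tuple[str, ...]


def _load_rules():
    raw = json.loads(
        resources.files("msescreen")
        .joinpath("data/fragmentation_rules.json")
        .read_text(encoding="utf-8")
    )
    losses = []
    for entry in raw["neutral_losses"]:
        f = Formula.parse(entry["formula"])
        mass = monoisotopic_mass(f)
        if abs(mass - entry["mass"]) > 1e-4:
            raise ValueError(
                f"neutral-loss mass mismatch for {entry['name']}: "
                f"{mass} vs audit value {entry['mass']}"
            )
        losses.append(
            NeutralLossRule(
                loss_name=entry["name"],
                loss_formula=f,
                loss_mass=mass,
                applicable_classes=tuple(entry["classes"]),
            )
        )
    series = tuple(
        (entry["ion"], monoisotopic_mass(Formula.parse(entry["neutral"])) + 1.00727646688)
        for entry in raw["amide_headgroup_series"]
    )
    return tuple(losses), series


#: The packaged rule set (versioned JSON resource, recomputed at load).
NEUTRAL_LOSS_RULES, HEADGROUP_SERIES = _load_rules()


def match_neutral_losses(
    precursor_mz: float,
    fragments: Sequence[float],
    rules: Sequence[NeutralLossRule] = NEUTRAL_LOSS_RULES,
    tol: float = DEFAULT_FRAGMENT_TOL,
) -> Dict[str, float]:
    """Match diagnostic neutral losses against a high-energy fragment list.

    A rule matches iff some fragment lies within ``tol`` (Da) of
    ``precursor_mz - loss_mass``.  Returns {loss_name: matching fragment}.
    """
    matched: Dict[str, float] = {}
    for rule in rules:
        expected = precursor_mz - rule.loss_mass
        if expected <= 0:
            continue
        for frag in fragments:
            if abs(frag - expected) <= tol:
                matched[rule.loss_name] = frag
                break
    return matched


def match_headgroup(
    fragments: Sequence[float],
    tol: float = DEFAULT_FRAGMENT_TOL,
    series: Sequence[Tuple[str, float]] = HEADGROUP_SERIES,
) -> Dict[str, float]:
    """Match the amide head-group ion series; nonempty is FAA-grade evidence.

    ``series`` defaults to the theoretical CH2-spaced protonated-amide ions;
    an alternative reference (e.g. empirically observed values) may be
    passed in its place.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    matched: Dict[str, float] = {}
    for name, mz in series:
        for frag in fragments:
            if abs(frag - mz) <= tol:
                matched[name] = frag
                break
    return matched


@dataclass(frozen=True)
class ClassAssignment:
    """A class label with its saturation/oxygenation bookkeeping.

    ``cc_double_bonds`` is the number of carbon-carbon double bonds in the
    acyl chain, derived by subtracting the class's fixed carbonyl RDBE
    (1 for MFA/FAA, 2 for DFA, plus 1 for a keto group when ``oxo_flag``)
    from the formula's RDBE.  ``oxygen_excess`` counts oxygens beyond the
    carboxyl/amide oxygens the class implies (hydroxyl/keto oxygens).
    Both are None for CAD, whose RDBE is dominated by the aromatic ring.
    """

    class_label: str  # "MFA" | "DFA" | "FAA" | "CAD" | "unclassified"
    formula: Optional[Formula]
    chain_carbons: int = 0
    cc_double_bonds: Optional[int] = None
    oxygen_excess: Optional[int] = None
    oxo_flag: bool = False
    ambiguous: bool = False
    evidence: Tuple[str, ...] = ()

    @property
    def dbe(self) -> Optional[float]:
        return rdbe(self.formula) if self.formula is not None else None

    @property
    def saturated(self) -> bool:
        """No chain C=C and no extra oxygenation (plain saturated member)."""
        return (
            self.class_label in ("MFA", "DFA", "FAA")
            and self.cc_double_bonds == 0
            and (self.oxygen_excess or 0) == 0
            and not self.oxo_flag
        )


_CLASSES = ("MFA", "DFA", "FAA", "CAD")

# carbonyl RDBE and implied oxygen count per acyl class
_CLASS_CARBONYLS = {"MFA": 1, "DFA": 2, "FAA": 1}
_CLASS_OXYGENS = {"MFA": 2, "DFA": 4, "FAA": 1}


def _rule_class(
    formula: Mapping[str, int],
    dfa_evidence: bool,
    hint: Optional[str],
) -> Optional[str]:
    """Decision order: FAA -> CAD -> DFA -> MFA.

    The DFA rule fires on fragment evidence only when no hint exists; a
    hint adjudicates the contested oxygenated-DFA/polyhydroxy-MFA boundary
    in both directions.
    """
    n = formula.get("N", 0)
    o = formula.get("O", 0)
    c = formula.get("C", 0)
    dbe = rdbe(formula)
    if dbe < 0 or dbe != int(dbe):
        return None
    if n == 1 and o == 1:
        return "FAA" if dbe >= 1 else None
    if n != 0:
        return None
    if dbe >= 4 and 7 <= c <= 15:
        return "CAD"
    if o >= 4 and dbe >= 2 and (hint == "DFA" or (hint is None and dfa_evidence)):
        return "DFA"
    if o >= 2:
        return "MFA"
    return None


def classify_compound(
    formula: Mapping[str, int],
    adduct: Adduct | str | None = None,
    fragments: Sequence[float] = (),
    library_hint: Optional[str] = None,
    precursor_mz: Optional[float] = None,
    oxo_hint: bool = False,
    frag_tol: float = DEFAULT_FRAGMENT_TOL,
) -> ClassAssignment:
    """Classify a neutral CHNO formula into MFA/DFA/FAA/CAD.

    ``formula`` is the neutral molecule (adduct hydrogen already handled).
    When ``precursor_mz`` is given, neutral-loss evidence is evaluated
    against the fragment list; head-group evidence needs only fragments.
    A formula violating all rules yields an "unclassified" assignment,
    never an exception.
    """
    if library_hint is not None and library_hint not in _CLASSES:
        raise ValueError(f"unknown class hint {library_hint!r}")
    formula = formula if isinstance(formula, Formula) else Formula(**dict(formula))

    evidence: List[str] = []
    losses = {}
    if precursor_mz is not None and fragments:
        losses = match_neutral_losses(precursor_mz, fragments, tol=frag_tol)
        evidence += [f"loss:{k}@{v:.4f}" for k, v in losses.items()]
    heads = match_headgroup(fragments, tol=frag_tol) if fragments else {}
    evidence += [f"headgroup:{k}@{v:.4f}" for k, v in heads.items()]
    if library_hint:
        evidence.append(f"hint:{library_hint}")

    dfa_evidence = bool(losses)
    cls = _rule_class(formula, dfa_evidence, library_hint)

    n = formula.get("N", 0)
    o = formula.get("O", 0)
    c = formula.get("C", 0)
    dbe = rdbe(formula)
    # the contested oxygenated-DFA vs polyhydroxy-MFA zone: flagged as
    # ambiguous only when neither a hint nor fragment evidence decided it
    boundary = n == 0 and o >= 4 and dbe >= 2 and dbe == int(dbe)
    undecided = boundary and library_hint is None and not dfa_evidence

    if cls is None:
        return ClassAssignment(
            class_label="unclassified",
            formula=formula,
            chain_carbons=c,
            ambiguous=True,
            evidence=tuple(evidence),
        )

    if cls == "CAD":
        return ClassAssignment(
            class_label="CAD",
            formula=formula,
            chain_carbons=c,
            evidence=tuple(evidence),
        )

    oxo = oxo_hint
    carbonyls = _CLASS_CARBONYLS[cls] + (1 if oxo else 0)
    cc = int(dbe) - carbonyls
    excess = o - _CLASS_OXYGENS[cls]
    if cc < 0 or excess < 0:
        return ClassAssignment(
            class_label="unclassified",
            formula=formula,
            chain_carbons=c,
            ambiguous=True,
            evidence=tuple(evidence),
        )
    return ClassAssignment(
        class_label=cls,
        formula=formula,
        chain_carbons=c,
        cc_double_bonds=cc,
        oxygen_excess=excess,
        oxo_flag=oxo,
        ambiguous=undecided,
        evidence=tuple(evidence),
    )


def annotate_entry(
    observed_mz: float,
    adduct: Adduct | str,
    fragments: Sequence[float] = (),
    library_formula: Optional[Formula] = None,
    library_hint: Optional[str] = None,
    oxo_hint: bool = False,
    tolerance_ppm: float = 7.0,
    frag_tol: float = DEFAULT_FRAGMENT_TOL,
    use_hints: bool = True,
) -> ClassAssignment:
    """Decompose an observed ion and classify the resulting neutral.

    The formula is the best-ranked decomposition candidate; with hints
    enabled, the best candidate whose rule class agrees with the hint is
    preferred.  When no candidate exists within tolerance (possible for
    printed masses carrying transcription-level error), the library
    formula — when provided — stands in, and the fallback is recorded in
    the evidence trail.
    """
    if isinstance(adduct, str):
        adduct = get_adduct(adduct)
    hint = library_hint if use_hints else None
    candidates = decompose_mass(observed_mz, adduct, tolerance_ppm)

    chosen: Optional[Formula] = None
    for cand in candidates:
        if hint is None:
            chosen = cand.formula
            break
        trial = classify_compound(
            cand.formula,
            fragments=fragments,
            library_hint=hint,
            precursor_mz=observed_mz,
            oxo_hint=oxo_hint,
            frag_tol=frag_tol,
        )
        if trial.class_label == hint:
            chosen = cand.formula
            break

    fallback = False
    if chosen is None and library_formula is not None:
        chosen = library_formula
        fallback = True
    if chosen is None:
        return ClassAssignment(
            class_label="unclassified",
            formula=None,
            ambiguous=True,
            evidence=("no-formula-within-tolerance",),
        )
    result = classify_compound(
        chosen,
        fragments=fragments,
        library_hint=hint,
        precursor_mz=observed_mz,
        oxo_hint=oxo_hint,
        frag_tol=frag_tol,
    )
    if fallback:
        result = ClassAssignment(
            class_label=result.class_label,
            formula=result.formula,
            chain_carbons=result.chain_carbons,
            cc_double_bonds=result.cc_double_bonds,
            oxygen_excess=result.oxygen_excess,
            oxo_flag=result.oxo_flag,
            ambiguous=result.ambiguous,
            evidence=result.evidence + ("library-formula-fallback",),
        )
    return result


def count_by_class(assignments: Sequence[ClassAssignment]) -> Dict[str, object]:
    """Tally assignments by class and by (class, C=C count, oxygen excess).

    Returns ``{"by_class": {...}, "by_saturation": {...}, "saturated":
    {...}, "unclassified": int, "total_classified": int}``; the classified
    total equals the input length minus the unclassified count.
    """
    by_class: Dict[str, int] = {c: 0 for c in _CLASSES}
    by_sat: Dict[Tuple[str, Optional[int], Optional[int]], int] = {}
    saturated: Dict[str, int] = {c: 0 for c in _CLASSES}
    unclassified = 0
    for a in assignments:
        if a.class_label == "unclassified":
            unclassified += 1
            continue
        by_class[a.class_label] += 1
        key = (a.class_label, a.cc_double_bonds, a.oxygen_excess)
        by_sat[key] = by_sat.get(key, 0) + 1
        if a.saturated:
            saturated[a.class_label] += 1
    return {
        "by_class": by_class,
        "by_saturation": by_sat,
        "saturated": saturated,
        "unclassified": unclassified,
        "total_classified": len(assignments) - unclassified,
    }
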