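"""Post-targeted screening of peak lists against a target library.

A target library (name, neutral formula, class, adduct, diagnostic
fragments) is matched against per-extract peak lists within a ppm
tolerance window (default +/-7 ppm).  Matches are confirmed by diagnostic
fragment evidence, except for classes whose quasimolecular ion resists
collision-induced fragmentation (saturated fatty acids keep an intense
deprotonated molecule even at high collision energy), which may confirm
on the precursor alone.  Retention time is informational: screening is
mass-first, and RT only orders isomer labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import pandas as pd

from msescreen.chem_core import Adduct, Formula, get_adduct, ion_mz, ppm_error

__all__ = [
    "TargetEntry",
    "Peak",
    "ExtractRun",
    "Detection",
    "screen_targets",
    "assign_isomer_labels",
    "build_presence_matrix",
    "PRECURSOR_ONLY_CLASSES",
]

#: Classes allowed to confirm on the precursor ion alone (fragmentation-
#: resistant quasimolecular ions).  Overridable per screening call.
PRECURSOR_ONLY_CLASSES: FrozenSet[str] = frozenset({"MFA", "DFA"})

#: Instrument scan range (Th) used for peak validation.
SCAN_RANGE = (50.0, 1200.0)


@dataclass(frozen=True)
class TargetEntry:
    """One library record: a neutral compound screened as a fixed adduct."""

    name: str
    formula: Formula
    class_label: str
    adduct: Adduct
    diagnostic_fragments: Tuple[Tuple[str, float], ...] = ()
    reference_rt: Optional[float] = None  # minutes, informational
    expect_isomers: bool = False

    @property
    def theoretical_mz(self) -> float:
        return ion_mz(self.formula, self.adduct)


@dataclass(frozen=True)
class Peak:
    """A low-energy precursor peak with its high-energy fragment list."""

    mz: float
    rt: float  # minutes
    intensity: float = 0.0
    fragments: Tuple[float, ...] = ()


@dataclass(frozen=True)
class ExtractRun:
    """All peaks of one extract acquired in one polarity."""

    extract_id: str
    polarity: int  # +1 or -1
    peaks: Tuple[Peak, ...] = ()
    condition: Optional[Tuple[float, float]] = None  # (pressure bar, temp C)

    def __post_init__(self) -> None:
        if self.polarity not in (+1, -1):
            raise ValueError("polarity must be +1 or -1")


@dataclass(frozen=True)
class Detection:
    """A target matched to an observed peak."""

    target: TargetEntry
    extract_id: str
    observed_mz: float
    rt: float
    intensity: float
    ppm_error: float
    matched_fragments: Tuple[Tuple[str, float], ...] = ()
    confirmed: bool = False
    compound_label: Optional[str] = None

    @property
    def label(self) -> str:
        return self.compound_label if self.compound_label else self.target.name


def screen_targets(
    run: ExtractRun,
    library: Sequence[TargetEntry],
    tolerance_ppm: float = 7.0,
    frag_tol: float = 0.01,
    precursor_only_classes: FrozenSet[str] = PRECURSOR_ONLY_CLASSES,
    min_intensity: float = 0.0,
    keep_all_matches: bool = False,
) -> List[Detection]:
    """Screen one run against the library within a ppm tolerance window.

    For each polarity-matching target, peaks within ``tolerance_ppm`` of
    the target ion m/z become candidate detections.  Unless
    ``keep_all_matches``, only the apex-equivalent candidate (smallest
    \\|ppm error\\|, ties to higher intensity) is kept per target.  A
    candidate is confirmed when at least one diagnostic fragment matches
    within ``frag_tol`` Da, or when the target's class confirms on the
    precursor alone; unconfirmed candidates are retained but flagged.
    """
    if not library:
        raise ValueError("target library is empty")
    if not any(t.adduct.charge == run.polarity for t in library):
        warnings.warn(
            f"no target matches run polarity {run.polarity:+d}; empty result",
            stacklevel=2,
        )
        return []

    detections: List[Detection] = []
    for target in library:
        if target.adduct.charge != run.polarity:
            continue
        theo = target.theoretical_mz
        candidates = [
            p
            for p in run.peaks
            if p.intensity >= min_intensity
            and abs(ppm_error(p.mz, theo)) <= tolerance_ppm
        ]
        if not candidates:
            continue
        if not keep_all_matches:
            candidates = [
                min(candidates, key=lambda p: (abs(ppm_error(p.mz, theo)), -p.intensity))
            ]
        for peak in candidates:
            matched = []
            for name, frag_mz in target.diagnostic_fragments:
                for obs_frag in peak.fragments:
                    if abs(obs_frag - frag_mz) <= frag_tol:
                        matched.append((name, obs_frag))
                        break
            confirmed = bool(matched) or target.class_label in precursor_only_classes
            detections.append(
                Detection(
                    target=target,
                    extract_id=run.extract_id,
                    observed_mz=peak.mz,
                    rt=peak.rt,
                    intensity=peak.intensity,
                    ppm_error=ppm_error(peak.mz, theo),
                    matched_fragments=tuple(matched),
                    confirmed=confirmed,
                )
            )
    return detections


_ROMAN = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X")


def _to_roman(i: int) -> str:
    if 1 <= i <= len(_ROMAN):
        return _ROMAN[i - 1]
    raise ValueError(f"isomer ordinal {i} out of supported range")


def _base_name(name: str) -> str:
    parts = name.rsplit(" ", 1)
    if len(parts) == 2 and parts[1] in _ROMAN:
        return parts[0]
    return name


def assign_isomer_labels(detections: Sequence[Detection]) -> List[Detection]:
    """Label co-eluting isomers with Roman numerals in ascending RT order.

    Detections sharing a base compound identity (target name, any existing
    Roman suffix stripped) but distinct retention times receive suffixes
    I, II, ... by ascending RT.  RT ties break by descending intensity,
    then ascending observed m/z, so labels are a permutation-invariant
    function of the detection set.  Singleton groups keep their plain name
    unless the library pre-declares isomers.
    """
    groups: Dict[Tuple[str, str], List[Detection]] = {}
    for det in detections:
        key = (det.extract_id, _base_name(det.target.name))
        groups.setdefault(key, []).append(det)

    out: List[Detection] = []
    for (_, base), group in groups.items():
        group = sorted(group, key=lambda d: (d.rt, -d.intensity, d.observed_mz))
        needs_suffix = len(group) > 1 or any(d.target.expect_isomers for d in group)
        for i, det in enumerate(group, start=1):
            label = f"{base} {_to_roman(i)}" if needs_suffix else base
            out.append(replace(det, compound_label=label))
    return out


def build_presence_matrix(
    detections: Sequence[Detection],
    extracts: Sequence[str],
    only_confirmed: bool = True,
) -> pd.DataFrame:
    """Binary extracts x compounds occurrence matrix from detections.

    Compounds never confirmed anywhere are excluded; duplicate
    (extract, compound) detections collapse to a single 1.  Column order
    follows first appearance in the detection sequence.
    """
    columns: List[str] = []
    cells: Dict[Tuple[str, str], int] = {}
    for det in detections:
        if only_confirmed and not det.confirmed:
            continue
        if det.extract_id not in extracts:
            raise ValueError(f"detection extract {det.extract_id!r} not in extracts")
        if det.label not in columns:
            columns.append(det.label)
        cells[(det.extract_id, det.label)] = 1
    matrix = pd.DataFrame(0, index=list(extracts), columns=columns, dtype=int)
    for (extract, label), value in cells.items():
        matrix.loc[extract, label] = value
    return matrix
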