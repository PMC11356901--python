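"""File formats, the packaged identification-table fixture, and run config.

Formats
-------
peak table (CSV/TSV)
    one file per extract per polarity; columns ``mz, rt_min, intensity,
    fragments`` with fragments as a semicolon-separated m/z list.
target library (CSV/TSV)
    columns ``name, formula, class, adduct, fragments, rt_min`` (rt_min
    optional/blank); fragments as ``label:mz`` pairs or bare m/z values,
    semicolon-separated.
fixture
    the packaged 166-row identification table for the five supercritical-
    CO2 leaf extracts (CTL1-CTL5), transcribed from print with a curated
    neutral-formula column and a verbatim ``printed_flags`` provenance
    column.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from importlib import resources
from io import StringIO
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
import yaml

from msescreen.chem_core import Formula, get_adduct
from msescreen.screening import (
    SCAN_RANGE,
    Detection,
    ExtractRun,
    Peak,
    TargetEntry,
)

__all__ = [
    "FixtureValidationError",
    "FixtureTable",
    "load_fixture",
    "validate_fixture",
    "EXTRACTS",
    "read_peak_table",
    "write_peak_table",
    "read_target_library",
    "write_target_library",
    "RunConfig",
    "load_config",
]

#: Extract labels and their supercritical-CO2 conditions (pressure bar, temp C).
EXTRACTS: Dict[str, Tuple[float, float]] = {
    "CTL1": (100.0, 55.0),
    "CTL2": (150.0, 55.0),
    "CTL3": (250.0, 55.0),
    "CTL4": (300.0, 55.0),
    "CTL5": (500.0, 55.0),
}

_EXPECTED_ROWS = 166
_EXPECTED_TALLIES = {"MFA": 66, "DFA": 52, "FAA": 27, "CAD": 21}


class FixtureValidationError(ValueError):
    """The packaged fixture failed a structural validation rule."""


@dataclass
class FixtureTable:
    """The transcribed identification table, validated."""

    df: pd.DataFrame

    @property
    def extracts(self) -> List[str]:
        return list(EXTRACTS)

    def presence_matrix(self, mode: Optional[str] = None) -> pd.DataFrame:
        """Binary extracts x compounds matrix from the presence columns.

        ``mode``: None for both polarities, "+" for protonated-ion rows,
        "-" for deprotonated-ion rows (a compound belongs to the mode of
        its molecular-ion column).
        """
        df = self.df
        if mode is not None:
            if mode not in ("+", "-"):
                raise ValueError("mode must be '+', '-' or None")
            df = df[df["ion"].str.endswith(mode)]
        return df.set_index("label")[self.extracts].T.astype(int)

    def classify(self, use_hints: bool = True):
        """Decompose and classify every fixture row.

        Returns one :class:`~msescreen.annotation.ClassAssignment` per row
        (table order).  With ``use_hints`` the printed class column acts as
        the library hint resolving the oxygenated-DFA/MFA boundary; without
        it the fragment evidence alone decides and contested rows are
        flagged ambiguous.
        """
        from msescreen.annotation import annotate_entry

        out = []
        for _, row in self.df.iterrows():
            out.append(
                annotate_entry(
                    observed_mz=row["observed_mz"],
                    adduct=row["ion"],
                    fragments=row["fragment_list"],
                    library_formula=Formula.parse(row["formula"]),
                    library_hint=row["class"],
                    oxo_hint=row["name"].lower().startswith("oxo"),
                    use_hints=use_hints,
                )
            )
        return out

    def to_targets(self) -> List[TargetEntry]:
        """The fixture as a screening library (one target per row)."""
        targets = []
        for _, row in self.df.iterrows():
            frags = tuple(
                (f"frag{i}", mz) for i, mz in enumerate(row["fragment_list"], 1)
            )
            targets.append(
                TargetEntry(
                    name=row["label"],
                    formula=Formula.parse(row["formula"]),
                    class_label=row["class"],
                    adduct=get_adduct(row["ion"]),
                    diagnostic_fragments=frags,
                    reference_rt=row["rt_min"],
                )
            )
        return targets


def _parse_fixture(text: str) -> pd.DataFrame:
    df = pd.read_csv(StringIO(text), sep="\t", comment="#", dtype={"peak": int})
    df["fragment_list"] = df["fragments"].fillna("").map(
        lambda s: tuple(float(x) for x in s.split(";") if x)
    )
    return df


def load_fixture() -> FixtureTable:
    """Load and validate the packaged identification table.

    Raises :class:`FixtureValidationError` naming the offending row or
    rule on any structural failure.
    """
    text = (
        resources.files("msescreen")
        .joinpath("data/ctl_identifications.tsv")
        .read_text(encoding="utf-8")
    )
    df = _parse_fixture(text)
    validate_fixture(df)
    return FixtureTable(df=df)


def validate_fixture(df: pd.DataFrame) -> None:
    """Structural validation of an identification table DataFrame."""
    if len(df) != _EXPECTED_ROWS:
        raise FixtureValidationError(
            f"expected {_EXPECTED_ROWS} rows, found {len(df)}"
        )
    tallies = df["class"].value_counts().to_dict()
    if tallies != _EXPECTED_TALLIES:
        raise FixtureValidationError(f"class tallies {tallies} != {_EXPECTED_TALLIES}")
    if df["label"].duplicated().any():
        dup = df.loc[df["label"].duplicated(), "label"].iloc[0]
        raise FixtureValidationError(f"duplicate compound label {dup!r}")
    for _, row in df.iterrows():
        if not (SCAN_RANGE[0] <= row["observed_mz"] <= SCAN_RANGE[1]):
            raise FixtureValidationError(
                f"peak {row['peak']}: observed mass {row['observed_mz']} "
                f"outside scan range {SCAN_RANGE}"
            )
        if row["ion"] not in ("[M+H]+", "[M-H]-"):
            raise FixtureValidationError(f"peak {row['peak']}: bad ion {row['ion']!r}")
        for ctl in EXTRACTS:
            if row[ctl] not in (0, 1):
                raise FixtureValidationError(
                    f"peak {row['peak']}: presence flag {ctl}={row[ctl]!r}"
                )
        try:
            Formula.parse(row["formula"])
        except ValueError as exc:
            raise FixtureValidationError(f"peak {row['peak']}: {exc}") from None


# ---------------------------------------------------------------------------
# peak tables


def write_peak_table(run: ExtractRun, path: str | Path) -> None:
    rows = [
        {
            "mz": p.mz,
            "rt_min": p.rt,
            "intensity": p.intensity,
            "fragments": ";".join(f"{f:.6f}" for f in p.fragments),
        }
        for p in run.peaks
    ]
    pd.DataFrame(rows, columns=["mz", "rt_min", "intensity", "fragments"]).to_csv(
        path, index=False
    )


def read_peak_table(
    path: str | Path,
    extract_id: str,
    polarity: int,
    condition: Optional[Tuple[float, float]] = None,
) -> ExtractRun:
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ValueError(f"{path}: cannot parse peak table: {exc}") from exc
    required = {"mz", "rt_min", "intensity", "fragments"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    peaks = []
    for i, row in df.iterrows():
        frag_text = "" if pd.isna(row["fragments"]) else str(row["fragments"])
        try:
            frags = tuple(float(x) for x in frag_text.split(";") if x)
            peaks.append(
                Peak(
                    mz=float(row["mz"]),
                    rt=float(row["rt_min"]),
                    intensity=float(row["intensity"]),
                    fragments=frags,
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}: line {i + 2}: {exc}") from None
    return ExtractRun(
        extract_id=extract_id,
        polarity=polarity,
        peaks=tuple(peaks),
        condition=condition,
    )


# ---------------------------------------------------------------------------
# target libraries


def write_target_library(targets: Sequence[TargetEntry], path: str | Path) -> None:
    rows = [
        {
            "name": t.name,
            "formula": t.formula.hill(),
            "class": t.class_label,
            "adduct": t.adduct.name,
            "fragments": ";".join(f"{n}:{mz:.6f}" for n, mz in t.diagnostic_fragments),
            "rt_min": "" if t.reference_rt is None else t.reference_rt,
        }
        for t in targets
    ]
    pd.DataFrame(
        rows, columns=["name", "formula", "class", "adduct", "fragments", "rt_min"]
    ).to_csv(path, index=False)


def read_target_library(path: str | Path) -> List[TargetEntry]:
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ValueError(f"{path}: cannot parse target library: {exc}") from exc
    required = {"name", "formula", "class", "adduct", "fragments"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    targets = []
    for i, row in df.iterrows():
        try:
            frags = []
            frag_text = "" if pd.isna(row["fragments"]) else str(row["fragments"])
            for j, tok in enumerate(x for x in frag_text.split(";") if x):
                if ":" in tok:
                    name, mz = tok.split(":", 1)
                    frags.append((name, float(mz)))
                else:
                    frags.append((f"frag{j + 1}", float(tok)))
            rt = row.get("rt_min")
            targets.append(
                TargetEntry(
                    name=str(row["name"]),
                    formula=Formula.parse(str(row["formula"])),
                    class_label=str(row["class"]),
                    adduct=get_adduct(str(row["adduct"])),
                    diagnostic_fragments=tuple(frags),
                    reference_rt=None if pd.isna(rt) else float(rt),
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}: line {i + 2}: {exc}") from None
    return targets


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Tunable screening parameters with their defaults."""

    tolerance_ppm: float = 7.0
    fragment_tol_da: float = 0.01
    precursor_only_classes: Tuple[str, ...] = ("MFA", "DFA")
    min_intensity: float = 0.0
    pca_scale: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tolerance_ppm <= 0 or self.fragment_tol_da <= 0:
            raise ValueError("tolerances must be positive")


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML key-value config; unknown keys are rejected."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    known = {f.name for f in dc_fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    if "precursor_only_classes" in raw:
        raw["precursor_only_classes"] = tuple(raw["precursor_only_classes"])
    return RunConfig(**raw)
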