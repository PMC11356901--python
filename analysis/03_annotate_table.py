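"""Classify every row of the packaged identification table.

Decomposes each printed observed mass into a CHNO formula at 7 ppm, runs
the class decision rules (with the printed class as library hint), and
tallies classes and saturation levels. Also reports the hint-free
ambiguity count. Writes results/annotations.csv and results/tallies.json.
"""

import json
from pathlib import Path

import pandas as pd

from msescreen.annotation import count_by_class
from msescreen.io import load_fixture

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    fixture = load_fixture()
    assignments = fixture.classify(use_hints=True)
    hint_free = fixture.classify(use_hints=False)

    rows = []
    for (_, row), a in zip(fixture.df.iterrows(), assignments):
        rows.append(
            {
                "peak": row["peak"],
                "name": row["label"],
                "class": a.class_label,
                "formula": a.formula.hill(),
                "dbe": a.dbe,
                "cc_double_bonds": a.cc_double_bonds,
                "oxygen_excess": a.oxygen_excess,
                "oxo": a.oxo_flag,
                "evidence": "|".join(a.evidence),
            }
        )
    RESULTS.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(RESULTS / "annotations.csv", index=False)

    tallies = count_by_class(assignments)
    mono_dfa = sum(
        1 for a in assignments
        if a.class_label == "DFA" and a.cc_double_bonds == 1 and a.oxygen_excess == 0
    )
    oxy_dfa = sum(
        1 for a in assignments
        if a.class_label == "DFA" and (a.oxygen_excess or 0) > 0
    )
    faa_monounsat = sum(
        1 for a in assignments
        if a.class_label == "FAA" and a.cc_double_bonds == 1
    )
    ambiguous = sum(
        1 for a in hint_free if a.ambiguous or a.class_label == "unclassified"
    )
    summary = {
        "by_class": tallies["by_class"],
        "saturated": tallies["saturated"],
        "mono_unsaturated_dfa": mono_dfa,
        "oxygenated_dfa": oxy_dfa,
        "faa_one_double_bond": faa_monounsat,
        "hint_free_ambiguous": ambiguous,
    }
    (RESULTS / "tallies.json").write_text(json.dumps(summary, indent=2) + "\n")

    print(f"classified {tallies['total_classified']}/166 rows")
    print(f"classes: {tallies['by_class']}")
    print(f"saturated: MFA {tallies['saturated']['MFA']}, "
          f"FAA {tallies['saturated']['FAA']}, DFA {tallies['saturated']['DFA']}")
    print(f"mono-unsaturated DFA: {mono_dfa}; oxygenated DFA: {oxy_dfa}; "
          f"FAA with one C=C: {faa_monounsat}")
    print(f"hint-free ambiguous rows: {ambiguous}")


if __name__ == "__main__":
    main()
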