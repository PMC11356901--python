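"""Generate the synthetic MS^E experiment used to validate the pipeline.

Emits a homologous target library (20 MFA / 15 DFA / 10 FAA / 5 CAD), a
designed presence pattern over five pressure-series extracts, and one
peak table per (extract, polarity) with 2 ppm precursor noise, 3 mDa
fragment noise and 10 decoy peaks per run, under results/simulation/.
"""

from pathlib import Path

from msescreen.io import write_peak_table, write_target_library
from msescreen.simulate import SimConfig, generate_library, simulate_runs

OUT = Path(__file__).resolve().parent.parent / "results" / "simulation"


def main(seed: int = 11) -> None:
    config = SimConfig(seed=seed, n_decoys=10)
    library, truth = generate_library(config)
    runs = simulate_runs(library, truth, config)

    OUT.mkdir(parents=True, exist_ok=True)
    write_target_library(library, OUT / "library.csv")
    truth.presence.to_csv(OUT / "ground_truth_presence.csv")
    truth.table.to_csv(OUT / "ground_truth_compounds.csv", index=False)
    for run in runs:
        pol = "pos" if run.polarity > 0 else "neg"
        write_peak_table(run, OUT / f"peaks_{run.extract_id}_{pol}.csv")

    n_peaks = sum(len(r.peaks) for r in runs)
    print(f"library: {len(library)} targets; designed presences: "
          f"{int(truth.presence.to_numpy().sum())}")
    print(f"wrote {len(runs)} runs ({n_peaks} peaks incl. decoys) to {OUT}")


if __name__ == "__main__":
    main()
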