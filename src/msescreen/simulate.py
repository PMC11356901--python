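"""Synthetic MS^E extract runs with known ground truth.

The generator emulates, at desk scale, what the instrument produces for a
post-targeted screen: for each compound designed to be present in an
extract, a precursor peak at the theoretical adduct m/z perturbed by
ppm-scale Gaussian noise, class-consistent diagnostic fragments perturbed
by Da-scale Gaussian noise, a retention time linear in carbon chain
length (saturated homologs elute later the longer the chain) minus an
offset per double bond, and a log-normal intensity.  Optional decoy peaks
are placed at least 25 ppm from every target so specificity is testable
by construction.

What it does not emulate: chromatographic peak shapes, isotope envelopes,
in-source fragmentation, co-elution interference.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from msescreen.chem_core import Formula, get_adduct, ion_mz
from msescreen.annotation import HEADGROUP_SERIES, NEUTRAL_LOSS_RULES
from msescreen.screening import ExtractRun, Peak, TargetEntry

__all__ = ["SimConfig", "GroundTruth", "generate_library", "simulate_runs"]

#: Default extract panel: label -> (pressure bar, temperature C), mirroring
#: a five-point supercritical-CO2 pressure series at constant temperature.
DEFAULT_EXTRACTS: Tuple[Tuple[str, Tuple[float, float]], ...] = (
    ("CTL1", (100.0, 55.0)),
    ("CTL2", (150.0, 55.0)),
    ("CTL3", (250.0, 55.0)),
    ("CTL4", (300.0, 55.0)),
    ("CTL5", (500.0, 55.0)),
)

# small CAD panel: phenylpropanoid-type aromatics with a CO2-loss diagnostic
_CAD_PANEL: Tuple[Tuple[str, str, str], ...] = (
    ("cinnamic acid", "C9H8O2", "[M-H]-"),
    ("4-hydroxycinnamic acid", "C9H8O3", "[M-H]-"),
    ("4-methoxycinnamic acid", "C10H10O3", "[M-H]-"),
    ("3,4-dihydroxycinnamic acid", "C9H8O4", "[M-H]-"),
    ("ferulic acid", "C10H10O4", "[M-H]-"),
    ("coumarin", "C9H6O2", "[M+H]+"),
    ("benzoic acid", "C7H6O2", "[M-H]-"),
    ("salicylic acid", "C7H6O3", "[M-H]-"),
)


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for the synthetic MS^E experiment.

    Precursor mass noise defaults to 2 ppm (1 s.d.), comfortably inside
    the 7 ppm screening window; fragment noise to 3 mDa, inside the
    0.01 Da fragment window.  The retention model is linear in chain
    carbons with a positive slope so saturated homologs elute in chain
    order, with a per-double-bond offset and a small jitter.
    """

    n_per_class: Dict[str, int] = field(
        default_factory=lambda: {"MFA": 20, "DFA": 15, "FAA": 10, "CAD": 5}
    )
    chain_range: Tuple[int, int] = (9, 24)
    extracts: Tuple[Tuple[str, Tuple[float, float]], ...] = DEFAULT_EXTRACTS
    ppm_noise_sd: float = 2.0  # ppm
    fragment_noise_sd: float = 0.003  # Da
    rt_intercept: float = 1.0  # min
    rt_slope: float = 0.6  # min per chain carbon
    rt_unsat_offset: float = 0.4  # min per C=C
    rt_jitter_sd: float = 0.02  # min
    intensity_lognormal: Tuple[float, float] = (10.0, 1.0)  # (mu, sigma)
    p_present: float = 0.85  # per-cell presence probability off the common core
    p_common: float = 0.8  # fraction of compounds present in every extract
    n_decoys: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ppm_noise_sd < 0 or self.fragment_noise_sd < 0:
            raise ValueError("noise s.d. must be nonnegative")
        if self.rt_slope <= 0:
            raise ValueError("rt slope must be positive (later elution for longer chains)")
        if not (7 <= self.chain_range[0] <= self.chain_range[1] <= 30):
            raise ValueError("chain_range must lie within [7, 30]")


@dataclass
class GroundTruth:
    """Designed truth: per-compound identity plus the presence design."""

    table: pd.DataFrame  # name, formula, class, cc_double_bonds, adduct, mz
    presence: pd.DataFrame  # compounds x extracts, 0/1


def _acyl_formula(class_label: str, chain: int, unsat: int) -> Formula:
    if class_label == "MFA":
        h = 2 * chain - 2 * unsat
        f = Formula(C=chain, H=h, O=2)
    elif class_label == "DFA":
        h = 2 * chain - 2 - 2 * unsat
        f = Formula(C=chain, H=h, O=4)
    elif class_label == "FAA":
        h = 2 * chain + 1 - 2 * unsat
        f = Formula(C=chain, H=h, N=1, O=1)
    else:
        raise ValueError(f"not an acyl class: {class_label}")
    if f.get("H", 0) <= 0:
        raise ValueError(
            f"infeasible class/chain combination: {class_label} C{chain}:{unsat}"
        )
    return f


def _diagnostics(class_label: str, formula: Formula, adduct_name: str):
    """Class-consistent diagnostic fragment list (name, m/z)."""
    precursor = ion_mz(formula, adduct_name)
    if class_label == "FAA":
        return tuple(HEADGROUP_SERIES)
    if class_label in ("MFA", "DFA"):
        wanted = ("H2O", "CO2") if class_label == "MFA" else ("H2O", "CO2", "H2O+CO2")
    else:  # CAD
        wanted = ("CO2",)
    return tuple(
        (f"-{r.loss_name}", precursor - r.loss_mass)
        for r in NEUTRAL_LOSS_RULES
        if r.loss_name in wanted and precursor - r.loss_mass > 0
    )


def generate_library(config: SimConfig) -> Tuple[List[TargetEntry], GroundTruth]:
    """Enumerate a homologous target library with designed presence.

    Acyl classes walk the chain range, cycling through saturation levels
    0, 1, 2 C=C (0 or 1 for DFA); CAD entries come from a fixed aromatic
    panel.  The presence design puts a ``p_common`` fraction of compounds
    in every extract and Bernoulli(p_present) cells elsewhere, guaranteeing
    each remaining compound at least one presence.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.chain_range
    chains = list(range(lo, hi + 1))
    entries: List[Tuple[str, Formula, str, str, int]] = []

    for class_label, n in config.n_per_class.items():
        if n == 0:
            continue
        if class_label == "CAD":
            if n > len(_CAD_PANEL):
                raise ValueError(
                    f"infeasible class/chain combination: CAD supports at most "
                    f"{len(_CAD_PANEL)} panel compounds, requested {n}"
                )
            for name, formula, adduct in _CAD_PANEL[:n]:
                entries.append((name, Formula.parse(formula), "CAD", adduct, 0))
            continue
        adduct = "[M+H]+" if class_label == "FAA" else "[M-H]-"
        max_unsat = 1 if class_label == "DFA" else 2
        made = 0
        unsat = 0
        chain_i = 0
        while made < n:
            chain = chains[chain_i % len(chains)]
            if chain_i and chain_i % len(chains) == 0:
                unsat += 1
                if unsat > max_unsat:
                    raise ValueError(
                        f"infeasible class/chain combination: {class_label} "
                        f"needs more than {len(chains)} x {max_unsat + 1} homologs"
                    )
            suffix = f"C{chain}:{unsat}"
            entries.append(
                (
                    f"{class_label} {suffix}",
                    _acyl_formula(class_label, chain, unsat),
                    class_label,
                    adduct,
                    unsat,
                )
            )
            made += 1
            chain_i += 1

    targets = [
        TargetEntry(
            name=name,
            formula=formula,
            class_label=cls,
            adduct=get_adduct(adduct),
            diagnostic_fragments=_diagnostics(cls, formula, adduct),
        )
        for name, formula, cls, adduct, _ in entries
    ]

    extract_labels = [label for label, _ in config.extracts]
    n_compounds = len(entries)
    presence = np.ones((n_compounds, len(extract_labels)), dtype=int)
    n_common = int(round(config.p_common * n_compounds))
    order = rng.permutation(n_compounds)
    variable = order[n_common:]
    for i in variable:
        row = (rng.random(len(extract_labels)) < config.p_present).astype(int)
        if row.sum() == 0:
            row[rng.integers(len(extract_labels))] = 1
        presence[i] = row

    truth_rows = [
        {
            "name": name,
            "formula": formula.hill(),
            "class": cls,
            "cc_double_bonds": unsat,
            "adduct": adduct,
            "theoretical_mz": ion_mz(formula, adduct),
        }
        for name, formula, cls, adduct, unsat in entries
    ]
    truth = GroundTruth(
        table=pd.DataFrame(truth_rows),
        presence=pd.DataFrame(
            presence,
            index=[name for name, *_ in entries],
            columns=extract_labels,
        ),
    )
    return targets, truth


def _rt_for(config: SimConfig, target: TargetEntry, unsat: int) -> float:
    chain = target.formula.get("C", 0)
    return config.rt_intercept + config.rt_slope * chain - config.rt_unsat_offset * unsat


def simulate_runs(
    library: Sequence[TargetEntry],
    truth: GroundTruth,
    config: SimConfig,
) -> List[ExtractRun]:
    """Emit one ExtractRun per (extract, polarity) from the presence design.

    Each designed presence becomes one peak; absent compounds emit
    nothing.  With ``n_decoys`` > 0, decoy peaks are placed at least
    25 ppm from every target ion so they can never be matched at the
    screening tolerance.  A fixed seed gives identical output.
    """
    if list(truth.presence.index) != [t.name for t in library]:
        raise ValueError("presence design rows do not match the library")
    rng = np.random.default_rng(config.seed + 1)
    unsat_by_name = dict(zip(truth.table["name"], truth.table["cc_double_bonds"]))
    mu, sigma = config.intensity_lognormal

    runs: List[ExtractRun] = []
    for extract_label, condition in config.extracts:
        for polarity in (+1, -1):
            peaks: List[Peak] = []
            for target in library:
                if target.adduct.charge != polarity:
                    continue
                if not truth.presence.loc[target.name, extract_label]:
                    continue
                theo = target.theoretical_mz
                mz = theo * (1.0 + rng.normal(0.0, config.ppm_noise_sd) * 1e-6)
                rt = _rt_for(config, target, unsat_by_name[target.name]) + rng.normal(
                    0.0, config.rt_jitter_sd
                )
                frags = tuple(
                    fmz + rng.normal(0.0, config.fragment_noise_sd)
                    for _, fmz in target.diagnostic_fragments
                )
                peaks.append(
                    Peak(
                        mz=mz,
                        rt=rt,
                        intensity=float(rng.lognormal(mu, sigma)),
                        fragments=frags,
                    )
                )
            for _ in range(config.n_decoys):
                peaks.append(_decoy_peak(rng, library, polarity, config))
            runs.append(
                ExtractRun(
                    extract_id=extract_label,
                    polarity=polarity,
                    peaks=tuple(peaks),
                    condition=condition,
                )
            )
    return runs


def _decoy_peak(
    rng: np.random.Generator,
    library: Sequence[TargetEntry],
    polarity: int,
    config: SimConfig,
    min_ppm: float = 25.0,
) -> Peak:
    targets = [t.theoretical_mz for t in library if t.adduct.charge == polarity]
    mu, sigma = config.intensity_lognormal
    for _ in range(1000):
        mz = rng.uniform(60.0, 500.0)
        if all(abs(1e6 * (mz - t) / t) >= min_ppm for t in targets):
            return Peak(
                mz=mz,
                rt=float(rng.uniform(0.5, 18.0)),
                intensity=float(rng.lognormal(mu, sigma)),
                fragments=(),
            )
    raise RuntimeError("could not place a decoy peak away from all targets")
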