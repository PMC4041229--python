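"""Synthetic solvent-tolerance assays with known ground truth.

The generator embodies the structure the analysis assumes: every
culture shares its species' lag and phase timing, growth varies only in
*rate*, and the rate declines with dissolved solvent concentration
through a chosen dose-response shape (linear or logistic/Hill), both
normalized so that f(0) = 1 and f(EC50) = 0.5 exactly.  OD600 readings
carry additive Gaussian noise truncated at zero, mimicking
spectrophotometer read noise which dominates at the low ODs where the
fit window sits.

Every stage of the pipeline can therefore be scored against truth:
fitted μ against μ0_true·f(c), estimated EC50s against EC50_true, and
censoring behaviour against deliberately out-of-range truths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .growth import ODSeries

__all__ = [
    "SpeciesTruth",
    "SolventTruth",
    "TrueParams",
    "SimConfig",
    "dose_response_function",
    "geometric_doses",
    "simulate_od_curve",
    "simulate_assay",
    "default_true_params",
    "CONTROL_SOLVENT",
]

#: Solvent label used for no-solvent control series.
CONTROL_SOLVENT = "none"

Shape = Literal["linear", "logistic"]


@dataclass(frozen=True)
class SpeciesTruth:
    """Growth-curve truth for one species.

    All concentrations of one species share ``lag_h`` and the phase
    timing; only the exponential rate responds to solvent.
    """

    name: str
    mu0: float  # h⁻¹
    lag_h: float = 2.0
    od0: float = 0.02
    od_max: float = 0.8

    def __post_init__(self) -> None:
        if self.mu0 <= 0:
            raise ValueError("mu0 must be > 0")
        if self.od_max <= self.od0:
            raise ValueError("stationary OD must exceed initial OD")
        if self.lag_h < 0 or self.od0 <= 0:
            raise ValueError("lag_h must be >= 0 and od0 > 0")


@dataclass(frozen=True)
class SolventTruth:
    """Dose-response truth for one species × solvent pair."""

    ec50: float  # mmol L⁻¹
    shape: Shape = "logistic"
    hill: float = 2.0

    def __post_init__(self) -> None:
        if self.ec50 <= 0:
            raise ValueError("ec50 must be > 0")
        if self.shape not in ("linear", "logistic"):
            raise ValueError(f"unknown dose-response shape {self.shape!r}")
        if self.hill <= 0:
            raise ValueError("hill slope must be > 0")


@dataclass(frozen=True)
class TrueParams:
    """Full ground truth for a panel: species × solvent."""

    species: tuple[SpeciesTruth, ...]
    response: Mapping[str, Mapping[str, SolventTruth]]  # species → solvent → truth

    def __post_init__(self) -> None:
        names = {s.name for s in self.species}
        for sp in self.response:
            if sp not in names:
                raise ValueError(f"response truth for unknown species {sp!r}")


@dataclass(frozen=True)
class SimConfig:
    """Assay layout and noise model.

    Defaults mirror the tube-assay design the analysis expects: five
    non-zero concentrations plus a no-solvent control, in triplicate,
    with additive OD noise of SD 0.005.  ``concentrations`` may fix the
    dose series per solvent; when absent, a geometric series bracketing
    each pair's true EC50 is generated (``dose_ratio`` spacing).  The
    seed is mandatory: a simulated assay must be reproducible.
    """

    seed: int
    replicates: int = 3
    n_concentrations: int = 5
    dose_ratio: float = 2.0
    concentrations: Mapping[str, Sequence[float]] | None = None
    n_timepoints: int = 13
    noise_sd: float = 0.005

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_concentrations < 2:
            raise ValueError("need at least 2 non-zero concentrations")


def dose_response_function(c: float, ec50: float, shape: Shape = "logistic", hill: float = 2.0) -> float:
    """Fraction of μ0 retained at dissolved concentration ``c``.

    ``linear``: max(0, 1 − c/(2·EC50)); ``logistic``: 1/(1 + (c/EC50)^h).
    Both give f(0) = 1 and f(EC50) = 1/2 exactly.
    """
    if c < 0:
        raise ValueError("concentration must be >= 0")
    if c == 0:
        return 1.0
    if shape == "linear":
        return max(0.0, 1.0 - c / (2.0 * ec50))
    return 1.0 / (1.0 + (c / ec50) ** hill)


def geometric_doses(ec50: float, n: int = 5, ratio: float = 2.0) -> np.ndarray:
    """Geometric concentration series centred on a target EC50."""
    centre = (n - 1) / 2.0
    return ec50 * ratio ** (np.arange(n) - centre)


def _sample_times(sp: SpeciesTruth, n: int) -> np.ndarray:
    # span: lag plus 1.2× the control's time to plateau, so controls
    # plateau within the record and inhibited cultures stay in log phase
    t_plateau = sp.lag_h + math.log(sp.od_max / sp.od0) / sp.mu0
    return np.linspace(0.0, sp.lag_h + 1.2 * (t_plateau - sp.lag_h), n)


def _clean_curve(sp: SpeciesTruth, mu: float, times: np.ndarray) -> np.ndarray:
    od = np.full_like(times, sp.od0, dtype=float)
    growing = times > sp.lag_h
    od[growing] = sp.od0 * np.exp(mu * (times[growing] - sp.lag_h))
    return np.minimum(od, sp.od_max)


def simulate_od_curve(
    sp: SpeciesTruth,
    solvent: str,
    truth: SolventTruth | None,
    concentration: float,
    replicate: str,
    config: SimConfig,
    rng: np.random.Generator,
) -> ODSeries:
    """One noisy OD600 time course at a given dissolved concentration.

    ``truth=None`` (or concentration 0) simulates a no-solvent control.
    Noise is additive Gaussian per reading, truncated at 0 OD.
    """
    frac = 1.0 if truth is None or concentration == 0 else dose_response_function(
        concentration, truth.ec50, truth.shape, truth.hill
    )
    times = _sample_times(sp, config.n_timepoints)
    od = _clean_curve(sp, sp.mu0 * frac, times)
    if config.noise_sd > 0:
        od = np.maximum(od + rng.normal(0.0, config.noise_sd, od.shape), 0.0)
    return ODSeries(sp.name, solvent, float(concentration), replicate, times, od)


def simulate_assay(panel: TrueParams, config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a full factorial assay and return (od, truth) tables.

    The OD table is in the long CSV dialect the readers consume
    (``time_h, species, solvent, conc_mM, replicate, od600``), with one
    shared no-solvent control set per species (all solvents of a species
    are assayed in the same batch).  The truth table carries μ0_true and
    EC50_true per species × solvent for recovery scoring.  Identical
    seed and config give identical tables.
    """
    rng = np.random.default_rng(config.seed)
    od_rows: list[pd.DataFrame] = []
    truth_rows: list[dict] = []

    def emit(series: ODSeries) -> None:
        od_rows.append(
            pd.DataFrame(
                {
                    "time_h": series.times,
                    "species": series.species,
                    "solvent": series.solvent,
                    "conc_mM": series.concentration,
                    "replicate": series.replicate,
                    "od600": series.od,
                }
            )
        )

    for sp in panel.species:
        for r in range(config.replicates):
            emit(simulate_od_curve(sp, CONTROL_SOLVENT, None, 0.0, f"r{r + 1}", config, rng))
        for solvent, truth in panel.response.get(sp.name, {}).items():
            if config.concentrations is not None and solvent in config.concentrations:
                concs = np.asarray(config.concentrations[solvent], dtype=float)
            else:
                concs = geometric_doses(truth.ec50, config.n_concentrations, config.dose_ratio)
            truth_rows.append(
                {
                    "species": sp.name,
                    "solvent": solvent,
                    "mu0_true": sp.mu0,
                    "ec50_true": truth.ec50,
                    "shape": truth.shape,
                    "hill": truth.hill,
                }
            )
            for c in concs:
                for r in range(config.replicates):
                    emit(simulate_od_curve(sp, solvent, truth, float(c), f"r{r + 1}", config, rng))

    od = pd.concat(od_rows, ignore_index=True)
    truth = pd.DataFrame(truth_rows)
    return od, truth


def default_true_params() -> TrueParams:
    """An eight-species, four-solvent panel of plausible truths.

    μ0 spans fast fermenters (stationary in ~5 h) to slow sulfate
    reducers (~70 h); EC50s echo the curated reference panel's ordering:
    1,2-DCA mildest, CT and PCE harshest, respirers more sensitive than
    fermenters.
    """
    species = (
        SpeciesTruth("E. coli", 0.80),
        SpeciesTruth("Klebsiella sp.", 1.00),
        SpeciesTruth("Clostridium sp.", 0.35),
        SpeciesTruth("Paenibacillus sp.", 0.30),
        SpeciesTruth("P. aeruginosa", 0.50),
        SpeciesTruth("S. oneidensis", 0.25),
        SpeciesTruth("G. sulfurreducens", 0.10, lag_h=4.0),
        SpeciesTruth("D. vulgaris", 0.08, lag_h=4.0),
    )
    ec50 = {
        "E. coli": {"PCE": 2.0, "CT": 1.5, "CF": 6.0, "1,2-DCA": 15.0},
        "Klebsiella sp.": {"PCE": 4.95, "CT": 2.0, "CF": 8.0, "1,2-DCA": 23.0},
        "Clostridium sp.": {"PCE": 1.2, "CT": 0.8, "CF": 4.5, "1,2-DCA": 9.0},
        "Paenibacillus sp.": {"PCE": 1.0, "CT": 2.4, "CF": 4.0, "1,2-DCA": 8.0},
        "P. aeruginosa": {"PCE": 1.5, "CT": 0.5, "CF": 5.0, "1,2-DCA": 12.0},
        "S. oneidensis": {"PCE": 0.6, "CT": 0.04, "CF": 3.8, "1,2-DCA": 7.5},
        "G. sulfurreducens": {"PCE": 0.35, "CT": 0.015, "CF": 0.2, "1,2-DCA": 6.5},
        "D. vulgaris": {"PCE": 0.3, "CT": 0.04, "CF": 0.1, "1,2-DCA": 6.5},
    }
    response = {
        sp: {solv: SolventTruth(v) for solv, v in by_solv.items()}
        for sp, by_solv in ec50.items()
    }
    return TrueParams(species, response)
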