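"""Monte Carlo dosing simulation: probability of target attainment.

For each candidate regimen (dose, interval, 30-min infusion) and each
renal-function level, virtual subjects are drawn from the population
distribution with clearance scaled to the given creatinine clearance,
and first-course exposures are computed in closed form:

* Cmax — concentration 1 h after the start of the infusion;
* Cmin — concentration 30 min before the second dose (23.5, 47.5 or
  71.5 h after the start for q24h, q48h, q72h).

Targets are the aminoglycoside efficacy index Cmax/MIC >= 8 and the
nephrotoxicity-avoidance trough Cmin < 4 mg/L; the joint attainment
(both on the same virtual subject) drives regimen selection.  The
fractional target attainment weights the joint attainment by an
observed MIC frequency distribution for a pathogen.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from numpy.typing import NDArray

from .pk_model import DoseEvent, one_compartment_grid
from .population import PopulationModel

__all__ = [
    "Regimen",
    "TargetDefinition",
    "ExposureSamples",
    "MICDistribution",
    "PTAGrid",
    "simulate_exposures",
    "pta",
    "fta",
    "pta_table",
]

DEFAULT_DOSES = tuple(range(200, 2001, 200))
DEFAULT_INTERVALS = (24.0, 48.0, 72.0)
DEFAULT_CCRS = tuple(range(10, 91, 10))
DEFAULT_MICS = (4.0, 8.0, 16.0)


@dataclass(frozen=True)
class Regimen:
    """One candidate dosing regimen: dose every ``interval_h`` hours."""

    dose_mg: float
    interval_h: float
    infusion_h: float = 0.5

    def __post_init__(self) -> None:
        if self.dose_mg <= 0 or self.infusion_h <= 0:
            raise ValueError("dose and infusion duration must be positive")
        if self.interval_h not in (24.0, 48.0, 72.0):
            raise ValueError("interval must be 24, 48 or 72 h")

    @property
    def label(self) -> str:
        return f"{self.dose_mg:g} mg q{self.interval_h:g}h"


@dataclass(frozen=True)
class TargetDefinition:
    """PK/PD targets: efficacy Cmax/MIC threshold and safety trough cap."""

    efficacy_ratio: float = 8.0
    safety_cmin: float = 4.0
    safety_strict: bool = True  # Cmin < cap (default) vs Cmin <= cap

    def __post_init__(self) -> None:
        if self.efficacy_ratio <= 0 or self.safety_cmin <= 0:
            raise ValueError("targets must be positive")


@dataclass(frozen=True)
class ExposureSamples:
    """Simulated first-course (Cmax, Cmin) pairs for virtual subjects."""

    cmax: NDArray[np.float64]
    cmin: NDArray[np.float64]

    def __post_init__(self) -> None:
        cmax = np.asarray(self.cmax, dtype=float)
        cmin = np.asarray(self.cmin, dtype=float)
        object.__setattr__(self, "cmax", cmax)
        object.__setattr__(self, "cmin", cmin)
        if cmax.shape != cmin.shape:
            raise ValueError("cmax and cmin must align")

    def __len__(self) -> int:
        return int(self.cmax.size)


@dataclass(frozen=True)
class MICDistribution:
    """MIC frequency distribution for a pathogen.

    Frequencies must be non-negative and sum to one (within 1e-9);
    MICs strictly increasing.
    """

    mics: NDArray[np.float64]
    frequencies: NDArray[np.float64]

    def __post_init__(self) -> None:
        m = np.asarray(self.mics, dtype=float)
        f = np.asarray(self.frequencies, dtype=float)
        object.__setattr__(self, "mics", m)
        object.__setattr__(self, "frequencies", f)
        if m.shape != f.shape or m.ndim != 1 or m.size == 0:
            raise ValueError("mics and frequencies must be equal-length 1-d")
        if np.any(m <= 0) or np.any(np.diff(m) <= 0):
            raise ValueError("MICs must be positive and strictly increasing")
        if np.any(f < 0) or abs(f.sum() - 1.0) > 1e-9:
            raise ValueError("frequencies must be non-negative and sum to 1")

    @classmethod
    def from_csv(cls, path: str | Path) -> "MICDistribution":
        """Read a two-column CSV with header ``mic,frequency``."""
        df = pd.read_csv(path, comment="#")
        if not {"mic", "frequency"} <= set(df.columns):
            raise ValueError("MIC CSV needs columns 'mic' and 'frequency'")
        return cls(df["mic"].to_numpy(), df["frequency"].to_numpy())

    @classmethod
    def from_json(cls, path: str | Path) -> "MICDistribution":
        """Read ``{"mic": [...], "frequency": [...]}`` from JSON."""
        obj = json.loads(Path(path).read_text())
        return cls(np.asarray(obj["mic"]), np.asarray(obj["frequency"]))

    @classmethod
    def example_pseudomonas(cls) -> "MICDistribution":
        """Bundled synthetic example distribution (wild-type-like shape).

        A stand-in constructed for testing and demonstration; it is not
        surveillance data and carries no claim about any real species.
        """
        path = Path(__file__).parent / "data" / "synthetic_pa_mic.csv"
        return cls.from_csv(path)


def simulate_exposures(
    pop: PopulationModel,
    regimen: Regimen,
    ccr: float,
    n: int = 1000,
    seed: int | np.random.Generator = 0,
) -> ExposureSamples:
    """Simulate n first-course exposures at a fixed creatinine clearance.

    Individual (CLs, V) pairs are drawn from the population
    distribution; clearance is scaled by ccr over the model's reference
    value.  Cmax is evaluated 1 h after the start of the first
    infusion, Cmin 30 min before the second dose.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if ccr <= 0:
        raise ValueError("ccr must be positive")
    rng = np.random.default_rng(seed)
    params = pop.sample(n, rng)
    cov = getattr(pop, "covariate_model", None)
    cl = params[:, 0] * (ccr / cov.reference_ccr if cov is not None else 1.0)
    doses = [DoseEvent(0.0, regimen.dose_mg, regimen.infusion_h)]
    times = np.array([1.0, regimen.interval_h - 0.5])
    conc = one_compartment_grid(cl, params[:, 1], doses, times)
    return ExposureSamples(cmax=conc[:, 0], cmin=conc[:, 1])


def pta(
    samples: ExposureSamples,
    mic: float,
    targets: TargetDefinition = TargetDefinition(),
) -> tuple[float, float, float]:
    """Attainment percentages (efficacy, safety, joint) for one MIC.

    efficacy = % of draws with Cmax/MIC >= efficacy_ratio;
    safety = % with Cmin below the trough cap;
    joint = % meeting both on the same draw (never above either).
    """
    if mic <= 0:
        raise ValueError("mic must be positive")
    if len(samples) == 0:
        raise ValueError("samples must be non-empty")
    eff = samples.cmax / mic >= targets.efficacy_ratio
    if targets.safety_strict:
        safe = samples.cmin < targets.safety_cmin
    else:
        safe = samples.cmin <= targets.safety_cmin
    return (
        100.0 * float(eff.mean()),
        100.0 * float(safe.mean()),
        100.0 * float((eff & safe).mean()),
    )


def fta(pta_by_mic: dict[float, float], dist: MICDistribution) -> float:
    """Fractional target attainment: frequency-weighted attainment.

    Every MIC in the distribution must have a computed attainment entry
    (no interpolation); the result is sum over MICs of
    frequency(m) * attainment(m), in percent.
    """
    missing = [m for m in dist.mics if float(m) not in pta_by_mic]
    if missing:
        raise ValueError(f"no attainment entry for MIC(s) {missing}")
    values = np.array([pta_by_mic[float(m)] for m in dist.mics])
    return float(dist.frequencies @ values)


@dataclass(frozen=True)
class PTAGrid:
    """Tidy attainment table over (CCr, dose, interval) x MIC.

    One row per cell and MIC with efficacy, safety and joint attainment
    percentages; the safety column does not depend on the MIC.  The
    base seed and per-cell spawn index are recorded for exact re-runs.
    """

    table: pd.DataFrame
    n_per_cell: int
    seed: int
    targets: TargetDefinition = field(default_factory=TargetDefinition)

    def wide(self, mic: float, value: str = "joint_pct",
             interval_h: float | None = None) -> pd.DataFrame:
        """Dose-by-CCr layout for one MIC (and optionally one interval)."""
        sub = self.table[self.table["mic"] == mic]
        if interval_h is not None:
            sub = sub[sub["interval_h"] == interval_h]
            return sub.pivot(index="ccr", columns="dose_mg", values=value)
        return sub.pivot(index=["interval_h", "ccr"], columns="dose_mg",
                         values=value)

    def cell(self, ccr: float, dose_mg: float, interval_h: float,
             mic: float) -> pd.Series:
        t = self.table
        row = t[(t["ccr"] == ccr) & (t["dose_mg"] == dose_mg)
                & (t["interval_h"] == interval_h) & (t["mic"] == mic)]
        if row.empty:
            raise KeyError((ccr, dose_mg, interval_h, mic))
        return row.iloc[0]


def pta_table(
    pop: PopulationModel,
    doses: tuple[float, ...] = DEFAULT_DOSES,
    intervals: tuple[float, ...] = DEFAULT_INTERVALS,
    ccr_values: tuple[float, ...] = DEFAULT_CCRS,
    mics: tuple[float, ...] = DEFAULT_MICS,
    targets: TargetDefinition = TargetDefinition(),
    n: int = 1000,
    seed: int = 0,
    infusion_h: float = 0.5,
) -> PTAGrid:
    """Full factorial Monte Carlo attainment grid.

    Each (CCr, dose, interval) cell gets an independent, reproducible
    random stream spawned from the base seed; all MICs for a cell are
    evaluated on the same draws.
    """
    if not (doses and intervals and ccr_values and mics):
        raise ValueError("all grids must be non-empty")
    ss = np.random.SeedSequence(seed)
    rows = []
    cell_index = 0
    for ccr in ccr_values:
        for interval in intervals:
            for dose in doses:
                rng = np.random.default_rng(ss.spawn(1)[0])
                regimen = Regimen(float(dose), float(interval), infusion_h)
                samples = simulate_exposures(pop, regimen, float(ccr), n, rng)
                for mic in mics:
                    eff, safe, joint = pta(samples, float(mic), targets)
                    rows.append(
                        {"ccr": float(ccr), "dose_mg": float(dose),
                         "interval_h": float(interval), "mic": float(mic),
                         "efficacy_pct": eff, "safety_pct": safe,
                         "joint_pct": joint, "cell_index": cell_index}
                    )
                cell_index += 1
    return PTAGrid(table=pd.DataFrame(rows), n_per_cell=n, seed=seed,
                   targets=targets)
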