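"""Frame-level quantities: counts, viability, concentration, replicate CV,
and the viability-calibration regression.

Viability is 100 * live / (live + dead); debris never enter cell totals.
Concentration converts the per-image cell count to cells/ml through an
instrument calibration factor: the reference pairing is 437 counted cells
corresponding to 1e6 cells/ml for the supported counting slide.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .classify import ClassifiedObject

#: cells/ml represented by one counted cell, from the 437 cells <-> 1e6
#: cells/ml reference pairing of the supported counting slide geometry.
DEFAULT_VOLUME_FACTOR = 1e6 / 437.0


@dataclass
class CountResult:
    n_live: int
    n_dead: int
    n_debris: int
    n_total_cells: int
    viability_pct: Optional[float]
    concentration_cells_per_ml: float
    objects: List[ClassifiedObject]

    def summary_dict(self) -> dict:
        return {
            "n_live": self.n_live,
            "n_dead": self.n_dead,
            "n_debris": self.n_debris,
            "n_total_cells": self.n_total_cells,
            "viability_pct": self.viability_pct,
            "concentration_cells_per_ml": self.concentration_cells_per_ml,
        }

    def objects_frame(self) -> pd.DataFrame:
        rows = []
        for obj in self.objects:
            row = obj.features.as_dict()
            row["label"] = obj.label
            row["rule_fired"] = obj.rule_fired
            rows.append(row)
        return pd.DataFrame(rows)

    def write(self, out_dir: str | Path, stem: str = "count") -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / f"{stem}_summary.json").write_text(json.dumps(self.summary_dict(), indent=2))
        self.objects_frame().to_csv(out / f"{stem}_objects.csv", index=False)


@dataclass(frozen=True)
class CalibrationResult:
    slope: float
    intercept: float
    r_squared: float
    points: List[Tuple[float, float]]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "slope": self.slope,
                    "intercept": self.intercept,
                    "r_squared": self.r_squared,
                    "points": [list(p) for p in self.points],
                },
                indent=2,
            )
        )


def summarize(
    classified: Sequence[ClassifiedObject],
    volume_factor: float = DEFAULT_VOLUME_FACTOR,
) -> CountResult:
    """Tally labels into counts, viability % and concentration.

    An empty frame has no defined viability; it is reported as missing
    (``None``) with a warning, never as 0% or 100%.
    """
    if volume_factor <= 0:
        raise ValueError("volume_factor must be positive")
    n_live = sum(1 for c in classified if c.label == "live")
    n_dead = sum(1 for c in classified if c.label == "dead")
    n_debris = sum(1 for c in classified if c.label == "debris")
    n_total = n_live + n_dead
    if n_total > 0:
        viability: Optional[float] = 100.0 * n_live / n_total
    else:
        warnings.warn("no cells detected: viability undefined", stacklevel=2)
        viability = None
    return CountResult(
        n_live=n_live,
        n_dead=n_dead,
        n_debris=n_debris,
        n_total_cells=n_total,
        viability_pct=viability,
        concentration_cells_per_ml=n_total * volume_factor,
        objects=list(classified),
    )


def cv_of_counts(counts: Sequence[float]) -> float:
    """Coefficient of variation (%) of replicate counts.

    Sample (n-1) standard deviation over the mean, the conventional
    replicate-dispersion statistic.
    """
    arr = np.asarray(counts, dtype=np.float64)
    if arr.size < 2:
        raise ValueError("need at least two counts")
    if np.any(arr < 0):
        raise ValueError("counts must be non-negative")
    mean = arr.mean()
    if mean <= 0:
        raise ValueError("CV undefined: mean of counts is zero")
    return float(100.0 * arr.std(ddof=1) / mean)


def calibrate_viability(
    points: Sequence[Tuple[float, float]],
) -> CalibrationResult:
    """OLS fit of measured viability against theoretical viability.

    ``points`` are (theoretical_pct, measured_pct) pairs from a dilution
    design such as the five-level {0, 25, 50, 75, 100}% series. Returns the
    fitted line and R^2 (squared Pearson correlation).
    """
    pts = [(float(t), float(m)) for t, m in points]
    if len(pts) < 3:
        raise ValueError("need at least 3 calibration points")
    theo = np.array([p[0] for p in pts])
    meas = np.array([p[1] for p in pts])
    if np.allclose(theo, theo[0]):
        raise ValueError("degenerate design: all theoretical viabilities identical")
    fit = stats.linregress(theo, meas)
    return CalibrationResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        points=pts,
    )
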