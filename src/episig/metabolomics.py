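"""Biolog Phenotype Mammalian MicroArray (PM-M) statistics.

PM-M plates read out NADH-dependent dye reduction per well: plates
PM-M1..M4 vary the energy source, PM-M5..M8 vary metabolic effectors
(ions, hormones, growth factors, cytokines), and a custom tryptophan
plate contributes 8 analyzed well contents per line, for 776 analyzed
wells in total. Per well the endpoint relative absorbance (A590 - A750)
is normalized against the triplicate blank-plate readings and log10
transformed; case and control cell lines are compared per well with a
two-sided Mann-Whitney test and BH correction across all analyzed wells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .differential import adjust_bh

PLATES_ENERGY = ("PM-M1", "PM-M2", "PM-M3", "PM-M4")
PLATES_EFFECTOR = ("PM-M5", "PM-M6", "PM-M7", "PM-M8")
TRP_PLATE = "PM-Trp"
#: analyzed contents of the tryptophan plate (one well per content per line)
TRP_CONTENTS = (
    "alpha-D-Glucose",
    "Negative control (empty)",
    "L-Tryptophan",
    "Trp-Gly",
    "Trp-Lys",
    "Trp-Leu",
    "Trp-Arg",
    "Trp-Ala",
)

ROWS = "ABCDEFGH"


@dataclass
class PlateLayout:
    """Well -> compound map over the analyzed PM-M plates.

    Eight 96-well plates (PM-M1..M8) plus 8 analyzed tryptophan-plate
    wells give 776 analyzed wells per cell line. Kinetic series are read
    every 15 minutes for 24 h (96 timepoints).
    """

    n_timepoints: int = 96
    dt_minutes: float = 15.0
    compounds: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.compounds:
            for plate in PLATES_ENERGY + PLATES_EFFECTOR:
                for row in ROWS:
                    for col in range(1, 13):
                        well = f"{row}{col}"
                        self.compounds[(plate, well)] = f"{plate} {well}"
            for i, content in enumerate(TRP_CONTENTS):
                self.compounds[(TRP_PLATE, f"A{i+1}")] = content

    @property
    def plates(self) -> list[str]:
        return list(PLATES_ENERGY + PLATES_EFFECTOR) + [TRP_PLATE]

    def wells(self, plate: str) -> list[str]:
        return [w for (p, w) in self.compounds if p == plate]

    @property
    def analyzed_wells(self) -> list[tuple[str, str]]:
        return list(self.compounds.keys())

    @property
    def n_analyzed(self) -> int:
        return len(self.compounds)

    def plate_group(self, plate: str) -> str:
        if plate in PLATES_ENERGY:
            return "energy (M1-M4)"
        if plate == "PM-M5":
            return "ions (M5)"
        if plate in ("PM-M6", "PM-M7", "PM-M8"):
            return "hormones/cytokines (M6-M8)"
        return "tryptophan (Trp)"


@dataclass
class PlateRun:
    """One plate read for one cell line: endpoint A590/A750 per well and
    an optional wells x timepoints kinetic OD matrix."""

    line_id: str
    plate: str
    group: str  # case | control | blank
    endpoints: pd.DataFrame  # index well, columns a590/a750
    kinetics: pd.DataFrame | None = None

    def relative_absorbance(self) -> pd.Series:
        return self.endpoints["a590"] - self.endpoints["a750"]


def relative_absorbance(a590, a750):
    """Endpoint relative absorbance A590-750 = A590 - A750."""
    if isinstance(a590, pd.Series):
        return a590 - a750
    out = np.asarray(a590, dtype=float) - np.asarray(a750, dtype=float)
    return float(out) if out.ndim == 0 else out


def normalize_to_blank(values: pd.Series, blanks: list[pd.Series], floor: float = 1e-3) -> pd.Series:
    """Subtract the mean of the (triplicate) blank readings per well, floor
    the difference at ``floor`` and log10 transform."""
    if len(blanks) != 3:
        warnings.warn(f"expected triplicate blanks, got {len(blanks)}; using available mean")
    blank_mean = pd.concat(blanks, axis=1).mean(axis=1)
    diff = values - blank_mean.reindex(values.index)
    return np.log10(np.maximum(diff, floor))


def kinetic_params(series, dt_minutes: float = 15.0) -> tuple[float, float, float]:
    """(slope, endpoint, auc) of one kinetic OD series.

    slope: least-squares OD/hour; endpoint: final OD; auc: trapezoidal
    integral in OD*hour over the full incubation.
    """
    y = np.asarray(series, dtype=float)
    if y.size < 2:
        raise ValueError("kinetic series needs at least 2 points")
    t = np.arange(y.size) * dt_minutes / 60.0
    slope = float(np.polyfit(t, y, 1)[0])
    return slope, float(y[-1]), float(np.trapezoid(y, t))


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U: exact enumeration for small untied
    samples (n_x + n_y <= 12), normal approximation with tie and
    continuity correction otherwise. Returns (U of x, two-sided p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return x.size * y.size / 2.0, 1.0
    has_ties = len(np.unique(pooled)) < pooled.size
    if x.size + y.size <= 12 and not has_ties:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    return float(res.statistic), float(min(res.pvalue, 1.0))


class PlateComparison:
    """Per-well case-vs-control comparison across a plate panel.

    Parameters
    ----------
    case_runs, control_runs : lists of :class:`PlateRun` covering the
        layout's plates for each cell line.
    blanks : mapping plate -> list of blank PlateRuns (triplicate).
    layout : :class:`PlateLayout`.
    """

    def __init__(self, case_runs, control_runs, blanks, layout: PlateLayout | None = None):
        self.case_runs = list(case_runs)
        self.control_runs = list(control_runs)
        self.blanks = blanks
        self.layout = layout or PlateLayout()
        for name, runs in (("case", self.case_runs), ("control", self.control_runs)):
            if len({r.line_id for r in runs}) < 2:
                raise ValueError(f"need at least 2 {name} lines")

    def _normalized_matrix(self, runs: list[PlateRun]) -> pd.DataFrame:
        """(plate, well) x line matrix of blank-normalized log endpoints."""
        values: dict[str, dict[tuple[str, str], float]] = {}
        for run in runs:
            blanks = [b.relative_absorbance() for b in self.blanks.get(run.plate, [])]
            if not blanks:
                raise ValueError(f"no blank runs for plate {run.plate}")
            norm = normalize_to_blank(run.relative_absorbance(), blanks)
            col = values.setdefault(run.line_id, {})
            for well, v in norm.items():
                if (run.plate, well) in self.layout.compounds:
                    col[(run.plate, well)] = v
        df = pd.DataFrame(values)
        return df.sort_index()

    def fit(self, alpha: float = 0.05) -> "PlateComparisonResults":
        case = self._normalized_matrix(self.case_runs)
        control = self._normalized_matrix(self.control_runs)
        wells = sorted(self.layout.analyzed_wells)
        missing = [w for w in wells if w not in case.index or w not in control.index]
        if missing:
            warnings.warn(f"{len(missing)} analyzed wells missing from the runs; excluded")
        rows = []
        for key in wells:
            if key in missing:
                continue
            plate, well = key
            x = case.loc[[key]].to_numpy().ravel()
            y = control.loc[[key]].to_numpy().ravel()
            x = x[~np.isnan(x)]
            y = y[~np.isnan(y)]
            U, p = mann_whitney(x, y)
            mean_case, mean_control = float(x.mean()), float(y.mean())
            rows.append(
                {
                    "plate": plate,
                    "well": well,
                    "compound": self.layout.compounds[key],
                    "mean_case": mean_case,
                    "mean_control": mean_control,
                    "direction": "lower" if mean_case < mean_control else "higher",
                    "U": U,
                    "p": p,
                }
            )
        table = pd.DataFrame(rows)
        table["q"] = adjust_bh(table["p"].to_numpy())
        return PlateComparisonResults(table, self.layout, alpha=alpha)


class PlateComparisonResults:
    """Per-well test table plus significant-well summaries."""

    def __init__(self, table: pd.DataFrame, layout: PlateLayout, alpha: float = 0.05):
        self.table = table
        self.layout = layout
        self.alpha = alpha

    def significant(self, alpha: float | None = None) -> pd.DataFrame:
        alpha = self.alpha if alpha is None else alpha
        return self.table[self.table["q"] < alpha]

    def summary_dict(self, alpha: float | None = None) -> dict:
        alpha = self.alpha if alpha is None else alpha
        sig = self.significant(alpha)
        effector_block = self.table["plate"].isin(("PM-M6", "PM-M7", "PM-M8"))
        sig_block = sig["plate"].isin(("PM-M6", "PM-M7", "PM-M8"))
        return {
            "n_wells": int(len(self.table)),
            "n_significant": int(len(sig)),
            "fraction_significant": float(len(sig) / len(self.table)) if len(self.table) else 0.0,
            "n_lower": int((sig["direction"] == "lower").sum()),
            "n_higher": int((sig["direction"] == "higher").sum()),
            "m6_m8_wells": int(effector_block.sum()),
            "m6_m8_significant": int(sig_block.sum()),
            "by_plate": sig.groupby("plate").size().to_dict(),
        }

    def summary(self, alpha: float | None = None) -> str:
        d = self.summary_dict(alpha)
        lines = [
            "Phenotype-microarray comparison (endpoint relative absorbance)",
            f"  analyzed wells:            {d['n_wells']}",
            f"  significant (q < {self.alpha:g}):     {d['n_significant']} "
            f"({100 * d['fraction_significant']:.1f}%)",
            f"  direction lower / higher:  {d['n_lower']} / {d['n_higher']}",
            f"  PM-M6..M8 block:           {d['m6_m8_significant']} / {d['m6_m8_wells']}",
        ]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)
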