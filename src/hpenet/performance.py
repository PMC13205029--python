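"""Behavioural Performance Index from ISA ratings and reaction times.

Performance Index = (SME ISA / ATCO ISA) * (1 / ATCO RT): the expert rating
is the gold standard, the ratio re-weights the controller's reaction speed by
their self-assessment bias (ratio > 1 when the expert rates higher than the
controller, < 1 when lower).  SME ratings are given once per phase and
broadcast to every minute of that phase; ATCO ratings and RTs are per minute.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PHASES",
    "PerformanceSeries",
    "performance_index",
    "performance_series",
    "phase_attribution",
]

PHASES = ("HIGH", "BASELINE", "MALFUNCTION")


def _check_rating(value, name: str):
    arr = np.asarray(value)
    if not np.all(np.isin(arr, [1, 2, 3, 4, 5])):
        raise ValueError(f"{name} ratings must be integers in 1..5, got {arr}")


def performance_index(sme_isa, atco_isa, atco_rt) -> float:
    """Eq.-style scalar index for one minute; RT in seconds."""
    _check_rating(sme_isa, "SME ISA")
    _check_rating(atco_isa, "ATCO ISA")
    if atco_rt <= 0:
        raise ValueError(f"reaction time must be positive, got {atco_rt}")
    return (sme_isa / atco_isa) * (1.0 / atco_rt)


@dataclass
class PerformanceSeries:
    """Per-minute Performance Index with phase labels (RT unit: seconds)."""

    values: np.ndarray
    phases: tuple[str, ...]
    rt_unit: str = "s"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values <= 0):
            raise ValueError("Performance Index values must be positive")
        if len(self.phases) != len(self.values):
            raise ValueError("one phase label per minute is required")
        unknown = set(self.phases) - set(PHASES)
        if unknown:
            raise ValueError(f"unknown phase labels: {sorted(unknown)}")

    @property
    def n_minutes(self) -> int:
        return len(self.values)

    def phase_means(self) -> dict[str, float]:
        ph = np.asarray(self.phases)
        return {
            name: float(self.values[ph == name].mean())
            for name in PHASES
            if (ph == name).any()
        }


def performance_series(records: pd.DataFrame) -> PerformanceSeries:
    """Build the per-minute index from a behavioural table.

    Expects columns ``minute, phase, atco_isa, atco_rt_s, sme_isa`` with the
    per-phase SME rating already broadcast onto its minutes (constant within
    phase — validated here).
    """
    needed = {"minute", "phase", "atco_isa", "atco_rt_s", "sme_isa"}
    missing = needed - set(records.columns)
    if missing:
        raise ValueError(f"behavioural table lacks columns: {sorted(missing)}")
    df = records.sort_values("minute").reset_index(drop=True)
    for phase, grp in df.groupby("phase"):
        if grp["sme_isa"].nunique() > 1:
            raise ValueError(
                f"SME ISA must be constant within phase {phase!r} "
                "(it is rated once per phase)"
            )
    values = np.array(
        [
            performance_index(r.sme_isa, r.atco_isa, r.atco_rt_s)
            for r in df.itertuples()
        ]
    )
    return PerformanceSeries(values=values, phases=tuple(df["phase"]))


def phase_attribution(cohort: list[PerformanceSeries]) -> pd.DataFrame:
    """Where do the cohort's best/worst minutes fall, by phase?

    Tallies each subject's argmax and argmin minute (earliest on ties) by
    phase; each extremum's proportions sum to one.
    """
    counts = {"best": dict.fromkeys(PHASES, 0), "worst": dict.fromkeys(PHASES, 0)}
    for ps in cohort:
        counts["best"][ps.phases[int(np.argmax(ps.values))]] += 1
        counts["worst"][ps.phases[int(np.argmin(ps.values))]] += 1
    n = len(cohort)
    return pd.DataFrame(
        {ext: {ph: counts[ext][ph] / n for ph in PHASES} for ext in ("best", "worst")}
    )
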