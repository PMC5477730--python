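"""Plan-acceptance rules engine with three-level verdicts.

Each target-coverage objective classifies a metric (in percent of the
prescription) as *per protocol*, *variation acceptable*, or *deviation
unacceptable*; a plan is accepted iff no evaluated metric is an unacceptable
deviation.  The default objective set encodes the common head-and-neck
protocol:

=============  ============== ===================== =======================
metric         per protocol   variation acceptable  deviation unacceptable
=============  ============== ===================== =======================
D95%           100%           within +/-2%          beyond +/-2%
D5%            <=107%         <=110%                >110%
D98%           >=95%          >=90%                 <90%
hot spot       <=107%         <=110%                >110%
(0.03cm³ outside target)
=============  ============== ===================== =======================

D2% (a near-maximum volume percentile) is classified with the same bounds as
D5%.  A structure is additionally flagged *under-covered* when its D98% falls
below the 95% per-protocol level.  A packaged 14-case reference table of
CTV_L / CTV_Δ coverage values under soft-tissue-window-optimized plans is
shipped for the worked example (see :func:`run_table4_analysis`).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

__all__ = [
    "Level",
    "Objective",
    "ObjectiveSet",
    "MetricClassification",
    "PlanVerdict",
    "CoverageFlag",
    "default_objectives",
    "classify_metric",
    "evaluate_plan",
    "flag_under_coverage",
    "load_table4",
    "run_table4_analysis",
    "Table4Result",
]

UNDER_COVERAGE_THRESHOLD = 95.0  # % of prescription, D98 per-protocol level

#: Half-width absorbing one-decimal rounding when "per protocol" is a point
#: value (D95 = exactly 100%).
POINT_TOLERANCE = 0.05


class Level(enum.Enum):
    PER_PROTOCOL = "per_protocol"
    VARIATION_ACCEPTABLE = "variation_acceptable"
    DEVIATION_UNACCEPTABLE = "deviation_unacceptable"


@dataclass(frozen=True)
class Objective:
    """Three-level objective as nested inclusive ranges.

    ``None`` bounds are unbounded.  The per-protocol range must nest inside
    the variation-acceptable range so the three levels partition the axis;
    values outside the acceptable range are unacceptable deviations.
    Inclusive bounds mirror the protocol's non-strict inequalities, so a
    boundary value classifies into the better level.
    """

    metric: str
    pp_lo: float | None = None
    pp_hi: float | None = None
    va_lo: float | None = None
    va_hi: float | None = None

    def __post_init__(self) -> None:
        def lo_ok(inner, outer):
            return outer is None or (inner is not None and inner >= outer)

        def hi_ok(inner, outer):
            return outer is None or (inner is not None and inner <= outer)

        if not (lo_ok(self.pp_lo, self.va_lo) and hi_ok(self.pp_hi, self.va_hi)):
            raise ValueError(f"per-protocol range must nest in acceptable range ({self.metric})")

    def _within(self, value: float, lo: float | None, hi: float | None) -> bool:
        return (lo is None or value >= lo) and (hi is None or value <= hi)

    def classify(self, value: float) -> Level:
        if self._within(value, self.pp_lo, self.pp_hi):
            return Level.PER_PROTOCOL
        if self._within(value, self.va_lo, self.va_hi):
            return Level.VARIATION_ACCEPTABLE
        return Level.DEVIATION_UNACCEPTABLE


@dataclass
class ObjectiveSet:
    """Named collection of objectives, loadable from a YAML config."""

    objectives: dict[str, Objective]

    def __getitem__(self, metric: str) -> Objective:
        try:
            return self.objectives[metric]
        except KeyError:
            raise KeyError(f"no objective defined for metric {metric!r}") from None

    def __contains__(self, metric: str) -> bool:
        return metric in self.objectives

    @classmethod
    def from_yaml(cls, path) -> "ObjectiveSet":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        objs = {
            name: Objective(metric=name, **{k: v for k, v in spec.items()})
            for name, spec in raw.items()
        }
        return cls(objs)

    def to_yaml(self, path) -> None:
        raw = {
            name: {
                k: getattr(o, k)
                for k in ("pp_lo", "pp_hi", "va_lo", "va_hi")
                if getattr(o, k) is not None
            }
            for name, o in self.objectives.items()
        }
        Path(path).write_text(yaml.safe_dump(raw))


def default_objectives() -> ObjectiveSet:
    """The default coverage objectives (percent of prescription)."""
    return ObjectiveSet(
        {
            "d95": Objective(
                "d95",
                pp_lo=100.0 - POINT_TOLERANCE,
                pp_hi=100.0 + POINT_TOLERANCE,
                va_lo=98.0,
                va_hi=102.0,
            ),
            "d5": Objective("d5", pp_hi=107.0, va_hi=110.0),
            "d2": Objective("d2", pp_hi=107.0, va_hi=110.0),
            "d98": Objective("d98", pp_lo=95.0, va_lo=90.0),
            "hotspot": Objective("hotspot", pp_hi=107.0, va_hi=110.0),
        }
    )


@dataclass
class MetricClassification:
    metric: str
    value: float
    level: Level


@dataclass
class PlanVerdict:
    """Per-metric classifications and the resulting accept/reject decision.

    ``accepted`` is true iff no evaluated metric is an unacceptable
    deviation; metrics absent from the input are recorded in
    ``not_evaluated``.
    """

    classifications: dict[str, MetricClassification]
    not_evaluated: list[str] = field(default_factory=list)

    @property
    def accepted(self) -> bool:
        return all(
            c.level is not Level.DEVIATION_UNACCEPTABLE
            for c in self.classifications.values()
        )


@dataclass
class CoverageFlag:
    structure_id: str
    d98: float
    under_covered: bool


def classify_metric(
    value: float, metric: str, objectives: ObjectiveSet | None = None
) -> MetricClassification:
    """Classify one metric value at the tightest satisfied level."""
    objectives = objectives or default_objectives()
    obj = objectives[metric]
    return MetricClassification(metric=metric, value=value, level=obj.classify(value))


#: Metrics that must be present for a verdict; the rest are optional.
_REQUIRED_METRICS = ("d95", "d98")
_OPTIONAL_METRICS = ("d2", "d5", "hotspot")


def evaluate_plan(metrics, objectives: ObjectiveSet | None = None) -> PlanVerdict:
    """Accept/reject a plan from its coverage metrics.

    ``metrics`` is a mapping metric-name → value in % of prescription (a
    :class:`~ctvdelta.dosimetry.DoseMetrics` is accepted via ``as_mapping``).
    D5/D2/hot-spot are optional; when absent they are skipped and recorded.
    """
    if hasattr(metrics, "as_mapping"):
        metrics = metrics.as_mapping()
    objectives = objectives or default_objectives()
    missing = [m for m in _REQUIRED_METRICS if m not in metrics]
    if missing:
        raise KeyError(f"required metrics missing: {missing}")
    classifications = {}
    not_evaluated = []
    for name in (*_REQUIRED_METRICS, *_OPTIONAL_METRICS):
        if name in metrics and metrics[name] is not None:
            classifications[name] = classify_metric(metrics[name], name, objectives)
        elif name in _OPTIONAL_METRICS:
            not_evaluated.append(name)
    return PlanVerdict(classifications=classifications, not_evaluated=not_evaluated)


def flag_under_coverage(
    d98: float,
    threshold: float = UNDER_COVERAGE_THRESHOLD,
    structure_id: str = "",
) -> CoverageFlag:
    """Under-coverage flag: D98% strictly below the per-protocol level."""
    if d98 < 0:
        raise ValueError("d98 must be non-negative")
    return CoverageFlag(structure_id=structure_id, d98=d98, under_covered=d98 < threshold)


# ---------------------------------------------------------------------------
# packaged 14-case reference table
# ---------------------------------------------------------------------------

_TABLE4_COLUMNS = ("case", "ctvl_d2", "ctvl_d95", "ctvl_d98", "delta_d98")


def load_table4() -> pd.DataFrame:
    """The packaged 14-case CTV_L / CTV_Δ coverage table (percent values)."""
    with resources.files("ctvdelta.data").joinpath("table4.csv").open() as fh:
        return pd.read_csv(fh)


@dataclass
class CaseResult:
    case: int
    verdict: PlanVerdict
    delta_flag: CoverageFlag
    flagged_cells: frozenset  # subset of {"ctvl_d95", "ctvl_d98", "delta_d98"}


@dataclass
class Table4Result:
    per_case: list[CaseResult]
    accepted_ctvl: int
    under_covered_delta: int


def run_table4_analysis(fixture: pd.DataFrame | str | None = None) -> Table4Result:
    """Worked example on the packaged coverage table.

    Evaluates each case's CTV_L metrics against the default objectives and
    flags CTV_Δ under-coverage (D98% < 95%).  ``flagged_cells`` per case marks
    the cells a protocol report would annotate: an unacceptable CTV_L D95%, a
    CTV_L D98% below the per-protocol level, and an under-covered CTV_Δ.
    """
    if fixture is None:
        df = load_table4()
    elif isinstance(fixture, pd.DataFrame):
        df = fixture
    else:
        df = pd.read_csv(fixture)
    missing = set(_TABLE4_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"fixture is missing columns: {sorted(missing)}")
    objectives = default_objectives()
    per_case = []
    for row in df.itertuples(index=False):
        verdict = evaluate_plan(
            {"d2": row.ctvl_d2, "d95": row.ctvl_d95, "d98": row.ctvl_d98},
            objectives,
        )
        delta_flag = flag_under_coverage(row.delta_d98, structure_id=f"case{row.case}_delta")
        flags = set()
        if verdict.classifications["d95"].level is Level.DEVIATION_UNACCEPTABLE:
            flags.add("ctvl_d95")
        if flag_under_coverage(row.ctvl_d98).under_covered:
            flags.add("ctvl_d98")
        if delta_flag.under_covered:
            flags.add("delta_d98")
        per_case.append(
            CaseResult(
                case=int(row.case),
                verdict=verdict,
                delta_flag=delta_flag,
                flagged_cells=frozenset(flags),
            )
        )
    return Table4Result(
        per_case=per_case,
        accepted_ctvl=sum(c.verdict.accepted for c in per_case),
        under_covered_delta=sum(c.delta_flag.under_covered for c in per_case),
    )
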