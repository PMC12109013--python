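"""Ki67-interval evaluation protocol.

The Ki67 range is split into six clinically motivated intervals that form a
hierarchy: <0,1> splits into <0,0.5) and <0.5,1>; <0,0.5) splits into
<0,0.2) and <0.2,0.5); <0,0.2) splits into <0,0.1) and <0.1,0.2).  All
bounds are half-open (lower inclusive) except the top interval <0.5,1>,
which includes 1.  Real and generated image sets are assigned to intervals
by their Ki67 labels, cross FID/FHD matrices are computed between interval
sets, and each cell carries an expectation derived from the pair's set
relation: identical intervals should be closest (the diagonal), nested
(subset) pairs relatively close, and complementary (disjoint) pairs far.
The violation detector reports cells that contradict those expectations,
mirroring the red-text convention of the corresponding result tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import metrics

__all__ = [
    "Ki67Interval",
    "IntervalRelation",
    "MetricMatrixReport",
    "PAPER_INTERVALS",
    "FULL_RANGE",
    "build_interval_hierarchy",
    "relation",
    "assign",
    "metric_matrix",
    "check_relations",
]


@dataclass(frozen=True)
class Ki67Interval:
    lower: float
    upper: float
    upper_inclusive: bool
    label: str

    def __post_init__(self):
        if not 0.0 <= self.lower < self.upper <= 1.0:
            raise ValueError(f"invalid interval bounds [{self.lower}, {self.upper}]")

    def contains(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        hi = (x <= self.upper) if self.upper_inclusive else (x < self.upper)
        return (x >= self.lower) & hi


FULL_RANGE = Ki67Interval(0.0, 1.0, True, "<0,1>")

#: The six evaluation intervals, ordered as in the result tables.
PAPER_INTERVALS: tuple[Ki67Interval, ...] = (
    Ki67Interval(0.5, 1.0, True, "<0.5,1>"),
    Ki67Interval(0.0, 0.5, False, "<0,0.5)"),
    Ki67Interval(0.2, 0.5, False, "<0.2,0.5)"),
    Ki67Interval(0.0, 0.2, False, "<0,0.2)"),
    Ki67Interval(0.1, 0.2, False, "<0.1,0.2)"),
    Ki67Interval(0.0, 0.1, False, "<0,0.1)"),
)

_BY_LABEL = {iv.label: iv for iv in PAPER_INTERVALS + (FULL_RANGE,)}


@dataclass(frozen=True)
class IntervalRelation:
    pair: tuple[str, str]
    relation: str  # identical | subset | complementary | overlapping


def relation(a: Ki67Interval, b: Ki67Interval) -> str:
    """Set relation between two intervals, derived from their bounds."""
    if (a.lower, a.upper, a.upper_inclusive) == (b.lower, b.upper, b.upper_inclusive):
        return "identical"
    a_in_b = a.lower >= b.lower and (
        a.upper < b.upper or (a.upper == b.upper and
                              (b.upper_inclusive or not a.upper_inclusive)))
    b_in_a = b.lower >= a.lower and (
        b.upper < a.upper or (b.upper == a.upper and
                              (a.upper_inclusive or not b.upper_inclusive)))
    if a_in_b or b_in_a:
        return "subset"
    lo, hi = (a, b) if a.lower <= b.lower else (b, a)
    disjoint = lo.upper < hi.lower or (lo.upper == hi.lower and not lo.upper_inclusive)
    return "complementary" if disjoint else "overlapping"


def build_interval_hierarchy() -> tuple[list[Ki67Interval], list[IntervalRelation]]:
    """The six evaluation intervals plus the full range, with all pairwise
    relations computed from bounds."""
    ivs = list(PAPER_INTERVALS) + [FULL_RANGE]
    rels = [IntervalRelation((a.label, b.label), relation(a, b))
            for i, a in enumerate(ivs) for b in ivs[i + 1:]]
    return ivs, rels


def assign(labels, interval: Ki67Interval) -> np.ndarray:
    """Indices of ``labels`` falling inside ``interval``."""
    labels = np.asarray(labels, dtype=np.float64)
    if np.any(labels < 0) or np.any(labels > 1):
        raise ValueError("Ki67 labels must lie in [0, 1]")
    return np.flatnonzero(interval.contains(labels))


@dataclass
class MetricMatrixReport:
    """Cross matrix of Fréchet distances between interval image sets."""

    row_labels: list[str]
    col_labels: list[str]
    values: np.ndarray               # float matrix; NaN marks missing cells
    flags: np.ndarray                # object matrix of expectation flags
    metric: str = "fid"
    violations: list[dict] = field(default_factory=list)

    def to_dataframe(self, decimals: int | None = 2) -> pd.DataFrame:
        vals = self.values if decimals is None else np.round(self.values, decimals)
        return pd.DataFrame(vals, index=self.row_labels, columns=self.col_labels)


def _expectation_flag(row: Ki67Interval, col: Ki67Interval) -> str:
    rel = relation(row, col)
    return {"identical": "diagonal", "subset": "expect-low",
            "complementary": "expect-high"}.get(rel, "none")


def metric_matrix(row_sets: dict[str, np.ndarray],
                  col_sets: dict[str, np.ndarray],
                  metric: str = "fid",
                  embedder=None) -> MetricMatrixReport:
    """Full cross matrix of FID/FHD values between labelled image sets.

    Keys must be interval labels from the hierarchy.  Each set is embedded
    once; cells whose either set has fewer than 2 images are reported as
    missing (NaN), never imputed.  When row and column sets are the same
    object the matrix is exactly symmetric by construction.
    """
    if metric not in ("fid", "fhd"):
        raise ValueError("metric must be 'fid' or 'fhd'")
    if embedder is None:
        if metric == "fhd":
            raise ValueError("fhd requires a trained histological embedder")
        from . import embedders
        embedder = embedders.RandomFeatureEmbedder(kind="visual", seed=7)

    def stats_of(sets):
        out = {}
        for label, imgs in sets.items():
            out[label] = metrics.fit_gaussian(embedder.embed(imgs)) \
                if len(imgs) >= 2 else None
        return out

    row_stats = stats_of(row_sets)
    col_stats = row_stats if col_sets is row_sets else stats_of(col_sets)

    rows, cols = list(row_sets), list(col_sets)
    values = np.full((len(rows), len(cols)), np.nan)
    flags = np.empty((len(rows), len(cols)), dtype=object)
    cache: dict[tuple[str, str], float] = {}
    for i, rl in enumerate(rows):
        for j, cl in enumerate(cols):
            flags[i, j] = _expectation_flag(_BY_LABEL[rl], _BY_LABEL[cl])
            a, b = row_stats[rl], col_stats[cl]
            if a is None or b is None:
                continue
            key = (cl, rl) if col_stats is row_stats else None
            if key in cache:
                values[i, j] = cache[key]
            else:
                values[i, j] = metrics.frechet(a, b)
                if col_stats is row_stats:
                    cache[(rl, cl)] = values[i, j]
    report = MetricMatrixReport(rows, cols, values, flags, metric=metric)
    report.violations = check_relations(report)
    return report


def check_relations(report: MetricMatrixReport, tol: float = 1e-9) -> list[dict]:
    """Cells contradicting the interval-relation expectations.

    Two row-wise rules: a diagonal cell must be its row minimum, and a
    complementary (expect-high) cell must not fall below any nested
    (expect-low) or diagonal cell of the same row.
    """
    violations: list[dict] = []
    for i, rl in enumerate(report.row_labels):
        row = report.values[i]
        frow = report.flags[i]
        diag = [j for j in range(len(row)) if frow[j] == "diagonal"]
        low_refs = [row[j] for j in range(len(row))
                    if frow[j] in ("expect-low", "diagonal") and np.isfinite(row[j])]
        if diag:
            dv = row[diag[0]]
            if np.isfinite(dv):
                for j, v in enumerate(row):
                    if j != diag[0] and np.isfinite(v) and v < dv - tol:
                        violations.append({"kind": "diagonal-not-row-min",
                                           "row": rl,
                                           "col": report.col_labels[j],
                                           "value": float(v),
                                           "diagonal": float(dv)})
        for j, v in enumerate(row):
            if frow[j] == "expect-high" and np.isfinite(v) and low_refs:
                below = [r for r in low_refs if v < r - tol]
                if below:
                    violations.append({"kind": "complement-below-subset",
                                       "row": rl,
                                       "col": report.col_labels[j],
                                       "value": float(v),
                                       "reference": float(max(below))})
    return violations


def load_table_fixture(name: str) -> MetricMatrixReport:
    """Load one of the transcribed result-table fixtures (table1..table4)."""
    from importlib import resources

    with resources.files("ki67gan.data").joinpath(f"{name}.csv").open() as fh:
        df = pd.read_csv(fh, index_col=0)
    rows, cols = list(df.index), list(df.columns)
    flags = np.array([[_expectation_flag(_BY_LABEL[r], _BY_LABEL[c])
                       for c in cols] for r in rows], dtype=object)
    metric = "fid" if name == "table1" else "fhd"
    report = MetricMatrixReport(rows, cols, df.to_numpy(dtype=np.float64),
                                flags, metric=metric)
    report.violations = check_relations(report)
    return report
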