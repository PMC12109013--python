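"""Ordinal analysis of pathologist realism ratings of generated sequences.

Two raters judged each Ki67-sweep sequence on a 5-level ordinal scale from
"certainly unreal" to "certainly real".  The analysis encodes verdicts as
0..4, measures inter-rater disagreement as the absolute difference of the
encoded levels, summarises the distance histogram and the consistent
fraction (distance <= 1 by default), and tabulates per-rater and combined
category counts.  The shipped fixture CSV is a hand transcription of the
two published rating tables (synthetic reproduction of printed data, not a
new expert evaluation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "VERDICTS",
    "RatingRecord",
    "ConsistencyReport",
    "encode_verdict",
    "load_ratings_fixture",
    "consistency",
    "summarize",
]

#: Ordinal scale, ordered unreal -> real; index is the encoded level.
VERDICTS = (
    "certainly unreal",
    "rather unreal",
    "partially real and unreal",
    "rather real",
    "certainly real",
)
_LEVEL = {v: i for i, v in enumerate(VERDICTS)}

#: Aggregate categories used by the summary tables.
CATEGORY_OF = {
    "certainly unreal": "unreal",
    "rather unreal": "unreal",
    "partially real and unreal": "partially",
    "rather real": "real",
    "certainly real": "real",
}


@dataclass(frozen=True)
class RatingRecord:
    group: int      # sequence group, 1 or 2
    sequence: int   # 1..20
    rater: int      # 1 or 2
    verdict: str


@dataclass
class ConsistencyReport:
    distances: pd.Series        # per-sequence |r1 - r2|
    histogram: dict[int, int]   # distance -> sequence count, keys 0..4
    consistent_fraction: float
    max_distance: int
    threshold: int


def encode_verdict(verdict: str) -> int:
    """Encode a verdict string on the ordinal 0..4 scale."""
    try:
        return _LEVEL[verdict]
    except KeyError:
        raise ValueError(
            f"unknown verdict {verdict!r}; valid verdicts: {list(VERDICTS)}"
        ) from None


def load_ratings_fixture(path: str | None = None) -> pd.DataFrame:
    """Load a ratings CSV (group, sequence, rater, verdict).

    With no path, loads the packaged transcription of the two published
    rating tables (40 records per group).
    """
    if path is None:
        from importlib import resources
        with resources.files("ki67gan.data").joinpath(
                "ratings_tables_6_9.csv").open() as fh:
            df = pd.read_csv(fh)
    else:
        df = pd.read_csv(path)
    bad = set(df["verdict"]) - set(VERDICTS)
    if bad:
        raise ValueError(f"unknown verdicts in ratings file: {sorted(bad)}")
    return df


def _group_table(records: pd.DataFrame, group: int) -> pd.DataFrame:
    g = records[records["group"] == group]
    table = g.pivot(index="sequence", columns="rater", values="verdict")
    missing = [int(s) for s in table.index
               if table.loc[s].isna().any()] + \
              [int(s) for s in range(1, 21) if s not in table.index]
    if missing or set(table.columns) != {1, 2}:
        raise ValueError(
            f"group {group} incomplete: missing rater verdicts for sequences "
            f"{sorted(set(missing))}")
    return table


def consistency(records: pd.DataFrame, group: int,
                threshold: int = 1) -> ConsistencyReport:
    """Inter-rater ordinal distances for one complete sequence group.

    A sequence counts as consistent when the two raters' encoded verdicts
    differ by at most ``threshold`` (default 1).
    """
    table = _group_table(records, group)
    enc = table.map(encode_verdict)
    dist = (enc[1] - enc[2]).abs().astype(int)
    hist = {d: int((dist == d).sum()) for d in range(5)}
    return ConsistencyReport(
        distances=dist,
        histogram=hist,
        consistent_fraction=float((dist <= threshold).mean()),
        max_distance=int(dist.max()),
        threshold=threshold,
    )


def summarize(records: pd.DataFrame, group: int) -> pd.DataFrame:
    """Per-rater and combined verdict counts and category fractions.

    Rows: rater 1, rater 2 and their combination; columns: counts per
    verdict plus the aggregate real / partially / unreal fractions
    (real = rather + certainly real, unreal = rather + certainly unreal).
    """
    table = _group_table(records, group)
    rows = {}
    for rater in (1, 2):
        counts = table[rater].value_counts()
        rows[f"rater {rater}"] = [int(counts.get(v, 0)) for v in VERDICTS]
    rows["combined"] = [a + b for a, b in zip(rows["rater 1"], rows["rater 2"])]
    out = pd.DataFrame(rows, index=list(VERDICTS)).T
    totals = out.sum(axis=1)
    for cat in ("real", "partially", "unreal"):
        cols = [v for v in VERDICTS if CATEGORY_OF[v] == cat]
        out[f"{cat}_fraction"] = out[cols].sum(axis=1) / totals
    return out
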