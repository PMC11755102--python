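"""EQ-5D-5L scoring, dichotomization and EQ-VAS summaries.

A health state is a 5-character string, one digit (1..5) per dimension:
mobility, self-care, usual activities, pain/discomfort and
anxiety/depression.  The index utility is anchored at 1.0 for state 11111
and decreases by a value-set decrement for every dimension above level 1;
the floor (state 55555) may be negative.  The value set is a data file,
not code — no Romanian national 5L tariff exists, so the package ships a
synthetic illustrative tariff (``data/valueset_synthetic.csv``) and any
other tariff in the same CSV dialect plugs in.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import records as rc

DIMENSIONS = ("mobility", "self_care", "usual_activities", "pain_discomfort", "anxiety_depression")


@dataclass(frozen=True)
class ValueSet:
    """Additive EQ-5D-5L tariff: utility = 1 − Σ decrement(dim, level)."""

    name: str
    decrements: dict[tuple[str, int], float]  # (dimension, level 2..5) -> decrement

    def __post_init__(self) -> None:
        for dim in DIMENSIONS:
            prev = 0.0
            for level in range(2, 6):
                d = self.decrements.get((dim, level))
                if d is None:
                    raise ValueError(f"missing decrement for {dim} level {level}")
                if d < 0 or d < prev - 1e-12:
                    raise ValueError(f"decrements must be >= 0 and non-decreasing ({dim})")
                prev = d
        object.__setattr__(self, "decrements", dict(self.decrements))

    @property
    def anchor(self) -> float:
        return 1.0

    @property
    def floor(self) -> float:
        """Utility of the worst state 55555; may be negative."""
        return 1.0 - sum(self.decrements[(dim, 5)] for dim in DIMENSIONS)


def load_value_set(path: str | Path | None = None) -> ValueSet:
    """Load a tariff CSV (columns: dimension, level, decrement).

    With no path, the packaged synthetic illustrative tariff is used.
    """
    if path is None:
        with resources.as_file(
            resources.files("adcoi.data") / "valueset_synthetic.csv"
        ) as p:
            df = pd.read_csv(p)
        name = "synthetic-illustrative"
    else:
        df = pd.read_csv(path)
        name = Path(path).stem
    decs = {
        (str(row.dimension), int(row.level)): float(row.decrement)
        for row in df.itertuples()
    }
    return ValueSet(name=name, decrements=decs)


def _levels(state: str) -> tuple[int, ...]:
    state = str(state)
    if len(state) != 5 or not state.isdigit() or any(c not in "12345" for c in state):
        raise ValueError(f"malformed EQ-5D-5L state {state!r}")
    return tuple(int(c) for c in state)


def index(state: str, vs: ValueSet) -> float:
    """Index utility of one health state under the given tariff."""
    levels = _levels(state)
    return vs.anchor - sum(
        vs.decrements[(dim, lv)] for dim, lv in zip(DIMENSIONS, levels) if lv > 1
    )


def dichotomize(state: str) -> tuple[bool, bool, bool, bool, bool]:
    """Per-dimension problem flags: level 1 = no problems, 2..5 = problems."""
    return tuple(lv >= 2 for lv in _levels(state))


def score_records(records: pd.DataFrame, vs: ValueSet, state_col: str = rc.EQ5D_STATE) -> pd.Series:
    return records[state_col].map(lambda s: index(s, vs)).rename("utility")


def dimension_frequencies(records: pd.DataFrame, grouping: str, state_col: str = rc.EQ5D_STATE) -> pd.DataFrame:
    """Percent with/without problems per dimension per group (partition to 100%)."""
    flags = pd.DataFrame(
        records[state_col].map(dichotomize).tolist(),
        columns=DIMENSIONS,
        index=records.index,
    )
    flags[grouping] = records[grouping]
    rows = []
    for key, grp in flags.groupby(grouping, observed=True):
        for dim in DIMENSIONS:
            pct = 100.0 * grp[dim].mean()
            rows.append(
                {grouping: key, "dimension": dim, "problems_pct": pct, "no_problems_pct": 100.0 - pct, "n": len(grp)}
            )
    return pd.DataFrame(rows)


def vas_summary(records: pd.DataFrame, grouping: str, vas_col: str = rc.EQ_VAS) -> pd.DataFrame:
    """Mean, sample SD (n−1), median and quartiles of EQ-VAS per group.

    Quartiles use linear interpolation between closest ranks.  A group of
    one reports SD as NaN (zero-width); empty groups are omitted.
    """
    vals = records[vas_col]
    if ((vals < 0) | (vals > 100)).any():
        raise ValueError("EQ-VAS values must lie in [0, 100]")
    rows = []
    for key, grp in records.groupby(grouping, observed=True):
        x = grp[vas_col].dropna().to_numpy(dtype=float)
        if x.size == 0:
            continue
        rows.append(
            {
                grouping: key,
                "n": x.size,
                "mean": float(x.mean()),
                "sd": float(x.std(ddof=1)) if x.size > 1 else float("nan"),
                "median": float(np.percentile(x, 50)),
                "p25": float(np.percentile(x, 25)),
                "p75": float(np.percentile(x, 75)),
            }
        )
    return pd.DataFrame(rows)


def utility_ranges(
    records: pd.DataFrame, vs: ValueSet, grouping: str | Sequence[str], state_col: str = rc.EQ5D_STATE
) -> pd.DataFrame:
    """Min/max/mean index utility per group; every value lies in [floor, 1]."""
    df = records.copy()
    df["utility"] = score_records(df, vs, state_col)
    rows = []
    for key, grp in df.groupby(grouping, observed=True):
        rows.append(
            {
                "group": key if not isinstance(key, tuple) else "/".join(map(str, key)),
                "n": len(grp),
                "min": float(grp["utility"].min()),
                "max": float(grp["utility"].max()),
                "mean": float(grp["utility"].mean()),
            }
        )
    return pd.DataFrame(rows)
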