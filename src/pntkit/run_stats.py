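"""Per-run handedness classification and many-run aggregation.

Two aggregation rules are supported, matching the two total rows of the
packaged fixture table:

* *formula rule*: each run is classified by the sign of its chirality
  index (positive = right, negative = left, exact zeros bucketed apart),
* *fractional rule*: each run carries fractional left/right scores in
  [0, 1] (mixed structures score 0.5/0.5 etc.), which are summed.

Display percentages are rounded half away from zero to integer percent.
"""

from __future__ import annotations

import dataclasses
import hashlib
import math
from importlib import resources
from pathlib import Path

import pandas as pd

from .chirality import ChiralityReport

# sha256 of the packaged fixture, frozen so silent edits are detected
TABLE_FIXTURE_SHA256 = "e01daaff632e99c20d3a118b1de272be1e9f21f09fecbc057c6ef93a3a06475b"


class RunStatsError(ValueError):
    pass


@dataclasses.dataclass
class RunOutcome:
    run_id: int
    monomer_type: str            # 'L' or 'D'
    left_score: float
    right_score: float
    formula_value: float

    def validate(self) -> None:
        for s in (self.left_score, self.right_score):
            if not 0.0 <= s <= 1.0:
                raise RunStatsError(f"score {s} outside [0, 1]")
        if not math.isfinite(self.formula_value):
            raise RunStatsError("formula_value must be finite")


@dataclasses.dataclass
class SignCounts:
    n_left: int
    n_right: int
    n_zero: int
    pct_left: int
    pct_right: int


@dataclasses.dataclass
class FractionalTotals:
    sum_left: float
    sum_right: float
    pct_left: int
    pct_right: int


def display_percent(count: float, n: int) -> int:
    """Integer percent, round half away from zero (6/32 -> 19)."""
    if n == 0:
        return 0
    return int(math.floor(100.0 * count / n + 0.5))


def classify_by_formula(outcomes) -> SignCounts:
    """Count runs by the sign of the per-run chirality index."""
    values = [
        o.formula_value if isinstance(o, RunOutcome) else float(o)
        for o in outcomes
    ]
    n = len(values)
    n_right = sum(1 for v in values if v > 0)
    n_left = sum(1 for v in values if v < 0)
    n_zero = n - n_left - n_right
    return SignCounts(
        n_left=n_left,
        n_right=n_right,
        n_zero=n_zero,
        pct_left=display_percent(n_left, n),
        pct_right=display_percent(n_right, n),
    )


def aggregate_fractional(outcomes) -> FractionalTotals:
    """Sum the fractional left/right scores over all runs."""
    lefts, rights = [], []
    for o in outcomes:
        if isinstance(o, RunOutcome):
            o.validate()
            left, right = o.left_score, o.right_score
        else:
            left, right = float(o[0]), float(o[1])
            if not (0.0 <= left <= 1.0 and 0.0 <= right <= 1.0):
                raise RunStatsError("score outside [0, 1]")
        lefts.append(left)
        rights.append(right)
    n = len(lefts)
    sum_left, sum_right = float(sum(lefts)), float(sum(rights))
    return FractionalTotals(
        sum_left=sum_left,
        sum_right=sum_right,
        pct_left=display_percent(sum_left, n),
        pct_right=display_percent(sum_right, n),
    )


SNAP_LEVELS = (0.0, 0.2, 0.5, 0.8, 1.0)


def score_run(report: ChiralityReport, snap: bool = False) -> tuple[float, float]:
    """Fractional (left, right) scores from a windowed chirality profile.

    left = fraction of negative windows, right = fraction of positive
    windows, renormalized over signed windows; ``snap=True`` rounds to the
    display levels used by the fixture table.
    """
    if report.profile is None:
        raise RunStatsError("report has no chirality profile")
    fp = report.profile.fraction_positive
    fn = report.profile.fraction_negative
    total = fp + fn
    if total == 0:
        left = right = 0.5
    else:
        left, right = fn / total, fp / total
    if snap:
        left = min(SNAP_LEVELS, key=lambda s: abs(s - left))
        right = round(1.0 - left, 1)
    return left, right


# ---------------------------------------------------------------------------
# Fixture table I/O
# ---------------------------------------------------------------------------

def load_run_table(path: str | Path | None = None,
                   verify_checksum: bool | None = None) -> pd.DataFrame:
    """Load a run table TSV (columns run, monomer, left, right, value).

    Without a path the packaged 2 x 32-run fixture is loaded and its
    checksum verified.
    """
    if path is None:
        ref = resources.files("pntkit") / "data" / "table1_runs.tsv"
        raw = ref.read_bytes()
        if verify_checksum is None:
            verify_checksum = True
    else:
        raw = Path(path).read_bytes()
        verify_checksum = bool(verify_checksum)
    if verify_checksum:
        digest = hashlib.sha256(raw).hexdigest()
        if digest != TABLE_FIXTURE_SHA256:
            raise RunStatsError(
                f"run-table checksum mismatch: {digest}"
            )
    from io import BytesIO

    df = pd.read_csv(BytesIO(raw), sep="\t", comment="#")
    required = {"run", "monomer", "left", "right", "value"}
    if not required.issubset(df.columns):
        raise RunStatsError(f"run table must have columns {sorted(required)}")
    return df


def outcomes_from_table(df: pd.DataFrame, monomer: str) -> list[RunOutcome]:
    sel = df[df["monomer"] == monomer]
    return [
        RunOutcome(
            run_id=int(r.run),
            monomer_type=monomer,
            left_score=float(r.left),
            right_score=float(r.right),
            formula_value=float(r.value),
        )
        for r in sel.itertuples()
    ]


def stats_summary(df: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a run table into the two total rows per monomer type."""
    rows = []
    for monomer in sorted(df["monomer"].unique()):
        outcomes = outcomes_from_table(df, monomer)
        sc = classify_by_formula(outcomes)
        ft = aggregate_fractional(outcomes)
        rows.append({
            "monomer": monomer, "rule": "expert",
            "left": ft.sum_left, "right": ft.sum_right,
            "pct_left": ft.pct_left, "pct_right": ft.pct_right,
        })
        rows.append({
            "monomer": monomer, "rule": "formula",
            "left": sc.n_left, "right": sc.n_right,
            "pct_left": sc.pct_left, "pct_right": sc.pct_right,
        })
    return pd.DataFrame(rows)
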