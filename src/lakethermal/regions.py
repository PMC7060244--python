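"""Region-level summaries, cross-scheme comparison, and climate-shift accounting.

Summaries reproduce the structure of the reference region table (lake
counts, mean temperature and range, ice statistics).  ``cross_tabulate``
compares the thermal-region labelling with any other categorical scheme.
``shift_analysis`` counts label transitions between a historic and a future
labelling along the two warm-direction chains

    NF -> NC -> NT -> NW -> NH -> TH      (northern)
    ST -> SW -> SH -> TH                  (southern)

so that "moving toward a lower-latitude region" is a positive step along a
chain; cross-chain moves are counted as changed but unordered.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .curves import SeasonalCurve
from .synthetic import REGION_CODES, LakeSeries

NORTHERN_CHAIN = ("NF", "NC", "NT", "NW", "NH", "TH")
SOUTHERN_CHAIN = ("ST", "SW", "SH", "TH")


@dataclass(frozen=True)
class RegionOrdering:
    """The two warm-direction chains; TH is the shared terminal region."""

    northern: tuple[str, ...] = NORTHERN_CHAIN
    southern: tuple[str, ...] = SOUTHERN_CHAIN

    def steps(self, a: str, b: str) -> int | None:
        """Signed steps from a to b along a chain (positive = toward TH).

        Returns None for cross-chain moves, which have no defined order.
        """
        for code in (a, b):
            if code not in self.northern and code not in self.southern:
                raise ValueError(f"unknown region code {code!r}")
        for chain in (self.northern, self.southern):
            if a in chain and b in chain:
                return chain.index(b) - chain.index(a)
        return None


def summarize_regions(
    labels: dict[str, str] | pd.Series,
    series: list[LakeSeries],
    profiles: list[SeasonalCurve] | None = None,
) -> pd.DataFrame:
    """Per-region population statistics (reference-table analogue).

    Mean temperature and mean range are lake averages of seasonal-profile
    statistics when ``profiles`` is given, otherwise of the raw series.
    Percent time ice-covered is the mean fraction of flagged observations;
    percent of lakes with ice counts lakes with any flagged observation.
    Regions with no lakes are retained with NaN statistics.
    """
    lab = pd.Series(dict(labels)) if not isinstance(labels, pd.Series) else labels
    missing = [s.lake_id for s in series if s.lake_id not in lab.index]
    if missing:
        raise ValueError(f"lakes without labels: {missing[:5]}")
    per_lake = []
    for i, s in enumerate(series):
        if profiles is not None:
            mean, rng = profiles[i].mean, profiles[i].range
        else:
            mean, rng = float(s.values.mean()), float(s.values.max() - s.values.min())
        per_lake.append({
            "lake_id": s.lake_id, "region_code": lab[s.lake_id],
            "mean_c": mean, "range_c": rng,
            "ice_time": float(s.ice_flags.mean()),
            "has_ice": bool(s.ice_flags.any()),
        })
    df = pd.DataFrame(per_lake)
    total = len(df)
    rows = []
    for code in REGION_CODES:
        sub = df[df["region_code"] == code]
        n = len(sub)
        rows.append({
            "region_code": code,
            "n_lakes": n,
            "percent_of_total": 100.0 * n / total,
            "mean_temperature_c": sub["mean_c"].mean() if n else np.nan,
            "mean_range_c": sub["range_c"].mean() if n else np.nan,
            "percent_time_ice": 100.0 * sub["ice_time"].mean() if n else np.nan,
            "percent_lakes_with_ice": 100.0 * sub["has_ice"].mean() if n else np.nan,
        })
    extra = sorted(set(df["region_code"]) - set(REGION_CODES))
    for code in extra:
        sub = df[df["region_code"] == code]
        rows.append({
            "region_code": code, "n_lakes": len(sub),
            "percent_of_total": 100.0 * len(sub) / total,
            "mean_temperature_c": sub["mean_c"].mean(),
            "mean_range_c": sub["range_c"].mean(),
            "percent_time_ice": 100.0 * sub["ice_time"].mean(),
            "percent_lakes_with_ice": 100.0 * sub["has_ice"].mean(),
        })
    return pd.DataFrame(rows).set_index("region_code")


def cross_tabulate(labels_a: dict[str, str] | pd.Series,
                   labels_b: dict[str, str] | pd.Series) -> pd.DataFrame:
    """Row-normalized contingency table between two labelings.

    Rows are A-categories; entries are the percent of each A-category
    falling in each B-category (rows sum to 100).  The raw counts are
    attached as ``result.attrs["counts"]``.
    """
    a = pd.Series(dict(labels_a)) if not isinstance(labels_a, pd.Series) else labels_a
    b = pd.Series(dict(labels_b)) if not isinstance(labels_b, pd.Series) else labels_b
    only_a = sorted(set(a.index) - set(b.index))
    only_b = sorted(set(b.index) - set(a.index))
    if only_a or only_b:
        raise ValueError(
            f"mismatched lake sets: {only_a[:5]} only in A, {only_b[:5]} only in B")
    counts = pd.crosstab(a, b.loc[a.index])
    counts.index.name, counts.columns.name = "labels_a", "labels_b"
    pct = counts.div(counts.sum(axis=1), axis=0) * 100.0
    pct.attrs["counts"] = counts
    return pct


@dataclass
class ShiftReport:
    """Transition accounting between a historic and a future labelling."""

    matrix: pd.DataFrame               # historic x future counts
    percent_changed: float
    percent_toward_warmer: float       # moves with positive chain steps
    step_counts: dict[int, int]        # within-chain moves by |steps|
    unordered_changes: int             # cross-chain moves
    region_deltas: pd.DataFrame        # per-region historic/future counts, % change

    @property
    def n_lakes(self) -> int:
        return int(self.matrix.to_numpy().sum())


def shift_analysis(
    labels_historic: dict[str, str] | pd.Series,
    labels_future: dict[str, str] | pd.Series,
    ordering: RegionOrdering | None = None,
) -> ShiftReport:
    """Count region changes between two labelings of the same lakes/cells."""
    ordering = ordering or RegionOrdering()
    h = pd.Series(dict(labels_historic)) if not isinstance(labels_historic, pd.Series) \
        else labels_historic
    f = pd.Series(dict(labels_future)) if not isinstance(labels_future, pd.Series) \
        else labels_future
    if set(h.index) != set(f.index):
        raise ValueError("historic and future labelings cover different lakes")
    f = f.loc[h.index]
    for code in set(h) | set(f):
        if code not in REGION_CODES:
            raise ValueError(f"unknown region code {code!r}")

    codes = list(REGION_CODES)
    mat = pd.crosstab(h, f).reindex(index=codes, columns=codes, fill_value=0)
    mat.index.name, mat.columns.name = "historic", "future"

    n = len(h)
    changed = int((h != f).sum())
    step_counts: dict[int, int] = {}
    toward_warmer = 0
    unordered = 0
    for a, b in zip(h, f):
        if a == b:
            continue
        s = ordering.steps(a, b)
        if s is None:
            unordered += 1
        else:
            step_counts[abs(s)] = step_counts.get(abs(s), 0) + 1
            if s > 0:
                toward_warmer += 1

    hist_counts = h.value_counts().reindex(codes, fill_value=0)
    fut_counts = f.value_counts().reindex(codes, fill_value=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = 100.0 * (fut_counts - hist_counts) / hist_counts.replace(0, np.nan)
    deltas = pd.DataFrame({
        "historic_n": hist_counts, "future_n": fut_counts,
        "percent_change": delta,
    })
    return ShiftReport(
        matrix=mat,
        percent_changed=100.0 * changed / n,
        percent_toward_warmer=100.0 * toward_warmer / n,
        step_counts=step_counts,
        unordered_changes=unordered,
        region_deltas=deltas,
    )
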