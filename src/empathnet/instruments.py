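"""Instrument metadata, Likert binarization, item filtering, and scale totals.

Response tables are pandas DataFrames with two metadata columns,
``participant_id`` and ``time_point`` (values ``"PRE"``/``"POST"``), followed
by one column per item labelled ``"<instrument label>: <item number>"``
(e.g. ``"DASS-21: 11"``). Binary tables share the layout with values in {0, 1};
missing responses are NaN and are propagated, never imputed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

logger = logging.getLogger(__name__)

META_COLUMNS = ("participant_id", "time_point")
TIME_POINTS = ("PRE", "POST")

#: Default dual-category prevalence fraction for node selection.
DEFAULT_PREVALENCE_FRACTION = 0.30


class BinarizationError(ValueError):
    """An out-of-range score or an item column with no matching instrument."""


@dataclass(frozen=True)
class InstrumentSpec:
    """Static metadata for one self-report instrument.

    Parameters
    ----------
    instrument_id
        Enumerated name: ``DASS21``, ``EQ_SHORT``, ``JSE_S`` or ``EES``.
    label
        Column-label prefix, e.g. ``"DASS-21"``.
    n_items, scale_min, scale_max
        Item count and inclusive response range.
    reversed_items
        1-based numbers of reverse-keyed items.
    binarize_cut
        Cut point ``c``: an ordinary item scores 1 iff ``score >= c``; a
        reversed item scores 1 iff ``score < c`` (exact complement).
    subscale_of_item
        Map item number -> subscale label (empty for single-scale instruments).
    reverse_score_totals
        Whether reversed items are recoded (``min + max - score``) before
        summing scale totals, per the instrument's published scoring.
    source_items
        Optional provenance of short-form items in the parent instrument.
    """

    instrument_id: str
    label: str
    n_items: int
    scale_min: int
    scale_max: int
    binarize_cut: int
    reversed_items: frozenset[int] = frozenset()
    subscale_of_item: Mapping[int, str] = field(default_factory=dict)
    reverse_score_totals: bool = False
    source_items: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.n_items < 1:
            raise ValueError(f"{self.instrument_id}: n_items must be positive")
        if not self.scale_min <= self.binarize_cut <= self.scale_max:
            raise ValueError(
                f"{self.instrument_id}: binarize_cut {self.binarize_cut} outside "
                f"scale range [{self.scale_min}, {self.scale_max}]"
            )
        bad = set(self.reversed_items) - set(range(1, self.n_items + 1))
        if bad:
            raise ValueError(f"{self.instrument_id}: reversed items {sorted(bad)} out of range")

    def item_label(self, item_no: int) -> str:
        if not 1 <= item_no <= self.n_items:
            raise ValueError(f"{self.instrument_id}: item {item_no} out of range")
        return f"{self.label}: {item_no}"

    def is_reversed(self, item_no: int) -> bool:
        return item_no in self.reversed_items

    def presence_scores(self, item_no: int) -> tuple[int, ...]:
        """Scores that binarize to 1 for this item (preimage of 1)."""
        rng = range(self.scale_min, self.scale_max + 1)
        if self.is_reversed(item_no):
            return tuple(s for s in rng if s < self.binarize_cut)
        return tuple(s for s in rng if s >= self.binarize_cut)


def load_instrument_specs(path=None) -> dict[str, InstrumentSpec]:
    """Load the four packaged instrument definitions (or a user YAML file)."""
    if path is None:
        text = resources.files("empathnet.data").joinpath("instruments.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)["instruments"]
    specs = {}
    for iid, d in raw.items():
        subscales = {}
        for name, items in d.get("subscales", {}).items():
            for it in items:
                subscales[it] = name
        specs[iid] = InstrumentSpec(
            instrument_id=iid,
            label=d["label"],
            n_items=d["n_items"],
            scale_min=d["scale_min"],
            scale_max=d["scale_max"],
            binarize_cut=d["binarize_cut"],
            reversed_items=frozenset(d.get("reversed_items", [])),
            subscale_of_item=subscales,
            reverse_score_totals=d.get("reverse_score_totals", False),
            source_items=tuple(d.get("source_items", [])),
        )
    return specs


def spec_for_label(column: str, specs: Mapping[str, InstrumentSpec]) -> tuple[InstrumentSpec, int]:
    """Resolve a column label like ``"EES: 3"`` to its instrument spec and item number."""
    try:
        prefix, item_str = column.rsplit(": ", 1)
        item_no = int(item_str)
    except ValueError as exc:
        raise BinarizationError(f"column {column!r} is not an '<instrument>: <item>' label") from exc
    for spec in specs.values():
        if spec.label == prefix:
            if not 1 <= item_no <= spec.n_items:
                raise BinarizationError(f"column {column!r}: item number out of range")
            return spec, item_no
    raise BinarizationError(f"column {column!r} matches no known instrument")


def binarize_item(score, spec: InstrumentSpec, item_no: int) -> float:
    """Dichotomize one Likert score.

    Ordinary items map to 1 iff ``score >= binarize_cut``; reversed items use
    the exact complement (1 iff ``score < binarize_cut``), so e.g. a reversed
    7-point empathy item scores 1 ("empathic") for responses 1-3.
    Missing (NaN) propagates; out-of-range scores raise.
    """
    if score is None or (isinstance(score, float) and math.isnan(score)):
        return float("nan")
    score = int(score)
    if not spec.scale_min <= score <= spec.scale_max:
        raise BinarizationError(
            f"{spec.instrument_id} item {item_no}: score {score} outside "
            f"[{spec.scale_min}, {spec.scale_max}]"
        )
    presence = score >= spec.binarize_cut
    if spec.is_reversed(item_no):
        presence = not presence
    return 1.0 if presence else 0.0


def binarize_table(raw: pd.DataFrame, specs: Mapping[str, InstrumentSpec]) -> pd.DataFrame:
    """Apply :func:`binarize_item` elementwise; row/column order preserved."""
    out = raw.copy()
    for col in raw.columns:
        if col in META_COLUMNS:
            continue
        spec, item_no = spec_for_label(col, specs)
        vals = raw[col].to_numpy(dtype=float)
        finite = ~np.isnan(vals)
        bad = finite & ((vals < spec.scale_min) | (vals > spec.scale_max) | (vals != np.round(vals)))
        if bad.any():
            offending = vals[bad][0]
            raise BinarizationError(
                f"{spec.instrument_id} item {item_no}: score {offending:g} outside "
                f"[{spec.scale_min}, {spec.scale_max}]"
            )
        pres = np.where(finite, (vals >= spec.binarize_cut).astype(float), np.nan)
        if spec.is_reversed(item_no):
            pres = np.where(finite, 1.0 - pres, np.nan)
        out[col] = pres
    return out


def item_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in META_COLUMNS]


def split_meta(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a response table into (metadata, item block)."""
    return table.loc[:, [c for c in META_COLUMNS if c in table.columns]], table.loc[:, item_columns(table)]


def filter_items(
    binary: pd.DataFrame,
    prevalence_fraction: float = DEFAULT_PREVALENCE_FRACTION,
    per_time_point: bool = True,
) -> list[str]:
    """Select items with both response categories sufficiently prevalent.

    An item is retained iff both its 1-count and its 0-count are at least
    ``ceil(prevalence_fraction * N)`` (N participants per time point; with the
    study's N = 40 and fraction 0.30 the threshold is 12). With
    ``per_time_point`` (default) the criterion must hold at every time point,
    so both longitudinal networks share one node set; otherwise counts are
    pooled over all records. Returns labels in original column order.
    """
    items = item_columns(binary)
    if binary.empty or not items:
        raise ValueError("empty binary response table")
    if not 0.0 < prevalence_fraction < 1.0:
        raise ValueError("prevalence_fraction must lie in (0, 1)")

    if per_time_point and "time_point" in binary.columns:
        groups = [g for _, g in binary.groupby("time_point", sort=False)]
    else:
        groups = [binary]

    retained = []
    for col in items:
        ok = True
        for g in groups:
            vals = g[col].to_numpy(dtype=float)
            n = int(np.sum(~np.isnan(vals)))
            threshold = math.ceil(prevalence_fraction * n)
            ones = int(np.nansum(vals))
            zeros = n - ones
            if ones < threshold or zeros < threshold:
                ok = False
                break
        if ok:
            retained.append(col)
    return retained


def scale_totals(raw: pd.DataFrame, specs: Mapping[str, InstrumentSpec]) -> pd.DataFrame:
    """Per-record instrument (and DASS-21 subscale) totals.

    Instruments whose published scoring recodes reversed items (JSE-S, EES)
    are reverse-scored (``min + max - score``) before summing; DASS-21 and
    EQ-short sum raw scores. A record with any missing item in a sum yields a
    NaN total and is flagged in the ``incomplete`` column.
    """
    meta, items = split_meta(raw)
    out = meta.copy()
    by_instrument: dict[str, list[tuple[str, int, InstrumentSpec]]] = {}
    for col in items.columns:
        spec, item_no = spec_for_label(col, specs)
        by_instrument.setdefault(spec.instrument_id, []).append((col, item_no, spec))

    incomplete = np.zeros(len(raw), dtype=bool)
    for iid, cols in by_instrument.items():
        spec = cols[0][2]
        scored = {}
        for col, item_no, _ in cols:
            vals = raw[col].to_numpy(dtype=float)
            if spec.reverse_score_totals and spec.is_reversed(item_no):
                vals = np.where(np.isnan(vals), np.nan, spec.scale_min + spec.scale_max - vals)
            scored[item_no] = vals
        block = np.column_stack([scored[i] for i in sorted(scored)])
        missing = np.isnan(block).any(axis=1)
        incomplete |= missing
        out[f"{iid}_total"] = np.where(missing, np.nan, block.sum(axis=1))
        if spec.subscale_of_item:
            for sub in dict.fromkeys(spec.subscale_of_item.values()):
                members = [i for i in sorted(scored) if spec.subscale_of_item.get(i) == sub]
                if members:
                    sub_block = np.column_stack([scored[i] for i in members])
                    sub_missing = np.isnan(sub_block).any(axis=1)
                    out[f"{iid}_{sub}"] = np.where(sub_missing, np.nan, sub_block.sum(axis=1))
    out["incomplete"] = incomplete
    if incomplete.any():
        logger.warning("%d record(s) with missing items flagged in scale totals", int(incomplete.sum()))
    return out


@dataclass(frozen=True)
class TTestResult:
    """Paired t-test on post - pre differences (df = n - 1)."""

    t: float
    df: int
    p: float
    undefined: bool = False


def paired_t_test(pre_values: Sequence[float], post_values: Sequence[float]) -> TTestResult:
    """Standard paired t-test; degenerate difference variance is flagged.

    Identical vectors give t = 0, p = 1 (no evidence of change); a nonzero
    constant difference has zero variance, so t and p are undefined.
    """
    pre = np.asarray(pre_values, dtype=float)
    post = np.asarray(post_values, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("pre and post must have equal length")
    n = pre.size
    if n < 2:
        raise ValueError("paired t-test needs n >= 2")
    d = post - pre
    if np.std(d, ddof=1) == 0.0:
        if np.all(d == 0.0):
            return TTestResult(t=0.0, df=n - 1, p=1.0)
        return TTestResult(t=float("nan"), df=n - 1, p=float("nan"), undefined=True)
    res = stats.ttest_rel(post, pre)
    return TTestResult(t=float(res.statistic), df=n - 1, p=float(res.pvalue))


def paired_totals_tests(totals: pd.DataFrame) -> pd.DataFrame:
    """Paired t-tests of every total column between PRE and POST records."""
    wide = totals.pivot(index="participant_id", columns="time_point")
    rows = []
    for col in totals.columns:
        if col in META_COLUMNS or col == "incomplete":
            continue
        pre = wide[(col, "PRE")]
        post = wide[(col, "POST")]
        keep = pre.notna() & post.notna()
        res = paired_t_test(pre[keep].to_numpy(), post[keep].to_numpy())
        rows.append(
            {
                "measure": col,
                "n": int(keep.sum()),
                "mean_pre": float(pre[keep].mean()),
                "mean_post": float(post[keep].mean()),
                "t": res.t,
                "df": res.df,
                "p": res.p,
                "undefined": res.undefined,
            }
        )
    return pd.DataFrame(rows)
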