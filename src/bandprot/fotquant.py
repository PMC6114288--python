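"""Spectral counting and fraction-of-total (fot) class statistics.

For organisms without an annotated genome, protein-level inference is
unreliable, so the semi-quantitative comparison works at the level of
functional classes: every identified spectrum is assigned to the MapMan BIN
class(es) of its peptide's parent unigene(s), counts are summed per class and
condition, and each class's share of the condition total — the fraction of
total (fot) — is compared between conditions.  The enrichment display
statistic is the fot ratio minus one, so positive values mean enriched in the
first (acidic) condition and negative values depleted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EnrichmentRow",
    "spectral_counts",
    "aggregate_class",
    "rollup_to_level",
    "fot",
    "enrichment_percent",
    "round_half_away",
]


@dataclass(frozen=True)
class EnrichmentRow:
    """Acidic-versus-alkaline spectral-count excess for one key."""

    key: str
    count_acidic: int
    count_alkaline: int

    @property
    def total(self) -> int:
        return self.count_acidic + self.count_alkaline

    @property
    def percent_excess(self) -> float | None:
        """round(100 x (acidic - alkaline) / alkaline); None when alkaline=0."""
        if self.count_alkaline == 0:
            return None
        return round_half_away(
            100.0 * (self.count_acidic - self.count_alkaline) / self.count_alkaline
        )


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (printed-table style)."""
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def spectral_counts(
    annotated: pd.DataFrame,
    level: str = "bin",
    shared_mode: str = "once_per_class",
) -> pd.DataFrame:
    """Tally spectra per key (protein id or BIN code) per condition.

    Each evidence row is one spectral observation.  At ``level='protein'`` a
    shared peptide's spectrum counts towards every matching protein.  At
    ``level='bin'`` the ``shared_mode`` decides how spectra of shared peptides
    are attributed: ``once_per_class`` (default) counts a spectrum once per
    distinct class across its proteins, ``drop_shared`` counts proteotypic
    peptides only.

    Returns a DataFrame indexed by key with one integer column per condition;
    column sums are the per-condition margins.
    """
    if level not in ("protein", "bin"):
        raise ValueError(f"unknown level {level!r}")
    conditions = sorted(annotated["condition"].unique()) if len(annotated) else []
    if level == "protein":
        keycol = "protein_ids"
    else:
        keycol = "bin_codes"
    rows = annotated
    if shared_mode == "drop_shared" and len(rows):
        rows = rows[rows["proteotypic"]]
    elif shared_mode not in ("once_per_class", "drop_shared"):
        raise ValueError(f"unknown shared_mode {shared_mode!r}")
    tallies: dict[tuple[str, str], int] = {}
    for keys, cond in zip(rows[keycol] if len(rows) else [], rows["condition"] if len(rows) else []):
        for key in keys:
            tallies[(key, cond)] = tallies.get((key, cond), 0) + 1
    if not tallies:
        return pd.DataFrame(columns=conditions, dtype=int)
    table = (
        pd.Series(tallies).unstack(fill_value=0).astype(int)
    )
    table.index.name = "key"
    for c in conditions:
        if c not in table.columns:
            table[c] = 0
    return table[sorted(table.columns)]


def _truncate_code(code: str, level: int) -> str:
    return ".".join(code.split(".")[:level])


def aggregate_class(
    protein_table: pd.DataFrame,
    protein_to_codes: Mapping[str, Iterable[str]],
    level: int | None = None,
) -> pd.DataFrame:
    """Aggregate a protein-level count table to BIN classes.

    Each protein's counts add to every class code it carries; with ``level``
    set, codes are first truncated to that many dotted components so that
    e.g. 34.1.1 rolls up into 34.1 at level 2 and 34 at level 1.
    """
    acc: dict[str, np.ndarray] = {}
    for pid, counts in protein_table.iterrows():
        codes = set(protein_to_codes.get(pid, ()))
        if level is not None:
            codes = {_truncate_code(c, level) for c in codes}
        for code in codes:
            if code in acc:
                acc[code] = acc[code] + counts.to_numpy()
            else:
                acc[code] = counts.to_numpy().copy()
    out = pd.DataFrame.from_dict(acc, orient="index", columns=protein_table.columns)
    out.index.name = "bin_code"
    return out.sort_index()


def rollup_to_level(class_table: pd.DataFrame, level: int) -> pd.DataFrame:
    """Roll a class-level count table up the BIN hierarchy by code prefix."""
    out = class_table.groupby(
        class_table.index.map(lambda c: _truncate_code(str(c), level))
    ).sum()
    out.index.name = "bin_code"
    return out.sort_index()


def fot(
    class_table: pd.DataFrame,
    conditions: Sequence[str] = ("acidic", "alkaline"),
) -> pd.DataFrame:
    """Fraction-of-total per class and condition, with the ratio-1 statistic.

    fot(class, cond) = class count / condition margin.  ``ratio_minus1`` is
    fot(first)/fot(second) - 1 for the given condition pair and is NaN where
    the second condition's fot is zero (flagged, excluded from plots).
    """
    for cond in conditions:
        if cond not in class_table.columns:
            raise ValueError(f"condition {cond!r} absent from table")
        if class_table[cond].sum() <= 0:
            raise ValueError(f"condition {cond!r} has zero total count")
    margins = class_table.sum(axis=0)
    out = pd.DataFrame(index=class_table.index)
    for cond in class_table.columns:
        out[f"fot_{cond}"] = class_table[cond] / margins[cond]
    a, b = conditions[0], conditions[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = out[f"fot_{a}"] / out[f"fot_{b}"]
    out["ratio_minus1"] = np.where(out[f"fot_{b}"] > 0, ratio - 1.0, np.nan)
    return out


def enrichment_percent(
    key: str, count_acidic: int, count_alkaline: int
) -> EnrichmentRow:
    """Percent excess of acidic over alkaline counts for one protein/class."""
    if count_acidic < 0 or count_alkaline < 0:
        raise ValueError("counts must be non-negative")
    return EnrichmentRow(
        key=key, count_acidic=int(count_acidic), count_alkaline=int(count_alkaline)
    )
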