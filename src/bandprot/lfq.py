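"""Label-free intensity quantitation from peptide-ion evidence.

The workflow follows the cRacker-style normalization chain for MS1 label-free
data, applied in a fixed order:

1. **normalize** — within each sample, divide every peptide-ion intensity by
   the sample's total ion intensity, removing per-run loading and
   instrument-response differences.
2. **scale across treatments** — divide each ion by the grand mean of its
   per-treatment mean normalized intensities, putting ions on a common
   relative scale centred at 1.
3. **average replicates** — arithmetic mean per condition over the replicates
   in which the ion was observed (at least ``min_reps``, default 3).
4. **protein sums** — per protein per condition, sum the averaged scaled
   intensities of its proteotypic ions only.

An ion species is the (peptide sequence, charge, m/z) triple; zero or missing
intensities are treated as not-quantified and excluded from all means.
Differential testing is a two-sided Welch t-test on log-transformed
replicate-level values, at the ion or protein level, with optional
Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .evidence import ExperimentDesign, PeptideAssignment

__all__ = [
    "QuantMatrix",
    "matrix_from_evidence",
    "normalize",
    "scale_across_treatments",
    "average_replicates",
    "protein_sums",
    "differential",
]

ION_INDEX = ["peptide", "charge", "mz"]

_MIN_P = float(np.nextafter(0, 1))


@dataclass(frozen=True)
class QuantMatrix:
    """Ion x sample intensity matrix with its design and processing stage.

    ``values`` is indexed by the (peptide, charge, mz) ion key with one column
    per sample; NaN marks not-quantified.  ``stage`` is one of ``raw``,
    ``normalized``, ``scaled``, ``averaged`` (columns are conditions after
    averaging).
    """

    values: pd.DataFrame
    design: ExperimentDesign
    stage: str = "raw"

    def samples_of(self, condition: str) -> list[str]:
        return [
            s for s in self.values.columns
            if self.design.sample_map.get(s, (None,))[0] == condition
        ]

    @property
    def conditions(self) -> list[str]:
        return list(self.design.conditions)


def matrix_from_evidence(df: pd.DataFrame, design: ExperimentDesign) -> QuantMatrix:
    """Build the raw ion x sample matrix from standardized evidence rows.

    Multiple spectra of the same ion in one sample have their intensities
    summed; zero intensities (identified but not quantified) become NaN.
    """
    quantified = df[df["intensity"] > 0]
    wide = (
        quantified.pivot_table(
            index=ION_INDEX, columns="sample", values="intensity", aggfunc="sum"
        )
        .sort_index()
    )
    sample_map = dict(design.sample_map)
    missing = [s for s in wide.columns if s not in sample_map]
    if missing:
        # fall back to condition/replicate columns present in the evidence
        lookup = df.drop_duplicates("sample").set_index("sample")
        for s in missing:
            sample_map[s] = (lookup.loc[s, "condition"], int(lookup.loc[s, "replicate"]))
        design = ExperimentDesign(conditions=design.conditions, sample_map=sample_map)
    return QuantMatrix(values=wide, design=design, stage="raw")


def normalize(m: QuantMatrix) -> QuantMatrix:
    """Divide each sample column by its total ion intensity.

    After this stage every column of observed entries sums to one, so
    multiplying a whole sample by any constant upstream has no effect
    downstream.
    """
    if m.stage != "raw":
        raise ValueError(f"normalize expects a raw matrix, got {m.stage!r}")
    totals = m.values.sum(axis=0, skipna=True)
    dead = totals[totals <= 0]
    if len(dead):
        raise ValueError(f"sample {dead.index[0]!r} has zero total intensity")
    return replace(m, values=m.values / totals, stage="normalized")


def _treatment_means(values: pd.DataFrame, m: QuantMatrix) -> pd.DataFrame:
    cols = {}
    for cond in m.conditions:
        samples = [s for s in values.columns if m.design.sample_map[s][0] == cond]
        cols[cond] = values[samples].mean(axis=1, skipna=True)
    return pd.DataFrame(cols)


def scale_across_treatments(m: QuantMatrix) -> QuantMatrix:
    """Scale each ion by the mean of its treatment-mean normalized intensities.

    The grand mean is taken over the treatments in which the ion was observed
    at all; ions observed nowhere are dropped.  Where an ion is observed in
    every treatment, the mean of its treatment-averaged scaled values is 1 by
    construction.
    """
    if m.stage != "normalized":
        raise ValueError(f"scale expects a normalized matrix, got {m.stage!r}")
    observed = m.values.notna().any(axis=1)
    values = m.values[observed]
    grand = _treatment_means(values, m).mean(axis=1, skipna=True)
    return replace(m, values=values.div(grand, axis=0), stage="scaled")


def average_replicates(m: QuantMatrix, min_reps: int = 3) -> QuantMatrix:
    """Average scaled values per condition over observed replicates.

    Conditions with fewer than ``min_reps`` observations for an ion are
    marked missing (NaN) for that ion.
    """
    if m.stage != "scaled":
        raise ValueError(f"average expects a scaled matrix, got {m.stage!r}")
    if min_reps < 1:
        raise ValueError("min_reps must be >= 1")
    means = {}
    for cond in m.conditions:
        samples = m.samples_of(cond)
        block = m.values[samples]
        mean = block.mean(axis=1, skipna=True)
        n_obs = block.notna().sum(axis=1)
        means[cond] = mean.where(n_obs >= min_reps)
    out = pd.DataFrame(means)
    return replace(m, values=out, stage="averaged")


def _proteotypic_map(
    assignments: Sequence[PeptideAssignment],
) -> dict[str, str]:
    """peptide -> its single protein, for proteotypic peptides only."""
    return {
        a.peptide: next(iter(a.protein_ids))
        for a in assignments
        if a.proteotypic
    }


def protein_sums(
    m: QuantMatrix,
    assignments: Sequence[PeptideAssignment],
    conditions: Sequence[str] = ("acidic", "alkaline"),
) -> pd.DataFrame:
    """Per-protein condition intensities as sums over proteotypic ions.

    Non-proteotypic ions are excluded entirely; proteins with no proteotypic
    ion are omitted.  Returns a DataFrame indexed by protein id with one
    column per condition plus ``log2_ratio`` (first/second condition, NaN
    unless both means are positive) and ``n_peptides``.
    """
    if m.stage != "averaged":
        raise ValueError(f"protein_sums expects an averaged matrix, got {m.stage!r}")
    pep_to_prot = _proteotypic_map(assignments)
    ions = m.values
    proteins = ions.index.get_level_values("peptide").map(pep_to_prot.get)
    keep = proteins.notna()
    sums = ions[keep].groupby(proteins[keep]).sum(min_count=1)
    n_ions = ions[keep].notna().any(axis=1).groupby(proteins[keep]).sum()
    sums.index.name = "protein_id"
    a, b = conditions
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.log2(sums[a] / sums[b])
    sums["log2_ratio"] = np.where((sums[a] > 0) & (sums[b] > 0), ratio, np.nan)
    sums["n_peptides"] = n_ions.astype(int)
    return sums


def _welch_on_logs(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Welch t-test p-value on log-transformed values."""
    lx, ly = np.log(x), np.log(y)
    if lx.std(ddof=1) == 0 and ly.std(ddof=1) == 0:
        return 1.0 if np.isclose(lx.mean(), ly.mean()) else _MIN_P
    p = stats.ttest_ind(lx, ly, equal_var=False).pvalue
    if np.isnan(p):
        return 1.0
    return max(float(p), _MIN_P)


def differential(
    m: QuantMatrix,
    level: str = "ion",
    assignments: Sequence[PeptideAssignment] | None = None,
    conditions: Sequence[str] = ("acidic", "alkaline"),
    bh: bool = False,
    min_reps: int = 2,
) -> pd.DataFrame:
    """Log2 ratios and Welch-test p-values between two conditions.

    At ``level='ion'`` each ion's replicate-level scaled values are compared;
    at ``level='protein'`` replicate-wise proteotypic-ion sums are compared
    (``assignments`` required).  Keys with fewer than ``min_reps`` observed
    replicates in either condition are skipped.  ``bh=True`` appends a
    Benjamini-Hochberg adjusted column ``p_adj``.
    """
    if m.stage != "scaled":
        raise ValueError(f"differential expects a scaled matrix, got {m.stage!r}")
    a, b = conditions
    sa, sb = m.samples_of(a), m.samples_of(b)
    if level == "ion":
        data = m.values
    elif level == "protein":
        if assignments is None:
            raise ValueError("protein-level differential requires assignments")
        pep_to_prot = _proteotypic_map(assignments)
        proteins = m.values.index.get_level_values("peptide").map(pep_to_prot.get)
        keep = proteins.notna()
        data = m.values[keep].groupby(proteins[keep]).sum(min_count=1)
        data.index.name = "protein_id"
    else:
        raise ValueError(f"unknown level {level!r}")

    records = []
    for key, row in data.iterrows():
        va = row[sa].dropna().to_numpy(dtype=float)
        vb = row[sb].dropna().to_numpy(dtype=float)
        if len(va) < min_reps or len(vb) < min_reps:
            continue
        records.append(
            {
                "key": key,
                f"mean_{a}": va.mean(),
                f"mean_{b}": vb.mean(),
                "log2_ratio": float(np.log2(va.mean() / vb.mean())),
                "p_value": _welch_on_logs(va, vb),
                "n_a": len(va),
                "n_b": len(vb),
            }
        )
    out = pd.DataFrame.from_records(records)
    if len(out):
        out = out.set_index("key")
        if bh:
            out["p_adj"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out
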