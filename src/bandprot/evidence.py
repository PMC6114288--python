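"""Peptide-evidence ingestion, filtering, mapping and functional annotation.

The quantitation stages consume peptide-ion evidence tables of the kind a
search engine writes (one row per peptide ion per run, MaxQuant
``evidence.txt`` dialect by default).  This module standardizes such tables
into a fixed column schema, applies the study-style filters (drop reverse and
contaminant hits; keep only peptides observed in all biological replicates),
maps peptide sequences onto the transcript-derived protein database, and
attaches MapMan/Mercator BIN functional classes.

Standardized evidence columns: ``peptide`` (modification-stripped sequence),
``peptide_raw``, ``charge``, ``mz``, ``intensity``, ``sample``, ``condition``,
``replicate``, ``is_reverse``, ``is_contaminant``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .seqdb import fold_il

__all__ = [
    "DEFAULT_SCHEMA",
    "UNASSIGNED_BIN",
    "ExperimentDesign",
    "PeptideAssignment",
    "strip_modifications",
    "read_evidence",
    "standardize_evidence",
    "filter_rows",
    "replicate_presence_filter",
    "map_peptides",
    "read_bins",
    "annotate_evidence",
]

#: Default column mapping onto the MaxQuant evidence.txt dialect.
DEFAULT_SCHEMA: Mapping[str, str] = {
    "peptide": "Sequence",
    "charge": "Charge",
    "mz": "m/z",
    "intensity": "Intensity",
    "sample": "Raw file",
    "condition": "Condition",
    "replicate": "Replicate",
    "is_reverse": "Reverse",
    "is_contaminant": "Potential contaminant",
}

#: Reserved BIN code for peptides whose unigene carries no annotation.
UNASSIGNED_BIN = "35"

_BIN_CODE = re.compile(r"\d+(\.\d+)*\Z")
_MOD = re.compile(r"\([^)]*\)|\[[^\]]*\]|[^A-Z]")


def strip_modifications(seq: str) -> str:
    """Reduce a modified peptide string to its plain amino-acid sequence.

    Removes bracketed modification annotations (``(ox)``, ``[+57]``) and any
    non-letter decoration such as the underscores MaxQuant wraps sequences in.
    """
    return _MOD.sub("", seq.upper())


@dataclass(frozen=True)
class ExperimentDesign:
    """Declares conditions, their expected replicates, and the sample map."""

    conditions: Mapping[str, frozenset[int]]
    sample_map: Mapping[str, tuple[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.conditions:
            raise ValueError("design must declare at least one condition")
        for cond, reps in self.conditions.items():
            if not reps:
                raise ValueError(f"condition {cond!r} declares zero replicates")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentDesign":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        conditions = {
            str(c): frozenset(int(r) for r in reps)
            for c, reps in raw["conditions"].items()
        }
        sample_map = {
            str(s): (str(v["condition"]), int(v["replicate"]))
            for s, v in raw.get("samples", {}).items()
        }
        return cls(conditions=conditions, sample_map=sample_map)

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "conditions": {c: sorted(r) for c, r in self.conditions.items()},
            "samples": {
                s: {"condition": c, "replicate": r}
                for s, (c, r) in self.sample_map.items()
            },
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)


@dataclass(frozen=True)
class PeptideAssignment:
    """Peptide-to-protein mapping; proteotypic iff exactly one protein."""

    peptide: str
    protein_ids: frozenset[str]

    @property
    def proteotypic(self) -> bool:
        return len(self.protein_ids) == 1


def _flag_column(col: pd.Series) -> pd.Series:
    """MaxQuant marks flags with '+'; treat any non-empty value as set."""
    return col.fillna("").astype(str).str.strip().ne("")


def standardize_evidence(
    df: pd.DataFrame,
    schema: Mapping[str, str] | None = None,
    design: ExperimentDesign | None = None,
) -> pd.DataFrame:
    """Map a raw evidence table onto the standardized schema.

    ``condition``/``replicate`` come either from columns of the table or, when
    absent, from the design's sample map keyed on the raw-file/sample label.
    """
    schema = dict(DEFAULT_SCHEMA, **(schema or {}))
    mandatory = ["peptide", "intensity", "sample"]
    for key in mandatory:
        if schema[key] not in df.columns:
            raise ValueError(f"missing mandatory column {schema[key]!r}")
    out = pd.DataFrame(index=df.index)
    out["peptide_raw"] = df[schema["peptide"]].astype(str)
    out["peptide"] = out["peptide_raw"].map(strip_modifications)
    if (out["peptide"] == "").any():
        bad = int(out.index[out["peptide"] == ""][0])
        raise ValueError(f"empty peptide sequence at row {bad}")
    for key, dtype in (("charge", int), ("mz", float)):
        col = schema[key]
        out[key] = df[col].astype(dtype) if col in df.columns else (0 if dtype is int else float("nan"))
    intensity = pd.to_numeric(df[schema["intensity"]], errors="coerce")
    bad_num = intensity.isna() & df[schema["intensity"]].notna() & (df[schema["intensity"]].astype(str).str.strip() != "")
    if bad_num.any():
        raise ValueError(
            f"unparseable intensity at line {int(df.index[bad_num][0]) + 2}"
        )
    out["intensity"] = intensity.fillna(0.0)
    if (out["intensity"] < 0).any():
        raise ValueError("negative intensity encountered")
    out["sample"] = df[schema["sample"]].astype(str)
    if schema["condition"] in df.columns and schema["replicate"] in df.columns:
        out["condition"] = df[schema["condition"]].astype(str)
        out["replicate"] = df[schema["replicate"]].astype(int)
    elif design is not None and design.sample_map:
        unknown = set(out["sample"]) - set(design.sample_map)
        if unknown:
            raise ValueError(f"samples missing from design map: {sorted(unknown)}")
        out["condition"] = out["sample"].map(lambda s: design.sample_map[s][0])
        out["replicate"] = out["sample"].map(lambda s: design.sample_map[s][1])
    else:
        raise ValueError(
            "condition/replicate columns absent and no sample map supplied"
        )
    for key in ("is_reverse", "is_contaminant"):
        col = schema[key]
        if col in df.columns:
            out[key] = (
                df[col] if df[col].dtype == bool else _flag_column(df[col])
            )
        else:
            out[key] = False
    if design is not None:
        unknown_cond = set(out["condition"]) - set(design.conditions)
        if unknown_cond:
            raise ValueError(f"undeclared conditions: {sorted(unknown_cond)}")
    return out.reset_index(drop=True)


def read_evidence(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    design: ExperimentDesign | None = None,
) -> pd.DataFrame:
    """Read a tab-separated evidence table into the standardized schema."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty:
        raise ValueError(f"evidence file {path} contains no rows")
    # restore numerics that dtype=str flattened; standardize handles coercion
    return standardize_evidence(df, schema=schema, design=design)


def filter_rows(df: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop reverse and contaminant hits, reporting removal counts."""
    n_rev = int(df["is_reverse"].sum())
    n_con = int((df["is_contaminant"] & ~df["is_reverse"]).sum())
    kept = df[~df["is_reverse"] & ~df["is_contaminant"]].reset_index(drop=True)
    return kept, {"reverse": n_rev, "contaminant": n_con, "kept": len(kept)}


def replicate_presence_filter(
    df: pd.DataFrame,
    design: ExperimentDesign,
    scope: str = "any_condition",
) -> tuple[set[str], pd.DataFrame]:
    """Keep only peptides observed in every declared biological replicate.

    Presence means at least one unflagged evidence row in a replicate.  Under
    the default ``any_condition`` scope a peptide survives if it is complete
    in at least one condition (preserving condition-specific peptides); under
    ``all_conditions`` it must be complete everywhere.  Flagged rows never
    establish presence, so this filter commutes with :func:`filter_rows`.
    """
    if scope not in ("any_condition", "all_conditions"):
        raise ValueError(f"unknown scope {scope!r}")
    clean = df[~df["is_reverse"] & ~df["is_contaminant"]]
    seen = (
        clean.groupby(["peptide", "condition"])["replicate"]
        .agg(lambda s: frozenset(s))
    )
    retained: set[str] = set()
    for pep in clean["peptide"].unique():
        complete = [
            cond
            for cond, reps in design.conditions.items()
            if (pep, cond) in seen.index and reps <= seen.loc[(pep, cond)]
        ]
        if scope == "any_condition":
            ok = bool(complete)
        else:
            ok = len(complete) == len(design.conditions)
        if ok:
            retained.add(pep)
    out = df[df["peptide"].isin(retained)].reset_index(drop=True)
    return retained, out


def map_peptides(
    peptides: Iterable[str],
    protein_db: Mapping[str, str],
    il_equivalent: bool = True,
) -> list[PeptideAssignment]:
    """Assign each peptide to every database protein containing it.

    Containment is contiguous-substring matching, with I and L equivalent by
    default.  Unmatched peptides yield an empty protein set.
    """
    if il_equivalent:
        folded_db = {pid: fold_il(seq) for pid, seq in protein_db.items()}
    else:
        folded_db = dict(protein_db)
    out = []
    for pep in dict.fromkeys(peptides):  # preserve order, dedupe
        needle = fold_il(pep) if il_equivalent else pep
        hits = frozenset(pid for pid, seq in folded_db.items() if needle in seq)
        out.append(PeptideAssignment(peptide=pep, protein_ids=hits))
    return out


def read_bins(path: str | Path) -> pd.DataFrame:
    """Read a unigene -> BIN annotation map (2-3 column TSV, no header).

    Columns: unigene_id, bin_code[, bin_name].  A unigene may appear on
    several lines with different codes.  Malformed codes are rejected.
    """
    df = pd.read_csv(
        path, sep="\t", header=None, dtype=str,
        names=["unigene_id", "bin_code", "bin_name"],
    )
    df["bin_name"] = df["bin_name"].fillna("")
    bad = ~df["bin_code"].map(lambda c: bool(_BIN_CODE.match(str(c))))
    if bad.any():
        raise ValueError(f"malformed bin_code {df.loc[bad, 'bin_code'].iloc[0]!r}")
    return df


def annotate_evidence(
    df: pd.DataFrame,
    assignments: Sequence[PeptideAssignment],
    bins: pd.DataFrame | None = None,
    count_unmatched: bool = False,
) -> pd.DataFrame:
    """Attach protein and BIN-class annotation columns to evidence rows.

    Adds ``protein_ids`` (frozenset), ``proteotypic`` (bool) and ``bin_codes``
    (frozenset) columns.  A matched peptide inherits the union of its
    proteins' unigene BIN codes; unigenes without annotation map to the
    reserved class ``"35"``.  Unmatched peptides are dropped unless
    ``count_unmatched`` is set, in which case they carry class ``"35"``.
    """
    by_pep = {a.peptide: a for a in assignments}
    bin_map: dict[str, frozenset[str]] = {}
    if bins is not None:
        grouped = bins.groupby("unigene_id")["bin_code"].agg(frozenset)
        bin_map = dict(grouped)

    def pep_bins(a: PeptideAssignment) -> frozenset[str]:
        codes: set[str] = set()
        for pid in a.protein_ids:
            codes |= bin_map.get(pid, frozenset({UNASSIGNED_BIN}))
        return frozenset(codes) if codes else frozenset({UNASSIGNED_BIN})

    known = df["peptide"].map(lambda p: p in by_pep)
    if not known.all():
        missing = df.loc[~known, "peptide"].iloc[0]
        raise ValueError(f"no assignment record for peptide {missing!r}")
    out = df.copy()
    out["protein_ids"] = out["peptide"].map(lambda p: by_pep[p].protein_ids)
    out["proteotypic"] = out["peptide"].map(lambda p: by_pep[p].proteotypic)
    out["bin_codes"] = out["peptide"].map(lambda p: pep_bins(by_pep[p]))
    if not count_unmatched:
        out = out[out["protein_ids"].map(len) > 0].reset_index(drop=True)
    return out
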