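"""In-memory convenience chains over the pipeline stages.

These helpers wire the stages together for programmatic use (the CLI ``run``
subcommand is the file-based equivalent): raw-dialect evidence in, annotated
rows / class fot tables / protein quantitation out.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

from . import evidence as ev
from . import fotquant, lfq

__all__ = ["prepare_annotated", "class_fot", "protein_quant"]


def prepare_annotated(
    evidence_df: pd.DataFrame,
    proteins: Mapping[str, str],
    bins: pd.DataFrame,
    design: ev.ExperimentDesign,
    presence_scope: str = "any_condition",
    il_equivalent: bool = True,
    count_unmatched: bool = False,
) -> tuple[pd.DataFrame, list[ev.PeptideAssignment]]:
    """Standardize, filter, map and annotate a raw-dialect evidence table."""
    rows = ev.standardize_evidence(evidence_df, design=design)
    rows, _ = ev.filter_rows(rows)
    _, rows = ev.replicate_presence_filter(rows, design, scope=presence_scope)
    assignments = ev.map_peptides(
        rows["peptide"].unique(), proteins, il_equivalent=il_equivalent
    )
    annotated = ev.annotate_evidence(
        rows, assignments, bins, count_unmatched=count_unmatched
    )
    return annotated, assignments


def class_fot(
    annotated: pd.DataFrame,
    level: int = 1,
    conditions: Sequence[str] = ("acidic", "alkaline"),
    shared_mode: str = "once_per_class",
) -> pd.DataFrame:
    """Class-level fraction-of-total table from annotated evidence."""
    counts = fotquant.spectral_counts(annotated, level="bin", shared_mode=shared_mode)
    return fotquant.fot(fotquant.rollup_to_level(counts, level), conditions=conditions)


def protein_quant(
    annotated: pd.DataFrame,
    assignments: Sequence[ev.PeptideAssignment],
    design: ev.ExperimentDesign,
    min_reps: int = 3,
    conditions: Sequence[str] = ("acidic", "alkaline"),
    bh: bool = False,
) -> pd.DataFrame:
    """Normalize, scale, average and sum proteotypic ions per protein; attach
    protein-level Welch p-values."""
    scaled = lfq.scale_across_treatments(
        lfq.normalize(lfq.matrix_from_evidence(annotated, design))
    )
    averaged = lfq.average_replicates(scaled, min_reps=min_reps)
    quant = lfq.protein_sums(averaged, assignments, conditions=conditions)
    diff = lfq.differential(
        scaled, level="protein", assignments=assignments,
        conditions=conditions, bh=bh, min_reps=2,
    )
    cols = ["p_value"] + (["p_adj"] if bh else [])
    return quant.join(diff[cols], how="left") if len(diff) else quant.assign(p_value=float("nan"))
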