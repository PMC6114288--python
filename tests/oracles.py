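"""Independent reference implementations used to check pipeline operations.

Everything here is deliberately naive (brute force, direct recomputation,
third-party routines) and shares no code with the package's own
implementations of the operations it checks.
"""

from __future__ import annotations

import re

import numpy as np
import pandas as pd
from Bio.Seq import Seq


def bio_translate(nt: str) -> str:
    """Frame-0 translation via Biopython (ACGT-only sequences)."""
    trimmed = nt[: len(nt) - len(nt) % 3]
    return str(Seq(trimmed).translate())


def brute_force_longest_orf(nt: str) -> tuple[str, int, int, str]:
    """Longest stop-free stretch over all six frames by exhaustive enumeration.

    Returns (strand, frame, aa_start, aa_seq) under the fixed tie-break:
    forward frames 0,1,2 then reverse 0,1,2, leftmost within a frame.
    Only valid for ACGT sequences (Biopython resolves ambiguity differently).
    """
    rc = str(Seq(nt).reverse_complement())
    best = None
    for strand, seq in (("forward", nt), ("reverse", rc)):
        for frame in range(3):
            aa = bio_translate(seq[frame:])
            # every maximal '*'-free stretch, left to right
            pos = 0
            for stretch in aa.split("*"):
                if stretch and (best is None or len(stretch) > len(best[3])):
                    best = (strand, frame, pos, stretch)
                pos += len(stretch) + 1
    assert best is not None
    return best


def interval_union_coverage(protein: str, peptides: list[str], il: bool = True) -> int:
    """Residues covered by any peptide occurrence, via a boolean mask."""
    hay = protein.replace("L", "I") if il else protein
    mask = [False] * len(hay)
    for pep in peptides:
        q = pep.replace("L", "I") if il else pep
        if not q:
            continue
        for m in re.finditer("(?=" + re.escape(q) + ")", hay):
            for i in range(m.start(), m.start() + len(q)):
                mask[i] = True
    return sum(mask)


def presence_retained(
    observed: dict[str, dict[str, set[int]]],
    design: dict[str, set[int]],
    scope: str,
) -> set[str]:
    """Peptides complete in all replicates of >=1 (or all) conditions."""
    out = set()
    for pep, by_cond in observed.items():
        complete = [
            c for c, reps in design.items() if reps <= by_cond.get(c, set())
        ]
        if scope == "any_condition" and complete:
            out.add(pep)
        if scope == "all_conditions" and len(complete) == len(design):
            out.add(pep)
    return out


def normalize_then_scale(values: pd.DataFrame, cond_of: dict[str, str]) -> pd.DataFrame:
    """Direct recomputation of the normalization + cross-treatment scaling."""
    norm = values / values.sum(axis=0, skipna=True)
    conds = sorted(set(cond_of.values()))
    tmeans = pd.DataFrame({
        c: norm[[s for s in norm.columns if cond_of[s] == c]].mean(axis=1)
        for c in conds
    })
    grand = tmeans.mean(axis=1, skipna=True)
    return norm.div(grand, axis=0)
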