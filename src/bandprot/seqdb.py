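"""Protein search-database construction from assembled transcripts.

Non-genome-sequenced organisms have no reference proteome, so peptide-spectrum
matching runs against translated transcriptome assemblies instead: every
unigene is translated in all six reading frames and the longest open reading
frame is kept as that unigene's protein entry.  This module implements that
construction plus the sequence-level computations the downstream analysis
needs: in-silico proteolytic digestion (LysC/trypsin chemistry), average
molecular weight, and peptide sequence coverage.

Conventions
-----------
* Nucleotide coordinates are 0-based, half-open, and always reported on the
  forward strand of the parent transcript; reverse-strand ORFs carry a strand
  flag.
* ``frame`` is the 0/1/2 offset on the chosen strand (i.e. on the
  reverse-complemented sequence for reverse-strand frames).
* Stop codons translate to ``'*'``; any codon containing ``N`` translates to
  ``'X'`` rather than being resolved, even when the ambiguity is synonymous.
* Peptide-to-protein matching treats I and L as indistinguishable by default,
  as mass spectrometry cannot tell them apart.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "TranscriptRecord",
    "OrfProtein",
    "PeptideFragment",
    "CoverageResult",
    "read_transcripts",
    "translate_six_frames",
    "reverse_complement",
    "select_longest_orf",
    "build_database",
    "write_protein_fasta",
    "read_protein_fasta",
    "digest",
    "cleavage_sites",
    "protein_mw",
    "coverage",
    "fold_il",
    "AVERAGE_RESIDUE_MASS",
    "WATER_MASS",
    "NoOrfError",
]

_VALID_NT = re.compile(r"[ACGTN]*\Z")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# Codon -> amino acid under the standard genetic code, stops as '*'.
_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
_CODON_MAP: dict[str, str] = dict(_STANDARD_TABLE.forward_table)
for _stop in _STANDARD_TABLE.stop_codons:
    _CODON_MAP[_stop] = "*"

# IUPAC average residue masses (Da); a free peptide adds one water.
AVERAGE_RESIDUE_MASS: Mapping[str, float] = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594, "N": 114.1038,
    "D": 115.0886, "Q": 128.1307, "K": 128.1741, "E": 129.1155, "M": 131.1926,
    "H": 137.1411, "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}
WATER_MASS = 18.0153

_IL_FOLD = str.maketrans("L", "I")


class NoOrfError(ValueError):
    """No ORF candidate of the required minimum length exists."""


@dataclass(frozen=True)
class TranscriptRecord:
    """An assembled unigene nucleotide sequence."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("transcript id must be non-empty")
        seq = self.seq.upper()
        object.__setattr__(self, "seq", seq)
        if len(seq) < 3:
            raise ValueError(f"sequence too short: {self.id!r} has {len(seq)} nt")
        m = _VALID_NT.match(seq)
        if m is None or m.end() != len(seq):
            pos = next(i for i, c in enumerate(seq) if c not in "ACGTN")
            raise ValueError(
                f"illegal character {seq[pos]!r} at position {pos} in {self.id!r}"
            )


@dataclass(frozen=True)
class OrfProtein:
    """The selected translation product of one unigene.

    ``nt_start``/``nt_end`` are forward-strand coordinates of the coding
    stretch; for ``strand == 'reverse'`` the amino-acid sequence reads from
    ``nt_end`` towards ``nt_start`` on the complementary strand.
    """

    unigene_id: str
    strand: str  # 'forward' | 'reverse'
    frame: int
    nt_start: int
    nt_end: int
    aa_seq: str

    def __post_init__(self) -> None:
        if self.strand not in ("forward", "reverse"):
            raise ValueError(f"bad strand {self.strand!r}")
        if "*" in self.aa_seq or not self.aa_seq:
            raise ValueError("aa_seq must be non-empty and stop-free")
        if self.nt_end - self.nt_start != 3 * len(self.aa_seq):
            raise ValueError("nucleotide span must be 3 x residue count")

    @property
    def length_aa(self) -> int:
        return len(self.aa_seq)


@dataclass(frozen=True)
class PeptideFragment:
    """One proteolytic fragment with residue coordinates in its parent."""

    parent_id: str
    start: int
    end: int
    seq: str
    missed_cleavages: int

    def __post_init__(self) -> None:
        if self.end <= self.start or len(self.seq) != self.end - self.start:
            raise ValueError("inconsistent fragment coordinates")


@dataclass(frozen=True)
class CoverageResult:
    """Fraction of a protein's residues covered by at least one peptide."""

    protein_id: str
    covered_residues: int
    length_aa: int

    @property
    def percent(self) -> float:
        return 100.0 * self.covered_residues / self.length_aa


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _translate_frame(seq: str, frame: int) -> str:
    out = []
    for i in range(frame, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        out.append("X" if "N" in codon else _CODON_MAP[codon])
    return "".join(out)


def translate_six_frames(t: TranscriptRecord | str) -> dict[tuple[str, int], str]:
    """Translate a transcript in all six reading frames.

    Returns a dict keyed by ``(strand, frame)`` with strand in
    ``{'forward', 'reverse'}`` and frame in ``{0, 1, 2}``.  Frame *f* on a
    strand starts at offset *f* of that strand's sequence, so each translation
    has ``floor((len - f) / 3)`` residues.  Stops render as ``'*'`` and codons
    containing ``N`` as ``'X'``.
    """
    if isinstance(t, str):
        t = TranscriptRecord(id="_anon", seq=t)
    rc = reverse_complement(t.seq)
    frames: dict[tuple[str, int], str] = {}
    for f in range(3):
        frames[("forward", f)] = _translate_frame(t.seq, f)
        frames[("reverse", f)] = _translate_frame(rc, f)
    return frames


_FRAME_ORDER = [("forward", 0), ("forward", 1), ("forward", 2),
                ("reverse", 0), ("reverse", 1), ("reverse", 2)]


def _candidates(aa: str, policy: str, x_terminates: bool) -> Iterator[tuple[int, int]]:
    """Yield (start, end) residue intervals of ORF candidates in one frame.

    Under ``stop-to-stop`` a candidate is any maximal stretch free of '*'
    (and of 'X' when ``x_terminates``), including stretches truncated by the
    sequence ends.  Under ``met-to-stop`` a candidate runs from each stretch's
    first Met to the stretch end.
    """
    terminators = "*X" if x_terminates else "*"
    start = None
    for i, c in enumerate(aa + "*"):  # sentinel closes the final stretch
        if c in terminators:
            if start is not None:
                yield (start, i)
                start = None
        elif start is None:
            start = i


def select_longest_orf(
    frames: Mapping[tuple[str, int], str],
    transcript_length: int,
    unigene_id: str = "_anon",
    policy: str = "stop-to-stop",
    min_len: int = 1,
    x_terminates: bool = True,
) -> OrfProtein:
    """Pick the single longest ORF across all six frames.

    Ties break deterministically: forward frames 0,1,2 then reverse 0,1,2,
    and leftmost within a frame.  ``policy='met-to-stop'`` requires the
    candidate to begin at a Met.  Raises :class:`NoOrfError` when no candidate
    reaches ``min_len`` residues.
    """
    if policy not in ("stop-to-stop", "met-to-stop"):
        raise ValueError(f"unknown ORF policy {policy!r}")
    best: tuple[int, int, int] | None = None  # (-length, frame_rank, start)
    best_val: tuple[str, int, int, int] | None = None
    for rank, key in enumerate(_FRAME_ORDER):
        aa = frames[key]
        for s, e in _candidates(aa, policy, x_terminates):
            if policy == "met-to-stop":
                m = aa.find("M", s, e)
                if m < 0:
                    continue
                s = m
            if e - s < min_len:
                continue
            cand = (-(e - s), rank, s)
            if best is None or cand < best:
                best = cand
                best_val = (key[0], key[1], s, e)
    if best_val is None:
        raise NoOrfError(f"no ORF of length >= {min_len} in {unigene_id!r}")
    strand, frame, s, e = best_val
    if strand == "forward":
        nt_start, nt_end = frame + 3 * s, frame + 3 * e
    else:
        nt_start = transcript_length - (frame + 3 * e)
        nt_end = transcript_length - (frame + 3 * s)
    return OrfProtein(
        unigene_id=unigene_id,
        strand=strand,
        frame=frame,
        nt_start=nt_start,
        nt_end=nt_end,
        aa_seq=frames[(strand, frame)][s:e],
    )


def read_transcripts(path: str | Path) -> list[TranscriptRecord]:
    """Read a (possibly wrapped) multi-record nucleotide FASTA."""
    records = [
        TranscriptRecord(id=r.id, seq=str(r.seq)) for r in SeqIO.parse(str(path), "fasta")
    ]
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dup = next(i for i in ids if ids.count(i) > 1)
        raise ValueError(f"duplicate transcript id {dup!r}")
    return records


def build_database(
    transcripts: Iterable[TranscriptRecord],
    policy: str = "stop-to-stop",
    min_aa: int = 30,
    x_terminates: bool = True,
) -> list[OrfProtein]:
    """Six-frame translate every unigene and keep its longest ORF.

    Unigenes with no ORF of at least ``min_aa`` residues are skipped, matching
    proteogenomic practice of excluding spurious short translations.
    """
    db = []
    for t in transcripts:
        frames = translate_six_frames(t)
        try:
            db.append(
                select_longest_orf(
                    frames, len(t.seq), t.id,
                    policy=policy, min_len=min_aa, x_terminates=x_terminates,
                )
            )
        except NoOrfError:
            continue
    return db


def write_protein_fasta(db: Sequence[OrfProtein], path: str | Path) -> None:
    strand_code = {"forward": "f", "reverse": "r"}
    records = [
        SeqRecord(
            Seq(p.aa_seq),
            id=p.unigene_id,
            description=(
                f"strand={strand_code[p.strand]} frame={p.frame} "
                f"start={p.nt_start} end={p.nt_end}"
            ),
        )
        for p in db
    ]
    SeqIO.write(records, str(path), "fasta")


def read_protein_fasta(path: str | Path) -> dict[str, str]:
    """Read a protein FASTA into an id -> sequence mapping."""
    out: dict[str, str] = {}
    for r in SeqIO.parse(str(path), "fasta"):
        if r.id in out:
            raise ValueError(f"duplicate protein id {r.id!r}")
        out[r.id] = str(r.seq)
    return out


def cleavage_sites(aa_seq: str, enzyme: str) -> list[int]:
    """Residue indices *after* which the enzyme cleaves (never the terminus).

    * ``trypsin``: after K or R, except before P.
    * ``lysC``: after K, including before P.
    * ``lysC_then_trypsin``: the union (sequential digestion exposes both
      rule sets, so every site of either enzyme is eventually cut).
    """
    if enzyme == "trypsin":
        def rule(i: int) -> bool:
            return aa_seq[i] in "KR" and aa_seq[i + 1] != "P"
    elif enzyme == "lysC":
        def rule(i: int) -> bool:
            return aa_seq[i] == "K"
    elif enzyme == "lysC_then_trypsin":
        def rule(i: int) -> bool:
            return aa_seq[i] == "K" or (aa_seq[i] == "R" and aa_seq[i + 1] != "P")
    else:
        raise ValueError(f"unknown enzyme {enzyme!r}")
    return [i for i in range(len(aa_seq) - 1) if rule(i)]


def digest(
    protein: OrfProtein | str,
    enzyme: str = "lysC_then_trypsin",
    max_missed: int = 0,
    parent_id: str | None = None,
) -> list[PeptideFragment]:
    """In-silico digest a protein, emitting 0..max_missed missed cleavages.

    Fragments are ordered by start position then missed-cleavage count; the
    zero-missed fragments partition the parent sequence.
    """
    if isinstance(protein, OrfProtein):
        aa_seq = protein.aa_seq
        pid = protein.unigene_id
    else:
        aa_seq = protein
        pid = parent_id or "_anon"
    if not aa_seq:
        raise ValueError("cannot digest an empty sequence")
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    bounds = [0] + [i + 1 for i in cleavage_sites(aa_seq, enzyme)] + [len(aa_seq)]
    frags = []
    for i in range(len(bounds) - 1):
        for missed in range(max_missed + 1):
            j = i + 1 + missed
            if j >= len(bounds):
                break
            s, e = bounds[i], bounds[j]
            frags.append(
                PeptideFragment(
                    parent_id=pid, start=s, end=e, seq=aa_seq[s:e],
                    missed_cleavages=missed,
                )
            )
    return frags


def protein_mw(aa_seq: str) -> float:
    """Average molecular weight (Da) of a peptide or protein.

    Sum of average residue masses plus one water; rejects the empty sequence
    and any non-standard residue (including X).
    """
    if not aa_seq:
        raise ValueError("empty sequence has no molecular weight")
    total = WATER_MASS
    for c in aa_seq:
        try:
            total += AVERAGE_RESIDUE_MASS[c]
        except KeyError:
            raise ValueError(f"non-standard residue {c!r}") from None
    return total


def fold_il(seq: str) -> str:
    """Canonicalize a sequence for I/L-indistinguishable matching."""
    return seq.translate(_IL_FOLD)


def _occurrences(hay: str, needle: str) -> Iterator[int]:
    i = hay.find(needle)
    while i >= 0:
        yield i
        i = hay.find(needle, i + 1)


def coverage(
    protein: OrfProtein | str,
    peptides: Iterable[str],
    il_equivalent: bool = True,
    protein_id: str | None = None,
) -> CoverageResult:
    """Sequence coverage of a protein by a set of identified peptides.

    Every occurrence of every peptide (as a contiguous substring, I/L-folded
    by default) marks its residue interval; the result counts the union, so
    overlaps are not double-counted and absent peptides contribute nothing.
    """
    if isinstance(protein, OrfProtein):
        aa_seq, pid = protein.aa_seq, protein.unigene_id
    else:
        aa_seq, pid = protein, protein_id or "_anon"
    hay = fold_il(aa_seq) if il_equivalent else aa_seq
    covered = [False] * len(aa_seq)
    for pep in peptides:
        if not pep:
            continue
        needle = fold_il(pep) if il_equivalent else pep
        for s in _occurrences(hay, needle):
            for i in range(s, s + len(needle)):
                covered[i] = True
    return CoverageResult(
        protein_id=pid, covered_residues=sum(covered), length_aa=len(aa_seq)
    )
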