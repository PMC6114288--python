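"""Synthetic transcripts, annotations and peptide evidence with ground truth.

The generator emulates the structure of a region-resolved membrane-proteome
experiment on a non-genome-sequenced organism: assembled unigenes carrying one
protein-coding ORF each, a MapMan-style BIN annotation per unigene, and
two-condition (acidic/alkaline surface regions) x three-biological-replicate
peptide-ion evidence tables produced by searching spectra against the
transcript-derived protein database.

Model
-----
* Each protein's baseline abundance is log-normal; its acidic abundance is the
  baseline times a class-level enrichment factor, so enrichment is planted at
  the functional-class level as in the biology being emulated (e.g. transport
  and vesicle-trafficking classes up in acidic regions, photosynthesis down).
* Spectral counts per peptide ion per sample are Poisson with rate
  proportional to the parent protein's condition abundance.
* The total MS1 intensity of an ion in a sample is the condition abundance
  times log-normal multiplicative noise (CV ~ 0.2 by default), divided evenly
  across that sample's spectra of the ion, so that intensity-based signals
  stay proportional to abundance (not to abundance x spectral count).
* A configured fraction of peptides is planted into two parent proteins to
  exercise proteotypicity handling.

Because fot is a compositional statistic, the identifiable quantity for a
class is its enrichment relative to the count-weighted average enrichment of
the whole sample, not the absolute planted factor; the ground-truth object
records both.

Everything is driven by a single integer seed and is byte-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from pyteomics import mass as pyt_mass

from . import seqdb
from .evidence import ExperimentDesign
from .seqdb import TranscriptRecord, reverse_complement

__all__ = [
    "DEFAULT_CLASSES",
    "SimConfig",
    "GroundTruth",
    "simulate_transcripts",
    "simulate_evidence",
    "simulate_dataset",
    "expected_outputs",
    "write_evidence",
    "write_bins",
    "write_design",
]

#: Default BIN classes and their acidic/alkaline enrichment factors, chosen to
#: mirror the directionality observed along a pH-banding internodal cell:
#: transport (~40% up), vesicle trafficking (~45% up), TCA / cell wall /
#: amino-acid metabolism up, photosynthesis light reaction down.
DEFAULT_CLASSES: tuple[tuple[str, str, float], ...] = (
    ("1", "PS.lightreaction", 0.65),
    ("8", "TCA.organic acid transformations", 1.4),
    ("10", "cell wall", 1.3),
    ("13", "amino acid metabolism", 1.3),
    ("21", "redox", 1.0),
    ("26", "misc", 1.0),
    ("29", "protein", 1.0),
    ("30", "signalling", 1.0),
    ("31.4", "cell.vesicle transport", 1.45),
    ("34", "transport", 1.4),
)

# residue alphabet for random proteins; K/R frequencies tuned so tryptic
# peptides average ~9 residues, as in real digests
_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
_AA_W = np.array([
    0.07, 0.02, 0.05, 0.06, 0.04, 0.07, 0.02, 0.05, 0.055, 0.09,
    0.02, 0.04, 0.05, 0.04, 0.055, 0.07, 0.06, 0.065, 0.012, 0.033,
])
_AA_W = _AA_W / _AA_W.sum()

_NT = np.array(list("ACGT"))

# aa -> synonymous codons under the standard code
_BACK_TABLE: dict[str, list[str]] = {}
for _codon, _aa in seqdb._CODON_MAP.items():
    if _aa != "*":
        _BACK_TABLE.setdefault(_aa, []).append(_codon)
for _v in _BACK_TABLE.values():
    _v.sort()

_PROTON = 1.007276


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic experiment (defaults are the study design)."""

    classes: tuple[tuple[str, str, float], ...] = DEFAULT_CLASSES
    proteins_per_class: int = 3
    conditions: tuple[str, str] = ("acidic", "alkaline")
    n_replicates: int = 3
    abundance_mu: float = 0.0
    abundance_sigma: float = 0.7
    count_scale: float = 4.0       # expected spectra / peptide / sample at abundance 1
    intensity_cv: float = 0.2
    intensity_scale: float = 1e6
    shared_peptide_fraction: float = 0.05
    orf_length_range: tuple[int, int] = (80, 250)
    peptide_length_range: tuple[int, int] = (6, 30)
    n_reverse_rows: int = 5
    n_contaminant_rows: int = 5
    max_retries: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.count_scale <= 0 or self.intensity_scale <= 0:
            raise ValueError("rates must be > 0")
        lo, hi = self.orf_length_range
        if not (1 <= lo <= hi):
            raise ValueError("invalid orf_length_range")

    def class_effect(self) -> dict[str, float]:
        return {code: eff for code, _, eff in self.classes}

    def design(self) -> ExperimentDesign:
        reps = frozenset(range(1, self.n_replicates + 1))
        sample_map = {
            f"{cond}_{r}": (cond, r)
            for cond in self.conditions
            for r in sorted(reps)
        }
        return ExperimentDesign(
            conditions={c: reps for c in self.conditions}, sample_map=sample_map
        )


@dataclass
class GroundTruth:
    """Everything needed to recompute expected pipeline outputs."""

    protein_class: dict[str, str]
    protein_name: dict[str, str]
    orf_aa: dict[str, str]
    abundance: dict[str, dict[str, float]]        # protein -> condition -> A
    peptide_parents: dict[str, list[str]]
    peptide_rate: dict[str, dict[str, float]]     # peptide -> condition -> Poisson rate/sample
    sample_counts: dict[str, int] = field(default_factory=dict)
    config: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _random_protein(cfg: SimConfig, rng: np.random.Generator) -> str:
    length = int(rng.integers(cfg.orf_length_range[0], cfg.orf_length_range[1] + 1))
    return "".join(rng.choice(_AA, size=length, p=_AA_W))


def _plant_shared_segment(
    aa: str, donor_peptides: list[str], rng: np.random.Generator
) -> str | None:
    """Splice a donor tryptic peptide into ``aa`` behind a forced K boundary."""
    candidates = [p for p in donor_peptides if p[-1] in "KR" and len(p) >= 7]
    if not candidates:
        return None
    frag = candidates[int(rng.integers(len(candidates)))]
    cut = int(rng.integers(10, max(11, len(aa) - 10)))
    tail = aa[cut:]
    if tail.startswith("P"):
        tail = "A" + tail[1:]
    return aa[:cut] + "K" + frag + tail


def _back_translate(aa: str, rng: np.random.Generator) -> str:
    return "".join(
        _BACK_TABLE[c][int(rng.integers(len(_BACK_TABLE[c])))] for c in aa
    )


def _stop_free_maxima(frames: Mapping[tuple[str, int], str]) -> list[int]:
    """Lengths of all maximal stop-free stretches across the six frames."""
    lengths = []
    for aa in frames.values():
        for stretch in aa.replace("X", "*").split("*"):
            if stretch:
                lengths.append(len(stretch))
    return lengths


def _embed_in_transcript(
    aa: str, rng: np.random.Generator, attempts: int = 8
) -> str | None:
    """Wrap a coding sequence in stop guards and random flanks; accept only
    when the planted ORF is the strictly longest stop-free stretch on any
    frame."""
    for _ in range(attempts):
        orf_nt = _back_translate(aa, rng)
        f5 = "".join(rng.choice(_NT, size=int(rng.integers(5, 41))))
        f3 = "".join(rng.choice(_NT, size=int(rng.integers(5, 41))))
        nt = f5 + "TAA" + orf_nt + "TAA" + f3
        if rng.random() < 0.5:
            nt = reverse_complement(nt)
        lengths = sorted(_stop_free_maxima(seqdb.translate_six_frames(nt)))
        if lengths[-1] == len(aa) and (len(lengths) == 1 or lengths[-2] < len(aa)):
            return nt
    return None


def _make_unigene(
    cfg: SimConfig, rng: np.random.Generator, donor_frags: list[str] | None
) -> tuple[str, str]:
    """Draw an amino-acid sequence and a transcript uniquely encoding it.

    The residue draw is inside the retry loop: a fixed sequence lacking
    certain residues (e.g. Tyr/His/Gln) can leave an anti-sense frame with no
    possible stop codon at any synonymous codon choice, so codon re-draws
    alone need not converge.
    """
    for _ in range(cfg.max_retries):
        aa = _random_protein(cfg, rng)
        if donor_frags is not None:
            planted = _plant_shared_segment(aa, donor_frags, rng)
            if planted is not None:
                aa = planted
        nt = _embed_in_transcript(aa, rng)
        if nt is not None:
            return aa, nt
    raise RuntimeError(
        f"could not embed an ORF as the unique longest stretch within "
        f"{cfg.max_retries} protein draws"
    )


def simulate_transcripts(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[list[TranscriptRecord], GroundTruth]:
    """Generate unigenes, each with exactly one planted longest ORF.

    Returns the transcript records and a partially filled ground truth
    (protein classes, names, planted amino-acid sequences).  Peptide and
    abundance fields are filled by :func:`simulate_evidence`.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    truth = GroundTruth(
        protein_class={}, protein_name={}, orf_aa={}, abundance={},
        peptide_parents={}, peptide_rate={},
    )
    transcripts = []
    proteins: list[tuple[str, str]] = []  # (unigene_id, aa)
    idx = 0
    for code, cname, _eff in cfg.classes:
        for j in range(cfg.proteins_per_class):
            uid = f"CL{1000 + idx}.contig1"
            donor_frags = None
            if proteins and rng.random() < cfg.shared_peptide_fraction:
                _donor_uid, donor_aa = proteins[int(rng.integers(len(proteins)))]
                donor_frags = [
                    f.seq for f in seqdb.digest(donor_aa, "lysC_then_trypsin", 0)
                ]
            aa, nt = _make_unigene(cfg, rng, donor_frags)
            transcripts.append(TranscriptRecord(id=uid, seq=nt))
            proteins.append((uid, aa))
            truth.protein_class[uid] = code
            truth.protein_name[uid] = f"{cname} protein {j + 1}"
            truth.orf_aa[uid] = aa
            idx += 1
    truth.config = asdict(cfg)
    return transcripts, truth


def simulate_evidence(
    cfg: SimConfig,
    truth: GroundTruth,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw a two-condition peptide-evidence table over the planted proteins.

    Returns a raw-dialect evidence DataFrame (MaxQuant column names) and
    completes ``truth`` with abundances, peptide parentage, per-sample Poisson
    rates and the per-sample row tallies actually drawn.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 1)
    effects = cfg.class_effect()
    lo, hi = cfg.peptide_length_range

    # condition abundances per protein
    for uid in truth.orf_aa:
        base = float(rng.lognormal(cfg.abundance_mu, cfg.abundance_sigma))
        eff = effects[truth.protein_class[uid]]
        truth.abundance[uid] = {
            cfg.conditions[0]: base * eff,
            cfg.conditions[1]: base,
        }

    # peptide universe from the in-silico digest
    parents: dict[str, list[str]] = {}
    for uid, aa in truth.orf_aa.items():
        for f in seqdb.digest(aa, "lysC_then_trypsin", 0):
            if lo <= len(f.seq) <= hi:
                parents.setdefault(f.seq, [])
                if uid not in parents[f.seq]:
                    parents[f.seq].append(uid)
    peptides = sorted(parents)
    truth.peptide_parents = {p: parents[p] for p in peptides}

    charges = rng.choice([2, 3], size=len(peptides), p=[0.7, 0.3])
    mzs = np.array([
        pyt_mass.fast_mass(p, charge=int(z))
        for p, z in zip(peptides, charges)
    ])

    samples = [
        (f"{cond}_{r}", cond, r)
        for cond in cfg.conditions
        for r in range(1, cfg.n_replicates + 1)
    ]
    cond_abund = {
        cond: np.array([
            sum(truth.abundance[u][cond] for u in parents[p]) for p in peptides
        ])
        for cond in cfg.conditions
    }
    truth.peptide_rate = {
        p: {
            cond: float(cfg.count_scale * cond_abund[cond][i])
            for cond in cfg.conditions
        }
        for i, p in enumerate(peptides)
    }

    frames = []
    for sample_id, cond, _r in samples:
        rates = cfg.count_scale * cond_abund[cond]
        counts = rng.poisson(rates)
        n = int(counts.sum())
        truth.sample_counts[sample_id] = n
        if n == 0:
            continue
        rep = np.repeat(np.arange(len(peptides)), counts)
        # one noisy ion total per observed (ion, sample), split across spectra
        noise = rng.lognormal(0.0, cfg.intensity_cv, size=len(peptides))
        totals = cfg.intensity_scale * cond_abund[cond] * noise
        with np.errstate(divide="ignore", invalid="ignore"):
            per_row = np.where(counts > 0, totals / np.maximum(counts, 1), 0.0)
        frames.append(pd.DataFrame({
            "Sequence": np.array(peptides, dtype=object)[rep],
            "Charge": charges[rep],
            "m/z": np.round(mzs[rep], 4),
            "Intensity": np.round(per_row[rep], 2),
            "Raw file": sample_id,
            "Experiment": cond,
            "Reverse": "",
            "Potential contaminant": "",
        }))

    # decoy and contaminant rows exercise the exclusion filter
    decoys = []
    for i in range(cfg.n_reverse_rows):
        pep = peptides[int(rng.integers(len(peptides)))][::-1]
        decoys.append((pep, "+", ""))
    for i in range(cfg.n_contaminant_rows):
        pep = "".join(rng.choice(_AA, size=12, p=_AA_W))
        decoys.append((pep, "", "+"))
    if decoys:
        sample_id, cond, _ = samples[0]
        frames.append(pd.DataFrame({
            "Sequence": [d[0] for d in decoys],
            "Charge": 2,
            "m/z": [
                round(pyt_mass.fast_mass(d[0], charge=2), 4) for d in decoys
            ],
            "Intensity": np.round(
                rng.lognormal(0.0, cfg.intensity_cv, size=len(decoys))
                * cfg.intensity_scale, 2
            ),
            "Raw file": sample_id,
            "Experiment": cond,
            "Reverse": [d[1] for d in decoys],
            "Potential contaminant": [d[2] for d in decoys],
        }))
    return pd.concat(frames, ignore_index=True)


def expected_outputs(truth: GroundTruth) -> dict:
    """Closed-form expectations of the pipeline summaries under the truth.

    Returns per-class expected spectral counts and fot per condition (Poisson
    mean additivity over member peptides and replicates; shared peptides
    contribute once per class), the per-class expected fot ratio minus one,
    and per-protein expected log2 acidic/alkaline ratios.
    """
    cfg = truth.config
    conditions = list(cfg["conditions"])
    n_rep = int(cfg["n_replicates"])
    class_counts: dict[str, dict[str, float]] = {}
    for pep, rates in truth.peptide_rate.items():
        codes = {truth.protein_class[u] for u in truth.peptide_parents[pep]}
        for code in codes:
            slot = class_counts.setdefault(code, {c: 0.0 for c in conditions})
            for cond in conditions:
                slot[cond] += rates[cond] * n_rep
    totals = {
        cond: sum(v[cond] for v in class_counts.values()) for cond in conditions
    }
    class_fot = {
        code: {cond: v[cond] / totals[cond] for cond in conditions}
        for code, v in class_counts.items()
    }
    a, b = conditions[0], conditions[1]
    ratio_minus1 = {
        code: class_fot[code][a] / class_fot[code][b] - 1.0
        for code in class_fot
        if class_fot[code][b] > 0
    }
    log2_protein = {
        uid: float(np.log2(ab[a] / ab[b]))
        for uid, ab in truth.abundance.items()
    }
    return {
        "class_counts": class_counts,
        "class_fot": class_fot,
        "class_ratio_minus1": ratio_minus1,
        "protein_log2_ratio": log2_protein,
    }


def write_evidence(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_bins(truth: GroundTruth, cfg: SimConfig, path: str | Path) -> None:
    names = {code: name for code, name, _ in cfg.classes}
    with open(path, "w") as fh:
        for uid in sorted(truth.protein_class):
            code = truth.protein_class[uid]
            fh.write(f"{uid}\t{code}\t{names.get(code, '')}\n")


def write_design(cfg: SimConfig, path: str | Path) -> None:
    cfg.design().to_yaml(path)


def simulate_dataset(
    cfg: SimConfig, outdir: str | Path | None = None
) -> tuple[list[TranscriptRecord], pd.DataFrame, GroundTruth]:
    """Generate a complete dataset; optionally write it to ``outdir``.

    Files written: ``unigenes.fna``, ``evidence.tsv``, ``bins.tsv``,
    ``design.yaml``, ``truth.json``.
    """
    rng = np.random.default_rng(cfg.seed)
    transcripts, truth = simulate_transcripts(cfg, rng)
    ev = simulate_evidence(cfg, truth, rng)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        from Bio.Seq import Seq
        from Bio.SeqIO import write as seqio_write
        from Bio.SeqRecord import SeqRecord

        seqio_write(
            [SeqRecord(Seq(t.seq), id=t.id, description="") for t in transcripts],
            str(outdir / "unigenes.fna"), "fasta",
        )
        write_evidence(ev, outdir / "evidence.tsv")
        write_bins(truth, cfg, outdir / "bins.tsv")
        write_design(cfg, outdir / "design.yaml")
        truth.to_json(outdir / "truth.json")
    return transcripts, ev, truth
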