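# Methods

This note documents the models and procedures `bandprot` implements, the
parameters that matter, and the design choices made where the underlying
analysis recipe left room.

## Search-database construction

Assembled unigenes are translated in all six reading frames under the standard
genetic code. Stop codons render as `*`; any codon containing `N` renders as
`X` unconditionally — even where the ambiguity is synonymous (e.g. GGN) — so
no residue is ever fabricated from ambiguous bases. By default `X` also
terminates ORF candidates.

An ORF candidate is any maximal stop-free stretch within a frame, with
stretches truncated by the sequence ends allowed and no start codon required.
De novo assemblies are dominated by partial transcripts, so requiring a Met
start would discard most genuine coding sequence; the stricter Met-to-stop
policy is available via `--orf-policy met-to-stop`. The single longest
candidate across all six frames is selected; ties break deterministically by
frame order (forward 0, 1, 2, then reverse 0, 1, 2) and leftmost within a
frame. Note that a transcript and its reverse complement therefore yield the
same protein only up to this tie-break when two opposite-strand candidates
have exactly equal length.

Coordinates are 0-based half-open nucleotide positions on the forward strand
of the parent transcript, with a strand flag; `nt_end − nt_start` always
equals three times the residue count. Database construction skips unigenes
whose best ORF is shorter than `min_aa` (default 30 aa, ordinary
proteogenomics practice; the operation itself accepts `min_len=1`).

## In-silico digestion

The digestion chemistry is sequential LysC-then-trypsin. Cleavage rules:
trypsin cuts after K or R except before P; LysC cuts after K including before
P; the combined enzyme applies the union of both site sets, since sequential
digestion eventually exposes every site of either enzyme. Fragments carry
residue coordinates and missed-cleavage counts from 0 to `max_missed`;
zero-missed fragments partition the parent exactly. The implementation is
checked in the test suite against `pyteomics.parser.cleave` as an independent
rule engine.

## Masses and coverage

Molecular weights are sums of IUPAC average residue masses plus one water
(18.0153 Da), reported in Da and rounded to 0.1 kDa for display; non-standard
residues (including X) are rejected rather than approximated. Peptide
sequence coverage is the size of the union of all residue intervals where a
peptide occurs as a contiguous substring, divided by protein length. I and L
are treated as equivalent in all peptide-to-protein matching by default
because mass spectrometry cannot distinguish them; the equivalence is
switchable.

## Evidence filtering

Reverse and contaminant hits are removed first. The replicate-presence filter
keeps a peptide only if it is observed (at least one unflagged row) in every
declared replicate of at least one condition; the alternative global scope
(complete in every condition) is available but not the default, because
condition-specific proteins — rows with zero counts in one membrane fraction —
are an expected and biologically meaningful outcome. Flagged rows never
establish presence, which makes the two filters commute. Modified peptide
strings are stripped to their plain sequence for mapping and identity
purposes, while (sequence, charge, m/z) remains the ion identity for
quantitation.

## Spectral counting and fot

Each evidence row is one spectral observation. At the class level a shared
(non-proteotypic) peptide's spectrum counts once per distinct BIN class among
its parent proteins — never twice within one class — with a strict mode that
drops shared peptides entirely. Peptides whose unigene carries no annotation
fall into the reserved class 35 ("not assigned"), which is included in the
fot denominator: the fraction of total is read as a whole-sample share. Class
counts roll up the dotted BIN hierarchy by code prefix (34.1.1 → 34.1 → 34).

fot ratios are compositional: a class's fot(acidic)/fot(alkaline) − 1 equals
its enrichment factor relative to the count-weighted average enrichment of
the whole sample. Only this relative signal is identifiable from fractions;
classes whose planted factors equal the sample average come out at ratio 0.
Ratios with a zero denominator are reported as flagged missing values and
excluded from plots. Percent excess values are rounded to the nearest integer,
halves away from zero, matching the precision of printed report tables.

## Label-free quantitation

The stage order is fixed and semantic: (1) within each sample, divide every
ion intensity by the sample's total ion intensity — this makes the pipeline
exactly invariant to rescaling any single sample; (2) divide each ion by the
grand mean of its per-treatment mean normalized intensities, taken over the
treatments in which the ion was observed; (3) average per condition over
observed replicates, requiring at least `min_reps` (default 3) observations;
(4) sum averaged scaled intensities over proteotypic ions per protein. Zero
intensities are treated as not-quantified and excluded from every mean; no
imputation is performed.

Differential testing is a two-sided Welch t-test on log-transformed
replicate-level scaled values, at the ion level or on replicate-wise
proteotypic-ion sums at the protein level. The log transform stabilizes the
multiplicative noise; the reported ratio is log2 of the ratio of arithmetic
condition means. Degenerate inputs are handled explicitly: zero variance in
both groups yields p = 1 for equal means and the smallest representable
positive p (flagged by construction) for unequal means. Benjamini–Hochberg
adjustment is available behind a flag and off by default, mirroring analyses
that draw a raw p = 0.05 line. Welch's test is deliberately conservative at
3–4 replicates (true type-I error ≈ 0.035–0.045 at nominal 0.05); the
acceptance checks measure this calibration rather than assuming nominality.

## Synthetic data generator

The generator emulates the study design: two conditions (acidic/alkaline
surface regions) × 3 biological replicates (configurable, ≥3 by default) of
peptide evidence over a transcript-derived database. Defaults, chosen once as
the simulated study conditions:

- 10 MapMan-style BIN classes × 3 proteins, ORF lengths uniform in 80–250 aa
  (consistent with partial ORFs from an assembly whose unigenes average
  ~600 nt). Class enrichment factors mirror the biology being emulated:
  transport 1.4, vesicle transport 1.45, TCA 1.4, cell wall and amino-acid
  metabolism 1.3, photosynthesis light reaction 0.65, remainder 1.0.
- Protein baseline abundance log-normal(μ = 0, σ = 0.7); acidic abundance is
  the baseline times the class factor.
- Spectral counts per peptide per sample Poisson with rate
  `count_scale × abundance` (count_scale 4.0, giving a few hundred spectra
  per class per condition). A negative-binomial option is not provided; the
  Poisson default matches ordinary spectral-count practice and the class-level
  statistics aggregate over many peptides anyway.
- The total MS1 intensity of an ion in a sample is
  `intensity_scale × abundance × LogNormal(0, 0.2)`, split evenly across that
  sample's spectra of the ion. Intensities are noised per ion-sample rather
  than per spectrum so that the intensity signal stays proportional to
  abundance; noising each spectrum independently and summing would make ion
  totals scale with abundance × spectral count, i.e. quadratically.
- 5% of proteins embed one tryptic peptide copied from a previously generated
  protein (spliced behind a forced K boundary), producing genuinely shared,
  non-proteotypic peptides.
- A handful of reverse and contaminant rows exercise the exclusion filter.

Each unigene contains exactly one planted ORF: the coding sequence is wrapped
in in-frame stop guards and random flanks, placed on a random strand, and the
construct is rejection-sampled until the planted ORF is the strictly longest
stop-free stretch across all six frames. The amino-acid draw sits inside the
retry loop: a fixed residue sequence lacking Tyr/His/Gln can leave an
anti-sense frame with no possible stop codon under any synonymous codon
choice, in which case codon re-draws alone would never converge.

Everything is driven by one integer seed and is byte-reproducible.
`expected_outputs` returns closed-form expectations (Poisson mean additivity,
rate shares, abundance ratios) for every pipeline summary, used by the
recovery tests.

What the generator does **not** model: chromatography and retention time,
match-between-runs, modified peptides, peptide detectability differences,
count overdispersion beyond Poisson, and realistic decoy/contaminant
sequences. Passing recovery tests therefore demonstrate correctness of the
pipeline's arithmetic and its statistical behaviour under the stated noise
model, not robustness to every artefact of real LC-MS/MS data.

## Reference count table

The packaged table transcribes published per-protein spectral counts for the
transport and vesicle-transport BIN classes (89 + 32 member rows) together
with the printed per-section subtotals. One section (34.21 transport.calcium)
is incomplete at the member level in the transcription — three surviving rows
sum to 98/42/56 against a printed subtotal of 195/93/102 — so its printed
subtotal is treated as authoritative and the member-sum integrity check skips
it. All quantities the acceptance suite asserts (class 34.1.1 total 1469,
porins acidic 224, vesicle-transport acidic total 1002, enrichment 40% for
the P-/V-ATPase class and 45% for clathrin heavy chain) derive from complete
sections.

## Problem sizes in the checks

The acceptance computations use 200 random transcripts for the ORF oracle,
200 random protein/peptide sets for the coverage oracle, a ~110-protein
four-replicate null simulation yielding ≈1000 testable ions for type-I
calibration, one four-replicate experiment with a balanced two-fold design
(one class doubled, one halved — balanced so the whole-sample normalization
denominator stays comparable between conditions and absolute log2 effects
remain identifiable) for effect recovery, and 100 re-simulated experiments
for class-sign recovery. These sizes keep the full suite fast while leaving
Monte-Carlo error well inside the asserted tolerances.

## Known limitations

- Protein-level spectral counts attribute shared-peptide spectra to every
  matching protein; only the class-level statistic deduplicates within a
  class. Strict proteotypic-only counting is available.
- The fot statistic cannot recover absolute enrichment factors (composition
  constraint); interpretation is always relative to the sample average.
- The Welch test at 3 replicates has limited power and conservative size;
  the BH option controls FDR only across the keys actually tested.
- Longest-ORF selection reports exactly one ORF per unigene; polycistronic
  or chimeric unigenes are outside the model.
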