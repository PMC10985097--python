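"""Candidate screening: tiering, hydrophobicity, the SPM-style filter and
cysteine-count peptide screening.

Sea anemone toxin precursors translated from transcriptome assemblies are
split into *proteins* and *peptides* at 80 amino acids; secreted-peptide
candidates are additionally flagged by a length/hydrophobicity rule
(length <= 200 aa, hydrophobic fraction >= 0.70) and peptides are required
to carry at least 4 cysteines to count as disulfide-stabilised toxin
candidates.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

from .io_formats import SequenceRecord, ValidationError

#: Kyte-Doolittle-positive hydrophobic residues. 'X' is never hydrophobic.
HYDROPHOBIC_SET = frozenset("ACFILMV")

PEPTIDE_MAX_AA = 80
SPM_MAX_AA = 200
SPM_MIN_HYDRO = 0.70
MIN_CYS = 4

#: homolog-search E-value cutoffs recorded for provenance; the external
#: database searches themselves are out of scope for this artifact.
HOMOLOG_EVALUE_BLASTX = 1e-5
HOMOLOG_EVALUE_DIAMOND = 1e-8


@dataclass(frozen=True)
class ScreenResult:
    """Screening outcome for one sequence."""

    record: SequenceRecord
    tier: str                       # "protein" | "peptide"
    length_aa: int
    cys_count: int
    hydrophobic_fraction: float
    passed_spm: bool
    passed_peptide_screen: bool


def classify_tier(seq: str, peptide_max_aa: int = PEPTIDE_MAX_AA) -> str:
    """Tier a sequence: 'peptide' iff length <= 80 aa (inclusive), else
    'protein'."""
    if not seq:
        raise ValidationError("cannot tier an empty sequence")
    return "peptide" if len(seq) <= peptide_max_aa else "protein"


def hydrophobic_fraction(seq: str) -> float:
    """Fraction of residues in the hydrophobic set {A,C,F,I,L,M,V}.

    'X' counts in the denominator but never in the numerator.
    """
    if not seq:
        raise ValidationError("cannot compute hydrophobicity of empty sequence")
    return sum(1 for ch in seq if ch in HYDROPHOBIC_SET) / len(seq)


def spm_screen(seq: str, max_aa: int = SPM_MAX_AA,
               min_hydro: float = SPM_MIN_HYDRO) -> bool:
    """Secreted-peptide-mining style flag: length <= 200 and hydrophobic
    fraction >= 0.70.  A flag, not a hard filter: it is one of several
    prediction routes, so failing it does not remove a candidate."""
    return len(seq) <= max_aa and hydrophobic_fraction(seq) >= min_hydro


def peptide_screen(tier: str, cys_count: int, min_cys: int = MIN_CYS) -> bool:
    """Disulfide-rich peptide rule: peptide tier and >= 4 cysteines."""
    return tier == "peptide" and cys_count >= min_cys


def screen_record(record: SequenceRecord, *,
                  peptide_max_aa: int = PEPTIDE_MAX_AA,
                  min_cys: int = MIN_CYS,
                  spm_max_aa: int = SPM_MAX_AA,
                  spm_hydro: float = SPM_MIN_HYDRO) -> ScreenResult:
    tier = classify_tier(record.seq, peptide_max_aa)
    cys = record.seq.count("C")
    return ScreenResult(
        record=record,
        tier=tier,
        length_aa=len(record.seq),
        cys_count=cys,
        hydrophobic_fraction=hydrophobic_fraction(record.seq),
        passed_spm=spm_screen(record.seq, spm_max_aa, spm_hydro),
        passed_peptide_screen=peptide_screen(tier, cys, min_cys),
    )


def screen_records(records, **kw) -> list[ScreenResult]:
    return [screen_record(r, **kw) for r in records]


# ---------------------------------------------------------------------------
# ORF finding

_FRAMES = (1, 2, 3, -1, -2, -3)


def find_longest_orf(nucleotide_seq: str, min_nt: int = 30) -> str:
    """Translate the longest start-to-stop ORF across all six frames.

    Returns the amino-acid translation (without the stop). Ties between
    equally long ORFs are broken by frame order +1, +2, +3, -1, -2, -3 then
    by position.  Returns '' when no ORF of at least ``min_nt`` nucleotides
    (codons incl. stop) exists.
    """
    dna = nucleotide_seq.upper()
    if not set(dna) <= set("ACGTN"):
        bad = sorted(set(dna) - set("ACGTN"))
        raise ValidationError(f"illegal nucleotide characters {bad}")
    best = ""  # longest wins; earlier frame/position wins ties
    for frame in _FRAMES:
        s = dna if frame > 0 else str(Seq(dna).reverse_complement())
        off = abs(frame) - 1
        prot = str(Seq(s[off:off + (len(s) - off) // 3 * 3]).translate())
        start = 0
        while True:
            m = prot.find("M", start)
            if m == -1:
                break
            stop = prot.find("*", m)
            if stop == -1:
                start = m + 1
                continue
            orf_nt = (stop - m + 1) * 3
            if orf_nt >= min_nt and (stop - m) > len(best):
                best = prot[m:stop]
            start = m + 1
    return best
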