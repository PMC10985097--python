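"""Ground-truthed synthetic fixtures: toxin precursors with chosen cysteine
scaffolds and over-dispersed per-tissue count tables.

The generator emulates the architecture of secreted toxin precursors —
hydrophobic signal peptide + pro-region + cysteine-rich mature domain whose
cysteine spacing realizes a chosen family scaffold — plus scaffold-free
decoy sequences, so every downstream stage (screening, scaffold
classification, family annotation, expression sharing, phylogenetics) can
be tested against a known truth table without any external data.

Counts are negative binomial (over-dispersion is the norm in RNA-seq) with
a per-sequence tissue presence mask; the 'combine' dataset is the union of
the tissue datasets.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import scaffold as _scaffold
from .io_formats import (CountRow, ReferenceToxin, SequenceRecord, TISSUES,
                         ValidationError, write_counts, write_fasta)
from .screening import HYDROPHOBIC_SET, classify_tier

_NON_CYS = "ADEFGHIKLMNPQRSTVWY"        # 19 letters, no C, no X
_HYDRO = sorted(HYDROPHOBIC_SET - {"C"})


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic fixture.

    Defaults give five family cohorts of 25 mature peptides each at 10%
    non-cysteine divergence from the family prototype, 20% decoys, and
    negative binomial counts (mean 50, dispersion 5) over three tissues.
    """

    seed: int = 0
    n_per_family: int = 25
    families: tuple[str, ...] = tuple(t.family
                                      for t in _scaffold.DEFAULT_TEMPLATES)
    mutation_rate: float = 0.10
    preserve_cys: bool = True
    signal_len: int = 20
    pro_len_max: int = 30
    tissues: tuple[str, ...] = TISSUES
    nb_mean: float = 50.0
    nb_dispersion: float = 5.0
    decoy_fraction: float = 0.20
    emit: str = "mature"                 # "mature" | "precursor"

    def validate(self) -> None:
        if not 0 <= self.mutation_rate <= 1:
            raise ValidationError("mutation_rate must be in [0,1]")
        if not 0 <= self.decoy_fraction < 1:
            raise ValidationError("decoy_fraction must be in [0,1)")
        if self.n_per_family < 1 or self.signal_len < 0:
            raise ValidationError("invalid cohort sizes")
        if self.nb_mean <= 0 or self.nb_dispersion <= 0:
            raise ValidationError("negative binomial parameters must be > 0")
        if self.emit not in ("mature", "precursor"):
            raise ValidationError(f"unknown emit mode {self.emit!r}")
        known = {t.family for t in _scaffold.DEFAULT_TEMPLATES}
        unknown = set(self.families) - known
        if unknown:
            raise ValidationError(f"unknown families {sorted(unknown)}")


def _template(family: str) -> _scaffold.FamilyTemplate:
    return next(t for t in _scaffold.DEFAULT_TEMPLATES if t.family == family)


def make_mature(template: _scaffold.FamilyTemplate,
                rng: np.random.Generator,
                flank_max: int = 4) -> str:
    """Random mature domain realizing a family scaffold.

    Spacers written 'CXnC' get exactly n random non-Cys residues; '-'
    spacers draw uniformly from 4-12; short random non-Cys flanks are added
    at both termini.  Peptide-family outputs stay <= 80 aa.
    """
    spec = _scaffold.parse_pattern(template.pattern)
    spacers = [int(rng.integers(4, 13)) if s is None else s for s in spec]
    n_flank = [int(rng.integers(0, flank_max + 1)),
               int(rng.integers(0, flank_max + 1))]

    if template.peptide:
        # shrink the largest free spacers (never below 4) until <= 80 aa
        def total() -> int:
            return len(spec) + 1 + sum(spacers) + sum(n_flank)
        free = [i for i, s in enumerate(spec) if s is None]
        while total() > 80:
            if n_flank[0] + n_flank[1] > 0:
                k = 0 if n_flank[0] >= n_flank[1] else 1
                n_flank[k] -= 1
                continue
            if not free:
                raise ValidationError(
                    f"{template.family} template cannot fit a <=80 aa peptide")
            i = max(free, key=lambda k: spacers[k])
            if spacers[i] <= 4:
                raise ValidationError(
                    f"{template.family} template cannot fit a <=80 aa peptide")
            spacers[i] -= 1

    def fill(n: int) -> str:
        return "".join(rng.choice(list(_NON_CYS), size=n))

    parts = ["C"]
    for n in spacers:
        parts.append(fill(n) + "C")
    return fill(n_flank[0]) + "".join(parts) + fill(n_flank[1])


def mutate(seq: str, rate: float, preserve_cys: bool,
           rng: np.random.Generator) -> str:
    """Substitute each position independently with probability ``rate``.

    With ``preserve_cys`` cysteines are untouched and substitutions never
    introduce a cysteine, so the scaffold is invariant; without it,
    substitutions draw uniformly from the 19 alternative residues.
    """
    if not 0 <= rate <= 1:
        raise ValidationError("rate must be in [0,1]")
    alphabet = "ACDEFGHIKLMNPQRSTVWY"
    out = []
    for ch in seq:
        if preserve_cys and ch == "C":
            out.append(ch)
            continue
        if rng.random() < rate:
            choices = [a for a in alphabet if a != ch
                       and not (preserve_cys and a == "C")]
            out.append(str(rng.choice(choices)))
        else:
            out.append(ch)
    return "".join(out)


def make_signal(rng: np.random.Generator, length: int) -> str:
    """Hydrophobic-rich signal peptide (>= 70% residues from the
    hydrophobic set, cysteine-free) starting with M."""
    n_hydro = max(int(np.ceil(0.75 * length)), 1)
    body = [str(rng.choice(_HYDRO)) for _ in range(n_hydro - 1)]
    body += [str(rng.choice(list("DEKNQRST")))
             for _ in range(length - n_hydro)]
    rng.shuffle(body)
    return ("M" + "".join(body))[:length]


def make_decoy(rng: np.random.Generator) -> str:
    """Scaffold-free decoy: uniform non-Cys composition with at most 3
    cysteines sprinkled in, 30-70 aa."""
    n = int(rng.integers(30, 71))
    seq = list("".join(rng.choice(list(_NON_CYS), size=n)))
    for pos in rng.choice(n, size=int(rng.integers(0, 4)), replace=False):
        seq[pos] = "C"
    return "".join(seq)


@dataclass
class TruthRow:
    id: str
    family: str                 # family name or "decoy"
    pattern: str
    tier: str
    mature: str
    precursor: str
    presence: dict[str, bool]   # tissue -> expected presence


def simulate_counts(truth: Sequence[TruthRow], config: SimConfig,
                    rng: np.random.Generator) -> list[CountRow]:
    """Negative binomial counts per tissue, zeroed where the presence mask
    is off.  Parameterized by mean m and dispersion r: NB(r, r/(r+m))."""
    r = config.nb_dispersion
    m = config.nb_mean
    p = r / (r + m)
    rows = []
    for t in truth:
        seq = t.precursor if config.emit == "precursor" else t.mature
        counts = {}
        for tissue in config.tissues:
            if t.presence[tissue]:
                counts[tissue] = float(max(1, rng.negative_binomial(r, p)))
            else:
                counts[tissue] = 0.0
        rows.append(CountRow(t.id, len(seq) * 3, counts))
    return rows


def generate(config: SimConfig) -> tuple[list[SequenceRecord],
                                         list[ReferenceToxin],
                                         list[TruthRow],
                                         list[CountRow]]:
    """Generate the full fixture in memory.

    Returns (records, references, truth, count rows).  References are the
    unmutated family prototypes (one per family), suitable as a synthetic
    annotation reference set.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    truth: list[TruthRow] = []
    references: list[ReferenceToxin] = []

    for family in config.families:
        tmpl = _template(family)
        proto = make_mature(tmpl, rng)
        references.append(ReferenceToxin(
            id=f"ref_{family}_synthetic", seq=proto, family=family,
            connectivity=tmpl.connectivity))
        for k in range(config.n_per_family):
            mature = mutate(proto, config.mutation_rate,
                            config.preserve_cys, rng)
            signal = make_signal(rng, config.signal_len)
            pro = "".join(rng.choice(list(_NON_CYS),
                                     size=int(rng.integers(0, config.pro_len_max + 1))))
            precursor = signal + pro + mature
            presence = _random_presence(rng, config.tissues)
            seq = precursor if config.emit == "precursor" else mature
            truth.append(TruthRow(
                id=f"{family}_{k:03d}", family=family,
                pattern=_scaffold.canonical_pattern(mature),
                tier=classify_tier(seq), mature=mature, precursor=precursor,
                presence=presence))

    n_toxins = len(truth)
    n_decoys = round(config.decoy_fraction / (1 - config.decoy_fraction)
                     * n_toxins)
    for k in range(n_decoys):
        seq = make_decoy(rng)
        truth.append(TruthRow(
            id=f"decoy_{k:03d}", family="decoy",
            pattern=_scaffold.canonical_pattern(seq),
            tier=classify_tier(seq), mature=seq, precursor=seq,
            presence=_random_presence(rng, config.tissues)))

    records = [
        SequenceRecord(
            id=t.id,
            seq=t.precursor if config.emit == "precursor" else t.mature,
            dataset="combine", description=f"synthetic {t.family}")
        for t in truth
    ]
    counts = simulate_counts(truth, config, rng)
    return records, references, truth, counts


def _random_presence(rng: np.random.Generator,
                     tissues: Sequence[str]) -> dict[str, bool]:
    # every sequence is present somewhere; each tissue kept w.p. 2/3
    while True:
        mask = {t: bool(rng.random() < 2 / 3) for t in tissues}
        if any(mask.values()):
            return mask


def make_dataset(config: SimConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write the fixture to disk: one FASTA per dataset (tissues plus
    'combine' as their union), a counts TSV, a reference FASTA/JSON and the
    truth table JSON.  Byte-identical across runs with the same config."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records, references, truth, counts = generate(config)
    by_id = {r.id: r for r in records}

    paths: dict[str, Path] = {}
    for tissue in config.tissues:
        present = [dataclasses.replace(by_id[t.id], dataset=tissue)
                   for t in truth if t.presence[tissue]]
        paths[tissue] = out / f"{tissue}.fasta"
        write_fasta(present, paths[tissue])
    paths["combine"] = out / "combine.fasta"
    write_fasta([dataclasses.replace(r, dataset="combine") for r in records],
                paths["combine"])

    paths["counts"] = out / "counts.tsv"
    write_counts(counts, paths["counts"])

    paths["references"] = out / "references_synthetic.fasta"
    write_fasta([SequenceRecord(r.id, r.seq, "combine", f"family={r.family}")
                 for r in references], paths["references"])

    paths["truth"] = out / "truth.json"
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        json.dump([dataclasses.asdict(t) for t in truth], fh, indent=1,
                  sort_keys=True)
        fh.write("\n")
    return paths


def load_truth(path: str | Path) -> pd.DataFrame:
    with open(path, encoding="utf-8") as fh:
        return pd.DataFrame(json.load(fh))
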