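"""TPM normalization, presence calls, multi-dataset sharing (Venn) analysis,
top-N rankings, family aggregation and the |log2 FC| > 2 flag.

TPM (transcripts per million) is the length-normalized rate measure whose
values sum to 1e6 per sample: rate_i = count_i / (length_i / 1000),
tpm_i = rate_i / sum(rates) * 1e6.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import CountRow, ValidationError

MIN_TPM_DEFAULT = 0.0       # presence is strict TPM > min_tpm
LOGFC_THRESHOLD = 2.0
PSEUDOCOUNT = 1.0


@dataclass
class ExpressionTable:
    """Counts and derived TPM, transcripts x tissues."""

    counts: pd.DataFrame          # index transcript ids, columns tissues
    lengths: pd.Series            # bp per transcript
    tpm: pd.DataFrame
    empty_tissues: tuple[str, ...] = ()

    @property
    def transcripts(self) -> list[str]:
        return list(self.counts.index)

    @property
    def tissues(self) -> list[str]:
        return list(self.counts.columns)


def compute_tpm(counts: pd.DataFrame | Sequence[CountRow],
                lengths: pd.Series | None = None) -> ExpressionTable:
    """Compute TPM per tissue.  Accepts a counts DataFrame plus a lengths
    Series, or a list of :class:`CountRow`.

    An all-zero tissue yields an all-zero TPM column and is flagged in
    ``empty_tissues``.
    """
    if not isinstance(counts, pd.DataFrame):
        rows = list(counts)
        lengths = pd.Series({r.transcript_id: r.length_bp for r in rows})
        counts = pd.DataFrame({r.transcript_id: r.counts for r in rows}).T
        counts.index.name = "transcript_id"
    if lengths is None:
        raise ValidationError("lengths required with a counts DataFrame")
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = list(lengths[lengths.isna()].index)
        raise ValidationError(f"no length for transcripts {missing[:5]}")
    if (lengths <= 0).any():
        bad = list(lengths[lengths <= 0].index)
        raise ValidationError(f"non-positive length for {bad[:5]}")
    if (counts.to_numpy() < 0).any():
        raise ValidationError("negative counts")

    rate = counts.div(lengths / 1000.0, axis=0)
    colsum = rate.sum(axis=0)
    empty = tuple(colsum.index[colsum == 0])
    denom = colsum.replace(0, np.nan)
    tpm = (rate / denom * 1e6).fillna(0.0)
    return ExpressionTable(counts=counts, lengths=lengths, tpm=tpm,
                           empty_tissues=empty)


def presence_sets(table: ExpressionTable | Mapping[str, Iterable[str]],
                  min_tpm: float = MIN_TPM_DEFAULT) -> dict[str, set[str]]:
    """Per-dataset presence sets: id present iff TPM > min_tpm (strict).

    Explicit per-dataset id lists bypass the TPM rule and are used as-is.
    """
    if isinstance(table, ExpressionTable):
        return {t: set(table.tpm.index[table.tpm[t] > min_tpm])
                for t in table.tissues}
    return {k: set(v) for k, v in table.items()}


@dataclass
class SharingReport:
    """Region counts of a 2-4 set Venn decomposition plus pairwise overlaps."""

    sets: dict[str, set[str]]
    regions: dict[frozenset, int]            # exclusive region -> count
    pairwise: dict[tuple[str, str], int]     # |A ∩ B| (not exclusive)
    common_all: set[str] = field(default_factory=set)

    @property
    def n_common(self) -> int:
        return len(self.common_all)


def venn_counts(sets: Mapping[str, Iterable[str]]) -> SharingReport:
    """Exclusive region counts for every non-empty subset of 2-4 named sets,
    pairwise shared counts and the members common to all."""
    sets = {k: set(v) for k, v in sets.items()}
    names = sorted(sets)
    if not 2 <= len(names) <= 4:
        raise ValidationError(f"venn analysis needs 2-4 sets, got {len(names)}")
    universe = set().union(*sets.values())
    regions: dict[frozenset, int] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set.intersection(*(sets[n] for n in combo))
            outside = set().union(*(sets[n] for n in names if n not in combo),
                                  set())
            regions[frozenset(combo)] = len(inside - outside)
    pairwise = {(a, b): len(sets[a] & sets[b])
                for a, b in itertools.combinations(names, 2)}
    common = set.intersection(*sets.values())
    assert sum(regions.values()) == len(universe)
    return SharingReport(sets=sets, regions=regions, pairwise=pairwise,
                         common_all=common)


def family_breakdown(ids: Iterable[str],
                     family_of: Mapping[str, str]) -> pd.Series:
    """Count a set of transcript ids by family label."""
    fams = [family_of.get(i, "unknown") for i in ids]
    return pd.Series(fams).value_counts()


def top_n(table: ExpressionTable, tissue: str, n: int = 10,
          level: str = "transcript",
          family_of: Mapping[str, str] | None = None) -> pd.Series:
    """Top-n entries by TPM in one tissue, descending; ties broken by
    lexicographic id.  level='family' sums member TPMs per family first."""
    if n < 1:
        raise ValidationError(f"n must be >= 1, got {n}")
    if tissue not in table.tissues:
        raise ValidationError(f"unknown tissue {tissue!r}")
    col = table.tpm[tissue]
    if level == "family":
        if family_of is None:
            raise ValidationError("family level requires a family map")
        col = col.groupby(
            col.index.map(lambda i: family_of.get(i, "unknown"))).sum()
    elif level != "transcript":
        raise ValidationError(f"unknown level {level!r}")
    ranked = col.sort_index().sort_values(ascending=False, kind="stable")
    return ranked.head(n)


def deg_flag(tpm_a: float, tpm_b: float,
             pseudocount: float = PSEUDOCOUNT,
             threshold: float = LOGFC_THRESHOLD) -> bool:
    """Differential-expression flag: |log2((a+pc)/(b+pc))| > 2 (strict)."""
    if tpm_a < 0 or tpm_b < 0:
        raise ValidationError("TPM values must be >= 0")
    lfc = math.log2((tpm_a + pseudocount) / (tpm_b + pseudocount))
    return abs(lfc) > threshold
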