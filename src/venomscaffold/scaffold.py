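"""Cysteine scaffold canonicalization, category assignment and family
disulfide-connectivity templates.

Sea anemone peptide toxin families are keyed by the spacing of their
cysteines.  The canonical pattern string writes consecutive cysteines with
spacer s as::

    s = 0          ->  "CC"
    s = 1          ->  "CXC"
    2 <= s <= 3    ->  "CX{s}C"
    s > 3          ->  "C-C"

with shared 'C' glyphs merged left to right, e.g. spacers [5,4,6,3,2] give
"C-C-C-CX3CX2C" (the ShKT-domain scaffold).  Categories are the Roman
numeral of the cysteine count (IV, VI, ...); subcategories rank the distinct
patterns within a category.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from .io_formats import ValidationError

NO_SCAFFOLD = "no-scaffold"

#: spacers longer than this are written "-" (long loop); shorter ones are
#: written explicitly as CXnC.  This is the only threshold consistent with
#: the five published family patterns (Kunitz shows CX3C but "-" elsewhere).
EXPLICIT_SPACER_MAX = 3


@dataclass(frozen=True)
class CysteineScaffold:
    positions: tuple[int, ...]          # 1-based residue indices of 'C'
    spacers: tuple[int, ...]            # residues between consecutive Cys
    pattern: str                        # canonical string (or NO_SCAFFOLD)
    category: str                       # Roman numeral of cysteine count
    parity: str                         # "even" | "odd"
    subcategory: int | None = None      # run-local rank, set by the census

    @property
    def n_cys(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class FamilyTemplate:
    """A family's canonical scaffold and (when established) its disulfide
    connectivity as 1-based cysteine ordinal pairs."""

    family: str
    pattern: str
    connectivity: tuple[tuple[int, int], ...] = ()
    peptide: bool = True
    notes: str = ""

    @property
    def n_cys(self) -> int:
        return self.pattern.count("C")


#: bundled templates for the classic sea anemone peptide toxin families.
DEFAULT_TEMPLATES: tuple[FamilyTemplate, ...] = (
    FamilyTemplate("ShKT", "C-C-C-CX3CX2C", ((1, 6), (2, 4), (3, 5)),
                   notes="ShK-like Kv-channel blockers; 6 Cys, 3 disulfides"),
    FamilyTemplate("beta-defensin", "CXC-C-C-CC", ((1, 5), (2, 4), (3, 6)),
                   notes="defensin-fold Nav/Kv/ASIC toxins"),
    FamilyTemplate("Kunitz-type", "C-C-C-C-CX3C", ((1, 6), (3, 5), (2, 4)),
                   notes="protease-inhibitor fold, Kv/TRPV blockers"),
    FamilyTemplate("EGF-like", "C-C-C-CXC-C", (),
                   notes="EGF-fold toxins (Gigantoxin-I-like)"),
    FamilyTemplate("ICK", "C-C-CC-C-C-C-C", (),
                   notes="inhibitor cystine-knot; 8 Cys"),
)


def load_templates(path: str | None = None) -> tuple[FamilyTemplate, ...]:
    """Load a template registry from YAML (bundled registry by default)."""
    import yaml
    from importlib import resources

    if path is None:
        text = (resources.files("venomscaffold") / "data" /
                "templates.yaml").read_text(encoding="utf-8")
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    raw = yaml.safe_load(text) or {}
    return tuple(
        FamilyTemplate(family=fam, pattern=spec["pattern"],
                       connectivity=tuple(tuple(p) for p in
                                          spec.get("connectivity") or ()),
                       notes=spec.get("notes", ""))
        for fam, spec in sorted(raw.items())
    )


def bundled_reference_fasta():
    """Path to the bundled synthetic reference exemplar FASTA."""
    from importlib import resources

    return resources.files("venomscaffold") / "data" / \
        "references_synthetic.fasta"


def cys_positions(seq: str) -> list[int]:
    """1-based positions of every cysteine."""
    return [i for i, ch in enumerate(seq, start=1) if ch == "C"]


def spacers_from_positions(positions: Sequence[int]) -> list[int]:
    return [b - a - 1 for a, b in zip(positions, positions[1:])]


def _spacer_token(s: int) -> str:
    if s == 0:
        return ""
    if s == 1:
        return "X"
    if s <= EXPLICIT_SPACER_MAX:
        return f"X{s}"
    return "-"


def canonical_pattern(seq_or_spacers: str | Sequence[int]) -> str:
    """Canonical scaffold string from a sequence or its spacer list.

    Zero cysteines give the distinct ``"no-scaffold"`` marker, not an error.
    """
    if isinstance(seq_or_spacers, str):
        pos = cys_positions(seq_or_spacers)
        if not pos:
            return NO_SCAFFOLD
        spacers = spacers_from_positions(pos)
    else:
        spacers = list(seq_or_spacers)
    return "C" + "".join(_spacer_token(s) + "C" for s in spacers)


_PATTERN_RE = re.compile(r"C|X(\d+)|X|-")


def parse_pattern(pattern: str) -> list[int | None]:
    """Invert :func:`canonical_pattern`: spacer list where ``None`` marks a
    long ('-') spacer of unconstrained length > 3."""
    if pattern == NO_SCAFFOLD:
        return []
    spacers: list[int | None] = []
    pending: int | None = 0
    first = True
    for m in _PATTERN_RE.finditer(pattern):
        tok = m.group(0)
        if tok == "C":
            if not first:
                spacers.append(pending)
            pending = 0
            first = False
        elif tok == "-":
            pending = None
        elif tok == "X":
            pending = 1
        else:
            pending = int(m.group(1))
    return spacers


def roman(n: int) -> str:
    """Roman numeral for a positive cysteine count."""
    vals = ((1000, "M"), (900, "CM"), (500, "D"), (400, "CD"), (100, "C"),
            (90, "XC"), (50, "L"), (40, "XL"), (10, "X"), (9, "IX"),
            (5, "V"), (4, "IV"), (1, "I"))
    out = []
    for v, s in vals:
        while n >= v:
            out.append(s)
            n -= v
    return "".join(out)


def build_scaffold(seq: str) -> CysteineScaffold:
    pos = tuple(cys_positions(seq))
    spacers = tuple(spacers_from_positions(pos))
    pattern = canonical_pattern(seq)
    n = len(pos)
    return CysteineScaffold(
        positions=pos,
        spacers=spacers,
        pattern=pattern,
        category=roman(n) if n else "0",
        parity="even" if n % 2 == 0 else "odd",
    )


def relaxed_pattern(pattern: str) -> str:
    """Spacer-length-blind form: every explicit CXnC spacer collapses to CXC
    so homologs differing only in short-loop length compare equal."""
    return re.sub(r"X\d+", "X", pattern)


def match_template(scaffold: CysteineScaffold | str,
                   templates: Iterable[FamilyTemplate] = DEFAULT_TEMPLATES
                   ) -> list[tuple[FamilyTemplate, str]]:
    """Match a scaffold against family templates.

    Exact string equality ranks before relaxed (spacer-length-blind)
    equality; all matches are returned.
    """
    pattern = scaffold if isinstance(scaffold, str) else scaffold.pattern
    if pattern == NO_SCAFFOLD:
        return []
    exact = [(t, "exact") for t in templates if t.pattern == pattern]
    rp = relaxed_pattern(pattern)
    relaxed = [(t, "relaxed") for t in templates
               if t.pattern != pattern and relaxed_pattern(t.pattern) == rp]
    return exact + relaxed


def predict_connectivity(scaffold: CysteineScaffold,
                         family: str,
                         templates: Iterable[FamilyTemplate] = DEFAULT_TEMPLATES
                         ) -> tuple[list[tuple[int, int]], str]:
    """Look up the family's disulfide template for a scaffold.

    Returns ``(pairs, reason)``; pairs is empty with an explanatory reason
    when the family is unknown, has no established connectivity, or its
    cysteine count differs from the scaffold's.  Pairs are never invented.
    """
    tmpl = next((t for t in templates if t.family == family), None)
    if tmpl is None:
        return [], f"no template registered for family {family!r}"
    if not tmpl.connectivity:
        return [], f"family {family!r} has no established connectivity"
    if tmpl.n_cys != scaffold.n_cys:
        return [], (f"cysteine count mismatch: scaffold has {scaffold.n_cys}, "
                    f"template has {tmpl.n_cys}")
    return list(tmpl.connectivity), "template"


def assign_categories(scaffolds: Sequence[CysteineScaffold]
                      ) -> list[CysteineScaffold]:
    """Assign run-local subcategory indices: within each category, distinct
    patterns ranked lexicographically, 1-based."""
    by_cat: dict[str, list[str]] = {}
    for s in scaffolds:
        by_cat.setdefault(s.category, []).append(s.pattern)
    ranks = {cat: {p: i + 1 for i, p in enumerate(sorted(set(pats)))}
             for cat, pats in by_cat.items()}
    return [
        CysteineScaffold(s.positions, s.spacers, s.pattern, s.category,
                         s.parity, subcategory=ranks[s.category][s.pattern])
        for s in scaffolds
    ]


def pattern_census(scaffolds: Sequence[CysteineScaffold]):
    """Per-category counts and percentages (2 decimals) over a peptide set.

    Returns a pandas DataFrame indexed by category with columns
    ``n_cys, count, pct``; percentages sum to 100 up to rounding.
    """
    import pandas as pd

    if not scaffolds:
        raise ValidationError("pattern census needs at least one scaffold")
    counts = Counter(s.category for s in scaffolds)
    ncys = {s.category: s.n_cys for s in scaffolds}
    total = sum(counts.values())
    rows = [
        {"category": cat, "n_cys": ncys[cat], "count": c,
         "pct": round(100.0 * c / total, 2)}
        for cat, c in counts.items()
    ]
    df = pd.DataFrame(rows).sort_values("n_cys").set_index("category")
    return df
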