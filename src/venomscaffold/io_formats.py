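"""Readers and writers for the external formats the pipeline touches.

FASTA (amino-acid sequences), TSV count tables, newick trees and the JSON
run manifest. All tables are TSV, UTF-8, '.' decimal separator.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

#: the 20 standard amino acids plus X (unknown). X never counts as cysteine
#: or hydrophobic anywhere in the pipeline.
AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")

#: the four datasets of the multi-tissue design; "combine" is a first-class
#: tag, not a computed union (a helper can derive it when absent).
DATASETS = ("tentacles", "column", "filaments", "combine")

TISSUES = ("tentacles", "column", "filaments")


class ValidationError(ValueError):
    """Raised when an input file violates the documented contracts."""


@dataclass(frozen=True)
class SequenceRecord:
    """One translated transcript or peptide sequence."""

    id: str
    seq: str
    dataset: str = "combine"
    description: str = ""

    def __post_init__(self):
        if not self.id:
            raise ValidationError("sequence record id must be non-empty")
        if len(self.seq) < 1:
            raise ValidationError(f"sequence {self.id!r} is empty")


@dataclass(frozen=True)
class ReferenceToxin:
    """A labelled reference sequence used for family annotation.

    ``connectivity`` lists 1-based cysteine ordinal pairs (disulfide bonds)
    when the family's bonding pattern is established.
    """

    id: str
    seq: str
    family: str
    connectivity: tuple[tuple[int, int], ...] = ()

    def __post_init__(self):
        n_cys = self.seq.count("C")
        for i, j in self.connectivity:
            if not (1 <= i <= n_cys and 1 <= j <= n_cys):
                raise ValidationError(
                    f"reference {self.id!r}: connectivity ordinal ({i},{j}) "
                    f"exceeds cysteine count {n_cys}"
                )


@dataclass(frozen=True)
class CountRow:
    """One row of a per-tissue raw count table."""

    transcript_id: str
    length_bp: int
    counts: Mapping[str, float]

    def __post_init__(self):
        if self.length_bp <= 0:
            raise ValidationError(
                f"transcript {self.transcript_id!r}: effective length must be "
                f"positive, got {self.length_bp}"
            )
        for tissue, c in self.counts.items():
            if c < 0:
                raise ValidationError(
                    f"transcript {self.transcript_id!r}: negative count {c} "
                    f"in tissue {tissue!r}"
                )


# ---------------------------------------------------------------------------
# FASTA


def _clean_seq(raw: str, rec_id: str) -> str:
    seq = raw.upper()
    if seq.endswith("*"):
        seq = seq[:-1]
    for pos, ch in enumerate(seq, start=1):
        if ch == "*":
            raise ValidationError(
                f"record {rec_id!r}: internal stop '*' at position {pos}"
            )
        if not ch.isalpha() or not ch.isascii():
            raise ValidationError(
                f"record {rec_id!r}: illegal character {ch!r} at position {pos}"
            )
    if not seq:
        raise ValidationError(f"record {rec_id!r}: empty sequence")
    return seq


def read_fasta(path: str | Path, dataset_tag: str = "combine") -> list[SequenceRecord]:
    """Read an amino-acid FASTA into validated :class:`SequenceRecord` s.

    Sequences are uppercased and a single terminal stop ('*') is stripped.
    Duplicate ids, internal stops and non-letter characters are rejected.
    """
    if dataset_tag not in DATASETS:
        raise ValidationError(
            f"unknown dataset tag {dataset_tag!r}; expected one of {DATASETS}"
        )
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValidationError(f"duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        seq = _clean_seq(str(rec.seq), rec.id)
        records.append(
            SequenceRecord(
                id=rec.id,
                seq=seq,
                dataset=dataset_tag,
                description=rec.description[len(rec.id):].strip(),
            )
        )
    if not records:
        raise ValidationError(f"no records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records as FASTA (60-column wrap)."""
    bio = [
        _BioRecord(Seq(r.seq), id=r.id, description=r.description)
        for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


# ---------------------------------------------------------------------------
# count tables


def read_counts(path: str | Path) -> list[CountRow]:
    """Read a TSV count table: transcript_id, length, then one tissue column each.

    Every numeric field is validated; the tissue set is taken from the header.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = list(df.columns)
    if len(cols) < 3 or cols[0] != "transcript_id" or cols[1] != "length":
        raise ValidationError(
            "count table must start with columns 'transcript_id', 'length' "
            f"followed by tissue columns; got {cols}"
        )
    tissues = cols[2:]
    rows: list[CountRow] = []
    for idx, row in df.iterrows():
        rownum = int(idx) + 2  # header is line 1
        try:
            length = int(float(row["length"]))
        except (TypeError, ValueError):
            raise ValidationError(
                f"row {rownum}: non-numeric length {row['length']!r}"
            ) from None
        counts = {}
        for t in tissues:
            try:
                counts[t] = float(row[t])
            except (TypeError, ValueError):
                raise ValidationError(
                    f"row {rownum}: non-numeric count {row[t]!r} in {t!r}"
                ) from None
        rows.append(CountRow(str(row["transcript_id"]), length, counts))
    if not rows:
        raise ValidationError(f"no count rows found in {path}")
    return rows


def write_counts(rows: Sequence[CountRow], path: str | Path) -> None:
    tissues = list(rows[0].counts)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("transcript_id\tlength\t" + "\t".join(tissues) + "\n")
        for r in rows:
            vals = "\t".join(_fmt_num(r.counts[t]) for t in tissues)
            fh.write(f"{r.transcript_id}\t{r.length_bp}\t{vals}\n")


def _fmt_num(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


# ---------------------------------------------------------------------------
# trees / newick


@dataclass
class TreeNode:
    """Node of a phylogenetic tree; leaves carry ``name``, internal nodes may
    carry an integer bootstrap ``support`` in [0, 100]."""

    name: str | None = None
    length: float = 0.0
    support: int | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class PhyloTree:
    """Unrooted tree stored with an arbitrary root of degree 3 (or 2 for two
    leaves); branch lengths >= 0, optional bootstrap supports on internal
    edges."""

    root: TreeNode

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.root.leaves()]

    def bipartitions(self) -> set[frozenset[str]]:
        """Internal-edge bipartitions, each encoded as the smaller-or-equal
        side's leaf-name frozenset complement-canonicalized against the full
        leaf set."""
        full = frozenset(self.leaf_names())
        out: set[frozenset[str]] = set()

        def walk(node: TreeNode):
            below = frozenset(n.name for n in node.leaves())
            if 1 < len(below) < len(full) - 1:
                side = min(below, full - below, key=lambda s: (len(s), sorted(s)))
                out.add(side)
            for c in node.children:
                walk(c)

        for c in self.root.children:
            walk(c)
        return out


def write_newick(tree: PhyloTree) -> str:
    """Serialize a tree as newick: branch lengths to 6 decimals, integer
    bootstrap supports as internal node labels."""

    def render(node: TreeNode) -> str:
        if node.is_leaf:
            return f"{node.name}:{node.length:.6f}"
        inner = ",".join(render(c) for c in node.children)
        label = "" if node.support is None else str(int(node.support))
        return f"({inner}){label}:{node.length:.6f}"

    inner = ",".join(render(c) for c in tree.root.children)
    label = "" if tree.root.support is None else str(int(tree.root.support))
    return f"({inner}){label};"


def read_newick(text: str) -> PhyloTree:
    """Parse a newick string produced by :func:`write_newick`."""
    import dendropy

    dtree = dendropy.Tree.get(data=text, schema="newick",
                              suppress_internal_node_taxa=True)

    def convert(dnode) -> TreeNode:
        node = TreeNode(length=float(dnode.edge.length or 0.0))
        if dnode.is_leaf():
            node.name = dnode.taxon.label.replace(" ", "_")
        else:
            if dnode.label is not None and re.fullmatch(r"\d+", dnode.label):
                node.support = int(dnode.label)
            node.children = [convert(c) for c in dnode.child_nodes()]
        return node

    return PhyloTree(root=convert(dtree.seed_node))


# ---------------------------------------------------------------------------
# run manifest


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path: str | Path, *, seed: int | None,
                   inputs: Mapping[str, str | Path],
                   params: Mapping[str, object] | None = None) -> dict:
    """Write the JSON run manifest: package version, seed, input hashes."""
    from . import __version__

    manifest = {
        "version": __version__,
        "seed": seed,
        "inputs": {k: {"path": str(v), "sha256": sha256_file(v)}
                   for k, v in inputs.items() if Path(v).exists()},
        "params": dict(params or {}),
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def derive_combine(per_tissue: Mapping[str, list[SequenceRecord]]) -> list[SequenceRecord]:
    """Derive the 'combine' dataset as the id-union of the tissue datasets
    (used only when a combined assembly is not supplied)."""
    seen: dict[str, SequenceRecord] = {}
    for recs in per_tissue.values():
        for r in recs:
            if r.id not in seen:
                seen[r.id] = SequenceRecord(r.id, r.seq, "combine", r.description)
    return list(seen.values())
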