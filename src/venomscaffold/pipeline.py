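"""End-to-end orchestration: screen -> classify -> annotate -> compare ->
tree, with a JSON summary, a run manifest and a defensive reproduction mode
for externally supplied supplementary tables."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import annotate as _annotate
from . import expression as _expression
from . import phylogeny as _phylogeny
from . import scaffold as _scaffold
from . import screening as _screening
from .io_formats import (ReferenceToxin, SequenceRecord, ValidationError,
                         read_counts, read_fasta, write_manifest,
                         write_newick)

log = logging.getLogger("venomscaffold")


@dataclass
class RunConfig:
    fasta_by_dataset: dict[str, Path]
    counts_path: Path | None = None
    reference_fasta: Path | None = None
    out_dir: Path = Path("venomscaffold_out")
    peptide_max_aa: int = 80
    min_cys: int = 4
    identity_threshold: float = 75.0
    min_tpm: float = 0.0
    bootstrap: int = 1000
    deletion: float = 0.50
    distance_model: str = "p"
    seed: int = 0
    max_tree_taxa: int = 40

    def validate(self) -> None:
        if not self.fasta_by_dataset:
            raise ValidationError("at least one dataset FASTA is required")
        if not 0 < self.identity_threshold <= 100:
            raise ValidationError("identity_threshold must be in (0,100]")
        if not 0 <= self.deletion <= 1:
            raise ValidationError("deletion cutoff must be in [0,1]")
        if self.bootstrap < 0 or self.min_cys < 0 or self.peptide_max_aa < 1:
            raise ValidationError("thresholds out of range")


def load_references(fasta: Path) -> list[ReferenceToxin]:
    """Read a reference FASTA whose descriptions carry ``family=<label>``."""
    refs = []
    for rec in read_fasta(fasta):
        family = "unknown"
        for tok in rec.description.split():
            if tok.startswith("family="):
                family = tok.split("=", 1)[1]
        refs.append(ReferenceToxin(id=rec.id, seq=rec.seq, family=family))
    return refs


def screen_table(results: Sequence[_screening.ScreenResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "id": r.record.id, "dataset": r.record.dataset, "tier": r.tier,
        "length_aa": r.length_aa, "cys_count": r.cys_count,
        "hydrophobic_fraction": round(r.hydrophobic_fraction, 4),
        "passed_spm": r.passed_spm,
        "passed_peptide_screen": r.passed_peptide_screen,
    } for r in results])


def classify_table(records: Sequence[SequenceRecord]) -> pd.DataFrame:
    scaffolds = _scaffold.assign_categories(
        [_scaffold.build_scaffold(r.seq) for r in records])
    rows = []
    for rec, sc in zip(records, scaffolds):
        matches = _scaffold.match_template(sc)
        rows.append({
            "id": rec.id, "pattern": sc.pattern, "n_cys": sc.n_cys,
            "category": sc.category, "subcategory": sc.subcategory,
            "parity": sc.parity,
            "family_matches": ";".join(f"{t.family}:{kind}"
                                       for t, kind in matches),
        })
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write per-stage TSVs, the newick tree, the
    summary JSON and the manifest into ``config.out_dir``.

    Returns the summary dict.  Any stage failure leaves partial outputs plus
    a FAILED marker file.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    failed_marker = out / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()

    try:
        summary = _run_stages(config, out)
    except Exception as exc:
        failed_marker.write_text(f"{type(exc).__name__}: {exc}\n")
        raise

    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    inputs = dict(config.fasta_by_dataset)
    if config.counts_path:
        inputs["counts"] = config.counts_path
    if config.reference_fasta:
        inputs["references"] = config.reference_fasta
    write_manifest(out / "manifest.json", seed=config.seed, inputs=inputs,
                   params={"identity_threshold": config.identity_threshold,
                           "peptide_max_aa": config.peptide_max_aa,
                           "min_cys": config.min_cys,
                           "min_tpm": config.min_tpm,
                           "bootstrap": config.bootstrap,
                           "deletion": config.deletion})
    return summary


def _run_stages(config: RunConfig, out: Path) -> dict:
    summary: dict = {"datasets": {}}

    # screen + classify per dataset
    records_by_ds: dict[str, list[SequenceRecord]] = {}
    peptide_ids: dict[str, SequenceRecord] = {}
    for ds, path in config.fasta_by_dataset.items():
        records = read_fasta(path, ds)
        records_by_ds[ds] = records
        screened = _screening.screen_records(
            records, peptide_max_aa=config.peptide_max_aa,
            min_cys=config.min_cys)
        st = screen_table(screened)
        st.to_csv(out / f"screen_{ds}.tsv", sep="\t", index=False)
        ct = classify_table(records)
        ct.to_csv(out / f"classify_{ds}.tsv", sep="\t", index=False)
        n_pep = int((st["tier"] == "peptide").sum())
        summary["datasets"][ds] = {
            "n_records": len(records),
            "n_peptides": n_pep,
            "n_proteins": len(records) - n_pep,
            "n_peptide_screen_pass": int(st["passed_peptide_screen"].sum()),
        }
        log.info("%s: %d records, %d peptides", ds, len(records), n_pep)
        for r, s in zip(records, screened):
            if s.passed_peptide_screen and r.id not in peptide_ids:
                peptide_ids[r.id] = r

    # census over screened peptides (cysteine-bearing only)
    peptides = list(peptide_ids.values())
    if peptides:
        scaffolds = _scaffold.assign_categories(
            [_scaffold.build_scaffold(r.seq) for r in peptides])
        census = _scaffold.pattern_census(scaffolds)
        census.to_csv(out / "census.tsv", sep="\t")
        summary["census_pct"] = {cat: float(row["pct"])
                                 for cat, row in census.iterrows()}

    # annotate
    family_of: dict[str, str] = {}
    if config.reference_fasta:
        refs = load_references(Path(config.reference_fasta))
        all_records = {r.id: r for recs in records_by_ds.values()
                       for r in recs}
        calls = _annotate.annotate_records(
            all_records.values(), refs, threshold=config.identity_threshold)
        at = pd.DataFrame([{
            "id": c.query_id, "family": c.family, "best_ref": c.best_ref,
            "best_identity": c.best_identity,
            "scaffold_consistent": c.scaffold_consistent,
        } for c in calls])
        at.to_csv(out / "annotate.tsv", sep="\t", index=False)
        family_of = dict(zip(at["id"], at["family"]))
        fam_counts = at["family"].value_counts()
        summary["family_counts"] = {k: int(v) for k, v in fam_counts.items()}
        log.info("annotated %d sequences, %d families", len(at),
                 (fam_counts.index != "unknown").sum())

    # expression + sharing
    if config.counts_path:
        rows = read_counts(config.counts_path)
        table = _expression.compute_tpm(rows)
        table.tpm.round(4).to_csv(out / "tpm.tsv", sep="\t")
        sets = _expression.presence_sets(table, config.min_tpm)
        if "combine" not in sets and records_by_ds.get("combine"):
            sets["combine"] = {r.id for r in records_by_ds["combine"]}
        report = _expression.venn_counts(sets)
        summary["sharing"] = {
            "pairwise": {f"{a}&{b}": n
                         for (a, b), n in report.pairwise.items()},
            "common_all": report.n_common,
        }
        if family_of:
            summary["common_families"] = {
                k: int(v) for k, v in _expression.family_breakdown(
                    report.common_all, family_of).items()}
        top = {t: _expression.top_n(table, t).round(2).to_dict()
               for t in table.tissues}
        with open(out / "top10.json", "w", encoding="utf-8") as fh:
            json.dump(top, fh, indent=2, sort_keys=True)
        log.info("sharing: %d common across %d datasets", report.n_common,
                 len(sets))

    # phylogeny over the screened peptide set
    if len(peptides) >= 4:
        tree_peps = sorted(peptides, key=lambda r: r.id)[:config.max_tree_taxa]
        msa = _phylogeny.guide_msa({r.id: r.seq for r in tree_peps})
        msa = _phylogeny.site_coverage_filter(msa, config.deletion)
        dm = _phylogeny.distance_matrix(msa, config.deletion,
                                        config.distance_model)
        # drop taxa whose pairwise-deletion coverage is too low to place
        dm, excluded = _phylogeny.prune_undefined(dm)
        msa = {l: msa[l] for l in dm.labels}
        if len(msa) < 4:
            summary["tree"] = {"n_taxa": len(msa), "excluded": excluded,
                               "status": "too few comparable peptides"}
            return summary
        boot = _phylogeny.bootstrap_support(
            msa, B=config.bootstrap, seed=config.seed,
            min_fraction=config.deletion, model=config.distance_model)
        (out / "tree.nwk").write_text(write_newick(boot.tree) + "\n")
        summary["tree"] = {
            "n_taxa": len(msa),
            "excluded": excluded,
            "bootstrap_replicates": boot.replicates,
            "bootstrap_skipped": boot.skipped,
        }
        log.info("tree: %d taxa, %d bootstrap replicates", len(tree_peps),
                 boot.replicates)
    return summary


# ---------------------------------------------------------------------------
# reproduction mode for externally supplied supplementary tables

#: published statistics the reproduction mode compares against when the
#: corresponding supplementary tables are supplied by the user.
EXPECTED_PUBLISHED = {
    "peptide_pct": 9.0,
    "protein_pct": 91.0,
    "n_peptides": 93,
    "n_sequences": 1049,
    "census_VI_pct": 47.31,
    "census_IV_pct": 25.81,
    "venn_common_all": 42,
    "venn_tentacles_column": 81,
    "identity_HC18_HC19": 87.5,
}


def _find_seq_column(df: pd.DataFrame) -> str | None:
    best, best_frac = None, 0.0
    for col in df.columns:
        vals = df[col].dropna().astype(str).str.upper().str.strip()
        if vals.empty:
            continue
        ok = vals.str.fullmatch(r"[A-Z*]{5,}").fillna(False)
        frac = ok.mean()
        if frac > best_frac:
            best, best_frac = col, frac
    return best if best_frac > 0.8 else None


def _read_table(path: Path) -> pd.DataFrame:
    if path.suffix.lower() in (".xlsx", ".xls"):
        return pd.read_excel(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    return pd.read_csv(path, sep=sep)


def reproduce_supplementary(tables_dir: str | Path) -> dict:
    """Recompute published summary statistics from user-supplied
    supplementary tables and report expected vs computed.

    The tables are located by name (anything containing 'S3' or 'S4');
    parsing is defensive since their exact layout is not fixed.  Absent
    tables yield status 'skipped (no data)', not a failure.
    """
    tables_dir = Path(tables_dir)
    report: dict = {"expected": EXPECTED_PUBLISHED, "checks": {}}

    def locate(tag: str) -> Path | None:
        if not tables_dir.is_dir():
            return None
        hits = sorted(p for p in tables_dir.iterdir()
                      if tag.lower() in p.name.lower()
                      and p.suffix.lower() in (".xlsx", ".xls", ".csv",
                                               ".tsv", ".txt"))
        return hits[0] if hits else None

    s3, s4 = locate("S3"), locate("S4")

    if s3 is None:
        report["checks"]["tier_split"] = {"status": "skipped (no data)"}
        report["checks"]["sharing"] = {"status": "skipped (no data)"}
    else:
        df = _read_table(s3)
        col = _find_seq_column(df)
        if col is None:
            report["checks"]["tier_split"] = {
                "status": "failed", "reason": "no sequence column found"}
        else:
            seqs = df[col].dropna().astype(str).str.upper().str.strip(" *")
            tiers = [_screening.classify_tier(s) for s in seqs if s]
            n = len(tiers)
            pep = sum(t == "peptide" for t in tiers)
            report["checks"]["tier_split"] = {
                "status": "computed", "n_sequences": n, "n_peptides": pep,
                "peptide_pct": round(100.0 * pep / n, 1),
                "pass": round(100.0 * pep / n, 1)
                == EXPECTED_PUBLISHED["peptide_pct"],
            }
        report["checks"]["sharing"] = _sharing_check(df)

    if s4 is None:
        report["checks"]["census"] = {"status": "skipped (no data)"}
        report["checks"]["identity_HC18_HC19"] = {
            "status": "skipped (no data)"}
    else:
        df = _read_table(s4)
        col = _find_seq_column(df)
        if col is None:
            report["checks"]["census"] = {
                "status": "failed", "reason": "no sequence column found"}
        else:
            seqs = [s for s in df[col].dropna().astype(str).str.upper()
                    .str.strip(" *") if s]
            scaffolds = [_scaffold.build_scaffold(s) for s in seqs
                         if "C" in s]
            census = _scaffold.pattern_census(
                _scaffold.assign_categories(scaffolds))
            vi = float(census.loc["VI", "pct"]) if "VI" in census.index else 0.0
            iv = float(census.loc["IV", "pct"]) if "IV" in census.index else 0.0
            report["checks"]["census"] = {
                "status": "computed", "VI_pct": vi, "IV_pct": iv,
                "pass": (abs(vi - EXPECTED_PUBLISHED["census_VI_pct"]) < 0.5
                         and abs(iv - EXPECTED_PUBLISHED["census_IV_pct"])
                         < 0.5),
            }
            report["checks"]["identity_HC18_HC19"] = _identity_check(df, col)
    return report


def _identity_check(df: pd.DataFrame, seq_col: str) -> dict:
    ids = None
    for col in df.columns:
        vals = df[col].astype(str).str.upper().str.replace("-", "").str.strip()
        if vals.isin(["HC18", "HC 18"]).any():
            ids = col
            break
    if ids is None:
        return {"status": "failed", "reason": "HC-18/HC-19 ids not found"}
    norm = df[ids].astype(str).str.upper().str.replace("-", "").str.strip()
    try:
        a = str(df.loc[norm == "HC18", seq_col].iloc[0]).upper().strip(" *")
        b = str(df.loc[norm == "HC19", seq_col].iloc[0]).upper().strip(" *")
    except IndexError:
        return {"status": "failed", "reason": "HC-18/HC-19 rows incomplete"}
    aln = _annotate.global_align(a, b, query_id="HC-18", ref_id="HC-19")
    return {"status": "computed", "identity_pct": aln.identity_pct,
            "pass": abs(aln.identity_pct
                        - EXPECTED_PUBLISHED["identity_HC18_HC19"]) <= 0.5}


def _sharing_check(df: pd.DataFrame) -> dict:
    cols = {}
    for want in ("tentacles", "column", "filaments", "combine"):
        for col in df.columns:
            if want in str(col).lower():
                cols[want] = col
                break
    if len(cols) < 4:
        return {"status": "skipped (no data)",
                "reason": "per-dataset presence columns not found"}
    sets = {}
    for name, col in cols.items():
        flags = df[col].astype(str).str.strip().str.lower()
        present = ~flags.isin(["", "0", "no", "false", "nan", "-"])
        sets[name] = set(df.index[present])
    report = _expression.venn_counts(sets)
    return {
        "status": "computed",
        "common_all": report.n_common,
        "tentacles_column": report.pairwise.get(("column", "tentacles"), 0),
        "pass": (report.n_common == EXPECTED_PUBLISHED["venn_common_all"]),
    }
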