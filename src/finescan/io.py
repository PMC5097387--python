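"""Readers/writers for the standard formats the pipeline touches.

Conventions: internal coordinates are 1-based closed (VCF-native); BED input
is converted at the boundary. Multiallelic VCF records are split into one
pseudo-variant per ALT allele because all statistics are per-SNV biallelic.
Non-SNV records are skipped with a logged count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .core import NO_READS, GenotypeMatrix, variant_key

log = logging.getLogger(__name__)

RESULT_SCHEMAS = {
    "assoc": [
        "variant_id", "region_id", "population", "beta", "se", "z", "p",
        "loglik", "null_loglik", "n", "maf", "evaluable", "note",
    ],
    "meta": ["variant_id", "beta", "se", "z", "p", "populations", "evaluable", "note"],
    "gene": [
        "gene", "scope", "rule", "n_variants", "carrier_proportion",
        "burden_beta", "burden_se", "burden_or", "burden_ci_low", "burden_ci_high",
        "burden_p", "skat_q", "skat_p", "evaluable", "note",
    ],
    "posterior": ["region_id", "variant_id", "posterior", "rank", "member"],
}
_P_COLUMNS = {"p", "burden_p", "skat_p", "posterior"}


@dataclass
class ResultTable:
    """A homogeneous table of pipeline results (``kind`` picks the schema)."""

    kind: str
    frame: pd.DataFrame

    def __post_init__(self) -> None:
        if self.kind not in RESULT_SCHEMAS:
            raise ValueError(f"unknown result kind {self.kind!r}")
        missing = [c for c in RESULT_SCHEMAS[self.kind] if c not in self.frame.columns]
        if missing:
            raise ValueError(f"result table of kind {self.kind!r} lacks columns {missing}")
        self.frame = self.frame[RESULT_SCHEMAS[self.kind]].reset_index(drop=True)


# ----------------------------------------------------------------------
# VCF
# ----------------------------------------------------------------------
def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a VCF 4.2 with GT plus DP/GQ side channels when present."""
    path = Path(path)
    has_dp, has_gq = gm.depth is not None, gm.qual is not None
    fmt = "GT" + (":DP" if has_dp else "") + (":GQ" if has_gq else "")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n##source=finescan\n")
        for chrom in pd.unique(gm.variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if has_dp:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        if has_gq:
            fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(gm.samples) + "\n")
        gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        for j in range(gm.n_variants):
            var = gm.variants.iloc[j]
            cells = []
            for i in range(gm.n_samples):
                d = gm.dosage[i, j]
                cell = gt_map.get(d, "./.") if np.isfinite(d) else "./."
                if has_dp:
                    dp = gm.depth[i, j]
                    cell += ":" + ("." if dp == NO_READS else str(int(dp)))
                if has_gq:
                    gq = gm.qual[i, j]
                    cell += ":" + ("." if gq == NO_READS else str(int(gq)))
                cells.append(cell)
            fh.write(
                f"{var['chrom']}\t{var['pos']}\t{var['variant_id']}\t{var['ref']}\t{var['alt']}"
                f"\t.\tPASS\t.\t{fmt}\t" + "\t".join(cells) + "\n"
            )


def read_vcf(path, region_filter: pd.DataFrame | None = None) -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix`.

    Multiallelic records are split per ALT; non-SNV records are skipped (a
    count is logged). ``region_filter`` (region_id/chrom/start/end, 1-based
    closed) restricts to contained variants and tags each with its region.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    n = len(samples)
    dosage_cols, dp_cols, gq_cols, var_rows = [], [], [], []
    skipped = 0
    for rec in vcf:
        alts = rec.ALT
        if len(rec.REF) != 1 or not alts or any(len(a) != 1 or a not in "ACGT" for a in alts):
            skipped += 1
            continue
        region_id = ""
        if region_filter is not None:
            hit = region_filter[
                (region_filter["chrom"] == rec.CHROM)
                & (region_filter["start"] <= rec.POS)
                & (region_filter["end"] >= rec.POS)
            ]
            if hit.empty:
                continue
            region_id = hit.iloc[0]["region_id"]
        gts = rec.genotypes  # [allele0, allele1, phased] per sample
        a0 = np.array([g[0] for g in gts])
        a1 = np.array([g[1] if len(g) > 2 else -1 for g in gts])
        miss = (a0 < 0) | (a1 < 0)
        try:
            dp = rec.format("DP")
        except KeyError:
            dp = None
        try:
            gq = rec.format("GQ")
        except KeyError:
            gq = None
        dp = np.full(n, NO_READS, dtype=np.int32) if dp is None else np.where(dp[:, 0] < 0, NO_READS, dp[:, 0]).astype(np.int32)
        gq = np.full(n, NO_READS, dtype=np.int32) if gq is None else np.where(gq[:, 0] < 0, NO_READS, gq[:, 0]).astype(np.int32)
        for ai, alt in enumerate(alts, start=1):
            dos = (a0 == ai).astype(float) + (a1 == ai).astype(float)
            dos[miss] = np.nan
            dosage_cols.append(dos)
            dp_cols.append(dp)
            gq_cols.append(gq)
            var_rows.append((variant_key(rec.CHROM, rec.POS, rec.REF, alt), rec.CHROM, rec.POS, rec.REF, alt, region_id))
    if skipped:
        log.info("read_vcf: skipped %d non-SNV record(s)", skipped)
    variants = pd.DataFrame(var_rows, columns=["variant_id", "chrom", "pos", "ref", "alt", "region_id"])
    m = len(variants)
    return GenotypeMatrix(
        dosage=np.array(dosage_cols).T if m else np.empty((n, 0)),
        samples=samples,
        variants=variants,
        depth=np.array(dp_cols, dtype=np.int32).T if m else None,
        qual=np.array(gq_cols, dtype=np.int32).T if m else None,
    )


# ----------------------------------------------------------------------
# BED regions
# ----------------------------------------------------------------------
def read_regions_bed(path) -> pd.DataFrame:
    """3+ column BED -> region table with 1-based closed start/end."""
    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"BED line {i + 1}: fewer than 3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise ValueError(f"BED line {i + 1}: start {start} >= end {end}")
            name = parts[3] if len(parts) > 3 else f"region{len(rows) + 1}"
            rows.append((name, chrom, start + 1, end))
    return pd.DataFrame(rows, columns=["region_id", "chrom", "start", "end"])


def write_regions_bed(regions: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for _, r in regions.iterrows():
            fh.write(f"{r['chrom']}\t{r['start'] - 1}\t{r['end']}\t{r['region_id']}\n")


# ----------------------------------------------------------------------
# sample sheet / annotations
# ----------------------------------------------------------------------
def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    sheet.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.12g")


def read_sample_sheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
    for col in ("sample_id", "population", "status"):
        if col not in sheet.columns:
            raise ValueError(f"sample sheet lacks required column {col!r}")
    if sheet["sample_id"].duplicated().any():
        raise ValueError("sample sheet has duplicate sample ids")
    bad = set(sheet["status"]) - {"case", "control"}
    if bad:
        raise ValueError(f"sample sheet has invalid status values {sorted(bad)}")
    return sheet


def write_annotations(ann: pd.DataFrame, path) -> None:
    cols = ["variant_id", "region_id", "gene", "impact", "damaging"]
    ann.loc[:, [c for c in cols if c in ann.columns]].to_csv(path, sep="\t", index=False, na_rep="NA")


def read_annotations(path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
    for col in ("variant_id", "gene", "impact"):
        if col not in ann.columns:
            raise ValueError(f"annotation table lacks required column {col!r}")
    if "damaging" in ann.columns:
        ann["damaging"] = ann["damaging"].map(
            {True: True, False: False, "True": True, "False": False, "1": True, "0": False}
        ).fillna(False).astype(bool)
    return ann


# ----------------------------------------------------------------------
# result tables
# ----------------------------------------------------------------------
def write_results(table: ResultTable, path) -> None:
    """Tab-separated result table; p-values in scientific notation;
    roundtrip lossless to 1e-12 relative."""
    frame = table.frame.copy()
    for col in frame.columns:
        if col in _P_COLUMNS:
            frame[col] = frame[col].map(lambda v: "NA" if pd.isna(v) else f"{v:.12e}")
        elif pd.api.types.is_float_dtype(frame[col]):
            frame[col] = frame[col].map(lambda v: "NA" if pd.isna(v) else f"{v:.12g}")
    with open(path, "w") as fh:
        fh.write(f"# finescan-results kind={table.kind}\n")
        frame.to_csv(fh, sep="\t", index=False, na_rep="NA")


def read_results(path) -> ResultTable:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("# finescan-results kind="):
            raise ValueError("not a finescan result table (missing kind header)")
        kind = header.split("kind=", 1)[1]
        frame = pd.read_csv(fh, sep="\t", na_values=["NA"], keep_default_na=False)
    if "evaluable" in frame.columns:
        frame["evaluable"] = frame["evaluable"].astype(bool)
    if "note" in frame.columns:
        frame["note"] = frame["note"].fillna("").astype(str)
    return ResultTable(kind=kind, frame=frame)


# ----------------------------------------------------------------------
# dataset bundle
# ----------------------------------------------------------------------
def write_dataset(gm: GenotypeMatrix, sheet: pd.DataFrame, regions: pd.DataFrame, annotations: pd.DataFrame | None, out_dir) -> dict:
    """Write the four study inputs (VCF, sample sheet, regions BED,
    annotation table) under ``out_dir``; returns the path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "genotypes.vcf",
        "samples": out / "samples.tsv",
        "regions": out / "regions.bed",
    }
    write_vcf(gm, paths["vcf"])
    write_sample_sheet(sheet, paths["samples"])
    write_regions_bed(regions, paths["regions"])
    if annotations is not None:
        paths["annotations"] = out / "annotations.tsv"
        write_annotations(annotations, paths["annotations"])
    return paths
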