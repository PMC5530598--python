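"""Readers and writers for the package's tabular interfaces.

Variants travel either as a long-format TSV (one row per mutation per
sample with alt_count and depth) or as a multi-sample VCF with per-sample
AD/DP FORMAT fields; sample sheets, copy-number segments and colony VAF
tables are TSVs. VCF handling goes through pysam.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import pysam

from .filters import CnaSegment

COUNT_COLUMNS = ["patient", "sample_id", "mutation_id", "alt_count", "depth"]
SHEET_COLUMNS = ["patient", "sample_id", "tissue", "time_days", "platform",
                 "treatment_label"]

TISSUES = {"BM", "PB", "BM_MNC", "PB_MNC", "granulocytes", "HSC", "CMP",
           "GMP", "MEP", "T_cells", "MSC"}


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    missing = set(COUNT_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"counts TSV missing columns: {sorted(missing)}")
    return frame


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    missing = set(SHEET_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    frame["treatment_label"] = frame["treatment_label"].fillna("")
    bad = set(frame["tissue"]) - TISSUES
    if bad:
        raise ValueError(f"unknown tissue labels: {sorted(bad)}")
    return frame


def read_segments_tsv(path: str | Path) -> list[CnaSegment]:
    frame = pd.read_csv(path, sep="\t")
    return [
        CnaSegment(str(r.chrom), int(r.start), int(r.end), int(r.cn_total),
                   int(r.cn_minor), bool(r.is_cnloh),
                   bool(r.reaches_telomere))
        for r in frame.itertuples()
    ]


def read_colonies_tsv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    needed = {"colony_id", "mutation_id", "vaf"}
    missing = needed - set(frame.columns)
    if missing:
        raise ValueError(f"colony TSV missing columns: {sorted(missing)}")
    return frame


def write_counts_vcf(counts: pd.DataFrame, variants: pd.DataFrame,
                     patient: str, path: str | Path) -> Path:
    """Write per-sample read counts as an uncompressed multi-sample VCF.

    ``variants`` supplies chrom/pos/ref/alt per mutation_id; per-sample AD
    carries (ref_depth, alt_depth) and DP the total depth. Samples appear in
    sorted order. Indel alleles are written as given (already left-anchored
    by the simulator).
    """
    path = Path(path)
    sub = counts[counts["patient"] == patient]
    samples = sorted(sub["sample_id"].unique())
    var = variants.set_index("mutation_id")
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=AD,Number=R,Type=Integer,'
                    'Description="Allelic depths">')
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,'
                    'Description="Read depth">')
    header.add_line('##INFO=<ID=MID,Number=1,Type=String,'
                    'Description="Mutation id">')
    chroms = sorted(var["chrom"].astype(str).unique())
    for c in chroms:
        header.add_line(f"##contig=<ID={c}>")
    for s in samples:
        header.add_sample(s)
    wide_alt = sub.pivot(index="mutation_id", columns="sample_id",
                         values="alt_count")
    wide_dp = sub.pivot(index="mutation_id", columns="sample_id",
                        values="depth")
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        order = var.loc[wide_alt.index].sort_values(["chrom", "pos"]).index
        for mid in order:
            v = var.loc[mid]
            rec = vcf.new_record(
                contig=str(v.chrom), start=int(v.pos) - 1,
                alleles=(str(v.ref), str(v.alt)))
            rec.info["MID"] = str(mid)
            for s in samples:
                dp = int(wide_dp.at[mid, s])
                alt = int(wide_alt.at[mid, s])
                rec.samples[s]["AD"] = (dp - alt, alt)
                rec.samples[s]["DP"] = dp
            vcf.write(rec)
    return path


def read_counts_vcf(path: str | Path, patient: str = "NA") -> pd.DataFrame:
    """Read a multi-sample VCF with AD/DP into the long counts format.

    The mutation id comes from the MID INFO field when present, else from
    ``chrom:pos:ref>alt``.
    """
    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            mid = rec.info.get("MID",
                               f"{rec.chrom}:{rec.pos}:{rec.ref}>{rec.alts[0]}")
            for sample, call in rec.samples.items():
                ad = call.get("AD")
                dp = call.get("DP")
                alt = int(ad[1]) if ad is not None else 0
                depth = int(dp) if dp is not None else int(sum(ad))
                rows.append((patient, sample, str(mid), alt, depth))
    return pd.DataFrame(rows, columns=COUNT_COLUMNS)
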