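"""Readers and writers for the pipeline's on-disk formats.

Tab-separated UTF-8 tables with a header row and '.' decimals throughout:
variants (TSV or VCF 4.2 with AD-style depths), copy-number segments
(BED-like, 0-based half-open), structural variants (BEDPE-like),
microsatellite histograms in long form (locus_id, repeat_length,
read_count), microsatellite baselines, and JSON sidecars for ground truth
and run metadata. All writers round-trip: write -> read reproduces the
in-memory table.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .msi import MsatBaseline
from .simulate import GroundTruth
from .types import (
    CnaSegment,
    MsatProfile,
    SampleMeta,
    SomaticVariant,
    StructuralVariant,
)

__all__ = [
    "read_variants_tsv", "write_variants_tsv",
    "read_variants_vcf", "write_variants_vcf",
    "read_segments_tsv", "write_segments_tsv",
    "read_svs_tsv", "write_svs_tsv",
    "read_msat_tsv", "write_msat_tsv",
    "read_baseline_tsv", "write_baseline_tsv",
    "read_meta_tsv", "write_meta_tsv",
    "read_ground_truth_json", "write_ground_truth_json",
]

_VARIANT_COLUMNS = [
    "chrom", "pos", "ref", "alt", "gene", "effect",
    "cfdna_ref_depth", "cfdna_alt_depth", "wbc_ref_depth", "wbc_alt_depth",
    "hotspot", "local_total_cn", "multiplicity",
]


def write_variants_tsv(variants: list[SomaticVariant], path) -> None:
    rows = [{c: getattr(v, c) for c in _VARIANT_COLUMNS} for v in variants]
    pd.DataFrame(rows, columns=_VARIANT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_variants_tsv(path) -> list[SomaticVariant]:
    frame = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    return [
        SomaticVariant(
            chrom=r.chrom, pos=int(r.pos), ref=r.ref, alt=r.alt,
            gene=str(r.gene), effect=str(r.effect),
            cfdna_ref_depth=int(r.cfdna_ref_depth),
            cfdna_alt_depth=int(r.cfdna_alt_depth),
            wbc_ref_depth=int(r.wbc_ref_depth),
            wbc_alt_depth=int(r.wbc_alt_depth),
            hotspot=bool(r.hotspot),
            local_total_cn=float(r.local_total_cn),
            multiplicity=float(r.multiplicity),
        )
        for r in frame.itertuples()
    ]


# -- VCF 4.2 ----------------------------------------------------------------

_VCF_CONTIGS = [f"chr{i}" for i in range(1, 23)] + ["chrX", "chrY"]


def _vcf_header():
    import pysam

    header = pysam.VariantHeader()
    header.add_line('##source=plasmakit')
    for contig in _VCF_CONTIGS:
        header.contigs.add(contig)
    header.add_meta(
        "FORMAT",
        items=[("ID", "AD"), ("Number", "R"), ("Type", "Integer"),
               ("Description", "Allelic depths (ref, alt)")],
    )
    header.add_meta(
        "INFO",
        items=[("ID", "GENE"), ("Number", "1"), ("Type", "String"),
               ("Description", "Gene symbol")],
    )
    header.add_meta(
        "INFO",
        items=[("ID", "EFFECT"), ("Number", "1"), ("Type", "String"),
               ("Description", "Consequence class")],
    )
    header.add_meta(
        "INFO",
        items=[("ID", "HOTSPOT"), ("Number", "0"), ("Type", "Flag"),
               ("Description", "Known somatic hotspot")],
    )
    header.add_meta(
        "INFO",
        items=[("ID", "CH"), ("Number", "0"), ("Type", "Flag"),
               ("Description", "Clonal-hematopoiesis false positive")],
    )
    header.add_samples(("CFDNA", "WBC"))
    return header


def write_variants_vcf(
    variants: list[SomaticVariant], path, ch_flagged: set | None = None
) -> None:
    """VCF 4.2 with per-sample AD depths and a CH INFO flag.

    ``ch_flagged`` holds (chrom, pos, ref, alt) keys to mark as
    clonal-hematopoiesis false positives.
    """
    import pysam

    ch_flagged = ch_flagged or set()
    header = _vcf_header()
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for v in sorted(variants, key=lambda v: (_VCF_CONTIGS.index(v.chrom), v.pos)):
            record = vcf.new_record(
                contig=v.chrom, start=v.pos - 1, stop=v.pos - 1 + len(v.ref),
                alleles=(v.ref, v.alt),
            )
            record.info["GENE"] = v.gene
            record.info["EFFECT"] = v.effect
            if v.hotspot:
                record.info["HOTSPOT"] = True
            if v.key in ch_flagged:
                record.info["CH"] = True
            record.samples["CFDNA"]["AD"] = (v.cfdna_ref_depth, v.cfdna_alt_depth)
            record.samples["WBC"]["AD"] = (v.wbc_ref_depth, v.wbc_alt_depth)
            vcf.write(record)


def read_variants_vcf(path) -> tuple[list[SomaticVariant], set]:
    """Variants plus the set of keys flagged as CH false positives."""
    import pysam

    variants, ch_flagged = [], set()
    with pysam.VariantFile(str(path)) as vcf:
        for record in vcf:
            ad_cf = record.samples["CFDNA"]["AD"]
            ad_wbc = record.samples["WBC"]["AD"]
            v = SomaticVariant(
                chrom=record.contig, pos=record.pos,
                ref=record.ref, alt=record.alts[0],
                gene=record.info.get("GENE", "NA"),
                effect=record.info.get("EFFECT", "missense_nonhotspot"),
                cfdna_ref_depth=ad_cf[0], cfdna_alt_depth=ad_cf[1],
                wbc_ref_depth=ad_wbc[0], wbc_alt_depth=ad_wbc[1],
                hotspot=bool(record.info.get("HOTSPOT", False)),
            )
            variants.append(v)
            if record.info.get("CH", False):
                ch_flagged.add(v.key)
    return variants, ch_flagged


# -- segments ---------------------------------------------------------------

_SEGMENT_COLUMNS = ["chrom", "start", "end", "coverage_ratio", "baf", "n_snps", "cn_call"]


def write_segments_tsv(segments: list[CnaSegment], path) -> None:
    rows = [{c: getattr(s, c) for c in _SEGMENT_COLUMNS} for s in segments]
    pd.DataFrame(rows, columns=_SEGMENT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_segments_tsv(path) -> list[CnaSegment]:
    frame = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [
        CnaSegment(
            chrom=r.chrom, start=int(r.start), end=int(r.end),
            coverage_ratio=float(r.coverage_ratio), baf=float(r.baf),
            n_snps=int(r.n_snps), cn_call=str(r.cn_call),
        )
        for r in frame.itertuples()
    ]


# -- structural variants (BEDPE-like) --------------------------------------

_SV_COLUMNS = [
    "chrom1", "pos1", "chrom2", "pos2", "sv_type",
    "genes_disrupted", "supporting_fraction", "adjusted_fraction",
]


def write_svs_tsv(svs: list[StructuralVariant], path) -> None:
    rows = []
    for sv in svs:
        row = {c: getattr(sv, c) for c in _SV_COLUMNS}
        row["genes_disrupted"] = ";".join(f"{g}:{r}" for g, r in sv.genes_disrupted)
        row["adjusted_fraction"] = (
            "" if sv.adjusted_fraction is None else sv.adjusted_fraction
        )
        rows.append(row)
    pd.DataFrame(rows, columns=_SV_COLUMNS).to_csv(path, sep="\t", index=False)


def read_svs_tsv(path) -> list[StructuralVariant]:
    frame = pd.read_csv(
        path, sep="\t", dtype={"chrom1": str, "chrom2": str, "genes_disrupted": str}
    )
    out = []
    for r in frame.itertuples():
        genes = []
        if isinstance(r.genes_disrupted, str) and r.genes_disrupted:
            genes = [tuple(item.split(":")) for item in r.genes_disrupted.split(";")]
        adjusted = None if pd.isna(r.adjusted_fraction) else float(r.adjusted_fraction)
        out.append(
            StructuralVariant(
                chrom1=r.chrom1, pos1=int(r.pos1),
                chrom2=r.chrom2, pos2=int(r.pos2),
                sv_type=str(r.sv_type), genes_disrupted=genes,
                supporting_fraction=float(r.supporting_fraction),
                adjusted_fraction=adjusted,
            )
        )
    return out


# -- microsatellite histograms and baselines --------------------------------


def write_msat_tsv(profiles: list[MsatProfile], path) -> None:
    rows = [
        {"locus_id": p.locus_id, "repeat_length": int(l), "read_count": int(c)}
        for p in profiles
        for l, c in zip(p.repeat_lengths, p.read_counts)
    ]
    pd.DataFrame(rows, columns=["locus_id", "repeat_length", "read_count"]).to_csv(
        path, sep="\t", index=False
    )


def read_msat_tsv(path) -> list[MsatProfile]:
    frame = pd.read_csv(path, sep="\t", dtype={"locus_id": str})
    profiles = []
    for locus_id, group in frame.groupby("locus_id", sort=True):
        profiles.append(
            MsatProfile(
                locus_id=str(locus_id),
                repeat_lengths=group["repeat_length"].to_numpy(),
                read_counts=group["read_count"].to_numpy(),
            )
        )
    return profiles


def write_baseline_tsv(baseline: MsatBaseline, path) -> None:
    baseline.to_frame().to_csv(path, sep="\t", index=False)


def read_baseline_tsv(path) -> MsatBaseline:
    return MsatBaseline.from_frame(pd.read_csv(path, sep="\t", dtype={"locus_id": str}))


# -- metadata and ground truth ----------------------------------------------

_META_COLUMNS = [
    "patient_id", "sample_id", "timepoint", "stage_line",
    "ctc_count", "cfdna_concentration",
]


def write_meta_tsv(metas: list[SampleMeta], path) -> None:
    rows = [{c: getattr(m, c) for c in _META_COLUMNS} for m in metas]
    pd.DataFrame(rows, columns=_META_COLUMNS).to_csv(path, sep="\t", index=False)


def read_meta_tsv(path) -> list[SampleMeta]:
    frame = pd.read_csv(path, sep="\t", dtype={"patient_id": str, "sample_id": str})
    return [
        SampleMeta(
            patient_id=r.patient_id, sample_id=r.sample_id,
            timepoint=str(r.timepoint), stage_line=str(r.stage_line),
            ctc_count=None if pd.isna(r.ctc_count) else float(r.ctc_count),
            cfdna_concentration=(
                None if pd.isna(r.cfdna_concentration) else float(r.cfdna_concentration)
            ),
        )
        for r in frame.itertuples()
    ]


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def write_ground_truth_json(truth: GroundTruth, path) -> None:
    payload = dataclasses.asdict(truth)
    payload["variant_origin"] = {
        "|".join(map(str, k)): v for k, v in truth.variant_origin.items()
    }
    payload["variant_clonal"] = {
        "|".join(map(str, k)): bool(v) for k, v in truth.variant_clonal.items()
    }
    Path(path).write_text(json.dumps(payload, indent=1, default=_jsonable, sort_keys=True))


def read_ground_truth_json(path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())

    def unkey(s):
        chrom, pos, ref, alt = s.split("|")
        return (chrom, int(pos), ref, alt)

    return GroundTruth(
        true_tf=payload["true_tf"],
        msi_status=payload["msi_status"],
        variant_origin={unkey(k): v for k, v in payload["variant_origin"].items()},
        variant_clonal={unkey(k): v for k, v in payload["variant_clonal"].items()},
        gene_zygosity=payload["gene_zygosity"],
        gene_mechanism=payload["gene_mechanism"],
        unstable_loci=frozenset(payload["unstable_loci"]),
        residual_breakpoint_genes=frozenset(payload["residual_breakpoint_genes"]),
        cna_burden=payload["cna_burden"],
    )
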