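"""Variant impact, clonality and per-gene biallelic-inactivation calling.

Impact follows the reporting rules used for cfDNA tumor-suppressor
profiling: truncating, frameshift, splice and hotspot mutations are high
impact; non-hotspot missense changes without a pathogenicity annotation
are variants of unknown significance (VUS); structural variants spanning
exons are high impact while those confined to a single intron are VUS.

Clonality is operationalized against the ctDNA fraction: a variant is
subclonal when its allele fraction is below one quarter of the tumor
fraction (structural variants are first rescaled so that their median
supporting fraction matches the median mutation VAF, compensating the
systematic under-recovery of split/discordant reads).

Biallelic inactivation requires a homozygous deletion, or a clonal
high-impact event plus a second allele-inactivating event (LOH, a second
clonal high-impact mutation, or a disrupting structural variant). Two
hits are counted as biallelic without read-level phasing proof — a
documented limitation.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .types import CnaSegment, GeneHit, GeneStatus, SomaticVariant, StructuralVariant
from .simulate import GENE_MODELS

__all__ = [
    "classify_impact",
    "sv_median_adjustment",
    "classify_clonality",
    "collect_gene_hits",
    "call_biallelic",
    "interpret_sample",
    "gene_alteration_summary",
    "cna_burden",
]

_HIGH_IMPACT_MUTATION_EFFECTS = {"truncating", "frameshift", "splice"}
_SILENT_EFFECTS = {"synonymous", "intronic"}
HIGH_IMPACT_CLASSES = {"high_impact_mutation", "hotspot_mutation", "high_impact_sv"}


def classify_impact(variant) -> str | None:
    """Impact class of a small variant or structural variant.

    Returns one of ``high_impact_mutation``, ``hotspot_mutation``,
    ``vus_mutation``, ``high_impact_sv``, ``vus_sv``; ``None`` for silent
    (synonymous/intronic) point mutations; ``"unclassified"`` with a
    warning when annotation is missing.
    """
    if isinstance(variant, SomaticVariant):
        if variant.effect in _HIGH_IMPACT_MUTATION_EFFECTS:
            return "high_impact_mutation"
        if variant.effect == "hotspot_missense" or (
            variant.effect == "missense_nonhotspot" and variant.hotspot
        ):
            return "hotspot_mutation"
        if variant.effect == "missense_nonhotspot":
            return "vus_mutation"
        if variant.effect in _SILENT_EFFECTS:
            return None
        warnings.warn(f"variant at {variant.chrom}:{variant.pos} lacks annotation")
        return "unclassified"
    if isinstance(variant, StructuralVariant):
        if not variant.genes_disrupted:
            warnings.warn("structural variant lacks gene annotation")
            return "unclassified"
        regions = {region for _, region in variant.genes_disrupted}
        if "exonic_span" in regions:
            return "high_impact_sv"
        return "vus_sv"  # single-intron or promoter-confined
    raise TypeError(f"cannot classify {type(variant).__name__}")


def sv_median_adjustment(
    mutations: list[SomaticVariant], svs: list[StructuralVariant]
) -> float:
    """Rescale SV supporting fractions onto the mutation VAF scale.

    factor = median(mutation VAFs) / median(SV supporting fractions);
    every SV's ``adjusted_fraction`` is set to
    ``min(1, supporting_fraction * factor)`` in place. Without mutations
    there is no reference scale: factor 1 with a warning.
    """
    if not svs:
        return 1.0
    sv_fracs = [sv.supporting_fraction for sv in svs if sv.supporting_fraction > 0]
    mut_vafs = [v.vaf for v in mutations if v.vaf > 0]
    if not mut_vafs or not sv_fracs:
        warnings.warn("no mutation VAFs to anchor the SV allele-fraction adjustment")
        factor = 1.0
    else:
        factor = float(np.median(mut_vafs) / np.median(sv_fracs))
    for sv in svs:
        sv.adjusted_fraction = float(min(1.0, sv.supporting_fraction * factor))
    return factor


def classify_clonality(fraction: float, tf: float) -> str:
    """``subclonal`` iff allele fraction < tf/4 (strict), else ``clonal``.

    Mutations use the raw VAF; structural variants use the adjusted
    fraction. With no measurable tumor fraction clonality is ``NA``.
    """
    if tf <= 0:
        return "NA"
    if fraction < 0:
        raise ValueError("allele fraction must be >= 0")
    return "subclonal" if fraction < tf / 4.0 else "clonal"


def _gene_interval(gene: str, gene_models: dict | None):
    models = gene_models or GENE_MODELS
    if gene not in models:
        raise KeyError(f"no gene model for {gene!r}")
    return models[gene]


def collect_gene_hits(
    gene: str,
    variants: list[SomaticVariant],
    svs: list[StructuralVariant],
    segments: list[CnaSegment],
    tf: float,
    gene_models: dict | None = None,
    loh_baf_threshold: float = 0.65,
    amplification_ratio: float = 1.15,
    weak_amplification_ratio: float = 1.05,
) -> list[GeneHit]:
    """Assemble the annotated hit list for one gene in one sample.

    Copy-number hits come from segments overlapping the gene body:
    ``homozygous_deletion`` and LOH calls directly; LOH is additionally
    accepted from a deletion-consistent coverage ratio with mirrored BAF
    at or above ``loh_baf_threshold`` when the segmentation did not label
    it. Focal gains with coverage ratio >= ``amplification_ratio`` count
    as amplification (>= ``weak_amplification_ratio`` as a weak
    amplification, recorded but not allele-inactivating).
    """
    chrom, start, end = _gene_interval(gene, gene_models)
    hits: list[GeneHit] = []
    for v in variants:
        if v.gene != gene:
            continue
        impact = classify_impact(v)
        if impact is None:
            continue
        hits.append(GeneHit(v, impact, classify_clonality(v.vaf, tf)))
    for sv in svs:
        if not any(g == gene for g, _ in sv.genes_disrupted):
            continue
        impact = classify_impact(sv)
        hits.append(GeneHit(sv, impact, classify_clonality(sv.fraction, tf)))
    for seg in segments:
        if not seg.overlaps(chrom, start, end):
            continue
        if seg.cn_call == "homozygous_deletion":
            hits.append(GeneHit(seg, "homozygous_deletion", "clonal"))
        elif seg.cn_call in ("deletion_LOH", "neutral_LOH") or (
            seg.baf >= loh_baf_threshold and seg.coverage_ratio <= 0.95
        ):
            hits.append(GeneHit(seg, "loh", "clonal"))
        elif seg.cn_call in ("gain", "amplification") and (
            seg.coverage_ratio >= weak_amplification_ratio
        ):
            strong = seg.coverage_ratio >= amplification_ratio
            hits.append(
                GeneHit(seg, "amplification" if strong else "weak_amplification", "clonal")
            )
    return hits


def call_biallelic(
    gene: str,
    hits: list[GeneHit],
    segments: list[CnaSegment],
    msi_flag: bool = False,
    gene_models: dict | None = None,
) -> GeneStatus:
    """Zygosity call for one gene from its annotated hit list.

    homozygous deletion -> biallelic; clonal high-impact hit + (LOH |
    second clonal high-impact hit | disrupting SV) -> biallelic; a single
    clonal high-impact hit -> monoallelic; otherwise wild-type. A
    homozygous deletion co-occurring with a clonal mutation hit is
    contradictory (no template remains to mutate): conflict flag, no
    call. SV breakpoints persisting inside a homozygous deletion set
    ``residual_breakpoint``. In MSI samples high-impact hits are likely
    passengers: the status is flagged for exclusion from cohort
    biallelic-rate summaries.
    """
    status = GeneStatus(gene=gene, hits=list(hits), msi_excluded=msi_flag)
    homdel = [h for h in hits if h.hit_class == "homozygous_deletion"]
    clonal_high = [
        h for h in hits if h.hit_class in HIGH_IMPACT_CLASSES and h.clonality == "clonal"
    ]
    loh = [h for h in hits if h.hit_class == "loh"]

    if homdel:
        clonal_mutations = [
            h
            for h in clonal_high
            if h.hit_class in ("high_impact_mutation", "hotspot_mutation")
        ]
        if clonal_mutations:
            status.conflict = True
            status.zygosity_call = "no_call"
            return status
        status.zygosity_call = "biallelic"
        chrom, start, end = _gene_interval(gene, gene_models)
        homdel_segs = [
            s for s in segments
            if s.cn_call == "homozygous_deletion" and s.overlaps(chrom, start, end)
        ]
        for h in hits:
            if h.hit_class in ("high_impact_sv", "vus_sv") and any(
                seg.overlaps(h.variant.chrom1, h.variant.pos1, h.variant.pos1 + 1)
                or seg.overlaps(h.variant.chrom2, h.variant.pos2, h.variant.pos2 + 1)
                for seg in homdel_segs
            ):
                status.residual_breakpoint = True
        return status

    if clonal_high:
        if len(clonal_high) >= 2 or loh:
            status.zygosity_call = "biallelic"
        else:
            status.zygosity_call = "monoallelic"
    return status


def interpret_sample(
    variants: list[SomaticVariant],
    svs: list[StructuralVariant],
    segments: list[CnaSegment],
    tf: float,
    genes: list[str] | None = None,
    msi_flag: bool = False,
    gene_models: dict | None = None,
) -> dict[str, GeneStatus]:
    """Full per-sample interpretation: SV adjustment then per-gene calls."""
    sv_median_adjustment(variants, svs)
    genes = genes if genes is not None else sorted(
        {v.gene for v in variants}
        | {g for sv in svs for g, _ in sv.genes_disrupted}
    )
    out = {}
    for gene in genes:
        hits = collect_gene_hits(gene, variants, svs, segments, tf, gene_models)
        out[gene] = call_biallelic(gene, hits, segments, msi_flag, gene_models)
    return out


def cna_burden(segments: list[CnaSegment]) -> float:
    """Fraction of the covered genome in non-neutral segments."""
    total = sum(s.length for s in segments)
    if total == 0:
        return 0.0
    return sum(s.length for s in segments if s.is_aberrant) / total


_SUMMARY_CLASSES = {
    "amplification": lambda h: h.hit_class == "amplification",
    "structural_variant": lambda h: h.hit_class in ("high_impact_sv", "vus_sv"),
    "high_impact_mutation": lambda h: h.hit_class
    in ("high_impact_mutation", "hotspot_mutation"),
}


def gene_alteration_summary(
    samples: list[tuple],
    gene: str,
) -> pd.DataFrame:
    """Per-group fractions of patients with alterations in one gene.

    ``samples`` holds ``(meta, gene_statuses)`` pairs where
    ``gene_statuses`` maps gene -> :class:`GeneStatus`. Grouping is by
    line of therapy (``meta.stage_line``); a patient counts as positive
    within a group when any of their samples in that group carries the
    alteration class ("ever positive within the therapy line"). Empty
    groups are omitted.
    """
    records: dict[str, dict[str, dict[str, set]]] = {}
    patients_by_group: dict[str, set] = {}
    for meta, statuses in samples:
        group = meta.stage_line
        patients_by_group.setdefault(group, set()).add(meta.patient_id)
        bucket = records.setdefault(group, {name: set() for name in (*_SUMMARY_CLASSES, "any")})
        st = statuses.get(gene)
        if st is None:
            continue
        positive_any = False
        for name, pred in _SUMMARY_CLASSES.items():
            if any(pred(h) for h in st.hits):
                bucket[name].add(meta.patient_id)
                positive_any = True
        if positive_any:
            bucket["any"].add(meta.patient_id)
    rows = []
    for group in sorted(records):
        denom = len(patients_by_group[group])
        row = {"group": group, "n_patients": denom}
        for name in (*_SUMMARY_CLASSES, "any"):
            numer = len(records[group][name])
            row[f"n_{name}"] = numer
            row[f"frac_{name}"] = numer / denom if denom else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)
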