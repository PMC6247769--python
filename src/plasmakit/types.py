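"""Core record types shared across the pipeline.

Conventions: point variants are 1-based (VCF style), copy-number segments
are 0-based half-open (BED style). Mirrored B-allele fractions live in
[0.5, 1]. All allele fractions are plain alt/(ref+alt) ratios in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: recognised small-variant consequence classes
EFFECTS = frozenset(
    {
        "hotspot_missense",
        "truncating",
        "frameshift",
        "splice",
        "missense_nonhotspot",
        "synonymous",
        "intronic",
    }
)

#: copy-number segment calls produced by the (upstream) segmentation
CN_CALLS = frozenset(
    {
        "homozygous_deletion",
        "deletion_LOH",
        "neutral",
        "neutral_LOH",
        "gain",
        "amplification",
    }
)

#: nominal total copy number implied by each segment call
CN_OF_CALL = {
    "homozygous_deletion": 0,
    "deletion_LOH": 1,
    "neutral": 2,
    "neutral_LOH": 2,
    "gain": 3,
    "amplification": 4,
}

#: nominal major-allele copy number implied by each segment call
MAJOR_CN_OF_CALL = {
    "homozygous_deletion": 0,
    "deletion_LOH": 1,
    "neutral": 1,
    "neutral_LOH": 2,
    "gain": 2,
    "amplification": 3,
}

SV_TYPES = frozenset({"deletion", "duplication", "inversion", "translocation"})

#: regions an SV breakpoint pair can disrupt within a gene
SV_REGIONS = frozenset({"exonic_span", "single_intron", "promoter"})


@dataclass
class SomaticVariant:
    """One SNV or indel with cfDNA and matched-WBC allele depths."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    effect: str
    cfdna_ref_depth: int
    cfdna_alt_depth: int
    wbc_ref_depth: int = 0
    wbc_alt_depth: int = 0
    hotspot: bool = False
    local_total_cn: float = 2.0
    multiplicity: float = 1.0

    def __post_init__(self) -> None:
        if self.effect not in EFFECTS:
            raise ValueError(f"unknown effect class {self.effect!r}")
        for name in ("cfdna_ref_depth", "cfdna_alt_depth", "wbc_ref_depth", "wbc_alt_depth"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def cfdna_depth(self) -> int:
        return self.cfdna_ref_depth + self.cfdna_alt_depth

    @property
    def wbc_depth(self) -> int:
        return self.wbc_ref_depth + self.wbc_alt_depth

    @property
    def vaf(self) -> float:
        """cfDNA variant allele fraction; 0 when the site is uncovered."""
        d = self.cfdna_depth
        return self.cfdna_alt_depth / d if d else 0.0

    @property
    def wbc_vaf(self) -> float:
        d = self.wbc_depth
        return self.wbc_alt_depth / d if d else 0.0

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)

    @property
    def key(self) -> tuple:
        """Identity used to match variants between call sets."""
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class CnaSegment:
    """Copy-number segment with coverage ratio and mirrored het-SNP BAF."""

    chrom: str
    start: int
    end: int
    coverage_ratio: float
    baf: float = 0.5
    n_snps: int = 0
    cn_call: str = "neutral"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("segment start must be < end")
        if self.coverage_ratio <= 0:
            raise ValueError("coverage_ratio must be > 0")
        if not 0.5 <= self.baf <= 1.0:
            raise ValueError("mirrored baf must lie in [0.5, 1]")
        if self.cn_call not in CN_CALLS:
            raise ValueError(f"unknown cn_call {self.cn_call!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def is_aberrant(self) -> bool:
        return self.cn_call != "neutral"

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return self.chrom == chrom and self.start < end and start < self.end


@dataclass
class StructuralVariant:
    """Breakpoint pair with supporting-read fraction.

    ``genes_disrupted`` pairs each affected gene with the region class the
    breakpoints fall in (``exonic_span`` | ``single_intron`` | ``promoter``).
    """

    chrom1: str
    pos1: int
    chrom2: str
    pos2: int
    sv_type: str
    genes_disrupted: list = field(default_factory=list)
    supporting_fraction: float = 0.0
    adjusted_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.sv_type not in SV_TYPES:
            raise ValueError(f"unknown sv_type {self.sv_type!r}")
        if not 0.0 <= self.supporting_fraction <= 1.0:
            raise ValueError("supporting_fraction must lie in [0, 1]")
        for gene, region in self.genes_disrupted:
            if region not in SV_REGIONS:
                raise ValueError(f"unknown SV region {region!r} for gene {gene}")

    @property
    def fraction(self) -> float:
        """Adjusted allele fraction when available, else the raw one."""
        return self.supporting_fraction if self.adjusted_fraction is None else self.adjusted_fraction


@dataclass
class MsatProfile:
    """Read-count histogram over repeat lengths at one microsatellite locus."""

    locus_id: str
    repeat_lengths: np.ndarray
    read_counts: np.ndarray

    def __post_init__(self) -> None:
        self.repeat_lengths = np.asarray(self.repeat_lengths, dtype=int)
        self.read_counts = np.asarray(self.read_counts, dtype=int)
        if self.repeat_lengths.shape != self.read_counts.shape:
            raise ValueError("repeat_lengths and read_counts must align")
        if (self.read_counts < 0).any():
            raise ValueError("read counts must be >= 0")
        order = np.argsort(self.repeat_lengths)
        self.repeat_lengths = self.repeat_lengths[order]
        self.read_counts = self.read_counts[order]

    @property
    def depth(self) -> int:
        return int(self.read_counts.sum())


@dataclass
class TumorFractionEstimate:
    """ctDNA fraction from mutations and/or the CNA profile, with tier."""

    tf_vaf: float
    tf_cna: float
    tf_final: float
    tier: frozenset
    method: str  # {vaf, cna, none}
    cna_discordant: bool = False
    n_variants_used: int = 0
    n_segments_used: int = 0


@dataclass
class GeneHit:
    """One inactivating (or candidate) event on a gene."""

    variant: object  # SomaticVariant | StructuralVariant | CnaSegment | None
    hit_class: str  # high_impact_mutation | hotspot_mutation | vus_mutation |
    #                 high_impact_sv | vus_sv | loh | homozygous_deletion | amplification
    clonality: str = "NA"  # clonal | subclonal | NA


@dataclass
class GeneStatus:
    """Per-gene, per-sample hit list and zygosity classification."""

    gene: str
    hits: list = field(default_factory=list)
    zygosity_call: str = "wild_type"  # wild_type | monoallelic | biallelic | no_call
    residual_breakpoint: bool = False
    conflict: bool = False
    msi_excluded: bool = False


@dataclass
class CHCandidate:
    """Clonal-hematopoiesis candidate discovered in WBC DNA."""

    variant: SomaticVariant
    wbc_vaf: float
    cfdna_vaf: float
    hotspot: bool
    background_rate: float
    status: str = "candidate"  # candidate | excluded_germline | confirmed_CH | unconfirmed
    wbc_p: float = float("nan")
    cfdna_p: float = float("nan")
    note: str = ""


@dataclass
class SampleMeta:
    """Clinical metadata attached to one plasma sample."""

    patient_id: str
    sample_id: str
    timepoint: str = "baseline"  # baseline | follow_up
    stage_line: str = "mCRPC1"  # mHNPC | mHSPC | mCRPC1..mCRPC4+
    ctc_count: float | None = None
    cfdna_concentration: float | None = None
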