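"""Core genomic value objects shared across the pipeline.

Coordinates are 0-based half-open everywhere inside the package; the VCF
boundary (reading and writing) is the only place 1-based positions appear.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional


class VariantClass(str, Enum):
    SNV = "SNV"
    INS = "INS"
    DEL = "DEL"

    @staticmethod
    def of(ref: str, alt: str) -> "VariantClass":
        if len(ref) == 1 and len(alt) == 1:
            return VariantClass.SNV
        if len(alt) > len(ref):
            return VariantClass.INS
        return VariantClass.DEL


@dataclass(frozen=True, order=True)
class GenomicSite:
    """A candidate or truth variant locus.

    ``pos`` is the 0-based position of the first reference base of ``ref``.
    For indels this is the anchor base shared by ref and alt (VCF style,
    e.g. deletion ref="AGG" alt="A" anchored at the "A").
    """

    contig: str
    pos: int
    ref: str
    alt: str

    @property
    def variant_class(self) -> VariantClass:
        return VariantClass.of(self.ref, self.alt)

    @property
    def end(self) -> int:
        """0-based end (exclusive) of the reference span."""
        return self.pos + len(self.ref)

    @property
    def indel_length(self) -> int:
        return abs(len(self.alt) - len(self.ref))

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.contig}:{self.pos}{self.ref}>{self.alt}"


@dataclass(frozen=True)
class TruthVariant:
    """A simulator ground-truth variant with its designed allele fraction."""

    site: GenomicSite
    designed_vaf: float
    origin: str  # "somatic" | "germline"


@dataclass
class TruthSet:
    """Ground truth emitted by the read simulator."""

    variants: list[TruthVariant] = field(default_factory=list)

    @property
    def somatic(self) -> list[TruthVariant]:
        return [v for v in self.variants if v.origin == "somatic"]

    @property
    def germline(self) -> list[TruthVariant]:
        return [v for v in self.variants if v.origin == "germline"]

    def __len__(self) -> int:
        return len(self.variants)


@dataclass
class VariantCall:
    """A scored somatic call, serializable to VCF."""

    site: GenomicSite
    score: float
    filter: str = "PASS"  # PASS | GERMLINE_PROX | LOW_SCORE
    depth_tumor: int = 0
    depth_normal: int = 0
    alt_count_tumor: int = 0
    alt_count_normal: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score must be in [0,1], got {self.score}")
        if self.alt_count_tumor > self.depth_tumor:
            raise ValueError("tumor alt count exceeds depth")
        if self.alt_count_normal > self.depth_normal:
            raise ValueError("normal alt count exceeds depth")

    @property
    def tumor_vaf(self) -> Optional[float]:
        if self.depth_tumor == 0:
            return None
        return self.alt_count_tumor / self.depth_tumor
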