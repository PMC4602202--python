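"""Variant records and the canonical deleteriousness-score panel."""

from __future__ import annotations

from dataclasses import dataclass

from .exceptions import InputError

#: The 11 variant-level functional (deleteriousness) scores, in canonical
#: feature order.  SIFT and LRT are "smaller = more damaging" on their raw
#: scale and are flipped (1 - x) before min-max normalization.
VARIANT_SCORES: tuple[str, ...] = (
    "SIFT",
    "PolyPhen2",
    "LRT",
    "MutationTaster",
    "MutationAccessor",
    "MSRV",
    "GERP",
    "Phylop",
    "SiPhy",
    "CADD",
    "SInBaD",
)

#: Scores whose raw scale is inverted before normalization.
FLIPPED_SCORES: frozenset[str] = frozenset({"SIFT", "LRT"})

_BASES = frozenset("ACGT")


@dataclass(frozen=True, slots=True)
class VariantRecord:
    """A single-nucleotide variant with its host-gene annotation.

    Coordinates are 1-based (VCF convention); ``ref`` and ``alt`` are
    single bases and must differ.  The tuple ``(chrom, pos, ref, alt)``
    is the unique key of a variant within a dataset.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise InputError(f"ref and alt are identical for {self.chrom}:{self.pos}")
        if self.ref not in _BASES or self.alt not in _BASES:
            raise InputError(
                f"non-SNV alleles {self.ref!r}>{self.alt!r} at {self.chrom}:{self.pos}"
            )
        if self.pos < 1:
            raise InputError(f"position must be 1-based positive, got {self.pos}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    def __str__(self) -> str:  # pragma: no cover - repr convenience
        return f"{self.chrom}:{self.pos}{self.ref}>{self.alt}({self.gene})"
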