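"""Variant classification, filtering and set algebra shared by all workflows.

The EMS mutagen induces G→A transitions; on a forward-strand VCF the same
lesion on the reverse strand is reported as C→T, so both orientations count
as EMS-type.  Homozygosity in pooled samples is called from the allele
frequency (there is no meaningful diploid genotype for a pool), with a
threshold that absorbs binomial sampling noise at typical read depths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .genomeio import Variant, VariantSet

CLASS_LABELS = ("ems", "non_ems_snp", "insertion", "deletion")


@dataclass(frozen=True)
class FilterConfig:
    af_hom_min: float = 0.85
    min_dp: int = 5
    min_qual: float = 20.0
    report_classes: frozenset[str] = frozenset(CLASS_LABELS)

    def __post_init__(self):
        if not (0.5 < self.af_hom_min <= 1.0):
            raise ValueError("af_hom_min must be in (0.5, 1]")
        if self.min_dp < 0:
            raise ValueError("min_dp must be >= 0")
        unknown = set(self.report_classes) - set(CLASS_LABELS)
        if unknown:
            raise ValueError(f"unknown report classes: {sorted(unknown)}")
        if not self.report_classes:
            raise ValueError("report_classes is empty: nothing would be reportable")


def classify_ems(v: Variant) -> bool:
    """True for EMS-type transitions: G→A or its reverse-strand image C→T."""
    if v.vclass != "snp":
        return False
    return (v.ref, v.alt) in (("G", "A"), ("C", "T"))


def variant_label(v: Variant) -> str:
    """Report class of a variant: ems, non_ems_snp, insertion or deletion."""
    if v.vclass == "snp":
        return "ems" if classify_ems(v) else "non_ems_snp"
    return v.vclass


def subtract_control(
    test: VariantSet, control: VariantSet, position_only: bool = False
) -> VariantSet:
    """Test-specific variants: records of `test` absent from `control`.

    Allele-aware by default (same position with a different alt allele is
    retained); `position_only=True` drops any test variant at a position
    present in the control, the safer choice for pooled multi-genotype
    control compilations.
    """
    if position_only:
        ctrl_pos = {(v.chrom, v.pos) for v in control}
        kept = (v for v in test if (v.chrom, v.pos) not in ctrl_pos)
    else:
        kept = (v for v in test if v.key not in control)
    return test.spawn(kept)


def filter_homozygous(vset: VariantSet, cfg: FilterConfig = FilterConfig()) -> VariantSet:
    """Keep records with af >= af_hom_min and depth >= min_dp.

    Every record must carry a defined allele frequency; a record without one
    cannot be classified and is a hard error naming the offending key.
    """
    kept = []
    for v in vset:
        if v.af is None:
            raise ValueError(f"variant {v.key} has undefined allele frequency")
        if v.af >= cfg.af_hom_min and v.depth >= cfg.min_dp:
            kept.append(v)
    return vset.spawn(kept)


def filter_ems(vset: VariantSet) -> VariantSet:
    return vset.spawn(v for v in vset if classify_ems(v))


def intersect(a: VariantSet, b: VariantSet) -> VariantSet:
    """Records of `a` whose key is also present in `b` (fields from `a`)."""
    return a.spawn(v for v in a if v.key in b)


def filter_by_class(vset: VariantSet, cfg: FilterConfig = FilterConfig()) -> VariantSet:
    """Keep records whose report class is requested in cfg.report_classes."""
    if not cfg.report_classes:
        raise ValueError("report_classes is empty: nothing would be reportable")
    return vset.spawn(v for v in vset if variant_label(v) in cfg.report_classes)
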