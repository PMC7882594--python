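"""Track-independent gates: population rarity and CADD deleteriousness.

The rarity gate keeps variants whose aggregate minor allele frequency is
strictly below 0.001; aggregation is the maximum over every population
resource that reports the variant (the conservative choice — common in
any one reference population disqualifies). A variant absent from all
resources is kept by default: a never-observed allele is rare by
construction.

The CADD gate keeps variants with phred-scaled CADD strictly above 20,
i.e. the top 1% of ranked deleteriousness (phred s = -10*log10(rank/N),
so s > 20 <=> rank/N < 10^-2).
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import AnnotationProfile, DataError


@dataclass(frozen=True)
class FilterConfig:
    maf_threshold: float = 0.001
    cadd_threshold: float = 20.0
    missing_maf_policy: str = "treat_as_rare"     # or "treat_as_common"
    missing_cadd_policy: str = "fail"             # or "pass"

    def __post_init__(self) -> None:
        if self.maf_threshold <= 0 or self.cadd_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if self.missing_maf_policy not in ("treat_as_rare", "treat_as_common"):
            raise ValueError(
                f"unknown missing-MAF policy {self.missing_maf_policy!r}"
            )
        if self.missing_cadd_policy not in ("fail", "pass"):
            raise ValueError(
                f"unknown missing-CADD policy {self.missing_cadd_policy!r}"
            )


def passes_maf(profile: AnnotationProfile,
               cfg: FilterConfig = FilterConfig()) -> bool:
    """True iff max over present population AFs < threshold (strict)."""
    present = [af for af in profile.pop_afs.values() if af is not None]
    if any(af < 0 for af in present):
        raise DataError("negative allele frequency")
    if not present:
        return cfg.missing_maf_policy == "treat_as_rare"
    return max(present) < cfg.maf_threshold


def passes_cadd(profile: AnnotationProfile,
                cfg: FilterConfig = FilterConfig()) -> bool:
    """True iff CADD phred > threshold (strict); missing per policy."""
    if profile.cadd_phred is None:
        return cfg.missing_cadd_policy == "pass"
    return profile.cadd_phred > cfg.cadd_threshold
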