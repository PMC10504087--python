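"""Purity/CN-aware interpretation of bulk somatic variants.

A variant observed at raw VAF ``v`` in a sample of purity ``p`` whose locus
has tumor total copy number ``CN_t`` (normal copy number fixed at 2; both
target genes are autosomal) is interpreted with the standard linear mixture
model.  The expected raw VAF of a variant present on ``m`` copies in a
fraction ``CCF`` of tumor cells is

    v = p * CCF * m / (p * CN_t + (1 - p) * 2)

which inverts to the corrected (tumor-allele) VAF, the multiplicity estimate
and the cancer cell fraction.  Confidence intervals propagate a Wilson
binomial interval on the raw VAF through the same linear map.

``biallelic_status`` combines allele-specific CN with clonal protein-altering
mutations into the per-gene escape classes (biallelic deletion, deletion plus
mutation, compound mutations in trans, monoallelic loss, intact).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from statsmodels.stats.proportion import proportion_confint

CN_NORMAL = 2
CLONAL_CCF_THRESHOLD = 0.9

PROTEIN_ALTERING = frozenset({"missense", "nonsense", "inframe_del", "frameshift"})

BIALLELIC_STATUSES = (
    "intact",
    "monoallelic_loss",
    "biallelic_deletion",
    "deletion_plus_mutation",
    "compound_mutations",
)


class InconsistencyError(ValueError):
    """Mutually contradictory CN / variant inputs."""


@dataclass(frozen=True)
class PurityContext:
    """Sample purity and locus tumor copy number (optionally allele-specific)."""

    purity: float
    cn_t: int
    major: int | None = None
    minor: int | None = None

    def __post_init__(self) -> None:
        if not (0 < self.purity <= 1):
            raise ValueError(f"purity must be in (0, 1], got {self.purity}")
        if self.cn_t < 0:
            raise ValueError(f"CN_t must be >= 0, got {self.cn_t}")
        if (self.major is None) != (self.minor is None):
            raise ValueError("major and minor CN must be given together")
        if self.major is not None and self.major + self.minor != self.cn_t:
            raise InconsistencyError(
                f"major ({self.major}) + minor ({self.minor}) != CN_t ({self.cn_t})"
            )


def _denominator(p: float, cn_t: float) -> float:
    return p * cn_t + (1 - p) * CN_NORMAL


def corrected_vaf(raw_vaf: float, purity: float, cn_t: float) -> float:
    """Purity/CN-corrected tumor-allele fraction, clipped to [0, 1].

    ``cn_t`` may be fractional (a fraction-weighted average locus CN across
    subclones), in which case the correction is the exact inverse of the
    mixture forward model.
    """
    _check(raw_vaf, purity)
    if cn_t < 0:
        raise ValueError(f"CN_t must be >= 0, got {cn_t}")
    if cn_t == 0:
        if raw_vaf > 0:
            raise InconsistencyError("nonzero VAF at a locus with tumor CN 0")
        return 0.0
    return float(np.clip(raw_vaf * _denominator(purity, cn_t) / (purity * cn_t), 0, 1))


def inverse_corrected_vaf(corrected: float, purity: float, cn_t: float) -> float:
    """Raw VAF expected for a given corrected VAF (the forward mixture map)."""
    _check(corrected, purity)
    return corrected * purity * cn_t / _denominator(purity, cn_t)


def estimate_multiplicity(raw_vaf: float, purity: float, cn_t: float) -> int:
    """Nearest-integer multiplicity, clipped to [1, max(round(CN_t), 1)]."""
    _check(raw_vaf, purity)
    m = round(raw_vaf * _denominator(purity, cn_t) / purity)
    return int(np.clip(m, 1, max(int(round(cn_t)), 1)))


@dataclass(frozen=True)
class CCFEstimate:
    ccf: float
    multiplicity: int
    ci_low: float | None
    ci_high: float | None
    clonality: str      # "clonal" | "subclonal"

    @property
    def is_clonal(self) -> bool:
        return self.clonality == "clonal"


def ccf(
    raw_vaf: float | None,
    purity: float,
    cn_t: float,
    multiplicity: int,
    alt_count: int | None = None,
    depth: int | None = None,
) -> CCFEstimate:
    """Cancer cell fraction of a variant, with a propagated Wilson 95% CI.

    Provide ``alt_count``/``depth`` to derive the raw VAF and its CI from read
    counts; otherwise the point estimate alone is computed.  A variant is
    called clonal when CCF >= 0.9 or its CI covers 1.0.
    """
    if multiplicity < 1:
        raise ValueError(f"multiplicity must be >= 1, got {multiplicity}")
    if alt_count is not None and depth is not None:
        raw_vaf = alt_count / depth
        lo, hi = proportion_confint(alt_count, depth, alpha=0.05, method="wilson")
    else:
        if raw_vaf is None:
            raise ValueError("provide raw_vaf or alt_count/depth")
        lo = hi = None
    _check(raw_vaf, purity)
    scale = _denominator(purity, cn_t) / (purity * multiplicity)
    point = float(np.clip(raw_vaf * scale, 0, 1))
    ci_low = float(np.clip(lo * scale, 0, 1)) if lo is not None else None
    ci_high_raw = hi * scale if hi is not None else None
    ci_high = float(np.clip(ci_high_raw, 0, 1)) if hi is not None else None
    clonal = point >= CLONAL_CCF_THRESHOLD or (
        ci_high_raw is not None and ci_high_raw >= 1.0
    )
    return CCFEstimate(point, multiplicity, ci_low, ci_high,
                       "clonal" if clonal else "subclonal")


def _check(vaf: float, purity: float) -> None:
    if not (0 <= vaf <= 1):
        raise ValueError(f"VAF must be in [0, 1], got {vaf}")
    if not (0 < purity <= 1):
        raise ValueError(f"purity must be in (0, 1], got {purity}")


@dataclass(frozen=True)
class GeneMutation:
    """A mutation consumed by the biallelic-status caller."""

    consequence: str            # missense | nonsense | inframe_del | frameshift | ...
    clonality: str = "clonal"   # "clonal" | "subclonal"
    in_trans_with: str | None = None   # id of a phased-in-trans partner


def biallelic_status(
    gene: str,
    context: PurityContext,
    mutations: Sequence[GeneMutation] = (),
) -> str:
    """Classify a gene/sample into an inactivation status.

    CN_t = 0 (or both alleles at 0) is a biallelic deletion.  One remaining
    allele (CN_t = 1 or minor = 0) plus a clonal protein-altering mutation is
    deletion-plus-mutation; alone it is monoallelic loss.  Two protein-
    altering mutations established in trans on >= 2 copies are compound
    mutations.  Anything else is intact.
    """
    protein_altering = [m for m in mutations if m.consequence in PROTEIN_ALTERING]
    clonal_pa = [m for m in protein_altering if m.clonality == "clonal"]
    minor = context.minor
    lost_allele = context.cn_t == 1 or (minor is not None and minor == 0
                                        and context.cn_t >= 1)

    if context.cn_t == 0:
        return "biallelic_deletion"
    if lost_allele and clonal_pa:
        return "deletion_plus_mutation"
    if context.cn_t >= 2 and not (minor is not None and minor == 0):
        in_trans = [m for m in protein_altering if m.in_trans_with is not None]
        if len(in_trans) >= 2:
            return "compound_mutations"
    if lost_allele:
        return "monoallelic_loss"
    return "intact"
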