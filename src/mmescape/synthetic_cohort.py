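"""Synthetic pre/post-therapy cohorts with known clonal truth.

The generator resolves a user-declared clone tree (rooted at a diploid
"normal" genome) into per-clone, per-bin copy-number profiles, then emulates
the observables the analysis consumes:

* per-cell integer CN matrices with Poisson read-count noise and a fixed
  per-bin multiplicative (lognormal) bias — the stand-in for all systematic
  coverage effects;
* bulk VAFs under the standard purity/multiplicity mixture model,
  ``VAF = p·Σ f_c·m_c / (p·Σ f_c·CN_c + (1−p)·2)``, with binomial read
  sampling;
* phased read-pair counts for pairs of nearby variants, with a per-read
  error rate ε.

Preset scenarios reproduce the clonal architectures of published
antigen-escape cases (selective sweep of a pre-existing biallelically deleted
subclone; convergent inactivation by several mutually exclusive subclones) on
a compact synthetic genome, so every downstream stage can be tested against
generator truth without any external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .genomic_core import (
    BinGrid,
    CellCNMatrix,
    GenomicInterval,
    LocusDef,
    bins_overlapping,
)
from .convergence import PhasedEvidence

NOISE_FREE = float("inf")   # sentinel for reads_per_bin: exact CN observation

#: Synthetic genome used by the preset scenarios.  Chromosome "16" carries the
#: BCMA locus, "12" the GPRC5D locus, "1" is a neutral background chromosome.
PRESET_CHROM_LENGTHS = {"1": 1_000_000, "12": 2_000_000, "16": 2_000_000}
PRESET_BIN_WIDTH = 20_000
#: Synthetic target loci (coordinates on the synthetic genome above).
TNFRSF17_LOCUS = LocusDef("TNFRSF17", GenomicInterval("16", 1_000_001, 1_010_000))
GPRC5D_LOCUS = LocusDef("GPRC5D", GenomicInterval("12", 500_001, 510_000))
#: Focal deletions in the presets span 180 kb around the locus (9 bins).
_TNFRSF17_FOCAL = GenomicInterval("16", 940_001, 1_120_000)
_GPRC5D_FOCAL = GenomicInterval("12", 420_001, 600_000)


@dataclass(frozen=True)
class CNEventSpec:
    """A copy-number event: set an absolute CN or apply a signed delta."""

    interval: GenomicInterval
    cn: int | None = None
    delta: int | None = None
    allele: str | None = None

    def __post_init__(self) -> None:
        if (self.cn is None) == (self.delta is None):
            raise ValueError("specify exactly one of cn= or delta=")
        if self.cn is not None and not (0 <= self.cn <= 6):
            raise ValueError(f"absolute CN must be in [0, 6], got {self.cn}")


@dataclass(frozen=True)
class VariantSpec:
    """A somatic SNV/indel with per-clone multiplicity.

    ``carriers`` maps clone id -> multiplicity m_c (copies bearing the
    variant).  ``copy_offset`` selects which copies carry it (copies
    ``[offset, offset + m)``), so two variants in the same clone are in cis
    when their copy ranges overlap and in trans otherwise.
    """

    variant_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    carriers: Mapping[str, int]
    copy_offset: int = 0
    consequence: str = "missense"   # coding class used by downstream callers


@dataclass(frozen=True)
class CloneSpec:
    """A tumor clone: events layered on its parent, fractions per timepoint."""

    clone_id: str
    parent: str                      # "normal" for clones off the diploid root
    events: tuple[CNEventSpec, ...] = ()
    fractions: Mapping[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class CohortConfig:
    """Everything needed to generate one synthetic cohort."""

    chrom_lengths: Mapping[str, int]
    clones: tuple[CloneSpec, ...]
    purity: float = 1.0
    n_cells: Mapping[str, int] = field(default_factory=dict)
    bin_width: int = 20_000
    reads_per_bin: float = 100.0      # λ; NOISE_FREE for exact observation
    bias_sigma: float = 0.05          # lognormal σ of the fixed per-bin bias
    epsilon: float = 1e-3             # per-read error rate for phased pairs
    variants: tuple[VariantSpec, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.purity <= 1):
            raise ValueError(f"purity must be in (0, 1], got {self.purity}")
        if self.bias_sigma < 0 or self.epsilon < 0:
            raise ValueError("rates must be >= 0")


@dataclass
class CohortTruth:
    """Resolved generator truth: profiles, fractions and variants."""

    grid: BinGrid
    clone_ids: tuple[str, ...]
    profiles: dict[str, np.ndarray]            # clone -> per-bin total CN
    fractions: dict[str, dict[str, float]]     # timepoint -> clone -> f_c
    variants: tuple[VariantSpec, ...]
    config: CohortConfig

    def locus_cn(self, clone_id: str, chrom: str, pos: int) -> int:
        locus = LocusDef("_q", GenomicInterval(chrom, pos, pos))
        (b,) = bins_overlapping(locus, self.grid)
        return int(self.profiles[clone_id][b])


def build_truth(config: CohortConfig) -> CohortTruth:
    """Resolve clone specs into per-bin CN profiles; deterministic."""
    grid = BinGrid.uniform(dict(config.chrom_lengths), config.bin_width)
    by_id = {c.clone_id: c for c in config.clones}
    if len(by_id) != len(config.clones):
        raise ValueError("duplicate clone ids")
    if "normal" in by_id:
        raise ValueError('"normal" names the implicit diploid root')

    profiles: dict[str, np.ndarray] = {"normal": np.full(grid.n_bins, 2, dtype=np.int64)}

    def resolve(cid: str, seen: tuple[str, ...] = ()) -> np.ndarray:
        if cid in profiles:
            return profiles[cid]
        if cid in seen:
            raise ValueError(f"cycle in clone parent links at {cid!r}")
        spec = by_id.get(cid)
        if spec is None:
            raise ValueError(f"unknown parent clone {cid!r}")
        prof = resolve(spec.parent, seen + (cid,)).copy()
        for ev in spec.events:
            bin_ids = bins_overlapping(LocusDef("_ev", ev.interval), grid)
            if ev.cn is not None:
                prof[bin_ids] = ev.cn
            else:
                prof[bin_ids] += ev.delta
        if prof.min() < 0:
            raise ValueError(f"clone {cid!r}: event produces CN < 0")
        profiles[cid] = prof
        return prof

    for c in config.clones:
        resolve(c.clone_id)

    timepoints: set[str] = set()
    for c in config.clones:
        timepoints.update(c.fractions)
    fractions: dict[str, dict[str, float]] = {}
    for tp in sorted(timepoints):
        fr = {c.clone_id: float(c.fractions.get(tp, 0.0)) for c in config.clones}
        total = sum(fr.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"fractions at {tp!r} sum to {total}, not 1")
        fractions[tp] = fr

    for v in config.variants:
        for cid, m in v.carriers.items():
            cn_here = CohortTruth(
                grid, tuple(by_id), profiles, fractions, (), config
            ).locus_cn(cid, v.chrom, v.pos)
            if not (1 <= m <= max(cn_here, 1)):
                raise ValueError(
                    f"variant {v.variant_id}: multiplicity {m} exceeds "
                    f"clone {cid} CN {cn_here} at {v.chrom}:{v.pos}"
                )

    return CohortTruth(
        grid=grid,
        clone_ids=tuple(c.clone_id for c in config.clones),
        profiles=profiles,
        fractions=fractions,
        variants=tuple(config.variants),
        config=config,
    )


def simulate_cell_matrix(
    truth: CohortTruth,
    timepoint: str,
    seed: int | np.random.Generator | None = None,
) -> tuple[CellCNMatrix, list[str]]:
    """Draw a per-cell CN matrix and its true clone labels.

    Clone membership is multinomial in the timepoint fractions.  Per bin,
    reads ~ Poisson(λ · bias_b · CN/2) with a fixed lognormal per-bin bias;
    the observed CN is the instrument-style normalization
    ``round(reads / (λ · bias_b) · 2)`` clipped to [0, 6].  With
    ``reads_per_bin = NOISE_FREE`` the observed CN equals the true CN exactly.
    """
    cfg = truth.config
    n = int(cfg.n_cells.get(timepoint, 0))
    if n < 1:
        raise ValueError(f"n_cells for timepoint {timepoint!r} must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(
        cfg.seed if seed is None else seed
    )
    fr = truth.fractions[timepoint]
    clone_ids = [c for c in truth.clone_ids]
    probs = np.array([fr[c] for c in clone_ids], dtype=float)
    labels_idx = rng.choice(len(clone_ids), size=n, p=probs)
    labels = [clone_ids[i] for i in labels_idx]

    prof = np.stack([truth.profiles[c] for c in clone_ids])  # clones x bins
    true_cn = prof[labels_idx]                               # cells x bins

    if math.isinf(cfg.reads_per_bin):
        observed = true_cn.copy()
    else:
        lam = cfg.reads_per_bin
        bias = rng.lognormal(mean=0.0, sigma=cfg.bias_sigma, size=truth.grid.n_bins)
        reads = rng.poisson(lam * bias[None, :] * true_cn / 2.0)
        observed = np.rint(reads / (lam * bias[None, :]) * 2.0).astype(np.int64)
        observed = np.clip(observed, 0, 6)

    cell_ids = [f"{timepoint}_cell{i:05d}" for i in range(n)]
    return CellCNMatrix(cell_ids, truth.grid, observed), labels


def expected_bulk_vaf(variant: VariantSpec, truth: CohortTruth, timepoint: str,
                      purity: float | None = None) -> float:
    """Expected raw VAF under the purity/multiplicity mixture model."""
    p = truth.config.purity if purity is None else purity
    if not (0 < p <= 1):
        raise ValueError(f"purity must be in (0, 1], got {p}")
    fr = truth.fractions[timepoint]
    num = sum(fr[c] * m for c, m in variant.carriers.items())
    den = sum(fr[c] * truth.locus_cn(c, variant.chrom, variant.pos)
              for c in truth.clone_ids)
    return p * num / (p * den + (1 - p) * 2)


def simulate_bulk_vaf(
    variant: VariantSpec,
    truth: CohortTruth,
    timepoint: str,
    depth: int = 100,
    purity: float | None = None,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, int, int]:
    """Return (expected raw VAF, sampled alt count, depth)."""
    vaf = expected_bulk_vaf(variant, truth, timepoint, purity)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(
        truth.config.seed if seed is None else seed
    )
    alt = int(rng.binomial(depth, vaf))
    return vaf, alt, depth


def simulate_phased_pairs(
    v1: VariantSpec,
    v2: VariantSpec,
    truth: CohortTruth,
    timepoint: str,
    n_pairs: int,
    epsilon: float | None = None,
    seed: int | np.random.Generator | None = None,
) -> PhasedEvidence:
    """Draw read pairs informative for both sites.

    Each pair samples a tumor cell (clone ~ fractions) and one chromosome copy
    at the locus; the copy carries each variant according to the clone's
    multiplicity and copy offset.  Each of the two allele reads is flipped
    with probability ε.
    """
    eps = truth.config.epsilon if epsilon is None else epsilon
    if not (0 <= eps < 0.5):
        raise ValueError(f"epsilon must be in [0, 0.5), got {eps}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(
        truth.config.seed if seed is None else seed
    )
    fr = truth.fractions[timepoint]
    clone_ids = list(truth.clone_ids)
    probs = np.array([fr[c] for c in clone_ids])
    counts = {"rr": 0, "ra": 0, "ar": 0, "aa": 0}
    clone_draws = rng.choice(len(clone_ids), size=n_pairs, p=probs)
    for ci in clone_draws:
        cid = clone_ids[ci]
        cn = truth.locus_cn(cid, v1.chrom, v1.pos)
        if cn <= 0:
            counts["rr"] += 1  # no tumor copy: pair reports reference
            continue
        copy = rng.integers(0, cn)
        a1 = _copy_carries(v1, cid, copy)
        a2 = _copy_carries(v2, cid, copy)
        if eps > 0:
            if rng.random() < eps:
                a1 = not a1
            if rng.random() < eps:
                a2 = not a2
        key = ("a" if a1 else "r") + ("a" if a2 else "r")
        counts[key] += 1
    return PhasedEvidence(
        id1=v1.variant_id, id2=v2.variant_id,
        n_rr=counts["rr"], n_ra=counts["ra"],
        n_ar=counts["ar"], n_aa=counts["aa"],
        epsilon=eps,
    )


def _copy_carries(v: VariantSpec, clone_id: str, copy: int) -> bool:
    m = v.carriers.get(clone_id, 0)
    return v.copy_offset <= copy < v.copy_offset + m


# ---------------------------------------------------------------------------
# Preset scenarios
# ---------------------------------------------------------------------------

def preset_scenario(name: str) -> CohortConfig:
    """Fully resolved configs mirroring published clonal architectures.

    ``"MM1-like"``   pre-existing monoallelic focal deletion (2.1%) acquiring
                     a second focal hit at relapse (11.1% of cells unaltered).
    ``"MM2-like"``   monosomy 16 in 92.4% with a nested biallelic subclone at
                     0.8% sweeping to 99.5% post-therapy.
    ``"MM31-like"``  chr12p monoallelic background with four mutually
                     exclusive inactivating subclones (45/28/12/15%).
    ``"MM32-like"``  two exclusive inactivating subclones (35%/7%) leaving a
                     58% fraction without a biallelic event.
    ``"null-diploid"`` a single diploid clone with no events.
    """
    builders = {
        "MM1-like": _mm1_like,
        "MM2-like": _mm2_like,
        "MM31-like": _mm31_like,
        "MM32-like": _mm32_like,
        "null-diploid": _null_diploid,
    }
    try:
        return builders[name]()
    except KeyError:
        raise KeyError(
            f"unknown scenario {name!r}; choose from {sorted(builders)}"
        ) from None


_CHR1_GAIN = CNEventSpec(GenomicInterval("1", 1, 200_000), delta=+1)


def _mm1_like() -> CohortConfig:
    clones = (
        CloneSpec("founder", "normal", ( _CHR1_GAIN,),
                  {"pre": 0.979, "post": 0.111}),
        CloneSpec("mono_del", "founder",
                  (CNEventSpec(_TNFRSF17_FOCAL, delta=-1, allele="A"),),
                  {"pre": 0.021, "post": 0.021}),
        CloneSpec("biallelic", "mono_del",
                  (CNEventSpec(_TNFRSF17_FOCAL, delta=-1, allele="B"),),
                  {"pre": 0.0, "post": 0.868}),
    )
    return CohortConfig(
        chrom_lengths=PRESET_CHROM_LENGTHS, clones=clones,
        purity=0.9, n_cells={"pre": 2000, "post": 2000},
        bin_width=PRESET_BIN_WIDTH,
    )


def _mm2_like() -> CohortConfig:
    monosomy16 = CNEventSpec(GenomicInterval("16", 1, PRESET_CHROM_LENGTHS["16"]),
                             delta=-1, allele="A")
    clones = (
        CloneSpec("other", "normal", (_CHR1_GAIN,),
                  {"pre": 0.068, "post": 0.0}),
        CloneSpec("monosomy16", "normal", (monosomy16,),
                  {"pre": 0.924, "post": 0.005}),
        CloneSpec("biallelic", "monosomy16",
                  (CNEventSpec(_TNFRSF17_FOCAL, delta=-1, allele="B"),),
                  {"pre": 0.008, "post": 0.995}),
    )
    return CohortConfig(
        chrom_lengths=PRESET_CHROM_LENGTHS, clones=clones,
        purity=0.9, n_cells={"pre": 2000, "post": 2000},
        bin_width=PRESET_BIN_WIDTH,
    )


_CHR12P = GenomicInterval("12", 1, 600_000)   # stands in for the 12p arm loss


def _mm31_like() -> CohortConfig:
    del12p = CNEventSpec(_CHR12P, delta=-1, allele="A")
    clones = (
        CloneSpec("del12p", "normal", (del12p,), {"pre": 1.0, "post": 0.0}),
        CloneSpec("nonsense", "del12p", (), {"pre": 0.0, "post": 0.45}),
        CloneSpec("missense", "del12p", (), {"pre": 0.0, "post": 0.28}),
        CloneSpec("bi_del", "del12p",
                  (CNEventSpec(_GPRC5D_FOCAL, delta=-1, allele="B"),),
                  {"pre": 0.0, "post": 0.12}),
        CloneSpec("translocation", "del12p",
                  (CNEventSpec(GPRC5D_LOCUS.interval, delta=-1, allele="B"),),
                  {"pre": 0.0, "post": 0.15}),
    )
    variants = (
        VariantSpec("p.Arg233Ter", "12", 500_100, "C", "T", {"nonsense": 1},
                    consequence="nonsense"),
        VariantSpec("p.Tyr257Ser", "12", 500_200, "A", "C", {"missense": 1},
                    consequence="missense"),
    )
    return CohortConfig(
        chrom_lengths=PRESET_CHROM_LENGTHS, clones=clones,
        purity=0.83, n_cells={"pre": 2000, "post": 2000},
        bin_width=PRESET_BIN_WIDTH, variants=variants,
    )


def _mm32_like() -> CohortConfig:
    del12p = CNEventSpec(_CHR12P, delta=-1, allele="A")
    clones = (
        CloneSpec("del12p", "normal", (del12p,), {"pre": 1.0, "post": 0.58}),
        CloneSpec("nonsense", "del12p", (), {"pre": 0.0, "post": 0.35}),
        CloneSpec("bi_del", "del12p",
                  (CNEventSpec(_GPRC5D_FOCAL, delta=-1, allele="B"),),
                  {"pre": 0.0, "post": 0.07}),
    )
    variants = (
        VariantSpec("p.Glu146Ter", "12", 500_100, "G", "T", {"nonsense": 1},
                    consequence="nonsense"),
    )
    return CohortConfig(
        chrom_lengths=PRESET_CHROM_LENGTHS, clones=clones,
        purity=0.9, n_cells={"pre": 2000, "post": 2000},
        bin_width=PRESET_BIN_WIDTH, variants=variants,
    )


def _null_diploid() -> CohortConfig:
    clones = (CloneSpec("diploid", "normal", (), {"pre": 1.0, "post": 1.0}),)
    return CohortConfig(
        chrom_lengths=PRESET_CHROM_LENGTHS, clones=clones,
        purity=1.0, n_cells={"pre": 500, "post": 500},
        bin_width=PRESET_BIN_WIDTH,
    )


def noise_free(config: CohortConfig) -> CohortConfig:
    """A copy of ``config`` with exact (noise-free) CN observation."""
    return replace(config, reads_per_bin=NOISE_FREE, bias_sigma=0.0)
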