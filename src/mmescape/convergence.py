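"""Mutual exclusivity and convergent-evolution calls.

Two subclonal events can be shown to live in different cells either directly
— read pairs covering both variant sites never carry both alternate alleles
beyond what sequencing error explains — or indirectly, by the pigeonhole
principle: if the events' cancer cell fractions sum to no more than the
background clone's CCF, they can (and under selection typically do) occupy
disjoint cell populations.

Convergent evolution is declared when at least two independent events, each
completing biallelic inactivation of the same gene on top of a shared
monoallelic background, are mutually exclusive.  The unexplained fraction is
the part of the background clone not accounted for by any inactivating event.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

from scipy import stats

#: Event kinds that on their own complete biallelic inactivation on a
#: monoallelic background (CN events carry cell fractions as their CCF).
INACTIVATING_KINDS = frozenset({
    "nonsense", "missense", "inframe_del", "frameshift",
    "focal_biallelic_deletion", "translocation_disruption",
})

MIN_INFORMATIVE_PAIRS = 10   # ra + ar + aa needed for a phase call
MIN_ONE_SIDED_SUPPORT = 3    # ra and ar each needed to call "exclusive"
CO_OCCURRENCE_ALPHA = 0.01   # one-sided Poisson test on the alt/alt count
PIGEONHOLE_TOL = 0.05        # slack on sum(CCF) <= background


@dataclass(frozen=True)
class PhasedEvidence:
    """Read-pair counts informative for two variant sites.

    ``n_rr``..``n_aa`` count pairs by (site1 allele, site2 allele) with
    r = reference, a = alternate.  ``epsilon`` is the assumed per-read error
    rate used to model error-driven alt/alt pairs.
    """

    id1: str
    id2: str
    n_rr: int
    n_ra: int
    n_ar: int
    n_aa: int
    epsilon: float = 1e-3

    def __post_init__(self) -> None:
        if min(self.n_rr, self.n_ra, self.n_ar, self.n_aa) < 0:
            raise ValueError("pair counts must be >= 0")

    @property
    def n_informative(self) -> int:
        return self.n_ra + self.n_ar + self.n_aa

    def swapped(self) -> "PhasedEvidence":
        return PhasedEvidence(self.id2, self.id1, self.n_rr,
                              self.n_ar, self.n_ra, self.n_aa, self.epsilon)


def phase_call(
    evidence: PhasedEvidence,
    min_informative: int = MIN_INFORMATIVE_PAIRS,
    alpha: float = CO_OCCURRENCE_ALPHA,
) -> str:
    """Classify a variant pair as ``exclusive``/``co-occurring``/``indeterminate``.

    The expected error-driven alt/alt count is
    ``lambda0 = eps * (n_ra + n_ar) + eps**2 * n_rr`` (one mis-read on a
    single-alt pair, or two on a double-reference pair).  A one-sided Poisson
    excess of n_aa over lambda0 calls the pair co-occurring; n_aa within the
    99th percentile of Poisson(lambda0) with at least
    :data:`MIN_ONE_SIDED_SUPPORT` pairs supporting each variant alone calls it
    exclusive; anything else is indeterminate.
    """
    ev = evidence
    if ev.n_informative < min_informative:
        return "indeterminate"
    lam0 = ev.epsilon * (ev.n_ra + ev.n_ar) + ev.epsilon ** 2 * ev.n_rr
    # P(X >= n_aa) for X ~ Poisson(lam0)
    p_excess = stats.poisson.sf(ev.n_aa - 1, lam0) if ev.n_aa > 0 else 1.0
    if p_excess < alpha:
        return "co-occurring"
    if (
        ev.n_aa <= stats.poisson.ppf(0.99, lam0)
        and ev.n_ra >= MIN_ONE_SIDED_SUPPORT
        and ev.n_ar >= MIN_ONE_SIDED_SUPPORT
    ):
        return "exclusive"
    return "indeterminate"


def pigeonhole_test(
    event_ccfs: Sequence[float],
    background_ccf: float,
    tol: float = PIGEONHOLE_TOL,
) -> bool:
    """True iff the event CCFs can occupy disjoint cells of the background.

    Compatible with mutual exclusivity iff ``sum(CCFs) <= background + tol``.
    """
    for c in event_ccfs:
        if not (0 <= c <= 1):
            raise ValueError(f"CCF {c} outside [0, 1]")
    return sum(event_ccfs) <= background_ccf + tol


@dataclass(frozen=True)
class InactivatingEvent:
    """One candidate inactivating event on a gene."""

    event_id: str
    gene: str
    kind: str
    ccf: float
    evidence: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in INACTIVATING_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if not (0 <= self.ccf <= 1):
            raise ValueError(f"CCF {self.ccf} outside [0, 1]")


@dataclass
class ConvergenceReport:
    gene: str
    background_ccf: float
    events: list[InactivatingEvent]
    pairwise_calls: dict[tuple[str, str], str]
    verdict: str                       # convergent | single-route | indeterminate
    unexplained_fraction_pct: float
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "gene": self.gene,
            "background_ccf": self.background_ccf,
            "events": [
                {"event_id": e.event_id, "kind": e.kind, "ccf": e.ccf}
                for e in self.events
            ],
            "pairwise_calls": {f"{a}|{b}": c for (a, b), c in self.pairwise_calls.items()},
            "verdict": self.verdict,
            "unexplained_fraction_pct": self.unexplained_fraction_pct,
            "notes": self.notes,
        }


def detect_convergence(
    gene: str,
    events: Sequence[InactivatingEvent],
    phase_calls: Mapping[tuple[str, str], str] | None = None,
    background_ccf: float = 1.0,
    tol: float = PIGEONHOLE_TOL,
) -> ConvergenceReport:
    """Decide whether independent events converge on biallelic inactivation.

    Verdict is ``convergent`` iff there are >= 2 events, every available
    pairwise phase call is ``exclusive``, and pairs without phasing (always
    the case for CN-defined events) pass the pigeonhole test jointly.  Any
    ``co-occurring`` call collapses the events onto one route
    (``single-route``); missing support otherwise yields ``indeterminate``.
    The unexplained fraction is ``max(0, background - sum(CCFs))`` as a
    percentage.
    """
    for e in events:
        if e.gene != gene:
            raise ValueError(f"event {e.event_id} is on {e.gene}, not {gene}")
    phase_calls = dict(phase_calls or {})

    calls: dict[tuple[str, str], str] = {}
    for a, b in combinations([e.event_id for e in events], 2):
        call = phase_calls.get((a, b)) or phase_calls.get((b, a))
        calls[(a, b)] = call if call is not None else "unphased"

    notes: list[str] = []
    unexplained = max(0.0, background_ccf - sum(e.ccf for e in events)) * 100.0

    if len(events) < 2:
        return ConvergenceReport(gene, background_ccf, list(events), calls,
                                 "single-route", unexplained, notes)
    if any(c == "co-occurring" for c in calls.values()):
        notes.append("at least one pair phased as co-occurring")
        return ConvergenceReport(gene, background_ccf, list(events), calls,
                                 "single-route", unexplained, notes)
    if any(c == "indeterminate" for c in calls.values()):
        notes.append("at least one pair has indeterminate phasing")
        return ConvergenceReport(gene, background_ccf, list(events), calls,
                                 "indeterminate", unexplained, notes)
    # remaining pairs are exclusive or unphased; unphased pairs fall back to
    # the joint pigeonhole argument over all events
    if any(c == "unphased" for c in calls.values()):
        if not pigeonhole_test([e.ccf for e in events], background_ccf, tol):
            notes.append("pigeonhole test failed for unphased events")
            return ConvergenceReport(gene, background_ccf, list(events), calls,
                                     "indeterminate", unexplained, notes)
        notes.append("unphased pairs supported by pigeonhole accounting")
    return ConvergenceReport(gene, background_ccf, list(events), calls,
                             "convergent", unexplained, notes)
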