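"""CDS-level consequence annotation for antigen-escape variants.

Operates purely in coding-sequence (c.) space: missense/nonsense SNVs,
in-frame deletions with HGVS 3'-most normalization in repeated-residue
contexts, frameshifts with re-translation to the new stop, and mapping of
affected residues onto protein domains (extracellular / transmembrane /
intracellular), since only extracellular-domain changes can abolish the
binding of surface-targeted therapeutics.

A synthetic BCMA-like coding sequence is bundled for tests and examples: it
reproduces the coding-level facts that matter for the worked cases — codon 27
is CGA (Arg), residues 29/30 are consecutive serines with identical codons
and residues 33/34 consecutive prolines with identical codons — without being
the real transcript sequence.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

from Bio.Seq import Seq
from Bio.SeqUtils import seq3

STOP = "*"
_VALID_BASES = set("ACGT")


@dataclass(frozen=True)
class CodingSequence:
    """A complete CDS: starts ATG, length divisible by 3, ends with a stop."""

    gene: str
    seq: str

    def __post_init__(self) -> None:
        s = self.seq.upper()
        object.__setattr__(self, "seq", s)
        if set(s) - _VALID_BASES:
            raise ValueError("CDS contains non-ACGT characters")
        if len(s) % 3 != 0:
            raise ValueError(f"CDS length {len(s)} not divisible by 3")
        if not s.startswith("ATG"):
            raise ValueError("CDS must start with ATG")
        if str(Seq(s[-3:]).translate()) != STOP:
            raise ValueError("CDS must end with a stop codon")

    @property
    def protein(self) -> str:
        """Translated protein, stop excluded."""
        return str(Seq(self.seq).translate())[:-1]

    @property
    def n_codons(self) -> int:
        return len(self.seq) // 3

    def codon(self, index: int) -> str:
        """1-based codon."""
        if not (1 <= index <= self.n_codons):
            raise ValueError(f"codon index {index} out of range")
        return self.seq[(index - 1) * 3: index * 3]


@dataclass(frozen=True)
class ProteinDomainMap:
    """Non-overlapping (start_aa, end_aa, label) intervals, 1-based inclusive."""

    domains: tuple[tuple[int, int, str], ...]

    def __post_init__(self) -> None:
        prev_end = 0
        for start, end, _ in sorted(self.domains):
            if start < 1 or end < start:
                raise ValueError(f"bad domain interval ({start}, {end})")
            if start <= prev_end:
                raise ValueError("domain intervals overlap")
            prev_end = end


def domain_of_residue(position: int, domain_map: ProteinDomainMap,
                      protein_length: int | None = None) -> str:
    """Label of the domain containing an amino-acid position (inclusive ends)."""
    if position < 1 or (protein_length is not None and position > protein_length):
        raise ValueError(f"residue position {position} out of range")
    for start, end, label in domain_map.domains:
        if start <= position <= end:
            return label
    return "unannotated"


@dataclass(frozen=True)
class Consequence:
    """A classified coding change with its HGVS c. and p. renderings."""

    consequence: str            # synonymous | missense | nonsense | inframe_del | frameshift
    hgvs_c: str
    hgvs_p: str
    codons: tuple[int, ...]     # affected codon indices (1-based)
    domain: str | None = None
    hgvs_p_absolute: str | None = None   # fsTer with absolute residue numbering
    no_stop: bool = False


def codon_of_cds_pos(pos: int, cds: CodingSequence | None = None) -> int:
    """1-based codon index of a 1-based CDS position."""
    if pos < 1 or (cds is not None and pos > len(cds.seq)):
        raise ValueError(f"CDS position {pos} out of range")
    return (pos - 1) // 3 + 1


def _aa(codon: str) -> str:
    return str(Seq(codon).translate())


def annotate_snv(
    cds: CodingSequence,
    pos: int,
    alt: str,
    domain_map: ProteinDomainMap | None = None,
) -> Consequence:
    """Classify a single-nucleotide substitution at CDS position ``pos``."""
    alt = alt.upper()
    if alt not in _VALID_BASES:
        raise ValueError(f"alt base must be one of ACGT, got {alt!r}")
    if not (1 <= pos <= len(cds.seq)):
        raise ValueError(f"CDS position {pos} out of range")
    ref = cds.seq[pos - 1]
    if alt == ref:
        raise ValueError(f"alt equals reference base {ref!r} at c.{pos}")
    idx = codon_of_cds_pos(pos, cds)
    old_codon = cds.codon(idx)
    offset = (pos - 1) % 3
    new_codon = old_codon[:offset] + alt + old_codon[offset + 1:]
    old_aa, new_aa = _aa(old_codon), _aa(new_codon)
    hgvs_c = f"c.{pos}{ref}>{alt}"
    if new_aa == old_aa:
        kind, hgvs_p = "synonymous", f"p.{seq3(old_aa)}{idx}="
    elif new_aa == STOP:
        kind, hgvs_p = "nonsense", f"p.{seq3(old_aa)}{idx}Ter"
    else:
        kind, hgvs_p = "missense", f"p.{seq3(old_aa)}{idx}{seq3(new_aa)}"
    domain = (domain_of_residue(idx, domain_map, cds.n_codons - 1)
              if domain_map is not None else None)
    return Consequence(kind, hgvs_c, hgvs_p, (idx,), domain)


def annotate_inframe_del(
    cds: CodingSequence,
    start: int,
    end: int,
    domain_map: ProteinDomainMap | None = None,
) -> Consequence:
    """Classify a deletion of CDS positions ``start``..``end`` (inclusive).

    For lengths divisible by 3, the deleted residues are found by comparing
    the old and new proteins; taking the longest common prefix places the
    report at the 3'-most equivalent position when the deletion sits in a
    repeated-residue run (the HGVS normalization rule).  Lengths not
    divisible by 3 are routed to :func:`annotate_frameshift`.
    """
    if not (1 <= start <= end <= len(cds.seq)):
        raise ValueError(f"deletion c.{start}_{end} out of range")
    if (end - start + 1) % 3 != 0:
        return annotate_frameshift(cds, start, end, domain_map)
    new_seq = cds.seq[:start - 1] + cds.seq[end:]
    old_p = cds.protein
    new_p = str(Seq(new_seq).translate())
    new_p = new_p.split(STOP)[0]
    k = len(old_p) - len(new_p)
    # longest common prefix, then common suffix of the remainder
    lcp = 0
    while lcp < len(new_p) and old_p[lcp] == new_p[lcp]:
        lcp += 1
    lcs = 0
    while (lcs < len(new_p) - lcp
           and old_p[len(old_p) - 1 - lcs] == new_p[len(new_p) - 1 - lcs]):
        lcs += 1
    removed = old_p[lcp: len(old_p) - lcs]
    inserted = new_p[lcp: len(new_p) - lcs]
    first, last = lcp + 1, lcp + len(removed)
    hgvs_c = f"c.{start}_{end}del" if start != end else f"c.{start}del"
    if len(removed) == 1:
        span = f"{seq3(removed)}{first}"
    else:
        span = f"{seq3(removed[0])}{first}_{seq3(removed[-1])}{last}"
    if inserted:
        hgvs_p = f"p.{span}delins{''.join(seq3(a) for a in inserted)}"
    else:
        hgvs_p = f"p.{span}del"
    codons = tuple(range(first, last + 1))
    domain = (domain_of_residue(first, domain_map, cds.n_codons - 1)
              if domain_map is not None else None)
    return Consequence("inframe_del", hgvs_c, hgvs_p, codons, domain)


def annotate_frameshift(
    cds: CodingSequence,
    start: int,
    end: int,
    domain_map: ProteinDomainMap | None = None,
) -> Consequence:
    """Classify a frame-shifting deletion of CDS positions ``start``..``end``.

    The shifted sequence is re-translated; the p. string reports the first
    changed residue and the stop's position counted in the new reading frame
    (standard HGVS ``fsTer<k>``, with the changed residue as position 1).
    ``hgvs_p_absolute`` additionally renders the stop at its absolute residue
    number.  If no stop is reached before the end of the shifted sequence,
    ``no_stop`` is flagged instead of raising.
    """
    if not (1 <= start <= end <= len(cds.seq)):
        raise ValueError(f"deletion c.{start}_{end} out of range")
    if (end - start + 1) % 3 == 0:
        return annotate_inframe_del(cds, start, end, domain_map)
    new_seq = cds.seq[:start - 1] + cds.seq[end:]
    old_p = cds.protein
    new_trans = str(Seq(new_seq[: len(new_seq) - len(new_seq) % 3]).translate())
    d = 0
    while d < len(new_trans) and d < len(old_p) and new_trans[d] == old_p[d]:
        d += 1
    hgvs_c = f"c.{start}_{end}del" if start != end else f"c.{start}del"
    domain = (domain_of_residue(min(d + 1, cds.n_codons - 1), domain_map,
                                cds.n_codons - 1)
              if domain_map is not None else None)
    if d >= len(new_trans):
        # shift consumed the tail without producing any changed residue
        return Consequence("frameshift", hgvs_c, f"p.Ter{len(old_p) + 1}fs",
                           (d + 1,), domain, no_stop=True)
    old_aa = old_p[d] if d < len(old_p) else STOP
    new_aa = new_trans[d]
    stop_off = new_trans.find(STOP, d)
    if new_aa == STOP:
        # immediate stop at the first changed position
        hgvs_p = f"p.{seq3(old_aa)}{d + 1}Ter"
        return Consequence("frameshift", hgvs_c, hgvs_p, (d + 1,), domain,
                           hgvs_p_absolute=hgvs_p)
    prefix = f"p.{seq3(old_aa)}{d + 1}{seq3(new_aa)}fs"
    if stop_off == -1:
        return Consequence("frameshift", hgvs_c, prefix, (d + 1,), domain,
                           no_stop=True)
    k = stop_off - d + 1            # stop position in the new frame
    absolute = stop_off + 1         # stop position in absolute residue numbers
    return Consequence("frameshift", hgvs_c, f"{prefix}Ter{k}", (d + 1,),
                       domain, hgvs_p_absolute=f"{prefix}Ter{absolute}")


_SNV_RE = re.compile(r"^c\.(\d+)([ACGT])>([ACGT])$")
_DEL_RE = re.compile(r"^c\.(\d+)(?:_(\d+))?del$")


def annotate_cds_change(
    cds: CodingSequence,
    hgvs_c: str,
    domain_map: ProteinDomainMap | None = None,
) -> Consequence:
    """Dispatch a c.-notation string (SNV or deletion) to the annotators."""
    text = hgvs_c.strip()
    m = _SNV_RE.match(text)
    if m:
        pos, ref, alt = int(m.group(1)), m.group(2), m.group(3)
        if cds.seq[pos - 1] != ref:
            raise ValueError(
                f"reference mismatch at c.{pos}: CDS has {cds.seq[pos - 1]}, "
                f"variant says {ref}"
            )
        return annotate_snv(cds, pos, alt, domain_map)
    m = _DEL_RE.match(text)
    if m:
        start = int(m.group(1))
        end = int(m.group(2)) if m.group(2) else start
        return annotate_inframe_del(cds, start, end, domain_map)
    raise ValueError(f"unsupported HGVS c. string {hgvs_c!r}")


# ---------------------------------------------------------------------------
# Synthetic BCMA-like fixture
# ---------------------------------------------------------------------------

def bcma_synthetic_cds() -> CodingSequence:
    """A synthetic, BCMA-consistent coding sequence (not the real transcript).

    100 codons plus a stop.  Fixed coding-level facts: codon 27 = CGA (Arg),
    codons 29/30 = AGC/AGC (the Ser29-Ser30 repeat), codon 32 = ACT (Thr) and
    codons 33/34 = CCA/CCA (the Pro33-Pro34 repeat).  Filler codons are GCT
    (Ala); c.80 is the G of codon 27, so c.80G>C yields p.Arg27Pro.
    """
    codons = ["GCT"] * 100
    codons[0] = "ATG"
    codons[26] = "CGA"   # Arg27
    codons[27] = "TGT"   # Cys28
    codons[28] = "AGC"   # Ser29
    codons[29] = "AGC"   # Ser30
    codons[30] = "AAT"   # Asn31
    codons[31] = "ACT"   # Thr32
    codons[32] = "CCA"   # Pro33
    codons[33] = "CCA"   # Pro34
    codons.append("TAA")
    return CodingSequence("TNFRSF17", "".join(codons))


def bcma_synthetic_domains() -> ProteinDomainMap:
    """Domain layout for the synthetic BCMA-like protein (100 residues)."""
    return ProteinDomainMap((
        (1, 54, "extracellular"),
        (55, 77, "transmembrane"),
        (78, 100, "intracellular"),
    ))
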