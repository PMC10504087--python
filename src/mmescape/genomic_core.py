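"""Coordinate conventions, interval arithmetic, the bin lattice and file I/O.

All in-memory coordinates are 1-based inclusive (``length = end - start + 1``),
the convention under which the focal-deletion sizes printed in clinical
genomics reports (e.g. a 180-kb deletion spanning chr16:11,920,001-12,100,000)
come out exactly.  BED files, which are 0-based half-open, are converted at the
I/O boundary and nowhere else.

Chromosome labels are compared after stripping an optional ``chr`` prefix, so
``chr16`` and ``16`` refer to the same chromosome throughout.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class CoordinateError(ValueError):
    """Invalid genomic coordinates (start < 1, end < start, ...)."""


class FormatError(ValueError):
    """A file does not conform to its declared dialect."""


class LocusNotCoveredError(LookupError):
    """A locus maps to no bin of the grid (or its chromosome is absent)."""


def norm_chrom(label: str) -> str:
    """Normalize a chromosome label by stripping an optional ``chr`` prefix."""
    label = str(label).strip()
    if label.lower().startswith("chr"):
        label = label[3:]
    if not label:
        raise CoordinateError("empty chromosome label")
    return label


@dataclass(frozen=True)
class GenomicInterval:
    """A 1-based, inclusive genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", norm_chrom(self.chrom))
        if self.start < 1:
            raise CoordinateError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise CoordinateError(
                f"end ({self.end}) must be >= start ({self.start})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def kb(self) -> int:
        """Length rendered in kb, rounded half away from zero."""
        return int(np.floor(self.length / 1000 + 0.5))

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )

    def __str__(self) -> str:
        return f"chr{self.chrom}:{self.start:,}-{self.end:,}"


def interval_length(iv: GenomicInterval) -> int:
    """Length in bp of a 1-based inclusive interval."""
    return iv.length


_NUM_TOKEN = re.compile(r"[\d,.\s]*\d[\d,.\s]*")


def parse_coordinate_string(text: str) -> GenomicInterval:
    """Parse a free-form locus string like ``"chr16: 11,920,001–12,100,000"``.

    Numeric tokens are read by stripping every non-digit character, which makes
    the parse insensitive to comma grouping — including the malformed grouping
    that appears in some published coordinate strings (``"130,150,01"`` is read
    as 13015001).  The smaller number becomes the start.
    """
    m = re.search(r"(chr\w+|\b\w+\b)\s*[:]", text, flags=re.IGNORECASE)
    if m is None:
        raise FormatError(f"no chromosome token in {text!r}")
    chrom = m.group(1)
    rest = text[m.end():]
    tokens = [re.sub(r"\D", "", t) for t in _NUM_TOKEN.findall(rest)]
    tokens = [t for t in tokens if t]
    if len(tokens) < 2:
        raise FormatError(f"need two numeric tokens in {text!r}")
    a, b = int(tokens[0]), int(tokens[1])
    if a == 0 or b == 0:
        raise FormatError(f"zero coordinate in {text!r}")
    return GenomicInterval(chrom, min(a, b), max(a, b))


@dataclass(frozen=True)
class LocusDef:
    """A named gene locus."""

    gene: str
    interval: GenomicInterval

    def __post_init__(self) -> None:
        if not self.gene:
            raise ValueError("gene symbol must be non-empty")


@dataclass(frozen=True)
class VariantRecord:
    """A somatic variant with read support.

    ``alt_count``/``depth`` give the raw VAF; ``cds_change`` optionally carries
    a coding-level (c.) annotation and ``sample`` a sample/timepoint label.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    alt_count: int
    depth: int
    cds_change: str | None = None
    sample: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", norm_chrom(self.chrom))
        if self.pos < 1:
            raise CoordinateError(f"pos must be >= 1, got {self.pos}")
        if not (0 <= self.alt_count <= self.depth):
            raise ValueError(
                f"need 0 <= alt_count <= depth, got {self.alt_count}/{self.depth}"
            )

    @property
    def vaf(self) -> float:
        return self.alt_count / self.depth if self.depth else 0.0


class BinGrid:
    """An ordered, non-overlapping lattice of uniform-width bins.

    Bins are uniform (default 20 kb) except possibly the last bin of each
    chromosome.  ``bin_id`` is the 0-based index into the sorted bin list.
    """

    def __init__(self, intervals: Sequence[GenomicInterval]):
        ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start))
        prev: GenomicInterval | None = None
        for iv in ivs:
            if prev is not None and prev.chrom == iv.chrom and iv.start <= prev.end:
                raise CoordinateError(f"bins overlap: {prev} and {iv}")
            prev = iv
        if not ivs:
            raise CoordinateError("a BinGrid needs at least one bin")
        self.bins: tuple[GenomicInterval, ...] = tuple(ivs)
        self._by_chrom: dict[str, list[int]] = {}
        for i, iv in enumerate(self.bins):
            self._by_chrom.setdefault(iv.chrom, []).append(i)

    @classmethod
    def uniform(cls, chrom_lengths: dict[str, int], bin_width: int = 20_000) -> "BinGrid":
        if bin_width < 1:
            raise ValueError(f"bin_width must be >= 1, got {bin_width}")
        ivs = []
        for chrom, length in chrom_lengths.items():
            for start in range(1, length + 1, bin_width):
                ivs.append(GenomicInterval(chrom, start, min(start + bin_width - 1, length)))
        return cls(ivs)

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    @property
    def chroms(self) -> list[str]:
        return list(self._by_chrom)

    def chrom_bin_ids(self, chrom: str) -> list[int]:
        return list(self._by_chrom[norm_chrom(chrom)])

    def __len__(self) -> int:
        return len(self.bins)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, BinGrid) and self.bins == other.bins

    def __hash__(self) -> int:
        return hash(self.bins)


def bins_overlapping(locus: LocusDef, grid: BinGrid) -> list[int]:
    """Ids of the bins whose intervals intersect the locus interval."""
    chrom = locus.interval.chrom
    if chrom not in grid._by_chrom:
        raise LocusNotCoveredError(f"chromosome {chrom!r} absent from grid")
    hits = [
        i for i in grid._by_chrom[chrom]
        if grid.bins[i].overlaps(locus.interval)
    ]
    if not hits:
        raise LocusNotCoveredError(f"locus {locus.gene} not covered by any bin")
    return hits


# ---------------------------------------------------------------------------
# The per-cell copy-number matrix (the pipeline's central observable)
# ---------------------------------------------------------------------------

CN_MAX_RAW = 6     # raw integer CN ceiling in matrices
CN_CAP = 4         # reporting cap: CN > 4 is reported as 4, marked ">=4"


class CellCNMatrix:
    """Integer per-cell, per-bin copy number on a shared :class:`BinGrid`.

    Raw values live in [0, 6].  ``capped`` applies the reporting rule under
    which more than four copies are reduced to four; ``capped_flags`` marks the
    entries the rule changed (the ">=4" marker).
    """

    def __init__(self, cell_ids: Sequence[str], grid: BinGrid, cn: np.ndarray):
        cn = np.asarray(cn)
        if cn.ndim != 2 or cn.shape != (len(cell_ids), grid.n_bins):
            raise FormatError(
                f"CN matrix shape {cn.shape} does not match "
                f"{len(cell_ids)} cells x {grid.n_bins} bins"
            )
        if not np.issubdtype(cn.dtype, np.integer):
            if not np.all(np.equal(np.mod(cn, 1), 0)):
                raise FormatError("non-integer CN values in matrix")
            cn = cn.astype(np.int64)
        if cn.size and (cn.min() < 0 or cn.max() > CN_MAX_RAW):
            raise FormatError(f"raw CN values must lie in [0, {CN_MAX_RAW}]")
        if len(set(cell_ids)) != len(cell_ids):
            dup = next(c for c in cell_ids if list(cell_ids).count(c) > 1)
            raise FormatError(f"duplicate cell id {dup!r}")
        self.cell_ids: tuple[str, ...] = tuple(str(c) for c in cell_ids)
        self.grid = grid
        self.cn: np.ndarray = cn.astype(np.int64)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def capped(self) -> np.ndarray:
        return np.minimum(self.cn, CN_CAP)

    @property
    def capped_flags(self) -> np.ndarray:
        return self.cn > CN_CAP

    def row(self, cell_id: str) -> np.ndarray:
        return self.cn[self.cell_ids.index(cell_id)]

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, CellCNMatrix)
            and self.cell_ids == other.cell_ids
            and self.grid == other.grid
            and np.array_equal(self.cn, other.cn)
        )


# ---------------------------------------------------------------------------
# Readers and writers
# ---------------------------------------------------------------------------

def _bed_to_interval(chrom: str, start0: int, end0: int) -> GenomicInterval:
    # BED is 0-based half-open; internal coordinates are 1-based inclusive.
    return GenomicInterval(chrom, int(start0) + 1, int(end0))


def read_bed(path: str | Path) -> list[LocusDef]:
    """Read a BED file into named loci (name defaults to ``region_<i>``)."""
    out: list[LocusDef] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 BED columns")
            try:
                iv = _bed_to_interval(parts[0], int(parts[1]), int(parts[2]))
            except (ValueError, CoordinateError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            name = parts[3] if len(parts) > 3 else f"region_{len(out)}"
            out.append(LocusDef(name, iv))
    if not out:
        raise FormatError(f"{path}: no BED records")
    return out


def read_bin_bed(path: str | Path) -> BinGrid:
    """Read a BED file of bin definitions into a :class:`BinGrid`."""
    return BinGrid([ld.interval for ld in read_bed(path)])


def write_bed(loci: Iterable[LocusDef], path: str | Path) -> None:
    with open(path, "w") as fh:
        for ld in loci:
            iv = ld.interval
            fh.write(f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{ld.gene}\n")


def _bin_label(iv: GenomicInterval) -> str:
    return f"{iv.chrom}:{iv.start}-{iv.end}"


_BIN_LABEL = re.compile(r"^(?P<chrom>[^:]+):(?P<start>\d+)-(?P<end>\d+)$")


def write_cn_matrix(matrix: CellCNMatrix, path: str | Path) -> None:
    """Write a CN matrix as TSV: rows = cells, header = bin labels."""
    with open(path, "w") as fh:
        fh.write("cell_id\t" + "\t".join(_bin_label(b) for b in matrix.grid.bins) + "\n")
        for cid, row in zip(matrix.cell_ids, matrix.cn):
            fh.write(cid + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


def read_cn_matrix(path: str | Path) -> CellCNMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise FormatError(f"{path}: empty file")
        cols = header.split("\t")
        if cols[0] != "cell_id" or len(cols) < 2:
            raise FormatError(f"{path}:1: header must start with 'cell_id'")
        bins = []
        for c in cols[1:]:
            m = _BIN_LABEL.match(c)
            if m is None:
                raise FormatError(f"{path}:1: bad bin label {c!r}")
            bins.append(GenomicInterval(m["chrom"], int(m["start"]), int(m["end"])))
        grid = BinGrid(bins)
        cell_ids, rows = [], []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(cols):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(cols)} fields, got {len(parts)}"
                )
            try:
                rows.append([int(v) for v in parts[1:]])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer CN value") from exc
            cell_ids.append(parts[0])
    if not cell_ids:
        raise FormatError(f"{path}: no cell rows")
    try:
        return CellCNMatrix(cell_ids, grid, np.array(rows, dtype=np.int64))
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def read_variants(path: str | Path, dialect: str = "tsv") -> list[VariantRecord]:
    """Read somatic variants from a minimal VCF or a TSV dialect.

    The TSV dialect has columns chrom, pos, ref, alt, alt_count, depth and
    optionally cds_change and sample.  For VCF, AD/DP are taken from the first
    sample column when present, else from INFO.
    """
    if dialect == "tsv":
        return _read_variants_tsv(path)
    if dialect == "vcf":
        return _read_variants_vcf(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_variants_tsv(path: str | Path) -> list[VariantRecord]:
    try:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    required = {"chrom", "pos", "ref", "alt", "alt_count", "depth"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for _, r in df.iterrows():
        out.append(VariantRecord(
            chrom=str(r["chrom"]), pos=int(r["pos"]), ref=str(r["ref"]),
            alt=str(r["alt"]), alt_count=int(r["alt_count"]), depth=int(r["depth"]),
            cds_change=(str(r["cds_change"]) if "cds_change" in df.columns
                        and pd.notna(r.get("cds_change")) else None),
            sample=(str(r["sample"]) if "sample" in df.columns
                    and pd.notna(r.get("sample")) else None),
        ))
    return out


def _read_variants_vcf(path: str | Path) -> list[VariantRecord]:
    import pysam

    try:
        vf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise FormatError(f"{path}: not a readable VCF ({exc})") from exc
    out = []
    with vf:
        for rec in vf:
            if rec.alts is None:
                continue
            alt = rec.alts[0]
            alt_count, depth = 0, 0
            if rec.samples:
                smp = rec.samples[0]
                ad = smp.get("AD")
                dp = smp.get("DP")
                if ad is not None and ad[0] is not None and len(ad) > 1:
                    alt_count = int(ad[1])
                    depth = int(dp) if dp is not None else int(sum(a or 0 for a in ad))
                elif dp is not None:
                    depth = int(dp)
            else:
                dp = rec.info.get("DP")
                if dp is not None:
                    depth = int(dp)
            depth = max(depth, alt_count)
            out.append(VariantRecord(
                chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=alt,
                alt_count=alt_count, depth=depth,
            ))
    if not out:
        raise FormatError(f"{path}: no variant records")
    return out


def write_variants_tsv(records: Iterable[VariantRecord], path: str | Path) -> None:
    rows = [{
        "chrom": r.chrom, "pos": r.pos, "ref": r.ref, "alt": r.alt,
        "alt_count": r.alt_count, "depth": r.depth,
        "cds_change": r.cds_change, "sample": r.sample,
    } for r in records]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_report(records: Sequence[dict], path: str | Path, fmt: str = "tsv") -> None:
    """Write a list of flat records as TSV or JSON."""
    if fmt == "tsv":
        pd.DataFrame(list(records)).to_csv(path, sep="\t", index=False)
    elif fmt == "json":
        with open(path, "w") as fh:
            json.dump(list(records), fh, indent=2, default=_json_default)
            fh.write("\n")
    else:
        raise ValueError(f"unknown report format {fmt!r}")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, GenomicInterval):
        return str(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
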