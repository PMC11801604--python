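"""I/O and in-memory genome model for SATAY insertion data.

Containers
----------
``InsertionMap``
    Per-chromosome sorted unique insertion sites with read counts — the
    primary experimental input, one record per transposon-genome junction.
``GeneAnnotation``
    A gene interval (1-based, inclusive) with strand and essentiality flag.
``CentromereMap``
    Plain ``dict`` mapping chromosome name to the (start, end) centromere
    interval, 1-based inclusive.

All coordinates are 1-based and inclusive throughout the package, matching
the native conventions of GFF3 and wig; no half-open conversion is ever
exposed. Insertion positions are strand-agnostic; gene strand only orients
relative position along the coding sequence.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

CentromereMap = dict[str, tuple[int, int]]

#: column order of the per-gene fitness table
FITNESS_COLUMNS = [
    "gene_id",
    "chrom",
    "n_observed",
    "expected_insertions",
    "n_zero_imputed",
    "n_used",
    "mean_reads",
    "fitness_median_scale",
    "fitness_generation_scale",
    "variance",
    "standard_error",
    "status",
]


class FormatError(ValueError):
    """Malformed input file; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene interval; ``start <= end``, both inclusive, 1-based."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    essential: bool = False

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class InsertionMap:
    """Sorted unique insertion sites with read counts, per chromosome.

    ``sites`` maps chromosome name to a pair of equal-length arrays
    ``(positions, reads)`` with positions strictly increasing and every
    read count a positive integer. Zero-read sites never appear here;
    they exist only as imputed records inside gene profiles.
    """

    sites: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    sample_name: str = ""

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple[str, int, int]],
        sample_name: str = "",
    ) -> "InsertionMap":
        """Build a map from (chrom, position, reads) triples; sorts and validates."""
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, pos, reads in records:
            by_chrom.setdefault(str(chrom), []).append((int(pos), int(reads)))
        sites: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, rows in by_chrom.items():
            rows.sort()
            pos = np.array([r[0] for r in rows], dtype=np.int64)
            reads = np.array([r[1] for r in rows], dtype=np.int64)
            _validate_chrom(chrom, pos, reads)
            sites[chrom] = (pos, reads)
        return cls(sites=sites, sample_name=sample_name)

    def records(self) -> Iterator[tuple[str, int, int]]:
        for chrom in sorted(self.sites):
            pos, reads = self.sites[chrom]
            for p, r in zip(pos.tolist(), reads.tolist()):
                yield chrom, p, r

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self.sites)

    def positions(self, chrom: str) -> np.ndarray:
        return self.sites[chrom][0]

    def reads(self, chrom: str) -> np.ndarray:
        return self.sites[chrom][1]

    @property
    def total_reads(self) -> int:
        return int(sum(int(r.sum()) for _, r in self.sites.values()))

    @property
    def total_insertions(self) -> int:
        return int(sum(len(p) for p, _ in self.sites.values()))

    def sites_in(self, chrom: str, start: int, end: int) -> tuple[np.ndarray, np.ndarray]:
        """Positions and reads with ``start <= position <= end`` (inclusive)."""
        if chrom not in self.sites:
            empty = np.array([], dtype=np.int64)
            return empty, empty
        pos, reads = self.sites[chrom]
        lo = np.searchsorted(pos, start, side="left")
        hi = np.searchsorted(pos, end, side="right")
        return pos[lo:hi], reads[lo:hi]

    def rename_chromosomes(self, rename: Mapping[str, str]) -> "InsertionMap":
        """Return a copy with chromosome names mapped through ``rename``."""
        new: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, (pos, reads) in self.sites.items():
            name = rename.get(chrom, chrom)
            if name in new:
                raise ValueError(f"rename collapses two chromosomes onto {name!r}")
            new[name] = (pos.copy(), reads.copy())
        return replace(self, sites=new)


def _validate_chrom(chrom: str, pos: np.ndarray, reads: np.ndarray) -> None:
    if len(pos) > 1 and np.any(np.diff(pos) == 0):
        dup = int(pos[np.nonzero(np.diff(pos) == 0)[0][0]])
        raise ValueError(f"duplicate insertion position {chrom}:{dup}")
    if len(reads) and reads.min() < 1:
        bad = int(pos[int(np.argmin(reads))])
        raise ValueError(f"non-positive read count at {chrom}:{bad}")


# ---------------------------------------------------------------------------
# insertion map readers / writers


def read_insertion_map(
    path: str | Path,
    dialect: str = "wig",
    rename: Mapping[str, str] | None = None,
    sample_name: str | None = None,
) -> InsertionMap:
    """Read per-site insertion read counts.

    ``dialect='wig'`` expects variableStep blocks
    (``variableStep chrom=<name>`` followed by ``<position> <count>`` lines);
    ``dialect='bedlike'`` expects a TSV with a ``chrom  position  reads``
    header. Duplicate positions within a chromosome are an error, never
    merged. ``rename`` maps input chromosome names onto the annotation's
    naming dialect (e.g. ``{"I": "chrI"}``).
    """
    path = Path(path)
    name = sample_name if sample_name is not None else path.stem
    with open(path) as fh:
        if dialect == "wig":
            records = list(_parse_wig(fh))
        elif dialect == "bedlike":
            records = list(_parse_bedlike(fh))
        else:
            raise ValueError(f"unknown dialect {dialect!r}")
    imap = InsertionMap.from_records(records, sample_name=name)
    if rename:
        imap = imap.rename_chromosomes(rename)
    return imap


def _parse_wig(fh: io.TextIOBase) -> Iterator[tuple[str, int, int]]:
    chrom: str | None = None
    for lineno, raw in enumerate(fh, start=1):
        line = raw.strip()
        if not line or line.startswith(("track", "#")):
            continue
        if line.startswith("variableStep"):
            chrom = None
            for token in line.split()[1:]:
                key, _, value = token.partition("=")
                if key == "chrom":
                    chrom = value
            if chrom is None:
                raise FormatError("variableStep without chrom=", lineno)
            continue
        if chrom is None:
            raise FormatError("data line before any variableStep header", lineno)
        parts = line.split()
        if len(parts) != 2:
            raise FormatError(f"expected '<position> <count>', got {line!r}", lineno)
        try:
            pos, reads = int(parts[0]), int(parts[1])
        except ValueError as exc:
            raise FormatError(f"non-integer field in {line!r}", lineno) from exc
        if reads < 1:
            raise FormatError(f"read count must be >= 1, got {reads}", lineno)
        if pos < 1:
            raise FormatError(f"position must be >= 1, got {pos}", lineno)
        yield chrom, pos, reads


def _parse_bedlike(fh: io.TextIOBase) -> Iterator[tuple[str, int, int]]:
    header = fh.readline().rstrip("\n")
    cols = header.split("\t")
    if cols[:3] != ["chrom", "position", "reads"]:
        raise FormatError(
            f"expected header 'chrom\\tposition\\treads', got {header!r}", 1
        )
    for lineno, raw in enumerate(fh, start=2):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise FormatError(f"expected 3 tab-separated fields, got {line!r}", lineno)
        try:
            pos, reads = int(parts[1]), int(parts[2])
        except ValueError as exc:
            raise FormatError(f"non-integer field in {line!r}", lineno) from exc
        if reads < 1:
            raise FormatError(f"read count must be >= 1, got {reads}", lineno)
        yield parts[0], pos, reads


def write_insertion_map(imap: InsertionMap, path: str | Path, dialect: str = "wig") -> None:
    """Write an insertion map; read->write->read is the identity."""
    path = Path(path)
    with open(path, "w") as fh:
        if dialect == "wig":
            for chrom in imap.chromosomes:
                fh.write(f"variableStep chrom={chrom}\n")
                pos, reads = imap.sites[chrom]
                for p, r in zip(pos.tolist(), reads.tolist()):
                    fh.write(f"{p} {r}\n")
        elif dialect == "bedlike":
            fh.write("chrom\tposition\treads\n")
            for chrom, p, r in imap.records():
                fh.write(f"{chrom}\t{p}\t{r}\n")
        else:
            raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# gene annotation


def read_gff3(path: str | Path, rename: Mapping[str, str] | None = None) -> list[GeneAnnotation]:
    """Read records of type ``gene`` from a GFF3 file.

    Coordinates are kept 1-based inclusive as in GFF3; the gene identifier is
    the ``ID`` attribute. Duplicate IDs or a gene without an ID are errors.
    """
    genes: list[GeneAnnotation] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if line.startswith("##FASTA"):
                break
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise FormatError(f"expected 9 GFF3 columns, got {len(parts)}", lineno)
            chrom, _source, ftype, start, end, _score, strand, _phase, attrs = parts
            if ftype != "gene":
                continue
            attributes = dict(
                kv.partition("=")[::2] for kv in attrs.split(";") if kv
            )
            gene_id = attributes.get("ID")
            if not gene_id:
                raise FormatError("gene record without ID attribute", lineno)
            if gene_id in seen:
                raise FormatError(f"duplicate gene ID {gene_id!r}", lineno)
            seen.add(gene_id)
            if rename:
                chrom = rename.get(chrom, chrom)
            genes.append(
                GeneAnnotation(
                    gene_id=gene_id,
                    chrom=chrom,
                    start=int(start),
                    end=int(end),
                    strand=strand if strand in ("+", "-") else "+",
                )
            )
    return genes


def write_gff3(genes: Iterable[GeneAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
            attrs = f"ID={g.gene_id}"
            if g.essential:
                attrs += ";essential=true"
            fh.write(
                f"{g.chrom}\tsatay_fitness\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )


def apply_essential(
    genes: Iterable[GeneAnnotation], essential_ids: set[str]
) -> list[GeneAnnotation]:
    """Return genes with the essential flag set for IDs in ``essential_ids``."""
    return [replace(g, essential=g.gene_id in essential_ids) for g in genes]


def read_essential_genes(path: str | Path) -> set[str]:
    """One gene ID per line; blank lines and '#' comments ignored."""
    out: set[str] = set()
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if line and not line.startswith("#"):
                out.add(line)
    return out


def write_essential_genes(ids: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gid in sorted(ids):
            fh.write(f"{gid}\n")


# ---------------------------------------------------------------------------
# centromeres


def read_centromeres(
    path: str | Path, rename: Mapping[str, str] | None = None
) -> CentromereMap:
    """TSV with header ``chrom  start  end``; one interval per chromosome."""
    cen: CentromereMap = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["chrom", "start", "end"]:
            raise FormatError("expected header 'chrom\\tstart\\tend'", 1)
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"expected 3 fields, got {line!r}", lineno)
            chrom = parts[0]
            if rename:
                chrom = rename.get(chrom, chrom)
            if chrom in cen:
                raise FormatError(f"duplicate centromere for {chrom!r}", lineno)
            start, end = int(parts[1]), int(parts[2])
            if start > end:
                raise FormatError(f"centromere start {start} > end {end}", lineno)
            cen[chrom] = (start, end)
    return cen


def write_centromeres(cen: CentromereMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\n")
        for chrom in sorted(cen):
            start, end = cen[chrom]
            fh.write(f"{chrom}\t{start}\t{end}\n")


# ---------------------------------------------------------------------------
# fitness tables


def write_fitness_table(
    records: Iterable,
    path: str | Path,
    header_comments: Iterable[str] = (),
) -> None:
    """Write per-gene fitness records as TSV, gene_id ascending.

    Undetermined genes keep their count columns but leave the numeric
    estimate fields empty. ``header_comments`` (e.g. the fitted alpha and
    the effective config) are written as leading ``#`` lines.
    """
    numeric_when_ok = [
        "mean_reads",
        "fitness_median_scale",
        "fitness_generation_scale",
        "variance",
        "standard_error",
    ]
    with open(path, "w") as fh:
        for line in header_comments:
            fh.write(line.rstrip("\n") + "\n")
        fh.write("\t".join(FITNESS_COLUMNS) + "\n")
        for rec in sorted(records, key=lambda r: r.gene_id):
            row = []
            for col in FITNESS_COLUMNS:
                value = getattr(rec, col)
                if col in numeric_when_ok and (
                    rec.status != "ok" or value is None or not np.isfinite(value)
                ):
                    row.append("")
                elif isinstance(value, float):
                    row.append(repr(float(value)))
                else:
                    row.append(str(value))
            fh.write("\t".join(row) + "\n")


def read_fitness_table(path: str | Path) -> pd.DataFrame:
    """Read a fitness TSV back into a DataFrame (comments skipped)."""
    return pd.read_csv(path, sep="\t", comment="#")
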