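"""Readers and writers for the plain-text genomic formats the pipeline consumes.

All coordinates are 0-based half-open throughout the package, exactly as in
BED.  Nothing here (or anywhere downstream) emits 1-based values.

Formats handled:

* BED (3+ columns) for DHS peaks, alignment blocks and marker peaks;
* BEDPE (6+ columns) for pre-mapped Hi-C contact pairs;
* a 5-column gene table TSV, or a GTF restricted to ``gene`` features;
* the tab-separated prediction table written by :func:`write_predictions`.

GO (OBO + annotation TSV) and the expression matrix are read by
:mod:`drelink.cluster_analysis`, which owns their in-memory containers.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence
import warnings


class ParseError(ValueError):
    """A malformed line in an input file; the message names the line number."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A genomic interval: chromosome + 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must be > start, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"unknown strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def gap_to(self, other: "GenomicInterval") -> int:
        """Minimum bp separation between two same-chromosome intervals (0 if
        they overlap)."""
        if self.chrom != other.chrom:
            raise ValueError("gap_to requires intervals on one chromosome")
        return max(0, max(self.start, other.start) - min(self.end, other.end))

    def distance_to_point(self, pos: int) -> int:
        """Minimum |bp| from any base of the interval to a point position."""
        if pos < self.start:
            return self.start - pos
        if pos >= self.end:
            return pos - (self.end - 1)
        return 0

    def contains_point(self, pos: int) -> bool:
        return self.start <= pos < self.end

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True, order=True)
class BedInterval(GenomicInterval):
    """A BED record: interval plus the optional name and score columns."""

    name: str | None = None
    score: float | None = None


@dataclass(frozen=True)
class GeneModel:
    """A protein-coding gene: body interval plus the strand-aware TSS.

    ``body`` spans transcription start to gene end; on the + strand the TSS is
    ``body.start`` and on the - strand it is ``body.end - 1``.
    """

    gene_id: str
    body: GenomicInterval

    def __post_init__(self) -> None:
        if self.body.strand not in ("+", "-"):
            raise ValueError(
                f"gene {self.gene_id}: strand must be + or -, "
                f"got {self.body.strand!r}"
            )

    @property
    def tss(self) -> int:
        return self.body.start if self.body.strand == "+" else self.body.end - 1

    @property
    def chrom(self) -> str:
        return self.body.chrom


@dataclass(frozen=True)
class HiCContact:
    """One Hi-C contact: two mapped end points tagged with the dataset
    (cell line x replicate) the read came from."""

    chrom1: str
    pos1: int
    chrom2: str
    pos2: int
    dataset_id: str

    def __post_init__(self) -> None:
        if self.pos1 < 0 or self.pos2 < 0:
            raise ValueError("contact end positions must be >= 0")


def _split_line(line: str) -> list[str]:
    return line.rstrip("\n").rstrip("\r").split("\t")


def load_intervals(path: str | os.PathLike) -> list[BedInterval]:
    """Load a BED file (3+ tab-separated columns) preserving input order.

    Columns beyond the third populate ``name`` and ``score``.  Malformed lines
    raise :class:`ParseError` naming the offending line number; an interval
    with end <= start raises ``ValueError``.
    """
    out: list[BedInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = _split_line(line)
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: expected >=3 tab-separated columns, "
                    f"got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score: float | None = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                score = float(fields[4])
            strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "."
            try:
                out.append(
                    BedInterval(fields[0], start, end, strand, name=name, score=score)
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return out


def _genes_from_rows(
    rows: Iterable[tuple[str, str, int, int, str]], source: str
) -> list[GeneModel]:
    genes: list[GeneModel] = []
    seen: set[str] = set()
    for gene_id, chrom, start, end, strand in rows:
        if gene_id in seen:
            raise ValueError(f"{source}: duplicate gene_id {gene_id!r}")
        seen.add(gene_id)
        if strand not in ("+", "-"):
            raise ValueError(
                f"{source}: gene {gene_id}: unknown strand symbol {strand!r}"
            )
        genes.append(GeneModel(gene_id, GenomicInterval(chrom, start, end, strand)))
    return genes


def load_genes(path: str | os.PathLike, format: str = "tsv") -> list[GeneModel]:
    """Load gene models from a 5-column TSV or a GTF.

    TSV columns: gene_id, chrom, start, end, strand with 0-based half-open
    coordinates.  GTF: one record per ``gene`` feature (1-based inclusive,
    converted here).  Duplicate gene ids are rejected.
    """
    fmt = format.lower()
    if fmt == "tsv":
        rows = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip() or line.startswith("#"):
                    continue
                f = _split_line(line)
                if f[0] == "gene_id":  # header
                    continue
                if len(f) < 5:
                    raise ParseError(f"{path}:{lineno}: expected 5 columns")
                rows.append((f[0], f[1], int(f[2]), int(f[3]), f[4]))
        return _genes_from_rows(rows, str(path))
    if fmt == "gtf":
        rows = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip() or line.startswith("#"):
                    continue
                f = _split_line(line)
                if len(f) < 9:
                    raise ParseError(f"{path}:{lineno}: expected 9 GTF columns")
                if f[2] != "gene":
                    continue
                attrs = _parse_gtf_attributes(f[8])
                if "gene_id" not in attrs:
                    raise ParseError(f"{path}:{lineno}: gene feature without gene_id")
                # GTF is 1-based inclusive
                rows.append((attrs["gene_id"], f[0], int(f[3]) - 1, int(f[4]), f[6]))
        return _genes_from_rows(rows, str(path))
    raise ValueError(f"unknown gene table format {format!r}")


def _parse_gtf_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in text.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def load_alignment_blocks(
    directory: str | os.PathLike, species_list: Sequence[str]
) -> dict[str, list[BedInterval]]:
    """Load one human-coordinate block BED per species.

    The mapping preserves ``species_list`` order (this order defines the
    profile axis pipeline-wide).  A listed species without a ``<name>.bed``
    file is an error; an unlisted file in the directory triggers a warning and
    is skipped.  Overlapping blocks within a species (multiple homologs) are
    retained as-is: downstream treats coverage as binary.
    """
    directory = Path(directory)
    listed = {f"{sp}.bed" for sp in species_list}
    for entry in sorted(p.name for p in directory.glob("*.bed")):
        if entry not in listed:
            warnings.warn(
                f"alignment file {entry} does not match any listed species; skipped",
                stacklevel=2,
            )
    blocks: dict[str, list[BedInterval]] = {}
    for sp in species_list:
        path = directory / f"{sp}.bed"
        if not path.exists():
            raise FileNotFoundError(
                f"listed species {sp!r} has no alignment file {path}"
            )
        blocks[sp] = load_intervals(path)
    return blocks


def load_hic_contacts(path: str | os.PathLike, dataset_id: str) -> list[HiCContact]:
    """Load a BEDPE file as contacts, one per record, tagged with dataset_id.

    Each end's mapped position is the floor midpoint of its interval.
    Zero-length end intervals are rejected.
    """
    contacts: list[HiCContact] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = _split_line(line)
            if len(f) < 6:
                raise ParseError(
                    f"{path}:{lineno}: BEDPE needs >=6 columns, got {len(f)}"
                )
            s1, e1, s2, e2 = int(f[1]), int(f[2]), int(f[4]), int(f[5])
            if e1 <= s1 or e2 <= s2:
                raise ParseError(f"{path}:{lineno}: zero/negative-length end interval")
            contacts.append(
                HiCContact(f[0], (s1 + e1) // 2, f[3], (s2 + e2) // 2, dataset_id)
            )
    return contacts


def write_intervals(intervals: Iterable[BedInterval], path: str | os.PathLike) -> None:
    """Write BED records; inverse of :func:`load_intervals` for round-trips."""
    with open(path, "w") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None or iv.strand != ".":
                fields.append(iv.name if iv.name is not None else ".")
            if iv.score is not None or iv.strand != ".":
                fields.append(f"{iv.score:g}" if iv.score is not None else ".")
            if iv.strand != ".":
                fields.append(iv.strand)
            fh.write("\t".join(fields) + "\n")


PREDICTION_HEADER_FIXED = ["dre_id", "chrom", "start", "end", "gene_id", "pcc",
                           "evidence", "cell_lines"]


def write_predictions(predictions, path: str | os.PathLike) -> None:
    """Write the final prediction table as TSV.

    Deterministic ordering: by DRE locus (chrom, start, end), then gene_id.
    One count column per dataset; the per-dataset columns come from the union
    of dataset ids seen in the predictions, sorted.
    """
    preds = list(predictions)
    datasets = sorted({ds for p in preds for ds in p.counts})
    header = PREDICTION_HEADER_FIXED + [f"count_{ds}" for ds in datasets]
    preds.sort(key=lambda p: (p.dre.chrom, p.dre.start, p.dre.end, p.gene_id))
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for p in preds:
            row = [
                p.dre_id,
                p.dre.chrom,
                str(p.dre.start),
                str(p.dre.end),
                p.gene_id,
                f"{p.pcc:.6f}",
                p.evidence,
                ",".join(sorted(p.cell_lines)),
            ]
            row += [str(p.counts.get(ds, 0)) for ds in datasets]
            fh.write("\t".join(row) + "\n")


def load_predictions(path: str | os.PathLike):
    """Read back a prediction table written by :func:`write_predictions`."""
    from .prediction import Prediction  # local import to avoid a cycle

    preds = []
    with open(path) as fh:
        header = _split_line(next(fh))
        count_cols = [
            (i, h[len("count_"):]) for i, h in enumerate(header)
            if h.startswith("count_")
        ]
        for line in fh:
            if not line.strip():
                continue
            f = _split_line(line)
            rec = dict(zip(header, f))
            counts = {ds: int(f[i]) for i, ds in count_cols}
            preds.append(
                Prediction(
                    dre_id=rec["dre_id"],
                    dre=GenomicInterval(
                        rec["chrom"], int(rec["start"]), int(rec["end"])
                    ),
                    gene_id=rec["gene_id"],
                    pcc=float(rec["pcc"]),
                    evidence=rec["evidence"],
                    cell_lines=frozenset(rec["cell_lines"].split(",")),
                    counts=counts,
                )
            )
    return preds
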