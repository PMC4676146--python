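"""Streaming VCF input/output.

Multi-sample VCF 4.x files are read line by line as tab-separated text, the
way a variant-clustering pipeline consumes them: only the GT subfield of each
sample column is retained, everything else (QUAL, FILTER, INFO, other FORMAT
fields) is discarded at parse time. Peak memory is bounded by a single
record, so whole-genome files stream through without being materialised.

The writer exists for the synthetic cohort generator and round-trips exactly
through :func:`read_vcf`.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence

__all__ = [
    "VariantRecord",
    "VcfHeader",
    "VcfFormatError",
    "read_vcf",
    "read_vcf_many",
    "write_vcf",
]

N_FIXED_COLUMNS = 9


class VcfFormatError(ValueError):
    """Raised when a file violates the VCF layout this pipeline relies on."""


@dataclass(frozen=True)
class VariantRecord:
    """One VCF site: locus, alleles and the raw per-sample GT strings.

    ``gt_strings`` holds only the GT subfield (text before the first ``:``)
    of each sample column, in header order. Positions are 1-based as in VCF;
    no coordinate arithmetic happens anywhere downstream.
    """

    chrom: str
    pos: int
    var_id: str
    ref: str
    alts: tuple[str, ...]
    gt_strings: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise VcfFormatError(f"position must be >= 1, got {self.pos}")
        if not self.ref:
            raise VcfFormatError("reference allele must be non-empty")
        if not self.alts:
            raise VcfFormatError("at least one alternate allele is required")


@dataclass(frozen=True)
class VcfHeader:
    """Sample names declared on the ``#CHROM`` line."""

    sample_ids: tuple[str, ...]
    n_fixed_columns: int = field(default=N_FIXED_COLUMNS)

    def __post_init__(self) -> None:
        if self.n_fixed_columns != N_FIXED_COLUMNS:
            raise VcfFormatError(
                f"VCF has {N_FIXED_COLUMNS} fixed columns, got {self.n_fixed_columns}"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise VcfFormatError("sample IDs in header are not unique")
        if any(not s for s in self.sample_ids):
            raise VcfFormatError("empty sample ID in header")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


def _open_text(source: str | Path | IO, gzipped: bool | None) -> IO[str]:
    if hasattr(source, "read"):
        stream = source
        if gzipped:
            stream = gzip.open(stream, "rt")  # type: ignore[arg-type]
        elif isinstance(stream.read(0), bytes):  # type: ignore[union-attr]
            stream = io.TextIOWrapper(stream)  # type: ignore[arg-type]
        return stream  # type: ignore[return-value]
    path = Path(source)
    if gzipped is None:
        gzipped = path.suffix == ".gz"
    if gzipped:
        return gzip.open(path, "rt")
    return open(path, "rt")


def _gt_index(format_field: str) -> int | None:
    """Position of GT within the FORMAT column, or None for 'no FORMAT'."""
    if format_field in (".", ""):
        return None
    subfields = format_field.split(":")
    try:
        return subfields.index("GT")
    except ValueError:
        return None


def _parse_data_line(
    line: str, line_no: int, n_samples: int
) -> VariantRecord:
    fields = line.rstrip("\n").split("\t")
    if len(fields) != N_FIXED_COLUMNS + n_samples:
        raise VcfFormatError(
            f"line {line_no}: expected {N_FIXED_COLUMNS + n_samples} columns "
            f"({n_samples} samples), found {len(fields)}"
        )
    try:
        pos = int(fields[1])
    except ValueError as exc:
        raise VcfFormatError(f"line {line_no}: POS is not an integer: {fields[1]!r}") from exc
    gt_at = _gt_index(fields[8])
    samples = fields[N_FIXED_COLUMNS:]
    if gt_at is None or gt_at == 0:
        # GT first (the common case, and what the VCF spec mandates when GT
        # is present) or no FORMAT at all: the GT string is everything before
        # the first ':'.
        gts = tuple(s.split(":", 1)[0] for s in samples)
    else:
        gts = tuple(s.split(":")[gt_at] for s in samples)
    return VariantRecord(
        chrom=fields[0],
        pos=pos,
        var_id=fields[2],
        ref=fields[3],
        alts=tuple(fields[4].split(",")),
        gt_strings=gts,
    )


def read_vcf(
    source: str | Path | IO, gzipped: bool | None = None
) -> tuple[VcfHeader, Iterator[VariantRecord]]:
    """Stream a VCF file: return the header and a lazy record iterator.

    Parameters
    ----------
    source
        Path to a plain or gzip-compressed VCF, or an open stream.
    gzipped
        Force gzip decoding; by default inferred from a ``.gz`` suffix.

    Returns
    -------
    header, records
        ``header`` carries the ordered sample IDs; ``records`` yields one
        :class:`VariantRecord` per data line, in file order, holding only the
        GT subfields. The iterator buffers a single line at a time.

    Raises
    ------
    VcfFormatError
        If the ``#CHROM`` header line is missing, or any data line has the
        wrong number of columns (the error names the line number).
    """
    handle = _open_text(source, gzipped)
    header: VcfHeader | None = None
    line_no = 0
    for raw in handle:
        line_no += 1
        if raw.startswith("##"):
            continue
        if raw.startswith("#CHROM"):
            cols = raw.rstrip("\n").split("\t")
            if len(cols) < N_FIXED_COLUMNS:
                raise VcfFormatError(
                    f"line {line_no}: header line has fewer than "
                    f"{N_FIXED_COLUMNS} columns"
                )
            header = VcfHeader(sample_ids=tuple(cols[N_FIXED_COLUMNS:]))
            break
        raise VcfFormatError(
            f"line {line_no}: expected meta ('##') or '#CHROM' header line"
        )
    if header is None:
        raise VcfFormatError("no '#CHROM' header line found")

    def _records() -> Iterator[VariantRecord]:
        nonlocal line_no
        with handle:
            for raw in handle:
                line_no += 1
                if not raw.strip():
                    continue
                yield _parse_data_line(raw, line_no, header.n_samples)

    return header, _records()


def read_vcf_many(
    sources: Sequence[str | Path], gzipped: bool | None = None
) -> tuple[VcfHeader, Iterator[VariantRecord]]:
    """Concatenate several VCFs (e.g. per-chromosome files) in caller order.

    All files must declare the same samples in the same order.
    """
    if not sources:
        raise ValueError("at least one VCF source is required")
    first_header, first_records = read_vcf(sources[0], gzipped)

    def _chain() -> Iterator[VariantRecord]:
        yield from first_records
        for src in sources[1:]:
            header, records = read_vcf(src, gzipped)
            if header.sample_ids != first_header.sample_ids:
                raise VcfFormatError(
                    f"{src}: sample columns differ from {sources[0]}"
                )
            yield from records

    return first_header, _chain()


def write_vcf(
    header: VcfHeader,
    records: Iterable[VariantRecord],
    dest: str | Path,
    gzipped: bool | None = None,
) -> int:
    """Write records to ``dest`` as VCF 4.2 with a ``GT``-only FORMAT column.

    Returns the number of records written. The output re-parses through
    :func:`read_vcf` to an identical (header, records) sequence.
    """
    path = Path(dest)
    if gzipped is None:
        gzipped = path.suffix == ".gz"
    opener = gzip.open if gzipped else open
    count = 0
    with opener(path, "wt") as out:  # type: ignore[operator]
        out.write("##fileformat=VCFv4.2\n")
        out.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(header.sample_ids)
            + "\n"
        )
        for rec in records:
            if len(rec.gt_strings) != header.n_samples:
                raise VcfFormatError(
                    f"record at {rec.chrom}:{rec.pos} has "
                    f"{len(rec.gt_strings)} genotypes for {header.n_samples} samples"
                )
            out.write(
                "\t".join(
                    (
                        rec.chrom,
                        str(rec.pos),
                        rec.var_id,
                        rec.ref,
                        ",".join(rec.alts),
                        ".",
                        ".",
                        ".",
                        "GT",
                        *rec.gt_strings,
                    )
                )
                + "\n"
            )
            count += 1
    return count
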