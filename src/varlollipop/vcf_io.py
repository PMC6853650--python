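"""Reading, validation and normalization of multi-sample VCF files.

The parser is deliberately forgiving at the row level: a malformed data row
is collected as a :class:`ValidationIssue` (with its 1-based line number) and
parsing continues, so one bad row never aborts an exome-sized file.  The
file-level contract is strict: the first line must be ``##fileformat=VCFvX.Y``.

Multi-allelic rows are expanded into bi-allelic :class:`VariantRecord` atoms
(one per ALT allele) so that every downstream stage — annotation,
cross-referencing, plotting — sees exactly one reference/alternate base
change per record.  All parsing is local; no sample identifier ever leaves
the process.
"""

from __future__ import annotations

import gzip
import io
import logging
import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Sequence

logger = logging.getLogger(__name__)

_DNA = frozenset("ACGTN")
_FILEFORMAT_RE = re.compile(r"^##fileformat=(VCFv4\.\d+)\s*$")
_CONTIG_RE = re.compile(r"^##contig=<(.*)>\s*$")

#: genotype allele value used for "not called" (``.`` in GT strings)
MISSING = None


class VcfError(Exception):
    """Fatal, file-level VCF problem (bad header, unreadable stream)."""


@dataclass(frozen=True)
class Genotype:
    """One sample's call at one site.

    ``allele_indices`` holds ints (0 = REF, 1.. = ALT index) or ``None`` for
    a missing allele; ``phased`` records the ``|`` separator.
    """

    sample_id: str
    allele_indices: tuple[int | None, ...]
    phased: bool = False

    @property
    def is_missing(self) -> bool:
        return all(a is None for a in self.allele_indices)

    def alt_allele_count(self) -> int:
        """Number of called non-reference alleles."""
        return sum(1 for a in self.allele_indices if a is not None and a != 0)


@dataclass
class VcfHeader:
    fileformat_version: str
    sample_names: list[str]
    raw_meta_lines: list[str] = field(default_factory=list)
    assembly_label: str | None = None
    contig_declarations: list[tuple[str, int | None]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.sample_names)) != len(self.sample_names):
            raise VcfError("duplicate sample names in #CHROM header line")


@dataclass
class VariantRecord:
    """One normalized, bi-allelic variant row — the pipeline's atom."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    genotypes: tuple[Genotype, ...]
    qual: float | None = None
    filter_status: str = "."
    id_field: str = "."
    info: str = "."
    source_line: int = 0

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref_allele, self.alt_allele)

    @property
    def is_snv(self) -> bool:
        return len(self.ref_allele) == 1 and len(self.alt_allele) == 1

    def carrier_genotypes(self) -> list[Genotype]:
        return [g for g in self.genotypes if g.alt_allele_count() > 0]


@dataclass(frozen=True)
class ValidationIssue:
    severity: str  # "error" | "warning"
    line: int
    message: str


def _open_text(stream: str | bytes | IO) -> IO[str]:
    """Accept a path, raw bytes, or an open handle; transparently gunzip."""
    if isinstance(stream, (str,)):
        with open(stream, "rb") as fh:
            head = fh.read(2)
        if head == b"\x1f\x8b":
            return io.TextIOWrapper(gzip.open(stream, "rb"), encoding="utf-8")
        return open(stream, "rt", encoding="utf-8")
    if isinstance(stream, bytes):
        if stream[:2] == b"\x1f\x8b":
            stream = gzip.decompress(stream)
        return io.StringIO(stream.decode("utf-8"))
    if isinstance(stream, io.TextIOBase):
        return stream
    # binary handle
    peek = stream.read(2)
    stream.seek(0)
    if peek == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.GzipFile(fileobj=stream), encoding="utf-8")
    return io.TextIOWrapper(stream, encoding="utf-8")


def _parse_gt(gt: str, sample_id: str) -> Genotype:
    phased = "|" in gt
    alleles = tuple(
        None if a in (".", "") else int(a) for a in re.split(r"[/|]", gt)
    )
    return Genotype(sample_id=sample_id, allele_indices=alleles, phased=phased)


def parse_vcf(
    stream: str | bytes | IO,
    issues: list[ValidationIssue] | None = None,
) -> tuple[VcfHeader, Iterator[VariantRecord]]:
    """Parse a VCF 4.x text (plain or gzipped) into a header and records.

    Returns the fully-parsed header and a lazy iterator of bi-allelic
    :class:`VariantRecord` (multi-allelic rows are expanded, symbolic ALTs
    dropped with a warning).  Per-row problems are appended to *issues* when
    a list is supplied, otherwise logged; parsing continues either way.
    """
    fh = _open_text(stream)
    first = fh.readline()
    m = _FILEFORMAT_RE.match(first.rstrip("\n"))
    if not m:
        raise VcfError(
            "not a VCF: first line must be '##fileformat=VCFv4.x', got %r"
            % first[:60]
        )
    version = m.group(1)
    meta_lines = [first.rstrip("\n")]
    contigs: list[tuple[str, int | None]] = []
    sample_names: list[str] = []
    lineno = 1
    for line in fh:
        lineno += 1
        line = line.rstrip("\n")
        if line.startswith("##"):
            meta_lines.append(line)
            cm = _CONTIG_RE.match(line)
            if cm:
                attrs = dict(
                    kv.split("=", 1) for kv in cm.group(1).split(",") if "=" in kv
                )
                length = int(attrs["length"]) if "length" in attrs else None
                if "ID" in attrs:
                    contigs.append((attrs["ID"], length))
            continue
        if line.startswith("#CHROM"):
            cols = line.split("\t")
            if len(cols) > 9:
                sample_names = cols[9:]
            break
        raise VcfError(f"line {lineno}: expected meta or #CHROM line, got {line[:40]!r}")
    else:
        raise VcfError("truncated VCF: no #CHROM header line")

    header = VcfHeader(
        fileformat_version=version,
        sample_names=sample_names,
        raw_meta_lines=meta_lines,
        contig_declarations=contigs,
    )
    header.assembly_label = detect_assembly(header)

    def _records() -> Iterator[VariantRecord]:
        nonlocal lineno
        n_fixed = 9 if sample_names else 8
        for line in fh:
            lineno += 1
            row = line.rstrip("\n")
            if not row:
                continue
            cols = row.split("\t")
            expected = n_fixed + len(sample_names)
            if len(cols) != expected and not (
                not sample_names and len(cols) == 8
            ):
                _report(
                    issues,
                    ValidationIssue(
                        "error",
                        lineno,
                        f"column count {len(cols)} != expected {expected}; row skipped",
                    ),
                )
                continue
            try:
                yield from _parse_row(cols, sample_names, lineno, issues)
            except (ValueError, IndexError) as exc:
                _report(
                    issues,
                    ValidationIssue("error", lineno, f"unparseable row: {exc}; skipped"),
                )

    return header, _records()


def _report(issues: list[ValidationIssue] | None, issue: ValidationIssue) -> None:
    if issues is not None:
        issues.append(issue)
    else:
        logger.warning("line %d: %s", issue.line, issue.message)


def _parse_row(
    cols: Sequence[str],
    sample_names: list[str],
    lineno: int,
    issues: list[ValidationIssue] | None,
) -> Iterator[VariantRecord]:
    chrom, pos_s, vid, ref, alt_s = cols[0], cols[1], cols[2], cols[3], cols[4]
    qual = None if cols[5] == "." else float(cols[5])
    filt = cols[6]
    info = cols[7]
    pos = int(pos_s)
    if pos < 1:
        raise ValueError(f"POS {pos} < 1")
    genotypes: list[Genotype] = []
    if sample_names:
        fmt_keys = cols[8].split(":")
        try:
            gt_i = fmt_keys.index("GT")
        except ValueError:
            raise ValueError("FORMAT lacks GT")
        for name, cell in zip(sample_names, cols[9:]):
            fields = cell.split(":")
            gt = fields[gt_i] if gt_i < len(fields) else "."
            genotypes.append(_parse_gt(gt, name))
    yield from split_multiallelic(
        chrom=chrom,
        pos=pos,
        ref=ref.upper(),
        alts=[a.upper() for a in alt_s.split(",")],
        genotypes=genotypes,
        qual=qual,
        filter_status=filt,
        id_field=vid,
        info=info,
        source_line=lineno,
        issues=issues,
    )


def split_multiallelic(
    chrom: str,
    pos: int,
    ref: str,
    alts: Sequence[str],
    genotypes: Sequence[Genotype],
    qual: float | None = None,
    filter_status: str = ".",
    id_field: str = ".",
    info: str = ".",
    source_line: int = 0,
    issues: list[ValidationIssue] | None = None,
) -> list[VariantRecord]:
    """Expand one raw (possibly multi-allelic) row into bi-allelic records.

    For the record keeping ALT *k*, genotype allele indices are remapped so
    that allele *k* becomes 1 and every other ALT becomes a missing allele.
    The summed non-reference allele count across the outputs therefore equals
    the input's, and symbolic ALTs (``<DEL>``, ``*`` …) are dropped with a
    warning rather than mis-annotated.
    """
    out: list[VariantRecord] = []
    for k, alt in enumerate(alts, start=1):
        if alt.startswith("<") or alt in ("*", "."):
            _report(
                issues,
                ValidationIssue(
                    "warning",
                    source_line,
                    f"symbolic/star ALT {alt!r} at {chrom}:{pos} dropped",
                ),
            )
            continue
        remapped = tuple(
            Genotype(
                sample_id=g.sample_id,
                allele_indices=tuple(
                    None if a is None else (0 if a == 0 else (1 if a == k else None))
                    for a in g.allele_indices
                ),
                phased=g.phased,
            )
            for g in genotypes
        )
        out.append(
            VariantRecord(
                chrom=chrom,
                pos=pos,
                ref_allele=ref,
                alt_allele=alt,
                genotypes=remapped,
                qual=qual,
                filter_status=filter_status,
                id_field=id_field,
                info=info,
                source_line=source_line,
            )
        )
    return out


_ASSEMBLY_TOKENS = [
    ("grch38", "GRCh38"),
    ("hg38", "GRCh38"),
    ("grch37", "GRCh37"),
    ("hg19", "GRCh37"),
]


def detect_assembly(header: VcfHeader) -> str:
    """Identify the genome assembly from the header meta lines.

    Precedence: ``##reference`` lines, then ``##assembly``, then contig
    attributes; first match wins.  ``hg19``/``hg38`` aliases map to the
    GRC labels.  Returns ``"unknown"`` when no line identifies one.
    """
    groups = (
        [l for l in header.raw_meta_lines if l.lower().startswith("##reference")],
        [l for l in header.raw_meta_lines if l.lower().startswith("##assembly")],
        [l for l in header.raw_meta_lines if l.lower().startswith("##contig")],
    )
    for lines in groups:
        for line in lines:
            low = line.lower()
            for token, label in _ASSEMBLY_TOKENS:
                if token in low:
                    return label
    return "unknown"


def validate(
    header: VcfHeader,
    records: Iterable[VariantRecord],
    contig_names: set[str] | None = None,
) -> list[ValidationIssue]:
    """Check accepted records against the gene-model contigs and VCF rules.

    An empty return value means the file is accepted.  Position order is a
    warning only (VCFs are commonly sorted but need not be).
    """
    issues: list[ValidationIssue] = []
    last_pos: dict[str, int] = {}
    n_samples = len(header.sample_names)
    for rec in records:
        if contig_names is not None and rec.chrom not in contig_names:
            issues.append(
                ValidationIssue(
                    "error", rec.source_line, f"unknown contig {rec.chrom!r}"
                )
            )
        for allele, label in ((rec.ref_allele, "REF"), (rec.alt_allele, "ALT")):
            if not allele or not set(allele) <= _DNA:
                issues.append(
                    ValidationIssue(
                        "error", rec.source_line, f"non-DNA allele in {label}: {allele!r}"
                    )
                )
        if rec.ref_allele == rec.alt_allele:
            issues.append(
                ValidationIssue("error", rec.source_line, "REF equals ALT")
            )
        if len(rec.genotypes) != n_samples:
            issues.append(
                ValidationIssue(
                    "error",
                    rec.source_line,
                    f"{len(rec.genotypes)} genotypes for {n_samples} samples",
                )
            )
        if rec.chrom in last_pos and rec.pos < last_pos[rec.chrom]:
            issues.append(
                ValidationIssue(
                    "warning",
                    rec.source_line,
                    f"position {rec.pos} not in increasing order on {rec.chrom}",
                )
            )
        last_pos[rec.chrom] = rec.pos
    return issues


def format_genotype(g: Genotype) -> str:
    sep = "|" if g.phased else "/"
    return sep.join("." if a is None else str(a) for a in g.allele_indices)


def write_vcf(header: VcfHeader, records: Iterable[VariantRecord]) -> str:
    """Serialize records back to VCF text (used for round-trip checks)."""
    lines = list(header.raw_meta_lines)
    cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
    if header.sample_names:
        cols += ["FORMAT"] + header.sample_names
    lines.append("\t".join(cols))
    for rec in records:
        row = [
            rec.chrom,
            str(rec.pos),
            rec.id_field,
            rec.ref_allele,
            rec.alt_allele,
            "." if rec.qual is None else f"{rec.qual:g}",
            rec.filter_status,
            rec.info,
        ]
        if header.sample_names:
            row.append("GT")
            row.extend(format_genotype(g) for g in rec.genotypes)
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"
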