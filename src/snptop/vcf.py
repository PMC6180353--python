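"""Reader/writer for the simplified 8-column VCF dialect.

The dialect stores one SNP per data line::

    #CHROM POS ID REF ALT QUAL FILTER TYPE
    1 13110 rs540538026 G A 100 PASS heterozygous

Meta-information lines start with ``##``, a single header line with ``#``.
REF and ALT are non-equal symbols from {A, C, G, T, N}; TYPE marks the
variant heterozygous or homozygous; records are sorted by (chromosome,
position).  QUAL and FILTER are carried for format fidelity only.

This module never reads generic VCF 4.x (INFO/FORMAT/sample columns,
indels, arbitrary contigs are out of scope).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import IO, Iterable, Iterator

from .errors import VcfFieldError, VcfFormatError, VcfOrderingError

__all__ = [
    "Zygosity",
    "SnpRecord",
    "parse_vcf",
    "write_vcf",
    "chrom_to_code",
    "code_to_chrom",
    "BASES",
    "HEADER",
]

BASES = frozenset("ACGTN")

HEADER = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tTYPE"

# Symbolic contigs map onto the 5-bit chromosome code space (1..25).
_SYMBOLIC = {"X": 23, "Y": 24, "MT": 25}
_SYMBOLIC_INV = {v: k for k, v in _SYMBOLIC.items()}

MAX_POS = 2**32 - 1


class Zygosity(enum.Enum):
    HETEROZYGOUS = "heterozygous"
    HOMOZYGOUS = "homozygous"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def chrom_to_code(symbol: str) -> int:
    """Map a chromosome column value to its 5-bit code.

    "1".."22" map to 1..22, "X"->23, "Y"->24, "MT"->25; numeric 23..25
    are accepted as aliases of the symbolic names.
    """
    if symbol in _SYMBOLIC:
        return _SYMBOLIC[symbol]
    try:
        code = int(symbol)
    except ValueError:
        raise VcfFieldError(f"unknown chromosome symbol {symbol!r}") from None
    if not 1 <= code <= 25:
        raise VcfFieldError(f"chromosome code {code} outside 1..25")
    return code


def code_to_chrom(code: int) -> str:
    """Inverse of :func:`chrom_to_code` (23..25 render symbolically)."""
    if code in _SYMBOLIC_INV:
        return _SYMBOLIC_INV[code]
    if not 1 <= code <= 22:
        raise VcfFieldError(f"chromosome code {code} outside 1..25")
    return str(code)


@dataclass(frozen=True, slots=True)
class SnpRecord:
    """One SNP data line.

    chrom is the 5-bit chromosome code (1-25), pos the 1-based position
    as printed in the file, id the SNP identifier string, ref/alt the
    non-equal bases, zygosity the TYPE column.
    """

    chrom: int
    pos: int
    id: str
    ref: str
    alt: str
    zygosity: Zygosity

    def locus(self) -> tuple[int, int]:
        return (self.chrom, self.pos)

    def validate(self) -> "SnpRecord":
        if not 1 <= self.chrom <= 25:
            raise VcfFieldError(f"chromosome code {self.chrom} outside 1..25")
        if not 0 <= self.pos <= MAX_POS:
            raise VcfFieldError(f"position {self.pos} does not fit in 32 bits")
        if self.ref not in BASES or self.alt not in BASES:
            raise VcfFieldError(f"bases must be in {{A,C,G,T,N}}, got {self.ref}/{self.alt}")
        if self.ref == self.alt:
            raise VcfFieldError(f"REF and ALT must differ, both are {self.ref}")
        return self


def _parse_data_line(fields: list[str], lineno: int) -> SnpRecord:
    chrom_s, pos_s, snp_id, ref, alt, _qual, _filter, type_s = fields
    try:
        chrom = chrom_to_code(chrom_s)
    except VcfFieldError as exc:
        raise VcfFieldError(str(exc), lineno) from None
    try:
        pos = int(pos_s)
    except ValueError:
        raise VcfFieldError(f"position {pos_s!r} is not an integer", lineno) from None
    if not 0 <= pos <= MAX_POS:
        raise VcfFieldError(f"position {pos} does not fit in 32 bits", lineno)
    if ref not in BASES or alt not in BASES:
        raise VcfFieldError(f"invalid base pair {ref!r}/{alt!r}", lineno)
    if ref == alt:
        raise VcfFieldError(f"REF equals ALT ({ref})", lineno)
    try:
        zyg = Zygosity(type_s)
    except ValueError:
        raise VcfFieldError(f"invalid TYPE token {type_s!r}", lineno) from None
    return SnpRecord(chrom, pos, snp_id, ref, alt, zyg)


def parse_vcf(stream: IO[str] | Iterable[str]) -> Iterator[SnpRecord]:
    """Parse a dialect VCF, yielding :class:`SnpRecord` in file order.

    Fields may be separated by any run of ASCII whitespace (the dialect
    is shown space-separated; real VCF uses tabs — both are accepted).
    Raises :class:`VcfFormatError` on a malformed line,
    :class:`VcfOrderingError` when (chrom, pos) decreases, and
    :class:`VcfFieldError` on an out-of-dialect field value.
    """
    seen_header = False
    last_locus: tuple[int, int] | None = None
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line.strip():
            continue
        if line.startswith("##"):
            if seen_header:
                raise VcfFormatError("meta line after header", lineno)
            continue
        if line.startswith("#"):
            if seen_header:
                raise VcfFormatError("duplicate header line", lineno)
            seen_header = True
            continue
        if not seen_header:
            raise VcfFormatError("data line before header", lineno)
        fields = line.split()
        if len(fields) != 8:
            raise VcfFormatError(
                f"expected 8 fields, found {len(fields)}", lineno
            )
        record = _parse_data_line(fields, lineno)
        locus = record.locus()
        if last_locus is not None and locus < last_locus:
            raise VcfOrderingError(
                f"line {lineno}: SNP at {locus} after {last_locus}; "
                "records must be sorted by (chromosome, position)"
            )
        last_locus = locus
        yield record


def write_vcf(
    records: Iterable[SnpRecord],
    sink: IO[str],
    meta: Iterable[str] = (),
) -> int:
    """Write records as a dialect VCF (tab separated, QUAL=100, FILTER=PASS).

    ``meta`` lines are emitted first (each prefixed with ``##`` if not
    already).  Input must be sorted by (chrom, pos); returns the number
    of data lines written.  ``parse_vcf`` inverts this exactly.
    """
    for m in meta:
        sink.write(m if m.startswith("##") else "##" + m)
        sink.write("\n")
    sink.write(HEADER + "\n")
    n = 0
    last_locus: tuple[int, int] | None = None
    for rec in records:
        rec.validate()
        locus = rec.locus()
        if last_locus is not None and locus < last_locus:
            raise VcfOrderingError(
                f"record at {locus} after {last_locus}; input must be sorted"
            )
        last_locus = locus
        sink.write(
            f"{code_to_chrom(rec.chrom)}\t{rec.pos}\t{rec.id}\t{rec.ref}\t"
            f"{rec.alt}\t100\tPASS\t{rec.zygosity.value}\n"
        )
        n += 1
    return n
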