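"""80-bit binary SNP codec.

A data line compresses to 10 bytes laid out as one 80-bit big-endian
integer, fields most-significant first:

    CHROM (5) | POS (32) | ID (37) | REF&ALT (5) | TYPE (1)

ID stores the numeric suffix of an rs identifier; the 20 ordered
non-equal base pairs share a 5-bit code; TYPE is 0 for heterozygous and
1 for homozygous.  Big-endian serialization makes unsigned byte-wise
comparison of packed records agree with (chrom, pos) order, which the
streaming engine relies on.

The dialect only ever contains rs-numbered identifiers, so any other ID
is rejected rather than encoded lossily.
"""

from __future__ import annotations

from .errors import CodecError, CorruptRecordError
from .vcf import SnpRecord, Zygosity

__all__ = [
    "encode_refalt",
    "decode_refalt",
    "pack_snp",
    "unpack_snp",
    "PACKED_SNP_BYTES",
    "REFALT_PAIRS",
]

PACKED_SNP_BYTES = 10

MAX_RSID = 2**37 - 1

# ASCII-sorted alphabet; the 20 ordered non-equal pairs enumerate
# ref-major: (A,C)=0, (A,G)=1, (A,N)=2, (A,T)=3, (C,A)=4, ... (T,N)=19.
_ALPHABET = "ACGNT"
REFALT_PAIRS: tuple[tuple[str, str], ...] = tuple(
    (r, a) for r in _ALPHABET for a in _ALPHABET if r != a
)
_PAIR_CODE = {pair: i for i, pair in enumerate(REFALT_PAIRS)}


def encode_refalt(ref: str, alt: str) -> int:
    """Map an ordered non-equal base pair to its 5-bit code in [0, 20)."""
    try:
        return _PAIR_CODE[(ref, alt)]
    except KeyError:
        if ref == alt:
            raise CodecError(f"REF and ALT must differ, both are {ref!r}") from None
        raise CodecError(f"invalid base pair {ref!r}/{alt!r}") from None


def decode_refalt(code: int) -> tuple[str, str]:
    """Inverse of :func:`encode_refalt`."""
    if not 0 <= code < len(REFALT_PAIRS):
        raise CorruptRecordError(f"REF&ALT code {code} outside [0, 20)")
    return REFALT_PAIRS[code]


def _rsid_number(snp_id: str) -> int:
    if len(snp_id) < 3 or not snp_id.startswith("rs") or not snp_id[2:].isdigit():
        raise CodecError(f"cannot encode non-rs identifier {snp_id!r}")
    num = int(snp_id[2:])
    if num > MAX_RSID:
        raise CodecError(f"rs number {num} does not fit in 37 bits")
    return num


def pack_snp(record: SnpRecord) -> bytes:
    """Pack one record into its 10-byte binary form."""
    if not 1 <= record.chrom <= 25:
        raise CodecError(f"chromosome code {record.chrom} outside 1..25")
    if not 0 <= record.pos < 2**32:
        raise CodecError(f"position {record.pos} does not fit in 32 bits")
    num = _rsid_number(record.id)
    code = encode_refalt(record.ref, record.alt)
    tbit = 1 if record.zygosity is Zygosity.HOMOZYGOUS else 0
    value = (
        (record.chrom << 75) | (record.pos << 43) | (num << 6) | (code << 1) | tbit
    )
    return value.to_bytes(PACKED_SNP_BYTES, "big")


def unpack_snp(packed: bytes) -> SnpRecord:
    """Field-wise inverse of :func:`pack_snp`.

    Raises :class:`CorruptRecordError` when the bytes decode to field
    values no valid record can produce (chromosome code 0 or >25,
    REF&ALT code >= 20).
    """
    if len(packed) != PACKED_SNP_BYTES:
        raise CodecError(f"packed SNP must be {PACKED_SNP_BYTES} bytes, got {len(packed)}")
    value = int.from_bytes(packed, "big")
    chrom = value >> 75
    pos = (value >> 43) & 0xFFFFFFFF
    num = (value >> 6) & 0x1FFFFFFFFF
    code = (value >> 1) & 0x1F
    tbit = value & 1
    if not 1 <= chrom <= 25:
        raise CorruptRecordError(f"chromosome code {chrom} outside 1..25")
    ref, alt = decode_refalt(code)
    zyg = Zygosity.HOMOZYGOUS if tbit else Zygosity.HETEROZYGOUS
    return SnpRecord(chrom, pos, f"rs{num}", ref, alt, zyg)
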