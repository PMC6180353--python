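"""Encrypted SNP block framing.

A compressed-and-encrypted VCF is a concatenation of blocks::

    SNP count n (4, little-endian) | IV (12) | MAC (16) | ciphertext (10*n)

so a block serializes to exactly 32 + 10*n bytes.  The ciphertext is the
AES-128-GCM encryption of n packed 10-byte SNPs; the count field is
bound as associated data, so truncating or altering it fails tag
verification just like flipping a ciphertext bit.  Every block of a
file holds the configured block size B (default 2080 SNPs, a common
multiple of the 10-byte SNP and 16-byte AES block sizes, roughly 20 KB)
except possibly the last.
"""

from __future__ import annotations

import io
import os
import struct
from dataclasses import dataclass
from typing import IO, Callable, Iterable, Iterator

from .codec import PACKED_SNP_BYTES, pack_snp, unpack_snp
from .errors import FramingError, SnptopError
from .gcm import IV_BYTES, TAG_BYTES, AesGcm
from .vcf import SnpRecord

__all__ = [
    "EncryptedBlock",
    "DEFAULT_BLOCK_SIZE",
    "BLOCK_OVERHEAD",
    "encrypt_block",
    "decrypt_block",
    "compress_encrypt_file",
    "write_blocks",
    "read_blocks",
    "scan_block_offsets",
    "decrypt_file_records",
]

DEFAULT_BLOCK_SIZE = 2080
BLOCK_OVERHEAD = 4 + IV_BYTES + TAG_BYTES  # 32 bytes of framing per block

_COUNT = struct.Struct("<I")


@dataclass(frozen=True, slots=True)
class EncryptedBlock:
    snp_count: int
    iv: bytes
    mac: bytes
    ciphertext: bytes

    def serialize(self) -> bytes:
        return _COUNT.pack(self.snp_count) + self.iv + self.mac + self.ciphertext

    @property
    def size(self) -> int:
        return BLOCK_OVERHEAD + len(self.ciphertext)


def encrypt_block(
    snps: Iterable[bytes],
    key: bytes | AesGcm,
    rng: Callable[[int], bytes] = os.urandom,
) -> EncryptedBlock:
    """Encrypt a sequence of packed SNPs into one block.

    ``rng`` supplies the fresh 12-byte IV; it defaults to the OS CSPRNG
    and is injectable only for reproducible fixtures.
    """
    cipher = key if isinstance(key, AesGcm) else AesGcm(key)
    payload = b"".join(snps)
    if not payload:
        raise SnptopError("cannot encrypt an empty SNP block")
    if len(payload) % PACKED_SNP_BYTES:
        raise SnptopError("payload is not a whole number of packed SNPs")
    n = len(payload) // PACKED_SNP_BYTES
    iv = rng(IV_BYTES)
    ciphertext, tag = cipher.encrypt(iv, payload, aad=_COUNT.pack(n))
    return EncryptedBlock(n, iv, tag, ciphertext)


def decrypt_block(block: EncryptedBlock, key: bytes | AesGcm) -> list[bytes]:
    """Verify and decrypt a block, returning its packed 10-byte SNPs.

    Any modification of count, IV, MAC or ciphertext raises
    :class:`AuthenticationError`; corruption is never silent.
    """
    cipher = key if isinstance(key, AesGcm) else AesGcm(key)
    payload = cipher.decrypt(
        block.iv, block.ciphertext, block.mac, aad=_COUNT.pack(block.snp_count)
    )
    return [
        payload[i : i + PACKED_SNP_BYTES]
        for i in range(0, len(payload), PACKED_SNP_BYTES)
    ]


def compress_encrypt_file(
    records: Iterable[SnpRecord],
    key: bytes | AesGcm,
    block_size: int = DEFAULT_BLOCK_SIZE,
    rng: Callable[[int], bytes] = os.urandom,
) -> list[EncryptedBlock]:
    """Pack records and group them into ceil(m / B) encrypted blocks.

    SNP order is preserved across block boundaries; total serialized
    size is 32 * n_blocks + 10 * m bytes.
    """
    if block_size < 1:
        raise SnptopError(f"block size must be >= 1, got {block_size}")
    cipher = key if isinstance(key, AesGcm) else AesGcm(key)
    blocks: list[EncryptedBlock] = []
    chunk: list[bytes] = []
    for rec in records:
        chunk.append(pack_snp(rec))
        if len(chunk) == block_size:
            blocks.append(encrypt_block(chunk, cipher, rng))
            chunk = []
    if chunk:
        blocks.append(encrypt_block(chunk, cipher, rng))
    return blocks


def write_blocks(blocks: Iterable[EncryptedBlock], sink: IO[bytes]) -> int:
    """Serialize blocks back-to-back; returns bytes written."""
    total = 0
    for block in blocks:
        data = block.serialize()
        sink.write(data)
        total += len(data)
    return total


def _read_one(stream: IO[bytes], index: int) -> EncryptedBlock | None:
    header = stream.read(BLOCK_OVERHEAD)
    if not header:
        return None
    if len(header) < BLOCK_OVERHEAD:
        raise FramingError(f"block {index}: truncated header ({len(header)} bytes)")
    (n,) = _COUNT.unpack(header[:4])
    iv = header[4 : 4 + IV_BYTES]
    mac = header[4 + IV_BYTES :]
    ciphertext = stream.read(PACKED_SNP_BYTES * n)
    if len(ciphertext) < PACKED_SNP_BYTES * n:
        raise FramingError(
            f"block {index}: truncated payload "
            f"({len(ciphertext)} of {PACKED_SNP_BYTES * n} bytes)"
        )
    return EncryptedBlock(n, iv, mac, ciphertext)


def read_blocks(
    source: str | os.PathLike | IO[bytes] | bytes,
    start_index: int = 0,
) -> Iterator[EncryptedBlock]:
    """Lazily yield blocks from a serialized encrypted VCF.

    Blocks before ``start_index`` are skipped without decryption, which
    lets the engine resume from a remembered per-file cursor.  A
    truncated block raises :class:`FramingError` naming its index.
    """
    if isinstance(source, bytes):
        stream: IO[bytes] = io.BytesIO(source)
        yield from _iter_stream(stream, start_index)
    elif isinstance(source, (str, os.PathLike)):
        with open(source, "rb") as stream:
            yield from _iter_stream(stream, start_index)
    else:
        yield from _iter_stream(source, start_index)


def _iter_stream(stream: IO[bytes], start_index: int) -> Iterator[EncryptedBlock]:
    index = 0
    while True:
        block = _read_one(stream, index)
        if block is None:
            return
        if index >= start_index:
            yield block
        index += 1


def scan_block_offsets(path: str | os.PathLike) -> list[tuple[int, int]]:
    """Return (byte offset, snp count) of every block without decrypting.

    Validates framing for the whole file; used by the engine to give
    each file random-access cursors over its blocks.
    """
    out: list[tuple[int, int]] = []
    with open(path, "rb") as fh:
        fh.seek(0, os.SEEK_END)
        end = fh.tell()
        offset = 0
        index = 0
        while offset < end:
            fh.seek(offset)
            header = fh.read(BLOCK_OVERHEAD)
            if len(header) < BLOCK_OVERHEAD:
                raise FramingError(f"block {index}: truncated header")
            (n,) = _COUNT.unpack(header[:4])
            size = BLOCK_OVERHEAD + PACKED_SNP_BYTES * n
            if offset + size > end:
                raise FramingError(f"block {index}: truncated payload")
            out.append((offset, n))
            offset += size
            index += 1
    return out


def decrypt_file_records(
    source: str | os.PathLike | IO[bytes] | bytes, key: bytes | AesGcm
) -> Iterator[SnpRecord]:
    """Decrypt a whole encrypted VCF back to records (debug / oracle path)."""
    cipher = key if isinstance(key, AesGcm) else AesGcm(key)
    for block in read_blocks(source):
        for packed in decrypt_block(block, cipher):
            yield unpack_snp(packed)
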