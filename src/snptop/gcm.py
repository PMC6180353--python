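"""AES-128-GCM authenticated encryption.

Self-contained implementation of AES-128 in Galois/Counter Mode used to
protect SNP blocks: GCM provides both confidentiality (CTR encryption)
and integrity (a 16-byte GHASH-based tag covering ciphertext and
associated data).  The cipher core is vectorized with numpy — all CTR
keystream blocks of a message go through the ten AES rounds as one
(n, 16) byte array — and GHASH multiplies by the fixed hash key H via
per-key precomputed 8-bit tables.

Correctness is pinned in the test suite against the FIPS-197 AES
example vector and the standard GCM known-answer test cases.

Security notes: this is a research artifact.  Tag comparison is
constant-time (``hmac.compare_digest``), but the table-driven GHASH and
numpy S-box lookups are not hardened against cache-timing adversaries.
"""

from __future__ import annotations

import hmac
import numpy as np

from .errors import AuthenticationError

__all__ = ["AesGcm", "KEY_BYTES", "IV_BYTES", "TAG_BYTES"]

KEY_BYTES = 16
IV_BYTES = 12
TAG_BYTES = 16

# ---------------------------------------------------------------------------
# AES-128 core
# ---------------------------------------------------------------------------


def _build_sbox() -> np.ndarray:
    """Generate the AES S-box from GF(2^8) arithmetic (no typed-in table)."""
    # log/antilog tables for GF(2^8) with generator 3
    exp = [0] * 256
    log = [0] * 256
    x = 1
    for i in range(255):
        exp[i] = x
        log[x] = i
        # multiply by generator 0x03 = x * 2 ^ x
        x ^= (x << 1) ^ (0x1B if x & 0x80 else 0)
        x &= 0xFF
    exp[255] = 1  # generator^255 = 1 (needed for inverse of 1 via exp[255 - log])
    sbox = [0] * 256
    for b in range(256):
        inv = 0 if b == 0 else exp[255 - log[b]]
        # affine transform
        s = inv
        for shift in (1, 2, 3, 4):
            s ^= ((inv << shift) | (inv >> (8 - shift))) & 0xFF
        sbox[b] = s ^ 0x63
    return np.array(sbox, dtype=np.uint8)


_SBOX = _build_sbox()

# ShiftRows on the flat 16-byte state (byte 4c+r holds row r, column c):
# output byte (r, c) comes from input column (c + r) mod 4.
_SHIFT_ROWS = np.array(
    [4 * ((i // 4 + i % 4) % 4) + i % 4 for i in range(16)], dtype=np.intp
)


def _xtime(v: np.ndarray) -> np.ndarray:
    """GF(2^8) doubling, elementwise on uint8 arrays."""
    return (((v.astype(np.uint16) << 1) ^ ((v >> 7).astype(np.uint16) * 0x1B)) & 0xFF).astype(
        np.uint8
    )


def _expand_key(key: bytes) -> np.ndarray:
    """AES-128 key schedule -> (11, 16) uint8 round keys."""
    rcon = 1
    words = [list(key[4 * i : 4 * i + 4]) for i in range(4)]
    sbox = _SBOX
    for i in range(4, 44):
        w = list(words[i - 1])
        if i % 4 == 0:
            w = w[1:] + w[:1]
            w = [int(sbox[b]) for b in w]
            w[0] ^= rcon
            rcon = ((rcon << 1) ^ (0x1B if rcon & 0x80 else 0)) & 0xFF
        words.append([a ^ b for a, b in zip(words[i - 4], w)])
    flat = [b for w in words for b in w]
    return np.array(flat, dtype=np.uint8).reshape(11, 16)


def _aes_encrypt_blocks(round_keys: np.ndarray, blocks: np.ndarray) -> np.ndarray:
    """Encrypt an (n, 16) uint8 array of AES blocks in place-parallel."""
    s = blocks ^ round_keys[0]
    for r in range(1, 10):
        s = _SBOX[s]
        s = s[:, _SHIFT_ROWS]
        # MixColumns on the (n, 4 cols, 4 rows) view
        a = s.reshape(-1, 4, 4)
        t = a[:, :, 0] ^ a[:, :, 1] ^ a[:, :, 2] ^ a[:, :, 3]
        out = np.empty_like(a)
        out[:, :, 0] = a[:, :, 0] ^ t ^ _xtime(a[:, :, 0] ^ a[:, :, 1])
        out[:, :, 1] = a[:, :, 1] ^ t ^ _xtime(a[:, :, 1] ^ a[:, :, 2])
        out[:, :, 2] = a[:, :, 2] ^ t ^ _xtime(a[:, :, 2] ^ a[:, :, 3])
        out[:, :, 3] = a[:, :, 3] ^ t ^ _xtime(a[:, :, 3] ^ a[:, :, 0])
        s = out.reshape(-1, 16) ^ round_keys[r]
    s = _SBOX[s]
    s = s[:, _SHIFT_ROWS]
    return s ^ round_keys[10]


# ---------------------------------------------------------------------------
# GHASH (multiplication by the fixed hash key H in GF(2^128))
# ---------------------------------------------------------------------------

_R_POLY = 0xE1 << 120  # x^128 + x^7 + x^2 + x + 1, GCM bit order


def _gf_mul_x(v: int) -> int:
    """Multiply a GCM field element by x (right shift with reduction)."""
    carry = v & 1
    v >>= 1
    if carry:
        v ^= _R_POLY
    return v


def _build_ghash_tables(h: int) -> list[list[int]]:
    """8-bit tables T[j][b] = (byte b at position j) * H for byte-wise GHASH.

    Position j = 0 is the most significant byte (lowest-degree
    coefficients in GCM bit order).
    """
    # hx[i] = H * x^i
    hx = [0] * 128
    v = h
    for i in range(128):
        hx[i] = v
        v = _gf_mul_x(v)
    tables: list[list[int]] = []
    for j in range(16):
        tab = [0] * 256
        for b in range(1, 256):
            low = b & (-b)  # lowest set bit
            t = low.bit_length() - 1  # bit index within the byte
            # bit t of byte j is polynomial coefficient 8*j + (7 - t)
            tab[b] = tab[b ^ low] ^ hx[8 * j + 7 - t]
        tables.append(tab)
    return tables


class _Ghash:
    def __init__(self, tables: list[list[int]]):
        self._tables = tables
        self._y = 0

    def update(self, data: bytes) -> None:
        """Absorb data, zero-padded on the right to a 16-byte multiple."""
        tables = self._tables
        y = self._y
        for off in range(0, len(data), 16):
            block = data[off : off + 16]
            if len(block) < 16:
                block = block + b"\x00" * (16 - len(block))
            y ^= int.from_bytes(block, "big")
            acc = 0
            for j in range(16):
                acc ^= tables[j][(y >> (8 * (15 - j))) & 0xFF]
            y = acc
        self._y = y

    def digest(self) -> int:
        return self._y


# ---------------------------------------------------------------------------
# GCM mode
# ---------------------------------------------------------------------------


class AesGcm:
    """AES-128-GCM with 96-bit IVs and full 16-byte tags.

    >>> cipher = AesGcm(bytes(16))
    >>> ct, tag = cipher.encrypt(bytes(12), b"payload", b"aad")
    >>> cipher.decrypt(bytes(12), ct, tag, b"aad")
    b'payload'
    """

    def __init__(self, key: bytes):
        if len(key) != KEY_BYTES:
            raise ValueError(f"key must be {KEY_BYTES} bytes, got {len(key)}")
        self._round_keys = _expand_key(key)
        h_block = _aes_encrypt_blocks(
            self._round_keys, np.zeros((1, 16), dtype=np.uint8)
        )
        h = int.from_bytes(h_block.tobytes(), "big")
        self._ghash_tables = _build_ghash_tables(h)

    # -- internals ---------------------------------------------------------

    def _keystream(self, iv: bytes, n_blocks: int, start_counter: int) -> np.ndarray:
        counters = np.zeros((n_blocks, 16), dtype=np.uint8)
        iv_arr = np.frombuffer(iv, dtype=np.uint8)
        counters[:, :12] = iv_arr
        ctr_vals = (start_counter + np.arange(n_blocks, dtype=np.uint64)) & 0xFFFFFFFF
        counters[:, 12] = (ctr_vals >> 24).astype(np.uint8)
        counters[:, 13] = (ctr_vals >> 16).astype(np.uint8)
        counters[:, 14] = (ctr_vals >> 8).astype(np.uint8)
        counters[:, 15] = ctr_vals.astype(np.uint8)
        return _aes_encrypt_blocks(self._round_keys, counters)

    def _ctr_xor(self, iv: bytes, data: bytes) -> bytes:
        if not data:
            return b""
        n_blocks = (len(data) + 15) // 16
        ks = self._keystream(iv, n_blocks, start_counter=2).reshape(-1)[: len(data)]
        arr = np.frombuffer(data, dtype=np.uint8) ^ ks
        return arr.tobytes()

    def _tag(self, iv: bytes, ciphertext: bytes, aad: bytes) -> bytes:
        gh = _Ghash(self._ghash_tables)
        gh.update(aad)
        gh.update(ciphertext)
        lengths = (len(aad) * 8).to_bytes(8, "big") + (len(ciphertext) * 8).to_bytes(8, "big")
        gh.update(lengths)
        e_j0 = int.from_bytes(self._keystream(iv, 1, start_counter=1).tobytes(), "big")
        return (gh.digest() ^ e_j0).to_bytes(16, "big")

    # -- public API --------------------------------------------------------

    def encrypt(self, iv: bytes, plaintext: bytes, aad: bytes = b"") -> tuple[bytes, bytes]:
        """Return (ciphertext, 16-byte tag) for a fresh 12-byte IV."""
        if len(iv) != IV_BYTES:
            raise ValueError(f"IV must be {IV_BYTES} bytes, got {len(iv)}")
        ciphertext = self._ctr_xor(iv, plaintext)
        return ciphertext, self._tag(iv, ciphertext, aad)

    def decrypt(self, iv: bytes, ciphertext: bytes, tag: bytes, aad: bytes = b"") -> bytes:
        """Verify the tag, then decrypt; raises AuthenticationError on mismatch."""
        if len(iv) != IV_BYTES:
            raise ValueError(f"IV must be {IV_BYTES} bytes, got {len(iv)}")
        if len(tag) != TAG_BYTES:
            raise AuthenticationError("truncated authentication tag")
        expected = self._tag(iv, ciphertext, aad)
        if not hmac.compare_digest(expected, tag):
            raise AuthenticationError("GCM tag mismatch: block is corrupt or forged")
        return self._ctr_xor(iv, ciphertext)
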