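"""Horizontally-partitioned top-K search over encrypted cohorts.

The engine mirrors the five-call enclave-style interface of trusted-
execution deployments: initialize (:func:`engine_init`), register the
labeled encrypted files (:meth:`SearchEngine.register`), then iterate
begin-range / run-range / end-range until every SNP has been treated
(:meth:`SearchEngine.run_search` drives the loop).

Each main-loop iteration treats one (chromosome, position) range.  The
next ``range_blocks`` blocks (default 4) of the *first* registered file
define the reference range: it starts at the first SNP of the first
such block and ends, inclusively, at the last SNP of the last one.
Every file then advances its own cursor, decrypting successive blocks
and feeding each SNP with locus <= range end into the CTRL_CNT or
CASE_CNT counter table (homozygous counts 2, heterozygous 1).  Cursors
carry an intra-block offset, so a block straddling the range boundary
is split logically and its remainder is consumed by the next iteration
— every SNP is counted exactly once.  Files holding SNPs beyond the
first file's last locus (or on chromosomes it lacks) are drained by one
final open-ended range.

At the end of each range the chi-square statistic is computed for every
key present in either table, the global top-K list is merged (ranking
by statistic descending, ties broken by (chrom, pos, refalt) ascending)
and the tables are cleared.  P-values are evaluated — through the
precomputed-grid survival function — only for the K survivors once the
scan terminates, never during it.

The result is invariant to block size, range_blocks, table capacity and
hash mask: those parameters shape the access schedule, not the answer.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import IO, Sequence

import numpy as np

from .blocks import decrypt_block, read_blocks, scan_block_offsets
from .chi2 import SurvivalTable, chi2_statistic
from .codec import decode_refalt, encode_refalt, unpack_snp
from .counter import DEFAULT_CAPACITY, CountTable, snp_key, split_key
from .errors import AuthenticationError, ConfigError, ManifestError, VcfOrderingError
from .gcm import KEY_BYTES, AesGcm
from .vcf import Zygosity, code_to_chrom

__all__ = [
    "CohortManifest",
    "SnpRange",
    "TopKEntry",
    "SearchEngine",
    "engine_init",
    "load_manifest",
    "write_results_tsv",
    "DEFAULT_RANGE_BLOCKS",
    "DEFAULT_TOP_K",
]

DEFAULT_RANGE_BLOCKS = 4
DEFAULT_TOP_K = 10

CONTROL = "control"
CASE = "case"


@dataclass(frozen=True, slots=True)
class CohortManifest:
    """Ordered (path, label) pairs; labels are 'control' or 'case'."""

    entries: tuple[tuple[str, str], ...]

    def __post_init__(self):
        labels = {label for _, label in self.entries}
        bad = labels - {CONTROL, CASE}
        if bad:
            raise ManifestError(f"unknown cohort labels: {sorted(bad)}")
        if CONTROL not in labels or CASE not in labels:
            raise ManifestError(
                "manifest must list at least one control and one case file"
            )


def load_manifest(path: str | os.PathLike) -> CohortManifest:
    """Read a manifest file: one 'path<TAB>label' line per encrypted VCF.

    Relative paths resolve against the manifest's directory.
    """
    base = os.path.dirname(os.path.abspath(path))
    entries = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ManifestError(
                    f"{path}: line {lineno}: expected 'path<TAB>label'"
                )
            fpath, label = parts
            if not os.path.isabs(fpath):
                fpath = os.path.join(base, fpath)
            entries.append((fpath, label))
    return CohortManifest(tuple(entries))


@dataclass(frozen=True, slots=True)
class SnpRange:
    """Inclusive (chrom, pos) range; ``end=None`` marks the final sweep."""

    start: tuple[int, int] | None
    end: tuple[int, int] | None

    @property
    def open_ended(self) -> bool:
        return self.end is None


@dataclass(slots=True)
class TopKEntry:
    key: int
    n_ctrl: int
    n_case: int
    statistic: float
    p_value: float | None = None

    @property
    def locus(self) -> tuple[int, int]:
        chrom, pos, _ = split_key(self.key)
        return chrom, pos


@dataclass(slots=True)
class _FileState:
    path: str
    label: str
    offsets: list[tuple[int, int]]  # (byte offset, snp count) per block
    block_idx: int = 0
    intra_offset: int = 0
    current: list | None = None  # decrypted records of block_idx
    last_locus: tuple[int, int] | None = None
    handle: IO[bytes] | None = None

    @property
    def exhausted(self) -> bool:
        return self.block_idx >= len(self.offsets)


def _decrypt_block_records(state: _FileState, cipher: AesGcm):
    """Decrypt the block at the cursor into (key, amount, locus) triples."""
    offset, _n = state.offsets[state.block_idx]
    if state.handle is None:
        state.handle = open(state.path, "rb")
    state.handle.seek(offset)
    try:
        block = next(read_blocks(state.handle))
        packed = decrypt_block(block, cipher)
    except AuthenticationError as exc:
        raise AuthenticationError(
            f"{state.path}: block {state.block_idx}: {exc}"
        ) from None
    records = []
    for raw in packed:
        rec = unpack_snp(raw)
        locus = (rec.chrom, rec.pos)
        if state.last_locus is not None and locus < state.last_locus:
            raise VcfOrderingError(
                f"{state.path}: block {state.block_idx}: SNP at {locus} "
                f"after {state.last_locus}"
            )
        state.last_locus = locus
        key = snp_key(rec.chrom, rec.pos, encode_refalt(rec.ref, rec.alt))
        amount = 2 if rec.zygosity is Zygosity.HOMOZYGOUS else 1
        records.append((key, amount, locus))
    return records


class SearchEngine:
    """Streaming search for the K most significant SNPs.

    Parameters
    ----------
    key
        16-byte AES key shared by all encrypted files.
    k
        Number of SNPs to return.
    range_blocks
        Reference-range width in blocks of the first file.
    table_capacity
        Slot count of each counter table.
    seed
        Seeds the counter-table masks; ``None`` draws fresh entropy.
    rank_lowest
        Rank by smallest statistic instead (the literal reading of the
        original prose; the default is the statistically standard
        largest-statistic / smallest-p direction).
    """

    def __init__(
        self,
        key: bytes,
        k: int = DEFAULT_TOP_K,
        range_blocks: int = DEFAULT_RANGE_BLOCKS,
        table_capacity: int = DEFAULT_CAPACITY,
        seed: int | None = None,
        rank_lowest: bool = False,
        survival_table: SurvivalTable | None = None,
    ):
        if len(key) != KEY_BYTES:
            raise ConfigError(f"key must be {KEY_BYTES} bytes, got {len(key)}")
        if k < 1:
            raise ConfigError(f"k must be >= 1, got {k}")
        if range_blocks < 1:
            raise ConfigError(f"range_blocks must be >= 1, got {range_blocks}")
        self._cipher = AesGcm(key)
        self.k = k
        self.range_blocks = range_blocks
        self.rank_lowest = rank_lowest
        rng = np.random.default_rng(seed)
        self.ctrl_cnt = CountTable(table_capacity, rng=rng)
        self.case_cnt = CountTable(table_capacity, rng=rng)
        self._survival = survival_table
        self._files: list[_FileState] = []
        self.n_ctrl_files = 0
        self.n_case_files = 0
        self._ref_cursor = 0
        self._final_sweep_done = False
        self._top: list[TopKEntry] = []

    # -- registration ------------------------------------------------------

    def register(self, manifest: CohortManifest) -> None:
        """Memorize the labeled files; fixes N_ctrl and N_case."""
        if self._files:
            raise ConfigError("engine already registered")
        for path, label in manifest.entries:
            try:
                offsets = scan_block_offsets(path)
            except OSError as exc:
                raise ManifestError(f"cannot read {path}: {exc}") from None
            self._files.append(_FileState(str(path), label, offsets))
            if label == CONTROL:
                self.n_ctrl_files += 1
            else:
                self.n_case_files += 1
        # each file contributes up to 2 per SNP (homozygous counts twice)
        self.N_ctrl = 2 * self.n_ctrl_files
        self.N_case = 2 * self.n_case_files

    # -- main loop ---------------------------------------------------------

    def next_range(self) -> SnpRange | None:
        """Begin a new iteration; ``None`` when all SNPs are treated."""
        if not self._files:
            raise ConfigError("no manifest registered")
        first = self._files[0]
        n_blocks = len(first.offsets)
        if self._ref_cursor < n_blocks:
            lo = self._ref_cursor
            hi = min(lo + self.range_blocks, n_blocks) - 1
            start = self._block_boundary(first, lo, first_snp=True)
            end = self._block_boundary(first, hi, first_snp=False)
            self._ref_cursor = hi + 1
            return SnpRange(start, end)
        if not self._final_sweep_done and any(
            not f.exhausted for f in self._files
        ):
            self._final_sweep_done = True
            return SnpRange(None, None)
        return None

    def _block_boundary(
        self, state: _FileState, block_idx: int, first_snp: bool
    ) -> tuple[int, int]:
        offset, _n = state.offsets[block_idx]
        if state.handle is None:
            state.handle = open(state.path, "rb")
        state.handle.seek(offset)
        try:
            block = next(read_blocks(state.handle))
            packed = decrypt_block(block, self._cipher)
        except AuthenticationError as exc:
            raise AuthenticationError(
                f"{state.path}: block {block_idx}: {exc}"
            ) from None
        rec = unpack_snp(packed[0] if first_snp else packed[-1])
        return (rec.chrom, rec.pos)

    def consume_range(self, rng: SnpRange) -> None:
        """Advance every file through the range, updating the presence maps."""
        end = rng.end
        for state in self._files:
            table = self.ctrl_cnt if state.label == CONTROL else self.case_cnt
            increment = table.increment
            while not state.exhausted:
                if state.current is None:
                    state.current = _decrypt_block_records(state, self._cipher)
                records = state.current
                i = state.intra_offset
                n = len(records)
                while i < n:
                    key, amount, locus = records[i]
                    if end is not None and locus > end:
                        break
                    increment(key, amount)
                    i += 1
                if i < n:
                    state.intra_offset = i  # boundary splits this block
                    break
                state.block_idx += 1
                state.intra_offset = 0
                state.current = None

    def end_range(self) -> None:
        """Score every key seen in this range, merge into top-K, clear maps."""
        counts: dict[int, list[int]] = {}
        for key, c in self.ctrl_cnt.items():
            counts.setdefault(key, [0, 0])[0] = c
        for key, c in self.case_cnt.items():
            counts.setdefault(key, [0, 0])[1] = c
        candidates = [
            TopKEntry(
                key,
                n_ctrl,
                n_case,
                chi2_statistic(n_ctrl, n_case, self.N_ctrl, self.N_case),
            )
            for key, (n_ctrl, n_case) in counts.items()
        ]
        merged = self._top + candidates
        sign = 1.0 if self.rank_lowest else -1.0
        merged.sort(key=lambda e: (sign * e.statistic, e.key))
        self._top = merged[: self.k]
        self.ctrl_cnt.clear()
        self.case_cnt.clear()

    def run_search(self) -> list[TopKEntry]:
        """Drive the main loop to exhaustion and attach final p-values."""
        try:
            while (rng := self.next_range()) is not None:
                self.consume_range(rng)
                self.end_range()
        finally:
            self._close_handles()
        if self._survival is None:
            self._survival = SurvivalTable()
        for entry in self._top:
            entry.p_value = self._survival.survival(entry.statistic)
        return list(self._top)

    def _close_handles(self) -> None:
        for state in self._files:
            if state.handle is not None:
                state.handle.close()
                state.handle = None


def engine_init(key: bytes, **config) -> SearchEngine:
    """Create a :class:`SearchEngine`; keyword names match the constructor."""
    return SearchEngine(key, **config)


def write_results_tsv(
    entries: Sequence[TopKEntry],
    sink: IO[str],
    k: int | None = None,
    n_ctrl_files: int | None = None,
    n_case_files: int | None = None,
    rank_lowest: bool = False,
) -> None:
    """Emit the ranked SNP table.

    The comment header records the ranking convention; the parameter
    lines deliberately exclude partition details (block size, range
    width, capacity, mask) so that equivalent runs produce byte-
    identical tables.
    """
    direction = (
        "statistic ascending (largest p first)"
        if rank_lowest
        else "statistic descending (most significant, smallest p, first)"
    )
    sink.write(f"# ranking: {direction}\n")
    if k is not None:
        sink.write(f"# top_k: {k}\n")
    if n_ctrl_files is not None and n_case_files is not None:
        sink.write(
            f"# cohort: {n_ctrl_files} control, {n_case_files} case files\n"
        )
    sink.write(
        "rank\tchrom\tpos\tref\talt\tn_ctrl\tn_case\tstatistic\tp_value\n"
    )
    for rank, e in enumerate(entries, start=1):
        chrom, pos, refalt = split_key(e.key)
        ref, alt = decode_refalt(refalt)
        p = "" if e.p_value is None else f"{e.p_value:.6e}"
        sink.write(
            f"{rank}\t{code_to_chrom(chrom)}\t{pos}\t{ref}\t{alt}\t"
            f"{e.n_ctrl}\t{e.n_case}\t{e.statistic:.9g}\t{p}\n"
        )
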