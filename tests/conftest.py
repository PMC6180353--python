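"""Shared fixtures, random-record generators and the naive search oracle."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings, strategies as hst

from snptop.chi2 import chi2_statistic
from snptop.codec import REFALT_PAIRS, encode_refalt
from snptop.counter import snp_key
from snptop.engine import CASE, CONTROL
from snptop.vcf import SnpRecord, Zygosity

settings.register_profile(
    "ci",
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def key() -> bytes:
    return bytes(range(16))


# --------------------------------------------------------------------------
# hypothesis strategies
# --------------------------------------------------------------------------

refalt_pairs = hst.sampled_from(REFALT_PAIRS)


@hst.composite
def snp_records(draw) -> SnpRecord:
    chrom = draw(hst.integers(1, 25))
    pos = draw(hst.integers(0, 2**32 - 1))
    rs = draw(hst.integers(0, 2**37 - 1))
    ref, alt = draw(refalt_pairs)
    zyg = draw(hst.sampled_from(list(Zygosity)))
    return SnpRecord(chrom, pos, f"rs{rs}", ref, alt, zyg)


# --------------------------------------------------------------------------
# fast bulk record generation (numpy-driven)
# --------------------------------------------------------------------------


def random_records(
    rng: np.random.Generator, n: int, sort: bool = True
) -> list[SnpRecord]:
    """n random dialect-valid records, optionally sorted by (chrom, pos)."""
    chrom = rng.integers(1, 26, size=n)
    pos = rng.integers(0, 2**32, size=n)
    rs = rng.integers(0, 2**37, size=n)
    pair = rng.integers(0, 20, size=n)
    hom = rng.integers(0, 2, size=n)
    order = np.lexsort((pos, chrom)) if sort else np.arange(n)
    out = []
    for i in order:
        ref, alt = REFALT_PAIRS[int(pair[i])]
        out.append(
            SnpRecord(
                int(chrom[i]),
                int(pos[i]),
                f"rs{int(rs[i])}",
                ref,
                alt,
                Zygosity.HOMOZYGOUS if hom[i] else Zygosity.HETEROZYGOUS,
            )
        )
    return out


# --------------------------------------------------------------------------
# naive reference search (the oracle the engine must match)
# --------------------------------------------------------------------------


def naive_search(
    cohort: list[tuple[list[SnpRecord], str]],
    k: int,
    rank_lowest: bool = False,
) -> list[tuple[int, int, int, float]]:
    """Single-pass reference: global dict counters, full sort, truncate.

    ``cohort`` pairs each file's plaintext records with its label.
    Returns [(key, n_ctrl, n_case, statistic)] in ranked order —
    independent of blocks, ranges, hashing and encryption.
    """
    ctrl: dict[int, int] = {}
    case: dict[int, int] = {}
    n_ctrl_files = sum(1 for _, lab in cohort if lab == CONTROL)
    n_case_files = sum(1 for _, lab in cohort if lab == CASE)
    for records, label in cohort:
        target = ctrl if label == CONTROL else case
        for rec in records:
            k_ = snp_key(rec.chrom, rec.pos, encode_refalt(rec.ref, rec.alt))
            amount = 2 if rec.zygosity is Zygosity.HOMOZYGOUS else 1
            target[k_] = target.get(k_, 0) + amount
    N_ctrl, N_case = 2 * n_ctrl_files, 2 * n_case_files
    rows = []
    for k_ in set(ctrl) | set(case):
        nc, nk = ctrl.get(k_, 0), case.get(k_, 0)
        rows.append((k_, nc, nk, chi2_statistic(nc, nk, N_ctrl, N_case)))
    sign = 1.0 if rank_lowest else -1.0
    rows.sort(key=lambda r: (sign * r[3], r[0]))
    return rows[:k]
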