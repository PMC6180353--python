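"""Streaming engine vs the naive full-decrypt oracle, plus range mechanics."""

import io

import numpy as np
import pytest

from snptop.blocks import compress_encrypt_file, write_blocks
from snptop.counter import snp_key
from snptop.engine import (
    CASE,
    CONTROL,
    CohortManifest,
    SearchEngine,
    SnpRange,
    engine_init,
    load_manifest,
    write_results_tsv,
)
from snptop.errors import AuthenticationError, ConfigError, ManifestError
from snptop.gcm import AesGcm
from snptop.vcf import SnpRecord, Zygosity

from conftest import naive_search, random_records

HET, HOM = Zygosity.HETEROZYGOUS, Zygosity.HOMOZYGOUS


def rec(chrom, pos, zyg=HET, ref="G", alt="A", rs=1):
    return SnpRecord(chrom, pos, f"rs{rs}", ref, alt, zyg)


def encrypt_cohort(tmp_path, cohort, key, block_size=2080):
    """Write each (records, label) as an encrypted file; return a manifest."""
    cipher = AesGcm(key)
    entries = []
    for i, (records, label) in enumerate(cohort):
        path = tmp_path / f"f{i:03d}.evcf"
        with open(path, "wb") as fh:
            write_blocks(compress_encrypt_file(records, cipher, block_size), fh)
        entries.append((str(path), label))
    return CohortManifest(tuple(entries))


def run(tmp_path, cohort, key, k=10, block_size=2080, **kw):
    manifest = encrypt_cohort(tmp_path, cohort, key, block_size)
    engine = SearchEngine(key, k=k, **kw)
    engine.register(manifest)
    return engine, engine.run_search()


def random_cohort(rng, n_files=None, n_snps=None):
    """Files share a template so the same loci recur across the cohort."""
    n_files = n_files or int(rng.integers(5, 41))
    n_snps = n_snps or int(rng.integers(100, 1001))
    template = random_records(rng, n_snps)
    cohort = []
    for i in range(n_files):
        present = rng.random(n_snps) < 0.4
        hom = rng.random(n_snps) < 0.3
        records = []
        for j in np.flatnonzero(present):
            r = template[j]
            records.append(
                SnpRecord(r.chrom, r.pos, r.id, r.ref, r.alt, HOM if hom[j] else HET)
            )
        label = CONTROL if i % 2 == 0 else CASE
        cohort.append((records, label))
    if not any(lab == CASE for _, lab in cohort):
        cohort[-1] = (cohort[-1][0], CASE)
    return cohort


# --------------------------------------------------------------------------
# configuration & registration
# --------------------------------------------------------------------------


class TestConfig:
    def test_defaults(self, key):
        eng = engine_init(key)
        assert eng.range_blocks == 4
        assert eng.ctrl_cnt.capacity == 282914
        assert eng.k == 10

    def test_k_zero_is_rejected(self, key):
        with pytest.raises(ConfigError):
            SearchEngine(key, k=0)

    def test_bad_key_length_is_rejected(self):
        with pytest.raises(ConfigError):
            SearchEngine(bytes(8))

    def test_same_seed_gives_identical_masks(self, key):
        a, b = SearchEngine(key, seed=9), SearchEngine(key, seed=9)
        assert (a.ctrl_cnt.mask, a.case_cnt.mask) == (b.ctrl_cnt.mask, b.case_cnt.mask)
        assert a.ctrl_cnt.mask != a.case_cnt.mask

    def test_register_fixes_cohort_totals(self, key, tmp_path):
        cohort = [([rec(1, 10)], CONTROL) for _ in range(3)]
        cohort += [([rec(1, 10)], CASE) for _ in range(2)]
        manifest = encrypt_cohort(tmp_path, cohort, key)
        eng = SearchEngine(key)
        eng.register(manifest)
        assert (eng.N_ctrl, eng.N_case) == (6, 4)

    def test_manifest_requires_both_labels(self):
        with pytest.raises(ManifestError):
            CohortManifest((("a.evcf", CONTROL),))
        with pytest.raises(ManifestError):
            CohortManifest((("a.evcf", "kontrol"), ("b.evcf", CASE)))

    def test_manifest_loader_resolves_relative_paths(self, tmp_path):
        (tmp_path / "m.tsv").write_text("a.evcf\tcontrol\nb.evcf\tcase\n")
        manifest = load_manifest(tmp_path / "m.tsv")
        assert all(p.startswith(str(tmp_path)) for p, _ in manifest.entries)


# --------------------------------------------------------------------------
# range iteration
# --------------------------------------------------------------------------


class TestRanges:
    def test_ten_block_first_file_yields_three_ranges(self, key, tmp_path):
        first = [rec(1, 10 * i + 10, rs=i) for i in range(100)]  # 10 blocks of 10
        other = [rec(1, 5), rec(2, 99999)]  # before and after the first file
        cohort = [(first, CONTROL), (other, CASE)]
        manifest = encrypt_cohort(tmp_path, cohort, key, block_size=10)
        eng = SearchEngine(key, range_blocks=4)
        eng.register(manifest)
        ranges = []
        while (r := eng.next_range()) is not None:
            ranges.append(r)
            eng.consume_range(r)
            eng.end_range()
        assert [(r.start, r.end) for r in ranges[:3]] == [
            ((1, 10), (1, 400)),
            ((1, 410), (1, 800)),
            ((1, 810), (1, 1000)),
        ]
        assert ranges[3].open_ended  # drains (2, 99999)
        assert len(ranges) == 4

    def test_short_first_file_gives_single_range(self, key, tmp_path):
        cohort = [([rec(1, 10), rec(1, 20)], CONTROL), ([rec(1, 15)], CASE)]
        manifest = encrypt_cohort(tmp_path, cohort, key, block_size=1)
        eng = SearchEngine(key, range_blocks=4)
        eng.register(manifest)
        r = eng.next_range()
        assert (r.start, r.end) == ((1, 10), (1, 20))
        eng.consume_range(r)
        eng.end_range()
        assert eng.next_range() is None

    def test_counts_within_a_range(self, key, tmp_path):
        snp = rec(3, 777, HOM)
        cohort = [([snp], CASE) for _ in range(5)]
        cohort += [([rec(3, 900)], CONTROL) for _ in range(5)]
        manifest = encrypt_cohort(tmp_path, cohort, key)
        eng = SearchEngine(key)
        eng.register(manifest)
        r = eng.next_range()
        eng.consume_range(r)
        k = snp_key(3, 777, 8)  # (G, A) pair code
        assert eng.case_cnt.get(k) == 10  # homozygous in all 5 case files
        assert eng.ctrl_cnt.get(k) == 0

    def test_heterozygous_counts_once_per_file(self, key, tmp_path):
        carrier = [([rec(1, 50, HET)], CONTROL) for _ in range(3)]
        non = [([rec(1, 60)], CONTROL) for _ in range(2)]
        cohort = carrier + non + [([rec(1, 70)], CASE)]
        manifest = encrypt_cohort(tmp_path, cohort, key)
        eng = SearchEngine(key)
        eng.register(manifest)
        eng.consume_range(SnpRange(None, None))
        assert eng.ctrl_cnt.get(snp_key(1, 50, 8)) == 3


# --------------------------------------------------------------------------
# top-K semantics
# --------------------------------------------------------------------------


class TestTopK:
    def test_k_truncation_keeps_largest_statistics(self, key, tmp_path):
        # five loci with graded case/control imbalance
        cohort = []
        for i in range(6):
            ctrl = [rec(1, 100 + j, rs=j) for j in range(5) if j >= i]
            case = [rec(1, 100 + j, rs=j) for j in range(5) if j < i]
            cohort.append((ctrl, CONTROL))
            cohort.append((case, CASE))
        _, res = run(tmp_path, cohort, key, k=3)
        assert len(res) == 3
        stats = [e.statistic for e in res]
        assert stats == sorted(stats, reverse=True)
        oracle = naive_search(cohort, 3)
        assert [e.key for e in res] == [o[0] for o in oracle]
        assert stats == pytest.approx([o[3] for o in oracle], rel=1e-9)

    def test_tie_break_is_locus_ascending(self, key, tmp_path):
        a, b = rec(2, 100, rs=1), rec(1, 500, rs=2)  # identical statistics
        cohort = [([b, a], CASE), ([], CONTROL)]
        _, res = run(tmp_path, cohort, key, k=1)
        assert res[0].locus == (1, 500)

    def test_k_larger_than_snp_count_returns_all(self, key, tmp_path):
        cohort = [([rec(1, 1), rec(1, 2), rec(1, 3)], CASE), ([], CONTROL)]
        _, res = run(tmp_path, cohort, key, k=50)
        assert len(res) == 3

    def test_planted_snp_ranks_first(self, key, tmp_path):
        planted = rec(9, 123456, HOM, rs=99)
        cohort = [([planted], CASE) for _ in range(5)]
        cohort += [([rec(9, 200000)], CONTROL) for _ in range(5)]
        _, res = run(tmp_path, cohort, key)
        assert res[0].locus == (9, 123456)
        assert res[0].n_case == 10 and res[0].n_ctrl == 0

    def test_p_values_only_on_final_entries_and_consistent(self, key, tmp_path):
        cohort = [([rec(1, 1), rec(1, 2)], CASE), ([rec(1, 2)], CONTROL)]
        eng, res = run(tmp_path, cohort, key, k=1)
        assert all(e.p_value is not None for e in res)
        assert res[0].p_value == pytest.approx(
            eng._survival.survival(res[0].statistic), abs=1e-12
        )

    def test_rank_lowest_flag_flips_the_order(self, key, tmp_path):
        cohort = [([rec(1, 1), rec(1, 2)], CASE), ([rec(1, 2), rec(1, 3)], CONTROL)]
        _, res_std = run(tmp_path, cohort, key, k=3)
        _, res_flip = run(tmp_path, cohort, key, k=3, rank_lowest=True)
        assert [e.statistic for e in res_flip] == sorted(
            e.statistic for e in res_std
        )


# --------------------------------------------------------------------------
# oracle equivalence & partition invariance
# --------------------------------------------------------------------------


def result_signature(entries):
    return [(e.key, e.n_ctrl, e.n_case, round(e.statistic, 9)) for e in entries]


@pytest.mark.parametrize("seed", range(10))
def test_oracle_equivalence_random_cohorts(seed, key, tmp_path):
    rng = np.random.default_rng(300 + seed)
    cohort = random_cohort(rng, n_files=int(rng.integers(5, 15)),
                           n_snps=int(rng.integers(100, 500)))
    _, res = run(tmp_path, cohort, key, k=20, block_size=64, seed=seed)
    oracle = naive_search(cohort, 20)
    assert [(e.key, e.n_ctrl, e.n_case) for e in res] == [o[:3] for o in oracle]
    for e, o in zip(res, oracle):
        assert e.statistic == pytest.approx(o[3], rel=1e-9, abs=1e-12)


def test_partition_invariance(key, tmp_path):
    """Output is byte-identical across block sizes, range widths, capacity."""
    rng = np.random.default_rng(77)
    cohort = random_cohort(rng, n_files=8, n_snps=300)
    outputs = set()
    for block_size in (13, 160, 2080):
        for range_blocks in (1, 4, 7):
            sub = tmp_path / f"b{block_size}r{range_blocks}"
            sub.mkdir()
            eng, res = run(
                sub, cohort, key, k=15, block_size=block_size,
                range_blocks=range_blocks,
                table_capacity=4099 if block_size == 13 else 282914,
                seed=block_size + range_blocks,
            )
            buf = io.StringIO()
            write_results_tsv(res, buf, k=15, n_ctrl_files=eng.n_ctrl_files,
                              n_case_files=eng.n_case_files)
            outputs.add(buf.getvalue())
    assert len(outputs) == 1


def test_counting_mass_is_conserved_across_ranges(key, tmp_path):
    rng = np.random.default_rng(88)
    cohort = random_cohort(rng, n_files=6, n_snps=200)
    expected_mass = sum(
        sum(2 if r.zygosity is HOM else 1 for r in records)
        for records, _ in cohort
    )
    manifest = encrypt_cohort(tmp_path, cohort, key, block_size=16)
    eng = SearchEngine(key, range_blocks=2, seed=0)
    eng.register(manifest)
    mass = 0
    while (r := eng.next_range()) is not None:
        eng.consume_range(r)
        mass += eng.ctrl_cnt.total_mass() + eng.case_cnt.total_mass()
        eng.end_range()
    assert mass == expected_mass


def test_tampered_block_aborts_with_file_context(key, tmp_path):
    cohort = [([rec(1, 10)], CONTROL), ([rec(1, 20)], CASE)]
    manifest = encrypt_cohort(tmp_path, cohort, key)
    victim = manifest.entries[1][0]
    data = bytearray(open(victim, "rb").read())
    data[-1] ^= 0x80
    open(victim, "wb").write(bytes(data))
    eng = SearchEngine(key)
    eng.register(manifest)
    with pytest.raises(AuthenticationError, match="f001"):
        eng.run_search()
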