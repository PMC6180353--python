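"""Synthetic control/case cohort generator with known ground truth.

Emulates the contest-style input: a cohort of per-individual simplified
VCF files, each listing the SNPs carried by that genome, sorted by
(chromosome, position), rs-numbered, QUAL=100, FILTER=PASS, TYPE
heterozygous or homozygous.  All files draw from one shared site
template; each file includes site i independently with its cohort's
carrier probability, and a carried site is homozygous with a fixed
fraction.  A subset of "planted" sites gets different carrier
probabilities in the two cohorts — the association signal the search
must recover; every other site uses the shared background probability.

The generator writes the VCF files, a manifest (path TAB label) and a
truth table holding, per site, the exact expected presence counts
E[n] = n_files * p * (1 + hom_fraction) and the chi-square statistic
evaluated at those expectations, which predicts the ranking of planted
sites.

No linkage structure, allele-frequency spectrum or population
stratification is simulated: the association scan uses none of these,
and independent per-file draws are the matching null model.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .chi2 import chi2_statistic
from .codec import REFALT_PAIRS
from .vcf import SnpRecord, Zygosity, write_vcf

__all__ = ["SynthConfig", "SiteTruth", "generate_cohort", "truth_statistic"]


@dataclass(frozen=True, slots=True)
class SynthConfig:
    """Cohort generation parameters.

    Defaults reproduce the planted-effect study condition used
    throughout the test suite: 50 control + 50 case files with one
    planted SNP carried with probability 0.1 in controls and 0.9 in
    cases, against a 0.3 background carrier probability on a 200-site
    template with 30% homozygous calls.
    """

    n_control_files: int = 50
    n_case_files: int = 50
    n_snps: int = 200
    n_planted: int = 1
    carrier_prob_control: float = 0.1
    carrier_prob_case: float = 0.9
    background_prob: float = 0.3
    hom_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self):
        for name in (
            "carrier_prob_control",
            "carrier_prob_case",
            "background_prob",
            "hom_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_planted > self.n_snps:
            raise ValueError("n_planted cannot exceed n_snps")
        if self.n_control_files < 1 or self.n_case_files < 1:
            raise ValueError("both cohorts need at least one file")


@dataclass(frozen=True, slots=True)
class SiteTruth:
    chrom: int
    pos: int
    id: str
    ref: str
    alt: str
    planted: bool
    p_ctrl: float
    p_case: float
    expected_n_ctrl: float
    expected_n_case: float
    expected_statistic: float


def truth_statistic(
    p_ctrl: float,
    p_case: float,
    n_control_files: int,
    n_case_files: int,
    hom_fraction: float,
) -> float:
    """Chi-square statistic at the analytically expected presence counts.

    A carried site contributes 1 + hom_fraction in expectation
    (heterozygous 1, homozygous 2), so E[n] = files * p * (1 + h).
    Monotone in |p_case - p_ctrl| for fixed margins.
    """
    per_file = 1.0 + hom_fraction
    return chi2_statistic(
        n_control_files * p_ctrl * per_file,
        n_case_files * p_case * per_file,
        2 * n_control_files,
        2 * n_case_files,
    )


def _make_template(
    config: SynthConfig, rng: np.random.Generator
) -> tuple[list[SnpRecord], np.ndarray]:
    """Shared site template: sorted loci on chromosomes 1-22, unique rs ids."""
    n = config.n_snps
    chroms = np.sort(rng.integers(1, 23, size=n))
    # strictly increasing positions within each chromosome
    pos = np.empty(n, dtype=np.int64)
    for c in range(1, 23):
        sel = chroms == c
        gaps = rng.integers(1, 10_000, size=int(sel.sum()))
        pos[sel] = np.cumsum(gaps) + int(rng.integers(1, 1_000_000))
    rs_numbers = np.cumsum(rng.integers(1, 1_000, size=n)) + 1
    pair_codes = rng.integers(0, len(REFALT_PAIRS), size=n)
    sites = []
    for i in range(n):
        ref, alt = REFALT_PAIRS[int(pair_codes[i])]
        sites.append(
            SnpRecord(
                int(chroms[i]),
                int(pos[i]),
                f"rs{int(rs_numbers[i])}",
                ref,
                alt,
                Zygosity.HETEROZYGOUS,  # placeholder; drawn per file
            )
        )
    planted = np.zeros(n, dtype=bool)
    planted[rng.choice(n, size=config.n_planted, replace=False)] = True
    return sites, planted


def generate_cohort(
    config: SynthConfig, out_dir: str | os.PathLike
) -> tuple[Path, list[SiteTruth]]:
    """Write the cohort; returns (manifest path, per-site truth table).

    Output is fully determined by ``config.seed``: the same
    configuration produces byte-identical files.  Also writes
    ``truth.tsv`` next to the manifest.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    sites, planted = _make_template(config, rng)
    n = config.n_snps

    p_site = {
        "control": np.where(
            planted, config.carrier_prob_control, config.background_prob
        ),
        "case": np.where(planted, config.carrier_prob_case, config.background_prob),
    }

    manifest_lines = []
    cohorts = [
        ("control", "ctrl", config.n_control_files),
        ("case", "case", config.n_case_files),
    ]
    for label, prefix, n_files in cohorts:
        probs = p_site[label]
        for fi in range(n_files):
            carried = rng.random(n) < probs
            hom = rng.random(n) < config.hom_fraction
            records = [
                replace(
                    sites[i],
                    zygosity=Zygosity.HOMOZYGOUS if hom[i] else Zygosity.HETEROZYGOUS,
                )
                for i in np.flatnonzero(carried)
            ]
            name = f"{prefix}_{fi:04d}.vcf"
            with open(out / name, "wt", encoding="utf-8") as fh:
                write_vcf(records, fh, meta=[f"synthetic cohort file {name}"])
            manifest_lines.append(f"{name}\t{label}")

    manifest_path = out / "manifest.tsv"
    manifest_path.write_text("\n".join(manifest_lines) + "\n", encoding="utf-8")

    truth: list[SiteTruth] = []
    for i, site in enumerate(sites):
        pc = float(p_site["control"][i])
        pk = float(p_site["case"][i])
        per_file = 1.0 + config.hom_fraction
        truth.append(
            SiteTruth(
                site.chrom,
                site.pos,
                site.id,
                site.ref,
                site.alt,
                bool(planted[i]),
                pc,
                pk,
                config.n_control_files * pc * per_file,
                config.n_case_files * pk * per_file,
                truth_statistic(
                    pc,
                    pk,
                    config.n_control_files,
                    config.n_case_files,
                    config.hom_fraction,
                ),
            )
        )
    _write_truth(out / "truth.tsv", truth)
    return manifest_path, truth


def _write_truth(path: Path, truth: list[SiteTruth]) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(
            "chrom\tpos\tid\tref\talt\tplanted\tp_ctrl\tp_case\t"
            "expected_n_ctrl\texpected_n_case\texpected_statistic\n"
        )
        for s in truth:
            fh.write(
                f"{s.chrom}\t{s.pos}\t{s.id}\t{s.ref}\t{s.alt}\t"
                f"{int(s.planted)}\t{s.p_ctrl:g}\t{s.p_case:g}\t"
                f"{s.expected_n_ctrl:.6g}\t{s.expected_n_case:.6g}\t"
                f"{s.expected_statistic:.9g}\n"
            )
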