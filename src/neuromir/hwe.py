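"""X-linked Hardy-Weinberg equilibrium chi-square test with hemizygous males.

For a biallelic X-linked SNP, females carry two alleles (genotypes AA/AG/GG)
while males are hemizygous (single-allele classes A and G).  Under
Hardy-Weinberg equilibrium with a single pooled allele frequency q for the G
allele, female genotypes are expected in proportions (p^2, 2pq, q^2) and male
classes in proportions (p, q), with p = 1 - q.  The test statistic is the
Pearson chi-square over the five cells; the degrees of freedom are
(3 - 1) + (2 - 1) - 1 = 2, one being spent on estimating q from the pooled
sample.  The statistic jointly tests female-genotype HWE and male-female
allele-frequency homogeneity.

The packaged worked example is an ADNI-style genotype table for a SNP
upstream of an X-chromosome miRNA gene: females 229 AA / 24 AG / 1 GG, males
312 A / 14 G (580 subjects), which gives chi2 = 0.510 and p = 0.775.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import ComputationError, ValidationError


@dataclass(frozen=True)
class XGenotypeCounts:
    """Genotype counts for one biallelic X-linked SNP.

    Females are diploid (AA/AG/GG); males are hemizygous (A/G).
    """

    n_AA: int
    n_AG: int
    n_GG: int
    n_A: int
    n_G: int

    def __post_init__(self):
        for name in ("n_AA", "n_AG", "n_GG", "n_A", "n_G"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValidationError(f"{name}={v!r} must be a nonnegative integer")
        if self.total_subjects == 0:
            raise ValidationError("all genotype counts are zero")

    @property
    def n_female(self) -> int:
        return self.n_AA + self.n_AG + self.n_GG

    @property
    def n_male(self) -> int:
        return self.n_A + self.n_G

    @property
    def total_subjects(self) -> int:
        return self.n_female + self.n_male

    @property
    def total_alleles(self) -> int:
        return 2 * self.n_female + self.n_male

    def swap_labels(self) -> "XGenotypeCounts":
        """Relabel A <-> G (AA<->GG, A<->G); AG is label-symmetric."""
        return XGenotypeCounts(self.n_GG, self.n_AG, self.n_AA,
                               self.n_G, self.n_A)


#: The packaged worked example: genotype counts of an ADNI-style cohort for
#: the X-linked SNP analysis (females AA/AG/GG = 229/24/1, males A/G = 312/14).
EXAMPLE_SNP_COUNTS = XGenotypeCounts(n_AA=229, n_AG=24, n_GG=1,
                                     n_A=312, n_G=14)


def pooled_allele_frequency(counts: XGenotypeCounts) -> tuple[float, float]:
    """Pooled (p_hat, q_hat) allele frequencies over both sexes.

    q counts the G allele: q_hat = (n_AG + 2 n_GG + n_G) / total alleles.
    """
    total = counts.total_alleles
    if total == 0:
        raise ValidationError("no alleles observed")
    q_hat = (counts.n_AG + 2 * counts.n_GG + counts.n_G) / total
    return 1.0 - q_hat, q_hat


@dataclass(frozen=True)
class HweXResult:
    """Outcome of the X-linked HWE chi-square test."""

    q_hat: float
    chi2: float
    df: int
    p: float
    expected: dict[str, float]
    minor_allele: str
    small_expected_cells: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "q_hat": self.q_hat,
            "chi2": self.chi2,
            "df": self.df,
            "p": self.p,
            "minor_allele": self.minor_allele,
            "expected": dict(self.expected),
            "small_expected_cells": list(self.small_expected_cells),
        }


def hwe_x_chisq(counts: XGenotypeCounts) -> HweXResult:
    """Pearson chi-square test of X-linked HWE (df = 2, pooled frequency).

    Expected female counts are n_female * (p^2, 2pq, q^2) and expected male
    counts n_male * (p, q) at the pooled estimate.  No continuity correction
    is applied.  Expected cells below 5 are flagged (the chi-square
    approximation weakens); an expected cell of exactly zero is an error
    (an exact test would be needed; none is provided).
    """
    if counts.n_female < 1 or counts.n_male < 1:
        raise ValidationError("need at least one female and one male subject")
    p_hat, q_hat = pooled_allele_frequency(counts)
    nf, nm = counts.n_female, counts.n_male
    expected = {
        "AA": nf * p_hat ** 2,
        "AG": nf * 2 * p_hat * q_hat,
        "GG": nf * q_hat ** 2,
        "A": nm * p_hat,
        "G": nm * q_hat,
    }
    observed = {"AA": counts.n_AA, "AG": counts.n_AG, "GG": counts.n_GG,
                "A": counts.n_A, "G": counts.n_G}
    if any(e == 0.0 for e in expected.values()):
        raise ComputationError(
            "an expected genotype count is zero (monomorphic sample); the "
            "chi-square test is undefined — an exact test would be required")
    chi2 = sum((observed[k] - expected[k]) ** 2 / expected[k] for k in expected)
    df = 2
    small = tuple(k for k, e in expected.items() if e < 5.0)
    return HweXResult(
        q_hat=q_hat,
        chi2=float(chi2),
        df=df,
        p=float(stats.chi2.sf(chi2, df)),
        expected=expected,
        minor_allele="G" if q_hat <= 0.5 else "A",
        small_expected_cells=small,
    )
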