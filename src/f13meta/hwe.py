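"""Hardy-Weinberg equilibrium goodness-of-fit test for biallelic genotypes.

The chi-square statistic compares observed genotype counts (VV, VL, LL)
with the counts expected at the sample's own allele frequency,
``n*(1-q)^2, 2n*q*(1-q), n*q^2`` with ``q`` the Leu-allele frequency.
One degree of freedom (three genotype classes, minus one, minus one
estimated allele frequency); no Yates continuity correction. Control-group
departure from HWE flags possible genotyping or sampling problems.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

ALPHA = 0.05


@dataclass(frozen=True)
class HweResult:
    chi2: float
    p_value: float
    allele_freq_leu: float
    monomorphic: bool = False

    @property
    def in_equilibrium(self) -> bool:
        """True when the test does not reject at the 0.05 level."""
        return self.p_value > ALPHA


def hwe_chi_square(vv: int, vl: int, ll: int) -> HweResult:
    """Test genotype counts for Hardy-Weinberg equilibrium (df=1).

    A monomorphic sample (Leu frequency 0 or 1) fits HWE trivially and is
    returned as chi2=0, p=1 with the ``monomorphic`` flag set.
    """
    if min(vv, vl, ll) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = vv + vl + ll
    if n < 1:
        raise ValueError("at least one genotyped individual required")
    q = (2 * ll + vl) / (2 * n)
    if q == 0.0 or q == 1.0:
        return HweResult(chi2=0.0, p_value=1.0, allele_freq_leu=q, monomorphic=True)
    expected = (n * (1 - q) ** 2, 2 * n * q * (1 - q), n * q ** 2)
    chi2 = sum((o - e) ** 2 / e for o, e in zip((vv, vl, ll), expected))
    p = float(stats.chi2.sf(chi2, df=1))
    return HweResult(chi2=float(chi2), p_value=p, allele_freq_leu=q)
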