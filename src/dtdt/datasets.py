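"""Small published reference datasets used in examples and regression checks.

The alcohol-dependence family study (COGA) that motivated the dTDT reported a
table of its 30 top-ranked SNPs by Mantel-Haenszel p-value, pooling a
case-control allele test (847 cases, 552 controls) with the dTDT on 893
inferred trios.  The MH p-value column of that table is reproduced here so
that its summary statistics (mean 5.04e-6, sample variance 9.09e-12) can be
recomputed without access to the restricted genotype data.  After Bonferroni
correction over the 19 experimentally re-genotyped markers (0.05/19 ≈ 0.0026),
one SNP, rs4903712 on chromosome 14, remained significant.
"""

from __future__ import annotations

from typing import Dict, Tuple

__all__ = [
    "COGA_TOP30_MH_PVALUES",
    "COGA_N_CASES",
    "COGA_N_CONTROLS",
    "COGA_N_VALIDATED_MARKERS",
]

# sample sizes of the two pooled strata in the COGA application
COGA_N_CASES = 847
COGA_N_CONTROLS = 552

# number of top markers taken forward to experimental validation genotyping
COGA_N_VALIDATED_MARKERS = 19

# MH-test p-values of the 30 top-ranked SNPs (SNP id -> p-value)
COGA_TOP30_MH_PVALUES: Dict[str, float] = {
    "rs12116935": 6.98e-06,
    "rs11583322": 1.10e-08,
    "rs1932933": 5.82e-06,
    "rs10801629": 4.13e-06,
    "rs10922323": 6.46e-06,
    "rs1850344": 8.16e-06,
    "rs4384980": 5.78e-07,
    "rs2857839": 6.60e-06,
    "rs1801058": 6.48e-06,
    "rs2798303": 1.28e-06,
    "rs994029": 1.98e-07,
    "rs2398236": 9.07e-06,
    "rs9423593": 8.32e-06,
    "rs7076488": 2.13e-06,
    "rs3781458": 4.27e-06,
    "rs3781452": 6.86e-06,
    "rs1503452": 3.21e-06,
    "rs3924047": 8.77e-06,
    "rs4356270": 8.42e-06,
    "rs12427267": 6.00e-07,
    "rs11106345": 7.22e-06,
    "rs10848190": 5.43e-06,
    "rs1035717": 6.36e-06,
    "rs4903712": 1.67e-06,
    "rs17754467": 5.54e-07,
    "rs1568447": 4.08e-06,
    "rs9901283": 9.31e-06,
    "rs11652088": 3.50e-06,
    "rs8111589": 8.27e-06,
    "rs2830045": 6.31e-06,
}
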