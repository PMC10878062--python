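"""Phenotype computations: GSI, comparative-Ct expression, group tests.

Shows the three statistical building blocks on small worked inputs: the
gonadosomatic index for a maturing vs an immature male, a comparative-Ct
(2^-ddCt) fold change, a small-sample exact Mann-Whitney comparison, and
the genotype-by-maturity tally of the bundled F1 cohort. The maturity
table is the study's key contrast: every fish with two frameshift
alleles stayed immature while most wild-type-class fish matured.
"""

from crispamp import compare_groups, gsi, maturity_by_genotype, relative_expression
from crispamp.datasets import load_f1_phenotypes

print("GSI of a maturing male (gonads 6 g, body 100 g):", gsi(6, 100), "%")
print("GSI of an immature male (gonads 0.08 g, body 95 g):",
      round(gsi(0.08, 95), 3), "%")

fold = relative_expression(ct_target=25.0, ct_ref=20.0, calibrator_dct=7.0)
print(f"\n2^-ddCt fold change for dCt=5 vs calibrator dCt=7: {fold:.1f}x")

res = compare_groups({"immature": [0.04, 0.06, 0.09, 0.05], "mature": [4.2, 6.1, 5.5, 7.0]})
print(f"\nGSI comparison ({res.test}): U={res.statistic:.1f}, p={res.p_value:.4f}, "
      f"significant={res.significant}")

print("\nmaturity by recorded genotype (bundled cohort):")
tally = maturity_by_genotype(load_f1_phenotypes())
print(tally.to_string(index=False))
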