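"""Quantify the excess of clustered variants at the study's own scale.

Randomizes 134 variants over 61,165 bp and 30 branches (1,000 replicates),
takes the mean clustered count as the Poisson rate, and evaluates the upper
tail of the observed 25 clustered variants.
"""

from ltrconv import permutation_null, poisson_tail_log10_p

null = permutation_null(n_variants=134, L=61165, n_branches=30,
                        reps=1000, max_gap=50, seed=7)
log10p = poisson_tail_log10_p(25, null.lam)
print(f"lambda (mean clustered variants under the null) = {null.lam:.3f}")
print(f"P(X >= 25 | Poisson(lambda)) = 1e{log10p:.1f}")
print("under random mutation alone, about one variant per dataset would sit "
      "in a cluster; observing 25 is astronomically unlikely, pointing to "
      "gene conversion planting several variants per event")
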