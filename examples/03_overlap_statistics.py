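"""The two headline overlap statistics, computed from their published inputs.

1. Fisher's exact test for whether significantly interacting capture-region
   bins preferentially overlap the strongest disease-association signals:
   366 mapability-passing test bins, 88 overlapping low association P values,
   61 significant bins of which 23 overlap.

2. The combinatorial test for the three-cell-line intersection of significant
   contacts: 147 shared contacts among per-line call sets of ~2x10^5 drawn
   from universes of ~10^8 testable bin pairs.
"""

from chicflow import association_overlap_test, combinatorial_overlap_pvalue

p, odds = association_overlap_test(
    all_bins=366, overlap_bins=88, sig_bins=61, sig_overlap_bins=23
)
print(f"association overlap: odds ratio {odds:.2f}, two-sided Fisher P = {p:.3g}")
print("  -> significant bins overlap strong association signals ~2.2x more often\n")

res = combinatorial_overlap_pvalue(
    k=147,
    n=(216379, 177893, 217396),
    N=(97376960, 95608750, 92912739),
)
print(f"three-library intersection: {res.report} "
      f"(log10 P = {res.log10_pvalue:.1f})")
print("  -> 147 shared contacts could not arise from independent random call sets")
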