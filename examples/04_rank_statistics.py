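"""Rank-based comparison of optimizers from a results table.

Loads the packaged reference table (mean results of eight metaheuristics
over the ten-function suite, 30 runs each, minimization) and computes
Friedman mean ranks, the final ordering, and a pairwise Wilcoxon
rank-sum test between the two related optimizers in the field.
"""

from msar import friedman_mean_ranks, load_reference_means, wilcoxon_rank_sum

matrix = load_reference_means()
fr = friedman_mean_ranks(matrix)

print("algorithm   mean rank   final rank")
for name, mean_rank, order in zip(fr.algorithms, fr.mean_ranks, fr.final_order):
    print(f"  {name:6s}     {mean_rank:5.2f}        {order}")
print(f"Friedman chi-square = {fr.chi_square:.3f}, p = {fr.p_value:.2e}")

i, j = fr.algorithms.index("SAR"), fr.algorithms.index("mSAR")
p, h = wilcoxon_rank_sum(matrix.values[:, i], matrix.values[:, j])
print(f"Wilcoxon rank-sum SAR vs mSAR: p = {p:.4f}, H = {h}")

# A mean rank of 2.40 across ten problems puts mSAR first overall; the
# Friedman p-value tests whether the eight algorithms differ at all,
# while the Wilcoxon H flags whether the two-sample difference between
# per-function means is significant at alpha = 0.05.
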