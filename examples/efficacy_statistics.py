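"""Clinical efficacy statistics for a two-arm treatment comparison.

Computes total effective rates from per-arm outcome counts and tests the
difference with the collapsed 2x2 chi-square.
"""

from lgcw import EfficacyCounts, chi_square_2x2, total_effective_rate

control = EfficacyCounts(markedly_effective=20, effective=32, ineffective=16)
experimental = EfficacyCounts(markedly_effective=29, effective=34, ineffective=5)

for name, counts in [("control", control), ("experimental", experimental)]:
    print(f"{name:13s} total effective rate: {total_effective_rate(counts):.2f}%")

stat, p = chi_square_2x2([experimental.collapsed(), control.collapsed()])
print(f"chi2 = {stat:.3f}, p = {p:.4f}")
# p < 0.05: the experimental arm's higher effective rate is statistically
# significant at the conventional level
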