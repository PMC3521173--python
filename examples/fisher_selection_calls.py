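"""Per-enhancer selection classification with Fisher's exact test.

Each enhancer contributes a 2x2 table of substituted vs unsubstituted sites,
for itself and for the neutral reference (fourfold/intron sites of the nearest
orthologous gene). A significant excess of substitutions means positive
selection; a deficit means purifying selection.
"""

from enhscan import fisher_classify

cases = [
    ("balanced", (10, 100), (10, 100)),
    ("accelerated", (30, 100), (10, 100)),
    ("constrained", (1, 100), (20, 100)),
    ("large neutral reference", (220, 1400), (150, 1400)),
]
for label, enh, neut in cases:
    call = fisher_classify(enh, neut, alpha=0.05)
    print(
        f"{label:<24} enhancer {enh[0]:>3}/{enh[1]:<5} neutral {neut[0]:>3}/{neut[1]:<5}"
        f" p = {call.p_value:.3g}  ->  {call.call}"
    )
print()
print("p is the exact two-sided hypergeometric tail; 'neutral' means the")
print("neutral model cannot be rejected at alpha = 0.05.")
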