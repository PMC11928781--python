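"""Worked example: multiplicity correction can raise the false discovery rate.

Two constructed sets of ten tests (4 true effects, 6 nulls) with identical
behaviour at the raw threshold 0.05 — six discoveries, two of them false,
FDR 1/3. Bonferroni correction (0.05/10 = 0.005) drops the FDR to 0 in one
scenario and raises it to 1 in the other: which happens depends on the
unknown mix of true and false positives, which the correction cannot see.
"""

from compatint import bonferroni_threshold, empirical_fdr, figure4_fixtures

scenario_a, scenario_b = figure4_fixtures()
threshold = bonferroni_threshold(0.05, 10)
print(f"Bonferroni threshold for 10 tests: {threshold:g}\n")

for name, pset in (("scenario A", scenario_a), ("scenario B", scenario_b)):
    raw = empirical_fdr(pset, 0.05)
    adj = empirical_fdr(pset, threshold)
    print(f"{name}:")
    print(
        f"  at 0.05:  {raw.n_significant} significant, "
        f"{raw.n_false_positive} false -> FDR = {raw.fdr:.3g}"
    )
    fdr = "undefined" if adj.fdr is None else f"{adj.fdr:.3g}"
    print(
        f"  at 0.005: {adj.n_significant} significant, "
        f"{adj.n_false_positive} false -> FDR = {fdr}"
    )
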