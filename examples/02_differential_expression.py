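"""Two-library contrast with the Audic-Claverie count test.

Counts two small libraries, excludes singlets, normalises to tags per
million and classifies each unitag as UR (induced), DR (repressed) or ns
at p <= 0.05, with the signed fold-change convention (negative = repressed,
zero frequencies replaced by one).
"""

from supersage import UnitagTable, exclude_singlets, normalize_tpm, run_contrast

t = ["CATG" + s * 22 for s in "ACGT"]  # four distinct unitags

stress = normalize_tpm(
    exclude_singlets(UnitagTable("TS", {t[0]: 80, t[1]: 10, t[2]: 40, t[3]: 1}))
)
control = normalize_tpm(
    exclude_singlets(UnitagTable("TC", {t[0]: 10, t[1]: 12, t[2]: 40}))
)

result, summary = run_contrast(stress, control, alpha=0.05)
print(result[["tag", "count_A", "count_B", "p_value", "fold_change", "regulation"]]
      .to_string(index=False))
print()
print("summary:", summary)
print()
print("The first tag is induced (UR). Fold changes are ratios of normalised")
print("frequencies, so the third tag (40 vs 40 raw counts) is repressed once")
print("library size is accounted for. The count-1 tag was excluded as a")
print("singlet before testing.")
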