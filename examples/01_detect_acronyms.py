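"""Classify tokens with the half-upper-case acronym rule.

Builds a handful of tokens and a full sentence, runs the detector, and
prints each verdict with the character arithmetic behind it.
"""

from acrotrend import classify, count_acronyms, is_acronym

for surface in ["mRNA", "BRCA1", "N95", "laser", "DNA", "CD4", "HC-MVECs"]:
    n_upper = sum(c.isupper() for c in surface)
    verdict = classify(surface)
    kind = verdict.kind.value if verdict else "not an acronym"
    print(f"{surface:>10}: {n_upper}/{len(surface)} upper-case -> "
          f"{is_acronym(surface)} ({kind})")

sentence = ("Toward this goal, the CNNT, the CRN, and the CNSW will each "
            "propose programs to the NKF for improving the knowledge and "
            "skills of the professionals within these councils.")
s = count_acronyms(sentence)
print(f"\nsentence: {s.n_acronym_tokens} acronyms in {s.n_words} words "
      f"({s.density_per_100_words:.1f} per 100 words): {s.surfaces}")
# A token is an acronym when at least half of its characters are
# upper-case letters and it is at least two characters long; digits
# count in the denominator, which is why N95 (1/3) fails.
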