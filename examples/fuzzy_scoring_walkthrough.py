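"""Follow one measurement through the fuzzy scoring chain.

A hardness reading (a cost criterion: firmer rice is worse) is min-max
mapped onto the 0-10 fuzzy scale with the reversed transform, fuzzified
into the six triangular grades A-F, weighted by its per-datum share of
the criterion weight, and the resulting index score is defuzzified back
to a number on the same scale.
"""

import famrank as fr

# pooled hardness range across all conditions: 24 N (best) to 36 N (worst)
bounds = fr.ScaleBounds("hardness", a=24.0, b=36.0)
reading = 27.0  # N, one texture-analyzer replicate

score = fr.fuzzy_scale(reading, bounds, direction="cost")
print(f"hardness {reading} N on pooled range [{bounds.a}, {bounds.b}] N")
print(f"fuzzy score (reverse transform): {score:.3f}  (10 = softest observed)")

memberships = fr.grade_memberships(score)
for label, mu in zip("ABCDEF", memberships):
    if mu > 0:
        print(f"  grade {label}: membership {mu:.3f}")

hardness = fr.CriterionSpec("hardness", "physical", weight=10.0, direction="cost")
share = fr.per_datum_weight(hardness, n_data=3)  # 3 replicates split weight 10
print(f"per-datum weight share: {share:.4f} (criterion weight 10 over 3 replicates)")

iscore = fr.index_score(memberships, share)
print(f"index score masses (A..F): {iscore.masses.round(4)}")
print(f"defuzzified back: {fr.defuzzify(iscore):.3f}  (= the fuzzy score: the default")
print("grade set is an exact interpolation basis, so one datum round-trips)")
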