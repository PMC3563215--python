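"""Score domain predictions with the NDO measure.

Shows the worked merged-domain case (two true domains predicted as one) and
how stable-marriage label matching repairs an arbitrary relabeling.
"""

from domaincut import ndo_score, parse_chopping

reference = parse_chopping("1-50/51-100", 100)
merged = parse_chopping("1-100", 100)
for variant in ("balanced", "fraction"):
    r = ndo_score(reference, merged, variant=variant)
    print(f"merged prediction, {variant}: score={r.score:.0f} (M={r.M}, l={r.l})")
# balanced = 100*(2M-l)/l punishes the 50 mislabeled residues down to 0;
# fraction = 100*M/l reports the plain 50% agreement.

# a short spurious N-terminal segment makes the predicted big domain
# discontinuous: its first residue is 1, so it receives label 1 even though
# it is really the reference's domain 2. The matching swaps the labels back
# instead of charging 50 mislabeled residues.
ref2 = parse_chopping("1-10/11-100", 100)
discontinuous = parse_chopping("1-2,11-100/3-10", 100)
r = ndo_score(ref2, discontinuous, variant="balanced")
print(f"discontinuous prediction: score={r.score:.0f}, matching={r.matching}")
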