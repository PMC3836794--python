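"""Mantel isolation-by-distance tests on the published blackcap survey.

Uses the packaged 12-site pairwise genetic-distance matrix and coordinates to
rerun the Mantel tests over all sites and over the eastern/western subsets of
the 13 degrees E migratory divide.
"""
from migradiv import blackcap_differentiation, blackcap_metadata, geo_distances, mantel_test
from migradiv.differentiation import slatkin_matrix
from migradiv.spatial import split_by_divide

metadata = blackcap_metadata()
dest, _ = blackcap_differentiation()
distance = slatkin_matrix(dest)

west, east = split_by_divide(metadata, 13.0)
for name, codes in [("all 12", [m.code for m in metadata]), ("east of divide", east),
                    ("west of divide", west)]:
    md = [m for m in metadata if m.code in codes]
    res = mantel_test(distance.submatrix(codes), geo_distances(md),
                      permutations=10_000, seed=7)
    print(f"{name:15s}  r = {res.r: .3f}   p = {res.p:.4f}")
# Strong, significant IBD among the eastern (SE-migrating) populations;
# no significant IBD among the western (NW/SW) populations — the published
# east/west contrast in how genetic distance scales with geography.
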