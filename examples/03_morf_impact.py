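"""Detect alpha-MoRF candidates and the impact of a mutation on them.

A MoRF candidate is a short ordered stretch (5-25 residues) flanked on both
sides by at least 10 disordered residues. A mutation's impact compares MoRFs
overlapping the mutated position before and after the substitution:
lost / gained / present_no_change / absent.
"""

from disomut import (
    MutationRecord,
    PropensityPredictor,
    ProteinRecord,
    classify_morf_impact,
    scan_candidates,
)

# 24 disordered residues, a 7-residue order-prone island, 24 more disordered
protein = ProteinRecord("demo", "PEPSKEPSSKEPEPSKEPEPSKEP" + "WWFYLIV" + "PEPSKEPSSKEPEPSKEPEPSKEP")
predictor = PropensityPredictor(window=7)  # short window resolves the island

wt_profile = predictor.predict(protein)
wt_morfs = scan_candidates(wt_profile, min_flank=10)
print("wild-type MoRF candidates:", [(r.start, r.end) for r in wt_morfs])

# W25P melts the island: tryptophan -> proline destroys the ordered stretch
mutation = MutationRecord("demo", 25, "W", "P")
mut_profile = predictor.predict_mutant(protein, mutation)
mut_morfs = scan_candidates(mut_profile, min_flank=10)
print("mutant MoRF candidates  :", [(r.start, r.end) for r in mut_morfs])

impact = classify_morf_impact(wt_morfs, mut_morfs, mutation.position)
print("impact of W25P at position 25:", impact)
# "lost" means a MoRF overlapped the site in the wild type but none does in
# the mutant - the binding-competent element is predicted to be destroyed.
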