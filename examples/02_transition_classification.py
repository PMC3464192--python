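"""Classify missense mutations by order/disorder transition.

Each mutation is rescored on the full mutant sequence; the class (D->O,
O->D, D->D, O->O) depends only on whether the mutated residue's score
crosses the 0.5 threshold, and delta_ps = ps(wild type) - ps(mutant).
"""

from disomut import (
    MutationRecord,
    PropensityPredictor,
    ProteinRecord,
    classify_dataset,
)

# an arginine sitting in a marginally disordered context: hydrophobic
# neighbours pull the windowed score down to just above the 0.5 threshold
protein = ProteinRecord("demo", "PEPSKEPSSKEP" + "LIVLIVL" + "R" + "LVILVIL" + "PEPSKEPSSKEP")
# R20W swaps in strongly order-promoting tryptophan; R20K swaps in lysine,
# which is itself disorder-promoting
mutations = [
    MutationRecord("demo", 20, "R", "W", "DM"),
    MutationRecord("demo", 20, "R", "K", "Poly"),
]

result = classify_dataset(mutations, [protein], PropensityPredictor())
for call in result.calls:
    m = call.mutation
    print(
        f"{m.wt_aa}{m.position}{m.mut_aa} ({m.dataset}): "
        f"wt_ps={call.wt_ps:.3f} mut_ps={call.mut_ps:.3f} "
        f"class={call.klass} delta_ps={call.delta_ps:+.3f}"
    )
# A positive delta_ps means the mutation pushed the site toward order; only
# the R->W substitution flips the call, giving a D->O transition.
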