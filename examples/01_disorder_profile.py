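"""Score a sequence for intrinsic disorder and call ordered/disordered regions.

The built-in predictor averages TOP-IDP disorder propensities over a sliding
window and squashes the result through a logistic, giving a per-residue score
ps in [0, 1]; ps >= 0.5 calls the residue disordered.
"""

from disomut import PropensityPredictor, disorder_content

# an order-prone core (hydrophobic) flanked by disorder-prone stretches (P/E/S/K)
sequence = "PEPSKEPSSKEPEPSKE" + "WFYLIVMWFYLIVMWFYLIVM" + "EKSPEPSSKEPEPSKEP"

predictor = PropensityPredictor()  # TOP-IDP scale, window 21, steepness 8
profile = predictor.predict_sequence(sequence, "demo")

print(f"sequence length      : {len(sequence)}")
print(f"disorder content     : {disorder_content(profile):.2f}")
print(f"ps at residue 5      : {profile[4]:.3f}  (disordered flank)")
print(f"ps at residue 27     : {profile[26]:.3f}  (ordered core)")
# The flank scores sit near 1 (strong disorder), the hydrophobic core falls
# below 0.5; disorder content is the fraction of residues called disordered.
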