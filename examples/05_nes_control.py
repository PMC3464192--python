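"""Build a neutral-evolutionary-substitution (NES) control from orthologs.

Close orthologs (>= 95% identity) of a disease protein are globally aligned
(BLOSUM85, affine gaps); every aligned residue difference becomes a
pseudo-mutation at the human coordinate, minus anything that coincides with
an annotated disease mutation.
"""

from disomut import MutationRecord, ProteinRecord, extract_nes

human = ProteinRecord("TP63_demo", "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSG")

orthologs = {
    # one difference each (98% identity): both qualify
    "chimp": human.sequence[:9] + "K" + human.sequence[10:],
    "mouse": human.sequence[:29] + "T" + human.sequence[30:],
    # a distant paralog-like sequence (< 95% identity): excluded
    "distant": "MKTAYIWKQRQIWFVKWHFWRQLEWRLGLIWVQAPILWRVGDGTQDNLWG",
}

# suppose R10K is already annotated as a disease mutation: it must not leak
# into the neutral control
disease = [MutationRecord("TP63_demo", 10, "R", "K", "DM")]

records = extract_nes(human, orthologs=orthologs, disease_mutations=disease)
for r in records:
    print(f"NES pseudo-mutation: {r.wt_aa}{r.position}{r.mut_aa} (from ortholog)")
print(f"total: {len(records)} record(s)")
# Only the mouse difference survives: the chimp difference equals an
# annotated disease mutation and the distant sequence fails the identity bar.
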