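"""Enrichment statistics on published-scale count tables.

Using the published disease (DM), polymorphism (Poly) and neutral
evolutionary substitution (NES) tallies as inputs, recompute the D->O
enrichment: two-sided Fisher exact P, fold difference with a delta-method
standard error, and Bonferroni correction.
"""

from disomut import bonferroni, fisher_exact_2x2, fold_difference

# rows: [D->O, D->D] counts among mutations at disordered wild-type sites
DM = [670, 2686]
POLY = [1125, 8665]
NES = [1971, 24956]

tables = {"DM vs Poly": [DM, POLY], "DM vs NES": [DM, NES]}
raw = {name: fisher_exact_2x2(t) for name, t in tables.items()}
adjusted = dict(zip(tables, bonferroni(list(raw.values()))))

for name, table in tables.items():
    fold, se = fold_difference(table)
    print(
        f"{name}: fold={fold:.2f} +/- {se:.2f}, "
        f"P={raw[name]:.3g}, Bonferroni P={adjusted[name]:.3g}"
    )
# Disease mutations at disordered sites convert to order ~1.7x more often
# than polymorphisms and ~2.7x more often than neutral substitutions, at
# overwhelming significance - the study's central enrichment result.
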