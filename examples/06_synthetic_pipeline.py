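"""Run the full pipeline on a synthetic study and recover planted truth.

The generator builds block-architecture proteins, plants D->O transitions
at known per-site probabilities in two datasets (20% vs 10%), and adds a
zero-planting baseline arm that measures the accidental flip rate. The
pipeline should recover the planted fold of 2.0.
"""

from disomut import PropensityPredictor, SimConfig, classify_dataset
from disomut.simulate import gen_mutations, gen_proteins

config = SimConfig(
    n_proteins=40,
    mutations_per_dataset={"A": 3000, "B": 3000, "base": 3000},
    p_do={"A": 0.2, "B": 0.1, "base": 0.0},
    p_od={"A": 0.0, "B": 0.0, "base": 0.0},
    seed=4,
)
synthetic = gen_proteins(config)
mutations = gen_mutations(synthetic, config)
all_mutations = [m for records in mutations.datasets.values() for m in records]
counts = classify_dataset(
    all_mutations, synthetic.proteins, PropensityPredictor()
).counts()
print(counts)


def do_share(ds):
    do, dd = counts.loc[ds, "D->O"], counts.loc[ds, "D->D"]
    return do / (do + dd)


baseline = do_share("base")
p_a = (do_share("A") - baseline) / (1 - baseline)
p_b = (do_share("B") - baseline) / (1 - baseline)
print(f"accidental flip baseline : {baseline:.3f}")
print(f"recovered planted rates  : A={p_a:.3f}  B={p_b:.3f}")
print(f"recovered fold (true 2.0): {p_a / p_b:.2f}")
# After subtracting the measured accidental baseline, the D->O rate ratio
# between the two arms estimates the planted 2-fold enrichment.
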