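"""Synthetic ground-truth data with the statistical structure the analysis
assumes.

Proteins are built from alternating ordered/disordered blocks with
geometrically distributed lengths; block residues are drawn with probability
proportional to exp(±β·z), where z is the standardized disorder propensity
and the sign follows the block type, so disordered blocks are enriched in
disorder-promoting residues. Mutation datasets plant disorder-to-order (and
order-to-disorder) transitions at configured per-site probabilities by
rejection-sampling a mutant residue that flips the built-in predictor's call
at the site. Feature annotations are placed preferentially on disordered
blocks at configured odds. Every planting decision is recorded in a truth
table, and unplanted "accidental" call flips are a property of the data to
be measured (on a zero-probability run), not suppressed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .disorder import DISORDER_THRESHOLD, PropensityPredictor, PropensityScale
from .io import CANONICAL_AA, FeatureAnnotation, MutationRecord, ProteinRecord


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for the synthetic generator.

    Defaults emulate the structure of a disease/polymorphism/neutral
    three-dataset design: three mutation sets over one protein universe,
    with planted per-site transition probabilities matching the observed
    D→O shares (20%, 11.5%, 7.3% among IDR mutations) and O→D shares
    (4.9%, 4.9%, 5.6% among OR mutations) of the disease, polymorphism
    and neutral-substitution datasets.
    """

    n_proteins: int = 60
    length_min: int = 300
    length_max: int = 800
    mean_ordered_block: float = 40.0
    mean_disordered_block: float = 30.0
    beta: float = 1.0
    mutations_per_dataset: Mapping[str, int] = field(
        default_factory=lambda: {"DM": 5000, "Poly": 5000, "NES": 5000}
    )
    p_do: Mapping[str, float] = field(
        default_factory=lambda: {"DM": 0.20, "Poly": 0.115, "NES": 0.073}
    )
    p_od: Mapping[str, float] = field(
        default_factory=lambda: {"DM": 0.049, "Poly": 0.049, "NES": 0.056}
    )
    morf_density: float = 0.0  # planted MoRF dips per disordered block
    annotation_odds: float = 3.0  # disordered vs ordered placement odds
    annotation_tile: int = 10  # residues per annotation tile
    annotation_q_ordered: float = 0.05  # per-tile coverage prob in ordered blocks
    max_flip_retries: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        for mapping in (self.p_do, self.p_od):
            if any(not 0.0 <= p <= 1.0 for p in mapping.values()):
                raise ValueError("planted probabilities must be in [0, 1]")
        if self.length_min < 1 or self.length_max < self.length_min:
            raise ValueError("invalid length bounds")
        if self.beta < 0:
            raise ValueError("composition bias beta must be >= 0")


@dataclass
class SyntheticProteins:
    """Generated proteins with their true block labels (True = disordered)."""

    proteins: list[ProteinRecord]
    labels: dict[str, np.ndarray]
    morf_truth: list[tuple[str, int, int]]  # (protein_id, start, end) 1-based


def _block_weights(scale: PropensityScale, beta: float, disordered: bool):
    values = scale.encode(CANONICAL_AA)
    z = (values - values.mean()) / values.std()
    w = np.exp((beta if disordered else -beta) * z)
    return w / w.sum()


def gen_proteins(config: SimConfig, rng=None) -> SyntheticProteins:
    """Generate block-architecture proteins with true region labels."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    scale = PropensityScale.top_idp()
    residues = np.array(list(CANONICAL_AA))
    weights = {
        True: _block_weights(scale, config.beta, disordered=True),
        False: _block_weights(scale, config.beta, disordered=False),
    }
    order_first = scale.order_promoting_first()
    proteins, labels = [], {}
    morf_truth = []
    for i in range(config.n_proteins):
        pid = f"syn{i:04d}"
        length = int(rng.integers(config.length_min, config.length_max + 1))
        seq_parts: list[str] = []
        lab_parts: list[np.ndarray] = []
        disordered = bool(rng.integers(2))
        built = 0
        while built < length:
            mean = (
                config.mean_disordered_block
                if disordered
                else config.mean_ordered_block
            )
            block_len = min(int(rng.geometric(1.0 / mean)), length - built)
            block = rng.choice(residues, size=block_len, p=weights[disordered])
            if (
                disordered
                and config.morf_density > 0
                and block_len >= 30
                and rng.random() < config.morf_density
            ):
                # plant an order-prone dip with >=10-residue disordered margins
                dip_len = int(rng.integers(8, min(16, block_len - 20)))
                offset = int(rng.integers(10, block_len - dip_len - 10 + 1))
                dip = rng.choice(order_first[:6], size=dip_len)
                block[offset : offset + dip_len] = dip
                morf_truth.append(
                    (pid, built + offset + 1, built + offset + dip_len)
                )
            seq_parts.append("".join(block))
            lab_parts.append(np.full(block_len, disordered))
            built += block_len
            disordered = not disordered
        proteins.append(ProteinRecord(pid, "".join(seq_parts)))
        labels[pid] = np.concatenate(lab_parts)
    return SyntheticProteins(proteins, labels, morf_truth)


@dataclass
class SyntheticMutations:
    """Generated mutation datasets plus the per-mutation planting truth."""

    datasets: dict[str, list[MutationRecord]]
    truth: pd.DataFrame  # protein_id, position, wt_aa, mut_aa, dataset, intent
    n_unsatisfiable: int  # planted flips abandoned after max retries


def _try_flip(
    predictor: PropensityPredictor,
    values: np.ndarray,
    index: int,
    wt_aa: str,
    want_disordered: bool,
    rng,
) -> str | None:
    """A mutant residue that flips the call at ``index``; None if none can.

    The window average is monotone in the substituted propensity, so if the
    most extreme residue does not flip the call no residue will (fail fast);
    otherwise the mutant is drawn uniformly among all residues that flip.
    """
    scale = predictor.scale
    pool = scale.order_promoting_first()
    if want_disordered:
        pool = pool[::-1]  # most disorder-promoting first
    original = values[index]

    def flips(mut_aa: str) -> bool:
        values[index] = scale[mut_aa]
        ps = predictor.score_at(values, index)
        values[index] = original
        return (ps >= DISORDER_THRESHOLD) == want_disordered

    extreme = pool[0] if pool[0] != wt_aa else pool[1]
    if not flips(extreme):
        return None
    candidates = [aa for aa in pool if aa != wt_aa and flips(aa)]
    return candidates[int(rng.integers(len(candidates)))]


def gen_mutations(
    synthetic: SyntheticProteins,
    config: SimConfig,
    predictor: PropensityPredictor | None = None,
    rng=None,
) -> SyntheticMutations:
    """Generate mutation datasets with planted transition probabilities.

    Sites are sampled uniformly over residues. A site whose wild-type call
    is disordered is, with probability ``p_do[dataset]``, planted as a D→O
    transition: the wild-type residue is replaced by a more order-promoting
    residue, drawn uniformly among those that flip the predictor's call at
    the site. O→D planting is symmetric at ordered sites. Unplanted mutations receive a uniform random substitution, and
    may still flip the call by accident — that baseline is part of the
    data. Sites where no single substitution can flip the call are
    resampled (bounded retries) and counted.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    predictor = predictor or PropensityPredictor()
    scale = predictor.scale
    proteins = synthetic.proteins
    value_arrays = {p.id: scale.encode(p.sequence) for p in proteins}
    call_arrays = {p.id: predictor.predict(p).calls() for p in proteins}
    residues = list(CANONICAL_AA)
    # global per-class site pools: uniform over residues of each call class
    pools = {True: [], False: []}
    for p_idx, protein in enumerate(proteins):
        for i, disordered in enumerate(call_arrays[protein.id]):
            pools[bool(disordered)].append((p_idx, i))
    n_sites = len(pools[True]) + len(pools[False])

    datasets: dict[str, list[MutationRecord]] = {}
    truth_rows = []
    n_unsatisfiable = 0
    for dataset, n_mut in config.mutations_per_dataset.items():
        p_do = config.p_do.get(dataset, 0.0)
        p_od = config.p_od.get(dataset, 0.0)
        records = []
        while len(records) < n_mut:
            site = rng.integers(n_sites)
            site_disordered = site < len(pools[True])
            pool = pools[site_disordered]
            p_idx, index = pool[site if site_disordered else site - len(pools[True])]
            protein = proteins[p_idx]
            wt_aa = protein.sequence[index]
            plant = rng.random() < (p_do if site_disordered else p_od)
            intent = "none"
            if plant:
                mut_aa = None
                for _ in range(config.max_flip_retries):
                    mut_aa = _try_flip(
                        predictor,
                        value_arrays[protein.id],
                        index,
                        wt_aa,
                        want_disordered=not site_disordered,
                        rng=rng,
                    )
                    if mut_aa is not None:
                        break
                    # unsatisfiable at this site: resample from the class pool
                    n_unsatisfiable += 1
                    p_idx, index = pool[rng.integers(len(pool))]
                    protein = proteins[p_idx]
                    wt_aa = protein.sequence[index]
                if mut_aa is None:
                    plant = False  # give up; fall through to a random substitution
                else:
                    intent = "planted_DO" if site_disordered else "planted_OD"
            if not plant:
                mut_aa = wt_aa
                while mut_aa == wt_aa:
                    mut_aa = residues[rng.integers(20)]
            record = MutationRecord(protein.id, index + 1, wt_aa, mut_aa, dataset)
            records.append(record)
            truth_rows.append(
                {
                    "protein_id": record.protein_id,
                    "position": record.position,
                    "wt_aa": record.wt_aa,
                    "mut_aa": record.mut_aa,
                    "dataset": dataset,
                    "intent": intent,
                    "site_disordered": site_disordered,
                }
            )
        datasets[dataset] = records
    return SyntheticMutations(datasets, pd.DataFrame(truth_rows), n_unsatisfiable)


@dataclass
class SyntheticAnnotations:
    """Planted feature annotations plus the generating parameters."""

    annotations: list[FeatureAnnotation]
    odds: float
    q_ordered: float
    q_disordered: float


_SYN_KEYS = ("DNA_BIND", "ZN_FING", "TRANSMEM", "MOD_RES", "COMPBIAS", "REGION")


def gen_annotations(
    synthetic: SyntheticProteins,
    config: SimConfig,
    rng=None,
) -> SyntheticAnnotations:
    """Block-tiled annotations enriched on disordered blocks at planted odds.

    Each true block is tiled into windows of ``annotation_tile`` residues;
    a tile becomes a feature with probability ``q_ordered`` in ordered
    blocks and with the probability whose odds are ``annotation_odds``
    times larger in disordered blocks. Tiles never straddle a block
    boundary, so the per-residue coverage odds ratio between disordered and
    ordered residues equals the planted odds exactly in expectation.
    """
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    q_ord = config.annotation_q_ordered
    odds_ord = q_ord / (1.0 - q_ord)
    odds_dis = config.annotation_odds * odds_ord
    q_dis = odds_dis / (1.0 + odds_dis)
    tile = config.annotation_tile
    annotations = []
    for protein in synthetic.proteins:
        lab = synthetic.labels[protein.id]
        boundaries = np.flatnonzero(np.diff(lab.astype(int))) + 1
        run_starts = np.concatenate(([0], boundaries))
        run_ends = np.concatenate((boundaries, [len(protein)]))
        for run_start, run_end in zip(run_starts, run_ends):
            q = q_dis if lab[run_start] else q_ord
            for start in range(run_start, run_end - tile + 1, tile):
                if rng.random() < q:
                    annotations.append(
                        FeatureAnnotation(
                            protein.id,
                            start + 1,
                            start + tile,
                            _SYN_KEYS[rng.integers(len(_SYN_KEYS))],
                            "synthetic planted feature",
                        )
                    )
    return SyntheticAnnotations(annotations, config.annotation_odds, q_ord, q_dis)


def simulate_all(config: SimConfig):
    """Convenience wrapper: proteins, mutations and annotations in one call."""
    synthetic = gen_proteins(config)
    mutations = gen_mutations(synthetic, config)
    annotations = gen_annotations(synthetic, config)
    return synthetic, mutations, annotations
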