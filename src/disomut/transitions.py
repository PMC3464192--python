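"""Order/disorder transition classification of missense mutations.

A mutation is classified from the disorder scores of the mutated residue in
the wild-type and the (fully re-scored) mutant sequence under the 0.5 rule:

=========  =====================================
class      condition
=========  =====================================
D→O        wt ps ≥ 0.5 and mutant ps < 0.5
O→D        wt ps < 0.5 and mutant ps ≥ 0.5
D→D        both ≥ 0.5
O→O        both < 0.5
=========  =====================================

Δps = ps(wild type) − ps(mutant) at the mutated residue; positive values mean
the mutation made the site look more ordered.

This module also tallies secondary-structure transitions (H/E/L) from
external state tracks, wild-type→mutant substitution matrices, and
per-region mutation rates.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .disorder import DISORDER_THRESHOLD, DisorderProfile
from .io import CANONICAL_AA, MutationRecord, ProteinRecord

# Transition class labels (ASCII-safe for TSV output).
D_TO_O = "D->O"
O_TO_D = "O->D"
D_TO_D = "D->D"
O_TO_O = "O->O"
KLASSES = (D_TO_O, O_TO_D, D_TO_D, O_TO_O)

SS_STATES = ("H", "E", "L")


def classify_transition(wt_ps: float, mut_ps: float) -> str:
    """Transition class of a mutation from its two site scores."""
    for name, ps in (("wild-type", wt_ps), ("mutant", mut_ps)):
        if not 0.0 <= ps <= 1.0:
            raise ValueError(f"{name} score {ps} outside [0, 1]")
    wt_dis = wt_ps >= DISORDER_THRESHOLD
    mut_dis = mut_ps >= DISORDER_THRESHOLD
    if wt_dis and not mut_dis:
        return D_TO_O
    if not wt_dis and mut_dis:
        return O_TO_D
    return D_TO_D if wt_dis else O_TO_O


@dataclass(frozen=True)
class TransitionCall:
    """Per-mutation transition class with the underlying site scores."""

    mutation: MutationRecord
    wt_ps: float
    mut_ps: float
    klass: str
    delta_ps: float

    @classmethod
    def from_scores(
        cls, mutation: MutationRecord, wt_ps: float, mut_ps: float
    ) -> "TransitionCall":
        return cls(
            mutation,
            wt_ps,
            mut_ps,
            classify_transition(wt_ps, mut_ps),
            wt_ps - mut_ps,
        )

    @property
    def in_idr(self) -> bool:
        """Wild-type placement: True if the wild-type residue is disordered."""
        return self.wt_ps >= DISORDER_THRESHOLD


@dataclass
class DatasetClassification:
    """All transition calls for one or more mutation datasets."""

    calls: list[TransitionCall]

    def counts(self) -> pd.DataFrame:
        """Class counts per dataset (rows: dataset, columns: the 4 classes)."""
        tally: dict[str, Counter] = {}
        for call in self.calls:
            tally.setdefault(call.mutation.dataset, Counter())[call.klass] += 1
        frame = pd.DataFrame(
            [
                {"dataset": ds, **{k: counter.get(k, 0) for k in KLASSES}}
                for ds, counter in sorted(tally.items())
            ]
        ).set_index("dataset")
        return frame

    def idr_table(self, dataset_a: str, dataset_b: str) -> np.ndarray:
        """2×2 table {D→O vs D→D} for mutations at disordered wild-type sites."""
        counts = self.counts()
        return np.array(
            [
                [counts.loc[dataset_a, D_TO_O], counts.loc[dataset_a, D_TO_D]],
                [counts.loc[dataset_b, D_TO_O], counts.loc[dataset_b, D_TO_D]],
            ],
            dtype=int,
        )

    def or_table(self, dataset_a: str, dataset_b: str) -> np.ndarray:
        """2×2 table {O→D vs O→O} for mutations at ordered wild-type sites."""
        counts = self.counts()
        return np.array(
            [
                [counts.loc[dataset_a, O_TO_D], counts.loc[dataset_a, O_TO_O]],
                [counts.loc[dataset_b, O_TO_D], counts.loc[dataset_b, O_TO_O]],
            ],
            dtype=int,
        )

    def to_frame(self) -> pd.DataFrame:
        """One row per mutation: scores, class, Δps."""
        return pd.DataFrame(
            {
                "protein_id": [c.mutation.protein_id for c in self.calls],
                "position": [c.mutation.position for c in self.calls],
                "wt_aa": [c.mutation.wt_aa for c in self.calls],
                "mut_aa": [c.mutation.mut_aa for c in self.calls],
                "dataset": [c.mutation.dataset for c in self.calls],
                "wt_ps": [c.wt_ps for c in self.calls],
                "mut_ps": [c.mut_ps for c in self.calls],
                "klass": [c.klass for c in self.calls],
                "delta_ps": [c.delta_ps for c in self.calls],
            }
        )


def classify_dataset(
    mutations: Iterable[MutationRecord],
    proteins: Iterable[ProteinRecord],
    predictor,
) -> DatasetClassification:
    """Classify every mutation by rescoring the full mutant sequence.

    The wild-type profile of each protein is computed once; each mutant
    sequence is rescored in full and only the mutated residue's score enters
    the classification.
    """
    by_id = {p.id: p for p in proteins}
    wt_profiles: dict[str, DisorderProfile] = {}
    calls = []
    for mutation in mutations:
        try:
            protein = by_id[mutation.protein_id]
            if mutation.protein_id not in wt_profiles:
                wt_profiles[mutation.protein_id] = predictor.predict(protein)
            wt_ps = wt_profiles[mutation.protein_id][mutation.index]
            mut_ps = predictor.predict_mutant(protein, mutation)[mutation.index]
        except Exception as exc:
            raise RuntimeError(
                f"prediction failed for protein {mutation.protein_id!r}: {exc}"
            ) from exc
        calls.append(TransitionCall.from_scores(mutation, wt_ps, mut_ps))
    return DatasetClassification(calls)


def delta_ps_summary(
    calls: Sequence[TransitionCall], cutoffs: Sequence[float] = (0.2,)
) -> pd.DataFrame:
    """Δps dispersion summary per dataset.

    Reports the observed Δps range, the fraction of mutations with |Δps|
    above each cutoff (tail mass: a flatter, heavier-tailed distribution
    means mutations more often shift the score strongly), and unbiased
    sample excess kurtosis.
    """
    if len(calls) < 4:
        raise ValueError("need at least 4 calls for a Δps summary")
    rows = []
    frame = pd.DataFrame(
        {
            "dataset": [c.mutation.dataset for c in calls],
            "delta_ps": [c.delta_ps for c in calls],
        }
    )
    for dataset, group in frame.groupby("dataset"):
        d = group["delta_ps"].to_numpy()
        row = {
            "dataset": dataset,
            "n": d.size,
            "min": d.min(),
            "max": d.max(),
            "excess_kurtosis": _sps.kurtosis(d, fisher=True, bias=False)
            if d.size >= 4
            else np.nan,
        }
        for cut in cutoffs:
            row[f"tail_frac_{cut:g}"] = float(np.mean(np.abs(d) >= cut))
        rows.append(row)
    return pd.DataFrame(rows).set_index("dataset")


@dataclass(frozen=True)
class SsPair:
    """Predicted secondary-structure state at the mutated residue, before and
    after the mutation, with the predictor's reliability indices (0-9)."""

    from_state: str
    to_state: str
    from_reliability: int
    to_reliability: int


@dataclass
class SsTransitionTable:
    """3×3 H/E/L transition counts plus the number of filtered-out pairs."""

    table: pd.DataFrame
    n_excluded: int

    @property
    def n_counted(self) -> int:
        return int(self.table.to_numpy().sum())


def ss_transitions(
    pairs: Iterable[SsPair], reliability_min: int = 4
) -> SsTransitionTable:
    """Tally secondary-structure transitions among reliable predictions.

    A pair is counted only when both the "from" and "to" assignment have
    reliability ≥ ``reliability_min``; excluded pairs are counted, not
    silently dropped.
    """
    counts = pd.DataFrame(0, index=list(SS_STATES), columns=list(SS_STATES))
    excluded = 0
    for pair in pairs:
        for state in (pair.from_state, pair.to_state):
            if state not in SS_STATES:
                raise ValueError(f"unknown secondary-structure state {state!r}")
        if min(pair.from_reliability, pair.to_reliability) < reliability_min:
            excluded += 1
            continue
        counts.loc[pair.from_state, pair.to_state] += 1
    return SsTransitionTable(counts, excluded)


def _residue_ordering(ordering: str) -> list[str]:
    if ordering == "alphabetical":
        return list(CANONICAL_AA)
    if ordering == "vihinen":
        from importlib import resources

        text = (
            resources.files("disomut.data")
            .joinpath("vihinen_flexibility.tsv")
            .read_text("utf-8")
        )
        order = []
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("residue"):
                continue
            order.append(line.split("\t")[0])
        return order
    raise ValueError(f"unknown residue ordering {ordering!r}")


def substitution_matrix(
    calls: Sequence[TransitionCall],
    dataset: str | None = None,
    klass: str | None = None,
    ordering: str = "vihinen",
) -> pd.DataFrame:
    """20×20 wild-type (rows) → mutant (columns) substitution counts.

    ``dataset`` and ``klass`` select the stratum; ``ordering`` is
    ``"vihinen"`` (rigid-to-flexible axis, the conventional heat-map layout)
    or ``"alphabetical"``.
    """
    order = _residue_ordering(ordering)
    matrix = pd.DataFrame(0, index=order, columns=order)
    for call in calls:
        if dataset is not None and call.mutation.dataset != dataset:
            continue
        if klass is not None and call.klass != klass:
            continue
        matrix.loc[call.mutation.wt_aa, call.mutation.mut_aa] += 1
    return matrix


def matrix_percent_difference(
    matrix_a: pd.DataFrame, matrix_b: pd.DataFrame
) -> pd.DataFrame:
    """Element-wise difference of within-stratum percentages (A − B)."""
    pct_a = 100.0 * matrix_a / matrix_a.to_numpy().sum()
    pct_b = 100.0 * matrix_b / matrix_b.to_numpy().sum()
    return pct_a - pct_b


def mutation_rates(
    mutations_by_dataset: Mapping[str, Sequence[MutationRecord]],
    profiles: Mapping[str, DisorderProfile],
) -> pd.DataFrame:
    """Mutations per residue in disordered (IDR) and ordered (OR) regions.

    For each dataset, the denominator counts residues of each region type
    over the proteins that carry that dataset's mutations; the numerator
    counts mutations whose wild-type residue is called in that region.
    A dataset with zero mutations in a region has rate 0.
    """
    rows = []
    for dataset, mutations in sorted(mutations_by_dataset.items()):
        protein_ids = sorted({m.protein_id for m in mutations})
        n_dis = sum(int(profiles[pid].calls().sum()) for pid in protein_ids)
        n_ord = sum(len(profiles[pid]) for pid in protein_ids) - n_dis
        counts = {"IDR": 0, "OR": 0}
        for m in mutations:
            region = "IDR" if profiles[m.protein_id].calls()[m.index] else "OR"
            counts[region] += 1
        for region, n_res in (("IDR", n_dis), ("OR", n_ord)):
            rows.append(
                {
                    "dataset": dataset,
                    "region": region,
                    "n_mutations": counts[region],
                    "n_residues": n_res,
                    "rate": counts[region] / n_res if n_res else np.nan,
                }
            )
    return pd.DataFrame(rows)
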