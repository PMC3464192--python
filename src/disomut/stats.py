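"""Enrichment statistics: exact tests, Bonferroni correction, fold
differences, composition profiling, feature normalization and stratified
evaluation of external predictor calls.

The two-sided Fisher exact P follows the point-probability convention: it
sums the hypergeometric probabilities of every table with the observed
margins whose point probability does not exceed that of the observed table
(within a small relative slack guarding against floating-point ties). All
probability mass is accumulated in log space, so extremely small P-values
(down to ~1e-300) remain exact.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import hypergeom

from .io import CANONICAL_AA, FeatureAnnotation, MutationRecord

#: Relative slack when comparing point probabilities (floating-point ties).
_TIE_SLACK = 1e-7


def _as_table(table) -> np.ndarray:
    arr = np.asarray(table, dtype=np.int64)
    if arr.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {arr.shape}")
    if np.any(arr < 0):
        raise ValueError("table counts must be non-negative")
    if arr.sum() == 0:
        raise ValueError("table is all zero")
    return arr


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact P for a 2×2 count table.

    P is the total hypergeometric probability, over all tables with the
    observed margins, of outcomes no more probable than the observed one.
    Computed in log space for numerical exactness at extreme significance.
    """
    arr = _as_table(table)
    a, b = int(arr[0, 0]), int(arr[0, 1])
    c, d = int(arr[1, 0]), int(arr[1, 1])
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    k = np.arange(max(0, col1 - (c + d)), min(row1, col1) + 1)
    logpmf = hypergeom.logpmf(k, n, col1, row1)
    log_obs = hypergeom.logpmf(a, n, col1, row1)
    mask = logpmf <= log_obs + np.log1p(_TIE_SLACK)
    p = float(np.exp(logsumexp(logpmf[mask])))
    # the total mass is a true probability; snap floating-point residue at 1
    return 1.0 if p > 1.0 - 1e-9 else p


def bonferroni(p_values: Sequence[float]) -> list[float]:
    """Bonferroni correction: multiply by the family size, cap at 1."""
    m = len(p_values)
    out = []
    for p in p_values:
        if not 0.0 < p <= 1.0:
            raise ValueError(f"p-value {p} outside (0, 1]")
        out.append(min(1.0, p * m))
    return out


def fold_difference(table) -> tuple[float, float]:
    """Fold = (a/(a+b)) / (c/(c+d)) with a delta-method standard error.

    The SE comes from the asymptotic variance of the log proportion ratio:
    SE = fold × sqrt(1/a − 1/(a+b) + 1/c − 1/(c+d)). Undefined (zero) group
    proportions raise ``ValueError`` — callers that must keep going should
    catch and flag.
    """
    arr = _as_table(table)
    a, b = int(arr[0, 0]), int(arr[0, 1])
    c, d = int(arr[1, 0]), int(arr[1, 1])
    if a == 0 or c == 0:
        raise ValueError("fold difference undefined: zero proportion in a group")
    p1 = a / (a + b)
    p2 = c / (c + d)
    fold = p1 / p2
    se = fold * np.sqrt(1.0 / a - 1.0 / (a + b) + 1.0 / c - 1.0 / (c + d))
    return float(fold), float(se)


def fold_se_bootstrap(table, reps: int = 10_000, seed: int = 0) -> float:
    """Bootstrap SE of the fold (binomial resampling of both proportions)."""
    arr = _as_table(table)
    a, b = int(arr[0, 0]), int(arr[0, 1])
    c, d = int(arr[1, 0]), int(arr[1, 1])
    rng = np.random.default_rng(seed)
    n1, n2 = a + b, c + d
    a_star = rng.binomial(n1, a / n1, size=reps)
    c_star = rng.binomial(n2, c / n2, size=reps)
    ok = (a_star > 0) & (c_star > 0)
    folds = (a_star[ok] / n1) / (c_star[ok] / n2)
    return float(np.std(folds, ddof=1))


@dataclass(frozen=True)
class EnrichmentResult:
    """One 2×2 enrichment comparison with raw and corrected significance."""

    label: str
    table: tuple[tuple[int, int], tuple[int, int]]
    fold: float
    fold_se: float
    p_raw: float
    p_adjusted: float
    test_count: int


@dataclass(frozen=True)
class CompositionProfile:
    """Per-residue fractional compositional difference with bootstrap SEs.

    ``difference[i] = (f_sample[i] − f_background[i]) / f_background[i]``;
    −1 means the residue is absent from the sample.
    """

    residues: tuple[str, ...]
    difference: np.ndarray
    se: np.ndarray
    reps: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"residue": self.residues, "difference": self.difference, "se": self.se}
        )


def composition_profile(
    sample_counts,
    background_counts,
    reps: int = 10_000,
    seed: int = 0,
    residues: Sequence[str] = tuple(CANONICAL_AA),
) -> CompositionProfile:
    """Residue composition of a sample relative to a background.

    The statistic per residue is the fractional difference of frequencies,
    normalized by the background frequency. SEs are the standard deviation
    of the statistic over ``reps`` multinomial bootstrap resamples of the
    sample counts (seeded, bit-reproducible).
    """
    sample = np.asarray(sample_counts, dtype=float)
    background = np.asarray(background_counts, dtype=float)
    if sample.shape != (len(residues),) or background.shape != (len(residues),):
        raise ValueError(f"count vectors must have length {len(residues)}")
    if reps < 100:
        raise ValueError("need at least 100 bootstrap replicates")
    fs = sample / sample.sum()
    fb = background / background.sum()
    bad = (fb == 0) & (fs > 0)
    if np.any(bad):
        names = [residues[i] for i in np.flatnonzero(bad)]
        raise ValueError(f"background frequency zero for sampled residues {names}")
    with np.errstate(divide="ignore", invalid="ignore"):
        diff = np.where(fb > 0, (fs - fb) / fb, 0.0)
    rng = np.random.default_rng(seed)
    n = int(sample.sum())
    resamples = rng.multinomial(n, fs, size=reps) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        stats = np.where(fb > 0, (resamples - fb) / fb, 0.0)
    return CompositionProfile(
        tuple(residues), diff, np.std(stats, axis=0, ddof=1), reps, seed
    )


# --- UniProt-FT-style feature normalization ---------------------------------

#: Evidence qualifiers whose features are dropped outright.
DEFAULT_DROP_QUALIFIERS = ("Potential", "Probable", "By similarity")

#: Description prefixes stripped for level-2 labels (longest first at match time).
DEFAULT_STRIP_PREFIXES = (
    "required for",
    "sufficient for",
    "essential for",
    "essential to",
    "important for",
    "critical for",
    "necessary for",
    "involved in",
    "mediates",
    "for",
)

#: Keywords excluded because they would be trivially disease-enriched.
DEFAULT_DISEASE_KEYWORDS = ("DISEASE", "VARIANT")


def normalize_description(description: str, prefixes=DEFAULT_STRIP_PREFIXES) -> str:
    """Strip boilerplate prefixes (case-insensitive, longest first) and
    collapse whitespace."""
    text = " ".join(description.split())
    for prefix in sorted(prefixes, key=len, reverse=True):
        pattern = rf"^{re.escape(prefix)}\b[\s:,]*"
        new = re.sub(pattern, "", text, flags=re.IGNORECASE)
        if new != text:
            text = new.strip()
            break
    return text


@dataclass
class NormalizedFeatures:
    """Feature annotations with level-1/level-2 labels after normalization."""

    annotations: list[FeatureAnnotation]
    level1: list[str]  # parallel to annotations
    level2: list[str]
    n_dropped_qualifier: int
    n_dropped_rare: int
    n_dropped_disease: int

    def labelled(self, level: int) -> list[tuple[FeatureAnnotation, str]]:
        labels = self.level1 if level == 1 else self.level2
        return list(zip(self.annotations, labels))


def normalize_ft(
    annotations: Iterable[FeatureAnnotation],
    dm_mutations: Iterable[MutationRecord] = (),
    min_dm_count: int = 5,
    drop_qualifiers: Sequence[str] = DEFAULT_DROP_QUALIFIERS,
    strip_prefixes: Sequence[str] = DEFAULT_STRIP_PREFIXES,
    disease_keywords: Sequence[str] = DEFAULT_DISEASE_KEYWORDS,
) -> NormalizedFeatures:
    """Normalize feature annotations for enrichment analysis.

    Features carrying an evidence qualifier are dropped; level-1 labels are
    the keyword, level-2 labels the keyword plus the prefix-stripped
    description; disease-named keywords are removed; and labels hit by fewer
    than ``min_dm_count`` disease mutations are removed (rare-feature
    filter, applied per level on the level-2 label).
    """
    qualifier_set = {q.lower() for q in drop_qualifiers}
    disease_set = {k.upper() for k in disease_keywords}
    kept: list[FeatureAnnotation] = []
    n_qualifier = n_disease = 0
    for ann in annotations:
        if ann.qualifier and ann.qualifier.lower() in qualifier_set:
            n_qualifier += 1
            continue
        if ann.key.upper() in disease_set:
            n_disease += 1
            continue
        kept.append(ann)

    level1 = [ann.key for ann in kept]
    level2 = [
        f"{ann.key}: {normalize_description(ann.description, strip_prefixes)}"
        if ann.description
        else ann.key
        for ann in kept
    ]

    dm = list(dm_mutations)
    n_rare = 0
    if dm and min_dm_count > 0:
        hit_counts: dict[str, int] = {}
        for ann, label in zip(kept, level2):
            hits = sum(
                1
                for m in dm
                if m.protein_id == ann.protein_id and ann.overlaps(m.position)
            )
            hit_counts[label] = hit_counts.get(label, 0) + hits
        keep_mask = [hit_counts[label] >= min_dm_count for label in level2]
        n_rare = keep_mask.count(False)
        kept = [a for a, ok in zip(kept, keep_mask) if ok]
        level1 = [l for l, ok in zip(level1, keep_mask) if ok]
        level2 = [l for l, ok in zip(level2, keep_mask) if ok]

    return NormalizedFeatures(kept, level1, level2, n_qualifier, n_rare, n_disease)


def _overlap_counts(
    mutations: Sequence[MutationRecord],
    features_by_label: Mapping[str, Sequence[FeatureAnnotation]],
) -> dict[str, int]:
    index: dict[str, list[tuple[int, int, str]]] = {}
    for label, anns in features_by_label.items():
        for ann in anns:
            index.setdefault(ann.protein_id, []).append((ann.start, ann.end, label))
    counts = {label: 0 for label in features_by_label}
    for m in mutations:
        hit_labels = {
            label
            for start, end, label in index.get(m.protein_id, ())
            if start <= m.position <= end
        }
        for label in hit_labels:
            counts[label] += 1
    return counts


def ft_enrichment(
    features: NormalizedFeatures,
    mutations_a: Sequence[MutationRecord],
    mutations_b: Sequence[MutationRecord],
    level: int = 1,
    labels: tuple[str, str] = ("A", "B"),
) -> list[EnrichmentResult]:
    """Per-feature enrichment of stratum A mutations relative to stratum B.

    Each tested feature label gets the 2×2 table
    [[hits_A, misses_A], [hits_B, misses_B]], a two-sided Fisher P,
    Bonferroni correction over the labels actually tested (one family per
    analysis), and the fold with its delta-method SE. Features hit by no
    mutation in either stratum are excluded. Results are sorted by
    decreasing fold.
    """
    by_label: dict[str, list[FeatureAnnotation]] = {}
    for ann, label in features.labelled(level):
        by_label.setdefault(label, []).append(ann)
    hits_a = _overlap_counts(mutations_a, by_label)
    hits_b = _overlap_counts(mutations_b, by_label)
    n_a, n_b = len(mutations_a), len(mutations_b)

    tested = [
        label for label in sorted(by_label) if hits_a[label] + hits_b[label] > 0
    ]
    raw_ps, tables = [], []
    for label in tested:
        a, c = hits_a[label], hits_b[label]
        table = ((a, n_a - a), (c, n_b - c))
        tables.append(table)
        raw_ps.append(fisher_exact_2x2(table))
    adjusted = bonferroni(raw_ps) if raw_ps else []

    results = []
    for label, table, p_raw, p_adj in zip(tested, tables, raw_ps, adjusted):
        try:
            fold, se = fold_difference(table)
        except ValueError:
            fold, se = float("nan"), float("nan")
        results.append(
            EnrichmentResult(label, table, fold, se, p_raw, p_adj, len(tested))
        )
    results.sort(key=lambda r: (-(r.fold if np.isfinite(r.fold) else -np.inf), r.label))
    return results


def interval_overlap(
    mutations: Sequence[MutationRecord],
    intervals: Sequence[FeatureAnnotation],
    klass_of: Mapping[tuple, str] | None = None,
) -> pd.DataFrame:
    """Overlap counts of mutations with motif-style intervals.

    A mutation overlaps iff its position lies in [start, end] (1-based
    inclusive) of an interval on the same protein. Counts are stratified by
    dataset and, if ``klass_of`` maps mutation keys to transition classes,
    by class.
    """
    by_protein: dict[str, list[FeatureAnnotation]] = {}
    for interval in intervals:
        by_protein.setdefault(interval.protein_id, []).append(interval)
    rows: dict[tuple[str, str], dict[str, int]] = {}
    for m in mutations:
        klass = klass_of.get(m.key(), "all") if klass_of else "all"
        cell = rows.setdefault((m.dataset, klass), {"overlap": 0, "no_overlap": 0})
        hit = any(
            iv.start <= m.position <= iv.end
            for iv in by_protein.get(m.protein_id, ())
        )
        cell["overlap" if hit else "no_overlap"] += 1
    return pd.DataFrame(
        [
            {
                "dataset": ds,
                "klass": kl,
                "overlap": cell["overlap"],
                "no_overlap": cell["no_overlap"],
            }
            for (ds, kl), cell in sorted(rows.items())
        ]
    )


def stratified_calls(
    calls: Sequence[tuple[str, str]],
    unknown_label: str = "unknown",
) -> pd.DataFrame:
    """Fractions of external predictor call categories per stratum.

    ``calls`` is a sequence of (stratum, call-category) pairs, e.g.
    ("IDR", "damaging"). Unknown calls are tabulated but reported in a
    separate column and excluded from the known-call fractions. Fractions
    over known categories sum to 1 per stratum.
    """
    frame = pd.DataFrame(calls, columns=["stratum", "call"])
    counts = frame.pivot_table(
        index="stratum", columns="call", aggfunc="size", fill_value=0
    )
    known = counts.drop(columns=[unknown_label], errors="ignore")
    fractions = known.div(known.sum(axis=1), axis=0)
    fractions.columns = [f"frac_{c}" for c in fractions.columns]
    out = pd.concat([counts, fractions], axis=1)
    out["n_known"] = known.sum(axis=1)
    return out


def compare_strata(
    calls: Sequence[tuple[str, str]],
    stratum_a: str,
    stratum_b: str,
    category: str,
    unknown_label: str = "unknown",
) -> EnrichmentResult:
    """2×2 Fisher comparison of one call category between two strata."""
    tally = {stratum_a: [0, 0], stratum_b: [0, 0]}
    for stratum, call in calls:
        if stratum not in tally or call == unknown_label:
            continue
        tally[stratum][0 if call == category else 1] += 1
    table = (tuple(tally[stratum_a]), tuple(tally[stratum_b]))
    p = fisher_exact_2x2(table)
    try:
        fold, se = fold_difference(table)
    except ValueError:
        fold, se = float("nan"), float("nan")
    return EnrichmentResult(
        f"{category}: {stratum_a} vs {stratum_b}", table, fold, se, p, p, 1
    )
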