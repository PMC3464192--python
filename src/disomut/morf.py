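"""α-MoRF detection and per-mutation MoRF impact calls.

Molecular recognition features (MoRFs) are short order-prone segments
embedded in longer disordered regions that fold upon binding a partner.
Detection here is two-staged, mirroring the classic stacked architecture:

* **Stage 1** scans a disorder profile for maximal runs of ordered calls
  (ps < 0.5) whose length lies within configured bounds and which are
  flanked on both sides by sufficiently long runs of disordered calls.
* **Stage 2** classifies each candidate with a quadratic discriminant model
  (Gaussian class densities with class-specific covariances) over simple
  candidate features; the score is the log posterior odds of the MoRF class
  and a candidate is accepted when it is positive.

The per-mutation impact call compares accepted MoRFs in the wild-type and
mutant profiles at the mutated position: *lost*, *gained*,
*present_no_change*, or *absent* (the last is excluded from enrichment
denominators).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence
import json
import warnings

import numpy as np
from scipy.stats import multivariate_normal

from .disorder import DisorderProfile, PropensityScale

MORF_LOST = "lost"
MORF_GAINED = "gained"
MORF_NO_CHANGE = "present_no_change"
MORF_ABSENT = "absent"
MORF_IMPACTS = (MORF_LOST, MORF_GAINED, MORF_NO_CHANGE, MORF_ABSENT)

#: Stage-2 feature names, in vector order.
FEATURE_NAMES = (
    "mean_ps_stretch",
    "mean_ps_flanks",
    "stretch_len",
    "left_flank_len",
    "right_flank_len",
    "mean_scale_stretch",
)


@dataclass(frozen=True)
class MorfRegion:
    """A candidate or accepted α-MoRF: a short ordered stretch inside disorder.

    ``start``/``end`` are 1-based inclusive bounds of the ordered stretch
    (flanks excluded); flank lengths give the adjacent disordered runs.
    """

    protein_id: str
    start: int
    end: int
    left_flank_len: int
    right_flank_len: int
    stage2_score: float = float("nan")
    accepted: bool | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"invalid MoRF interval [{self.start}, {self.end}]")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, position: int) -> bool:
        """True if the 1-based position lies within the ordered stretch."""
        return self.start <= position <= self.end


def scan_candidates(
    profile: DisorderProfile,
    min_len: int = 5,
    max_len: int = 25,
    min_flank: int = 10,
) -> list[MorfRegion]:
    """Stage 1: ordered stretches of bounded length inside long disorder.

    Returns maximal runs of ordered calls with length in [min_len, max_len]
    flanked on both sides by at least ``min_flank`` consecutive disordered
    calls. A run touching a sequence terminus has no flank there and is
    rejected. Output is non-overlapping and sorted by start.
    """
    if not 1 <= min_len <= max_len:
        raise ValueError("need 1 <= min_len <= max_len")
    calls = profile.calls()  # True = disordered
    n = calls.size
    candidates = []
    # run-length encode the call track
    boundaries = np.flatnonzero(np.diff(calls.astype(int))) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [n]))  # half-open runs
    for i, (s, e) in enumerate(zip(starts, ends)):
        if calls[s]:  # disordered run, not a candidate stretch
            continue
        if not min_len <= e - s <= max_len:
            continue
        if i == 0 or i == len(starts) - 1:
            continue  # touches a terminus: no flank on that side
        left = starts[i] - starts[i - 1]
        right = ends[i + 1] - starts[i + 1]
        if left >= min_flank and right >= min_flank:
            candidates.append(
                MorfRegion(profile.protein_id, int(s) + 1, int(e), int(left), int(right))
            )
    return candidates


def candidate_features(
    region: MorfRegion,
    profile: DisorderProfile,
    sequence: str,
    scale: PropensityScale,
) -> np.ndarray:
    """Stage-2 feature vector for one candidate (see FEATURE_NAMES)."""
    s, e = region.start - 1, region.end  # 0-based half-open
    stretch_ps = profile.scores[s:e]
    left = profile.scores[s - region.left_flank_len : s]
    right = profile.scores[e : e + region.right_flank_len]
    flank_ps = np.concatenate([left, right])
    return np.array(
        [
            stretch_ps.mean(),
            flank_ps.mean(),
            float(region.length),
            float(region.left_flank_len),
            float(region.right_flank_len),
            scale.encode(sequence[s:e]).mean(),
        ]
    )


@dataclass
class QdModel:
    """Two-class quadratic discriminant model over candidate features."""

    means: dict[int, np.ndarray]
    covariances: dict[int, np.ndarray]
    priors: dict[int, float]
    feature_names: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self) -> None:
        if abs(sum(self.priors.values()) - 1.0) > 1e-9:
            raise ValueError("class priors must sum to 1")

    def log_density(self, x: np.ndarray, label: int) -> float:
        return float(
            multivariate_normal.logpdf(
                x, mean=self.means[label], cov=self.covariances[label]
            )
        )

    def save(self, path: str | Path) -> None:
        payload = {
            "feature_names": list(self.feature_names),
            "classes": {
                str(k): {
                    "mean": self.means[k].tolist(),
                    "covariance": self.covariances[k].tolist(),
                    "prior": self.priors[k],
                }
                for k in self.means
            },
        }
        Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "QdModel":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        means, covs, priors = {}, {}, {}
        for key, entry in payload["classes"].items():
            label = int(key)
            means[label] = np.asarray(entry["mean"], dtype=float)
            covs[label] = np.asarray(entry["covariance"], dtype=float)
            priors[label] = float(entry["prior"])
        return cls(means, covs, priors, tuple(payload["feature_names"]))


def _regularize(cov: np.ndarray, label: int) -> np.ndarray:
    """Ridge-regularize a singular covariance (1e-6 × trace/dim on the diagonal)."""
    try:
        np.linalg.cholesky(cov)
        return cov
    except np.linalg.LinAlgError:
        ridge = 1e-6 * np.trace(cov) / cov.shape[0]
        if ridge <= 0:
            ridge = 1e-6
        warnings.warn(
            f"singular covariance for class {label}; adding ridge {ridge:g}",
            stacklevel=3,
        )
        cov = cov + ridge * np.eye(cov.shape[0])
        # escalate the ridge until the matrix factors
        while True:
            try:
                np.linalg.cholesky(cov)
                return cov
            except np.linalg.LinAlgError:
                ridge *= 10.0
                cov = cov + ridge * np.eye(cov.shape[0])


def fit_qd(feature_vectors: np.ndarray, labels: Sequence[int]) -> QdModel:
    """Fit per-class Gaussians (mean, covariance, empirical prior)."""
    X = np.asarray(feature_vectors, dtype=float)
    y = np.asarray(labels)
    classes = sorted(set(y.tolist()))
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    means, covs, priors = {}, {}, {}
    for label in classes:
        Xk = X[y == label]
        if Xk.shape[0] <= X.shape[1]:
            raise ValueError(
                f"class {label} has {Xk.shape[0]} samples for "
                f"{X.shape[1]} features; need more samples than features"
            )
        means[label] = Xk.mean(axis=0)
        covs[label] = _regularize(np.cov(Xk, rowvar=False), label)
        priors[label] = Xk.shape[0] / X.shape[0]
    return QdModel(means, covs, priors)


def classify_qd(model: QdModel, features: np.ndarray) -> tuple[float, bool]:
    """Score = log posterior odds of class 1 vs class 0; accepted iff > 0."""
    x = np.asarray(features, dtype=float)
    score = (
        model.log_density(x, 1)
        + np.log(model.priors[1])
        - model.log_density(x, 0)
        - np.log(model.priors[0])
    )
    return float(score), bool(score > 0)


def apply_qd(
    candidates: Sequence[MorfRegion],
    model: QdModel,
    profile: DisorderProfile,
    sequence: str,
    scale: PropensityScale,
) -> list[MorfRegion]:
    """Stage 2 over a candidate list: attach scores and accept/reject."""
    out = []
    for region in candidates:
        score, accepted = classify_qd(
            model, candidate_features(region, profile, sequence, scale)
        )
        out.append(replace(region, stage2_score=score, accepted=accepted))
    return out


def classify_morf_impact(
    wt_morfs: Sequence[MorfRegion],
    mut_morfs: Sequence[MorfRegion],
    position: int,
) -> str:
    """Impact of a mutation on MoRF presence at the mutated position.

    Only accepted MoRFs count (candidates with ``accepted is None``, i.e. a
    stage-1-only run, are treated as accepted). The position must fall
    within the ordered stretch itself; flanks do not count as overlap.
    ``absent`` calls are excluded from enrichment denominators downstream.
    """

    def hit(regions: Sequence[MorfRegion]) -> bool:
        return any(
            r.overlaps(position) for r in regions if r.accepted is not False
        )

    in_wt, in_mut = hit(wt_morfs), hit(mut_morfs)
    if in_wt and not in_mut:
        return MORF_LOST
    if not in_wt and in_mut:
        return MORF_GAINED
    if in_wt and in_mut:
        return MORF_NO_CHANGE
    return MORF_ABSENT
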