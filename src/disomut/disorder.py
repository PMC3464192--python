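"""Per-residue intrinsic disorder scoring and order/disorder calls.

The built-in predictor turns a residue-level disorder propensity scale into a
smoothed per-residue probability-like score ps ∈ [0, 1]:

1. raw(i) = mean scale value over a centred window (mirror-padded at the
   sequence edges), and
2. ps(i) = logistic(steepness × (raw(i) − midpoint)), where the midpoint is
   the mean of the 20 scale values.

A residue is called *disordered* when ps ≥ 0.5 and *ordered* when ps < 0.5.
The predictor is a transparent, deterministic stand-in for neural-network
disorder predictors: it reproduces the qualitative behaviour the downstream
analysis relies on (region-level smoothing, monotone response to composition)
without claiming numerical equivalence with any published tool.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .io import CANONICAL_AA, MASK_RESIDUE, MutationRecord, ProteinRecord

#: Score threshold: ps >= DISORDER_THRESHOLD is called disordered.
DISORDER_THRESHOLD = 0.5

DISORDERED = "disordered"
ORDERED = "ordered"


def _read_scale_tsv(text: str) -> dict[str, float]:
    values: dict[str, float] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("residue"):
            continue
        aa, value = line.split("\t")
        values[aa] = float(value)
    return values


@dataclass(frozen=True)
class PropensityScale:
    """A residue → disorder-propensity map (higher = more disorder-promoting)."""

    name: str
    values: dict[str, float]

    def __post_init__(self) -> None:
        missing = set(CANONICAL_AA) - set(self.values)
        if missing:
            raise ValueError(f"scale {self.name!r} missing residues {sorted(missing)}")
        if len(self.values) != 20:
            raise ValueError(f"scale {self.name!r} must have exactly 20 entries")
        if not all(np.isfinite(v) for v in self.values.values()):
            raise ValueError(f"scale {self.name!r} has non-finite values")

    @property
    def midpoint(self) -> float:
        """Mean of the 20 scale values; the logistic inflection point."""
        return float(np.mean(list(self.values.values())))

    def __getitem__(self, aa: str) -> float:
        if aa == MASK_RESIDUE:
            return self.midpoint  # masked residues score neutrally
        return self.values[aa]

    def encode(self, sequence: str) -> np.ndarray:
        return np.array([self[aa] for aa in sequence], dtype=float)

    def order_promoting_first(self) -> list[str]:
        """The 20 residues sorted from most order- to most disorder-promoting."""
        return sorted(CANONICAL_AA, key=lambda aa: self.values[aa])

    @classmethod
    def from_file(cls, path: str | Path, name: str | None = None) -> "PropensityScale":
        text = Path(path).read_text(encoding="utf-8")
        return cls(name or Path(path).stem, _read_scale_tsv(text))

    @classmethod
    def top_idp(cls) -> "PropensityScale":
        """The TOP-IDP disorder propensity scale (shipped with the package)."""
        text = (
            resources.files("disomut.data").joinpath("top_idp.tsv").read_text("utf-8")
        )
        return cls("TOP-IDP", _read_scale_tsv(text))


@dataclass(frozen=True)
class DisorderProfile:
    """Per-residue disorder scores ps ∈ [0, 1] for one sequence."""

    protein_id: str
    scores: np.ndarray
    predictor_name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "scores", np.asarray(self.scores, dtype=float))
        if self.scores.ndim != 1 or self.scores.size == 0:
            raise ValueError(f"{self.protein_id}: profile must be a non-empty vector")
        if np.any((self.scores < 0.0) | (self.scores > 1.0)):
            raise ValueError(f"{self.protein_id}: scores outside [0, 1]")

    def __len__(self) -> int:
        return self.scores.size

    def __getitem__(self, index: int) -> float:
        return float(self.scores[index])

    def calls(self) -> np.ndarray:
        """Boolean per-residue calls; True = disordered (ps ≥ 0.5)."""
        return self.scores >= DISORDER_THRESHOLD


def call_state(ps: float) -> str:
    """Order/disorder call for a single score: disordered iff ps ≥ 0.5."""
    if not 0.0 <= ps <= 1.0:
        raise ValueError(f"score {ps} outside [0, 1]")
    return DISORDERED if ps >= DISORDER_THRESHOLD else ORDERED


def disorder_content(profile: DisorderProfile) -> float:
    """Fraction of residues called disordered."""
    return float(np.mean(profile.calls()))


@dataclass(frozen=True)
class PropensityPredictor:
    """Windowed propensity-average disorder predictor.

    Parameters
    ----------
    scale:
        Disorder propensity scale; defaults to TOP-IDP.
    window:
        Odd window length for the centred moving average. The default 21
        smooths single-residue noise to region-level signal, comparable in
        scope to long-disorder predictors.
    steepness:
        Logistic gain per propensity unit. The default 8 maps the scale's
        dynamic range onto a well-spread [0, 1] score (poly-P scores
        confidently disordered, poly-W confidently ordered).
    """

    scale: PropensityScale = field(default_factory=PropensityScale.top_idp)
    window: int = 21
    steepness: float = 8.0

    def __post_init__(self) -> None:
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError(f"window must be odd and >= 1, got {self.window}")
        if self.steepness <= 0:
            raise ValueError(f"steepness must be > 0, got {self.steepness}")

    @property
    def name(self) -> str:
        return f"propensity[{self.scale.name},w={self.window},k={self.steepness:g}]"

    def _raw(self, values: np.ndarray) -> np.ndarray:
        """Centred moving average with mirror padding (profile keeps length)."""
        half = self.window // 2
        if half == 0:
            return values
        if half > values.size - 1:
            # window cannot be mirrored into such a short sequence:
            # fall back to the full-sequence mean at every position
            return np.full_like(values, values.mean())
        padded = np.pad(values, half, mode="reflect")
        kernel = np.full(self.window, 1.0 / self.window)
        return np.convolve(padded, kernel, mode="valid")

    def _squash(self, raw: np.ndarray) -> np.ndarray:
        z = self.steepness * (raw - self.scale.midpoint)
        return 1.0 / (1.0 + np.exp(-z))

    def predict_sequence(self, sequence: str, protein_id: str = "") -> DisorderProfile:
        values = self.scale.encode(sequence)
        return DisorderProfile(protein_id, self._squash(self._raw(values)), self.name)

    def predict(self, protein: ProteinRecord) -> DisorderProfile:
        return self.predict_sequence(protein.sequence, protein.id)

    def predict_mutant(
        self, protein: ProteinRecord, mutation: MutationRecord
    ) -> DisorderProfile:
        """Full profile of the mutated sequence (never a local patch)."""
        mutated = mutation.apply(protein.sequence)
        return self.predict_sequence(mutated, protein.id)

    def score_at(self, values: np.ndarray, index: int) -> float:
        """ps at one position from a (possibly mutated) propensity vector.

        Equivalent to recomputing the full profile and indexing, but O(window);
        used by the synthetic generator's rejection sampler.
        """
        half = self.window // 2
        n = values.size
        if half > n - 1:
            raw = values.mean()
        else:
            idx = np.arange(index - half, index + half + 1)
            idx = np.abs(idx)  # mirror at the left edge
            over = idx > n - 1  # mirror at the right edge
            idx[over] = 2 * (n - 1) - idx[over]
            raw = values[idx].mean()
        return float(self._squash(np.array([raw]))[0])


class ExternalScorePredictor:
    """Disorder 'predictor' backed by pre-computed score files.

    Wild-type profiles are keyed by protein id; mutant profiles by
    (protein_id, position, mut_aa). Asking for a mutant profile that was not
    supplied is an error — external scores cannot be recomputed here.
    """

    def __init__(self, wt_profiles, mutant_profiles=None, name: str = "external"):
        self._wt = dict(wt_profiles)
        self._mut = dict(mutant_profiles or {})
        self.name = name

    def predict(self, protein: ProteinRecord) -> DisorderProfile:
        try:
            profile = self._wt[protein.id]
        except KeyError:
            raise KeyError(f"no external scores for protein {protein.id!r}") from None
        if len(profile) != len(protein):
            raise ValueError(
                f"{protein.id}: track length {len(profile)} != sequence "
                f"length {len(protein)}"
            )
        return profile

    def predict_mutant(
        self, protein: ProteinRecord, mutation: MutationRecord
    ) -> DisorderProfile:
        key = (mutation.protein_id, mutation.position, mutation.mut_aa)
        try:
            return self._mut[key]
        except KeyError:
            raise KeyError(
                f"mutant scores required: no external track for {key}"
            ) from None
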