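"""Domain types and readers/writers for the external formats the pipeline touches.

All on-disk coordinates are 1-based inclusive, matching mutation nomenclature
(e.g. R243W means position 243). Internal array indexing is 0-based; the
conversion happens here and nowhere else.

Tabular formats are UTF-8, tab-delimited, with a header line; lines starting
with ``#`` are ignored.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: The 20 canonical amino-acid one-letter codes.
CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
_CANONICAL_SET = frozenset(CANONICAL_AA)

#: Placeholder residue used by the "mask" sanitization policy.
MASK_RESIDUE = "X"

#: Non-canonical letters that the "mask" policy tolerates.
NONCANONICAL_AA = frozenset("BZXUOJ")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with a stable identifier."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if not self.sequence:
            raise ValueError(f"{self.id}: sequence must be non-empty")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MutationRecord:
    """A single amino-acid substitution.

    ``position`` is the 1-based residue index; ``dataset`` is a free label
    such as ``DM`` (disease), ``Poly`` (polymorphism) or ``NES`` (neutral
    evolutionary substitution).
    """

    protein_id: str
    position: int
    wt_aa: str
    mut_aa: str
    dataset: str = ""

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.wt_aa == self.mut_aa:
            raise ValueError(
                f"{self.protein_id}:{self.position} wild-type and mutant "
                f"residue are identical ({self.wt_aa})"
            )

    @property
    def index(self) -> int:
        """0-based index of the mutated residue."""
        return self.position - 1

    def key(self) -> tuple[str, int, str, str]:
        """Identity tuple ignoring the dataset label."""
        return (self.protein_id, self.position, self.wt_aa, self.mut_aa)

    def apply(self, sequence: str) -> str:
        """Return ``sequence`` with this substitution applied."""
        if not 1 <= self.position <= len(sequence):
            raise ValueError(
                f"{self.protein_id}: position {self.position} outside "
                f"sequence of length {len(sequence)}"
            )
        if sequence[self.index] != self.wt_aa:
            raise ValueError(
                f"{self.protein_id}:{self.position} sequence has "
                f"{sequence[self.index]}, mutation claims {self.wt_aa}"
            )
        return sequence[: self.index] + self.mut_aa + sequence[self.position :]


@dataclass(frozen=True)
class FeatureAnnotation:
    """A region/residue feature in the style of UniProt FT lines.

    ``key`` is the feature keyword (level-1 granularity); ``description`` is
    free text whose normalized form, concatenated with the key, gives the
    level-2 label. ``qualifier`` carries evidence tags such as "Potential".
    """

    protein_id: str
    start: int
    end: int
    key: str
    description: str = ""
    qualifier: str = ""

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"{self.protein_id}: invalid interval [{self.start}, {self.end}]"
            )

    def overlaps(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass(frozen=True)
class StateTrack:
    """Per-residue secondary-structure states (H/E/L) with 0-9 reliabilities."""

    protein_id: str
    states: str
    reliability: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.states) != len(self.reliability):
            raise ValueError(f"{self.protein_id}: state/reliability length mismatch")
        bad = set(self.states) - set("HEL")
        if bad:
            raise ValueError(f"{self.protein_id}: unknown state symbols {sorted(bad)}")
        if any(not 0 <= r <= 9 for r in self.reliability):
            raise ValueError(f"{self.protein_id}: reliability outside 0-9")


@dataclass(frozen=True)
class CallRecord:
    """One categorical call from an external deleteriousness predictor."""

    protein_id: str
    position: int
    wt_aa: str
    mut_aa: str
    call: str
    score: float = float("nan")

    def key(self) -> tuple[str, int, str, str]:
        return (self.protein_id, self.position, self.wt_aa, self.mut_aa)


@dataclass
class MutationReadReport:
    """Accepted mutations plus an account of every rejected row."""

    records: list[MutationRecord]
    rejected_wt_mismatch: list[dict] = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return len(self.rejected_wt_mismatch)


def _sanitize_sequence(seq: str, record_id: str, policy: str) -> str:
    seq = seq.upper()
    illegal = set(seq) - _CANONICAL_SET
    if not illegal:
        return seq
    if policy == "strict":
        raise FormatError(
            f"{record_id}: non-canonical residues {sorted(illegal)} "
            "(use policy='mask' to accept them)"
        )
    if policy == "mask":
        unknown = illegal - NONCANONICAL_AA
        if unknown:
            raise FormatError(f"{record_id}: illegal characters {sorted(unknown)}")
        return "".join(MASK_RESIDUE if c in illegal else c for c in seq)
    raise ValueError(f"unknown sanitization policy {policy!r}")


def read_fasta(path: str | Path, policy: str = "strict") -> list[ProteinRecord]:
    """Read protein records from a FASTA file.

    Ids are taken from the header up to the first whitespace; sequences are
    upper-cased. Under the default ``strict`` policy any letter outside the
    20-letter alphabet is an error; under ``mask`` the tolerated ambiguity
    codes (B, Z, X, U, O, J) are replaced by ``X``, which downstream
    predictors score at the propensity-scale midpoint.
    """
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        records.append(
            ProteinRecord(rec.id, _sanitize_sequence(str(rec.seq), rec.id, policy))
        )
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records),
        str(path),
        "fasta",
    )


def _tsv_rows(path: str | Path) -> Iterable[dict]:
    with open(path, newline="", encoding="utf-8") as handle:
        lines = (line for line in handle if not line.startswith("#"))
        yield from csv.DictReader(lines, delimiter="\t")


def _write_tsv(path: str | Path, header: Sequence[str], rows: Iterable[Sequence]) -> None:
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(header)
        writer.writerows(rows)


def read_mutations(
    path: str | Path, proteins: Iterable[ProteinRecord]
) -> MutationReadReport:
    """Read a mutation TSV and validate every row against its protein.

    Rows whose claimed wild-type residue does not match the sequence are
    rejected and reported (never silently dropped). An unknown protein id,
    an out-of-range position, or a row with identical wild-type and mutant
    residue is a hard error.
    """
    by_id = {p.id: p for p in proteins}
    report = MutationReadReport(records=[])
    for row in _tsv_rows(path):
        pid = row["protein_id"]
        if pid not in by_id:
            raise FormatError(f"unknown protein id {pid!r}")
        protein = by_id[pid]
        position = int(row["position"])
        if not 1 <= position <= len(protein):
            raise FormatError(
                f"{pid}: position {position} out of range 1..{len(protein)}"
            )
        record = MutationRecord(
            pid, position, row["wt_aa"], row["mut_aa"], row.get("dataset", "")
        )
        if protein.sequence[record.index] != record.wt_aa:
            report.rejected_wt_mismatch.append(dict(row))
            continue
        report.records.append(record)
    return report


def write_mutations(records: Iterable[MutationRecord], path: str | Path) -> None:
    _write_tsv(
        path,
        ("protein_id", "position", "wt_aa", "mut_aa", "dataset"),
        ((m.protein_id, m.position, m.wt_aa, m.mut_aa, m.dataset) for m in records),
    )


def read_score_tracks(path: str | Path):
    """Read dense per-residue tracks from a TSV.

    Columns: ``protein_id``, ``position`` (1-based), ``score``; optionally
    ``state`` and ``reliability`` for secondary-structure tracks. Positions
    for each protein must run 1..L without gaps — missing positions are an
    error, never imputed. Disorder scores must lie in [0, 1].

    Returns a dict keyed by protein id; values are
    :class:`~disomut.disorder.DisorderProfile` objects, or
    :class:`StateTrack` when the state column is present.
    """
    from .disorder import DisorderProfile  # local import avoids a cycle

    scores: dict[str, list[float]] = {}
    states: dict[str, list[str]] = {}
    reliab: dict[str, list[int]] = {}
    has_state = False
    for row in _tsv_rows(path):
        pid = row["protein_id"]
        position = int(row["position"])
        expected = len(scores.setdefault(pid, [])) + 1
        if position != expected:
            raise FormatError(
                f"{pid}: expected position {expected}, got {position} "
                "(tracks must be dense, no imputation)"
            )
        score = float(row.get("score") or "nan")
        if row.get("state"):
            has_state = True
            states.setdefault(pid, []).append(row["state"])
            reliab.setdefault(pid, []).append(int(row["reliability"]))
        else:
            if not 0.0 <= score <= 1.0:
                raise FormatError(f"{pid}:{position} score {score} outside [0, 1]")
        scores[pid].append(score)
    if not scores:
        raise FormatError(f"{path}: no track rows found")
    if has_state:
        return {
            pid: StateTrack(pid, "".join(states[pid]), tuple(reliab[pid]))
            for pid in states
        }
    return {
        pid: DisorderProfile(pid, scores[pid], predictor_name="external")
        for pid in scores
    }


def write_score_track(profiles, path: str | Path) -> None:
    """Write disorder profiles as a dense score-track TSV."""
    rows = []
    for profile in profiles:
        for i, ps in enumerate(profile.scores, start=1):
            rows.append((profile.protein_id, i, f"{ps:.6g}"))
    _write_tsv(path, ("protein_id", "position", "score"), rows)


def read_annotations(path: str | Path) -> list[FeatureAnnotation]:
    return [
        FeatureAnnotation(
            row["protein_id"],
            int(row["start"]),
            int(row["end"]),
            row["key"],
            row.get("description", ""),
            row.get("qualifier", ""),
        )
        for row in _tsv_rows(path)
    ]


def write_annotations(annotations: Iterable[FeatureAnnotation], path: str | Path) -> None:
    _write_tsv(
        path,
        ("protein_id", "start", "end", "key", "description", "qualifier"),
        (
            (a.protein_id, a.start, a.end, a.key, a.description, a.qualifier)
            for a in annotations
        ),
    )


def read_calls(path: str | Path) -> list[CallRecord]:
    return [
        CallRecord(
            row["protein_id"],
            int(row["position"]),
            row["wt_aa"],
            row["mut_aa"],
            row["call"],
            float(row.get("score") or "nan"),
        )
        for row in _tsv_rows(path)
    ]


def read_aligned_fasta(path: str | Path) -> dict[str, str]:
    """Read an aligned FASTA (gap symbol ``-``) as id → aligned string."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise FormatError(f"duplicate aligned FASTA id {rec.id!r}")
        out[rec.id] = str(rec.seq).upper()
    if not out:
        raise FormatError(f"{path}: no aligned records found")
    lengths = {len(s) for s in out.values()}
    if len(lengths) > 1:
        raise FormatError(f"{path}: aligned sequences have unequal lengths")
    return out
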