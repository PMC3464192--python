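"""Dataset curation: alignment, redundancy clustering, outlier removal, and
construction of the neutral-evolutionary-substitution (NES) control.

The curation conventions follow standard practice for mutation-enrichment
studies: proteins sharing ≥40% pairwise identity are collapsed to a single
random representative (single-linkage clustering, so identity is transitive
across the cluster), proteins with extreme mutation counts are flagged and
removed, and a neutral control is read off pairwise alignments against
close orthologs (≥95% identity), excluding any substitution that coincides
with an annotated disease mutation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .io import CANONICAL_AA, MutationRecord, ProteinRecord

_CANONICAL_SET = frozenset(CANONICAL_AA)


def blosum85() -> substitution_matrices.Array:
    """The BLOSUM85 substitution matrix as a Biopython scoring array.

    Biopython does not bundle BLOSUM85; the values are taken at run time
    from biotite's matrix database and restricted to the 20 canonical
    residues.
    """
    import biotite.sequence as bseq
    import biotite.sequence.align as balign

    alphabet = bseq.ProteinSequence.alphabet
    source = balign.SubstitutionMatrix(alphabet, alphabet, "BLOSUM85")
    target = substitution_matrices.Array(alphabet=CANONICAL_AA, dims=2)
    for a in CANONICAL_AA:
        for b in CANONICAL_AA:
            target[a, b] = source.get_score(a, b)
    return target


@dataclass(frozen=True)
class AlignmentResult:
    """A pairwise global alignment with its score and percent identity."""

    aligned_a: str
    aligned_b: str
    score: float
    identity_pct: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings must have equal length")


def percent_identity(
    aligned_a: str, aligned_b: str, denominator: str = "columns"
) -> float:
    """Identity of an aligned pair.

    ``denominator="columns"`` counts alignment columns excluding double-gap
    columns (relevant for pairs projected out of a multiple alignment);
    ``"shorter"`` divides by the shorter de-gapped sequence length.
    """
    matches = cols = 0
    for x, y in zip(aligned_a, aligned_b):
        if x == "-" and y == "-":
            continue
        cols += 1
        if x == y:
            matches += 1
    if denominator == "columns":
        denom = cols
    elif denominator == "shorter":
        denom = min(
            len(aligned_a.replace("-", "")), len(aligned_b.replace("-", ""))
        )
    else:
        raise ValueError(f"unknown identity denominator {denominator!r}")
    return 100.0 * matches / denom if denom else 0.0


def global_align(
    seq_a: str,
    seq_b: str,
    matrix: substitution_matrices.Array | None = None,
    gap_open: float = -11.0,
    gap_extend: float = -1.0,
    identity_denominator: str = "columns",
) -> AlignmentResult:
    """Optimal global alignment under affine gaps (Needleman–Wunsch).

    A gap of length L costs ``gap_open + (L-1) * gap_extend``; end gaps are
    penalized like internal ones. Defaults use BLOSUM85 with open −11 /
    extend −1. Among co-optimal alignments the engine's first traceback is
    returned, which is deterministic for fixed inputs.
    """
    if not seq_a or not seq_b:
        raise ValueError("cannot align an empty sequence")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = matrix if matrix is not None else blosum85()
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    alignment = aligner.align(seq_a, seq_b)[0]
    aligned_a, aligned_b = str(alignment[0]), str(alignment[1])
    return AlignmentResult(
        aligned_a,
        aligned_b,
        float(alignment.score),
        percent_identity(aligned_a, aligned_b, identity_denominator),
    )


@dataclass
class ClusterAssignment:
    """Partition of proteins into redundancy clusters with representatives."""

    cluster_of: dict[str, int]
    representatives: dict[int, str]
    seed: int

    def is_representative(self, protein_id: str) -> bool:
        return self.representatives[self.cluster_of[protein_id]] == protein_id

    def filter_mutations(
        self, mutations: Iterable[MutationRecord]
    ) -> tuple[list[MutationRecord], int]:
        """Keep mutations on representatives; return (kept, n_discarded)."""
        kept, discarded = [], 0
        for m in mutations:
            if self.is_representative(m.protein_id):
                kept.append(m)
            else:
                discarded += 1
        return kept, discarded


def pairwise_identities(
    proteins: Sequence[ProteinRecord], **align_kwargs
) -> np.ndarray:
    """Symmetric matrix of pairwise global-alignment identities (%)."""
    n = len(proteins)
    identities = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            result = global_align(
                proteins[i].sequence, proteins[j].sequence, **align_kwargs
            )
            identities[i, j] = identities[j, i] = result.identity_pct
    return identities


def cluster_redundant(
    proteins: Sequence[ProteinRecord],
    identity_threshold: float = 40.0,
    seed: int = 0,
    identities: np.ndarray | None = None,
) -> ClusterAssignment:
    """Single-linkage redundancy clusters at an identity threshold.

    Clusters are the connected components of the graph whose edges join
    protein pairs with identity ≥ threshold (single linkage makes identity
    transitive). One representative per cluster is drawn uniformly with the
    given seed; the partition itself never depends on the seed, and the
    members are sorted by id before drawing so the outcome is independent
    of input order.
    """
    if not proteins:
        raise ValueError("need at least one protein")
    if not 0.0 < identity_threshold <= 100.0:
        raise ValueError("identity threshold must be in (0, 100]")
    if identities is None:
        identities = pairwise_identities(proteins)
    adjacency = csr_matrix(identities >= identity_threshold)
    n_components, labels = connected_components(adjacency, directed=False)
    cluster_of = {p.id: int(labels[i]) for i, p in enumerate(proteins)}
    rng = np.random.default_rng(seed)
    representatives = {}
    for cluster in range(n_components):
        members = sorted(pid for pid, c in cluster_of.items() if c == cluster)
        representatives[cluster] = members[rng.integers(len(members))]
    return ClusterAssignment(cluster_of, representatives, seed)


@dataclass
class OutlierReport:
    """Proteins flagged for extreme mutation counts, plus the mutation mass removed."""

    flagged: list[str]
    removed_fraction: float

    def filter_mutations(
        self, mutations: Iterable[MutationRecord]
    ) -> list[MutationRecord]:
        flagged = set(self.flagged)
        return [m for m in mutations if m.protein_id not in flagged]


def flag_outliers(
    mutations: Sequence[MutationRecord],
    method: str = "top_k",
    k_or_threshold: int = 4,
) -> OutlierReport:
    """Flag proteins with an unusually high number of mutations.

    ``top_k`` flags the k proteins with the highest mutation counts (ties
    broken by id for determinism); ``count_ge`` flags proteins with at
    least the given number of mutations.
    """
    counts: dict[str, int] = {}
    for m in mutations:
        counts[m.protein_id] = counts.get(m.protein_id, 0) + 1
    if method == "top_k":
        if k_or_threshold > len(counts):
            raise ValueError(
                f"top_k={k_or_threshold} exceeds number of proteins ({len(counts)})"
            )
        ranked = sorted(counts, key=lambda pid: (-counts[pid], pid))
        flagged = ranked[:k_or_threshold]
    elif method == "count_ge":
        flagged = sorted(pid for pid, n in counts.items() if n >= k_or_threshold)
    else:
        raise ValueError(f"unknown outlier method {method!r}")
    removed = sum(counts[pid] for pid in flagged)
    total = len(mutations)
    return OutlierReport(list(flagged), removed / total if total else 0.0)


def nes_from_alignment(
    human_protein: ProteinRecord,
    aligned_human: str,
    aligned_ortholog: str,
    dataset: str = "NES",
) -> list[MutationRecord]:
    """Pseudo-mutations human→ortholog from one aligned pair.

    Every column where the two residues differ, neither is a gap, and both
    are canonical yields one record at the human 1-based coordinate.
    Columns where the human sequence is gapped have no human coordinate and
    are skipped.
    """
    if aligned_human.replace("-", "") != human_protein.sequence:
        raise ValueError(
            f"{human_protein.id}: de-gapped aligned human sequence does not "
            "match the protein record"
        )
    records = []
    human_pos = 0
    for h, o in zip(aligned_human, aligned_ortholog):
        if h != "-":
            human_pos += 1
        if h == "-" or o == "-" or h == o:
            continue
        if h in _CANONICAL_SET and o in _CANONICAL_SET:
            records.append(
                MutationRecord(human_protein.id, human_pos, h, o, dataset)
            )
    return records


def extract_nes(
    human_protein: ProteinRecord,
    ortholog_alignments: Mapping[str, tuple[str, str]] | None = None,
    orthologs: Mapping[str, str] | None = None,
    min_identity: float = 95.0,
    disease_mutations: Iterable[MutationRecord] = (),
    keep_multiplicity: bool = False,
    dataset: str = "NES",
    **align_kwargs,
) -> list[MutationRecord]:
    """Neutral-evolutionary-substitution control for one human protein.

    Orthologs can be supplied pre-aligned (``ortholog_alignments``: id →
    (aligned human, aligned ortholog)) or as raw sequences (``orthologs``),
    in which case pairwise global alignments are computed here. Only
    orthologs with identity ≥ ``min_identity`` contribute. Records identical
    (protein, position, wt, mut) to an annotated disease mutation are
    filtered out. By default the same substitution seen in several orthologs
    is collapsed to one record (``keep_multiplicity=True`` retains each
    occurrence, matching a per-ortholog counting convention).
    """
    if ortholog_alignments is None:
        if orthologs is None:
            raise ValueError("provide ortholog_alignments or orthologs")
        ortholog_alignments = {}
        for oid, seq in orthologs.items():
            result = global_align(human_protein.sequence, seq, **align_kwargs)
            ortholog_alignments[oid] = (result.aligned_a, result.aligned_b)

    disease_keys = {m.key() for m in disease_mutations}
    out: list[MutationRecord] = []
    seen: set[tuple] = set()
    for oid in sorted(ortholog_alignments):
        aligned_h, aligned_o = ortholog_alignments[oid]
        if percent_identity(aligned_h, aligned_o) < min_identity:
            continue
        for record in nes_from_alignment(
            human_protein, aligned_h, aligned_o, dataset
        ):
            if record.key() in disease_keys:
                continue
            if not keep_multiplicity:
                if record.key() in seen:
                    continue
                seen.add(record.key())
            out.append(record)
    return out
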