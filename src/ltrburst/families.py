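"""LTR family classification and intact-element dating.

Intact LTR retrotransposons are grouped into families from their 5'-LTR
sequences by greedy centroid clustering (CD-HIT style): sequences are
visited longest first and join the first existing centroid they match at
>= 80% identity with >= 80% coverage, else found a new cluster.  Clusters
reaching the copy-number threshold (default 100) are families; the rest
are reported as below-threshold clusters, never silently discarded.

Each family's representative is its most recent member — the element with
the smallest 5'/3'-LTR divergence, since the two LTRs are identical at
insertion.  The same divergence dates an individual intact element:
t = d / (factor * r), with factor 2 by default because both LTRs accumulate
substitutions after insertion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio import Align, SeqIO

from .hits import IntactLTRPair

__all__ = [
    "LTRFamily",
    "FamilyResult",
    "classify_families",
    "select_representative",
    "date_intact_ltr",
    "read_fasta",
    "pairwise_identity",
]

DEFAULT_MIN_IDENTITY = 0.80
DEFAULT_MIN_COVERAGE = 0.80
DEFAULT_MIN_COPIES = 100
_DNA_CHARS = frozenset("ACGTN")


@dataclass
class LTRFamily:
    """A cluster of 5'-LTR sequences passing the family thresholds."""

    family_id: str
    members: list[str]
    representative: str | None = None

    @property
    def copy_number(self) -> int:
        return len(self.members)


@dataclass
class FamilyResult:
    """Families plus the clusters that fell below the copy threshold."""

    families: list[LTRFamily]
    below_threshold: list[LTRFamily]

    def all_clusters(self) -> list[LTRFamily]:
        return self.families + self.below_threshold


def read_fasta(path) -> list[tuple[str, str]]:
    """Read (id, sequence) pairs from a FASTA file, uppercased."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def _make_aligner(match: float, mismatch: float, gap: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    return aligner


def pairwise_identity(
    seq_a: str,
    seq_b: str,
    aligner: Align.PairwiseAligner | None = None,
) -> tuple[float, float]:
    """Global-alignment identity and coverage of two sequences.

    Identity is matched columns over the aligned span (columns where both
    sequences have a base); coverage is the aligned span over the longer
    sequence's length.  Scoring defaults to match 1 / mismatch -1 / gap -2.
    """
    if seq_a == seq_b:
        return 1.0, 1.0
    if aligner is None:
        aligner = _make_aligner(1.0, -1.0, -2.0)
    aln = aligner.align(seq_a, seq_b)[0]
    matches = 0
    span = 0
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        span += a1 - a0
        for ca, cb in zip(seq_a[a0:a1], seq_b[b0:b1]):
            if ca == cb:
                matches += 1
    if span == 0:
        return 0.0, 0.0
    return matches / span, span / max(len(seq_a), len(seq_b))


def classify_families(
    ltr5_seqs: Sequence[tuple[str, str]],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    min_copies: int = DEFAULT_MIN_COPIES,
    match_score: float = 1.0,
    mismatch_score: float = -1.0,
    gap_score: float = -2.0,
) -> FamilyResult:
    """Cluster 5'-LTR sequences into families.

    ``ltr5_seqs`` is a sequence of (element_id, DNA sequence).  Clustering
    is deterministic and independent of input order: sequences are sorted
    by length descending then id ascending, and each joins the first
    centroid meeting both the identity and coverage thresholds (the
    centroid is the cluster's founding, longest sequence).
    """
    if not ltr5_seqs:
        raise ValueError("no sequences to classify")
    seen: set[str] = set()
    for sid, seq in ltr5_seqs:
        if sid in seen:
            raise ValueError(f"duplicate sequence id {sid!r}")
        seen.add(sid)
        if not seq:
            raise ValueError(f"empty sequence for record {sid!r}")
        bad = set(seq.upper()) - _DNA_CHARS
        if bad:
            raise ValueError(
                f"non-DNA characters {sorted(bad)} in record {sid!r}"
            )

    aligner = _make_aligner(match_score, mismatch_score, gap_score)
    ordered = sorted(ltr5_seqs, key=lambda r: (-len(r[1]), r[0]))
    centroids: list[str] = []  # centroid sequence per cluster
    clusters: list[list[str]] = []
    for sid, seq in ordered:
        seq = seq.upper()
        placed = False
        for ci, centroid in enumerate(centroids):
            ident, cov = pairwise_identity(seq, centroid, aligner)
            if ident >= min_identity and cov >= min_coverage:
                clusters[ci].append(sid)
                placed = True
                break
        if not placed:
            centroids.append(seq)
            clusters.append([sid])

    families: list[LTRFamily] = []
    below: list[LTRFamily] = []
    for ci, members in enumerate(clusters):
        fam = LTRFamily(family_id=f"LTRfam_{ci + 1:03d}", members=sorted(members))
        (families if fam.copy_number >= min_copies else below).append(fam)
    return FamilyResult(families=families, below_threshold=below)


def select_representative(
    family: LTRFamily, pair_divergences: Mapping[str, float]
) -> str:
    """Pick the family's most recent member as its representative.

    "Most recent" is the member with minimal 5'/3'-LTR divergence (LTR
    pairs are identical at insertion, so low divergence means young); ties
    break lexicographically by element id.  The chosen id is also stored on
    the family.
    """
    missing = [m for m in family.members if m not in pair_divergences]
    if missing:
        raise KeyError(
            f"no 5'/3' divergence for members {missing} of {family.family_id}"
        )
    rep = min(family.members, key=lambda m: (pair_divergences[m], m))
    family.representative = rep
    return rep


def date_intact_ltr(
    pair: IntactLTRPair | float,
    r: float = 7e-9,
    lineage_factor: int = 2,
) -> float:
    """Age in years of an intact element from its 5'/3'-LTR divergence d.

    t = d / (lineage_factor * r).  The default factor 2 reflects that both
    LTRs diverge from their common insertion-time state; factor 1 treats d
    as one lineage's substitutions (the convention of the fragment-based
    clock t = K/r).
    """
    if r <= 0:
        raise ValueError(f"substitution rate r must be positive, got {r}")
    if lineage_factor not in (1, 2):
        raise ValueError(f"lineage_factor must be 1 or 2, got {lineage_factor}")
    d = pair.divergence_d if isinstance(pair, IntactLTRPair) else float(pair)
    if not 0.0 <= d <= 1.0:
        raise ValueError(f"divergence {d} outside [0, 1]")
    return d / (lineage_factor * r)


def write_families(result: FamilyResult, path) -> None:
    """Write families (and below-threshold clusters) as TSV."""
    with open(path, "w") as fh:
        fh.write("# family_id\tcopy_number\trepresentative\tstatus\tmembers\n")
        for fam in result.families:
            fh.write(
                f"{fam.family_id}\t{fam.copy_number}\t{fam.representative or '.'}"
                f"\tfamily\t{','.join(fam.members)}\n"
            )
        for fam in result.below_threshold:
            fh.write(
                f"{fam.family_id}\t{fam.copy_number}\t{fam.representative or '.'}"
                f"\tbelow_threshold\t{','.join(fam.members)}\n"
            )
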