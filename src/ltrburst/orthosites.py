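"""SNP and identical-site statistics on paired CDS alignments.

Given a codon-anchored pairwise alignment of two orthologous coding
sequences (frame starting at column 0), a *SNP site* is a gap-free column
where the two bases differ, and an *identical site* is a SNP column whose
substitution is synonymous — the codons containing it translate to the
same amino acid in both sequences.  Counting identical sites across
ortholog pairs measures silent divergence and hence how closely two
genomes are related.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from Bio.Seq import Seq
from Bio import SeqIO

__all__ = ["CDSPairAlignment", "SiteCounts", "count_sites", "read_cds_pair"]

_GAP = "-"
_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class CDSPairAlignment:
    """Two aligned coding sequences of equal length, frame at column 0."""

    seq_a: str
    seq_b: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq_a", self.seq_a.upper())
        object.__setattr__(self, "seq_b", self.seq_b.upper())
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError(
                f"aligned sequences differ in length: "
                f"{len(self.seq_a)} vs {len(self.seq_b)}"
            )
        for name, seq in (("seq_a", self.seq_a), ("seq_b", self.seq_b)):
            degapped = seq.replace(_GAP, "")
            if len(degapped) % 3 != 0:
                raise ValueError(
                    f"{name}: degapped length {len(degapped)} not divisible by 3"
                )


@dataclass(frozen=True)
class SiteCounts:
    snp_sites: int
    identical_sites: int
    compared_columns: int
    ambiguous_codons: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.identical_sites <= self.snp_sites <= self.compared_columns:
            raise ValueError(
                f"invalid counts: identical {self.identical_sites} <= "
                f"snp {self.snp_sites} <= compared {self.compared_columns} violated"
            )


def _codon_aas(degapped: str) -> list[str | None]:
    """Amino acid per codon; None marks codons carrying ambiguity codes."""
    aas: list[str | None] = []
    for i in range(0, len(degapped), 3):
        codon = degapped[i : i + 3]
        if set(codon) <= _BASES:
            aas.append(str(Seq(codon).translate()))
        else:
            aas.append(None)
    return aas


def count_sites(aln: CDSPairAlignment, snp_codon_mode: str = "whole") -> SiteCounts:
    """Count SNP and identical (synonymous-SNP) sites in a CDS pair.

    Columns with a gap in either sequence are excluded from
    ``compared_columns``.  Codons containing an ambiguity code (N etc.) in
    either sequence are excluded from every count and tallied in
    ``ambiguous_codons``.  Gap runs must preserve the reading frame (length
    a multiple of 3); a frame shift raises an error naming the first
    offending codon.

    ``snp_codon_mode`` controls codons holding more than one SNP:
    ``"whole"`` (default) classifies every SNP column by comparing the two
    full observed codons, so the columns share the codon's status;
    ``"single"`` re-evaluates each SNP column in isolation, substituting
    only that column's base into the first sequence's codon.
    """
    if snp_codon_mode not in ("whole", "single"):
        raise ValueError(f"unknown snp_codon_mode {snp_codon_mode!r}")
    a, b = aln.seq_a, aln.seq_b
    da = a.replace(_GAP, "")
    db = b.replace(_GAP, "")
    aas_a = _codon_aas(da)
    aas_b = _codon_aas(db)

    compared = snp = identical = 0
    ambiguous: set[tuple[int, int]] = set()
    ia = ib = 0
    for col, (ca, cb) in enumerate(zip(a, b)):
        ga, gb = ca == _GAP, cb == _GAP
        if ga and gb:
            continue
        if ga or gb:
            ia += not ga
            ib += not gb
            continue
        if ia % 3 != ib % 3:
            raise ValueError(
                f"frame broken by gaps before alignment column {col} "
                f"(codon {ia // 3 + 1} of seq_a vs codon {ib // 3 + 1} of seq_b)"
            )
        codon_a_idx, codon_b_idx = ia // 3, ib // 3
        if aas_a[codon_a_idx] is None or aas_b[codon_b_idx] is None:
            ambiguous.add((codon_a_idx, codon_b_idx))
            ia += 1
            ib += 1
            continue
        compared += 1
        if ca != cb:
            snp += 1
            if snp_codon_mode == "whole":
                same_aa = aas_a[codon_a_idx] == aas_b[codon_b_idx]
            else:
                codon_a = da[3 * codon_a_idx : 3 * codon_a_idx + 3]
                mutated = codon_a[: ia % 3] + cb + codon_a[ia % 3 + 1 :]
                same_aa = str(Seq(mutated).translate()) == aas_a[codon_a_idx]
            if same_aa:
                identical += 1
        ia += 1
        ib += 1
    return SiteCounts(
        snp_sites=snp,
        identical_sites=identical,
        compared_columns=compared,
        ambiguous_codons=len(ambiguous),
    )


def read_cds_pair(path: str | Path) -> CDSPairAlignment:
    """Read the first two records of an aligned FASTA as a CDS pair."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) < 2:
        raise ValueError(f"{path}: need at least 2 aligned records")
    return CDSPairAlignment(str(records[0].seq), str(records[1].seq))
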