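"""Reading and writing TE hit tables and tabular results.

A *TE hit* is one alignment of a genomic fragment to a representative
transposable-element sequence; all downstream dating works from the hit's
percent identity and alignment length.  Two input dialects are supported —
RepeatMasker ``.out`` and 12-column BLAST tabular (``-outfmt 6``) — and both
map onto the same :class:`TEHit` record, so identical (identity, length)
pairs yield identical downstream results regardless of the aligner used.

Internal coordinates are 0-based half-open; RepeatMasker/BLAST 1-based
inclusive coordinates are converted on read so that ``end - start`` is the
span.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "TEHit",
    "IntactLTRPair",
    "read_repeatmasker_out",
    "read_blast_tab",
    "read_hits",
    "write_hits",
    "write_distribution",
    "read_distribution",
    "write_peaks",
    "read_peaks",
    "read_ltr_pairs",
    "write_ltr_pairs",
]

_HIT_COLUMNS = (
    "query_id",
    "target_id",
    "identity",
    "aln_length",
    "query_start",
    "query_end",
    "strand",
)


@dataclass(frozen=True)
class TEHit:
    """One alignment of a genomic fragment to a representative TE.

    ``identity`` is percent in [0, 100]; ``aln_length`` is the alignment
    length in bp; coordinates are 0-based half-open on the genomic query.
    """

    query_id: str
    target_id: str
    identity: float
    aln_length: int
    query_start: int = 0
    query_end: int = 0
    strand: str = "+"

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 100.0:
            raise ValueError(f"identity {self.identity} outside [0, 100]")
        if self.aln_length < 1:
            raise ValueError(f"aln_length {self.aln_length} must be >= 1")
        if self.query_end < self.query_start:
            raise ValueError(
                f"query_end {self.query_end} < query_start {self.query_start}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass(frozen=True)
class IntactLTRPair:
    """An intact element's 5'- and 3'-LTR divergence.

    The two LTRs of an element are identical at insertion; ``divergence_d``
    (substitutions per site, uncorrected p-distance) records how far they
    have drifted apart since and therefore the element's age.
    """

    element_id: str
    divergence_d: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.divergence_d <= 1.0:
            raise ValueError(
                f"divergence_d {self.divergence_d} outside [0, 1] "
                f"for element {self.element_id}"
            )

    @classmethod
    def from_aligned(cls, element_id: str, ltr5: str, ltr3: str) -> "IntactLTRPair":
        """Build from two aligned LTR sequences (gap character ``-``).

        d is the mismatch fraction over columns where both sequences have a
        base (uncorrected p-distance).
        """
        if len(ltr5) != len(ltr3):
            raise ValueError("aligned LTR sequences must have equal length")
        compared = 0
        mism = 0
        for a, b in zip(ltr5.upper(), ltr3.upper()):
            if a == "-" or b == "-":
                continue
            compared += 1
            if a != b:
                mism += 1
        if compared == 0:
            raise ValueError(f"no comparable columns for element {element_id}")
        return cls(element_id, mism / compared)


def _normalize_coords(start_1based: int, end_1based: int) -> tuple[int, int]:
    lo, hi = sorted((start_1based, end_1based))
    return lo - 1, hi


def read_repeatmasker_out(path: str | Path) -> list[TEHit]:
    """Parse a RepeatMasker ``.out`` file into TE hits.

    The dialect has 3 header lines followed by whitespace-delimited rows;
    column 2 is "perc div.".  Identity is taken as ``100 - perc_div`` and
    1-based inclusive query coordinates are converted to 0-based half-open,
    so ``aln_length = end - start``.
    """
    path = Path(path)
    hits: list[TEHit] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if lineno <= 3:
                continue  # two column-header lines and a blank line
            if not line.strip():
                continue
            fields = line.split()
            try:
                perc_div = float(fields[1])
                query = fields[4]
                qbegin = int(fields[5])
                qend = int(fields[6])
                strand = "-" if fields[8] in ("C", "-") else "+"
                target = fields[9]
            except (IndexError, ValueError) as exc:
                raise ValueError(
                    f"{path}: malformed RepeatMasker row at line {lineno}: {exc}"
                ) from exc
            start, end = _normalize_coords(qbegin, qend)
            hits.append(
                TEHit(
                    query_id=query,
                    target_id=target,
                    identity=100.0 - perc_div,
                    aln_length=end - start,
                    query_start=start,
                    query_end=end,
                    strand=strand,
                )
            )
    if not hits:
        logger.warning("%s: no hits after headers", path)
    return hits


def read_blast_tab(path: str | Path) -> list[TEHit]:
    """Parse 12-column BLAST tabular output (``-outfmt 6``) into TE hits.

    Expected columns: qseqid sseqid pident length mismatch gapopen qstart
    qend sstart send evalue bitscore.  Subject orientation is inferred from
    ``sstart > send``.
    """
    path = Path(path)
    hits: list[TEHit] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) == 1:  # tolerate space-delimited variants
                fields = line.split()
            if len(fields) < 12:
                raise ValueError(
                    f"{path}: expected >=12 columns at line {lineno}, "
                    f"got {len(fields)}"
                )
            try:
                pident = float(fields[2])
                length = int(fields[3])
                qstart = int(fields[6])
                qend = int(fields[7])
                sstart = int(fields[8])
                send = int(fields[9])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: non-numeric field at line {lineno}: {exc}"
                ) from exc
            start, end = _normalize_coords(qstart, qend)
            hits.append(
                TEHit(
                    query_id=fields[0],
                    target_id=fields[1],
                    identity=pident,
                    aln_length=length,
                    query_start=start,
                    query_end=end,
                    strand="-" if sstart > send else "+",
                )
            )
    if not hits:
        logger.warning("%s: no hits parsed", path)
    return hits


def write_hits(hits: Iterable[TEHit], path: str | Path) -> None:
    """Write hits as TSV with a commented header line."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# " + "\t".join(_HIT_COLUMNS) + "\n")
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.target_id}\t{h.identity!r}\t{h.aln_length}"
                f"\t{h.query_start}\t{h.query_end}\t{h.strand}\n"
            )


def read_hits(path: str | Path) -> list[TEHit]:
    """Read the TSV written by :func:`write_hits`."""
    path = Path(path)
    hits: list[TEHit] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 7:
                raise ValueError(f"{path}: expected 7 columns at line {lineno}")
            hits.append(
                TEHit(f[0], f[1], float(f[2]), int(f[3]), int(f[4]), int(f[5]), f[6])
            )
    return hits


def write_distribution(dist, path: str | Path) -> None:
    """Write an identity distribution as TSV (bin_lo, bin_hi, count).

    The overflow tally (dots outside the binning range) is preserved in a
    comment line so the file round-trips.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# overflow\t{dist.overflow!r}\n")
        fh.write("# bin_lo\tbin_hi\tcount\n")
        for lo, hi, c in zip(dist.bin_edges[:-1], dist.bin_edges[1:], dist.counts):
            fh.write(f"{float(lo)!r}\t{float(hi)!r}\t{float(c)!r}\n")


def read_distribution(path: str | Path):
    """Read the TSV written by :func:`write_distribution`."""
    from .dots import IdentityDistribution
    import numpy as np

    path = Path(path)
    edges: list[float] = []
    counts: list[float] = []
    overflow = 0.0
    with path.open() as fh:
        for line in fh:
            if line.startswith("# overflow"):
                overflow = float(line.split("\t")[1])
                continue
            if line.startswith("#") or not line.strip():
                continue
            lo, hi, c = line.split("\t")
            if not edges:
                edges.append(float(lo))
            edges.append(float(hi))
            counts.append(float(c))
    return IdentityDistribution(
        bin_edges=np.asarray(edges), counts=np.asarray(counts), overflow=overflow
    )


def write_peaks(estimates: Sequence, path: str | Path) -> None:
    """Write burst estimates as JSON carrying mu, sigma, amplitude, adjusted
    R-squared, K, t and r.  Round-trips via :func:`read_peaks`."""
    path = Path(path)
    payload = {
        "peaks": [
            {
                "mu": e.peak.mu,
                "sigma_pct": e.peak.sigma_pct,
                "amplitude": e.peak.amplitude,
                "adj_r2": e.peak.adj_r2,
                "fit_window": list(e.peak.fit_window),
                "rejected": e.peak.rejected,
                "K": e.K,
                "t": e.t,
                "r": e.r,
                "mode": e.mode,
                "too_recent": e.too_recent,
            }
            for e in estimates
        ]
    }
    with path.open("w") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")


def read_peaks(path: str | Path) -> list:
    """Read the JSON written by :func:`write_peaks` back into estimates."""
    from .gpdf import BurstEstimate, GaussianPeak

    with Path(path).open() as fh:
        payload = json.load(fh)
    out = []
    for p in payload["peaks"]:
        peak = GaussianPeak(
            mu=p["mu"],
            sigma_pct=p["sigma_pct"],
            amplitude=p["amplitude"],
            adj_r2=p["adj_r2"],
            fit_window=tuple(p["fit_window"]),
            rejected=p["rejected"],
        )
        out.append(
            BurstEstimate(
                peak=peak,
                K=p["K"],
                t=p["t"],
                r=p["r"],
                mode=p["mode"],
                too_recent=p["too_recent"],
            )
        )
    return out


def read_ltr_pairs(path: str | Path) -> list[IntactLTRPair]:
    """Read a TSV of (element_id, divergence_d) rows; '#' lines are comments."""
    path = Path(path)
    pairs: list[IntactLTRPair] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            f = line.split()
            if len(f) < 2:
                raise ValueError(f"{path}: expected 2 columns at line {lineno}")
            pairs.append(IntactLTRPair(f[0], float(f[1])))
    return pairs


def write_ltr_pairs(pairs: Iterable[IntactLTRPair], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# element_id\tdivergence_d\n")
        for p in pairs:
            fh.write(f"{p.element_id}\t{p.divergence_d!r}\n")
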