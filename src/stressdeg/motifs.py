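"""IUPAC degenerate-consensus motif scanning of gene-anchored windows.

Reproduces the behaviour of classic consensus-pattern searchers
(fuzznuc-style): exact degenerate matching, overlapping matches all
reported, minus-strand sites found by scanning the forward sequence
for the reverse complement of the pattern.  Windows are anchored on
codons — a fixed-length window 5' of the start codon ("upstream"), the
start-through-stop span introns included ("intragenic"), and a
fixed-length window 3' of the stop codon ("downstream") — and each
extracted window is scanned independently, so a site straddling a
window boundary counts in no window.

Built-in motifs are the SKN-1 consensus RTCAT, the DAF-16 binding
element DBE (TRTTTAC) and the DAF-16 associated element DAE (CTTATCA).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from itertools import product
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .io import AnalysisConfig, FormatError

logger = logging.getLogger(__name__)

__all__ = [
    "MotifDefinition",
    "MotifMatch",
    "MotifCountTable",
    "DEFAULT_MOTIFS",
    "WINDOWS",
    "expand_iupac",
    "scan_sequence",
    "extract_windows",
    "count_motifs_by_region",
    "aggregate_motif_table",
    "scan_upstream_region",
    "load_genome",
    "read_motif_definitions",
]

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGTN",  # pattern N matches any base, including hard-masked N
}

WINDOWS = ("upstream", "intragenic", "downstream")


@dataclass(frozen=True)
class MotifDefinition:
    """A named degenerate consensus, assigned to a regulator class."""

    name: str
    pattern: str
    motif_class: str  # "SKN1" | "DBE" | "DAE"

    def __post_init__(self) -> None:
        if not self.pattern:
            raise FormatError("motif pattern must be non-empty")
        bad = set(self.pattern.upper()) - set(IUPAC)
        if bad:
            raise FormatError(f"illegal IUPAC letter(s) {sorted(bad)} in {self.pattern!r}")
        object.__setattr__(self, "pattern", self.pattern.upper())

    @property
    def reverse_complement(self) -> str:
        return str(Seq(self.pattern).reverse_complement())

    @property
    def is_palindromic(self) -> bool:
        return self.pattern == self.reverse_complement


DEFAULT_MOTIFS = (
    MotifDefinition("SKN-1", "RTCAT", "SKN1"),
    MotifDefinition("DBE", "TRTTTAC", "DBE"),
    MotifDefinition("DAE", "CTTATCA", "DAE"),
)

#: Motif classes pooled into the DAF-16 column group of the count table.
DAF16_CLASSES = ("DBE", "DAE")


@dataclass(frozen=True)
class MotifMatch:
    """One motif occurrence (0-based half-open interval)."""

    chrom: str
    start: int
    end: int
    strand: str
    motif: str
    window: str | None = None


def expand_iupac(pattern: str) -> set[str]:
    """All concrete sequences a degenerate pattern matches.

    Note ``N`` expands over A/C/G/T/N, since a hard-masked base is
    accepted only by pattern letter N.
    """
    pattern = pattern.upper()
    bad = set(pattern) - set(IUPAC)
    if bad:
        raise FormatError(f"illegal IUPAC letter(s) {sorted(bad)} in {pattern!r}")
    return {"".join(p) for p in product(*(IUPAC[c] for c in pattern))}


def _regex(pattern: str) -> re.Pattern:
    # lookahead so overlapping occurrences are all reported
    return re.compile("(?=(" + "".join(f"[{IUPAC[c]}]" for c in pattern) + "))")


def scan_sequence(
    sequence: str,
    motif: MotifDefinition,
    both_strands: bool = True,
    chrom: str = "",
    offset: int = 0,
    window: str | None = None,
) -> list[MotifMatch]:
    """All occurrences of ``motif`` in ``sequence``.

    Soft-masked (lowercase) bases are uppercased first; a sequence
    ``N`` matches only pattern letter N.  Minus-strand sites are found
    by scanning the forward sequence for the reverse complement of the
    pattern and reported with strand ``-``.  For a palindromic pattern
    each interval is reported once (strand ``+``).  ``offset`` shifts
    reported coordinates into genome space.
    """
    seq = sequence.upper()
    if not seq:
        return []
    matches = [
        MotifMatch(chrom, offset + m.start(), offset + m.start() + len(motif.pattern),
                   "+", motif.name, window)
        for m in _regex(motif.pattern).finditer(seq)
    ]
    if both_strands and not motif.is_palindromic:
        matches += [
            MotifMatch(chrom, offset + m.start(),
                       offset + m.start() + len(motif.pattern),
                       "-", motif.name, window)
            for m in _regex(motif.reverse_complement).finditer(seq)
        ]
    return sorted(matches, key=lambda m: (m.start, m.strand))


# ---------------------------------------------------------------------------
# Window extraction
# ---------------------------------------------------------------------------


def load_genome(source) -> dict[str, str]:
    """Load a FASTA (path or mapping) into an in-memory chrom->sequence dict."""
    if isinstance(source, Mapping):
        return {str(k): str(v) for k, v in source.items()}
    import pyfaidx

    fasta = pyfaidx.Fasta(str(source), as_raw=True, sequence_always_upper=False)
    return {name: str(fasta[name][:]) for name in fasta.keys()}


def extract_windows(
    gene: pd.Series,
    genome: Mapping[str, str],
    upstream_bp: int = 2000,
    downstream_bp: int = 2000,
) -> dict[str, str]:
    """The three codon-anchored windows of a gene, in gene orientation.

    ``gene`` is an annotation row (needs chrom, strand,
    start_codon_pos = genomic position of the first base of the start
    codon in gene orientation, stop_codon_pos = genomic position of the
    last base of the stop codon).  Windows running off a contig end are
    clipped with a warning; a gene lying entirely off its contig is an
    error.
    """
    chrom = gene["chrom"]
    if chrom not in genome:
        raise KeyError(f"chromosome {chrom!r} absent from genome for gene {gene.name!r}")
    seq = genome[chrom]
    L = len(seq)
    strand = gene["strand"]
    start_codon = int(gene["start_codon_pos"])
    stop_codon = int(gene["stop_codon_pos"])
    if not (0 <= start_codon < L and 0 <= stop_codon < L):
        raise ValueError(f"gene {gene.name!r} lies off contig {chrom!r}")

    if strand == "+":
        intervals = {
            "upstream": (start_codon - upstream_bp, start_codon),
            "intragenic": (start_codon, stop_codon + 1),
            "downstream": (stop_codon + 1, stop_codon + 1 + downstream_bp),
        }
    else:
        intervals = {
            "upstream": (start_codon + 1, start_codon + 1 + upstream_bp),
            "intragenic": (stop_codon, start_codon + 1),
            "downstream": (stop_codon - downstream_bp, stop_codon),
        }

    out = {}
    for name, (lo, hi) in intervals.items():
        clipped_lo, clipped_hi = max(lo, 0), min(hi, L)
        if (clipped_lo, clipped_hi) != (lo, hi):
            logger.warning(
                "gene %s: %s window clipped to contig bounds [%d, %d)",
                gene.name, name, clipped_lo, clipped_hi,
            )
        piece = seq[clipped_lo:clipped_hi]
        if strand == "-":
            piece = str(Seq(piece).reverse_complement())
        out[name] = piece
    return out


# ---------------------------------------------------------------------------
# Counting
# ---------------------------------------------------------------------------


@dataclass
class MotifCountTable:
    """Per-gene, per-window motif counts with a column-sum totals row.

    ``rows`` is indexed by gene_id with one column group per regulator
    (SKN-1 counts; DBE and DAE pooled into the DAF-16 group), each
    group holding upstream / intragenic / downstream / total columns.
    """

    rows: pd.DataFrame
    totals: pd.Series

    def with_totals(self) -> pd.DataFrame:
        totals = self.totals.to_frame().T
        totals.index = pd.Index(["Total"], name=self.rows.index.name)
        return pd.concat([self.rows, totals])


COUNT_COLUMNS = [
    f"{group}_{window}"
    for group in ("skn1", "daf16")
    for window in (*WINDOWS, "total")
]


def _group_of(motif: MotifDefinition) -> str:
    return "daf16" if motif.motif_class in DAF16_CLASSES else "skn1"


def count_motifs_by_region(
    genes: pd.DataFrame,
    genome: Mapping[str, str],
    motifs: Sequence[MotifDefinition] = DEFAULT_MOTIFS,
    config: AnalysisConfig | None = None,
) -> MotifCountTable:
    """Both-strand motif counts per gene and window, plus totals.

    Each window is extracted and scanned independently, so only sites
    fully contained in a window are counted.  DBE and DAE counts are
    pooled into the DAF-16 column group.
    """
    config = config or AnalysisConfig()
    rows = {}
    for gene_id, gene in genes.iterrows():
        windows = extract_windows(
            gene, genome, config.upstream_window_bp, config.downstream_window_bp
        )
        counts = dict.fromkeys(COUNT_COLUMNS, 0)
        for window, seq in windows.items():
            for motif in motifs:
                n = len(scan_sequence(seq, motif, both_strands=True))
                group = _group_of(motif)
                counts[f"{group}_{window}"] += n
                counts[f"{group}_total"] += n
        rows[gene_id] = counts
    frame = pd.DataFrame.from_dict(rows, orient="index", dtype=np.int64)
    if frame.empty:
        frame = pd.DataFrame(columns=COUNT_COLUMNS, dtype=np.int64)
    frame = frame[COUNT_COLUMNS]
    frame.index.name = "gene_id"
    return MotifCountTable(frame, aggregate_motif_table(frame))


def aggregate_motif_table(rows: pd.DataFrame) -> pd.Series:
    """Column-wise totals row of a motif count table.

    Validates the row-total invariant (each gene's total column equals
    the sum of its three window columns) before summing.
    """
    if rows.empty:
        return pd.Series(0, index=COUNT_COLUMNS, dtype=np.int64)
    for group in ("skn1", "daf16"):
        window_sum = sum(rows[f"{group}_{w}"] for w in WINDOWS)
        if not (window_sum == rows[f"{group}_total"]).all():
            bad = rows.index[(window_sum != rows[f"{group}_total"]).to_numpy()][0]
            raise ValueError(f"row total mismatch for gene {bad!r} ({group})")
    return rows.sum(axis=0).astype(np.int64)


def scan_upstream_region(
    gene: pd.Series,
    genome: Mapping[str, str],
    motifs: Sequence[MotifDefinition] = DEFAULT_MOTIFS,
    window_bp: int = 4000,
) -> pd.DataFrame:
    """Strand-resolved counts in an upstream-only window (default 4 kb).

    Unlike the pooled count table, DBE and DAE are kept separate here,
    mirroring the per-motif description of single-promoter scans.
    Returns a frame indexed by motif name with columns plus / minus /
    both.
    """
    windows = extract_windows(gene, genome, upstream_bp=window_bp, downstream_bp=1)
    seq = windows["upstream"]
    out = {}
    for motif in motifs:
        matches = scan_sequence(seq, motif, both_strands=True)
        plus = sum(1 for m in matches if m.strand == "+")
        minus = sum(1 for m in matches if m.strand == "-")
        out[motif.name] = {"plus": plus, "minus": minus, "both": plus + minus}
    frame = pd.DataFrame.from_dict(out, orient="index", dtype=np.int64)
    frame.index.name = "motif"
    return frame


def matches_to_bed(matches: Iterable[MotifMatch]) -> pd.DataFrame:
    """Motif matches as a 6-column BED frame (score column unused)."""
    return pd.DataFrame(
        [
            {"chrom": m.chrom, "start": m.start, "end": m.end,
             "name": m.motif, "score": ".", "strand": m.strand}
            for m in matches
        ],
        columns=["chrom", "start", "end", "name", "score", "strand"],
    )


def read_motif_definitions(path: str | Path) -> tuple[MotifDefinition, ...]:
    """Read motif overrides from a TSV with columns name, pattern, class."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"name", "pattern", "class"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: motif TSV needs columns {sorted(required)}")
    return tuple(
        MotifDefinition(r["name"], r["pattern"], r["class"]) for _, r in df.iterrows()
    )
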