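"""Core data containers and TSV/JSON readers and writers.

The analysis operates on four single-replicate RNA-Seq libraries from a
two-strain (wild type vs. *pmk-1* knockout), two-condition (control vs.
cadmium stress) design.  This module holds the shared containers — the
read-count table, per-gene annotation, gene sets and the run
configuration — plus the plain-text formats they live in on disk.

Conventions
-----------
* Genomic intervals are 0-based, half-open internally (BED dialect on
  disk).  Readers accept 1-based inclusive coordinates only through an
  explicit ``one_based=True`` flag.
* Count and annotation tables are tab-separated with a header row;
  lines starting with ``#`` are provenance comments and are skipped.
* ``library_sizes`` defaults to the column sums of the count matrix;
  an explicit override row (gene_id ``__library_size__``) is honoured
  when present.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical library names of the two-strain, two-condition design.
CANONICAL_LIBRARIES = ("WT_ctrl", "WT_Cd", "pmk1_ctrl", "pmk1_Cd")

#: The 25 single-letter KOG functional categories (euKaryotic clusters
#: of Orthologous Groups).
KOG_CATEGORIES = "ABCDEFGHIJKLMNOPQRSTUVWYZ"

#: Row key that, when present in a counts TSV, carries per-library
#: total-mapped-read overrides instead of gene counts.
LIBRARY_SIZE_ROW = "__library_size__"

ANNOTATION_COLUMNS = (
    "gene_id",
    "transcript_length_bp",
    "kog_code",
    "chrom",
    "gene_start",
    "gene_end",
    "strand",
    "start_codon_pos",
    "stop_codon_pos",
)


class FormatError(ValueError):
    """Raised when an input file violates the documented format."""


# ---------------------------------------------------------------------------
# AnalysisConfig
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable thresholds and windows of the whole analysis.

    Parameters
    ----------
    fdr_threshold
        Benjamini–Hochberg q-value below which a gene is called a DEG
        (default 0.005).
    kog_alpha
        Chi-square significance level for a KOG category to be flagged
        as deviating from the contrast-wide up/down ratio (default
        0.001; 0.05 is the common alternative).
    strong_log2fc_cutoff, strong_diff_cutoff
        The strong-DEG rule: |log2 fold change| must exceed
        ``strong_log2fc_cutoff`` in at least one stress contrast and
        the WT-vs-mutant log2 fold-change difference must exceed
        ``strong_diff_cutoff`` (defaults 2 and 1, in log2 units).
    rpkm_pseudocount
        Added to numerator and denominator RPKM before forming the
        fold-change ratio; never added to the counts used by the
        significance test (default 0.1 RPKM).
    upstream_window_bp, downstream_window_bp
        Motif-scan window lengths 5' of the start codon and 3' of the
        stop codon (default 2000 bp each; 4000 bp is used for the
        dedicated upstream-only scan).
    change_metric
        Per-gene expression-change metric of the target-set analysis:
        ``"rpkm_difference"`` (signed, linear scale; default) or
        ``"log2_fold_change"``.
    rng_seed
        Seed recorded in all outputs and used by any stochastic step.
    """

    fdr_threshold: float = 0.005
    kog_alpha: float = 0.001
    strong_log2fc_cutoff: float = 2.0
    strong_diff_cutoff: float = 1.0
    rpkm_pseudocount: float = 0.1
    upstream_window_bp: int = 2000
    downstream_window_bp: int = 2000
    change_metric: str = "rpkm_difference"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fdr_threshold", "kog_alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v!r}")
        for name in (
            "strong_log2fc_cutoff",
            "strong_diff_cutoff",
            "upstream_window_bp",
            "downstream_window_bp",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.rpkm_pseudocount < 0:
            raise ValueError("rpkm_pseudocount must be non-negative")
        if self.change_metric not in ("rpkm_difference", "log2_fold_change"):
            raise ValueError(
                "change_metric must be 'rpkm_difference' or 'log2_fold_change', "
                f"got {self.change_metric!r}"
            )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True) + "\n"
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "AnalysisConfig":
        return cls(**json.loads(Path(path).read_text()))

    def replace(self, **changes) -> "AnalysisConfig":
        return dataclasses.replace(self, **changes)


# ---------------------------------------------------------------------------
# CountTable
# ---------------------------------------------------------------------------


@dataclass
class CountTable:
    """Integer read counts, one column per sequencing library.

    ``counts`` is indexed by unique gene identifiers; ``library_sizes``
    holds the total mapped reads per library and defaults to the column
    sums (the totals actually used by RPKM and by the count test).
    """

    counts: pd.DataFrame
    library_sizes: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise FormatError(f"duplicate gene id {dup!r} in count table")
        values = self.counts.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            if not np.all(np.isfinite(values)) or np.any(np.mod(values, 1) != 0):
                raise FormatError("count table contains non-integer cells")
            self.counts = self.counts.astype(np.int64)
        if values.size and (self.counts.to_numpy() < 0).any():
            raise FormatError("count table contains negative cells")
        if self.library_sizes is None:
            self.library_sizes = self.counts.sum(axis=0).astype(np.int64)
        else:
            self.library_sizes = pd.Series(self.library_sizes).reindex(
                self.counts.columns
            )
            if self.library_sizes.isna().any():
                missing = self.library_sizes.index[self.library_sizes.isna()]
                raise FormatError(f"library_sizes missing for {list(missing)}")
            self.library_sizes = self.library_sizes.astype(np.int64)
        if self.counts.shape[0] and (self.library_sizes <= 0).any():
            raise FormatError("library sizes must be positive")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def libraries(self) -> list[str]:
        return list(self.counts.columns)

    def merge_replicates(self, mapping: Mapping[str, Sequence[str]]) -> "CountTable":
        """Pool replicate columns by summation into one library each.

        ``mapping`` sends each output library name to the input columns
        it pools.  Library sizes are summed accordingly.
        """
        cols = {}
        sizes = {}
        for name, members in mapping.items():
            missing = [m for m in members if m not in self.counts.columns]
            if missing:
                raise FormatError(f"unknown replicate columns {missing} for {name!r}")
            cols[name] = self.counts[list(members)].sum(axis=1)
            sizes[name] = int(self.library_sizes[list(members)].sum())
        return CountTable(pd.DataFrame(cols), pd.Series(sizes))

    def to_tsv(self, path: str | Path, comment: str | None = None,
               include_library_sizes: bool = False) -> None:
        frame = self.counts
        if include_library_sizes:
            sizes = self.library_sizes.to_frame().T
            sizes.index = pd.Index([LIBRARY_SIZE_ROW])
            frame = pd.concat([sizes, frame])
        write_tsv(frame.rename_axis("gene_id").reset_index(), path, comment=comment)


def read_count_table(path: str | Path) -> CountTable:
    """Read a counts TSV (header ``gene_id`` + library names)."""
    df = _read_tsv(path)
    if df.columns[0] != "gene_id":
        raise FormatError(f"{path}: first column must be 'gene_id', got {df.columns[0]!r}")
    df = df.set_index("gene_id")
    sizes = None
    if LIBRARY_SIZE_ROW in df.index:
        sizes = df.loc[LIBRARY_SIZE_ROW].astype(np.int64).rename(None)
        df = df.drop(index=LIBRARY_SIZE_ROW)
    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() | (np.mod(numeric.fillna(0), 1) != 0) | (numeric < 0)
        if bad.any():
            row = df.index[bad.to_numpy().nonzero()[0][0]]
            raise FormatError(
                f"{path}: non-integer or negative count at gene {row!r}, column {col!r}"
            )
        df[col] = numeric.astype(np.int64)
    return CountTable(df, sizes)


# ---------------------------------------------------------------------------
# Gene annotation
# ---------------------------------------------------------------------------


def validate_annotation(ann: pd.DataFrame) -> pd.DataFrame:
    """Enforce the per-gene annotation invariants; returns the frame."""
    if ann.index.name != "gene_id":
        raise FormatError("annotation must be indexed by gene_id")
    if ann.index.has_duplicates:
        dup = ann.index[ann.index.duplicated()][0]
        raise FormatError(f"duplicate gene id {dup!r} in annotation")
    if (ann["transcript_length_bp"] <= 0).any():
        raise FormatError("transcript_length_bp must be positive")
    bad_strand = ~ann["strand"].isin(["+", "-"])
    if bad_strand.any():
        raise FormatError(
            f"unknown strand symbol {ann['strand'][bad_strand].iloc[0]!r}"
        )
    if (ann["gene_start"] >= ann["gene_end"]).any():
        gene = ann.index[(ann["gene_start"] >= ann["gene_end"]).to_numpy()][0]
        raise FormatError(f"gene_start >= gene_end for gene {gene!r}")
    for col in ("start_codon_pos", "stop_codon_pos"):
        outside = (ann[col] < ann["gene_start"]) | (ann[col] >= ann["gene_end"])
        if outside.any():
            gene = ann.index[outside.to_numpy()][0]
            raise FormatError(f"{col} outside gene span for gene {gene!r}")
    with_kog = ann["kog_code"].notna() & (ann["kog_code"] != "")
    letters = set("".join(ann.loc[with_kog, "kog_code"].astype(str)))
    unknown = letters - set(KOG_CATEGORIES)
    if unknown:
        raise FormatError(f"kog_code letters outside the category alphabet: {sorted(unknown)}")
    return ann


def read_annotation(path: str | Path, one_based: bool = False) -> pd.DataFrame:
    """Read the gene annotation TSV into a gene_id-indexed frame.

    With ``one_based=True``, coordinate columns are interpreted as
    1-based inclusive and converted to the internal 0-based half-open
    convention.
    """
    df = _read_tsv(path)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing annotation columns {missing}")
    df = df.set_index("gene_id")
    df["kog_code"] = df["kog_code"].fillna("").astype(str)
    for col in ("transcript_length_bp", "gene_start", "gene_end",
                "start_codon_pos", "stop_codon_pos"):
        df[col] = pd.to_numeric(df[col]).astype(np.int64)
    if one_based:
        for col in ("gene_start", "start_codon_pos", "stop_codon_pos"):
            df[col] -= 1
    return validate_annotation(df)


def write_annotation(ann: pd.DataFrame, path: str | Path,
                     comment: str | None = None) -> None:
    write_tsv(ann.reset_index(), path, comment=comment)


# ---------------------------------------------------------------------------
# GeneSet
# ---------------------------------------------------------------------------


@dataclass
class GeneSet:
    """A named collection of gene identifiers, optionally class-labelled.

    Stands in for published regulator target lists (SKN-1 targets,
    DAF-16 class I/II targets) and curated families (chaperones, ABC
    transporters).
    """

    name: str
    members: tuple[str, ...]
    class_labels: dict[str, str] | None = None

    def __post_init__(self) -> None:
        deduped = tuple(dict.fromkeys(self.members))
        if len(deduped) != len(self.members):
            logger.info(
                "gene set %s: %d duplicate entries dropped",
                self.name, len(self.members) - len(deduped),
            )
        self.members = deduped
        if self.class_labels is not None:
            missing = [m for m in self.members if m not in self.class_labels]
            if missing:
                raise FormatError(
                    f"gene set {self.name}: class_labels missing for {missing[:3]}"
                )

    def __len__(self) -> int:
        return len(self.members)


def read_gene_set(path: str | Path, name: str | None = None) -> GeneSet:
    """Read a gene set: one gene per line, optional second column = class."""
    path = Path(path)
    members: list[str] = []
    labels: dict[str, str] = {}
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        members.append(parts[0])
        if len(parts) > 1:
            labels[parts[0]] = parts[1]
    if not members:
        logger.warning("gene set file %s is empty", path)
    if labels and len(labels) < len(set(members)):
        # partial labels are treated as unlabelled to keep the invariant
        logger.warning("gene set %s: labels present for only some members; ignored", path)
        labels = {}
    return GeneSet(name or path.stem, tuple(members), labels or None)


def write_gene_set(gene_set: GeneSet, path: str | Path) -> None:
    lines = []
    for m in gene_set.members:
        if gene_set.class_labels:
            lines.append(f"{m}\t{gene_set.class_labels[m]}")
        else:
            lines.append(m)
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# BED and shared TSV helpers
# ---------------------------------------------------------------------------

BED_COLUMNS = ("chrom", "start", "end", "name", "score", "strand")


def read_genes_bed(path: str | Path) -> pd.DataFrame:
    """Read a 6-column BED of gene spans (name = gene_id)."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=BED_COLUMNS, dtype={"chrom": str, "name": str})
    if df.shape[0] and ((df["start"] < 0).any() or (df["start"] >= df["end"]).any()):
        raise FormatError(f"{path}: malformed BED interval")
    bad = ~df["strand"].isin(["+", "-"])
    if bad.any():
        raise FormatError(f"{path}: unknown strand {df['strand'][bad].iloc[0]!r}")
    return df


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    df.loc[:, list(BED_COLUMNS)].to_csv(path, sep="\t", header=False, index=False)


def write_tsv(df: pd.DataFrame, path: str | Path, comment: str | None = None,
              index: bool = False) -> None:
    """Write a TSV with an optional leading ``#`` provenance comment."""
    path = Path(path)
    with open(path, "w") as handle:
        if comment:
            handle.write(f"# {comment}\n")
        df.to_csv(handle, sep="\t", index=index)


def provenance_comment(config: AnalysisConfig, **extra) -> str:
    payload = {"config": dataclasses.asdict(config), **extra}
    return "stressdeg " + json.dumps(payload, sort_keys=True)


def _read_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype={0: str})
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: missing header row") from exc
    return df
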