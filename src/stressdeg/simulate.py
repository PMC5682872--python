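"""Seeded synthetic inputs with the statistical structure the analysis assumes.

The generator emulates the study design end to end: four single-replicate
Poisson (optionally negative-binomial) count libraries with planted
cadmium responses of known direction, magnitude and strain bias; KOG
letters; target-gene sets enriched for WT-biased responders; and a
synthetic genome whose gene-anchored windows carry motif occurrences at
recorded positions and strands, with a motif-free background guarantee
enforced by edit-and-verify.  Every sub-generator draws from a stream
split off one seed, so identical configurations reproduce byte-identical
bundles.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .io import (
    AnalysisConfig,
    CANONICAL_LIBRARIES,
    CountTable,
    GeneSet,
    KOG_CATEGORIES,
    validate_annotation,
    write_annotation,
    write_bed,
    write_gene_set,
    write_tsv,
)
from .motifs import DEFAULT_MOTIFS, MotifDefinition, expand_iupac, scan_sequence

logger = logging.getLogger(__name__)

__all__ = [
    "TargetSetSpec",
    "GenomeSpec",
    "SimulationConfig",
    "SimulatedData",
    "simulate_counts",
    "simulate_gene_sets",
    "simulate_genome",
    "simulate_bundle",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1").astype("U1")

#: Minimum background gap between two planted motif intervals; with the
#: built-in motif lengths this guarantees every spurious match overlaps
#: at least one editable background base.
_PLANT_GAP = 3


@dataclass(frozen=True)
class TargetSetSpec:
    """One synthetic stand-in for a published target-gene list."""

    name: str
    size: int
    wt_bias_enrichment: float = 0.7  # fraction of members drawn from WT-biased responders
    class_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.size < 0:
            raise ValueError("target set size must be non-negative")
        if not 0.0 <= self.wt_bias_enrichment <= 1.0:
            raise ValueError("wt_bias_enrichment must lie in [0, 1]")


@dataclass(frozen=True)
class GenomeSpec:
    """Layout of the synthetic genome used for motif scanning.

    Only the first ``n_genes`` genes of the simulated universe are
    placed on sequence contigs (a genome the size of the full gene
    universe adds nothing to window-level scanning); the rest keep
    placeholder coordinates on an unsequenced contig.
    """

    n_genes: int = 300
    n_contigs: int = 3
    upstream_bp: int = 2000
    downstream_bp: int = 2000
    intragenic_bp: tuple[int, int] = (900, 3000)
    spacer_bp: int = 200
    #: expected planted occurrences per gene, window and strand
    planted_rates: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "SKN-1": (1.0, 0.5, 0.8),
            "DBE": (0.6, 0.2, 0.4),
            "DAE": (0.6, 0.2, 0.4),
        }
    )

    def __post_init__(self) -> None:
        if self.n_contigs <= 0 or self.upstream_bp <= 0 or self.downstream_bp <= 0:
            raise ValueError("genome dimensions must be positive")
        lo, hi = self.intragenic_bp
        if lo < 100 or hi < lo:
            raise ValueError("intragenic_bp range must be sane (>=100, lo<=hi)")
        if self.spacer_bp < _PLANT_GAP:
            raise ValueError("spacer too tight to host window boundaries")


@dataclass(frozen=True)
class SimulationConfig:
    """Study-scale defaults for the synthetic bundle.

    The defaults mirror the real design: ~20k protein-coding genes,
    four libraries of ten million mapped reads, roughly a fifth of the
    genome cadmium-responsive with upregulation dominating, and a
    majority of responders reacting more strongly in the wild type
    than in the kinase mutant.
    """

    n_genes: int = 20_000
    baseline_rpkm_median: float = 10.0
    baseline_rpkm_log_sd: float = 1.5
    length_median_bp: int = 1500
    length_log_sd: float = 0.6
    library_sizes: tuple[int, int, int, int] = (10_000_000,) * 4
    deg_fraction_stress: float = 0.2
    effect_mean_log2: float = 3.0
    effect_sd_log2: float = 1.0
    up_fraction: float = 0.7
    wt_bias_fraction: float = 0.6
    bias_log2: float = 1.5
    kog_assigned_fraction: float = 0.7
    kog_alphabet: str = KOG_CATEGORIES
    kog_weights: tuple[float, ...] | None = None
    target_set_specs: tuple[TargetSetSpec, ...] = (
        TargetSetSpec("SKN1_targets", 400, 0.7),
        TargetSetSpec("DAF16_targets", 500, 0.6, ("I", "II")),
        TargetSetSpec("chaperones", 60, 0.7),
        TargetSetSpec("ABC_transporters", 60, 0.5),
    )
    genome: GenomeSpec = field(default_factory=GenomeSpec)
    overdispersion: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 0:
            raise ValueError("n_genes must be non-negative")
        for name in ("deg_fraction_stress", "up_fraction", "wt_bias_fraction",
                     "kog_assigned_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v!r}")
        if len(self.library_sizes) != 4 or any(n <= 0 for n in self.library_sizes):
            raise ValueError("library_sizes must be four positive integers")
        if self.overdispersion < 0:
            raise ValueError("overdispersion must be non-negative")
        if self.kog_weights is not None and len(self.kog_weights) != len(self.kog_alphabet):
            raise ValueError("kog_weights must match kog_alphabet length")

    def to_json(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        payload["target_set_specs"] = [dataclasses.asdict(s) for s in self.target_set_specs]
        payload["genome"] = dataclasses.asdict(self.genome)
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationConfig":
        payload = json.loads(Path(path).read_text())
        payload["target_set_specs"] = tuple(
            TargetSetSpec(
                name=s["name"], size=s["size"],
                wt_bias_enrichment=s["wt_bias_enrichment"],
                class_labels=tuple(s["class_labels"]) if s["class_labels"] else None,
            )
            for s in payload["target_set_specs"]
        )
        genome = payload["genome"]
        genome["intragenic_bp"] = tuple(genome["intragenic_bp"])
        genome["planted_rates"] = {
            k: tuple(v) for k, v in genome["planted_rates"].items()
        }
        payload["genome"] = GenomeSpec(**genome)
        payload["library_sizes"] = tuple(payload["library_sizes"])
        if payload.get("kog_weights") is not None:
            payload["kog_weights"] = tuple(payload["kog_weights"])
        return cls(**payload)


@dataclass
class SimulatedData:
    """A full in-memory synthetic bundle plus its ground truth."""

    config: SimulationConfig
    counts: CountTable
    annotation: pd.DataFrame
    truth: pd.DataFrame
    gene_sets: list[GeneSet]
    genome: dict[str, str]
    genes_bed: pd.DataFrame
    motif_truth: pd.DataFrame


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# Counts
# ---------------------------------------------------------------------------


def simulate_counts(
    config: SimulationConfig, rng: np.random.Generator | None = None
):
    """Draw the four-library count table, annotation and truth table.

    Expected counts are the RPKM-implied means given transcript length
    and library size; cadmium-responsive genes scale their stressed-
    library means by the planted fold change, with the strain bias
    applied to the mutant effect.  Counts are Poisson, or negative
    binomial when ``overdispersion`` > 0 (variance m + d*m^2).
    """
    rng = rng or _streams(config.rng_seed, 3)[0]
    n = config.n_genes
    gene_ids = pd.Index([f"g{i:05d}" for i in range(n)], name="gene_id")

    lengths = np.maximum(
        150,
        np.round(
            config.length_median_bp * np.exp(rng.normal(0.0, config.length_log_sd, n))
        ).astype(np.int64),
    ) if n else np.zeros(0, dtype=np.int64)
    baseline = config.baseline_rpkm_median * np.exp(
        rng.normal(0.0, config.baseline_rpkm_log_sd, n)
    )

    responsive = rng.random(n) < config.deg_fraction_stress
    sign = np.where(rng.random(n) < config.up_fraction, 1.0, -1.0)
    magnitude = np.maximum(
        0.25, np.abs(rng.normal(config.effect_mean_log2, config.effect_sd_log2, n))
    )
    fc_wt = np.where(responsive, sign * magnitude, 0.0)
    wt_biased = rng.random(n) < config.wt_bias_fraction
    bias_label = np.where(
        responsive, np.where(wt_biased, "wt", "pmk1"), "none"
    )
    shift = np.where(wt_biased, -config.bias_log2, config.bias_log2)
    fc_pk = np.where(responsive, fc_wt + sign * shift, 0.0)

    has_kog = rng.random(n) < config.kog_assigned_fraction
    letters = rng.choice(
        list(config.kog_alphabet),
        size=n if n else 0,
        p=(np.asarray(config.kog_weights) / np.sum(config.kog_weights))
        if config.kog_weights
        else None,
    ) if n else np.array([], dtype="U1")
    kog = np.where(has_kog, letters, "")

    sizes = dict(zip(CANONICAL_LIBRARIES, config.library_sizes))
    rpkm_by_lib = {
        "WT_ctrl": baseline,
        "WT_Cd": baseline * np.exp2(fc_wt),
        "pmk1_ctrl": baseline,
        "pmk1_Cd": baseline * np.exp2(fc_pk),
    }
    counts = {}
    for lib in CANONICAL_LIBRARIES:
        mean = rpkm_by_lib[lib] * (lengths / 1e3) * (sizes[lib] / 1e6)
        if config.overdispersion > 0:
            d = config.overdispersion
            r = 1.0 / d
            p = r / (r + mean)
            counts[lib] = rng.negative_binomial(r, p)
        else:
            counts[lib] = rng.poisson(mean)
    table = CountTable(
        pd.DataFrame(counts, index=gene_ids, dtype=np.int64),
        pd.Series(sizes, dtype=np.int64),
    )

    # placeholder coordinates on an unsequenced contig; the genome
    # builder overwrites them for the genes it places on sequence
    starts = np.arange(n, dtype=np.int64) * 10_000
    annotation = pd.DataFrame(
        {
            "transcript_length_bp": lengths,
            "kog_code": kog,
            "chrom": "chrU",
            "gene_start": starts,
            "gene_end": starts + lengths,
            "strand": "+",
            "start_codon_pos": starts,
            "stop_codon_pos": starts + lengths - 1,
        },
        index=gene_ids,
    )
    truth = pd.DataFrame(
        {
            "transcript_length_bp": lengths,
            "baseline_rpkm": baseline,
            "responsive": responsive,
            "bias": bias_label,
            "true_log2fc_wt": fc_wt,
            "true_log2fc_pmk1": fc_pk,
            "kog_code": kog,
        },
        index=gene_ids,
    )
    if n:
        validate_annotation(annotation)
    return table, annotation, truth


# ---------------------------------------------------------------------------
# Gene sets
# ---------------------------------------------------------------------------


def simulate_gene_sets(
    config: SimulationConfig,
    truth: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> list[GeneSet]:
    """Sample target-gene sets enriched for WT-biased responders.

    Each set draws ``wt_bias_enrichment`` of its members from the
    WT-biased responsive pool and the rest uniformly from the remaining
    genes, so the strain asymmetry of the downstream split analysis is
    recoverable by construction.
    """
    rng = rng or _streams(config.rng_seed, 3)[1]
    universe = truth.index.to_numpy()
    wt_pool = truth.index[(truth["bias"] == "wt")].to_numpy()
    sets: list[GeneSet] = []
    for spec in config.target_set_specs:
        if spec.size > len(universe):
            raise ValueError(
                f"target set {spec.name}: size {spec.size} exceeds gene universe"
            )
        n_biased = min(int(round(spec.size * spec.wt_bias_enrichment)), len(wt_pool))
        chosen = list(rng.choice(wt_pool, size=n_biased, replace=False)) if n_biased else []
        rest_pool = np.setdiff1d(universe, np.asarray(chosen, dtype=universe.dtype))
        n_rest = spec.size - n_biased
        chosen += list(rng.choice(rest_pool, size=n_rest, replace=False)) if n_rest else []
        members = tuple(sorted(chosen))
        labels = None
        if spec.class_labels:
            drawn = rng.choice(list(spec.class_labels), size=len(members))
            labels = dict(zip(members, drawn))
        sets.append(GeneSet(spec.name, members, labels))
    return sets


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------


def _random_instance(pattern: str, rng: np.random.Generator) -> str:
    options = sorted(s for s in expand_iupac(pattern) if "N" not in s)
    return options[rng.integers(len(options))]


def _window_intervals(lo: int, glen: int, strand: str, spec: GenomeSpec):
    """Genomic forward-strand intervals of the three windows of a gene block."""
    U, D = spec.upstream_bp, spec.downstream_bp
    if strand == "+":
        return {
            "upstream": (lo, lo + U),
            "intragenic": (lo + U, lo + U + glen),
            "downstream": (lo + U + glen, lo + U + glen + D),
        }
    return {
        "downstream": (lo, lo + D),
        "intragenic": (lo + D, lo + D + glen),
        "upstream": (lo + D + glen, lo + D + glen + U),
    }


def _scan_contig(seq: str, motifs: Sequence[MotifDefinition]):
    """All (start, end, strand, motif) occurrences on a forward contig."""
    found = set()
    for motif in motifs:
        for m in scan_sequence(seq, motif, both_strands=True):
            found.add((m.start, m.end, m.strand, m.motif))
    return found


def simulate_genome(
    config: SimulationConfig,
    annotation: pd.DataFrame,
    rng: np.random.Generator | None = None,
    motifs: Sequence[MotifDefinition] = DEFAULT_MOTIFS,
):
    """Build contigs with planted motif occurrences and clean background.

    Background DNA is drawn uniformly, spontaneous occurrences of the
    configured motifs are destroyed by single-base edits outside the
    planted intervals, motif instances are written at recorded
    positions, and a final re-scan verifies that the realised match set
    equals the planted truth exactly.

    Updates the coordinate columns of ``annotation`` in place for the
    placed genes and returns ``(genome, genes_bed, motif_truth)``.
    """
    rng = rng or _streams(config.rng_seed, 3)[2]
    spec = config.genome
    placed = annotation.index[: spec.n_genes]
    if len(placed) < spec.n_genes:
        logger.warning(
            "genome spec asks for %d genes but only %d exist", spec.n_genes, len(placed)
        )
    genome: dict[str, str] = {}
    bed_rows = []
    truth_rows = []

    per_contig = int(np.ceil(len(placed) / spec.n_contigs)) if len(placed) else 0
    chunks = [
        placed[i * per_contig : (i + 1) * per_contig]
        for i in range(spec.n_contigs)
    ] if per_contig else []

    for ci, chunk in enumerate(chunks):
        if not len(chunk):
            continue
        chrom = f"contig_{ci + 1}"
        blocks = []
        cursor = spec.spacer_bp
        gene_layout = []
        for gene_id in chunk:
            glen = int(rng.integers(spec.intragenic_bp[0], spec.intragenic_bp[1] + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            gene_layout.append((gene_id, cursor, glen, strand))
            cursor += spec.upstream_bp + glen + spec.downstream_bp + spec.spacer_bp
        contig_len = cursor

        seq = rng.integers(0, 4, size=contig_len)
        seq = _BASES[seq].copy()

        # plan the plants first so background cleaning can avoid them
        planted: set[tuple[int, int, str, str]] = set()
        occupied: list[tuple[int, int]] = []
        for gene_id, lo, glen, strand in gene_layout:
            intervals = _window_intervals(lo, glen, strand, spec)
            for window, (wlo, whi) in intervals.items():
                for motif in motifs:
                    rates = spec.planted_rates.get(motif.name, (0.0, 0.0, 0.0))
                    rate = dict(zip(("upstream", "intragenic", "downstream"), rates))[
                        window
                    ]
                    for rel_strand in "+-":
                        k = rng.poisson(rate)
                        for _ in range(k):
                            pos = _place(
                                rng, wlo, whi, len(motif.pattern), occupied
                            )
                            if pos is None:
                                continue
                            genomic_strand = "+" if strand == rel_strand else "-"
                            instance = _random_instance(motif.pattern, rng)
                            written = (
                                instance
                                if genomic_strand == "+"
                                else str(Seq(instance).reverse_complement())
                            )
                            seq[pos : pos + len(written)] = list(written)
                            occupied.append((pos, pos + len(written)))
                            planted.add(
                                (pos, pos + len(written), genomic_strand, motif.name)
                            )
                            truth_rows.append(
                                {
                                    "gene_id": gene_id,
                                    "window": window,
                                    "strand": rel_strand,
                                    "motif": motif.name,
                                    "chrom": chrom,
                                    "start": pos,
                                    "end": pos + len(written),
                                    "genomic_strand": genomic_strand,
                                }
                            )

        seq = _sanitize(seq, planted, motifs, rng)
        genome[chrom] = "".join(seq)

        for gene_id, lo, glen, strand in gene_layout:
            intervals = _window_intervals(lo, glen, strand, spec)
            g_lo, g_hi = intervals["intragenic"]
            annotation.loc[gene_id, ["chrom", "gene_start", "gene_end", "strand"]] = [
                chrom, g_lo, g_hi, strand,
            ]
            if strand == "+":
                annotation.loc[gene_id, "start_codon_pos"] = g_lo
                annotation.loc[gene_id, "stop_codon_pos"] = g_hi - 1
            else:
                annotation.loc[gene_id, "start_codon_pos"] = g_hi - 1
                annotation.loc[gene_id, "stop_codon_pos"] = g_lo
            bed_rows.append(
                {"chrom": chrom, "start": g_lo, "end": g_hi,
                 "name": gene_id, "score": ".", "strand": strand}
            )

    genes_bed = pd.DataFrame(
        bed_rows, columns=["chrom", "start", "end", "name", "score", "strand"]
    )
    motif_truth = pd.DataFrame(
        truth_rows,
        columns=["gene_id", "window", "strand", "motif", "chrom", "start", "end",
                 "genomic_strand"],
    )
    if len(annotation):
        for col in ("gene_start", "gene_end", "start_codon_pos", "stop_codon_pos"):
            annotation[col] = annotation[col].astype(np.int64)
        validate_annotation(annotation)
    return genome, genes_bed, motif_truth


def _place(rng, wlo: int, whi: int, length: int, occupied) -> int | None:
    """Pick a start for a planted instance, keeping a background gap."""
    if whi - wlo < length:
        return None
    for _ in range(200):
        pos = int(rng.integers(wlo, whi - length + 1))
        if all(
            pos + length + _PLANT_GAP <= lo or pos >= hi + _PLANT_GAP
            for lo, hi in occupied
        ):
            return pos
    logger.warning("could not place a motif instance in window [%d, %d)", wlo, whi)
    return None


def _sanitize(seq, planted, motifs, rng, max_rounds: int = 100):
    """Destroy all non-planted motif matches by edits outside planted bases."""
    protected = np.zeros(len(seq), dtype=bool)
    for lo, hi, _, _ in planted:
        protected[lo:hi] = True
    for _ in range(max_rounds):
        found = _scan_contig("".join(seq), motifs)
        spurious = found - planted
        if not spurious:
            if found != planted:
                missing = planted - found
                raise RuntimeError(f"planted motif instances destroyed: {sorted(missing)[:3]}")
            return seq
        # sorted iteration keeps the edit sequence independent of
        # string-hash randomisation (bundle bytes must be reproducible
        # across processes)
        for lo, hi, _, _ in sorted(spurious):
            editable = [i for i in range(lo, hi) if not protected[i]]
            if not editable:  # pragma: no cover - excluded by the gap invariant
                raise RuntimeError("spurious match with no editable base")
            i = editable[int(rng.integers(len(editable)))]
            current = seq[i]
            choices = [b for b in "ACGT" if b != current]
            seq[i] = choices[int(rng.integers(3))]
    raise RuntimeError("background sanitization did not converge")


# ---------------------------------------------------------------------------
# Bundle
# ---------------------------------------------------------------------------


def simulate_all(config: SimulationConfig) -> SimulatedData:
    """Run every sub-generator off one split seed."""
    rng_counts, rng_sets, rng_genome = _streams(config.rng_seed, 3)
    table, annotation, truth = simulate_counts(config, rng_counts)
    gene_sets = simulate_gene_sets(config, truth, rng_sets)
    genome, genes_bed, motif_truth = simulate_genome(config, annotation, rng_genome)
    return SimulatedData(
        config, table, annotation, truth, gene_sets, genome, genes_bed, motif_truth
    )


def simulate_bundle(config: SimulationConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write a complete synthetic input bundle plus ground truth to disk.

    Emits counts.tsv, annotation.tsv, sets/*.tsv, genome.fa, genes.bed,
    truth/counts_truth.tsv, truth/motif_truth.tsv and config.json, and
    returns the path of each artefact.
    """
    out = Path(out_dir)
    (out / "sets").mkdir(parents=True, exist_ok=True)
    (out / "truth").mkdir(exist_ok=True)
    data = simulate_all(config)
    comment = f"simulated bundle | seed={config.rng_seed}"

    paths = {
        "counts": out / "counts.tsv",
        "annotation": out / "annotation.tsv",
        "genome": out / "genome.fa",
        "genes_bed": out / "genes.bed",
        "counts_truth": out / "truth" / "counts_truth.tsv",
        "motif_truth": out / "truth" / "motif_truth.tsv",
        "config": out / "config.json",
        "sets_dir": out / "sets",
    }
    # the override row keeps the true sequencing depths across the round
    # trip; column sums alone would import composition bias from the
    # planted (asymmetric) fold changes
    data.counts.to_tsv(paths["counts"], comment=comment, include_library_sizes=True)
    write_annotation(data.annotation, paths["annotation"], comment=comment)
    for gene_set in data.gene_sets:
        write_gene_set(gene_set, out / "sets" / f"{gene_set.name}.tsv")
    with open(paths["genome"], "w") as handle:
        for chrom in sorted(data.genome):
            handle.write(f">{chrom}\n")
            seq = data.genome[chrom]
            for i in range(0, len(seq), 80):
                handle.write(seq[i : i + 80] + "\n")
    write_bed(data.genes_bed, paths["genes_bed"])
    write_tsv(data.truth.reset_index(), paths["counts_truth"], comment=comment)
    write_tsv(data.motif_truth, paths["motif_truth"], comment=comment)
    config.to_json(paths["config"])
    return paths
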