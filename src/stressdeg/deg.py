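"""RPKM quantification and the exact Poisson library-pair count test.

The design has a single sequencing library per strain x condition, so
differential expression between two libraries is assessed with the
Audic–Claverie test: conditioned on a gene's count ``x`` in library 1,
its count in library 2 follows

    p(k | x) = f^k (x + k)! / (x! k! (1 + f)^(x + k + 1)),    f = N2/N1,

a negative-binomial tail problem that this module evaluates through the
regularized incomplete beta function (no term-by-term summation, stable
for arbitrarily large counts).  Multiple testing across genes is
controlled per contrast with the Benjamini–Hochberg step-up procedure.

Four canonical contrasts cover the design: two stress-specific
(Cd vs. control within each strain; "up" = higher under cadmium) and two
strain-specific (WT vs. mutant within each condition; "up" = higher in
the wild type).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import special
from statsmodels.stats.multitest import multipletests

from .io import AnalysisConfig, CountTable

__all__ = [
    "ContrastSpec",
    "ContrastResult",
    "ContrastSummary",
    "CANONICAL_CONTRASTS",
    "STRESS_CONTRASTS",
    "compute_rpkm",
    "audic_claverie_p",
    "bh_fdr",
    "run_contrast",
    "summarize_contrast",
    "strong_change_rule",
    "select_strong_degs",
]


@dataclass(frozen=True)
class ContrastSpec:
    """An ordered library pair compared gene by gene."""

    name: str
    numerator_library: str
    denominator_library: str
    kind: str  # "stress" | "strain"

    def __post_init__(self) -> None:
        if self.numerator_library == self.denominator_library:
            raise ValueError("numerator and denominator libraries must differ")
        if self.kind not in ("stress", "strain"):
            raise ValueError(f"contrast kind must be 'stress' or 'strain', got {self.kind!r}")


#: The four canonical contrasts of the two-strain, two-condition design.
CANONICAL_CONTRASTS: dict[str, ContrastSpec] = {
    "WT_Cd_vs_WT_ctrl": ContrastSpec("WT_Cd_vs_WT_ctrl", "WT_Cd", "WT_ctrl", "stress"),
    "pmk1_Cd_vs_pmk1_ctrl": ContrastSpec(
        "pmk1_Cd_vs_pmk1_ctrl", "pmk1_Cd", "pmk1_ctrl", "stress"
    ),
    "WT_ctrl_vs_pmk1_ctrl": ContrastSpec(
        "WT_ctrl_vs_pmk1_ctrl", "WT_ctrl", "pmk1_ctrl", "strain"
    ),
    "WT_Cd_vs_pmk1_Cd": ContrastSpec("WT_Cd_vs_pmk1_Cd", "WT_Cd", "pmk1_Cd", "strain"),
}

STRESS_CONTRASTS = ("WT_Cd_vs_WT_ctrl", "pmk1_Cd_vs_pmk1_ctrl")


def compute_rpkm(counts, length_bp, library_size):
    """Reads per kilobase of transcript per million mapped reads.

    RPKM = count / ((L / 1000) * (N / 1e6)) for transcript length L and
    library size N.  Accepts scalars or aligned arrays.
    """
    counts = np.asarray(counts, dtype=float)
    length_bp = np.asarray(length_bp, dtype=float)
    library_size = np.asarray(library_size, dtype=float)
    if np.any(length_bp <= 0):
        raise ValueError("transcript length must be positive")
    if np.any(library_size <= 0):
        raise ValueError("library size must be positive")
    return counts / ((length_bp / 1e3) * (library_size / 1e6))


def _check_counts(arr, name):
    arr = np.asarray(arr)
    if arr.size == 0:
        return arr.astype(np.int64)
    if not np.issubdtype(arr.dtype, np.integer):
        if np.any(~np.isfinite(arr)) or np.any(np.mod(arr, 1) != 0):
            raise ValueError(f"{name} must contain non-negative integers")
        arr = arr.astype(np.int64)
    if np.any(arr < 0):
        raise ValueError(f"{name} must contain non-negative integers")
    return arr


def audic_claverie_pmf(y, x, n1, n2):
    """The conditional probability p(y | x) of the library-pair test."""
    x = _check_counts(x, "x")
    y = _check_counts(y, "y")
    f = n2 / n1
    logp = (
        special.gammaln(x + y + 1.0)
        - special.gammaln(x + 1.0)
        - special.gammaln(y + 1.0)
        + y * np.log(f)
        - (x + y + 1.0) * np.log1p(f)
    )
    return np.exp(logp)


def audic_claverie_p(x, y, n1, n2):
    """Two-sided library-pair count test p-value.

    With ``q = N1 / (N1 + N2)`` the lower tail ``sum_{k<=y} p(k|x)`` is
    the CDF of a negative binomial and equals ``I_q(x+1, y+1)`` (the
    regularized incomplete beta function); the upper tail includes the
    observed point, ``1 - lower + p(y|x) = I-based survival at y-1``.
    The two-sided value is ``min(1, 2 * min(lower, upper))``, so the
    observed count is included in both tails.

    ``x``/``y`` may be scalars or arrays (vectorized over genes);
    ``n1``/``n2`` are the library sizes the counts came from.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library sizes must be positive")
    x = _check_counts(x, "x")
    y = _check_counts(y, "y")
    x, y = np.broadcast_arrays(x, y)
    q = n1 / (n1 + n2)
    lower = special.betainc(x + 1.0, y + 1.0, q)
    upper = np.where(
        y > 0,
        1.0 - special.betainc(x + 1.0, np.maximum(y, 1).astype(float), q),
        1.0,
    )
    p = np.minimum(1.0, 2.0 * np.minimum(lower, upper))
    return p if p.ndim else float(p)


def bh_fdr(p_values):
    """Benjamini–Hochberg step-up adjusted q-values, order preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Contrast execution
# ---------------------------------------------------------------------------


@dataclass
class ContrastResult:
    """Per-gene outcome of one library-pair contrast.

    ``frame`` is indexed by gene_id with columns count_num, count_den,
    rpkm_num, rpkm_den, log2fc, p_value, q_value, direction, is_deg.
    """

    spec: ContrastSpec
    frame: pd.DataFrame
    fdr_threshold: float

    @property
    def degs(self) -> pd.DataFrame:
        return self.frame[self.frame["is_deg"]]

    def deg_ids(self) -> pd.Index:
        return self.degs.index


def run_contrast(
    table: CountTable,
    annotation: pd.DataFrame,
    spec: ContrastSpec,
    config: AnalysisConfig,
) -> ContrastResult:
    """Run one contrast: RPKM, fold change, exact test, BH-FDR, DEG call."""
    for lib in (spec.numerator_library, spec.denominator_library):
        if lib not in table.counts.columns:
            raise KeyError(f"library {lib!r} not present in count table")
    missing = table.gene_ids.difference(annotation.index)
    if len(missing):
        raise KeyError(f"annotation missing for {len(missing)} genes, e.g. {missing[0]!r}")
    lengths = annotation.loc[table.gene_ids, "transcript_length_bp"].to_numpy()

    x = table.counts[spec.numerator_library].to_numpy()
    y = table.counts[spec.denominator_library].to_numpy()
    n1 = int(table.library_sizes[spec.numerator_library])
    n2 = int(table.library_sizes[spec.denominator_library])

    rpkm_num = compute_rpkm(x, lengths, n1)
    rpkm_den = compute_rpkm(y, lengths, n2)
    eps = config.rpkm_pseudocount
    log2fc = np.log2((rpkm_num + eps) / (rpkm_den + eps))

    # the test conditions on the numerator-library count
    p = audic_claverie_p(x, y, n1, n2)
    q = bh_fdr(p)
    is_deg = q < config.fdr_threshold
    direction = np.where(log2fc > 0, "up", np.where(log2fc < 0, "down", "none"))

    frame = pd.DataFrame(
        {
            "count_num": x,
            "count_den": y,
            "rpkm_num": rpkm_num,
            "rpkm_den": rpkm_den,
            "log2fc": log2fc,
            "p_value": p,
            "q_value": q,
            "direction": direction,
            "is_deg": is_deg,
        },
        index=table.gene_ids,
    )
    return ContrastResult(spec, frame, config.fdr_threshold)


@dataclass
class ContrastSummary:
    """Headline numbers of one contrast.

    Mean log2 fold changes are computed on the antilog (linear) scale:
    the arithmetic mean of the linear fold changes of up-DEGs (or of
    the inverse fold changes of down-DEGs) is averaged first and then
    log2-transformed.  Ratios are ``None`` when a denominator is zero.
    """

    contrast: str
    n_up: int
    n_down: int
    ratio_R: float | None
    mean_log2fc_up: float | None
    mean_log2fc_down: float | None
    ratio_R_means: float | None


def summarize_contrast(result: ContrastResult) -> ContrastSummary:
    frame = result.frame
    # genes unobserved in both libraries carry no expression signal
    observed = (frame["count_num"] > 0) | (frame["count_den"] > 0)
    degs = frame[frame["is_deg"] & observed]
    up = degs[degs["log2fc"] > 0]
    down = degs[degs["log2fc"] < 0]
    n_up, n_down = len(up), len(down)

    mean_up = (
        float(np.log2(np.mean(np.exp2(up["log2fc"])))) if n_up else None
    )
    mean_down = (
        -float(np.log2(np.mean(np.exp2(-down["log2fc"])))) if n_down else None
    )
    ratio = n_up / n_down if n_down else None
    ratio_means = (
        abs(mean_up) / abs(mean_down)
        if mean_up is not None and mean_down is not None and mean_down != 0
        else None
    )
    return ContrastSummary(
        result.spec.name, n_up, n_down, ratio, mean_up, mean_down, ratio_means
    )


# ---------------------------------------------------------------------------
# Strong-DEG selection
# ---------------------------------------------------------------------------


def strong_change_rule(
    log2fc_wt: float,
    log2fc_pmk1: float,
    strong_log2fc_cutoff: float = 2.0,
    strong_diff_cutoff: float = 1.0,
) -> bool:
    """The strong-DEG magnitude rule on a (WT, mutant) fold-change pair.

    True when |log2fc| exceeds ``strong_log2fc_cutoff`` in at least one
    strain's stress response and the two strains differ by more than
    ``strong_diff_cutoff`` log2 units.
    """
    big = (
        abs(log2fc_wt) > strong_log2fc_cutoff
        or abs(log2fc_pmk1) > strong_log2fc_cutoff
    )
    apart = abs(log2fc_wt - log2fc_pmk1) > strong_diff_cutoff
    return bool(big and apart)


def select_strong_degs(
    stress_result_wt: ContrastResult,
    stress_result_pmk1: ContrastResult,
    config: AnalysisConfig,
) -> pd.DataFrame:
    """Strongly and differentially cadmium-responsive genes.

    A gene qualifies when it is a DEG with |log2fc| above the strong
    cutoff in at least one stress contrast and the WT and mutant log2
    fold changes differ by more than the difference cutoff.  Returns a
    frame (gene_id index, columns log2fc_WT / log2fc_pmk1) sorted by
    log2fc_WT descending.
    """
    wt, pk = stress_result_wt.frame, stress_result_pmk1.frame
    if not wt.index.equals(pk.index):
        raise ValueError("stress contrasts computed on different gene universes")
    cut, diff = config.strong_log2fc_cutoff, config.strong_diff_cutoff
    strong_wt = wt["is_deg"] & (wt["log2fc"].abs() > cut)
    strong_pk = pk["is_deg"] & (pk["log2fc"].abs() > cut)
    apart = (wt["log2fc"] - pk["log2fc"]).abs() > diff
    keep = (strong_wt | strong_pk) & apart
    out = pd.DataFrame(
        {"log2fc_WT": wt.loc[keep, "log2fc"], "log2fc_pmk1": pk.loc[keep, "log2fc"]}
    )
    return out.sort_values("log2fc_WT", ascending=False)
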