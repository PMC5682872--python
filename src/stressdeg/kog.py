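"""KOG functional-category classification of DEGs and deviation tests.

DEGs carrying a KOG letter are tallied per category by regulation
direction, and each category's up/down split is compared against the
contrast-wide split of all KOG-identified DEGs with a 1-degree-of-
freedom chi-square goodness-of-fit test.  Because the reference ratio
is taken over *all* KOG-identified DEGs (the category included), this
is a goodness-of-fit test against fixed proportions, not a 2x2
contingency test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .deg import ContrastResult
from .io import AnalysisConfig, KOG_CATEGORIES

__all__ = ["KOGTable", "KOG_CATEGORIES", "classify_degs", "kog_chi_square", "build_kog_table"]

#: Expected-count threshold below which the chi-square approximation is
#: conventionally considered unreliable.
LOW_EXPECTATION = 5.0


@dataclass
class KOGTable:
    """Per-category DEG tallies for one contrast.

    ``frame`` is indexed by category letter with columns n_up / n_down
    (plus test columns once :func:`build_kog_table` has run); ``U`` and
    ``D`` are the contrast-wide up/down totals over KOG-identified
    DEGs.
    """

    contrast: str
    frame: pd.DataFrame
    U: int
    D: int


def classify_degs(
    result: ContrastResult,
    annotation: pd.DataFrame,
    strict_single_letter: bool = False,
) -> KOGTable:
    """Tally KOG-identified DEGs per category and direction.

    DEGs without a KOG letter are excluded.  A multi-letter code counts
    the gene once in every listed category (set
    ``strict_single_letter=True`` to reject such codes instead); the
    contrast-wide totals U and D count genes once per letter as well,
    keeping the column-sum invariant exact.
    """
    degs = result.degs
    codes = annotation.reindex(degs.index)["kog_code"].fillna("")
    tallies: dict[str, list[int]] = {}
    U = D = 0
    for gene, code in codes.items():
        code = str(code)
        if not code:
            continue
        if strict_single_letter and len(code) > 1:
            raise ValueError(f"gene {gene!r} carries a multi-letter KOG code {code!r}")
        up = degs.at[gene, "log2fc"] > 0
        for letter in dict.fromkeys(code):
            if letter not in KOG_CATEGORIES:
                raise ValueError(f"gene {gene!r}: unknown KOG letter {letter!r}")
            row = tallies.setdefault(letter, [0, 0])
            row[0 if up else 1] += 1
            if up:
                U += 1
            else:
                D += 1
    frame = pd.DataFrame(
        {
            "n_up": {k: v[0] for k, v in tallies.items()},
            "n_down": {k: v[1] for k, v in tallies.items()},
        },
        dtype=np.int64,
    ).sort_index()
    frame.index.name = "category"
    return KOGTable(result.spec.name, frame, U, D)


def kog_chi_square(n_up: int, n_down: int, U: int, D: int, alpha: float = 0.001):
    """Test one category's up/down split against the contrast-wide ratio.

    Expected counts are ``n * U / (U + D)`` and ``n * D / (U + D)`` for
    ``n = n_up + n_down``; the statistic is the usual
    ``sum (obs - exp)^2 / exp`` referred to a chi-square distribution
    with 1 degree of freedom (no continuity correction).

    Returns a dict with expected counts, chi2, p_value, the deviating
    flag (p < alpha) and a low-count flag (any expectation < 5).  When
    U or D is zero the test is undefined and the row is marked
    untestable.
    """
    n = n_up + n_down
    if n <= 0:
        raise ValueError("category must contain at least one DEG")
    if U == 0 or D == 0:
        return {
            "expected_up": np.nan,
            "expected_down": np.nan,
            "chi2": np.nan,
            "p_value": np.nan,
            "deviating": False,
            "low_count_flag": True,
            "testable": False,
        }
    expected_up = n * U / (U + D)
    expected_down = n * D / (U + D)
    chi2 = (n_up - expected_up) ** 2 / expected_up + (
        n_down - expected_down
    ) ** 2 / expected_down
    p = float(stats.chi2.sf(chi2, df=1))
    return {
        "expected_up": expected_up,
        "expected_down": expected_down,
        "chi2": float(chi2),
        "p_value": p,
        "deviating": bool(p < alpha),
        "low_count_flag": bool(min(expected_up, expected_down) < LOW_EXPECTATION),
        "testable": True,
    }


def build_kog_table(
    result: ContrastResult,
    annotation: pd.DataFrame,
    config: AnalysisConfig,
    strict_single_letter: bool = False,
) -> KOGTable:
    """Classify DEGs and attach the per-category deviation test."""
    table = classify_degs(result, annotation, strict_single_letter)
    rows = [
        kog_chi_square(int(r.n_up), int(r.n_down), table.U, table.D, config.kog_alpha)
        for r in table.frame.itertuples()
    ]
    if rows:
        table.frame = pd.concat(
            [table.frame, pd.DataFrame(rows, index=table.frame.index)], axis=1
        )
    else:
        for col in ("expected_up", "expected_down", "chi2", "p_value",
                    "deviating", "low_count_flag", "testable"):
            table.frame[col] = pd.Series(dtype=float)
    return table
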