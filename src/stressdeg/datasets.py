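"""Small literature-reported reference tables used in examples and checks.

These are published numbers for a handful of well-characterised
cadmium-responsive *C. elegans* genes; they serve as worked-example
inputs (the package recomputes aggregates and rule outcomes from them)
and are not produced by this package.
"""

from __future__ import annotations

import pandas as pd

from .motifs import COUNT_COLUMNS

#: Reported per-gene motif counts (both strands; 2 kb upstream of the
#: start codon, intragenic, 2 kb downstream of the stop codon) for
#: seven cadmium-responsive genes: SKN-1 consensus sites and pooled
#: DAF-16 sites (DBE + DAE).  Column layout matches
#: :class:`stressdeg.motifs.MotifCountTable`.
REFERENCE_MOTIF_COUNTS = pd.DataFrame(
    [
        # gene        skn1: up intra down tot   daf16: up intra down tot
        ("nit-1",          5, 0, 3, 8,          1, 0, 0, 1),
        ("ctl-2",          3, 0, 1, 4,          3, 1, 2, 6),
        ("dhs-18",         4, 0, 3, 7,          1, 0, 0, 1),
        ("hsp-17",         6, 0, 2, 8,          2, 0, 1, 3),
        ("ugt-1",          3, 0, 2, 5,          3, 1, 1, 5),
        ("skr-5",          2, 0, 6, 8,          2, 0, 1, 3),
        ("hsp-12.6",       3, 0, 5, 8,          2, 0, 6, 8),
    ],
    columns=["gene_id", *COUNT_COLUMNS],
).set_index("gene_id")

#: Reported stress-contrast log2 fold changes (WT, pmk-1 mutant) of
#: known metal-responsive genes, from RNA-Seq of cadmium-stressed
#: worms.  Used as inputs to the strong-DEG magnitude rule.
CADMIUM_RESPONSE_LOG2FC = {
    "mtl-1": (11.13, 4.67),
    "cdr-1": (8.11, 5.54),
    "ttm-1": (4.04, 1.80),
    "mtl-2": (3.84, 1.05),
}

#: Reported DEG counts of the wild-type stress contrast (up, down);
#: used in the worked ratio example.
WT_STRESS_DEG_COUNTS = (2659, 1152)
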