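"""Reference tallies from a published TG-GATEs DILI coverage analysis.

These printed summary counts serve as worked-example inputs: the biotype
breakdown of dark genes (array background, per DILI-risk group, and the
combined dark-DEG column), the headline darkness counts, and the evidence
coverage counts. They let the display/arithmetic conventions of this
package (column sums, percentage rounding) be exercised against a
real-world-scale example without any database download.
"""

from __future__ import annotations

import pandas as pd

#: biotype × column dark-gene counts (categorized genes only)
REFERENCE_BIOTYPE_COUNTS: dict[str, dict[str, int]] = {
    "protein_coding": {"array": 1756, "most_dili": 444, "no_dili": 278, "all": 567},
    "antisense": {"array": 527, "most_dili": 69, "no_dili": 33, "all": 78},
    "lincRNA": {"array": 722, "most_dili": 53, "no_dili": 33, "all": 63},
    "processed_transcript": {"array": 113, "most_dili": 11, "no_dili": 8, "all": 15},
    "pseudogene": {"array": 56, "most_dili": 18, "no_dili": 14, "all": 25},
    "snoRNA": {"array": 8, "most_dili": 4, "no_dili": 3, "all": 5},
    "sense_intronic": {"array": 25, "most_dili": 3, "no_dili": 1, "all": 3},
    "sense_overlapping": {"array": 10, "most_dili": 1, "no_dili": 1, "all": 2},
    "miRNA": {"array": 3, "most_dili": 1, "no_dili": 0, "all": 1},
    "TEC": {"array": 11, "most_dili": 1, "no_dili": 1, "all": 1},
}

#: headline counts: DEG universe, dark DEGs, array background, evidence
REFERENCE_HEADLINE_COUNTS = {
    "n_unique_degs": 6918,
    "n_dark_degs": 916,
    "n_array_genes": 19441,
    "n_array_dark": 4210,
    "n_dark_with_evidence": 701,
}

#: per-compound DEG counts by DILI-risk group
REFERENCE_DEG_COUNTS = {
    "most_dili": {
        "Acetaminophen": 2280,
        "Diclofenac": 1888,
        "Isoniazid": 1024,
        "Nimesulide": 1697,
        "Valproic acid": 2290,
    },
    "no_dili": {
        "Caffeine": 2316,
        "Chloramphenicol": 108,
        "Chlorpheniramine": 93,
        "Hydroxyzine": 815,
        "Theophylline": 2918,
    },
}


def reference_biotype_table() -> pd.DataFrame:
    """Biotype count table as a DataFrame (no total row)."""
    return pd.DataFrame(REFERENCE_BIOTYPE_COUNTS).T[["array", "most_dili", "no_dili", "all"]]
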