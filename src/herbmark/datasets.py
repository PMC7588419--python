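"""Packaged datasets.

``nlem_family_verification.tsv`` carries the published per-sample
family-level verification counts for the 33 sequencable products of a
39-product audit of Thai herbal medicines on the National List of Essential
Medicines (two barcode loci per sample, with the percentages as printed in
the source report).  It feeds the count-level entry point of the
verification layer, which bypasses the sequencing stages entirely.
"""
from __future__ import annotations

from importlib import resources

import pandas as pd


def load_family_verification_counts() -> pd.DataFrame:
    """Per-sample family verification counts (sample x locus long format).

    Columns: sample_id, dosage_form, source_type, locus, n_listed,
    n_identified, plus the percentages as printed in the source report
    (strings, two decimals) for cross-checking the arithmetic.
    """
    ref = resources.files("herbmark.data") / "nlem_family_verification.tsv"
    with resources.as_file(ref) as path:
        return pd.read_csv(
            path, sep="\t",
            dtype={"pct_identified_printed": str, "pct_not_identified_printed": str},
        )
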