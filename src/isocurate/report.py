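"""Plain-text summary report over the pipeline tables."""

from __future__ import annotations

from typing import Optional

import pandas as pd


def summarize(classification: pd.DataFrame,
              filter_table: Optional[pd.DataFrame] = None,
              rescue_table: Optional[pd.DataFrame] = None) -> str:
    """Category/subcategory counts, end-support fractions and stage tallies."""
    lines = ["# Transcriptome curation summary", ""]
    n = len(classification)
    lines.append(f"transcripts: {n}")
    lines.append("")
    lines.append("## Structural categories")
    counts = (classification.groupby(["structural_category", "subcategory"])
              .size().sort_index())
    for (cat, sub), c in counts.items():
        lines.append(f"{cat}\t{sub}\t{c}")
    lines.append("")
    lines.append("## End support")
    for col, desc in [("within_CAGE_peak", "TSS inside CAGE peak"),
                      ("within_polyA_site", "TTS inside polyA site"),
                      ("intrapriming", "intrapriming flagged")]:
        if col in classification:
            frac = pd.Series(classification[col]).astype(bool).mean()
            lines.append(f"{desc}: {frac:.3f}")
    if "ratio_TSS" in classification:
        frac = (classification["ratio_TSS"] > 1.5).mean()
        lines.append(f"TSS ratio > 1.5: {frac:.3f}")
    if filter_table is not None and len(filter_table):
        lines.append("")
        lines.append("## Filter")
        for verdict, c in filter_table["filter_result"].value_counts().items():
            lines.append(f"{verdict}: {c}")
    if rescue_table is not None and len(rescue_table):
        lines.append("")
        lines.append("## Rescue")
        for action, c in rescue_table["action"].value_counts().items():
            lines.append(f"{action}: {c}")
    return "\n".join(lines) + "\n"


def category_counts(classification: pd.DataFrame) -> pd.Series:
    return (classification.groupby(["structural_category", "subcategory"])
            .size())
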