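"""Per-clone chromatin signature table and its correlation with
recombinant mRNA expression.

The signature table mirrors how such results are summarised: one row per
cell line with the HC/LC mRNA percentage, ChIP enrichments (H2A as raw
percent input, variant/modification marks relative to H2A), FAIRE
enrichment, per-window nucleosome occupancy, and the endogenous CpG
methylation percentage; plus a trailing row of Pearson correlations of
every metric against mRNA expression and a per-column maximum flag.

The columns deliberately mix units (raw % input vs relative-to-H2A %,
occupancy %, methylation %); they are correlated as reported, without
rescaling, and the report flags this heterogeneity.  With four cell
lines the correlations are descriptive: no p-values are attached.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MRNA_COLUMN = "mRNA_HC_LC_pct"
METRIC_COLUMNS = [
    "H2A", "H3.3", "H2A.Z", "H3K9ac", "H3K9me3", "H3K4me3", "H3K27me3",
    "FAIRE", "Nuc853", "Nuc1008", "methylation_pct",
]


def pearson(x, y) -> float:
    """Sample Pearson correlation coefficient of two equal-length
    vectors (n >= 3, both non-constant)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 3:
        raise ValueError(f"need >= 3 observations, got {x.size}")
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise ValueError("Pearson r is undefined for a constant vector")
    return float(np.corrcoef(x, y)[0, 1])


@dataclass
class SignatureTable:
    """Cell lines x metrics with optional correlation row and max flags."""

    data: pd.DataFrame                       # rows: clones; includes MRNA_COLUMN
    correlation: pd.Series | None = None     # per metric column, r vs mRNA
    max_flags: dict[str, list[str]] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    @property
    def clones(self) -> list[str]:
        return list(self.data.index)

    @property
    def metric_columns(self) -> list[str]:
        return [c for c in self.data.columns if c != MRNA_COLUMN]

    def to_csv(self, path: str | Path) -> None:
        out = self.data.copy()
        if self.correlation is not None:
            row = pd.Series({c: self.correlation.get(c, np.nan) for c in out.columns},
                            name="Pearson correlation")
            out = pd.concat([out, row.to_frame().T])
        out.to_csv(path, float_format="%.4f")


def build_signature_table(
    metrics: dict[str, dict[str, float]],
    column_order: list[str] | None = None,
    metadata: dict | None = None,
) -> SignatureTable:
    """Assemble the signature table from per-clone metric bundles.

    ``metrics`` maps clone name -> {column -> value}; every bundle must
    include the mRNA column.  Missing cells are permitted (NaN, logged).
    Per-column maxima are flagged; ties flag all tied clones.  The
    correlation row needs >= 3 clones and is suppressed (with a warning)
    below that.
    """
    if not metrics:
        raise ValueError("no clones supplied")
    cols = column_order or [MRNA_COLUMN] + [
        c for c in METRIC_COLUMNS
        if any(c in bundle for bundle in metrics.values())
    ]
    df = pd.DataFrame.from_dict(metrics, orient="index").reindex(columns=cols)
    df.index.name = "cell_line"
    if MRNA_COLUMN not in df.columns or df[MRNA_COLUMN].isna().all():
        raise ValueError(f"every bundle must provide {MRNA_COLUMN}")
    n_missing = int(df.isna().sum().sum())
    if n_missing:
        logger.warning("%d missing cells in signature table", n_missing)

    flags: dict[str, list[str]] = {}
    for c in df.columns:
        if c == MRNA_COLUMN or df[c].isna().all():
            continue
        mx = df[c].max()
        tied = [str(i) for i in df.index[df[c] == mx]]
        if len(tied) > 1:
            logger.warning("column %s: %d clones tied at maximum", c, len(tied))
        flags[c] = tied

    table = SignatureTable(df, None, flags, metadata or {})
    if len(df) >= 3:
        table.correlation = correlation_row(table)
    else:
        logger.warning("fewer than 3 clones: correlation row suppressed")
    return table


def correlation_row(table: SignatureTable) -> pd.Series:
    """Pearson r of every metric column against mRNA expression, using
    pairwise-complete rows per column."""
    df = table.data
    mrna = df[MRNA_COLUMN]
    out = {}
    for c in table.metric_columns:
        mask = df[c].notna() & mrna.notna()
        if mask.sum() < len(df):
            logger.warning("column %s: using %d pairwise-complete rows",
                           c, int(mask.sum()))
        out[c] = pearson(mrna[mask], df[c][mask])
    return pd.Series(out, name="pearson_r_vs_mrna")


def load_reference_signature() -> SignatureTable:
    """Load the packaged published signature matrix of the four PT1
    recombinant CHO cell lines and recompute its correlation row."""
    with resources.files("epicho.data").joinpath("reference_signature.csv").open() as fh:
        df = pd.read_csv(fh, index_col="cell_line")
    return build_signature_table(
        {clone: row.to_dict() for clone, row in df.iterrows()},
        column_order=list(df.columns),
        metadata={"source": "published four-clone reference matrix"},
    )


def render_report(table: SignatureTable, qc_warnings: list[str] | None = None) -> str:
    """Deterministic human-readable report: signature matrix, correlation
    row (2-decimal rounding alongside raw values), flagged maxima, and QC
    notes."""
    lines = ["# Clone chromatin signature report", ""]
    meta = dict(sorted(table.metadata.items()))
    if meta:
        lines += ["Metadata: " + json.dumps(meta, sort_keys=True), ""]
    lines.append("## Signature matrix")
    lines.append(table.data.to_string(float_format=lambda v: f"{v:.2f}"))
    lines.append("")
    if table.correlation is not None:
        lines.append("## Pearson correlation vs mRNA expression")
        for c, r in table.correlation.items():
            lines.append(f"  {c:16s} r = {r:+.2f}   (raw {r:+.6f})")
        lines.append("")
        lines.append("Note: columns mix units (H2A raw % input; marks relative "
                     "to H2A; occupancy, FAIRE and methylation in their own "
                     "scales); correlations are computed on values as reported.")
        lines.append("")
    lines.append("## Column maxima")
    for c, clones in sorted(table.max_flags.items()):
        lines.append(f"  {c:16s} max in {', '.join(clones)}")
    lines.append("")
    lines.append("## QC")
    if qc_warnings:
        lines += [f"  - {w}" for w in qc_warnings]
    else:
        lines.append("  (no warnings)")
    lines.append("")
    return "\n".join(lines)
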