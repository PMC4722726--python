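"""End-to-end orchestration: from a simulation config to the per-clone
signature table, alongside the planted-truth table it should recover."""

from __future__ import annotations

import pandas as pd

from .bisulfite import call_methylation, methylation_summary
from .footprinting import to_protection_map, window_occupancy
from .qpcr import chip_enrichment, faire_table, quantify_expression
from .signature import MRNA_COLUMN, SignatureTable, build_signature_table
from .simulate import MARKS, SimulationConfig, generate_promoter, simulate_ct_tables, simulate_epialleles


def truth_signature_table(config: SimulationConfig,
                          window_names: list[str]) -> SignatureTable:
    """The signature table implied directly by the planted clone profiles."""
    bundles = {}
    for c in config.clones:
        b = {MRNA_COLUMN: c.hc_lc_pct, "H2A": c.h2a_pct_input}
        b.update(c.enrichment_rel_h2a)
        b["FAIRE"] = c.faire_pct_input
        for w, p in zip(window_names, c.occupancy):
            b[w] = 100.0 * p
        b["methylation_pct"] = 100.0 * c.methylation_rate
        bundles[c.name] = b
    cols = [MRNA_COLUMN, "H2A", *MARKS, "FAIRE", *window_names, "methylation_pct"]
    return build_signature_table(bundles, column_order=cols,
                                 metadata={"source": "planted truth"})


def run_synthetic_study(config: SimulationConfig) -> tuple[SignatureTable, SignatureTable]:
    """Simulate the full study for every configured clone and assemble the
    measured signature table; returns (measured, planted-truth) tables.

    Measured metrics: HC/LC mRNA % by standard-curve quantification; ChIP
    percent input (H2A raw, marks relative to H2A); FAIRE enrichment in
    percent-input mode; per-window CpG-level nucleosome occupancy from
    M.SssI footprinting; overall endogenous methylation %.
    """
    ann = generate_promoter(config)
    window_names = [w.name for w in ann.windows]

    tables, _ = simulate_ct_tables(config)
    expr = quantify_expression(tables["expression"]).set_index("sample")
    chip = chip_enrichment(tables["chip"])
    faire = faire_table(tables["faire"]).set_index("sample")["enrichment"]

    bundles: dict[str, dict[str, float]] = {}
    for clone in config.clones:
        b = {MRNA_COLUMN: float(expr.loc[clone.name, "hc_lc_pct"])}
        sub = chip[chip["sample"] == clone.name].set_index("antibody")
        b["H2A"] = float(sub.loc["H2A", "pct_input"])
        for m in MARKS:
            b[m] = float(sub.loc[m, "rel_h2a_pct"])
        b["FAIRE"] = float(faire[clone.name])

        reads, _ = simulate_epialleles(ann, config, "mssi", clone)
        pmap = to_protection_map(call_methylation(reads, ann, "mssi"))
        for w in ann.windows:
            b[w.name] = window_occupancy(pmap, w, ann).cpg_level_pct

        reads, _ = simulate_epialleles(ann, config, "endogenous", clone)
        matrix = call_methylation(reads, ann, "endogenous")
        b["methylation_pct"] = methylation_summary(matrix).overall_pct
        bundles[clone.name] = b

    cols = [MRNA_COLUMN, "H2A", *MARKS, "FAIRE", *window_names, "methylation_pct"]
    measured = build_signature_table(
        bundles, column_order=cols,
        metadata={"seed": config.seed, "n_molecules": config.n_molecules,
                  "faire_normalization": "percent_input"})
    return measured, truth_signature_table(config, window_names)


def rank_concordance(measured: pd.Series, truth: pd.Series) -> bool:
    """True when both series order the clones identically."""
    return list(measured.sort_values().index) == list(truth.sort_values().index)
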