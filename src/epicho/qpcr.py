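"""Ct-based quantification: standard curves, absolute quantities,
transgene copy number, ChIP percent input and H2A-relative enrichment,
FAIRE enrichment, and the heavy/light-chain expression ratio.

Conventions: replicate Cts of a (sample, target, fraction) triple are
aggregated by the arithmetic mean of Ct (the geometric mean of the
underlying quantities), with the SD carried along as a dispersion
report.  The amplification-efficiency factor defaults to E = 2 (perfect
doubling) unless a fitted standard curve supplies E = 10^(-1/slope).
Missing Cts (non-detects) are excluded from means and counted.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

CT_COLUMNS = ["sample", "target", "fraction", "replicate", "ct"]
DEFAULT_EFFICIENCY = 2.0
DEFAULT_INPUT_FRACTION = 0.01


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """Read a Ct CSV; requires at least sample/target/fraction/replicate/ct."""
    df = pd.read_csv(path)
    missing = [c for c in CT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"Ct table missing columns: {missing}")
    if (df["ct"].dropna() <= 0).any():
        raise ValueError("Ct values must be positive")
    return df


def aggregate_replicates(df: pd.DataFrame,
                         by: list[str] | None = None) -> pd.DataFrame:
    """Mean/SD of Ct per group; non-detects (NaN Ct) are dropped and counted."""
    by = by or [c for c in ("sample", "antibody", "target", "fraction")
                if c in df.columns]
    n_censored = int(df["ct"].isna().sum())
    if n_censored:
        logger.warning("%d non-detect Ct values excluded from aggregation",
                       n_censored)
    agg = (df.dropna(subset=["ct"])
             .groupby(by, sort=False)["ct"]
             .agg(ct_mean="mean", ct_sd="std", n="count")
             .reset_index())
    agg.attrs["n_censored"] = n_censored
    return agg


# --------------------------------------------------------------------------
# standard curve
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class StandardCurve:
    """Log-linear calibration Ct = slope * log10(quantity) + intercept."""

    slope: float
    intercept: float
    r_squared: float

    @property
    def efficiency_factor(self) -> float:
        """Per-cycle amplification factor E = 10^(-1/slope)."""
        return 10.0 ** (-1.0 / self.slope)

    @property
    def efficiency_pct(self) -> float:
        """Efficiency as a percentage (E = 2 -> 100 %)."""
        return 100.0 * (self.efficiency_factor - 1.0)


def fit_standard_curve(points: list[tuple[float, float]]) -> StandardCurve:
    """Ordinary least squares of Ct on log10 quantity over a dilution
    series of >= 3 distinct points."""
    if len(points) < 3:
        raise ValueError(f"need >= 3 dilution points, got {len(points)}")
    x = np.array([p[0] for p in points], dtype=float)
    y = np.array([p[1] for p in points], dtype=float)
    if np.allclose(x, x[0]):
        raise ValueError("dilution series has zero variance in quantity")
    res = stats.linregress(x, y)
    curve = StandardCurve(float(res.slope), float(res.intercept),
                          float(res.rvalue) ** 2)
    if curve.slope >= 0:
        raise ValueError("standard curve slope must be negative "
                         f"(got {curve.slope:.3f}); check the dilution series")
    if not 1.0 < curve.efficiency_factor <= 2.2:
        warnings.warn(
            f"amplification efficiency factor {curve.efficiency_factor:.3f} "
            "outside the (1, 2.2] sanity band", UserWarning, stacklevel=2)
    return curve


def absolute_quantity(ct: float, curve: StandardCurve) -> float:
    """Invert the calibration: quantity = 10^((ct - intercept) / slope)."""
    return 10.0 ** ((ct - curve.intercept) / curve.slope)


# --------------------------------------------------------------------------
# ratio methods
# --------------------------------------------------------------------------

def copy_number(
    ct_target_sample: float,
    ct_ref_sample: float,
    ct_target_cal: float,
    ct_ref_cal: float,
    e_target: float = DEFAULT_EFFICIENCY,
    e_ref: float = DEFAULT_EFFICIENCY,
    calibrator_copies: float = 1.0,
) -> float:
    """Efficiency-corrected ratio-of-ratios transgene copy number,
    expressed relative to a calibrator of known copy number."""
    num = e_target ** (ct_target_cal - ct_target_sample)
    den = e_ref ** (ct_ref_cal - ct_ref_sample)
    return calibrator_copies * num / den


def percent_input(
    ct_input_raw: float,
    ct_chip: float,
    input_fraction: float = DEFAULT_INPUT_FRACTION,
    efficiency: float = DEFAULT_EFFICIENCY,
) -> float:
    """ChIP recovery as percent of starting chromatin.

    The measured input aliquot is only ``input_fraction`` of the
    chromatin, so its Ct is first shifted by log_E(1/fraction) cycles;
    then % input = 100 x E^(adjusted_input_ct - ct_chip).
    """
    if not 0.0 < input_fraction < 1.0:
        raise ValueError("input_fraction must be in (0, 1)")
    adjusted = ct_input_raw - math.log(1.0 / input_fraction, efficiency)
    return 100.0 * efficiency ** (adjusted - ct_chip)


def relative_to_h2a(pct_input_mark: float, pct_input_h2a: float) -> float:
    """Mark enrichment normalized to the canonical histone H2A (%)."""
    if pct_input_h2a <= 0:
        raise ValueError("H2A percent input must be positive")
    return 100.0 * pct_input_mark / pct_input_h2a


FAIRE_MODES = ("percent_input", "aqueous_over_organic")


def faire_enrichment(
    ct_aqueous: float,
    ct_reference: float,
    efficiency: float = DEFAULT_EFFICIENCY,
    normalization_mode: str = "percent_input",
    input_fraction: float = DEFAULT_INPUT_FRACTION,
) -> float:
    """Open-chromatin (aqueous-phase) enrichment.

    ``percent_input`` treats ``ct_reference`` as the raw input-fraction
    Ct; ``aqueous_over_organic`` treats it as the organic-phase Ct and
    reports 100 x E^(ct_organic - ct_aqueous).
    """
    if normalization_mode == "percent_input":
        return percent_input(ct_reference, ct_aqueous, input_fraction, efficiency)
    if normalization_mode == "aqueous_over_organic":
        return 100.0 * efficiency ** (ct_reference - ct_aqueous)
    raise ValueError(f"unknown normalization_mode {normalization_mode!r}; "
                     f"expected one of {FAIRE_MODES}")


def hc_lc_percentage(quantity_hc: float, quantity_lc: float) -> float:
    """Heavy-chain over light-chain transcript quantity, as a percentage."""
    if quantity_lc <= 0:
        raise ValueError("light-chain quantity must be positive")
    return 100.0 * quantity_hc / quantity_lc


# --------------------------------------------------------------------------
# table-level pipelines (operate on the ct_*.csv dialect)
# --------------------------------------------------------------------------

def fit_curve_from_table(df: pd.DataFrame, target: str) -> StandardCurve:
    """Fit the standard curve from a table's embedded dilution series
    (rows with a known_log10_quantity)."""
    if "known_log10_quantity" not in df.columns:
        raise ValueError("table has no known_log10_quantity column")
    std = df[(df["target"] == target) & df["known_log10_quantity"].notna()]
    agg = std.groupby("known_log10_quantity")["ct"].mean()
    return fit_standard_curve(list(zip(agg.index, agg.values)))


def quantify_expression(df: pd.DataFrame) -> pd.DataFrame:
    """Per-sample HC/LC percentage by absolute quantification.

    Fits one standard curve per target from the embedded dilution
    series, converts each sample's mean Ct to a quantity, and reports
    100 x HC / LC.
    """
    curves = {t: fit_curve_from_table(df, t) for t in ("HC", "LC")}
    samples = df[df["known_log10_quantity"].isna()]
    agg = aggregate_replicates(samples, by=["sample", "target"])
    out = []
    for sample, grp in agg.groupby("sample", sort=False):
        q = {row["target"]: absolute_quantity(row["ct_mean"], curves[row["target"]])
             for _, row in grp.iterrows()}
        out.append(dict(sample=sample, quantity_hc=q["HC"], quantity_lc=q["LC"],
                        hc_lc_pct=hc_lc_percentage(q["HC"], q["LC"])))
    return pd.DataFrame(out)


def quantify_copy_number(
    df: pd.DataFrame,
    calibrator: str,
    target: str = "LC",
    reference: str = "Vezt",
    calibrator_copies: float = 1.0,
    efficiency: float | None = None,
) -> pd.DataFrame:
    """Per-sample transgene copy number relative to a calibrator sample."""
    if efficiency is None:
        try:
            efficiency = fit_curve_from_table(df, target).efficiency_factor
        except ValueError:
            efficiency = DEFAULT_EFFICIENCY
    samples = df[df["known_log10_quantity"].isna()] \
        if "known_log10_quantity" in df.columns else df
    agg = aggregate_replicates(samples, by=["sample", "target"])
    ct = {(r["sample"], r["target"]): r["ct_mean"] for _, r in agg.iterrows()}
    if (calibrator, target) not in ct:
        raise ValueError(f"calibrator sample {calibrator!r} not in table")
    out = []
    for sample in agg["sample"].unique():
        out.append(dict(
            sample=sample,
            copies=copy_number(
                ct[(sample, target)], ct[(sample, reference)],
                ct[(calibrator, target)], ct[(calibrator, reference)],
                e_target=efficiency, e_ref=efficiency,
                calibrator_copies=calibrator_copies),
        ))
    return pd.DataFrame(out)


def chip_enrichment(
    df: pd.DataFrame,
    efficiency: float = DEFAULT_EFFICIENCY,
    input_fraction: float = DEFAULT_INPUT_FRACTION,
) -> pd.DataFrame:
    """Per-sample, per-antibody percent input and H2A-relative enrichment.

    Percent input is computed per primer pair against that primer's
    paired input row, then averaged over primers.  IgG rows are reported
    as a background track, not subtracted.
    """
    agg = aggregate_replicates(df, by=["sample", "antibody", "target", "fraction"])
    input_ct = {(r["sample"], r["target"]): r["ct_mean"]
                for _, r in agg[agg["fraction"] == "input"].iterrows()}
    rows = []
    pulls = agg[agg["fraction"].isin(["chip", "igg"])]
    for _, r in pulls.iterrows():
        key = (r["sample"], r["target"])
        if key not in input_ct:
            logger.warning("no input row for %s / %s; skipped", *key)
            continue
        pct = percent_input(input_ct[key], r["ct_mean"], input_fraction, efficiency)
        rows.append(dict(sample=r["sample"], antibody=r["antibody"],
                         primer=r["target"], pct_input=pct))
    per_primer = pd.DataFrame(rows)
    mean_pct = (per_primer.groupby(["sample", "antibody"], sort=False)["pct_input"]
                .mean().reset_index())
    h2a = mean_pct[mean_pct["antibody"] == "H2A"].set_index("sample")["pct_input"]
    mean_pct["rel_h2a_pct"] = [
        relative_to_h2a(r["pct_input"], h2a[r["sample"]])
        if r["sample"] in h2a.index and r["antibody"] not in ("H2A", "IgG", "input")
        else np.nan
        for _, r in mean_pct.iterrows()
    ]
    return mean_pct


def faire_table(
    df: pd.DataFrame,
    efficiency: float = DEFAULT_EFFICIENCY,
    normalization_mode: str = "percent_input",
    input_fraction: float = DEFAULT_INPUT_FRACTION,
) -> pd.DataFrame:
    """Per-sample FAIRE enrichment, averaged over primer pairs."""
    if normalization_mode not in FAIRE_MODES:
        raise ValueError(f"unknown normalization_mode {normalization_mode!r}")
    ref_fraction = "input" if normalization_mode == "percent_input" else "organic"
    agg = aggregate_replicates(df, by=["sample", "target", "fraction"])
    ref_ct = {(r["sample"], r["target"]): r["ct_mean"]
              for _, r in agg[agg["fraction"] == ref_fraction].iterrows()}
    rows = []
    for _, r in agg[agg["fraction"] == "aqueous"].iterrows():
        key = (r["sample"], r["target"])
        if key not in ref_ct:
            logger.warning("no %s row for %s / %s; skipped", ref_fraction, *key)
            continue
        rows.append(dict(sample=r["sample"], primer=r["target"],
                         enrichment=faire_enrichment(
                             r["ct_mean"], ref_ct[key], efficiency,
                             normalization_mode, input_fraction)))
    per_primer = pd.DataFrame(rows)
    out = (per_primer.groupby("sample", sort=False)["enrichment"]
           .mean().reset_index())
    out.attrs["normalization_mode"] = normalization_mode
    return out
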