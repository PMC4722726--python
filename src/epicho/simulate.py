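"""Synthetic data generation for the whole pipeline.

Emulates the data types produced in an epigenetic characterisation of
recombinant CHO cell lines: a ~1.3-kb promoter reference carrying two CpG
islands and two adjacent 147-bp nucleosome windows; single-molecule
bisulfite clone reads of a 231-bp amplicon (endogenous methylation,
M.SssI accessibility footprinting, and naked-DNA M.SssI controls); qPCR
Ct tables for transgene copy number, heavy/light-chain expression,
ChIP percent-input and FAIRE; and a multi-passage stability study.

Every generated dataset is a pure function of ``(config, seed)``:
per-molecule / per-sample random substreams are derived from
``numpy.random.SeedSequence`` so that enlarging a dataset never perturbs
previously generated molecules.  Ground truth is emitted alongside every
dataset and round-trips losslessly through its JSON sidecar.

The default configuration encodes the study conditions of the four PT1
clonal lines (PT1-1, PT1-7, PT1-30, PT1-55): 18 CpG sites in the
amplicon, 15 molecules per clone, 98 % naked-DNA M.SssI efficiency, and
per-clone occupancy / enrichment / expression profiles taken from the
published signature matrix.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import PromoterAnnotation, annotate, write_fasta
from .bisulfite import bisulfite_convert

MODES = ("endogenous", "mssi", "naked_dna")
_MODE_CODE = {m: i for i, m in enumerate(MODES)}
MARKS = ("H3.3", "H2A.Z", "H3K9ac", "H3K9me3", "H3K4me3", "H3K27me3")
CHIP_PRIMERS = ("Nuc853", "Nuc1008", "Nuc853-1008", "Nuc1008-right")

AMPLICON_LENGTH = 231          # bp, targeted bisulfite PCR product
WINDOW_SPAN = 147              # bp, nucleosomal DNA
_ISLAND_UNIT = "ACGTG"         # CpG-island repeat unit (GC 0.6, obs/exp 2.5)
_FILLER_UNIT = "TGGACT"        # amplicon filler: GC-rich, CpG-free, retains C's


@dataclass(frozen=True)
class CloneProfile:
    """Planted truth for one recombinant clone.

    ``occupancy`` holds the per-window probability that a molecule
    carries a nucleosome there, ordered as the annotation's windows
    (distal first, TSS-proximal second).  ChIP enrichment is expressed
    as percent input for H2A and relative-to-H2A (%) for the variant and
    modification marks, matching how such results are reported.
    """

    name: str
    occupancy: tuple[float, ...]
    h2a_pct_input: float
    enrichment_rel_h2a: dict[str, float]
    faire_pct_input: float
    hc_lc_pct: float
    methylation_rate: float       # per-CpG endogenous methylation probability
    copy_number: float
    titer_retention: float        # relative titer at the last passage


def default_clones() -> tuple[CloneProfile, ...]:
    """The four PT1 clone profiles used as study conditions."""
    rel = lambda v: dict(zip(MARKS, v))
    return (
        CloneProfile("PT1-1", (0.6000, 0.8667), 19.50,
                     rel((22.00, 5.26, 2.17, 3.90, 8.04, 17.20)),
                     46.90, 1.00, 0.0625, 1.0, 0.2),
        CloneProfile("PT1-7", (0.6067, 0.6667), 6.67,
                     rel((79.94, 135.97, 218.15, 66.96, 5.41, 32.23)),
                     2.60, 53.50, 0.0000, 1.0, 0.8),
        CloneProfile("PT1-30", (0.7333, 0.8000), 13.31,
                     rel((16.73, 11.13, 61.99, 97.82, 17.90, 51.18)),
                     6.00, 22.36, 0.0208, 2.0, 0.4),
        CloneProfile("PT1-55", (0.8750, 0.6250), 2.93,
                     rel((66.45, 7.29, 189.00, 577.78, 16.40, 47.40)),
                     207.50, 104.00, 0.0071, 3.0, 0.6),
    )


@dataclass
class SimulationConfig:
    seed: int = 0
    n_molecules: int = 15
    promoter_length: int = 1261
    cpg_site_count_in_amplicon: int = 18
    mssi_efficiency: float = 0.98
    conversion_failure_rate: float = 0.005
    inappropriate_conversion_rate: float = 0.005
    missing_call_rate: float = 0.02
    qpcr_efficiency: float = 2.0
    ct_noise_sd: float = 0.15          # cycles
    igg_recovery_pct: float = 0.1      # background % input recovered with IgG
    n_passages: int = 22
    sample_every: int = 3              # titer sampled every k-th passage
    passage_hours: float = 84.0        # 3.5 days per passage
    titer_noise_cv: float = 0.02
    clones: tuple[CloneProfile, ...] = field(default_factory=default_clones)

    def __post_init__(self) -> None:
        probs = {
            "mssi_efficiency": self.mssi_efficiency,
            "conversion_failure_rate": self.conversion_failure_rate,
            "inappropriate_conversion_rate": self.inappropriate_conversion_rate,
            "missing_call_rate": self.missing_call_rate,
        }
        for k, v in probs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{k} must be in [0, 1], got {v}")
        if not 1.0 < self.qpcr_efficiency <= 2.0:
            raise ValueError("qpcr_efficiency must be in (1, 2]")
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")
        if self.n_passages < 2:
            raise ValueError("need at least 2 passages")
        if self.ct_noise_sd < 0 or self.titer_noise_cv < 0:
            raise ValueError("noise parameters must be non-negative")
        for c in self.clones:
            if not all(0.0 <= p <= 1.0 for p in c.occupancy):
                raise ValueError(f"{c.name}: occupancy probabilities must be in [0, 1]")
            if not 0.0 <= c.methylation_rate <= 1.0:
                raise ValueError(f"{c.name}: methylation_rate must be in [0, 1]")
            if not 0.0 <= c.titer_retention <= 1.0:
                raise ValueError(f"{c.name}: titer_retention must be in [0, 1]")

    def rng(self, *keys: int) -> np.random.Generator:
        """Deterministic substream for a (dataset, sample, molecule) path."""
        return np.random.default_rng(np.random.SeedSequence([self.seed, *keys]))

    def clone(self, name: str) -> CloneProfile:
        for c in self.clones:
            if c.name == name:
                return c
        raise KeyError(name)


# --------------------------------------------------------------------------
# promoter construction
# --------------------------------------------------------------------------

def generate_promoter(config: SimulationConfig) -> PromoterAnnotation:
    """Construct the reference promoter with planted structure.

    Layout (1-based, for the default 1261-bp length): an upstream CpG
    island at nt 60-279; two adjacent 147-bp nucleosome windows ending
    107 bp before the 3' end (853-999 and 1008-1154); and a 231-bp
    bisulfite amplicon fully covering the TSS-proximal window and the 3'
    part of the distal one, carrying exactly
    ``cpg_site_count_in_amplicon`` CpG dinucleotides.  The constructed
    sequence is validated against the package's own island scanner.
    """
    L = config.promoter_length
    n_cpg = config.cpg_site_count_in_amplicon
    if L < 700:
        raise ValueError(
            "promoter_length must be >= 700 to fit two CpG islands and "
            f"two {WINDOW_SPAN}-bp nucleosome windows (got {L})")
    if not 12 <= n_cpg <= 56:
        # below ~12 sites the amplicon is no longer CpG-dense enough to
        # satisfy the island criteria it is meant to sit inside
        raise ValueError(
            f"cpg_site_count_in_amplicon={n_cpg} not supported for a "
            f"{AMPLICON_LENGTH}-bp amplicon CpG island (supported range 12-56)")

    w2_end = L - 107
    w2_start = w2_end - (WINDOW_SPAN - 1)
    w1_end = w2_start - 9
    w1_start = w1_end - (WINDOW_SPAN - 1)
    amp_end = w2_end + 10
    amp_start = amp_end - (AMPLICON_LENGTH - 1)
    isl1_start, isl1_end = 60, 60 + 219

    rng = config.rng(0)
    # CpG-free AT-rich background: never draw G directly after C
    seq = []
    bases, probs = "ACGT", np.array([0.35, 0.15, 0.15, 0.35])
    bases_after_c, probs_after_c = "ACT", np.array([0.35, 0.15, 0.35]) / 0.85
    for _ in range(L):
        if seq and seq[-1] == "C":
            seq.append(bases_after_c[rng.choice(3, p=probs_after_c)])
        else:
            seq.append(bases[rng.choice(4, p=probs)])

    # upstream island: tandem CpG-rich repeat
    isl = (_ISLAND_UNIT * 60)[: isl1_end - isl1_start + 1]
    seq[isl1_start - 1 : isl1_end] = list(isl)

    # amplicon: exactly n_cpg evenly spaced CpGs in GC-rich CpG-free filler
    offsets = sorted({round(i * (AMPLICON_LENGTH - 2) / (n_cpg - 1)) for i in range(n_cpg)})
    if len(offsets) != n_cpg:
        raise ValueError("CpG spacing collision in amplicon construction")
    amp = list((_FILLER_UNIT * 40)[:AMPLICON_LENGTH])
    for off in offsets:
        amp[off], amp[off + 1] = "C", "G"
    seq[amp_start - 1 : amp_end] = amp

    # remove any stray CpG created at segment boundaries or by filler joins
    intended = {isl1_start + i for i in range(len(isl) - 1) if isl[i : i + 2] == "CG"}
    intended |= {amp_start + off for off in offsets}
    for i in range(L - 1):
        if seq[i] == "C" and seq[i + 1] == "G" and (i + 1) not in intended:
            seq[i + 1] = "A"

    sequence = "".join(seq)
    ann = annotate(
        sequence,
        window_coords=[(f"Nuc{w1_start}", w1_start, w1_end),
                       (f"Nuc{w2_start}", w2_start, w2_end)],
        amplicon=(amp_start, amp_end),
    )
    amp_cpgs = ann.amplicon_cpg_positions()
    if len(amp_cpgs) != n_cpg:
        raise AssertionError(
            f"amplicon contains {len(amp_cpgs)} CpGs, expected {n_cpg}")
    if len(ann.islands) < 2:
        raise ValueError(
            "constructed promoter failed the CpG-island criteria; "
            "increase promoter_length or cpg_site_count_in_amplicon")
    return ann


# --------------------------------------------------------------------------
# single-molecule epialleles
# --------------------------------------------------------------------------

@dataclass
class EpialleleTruth:
    """Planted per-molecule ground truth for one epiallele dataset."""

    mode: str
    clone_name: str | None
    cpg_positions: list[int]              # 1-based on the promoter
    molecule_ids: list[str]
    methylated_sites: list[list[int]]     # per molecule: indices into cpg_positions
    intervals: list[list[tuple[int, int]]]  # per molecule: nucleosome intervals

    def to_json(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["intervals"] = [[list(iv) for iv in mol] for mol in self.intervals]
        Path(path).write_text(json.dumps(d, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "EpialleleTruth":
        d = json.loads(Path(path).read_text())
        d["intervals"] = [[tuple(iv) for iv in mol] for mol in d["intervals"]]
        return cls(**d)


def simulate_epialleles(
    annotation: PromoterAnnotation,
    config: SimulationConfig,
    mode: str,
    clone: CloneProfile | None = None,
) -> tuple[dict[str, str], EpialleleTruth]:
    """Simulate bisulfite clone reads of the amplicon for one sample.

    ``endogenous``: CpGs methylated i.i.d. at the clone's methylation
    rate.  ``mssi``: each molecule draws a nucleosome per annotated
    window with the clone's occupancy probability; CpGs under an
    interval stay unmethylated, accessible CpGs are methylated with
    ``mssi_efficiency``.  ``naked_dna``: no nucleosomes; every CpG is
    accessible.  Bisulfite conversion with the configured error rates
    then yields read sequences; unreadable CpG calls appear as ``N``.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    if mode != "naked_dna" and clone is None:
        raise ValueError(f"{mode} mode requires a clone profile")
    if annotation.amplicon is None:
        raise ValueError("annotation has no amplicon declared")

    amp_start, amp_end = annotation.amplicon
    amp_seq = annotation.sequence[amp_start - 1 : amp_end]
    amp_cpgs = annotation.amplicon_cpg_positions()
    clone_idx = (
        [c.name for c in config.clones].index(clone.name) if clone is not None else 99
    )
    label = clone.name if clone is not None else "naked"

    reads: dict[str, str] = {}
    meth_sites: list[list[int]] = []
    intervals: list[list[tuple[int, int]]] = []
    ids: list[str] = []
    for i in range(config.n_molecules):
        rng = config.rng(1, clone_idx, _MODE_CODE[mode], i)
        mol_intervals: list[tuple[int, int]] = []
        if mode == "mssi":
            for w, p_occ in zip(annotation.windows, clone.occupancy):
                if rng.random() < p_occ:
                    mol_intervals.append((w.start, w.end))
        covered = set()
        for s, e in mol_intervals:
            covered.update(range(s, e + 1))

        methylated: list[int] = []
        for j, pos in enumerate(amp_cpgs):
            if mode == "endogenous":
                if rng.random() < clone.methylation_rate:
                    methylated.append(j)
            else:  # mssi / naked_dna: methylation marks accessibility
                if pos not in covered and rng.random() < config.mssi_efficiency:
                    methylated.append(j)

        meth_local = {amp_cpgs[j] - amp_start + 1 for j in methylated}
        read = bisulfite_convert(
            amp_seq, meth_local,
            failure_rate=config.conversion_failure_rate,
            inappropriate_rate=config.inappropriate_conversion_rate,
            rng=rng,
        )
        if config.missing_call_rate > 0:
            read = list(read)
            for pos in amp_cpgs:
                if rng.random() < config.missing_call_rate:
                    read[pos - amp_start] = "N"
            read = "".join(read)

        mol_id = f"{label}|{mode}|mol{i:04d}"
        reads[mol_id] = read
        ids.append(mol_id)
        meth_sites.append(methylated)
        intervals.append(mol_intervals)

    truth = EpialleleTruth(
        mode=mode,
        clone_name=clone.name if clone is not None else None,
        cpg_positions=list(amp_cpgs),
        molecule_ids=ids,
        methylated_sites=meth_sites,
        intervals=intervals,
    )
    return reads, truth


# --------------------------------------------------------------------------
# qPCR Ct tables
# --------------------------------------------------------------------------

_CT_INTERCEPT = 35.0      # Ct of one quantity unit
_INPUT_CT_BASE = 24.0     # raw Ct of the 1 % input fraction
_LC_QUANTITY = 1000.0     # true light-chain cDNA quantity units
_REF_QUANTITY = 500.0     # reference-gene quantity per genome equivalent
_ORGANIC_PCT = 80.0       # FAIRE organic-phase recovery (% input)


def _ct_from_quantity(q: float, E: float, intercept: float = _CT_INTERCEPT) -> float:
    if q <= 0:
        raise ValueError(f"true quantity must be positive, got {q}")
    return intercept - math.log(q, E)


@dataclass
class CtTruth:
    """True quantities behind every simulated Ct table."""

    curve_slope: float
    curve_intercept: float
    copy_number: dict[str, float]
    expression: dict[str, dict[str, float]]     # clone -> {HC, LC}
    chip_pct_input: dict[str, dict[str, float]]  # clone -> {H2A + marks}
    faire_pct_input: dict[str, float]
    igg_recovery_pct: float

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "CtTruth":
        return cls(**json.loads(Path(path).read_text()))


def simulate_ct_tables(config: SimulationConfig) -> tuple[dict[str, pd.DataFrame], CtTruth]:
    """Simulate all Ct tables: standard curves, copy number, HC/LC
    expression, ChIP percent-input (with paired input and IgG rows), and
    FAIRE (aqueous/organic/input fractions).

    Ct model: ``Ct = intercept - log_E(quantity) + N(0, ct_noise_sd)``;
    each table embeds a 5-point 10-fold dilution series of known
    quantities for standard-curve fitting.
    """
    E = config.qpcr_efficiency
    slope = -1.0 / math.log10(E)
    noise_counter = [0]

    def noisy(ct: float, rng: np.random.Generator) -> float:
        noise_counter[0] += 1
        return ct + (rng.normal(0.0, config.ct_noise_sd) if config.ct_noise_sd > 0 else 0.0)

    n_rep = 3

    def curve_rows(target: str, rng_key: int) -> list[dict]:
        rows = []
        for d, log10_q in enumerate([4.0, 3.0, 2.0, 1.0, 0.0]):
            q = 10.0 ** log10_q
            for rep in range(1, n_rep + 1):
                rng = config.rng(2, rng_key, d, rep)
                rows.append(dict(sample=f"std_1e{int(log10_q)}", target=target,
                                 fraction="plain", replicate=rep,
                                 ct=noisy(_ct_from_quantity(q, E), rng),
                                 known_log10_quantity=log10_q))
        return rows

    tables: dict[str, pd.DataFrame] = {}

    # ---- transgene copy number (target LC vs reference gene) ----
    rows = curve_rows("LC", 10) + curve_rows("Vezt", 11)
    for ci, c in enumerate(config.clones):
        q_lc = c.copy_number * 100.0          # per-genome target quantity
        for target, q in (("LC", q_lc), ("Vezt", _REF_QUANTITY)):
            for rep in range(1, n_rep + 1):
                rng = config.rng(3, ci, 0 if target == "LC" else 1, rep)
                rows.append(dict(sample=c.name, target=target, fraction="plain",
                                 replicate=rep, ct=noisy(_ct_from_quantity(q, E), rng),
                                 known_log10_quantity=np.nan))
    tables["copy_number"] = pd.DataFrame(rows)

    # ---- HC/LC expression ----
    rows = curve_rows("HC", 12) + curve_rows("LC", 13)
    expr_truth: dict[str, dict[str, float]] = {}
    for ci, c in enumerate(config.clones):
        q_hc = _LC_QUANTITY * c.hc_lc_pct / 100.0
        expr_truth[c.name] = {"HC": q_hc, "LC": _LC_QUANTITY}
        for target, q in (("HC", q_hc), ("LC", _LC_QUANTITY)):
            for rep in range(1, n_rep + 1):
                rng = config.rng(4, ci, 0 if target == "HC" else 1, rep)
                rows.append(dict(sample=c.name, target=target, fraction="plain",
                                 replicate=rep, ct=noisy(_ct_from_quantity(q, E), rng),
                                 known_log10_quantity=np.nan))
    tables["expression"] = pd.DataFrame(rows)

    # ---- ChIP percent input ----
    adj = math.log(1.0 / 0.01, E)             # dilution adjustment, 1 % input
    rows = []
    chip_truth: dict[str, dict[str, float]] = {}
    for ci, c in enumerate(config.clones):
        marks = {"H2A": c.h2a_pct_input}
        marks.update({m: c.h2a_pct_input * c.enrichment_rel_h2a[m] / 100.0
                      for m in MARKS})
        chip_truth[c.name] = marks
        for pi, primer in enumerate(CHIP_PRIMERS):
            for rep in range(1, n_rep + 1):
                rng = config.rng(5, ci, pi, 0, rep)
                rows.append(dict(sample=c.name, antibody="input", target=primer,
                                 fraction="input", replicate=rep,
                                 ct=noisy(_INPUT_CT_BASE, rng)))
                rng = config.rng(5, ci, pi, 1, rep)
                rows.append(dict(sample=c.name, antibody="IgG", target=primer,
                                 fraction="igg", replicate=rep,
                                 ct=noisy(_INPUT_CT_BASE - adj
                                          - math.log(config.igg_recovery_pct / 100.0, E), rng)))
            for mi, (mark, pct) in enumerate(marks.items()):
                for rep in range(1, n_rep + 1):
                    rng = config.rng(5, ci, pi, 2 + mi, rep)
                    rows.append(dict(sample=c.name, antibody=mark, target=primer,
                                     fraction="chip", replicate=rep,
                                     ct=noisy(_INPUT_CT_BASE - adj
                                              - math.log(pct / 100.0, E), rng)))
    tables["chip"] = pd.DataFrame(rows)

    # ---- FAIRE ----
    rows = []
    faire_truth: dict[str, float] = {}
    for ci, c in enumerate(config.clones):
        faire_truth[c.name] = c.faire_pct_input
        for pi, primer in enumerate(CHIP_PRIMERS[:2]):
            for rep in range(1, n_rep + 1):
                rng = config.rng(6, ci, pi, 0, rep)
                rows.append(dict(sample=c.name, target=primer, fraction="input",
                                 replicate=rep, ct=noisy(_INPUT_CT_BASE, rng)))
                rng = config.rng(6, ci, pi, 1, rep)
                rows.append(dict(sample=c.name, target=primer, fraction="aqueous",
                                 replicate=rep,
                                 ct=noisy(_INPUT_CT_BASE - adj
                                          - math.log(c.faire_pct_input / 100.0, E), rng)))
                rng = config.rng(6, ci, pi, 2, rep)
                rows.append(dict(sample=c.name, target=primer, fraction="organic",
                                 replicate=rep,
                                 ct=noisy(_INPUT_CT_BASE - adj
                                          - math.log(_ORGANIC_PCT / 100.0, E), rng)))
    tables["faire"] = pd.DataFrame(rows)

    truth = CtTruth(
        curve_slope=slope,
        curve_intercept=_CT_INTERCEPT,
        copy_number={c.name: c.copy_number for c in config.clones},
        expression=expr_truth,
        chip_pct_input=chip_truth,
        faire_pct_input=faire_truth,
        igg_recovery_pct=config.igg_recovery_pct,
    )
    return tables, truth


# --------------------------------------------------------------------------
# stability study
# --------------------------------------------------------------------------

def simulate_stability_study(config: SimulationConfig) -> tuple[pd.DataFrame, dict]:
    """Simulate a long-term stability study sampled every k-th passage.

    The per-passage relative titer decays geometrically so that the last
    passage reaches each clone's configured retention; viable cell
    densities follow a saturating (logistic-like) growth value at each
    harvest.  Noise draws are shared across clones (one substream per
    passage), so clones with identical seed differ only through their
    configured rates.
    """
    if config.n_passages < 2:
        raise ValueError("need at least 2 passages")
    passages = list(range(1, config.n_passages + 1, config.sample_every))
    if passages[-1] != config.n_passages:
        passages.append(config.n_passages)

    # shared noise streams: one per sampled passage
    noise = {}
    for k, p in enumerate(passages):
        rng = config.rng(7, k)
        noise[p] = (rng.normal(0.0, 1.0), rng.normal(0.0, 1.0))

    titer0 = 50.0       # µg/mL at the first sampled passage
    k_sat = 1.2         # 1e9 cells/L harvest plateau
    rows = []
    truth: dict[str, dict] = {}
    for c in config.clones:
        r = c.titer_retention ** (1.0 / (config.n_passages - 1))
        rel = {p: r ** (p - 1) for p in passages}
        truth[c.name] = {"retention_per_passage": r, "relative_titer": rel}
        for p in passages:
            t = (p - 1) * config.passage_hours
            z_d, z_t = noise[p]
            # logistic-like saturation within a passage interval
            dens = k_sat / (1.0 + math.exp(-(0.12 * config.passage_hours - 5.0)))
            dens *= 1.0 + 0.05 * z_d if config.titer_noise_cv > 0 else 1.0
            titer = titer0 * rel[p]
            titer *= 1.0 + config.titer_noise_cv * z_t
            rows.append(dict(clone=c.name, passage=p, t_hours=t,
                             viable_density_1e9_per_L=max(dens, 0.0),
                             titer_ug_per_mL=max(titer, 0.0)))
    return pd.DataFrame(rows), truth


# --------------------------------------------------------------------------
# dataset writer
# --------------------------------------------------------------------------

def write_dataset(config: SimulationConfig, outdir: str | Path,
                  modes: tuple[str, ...] = MODES) -> dict[str, Path]:
    """Generate and write every pipeline input under ``outdir``.

    Emits reference.fasta, windows.bed, annotation.json, per-clone and
    naked-control read FASTAs with truth.json sidecars, ct_*.csv tables,
    and stability.csv.  Identical config and seed produce byte-identical
    files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    ann = generate_promoter(config)
    paths["reference"] = outdir / "reference.fasta"
    write_fasta({"promoter": ann.sequence}, paths["reference"])
    paths["annotation"] = outdir / "annotation.json"
    ann.to_json(paths["annotation"])
    paths["windows"] = outdir / "windows.bed"
    with open(paths["windows"], "w") as fh:
        for w in ann.windows:
            fh.write(f"promoter\t{w.start - 1}\t{w.end}\t{w.name}\n")

    for mode in modes:
        clones = [None] if mode == "naked_dna" else list(config.clones)
        for clone in clones:
            label = "naked" if clone is None else clone.name
            reads, truth = simulate_epialleles(ann, config, mode, clone)
            key = f"reads_{label}_{mode}"
            paths[key] = outdir / f"{key}.fasta"
            write_fasta(reads, paths[key])
            truth.to_json(outdir / f"{key}.truth.json")

    tables, ct_truth = simulate_ct_tables(config)
    for name, df in tables.items():
        p = outdir / f"ct_{name}.csv"
        df.to_csv(p, index=False, float_format="%.6f")
        paths[f"ct_{name}"] = p
    ct_truth.to_json(outdir / "ct_tables.truth.json")

    stab, stab_truth = simulate_stability_study(config)
    paths["stability"] = outdir / "stability.csv"
    stab.to_csv(paths["stability"], index=False, float_format="%.6f")
    (outdir / "stability.truth.json").write_text(
        json.dumps(stab_truth, indent=1, sort_keys=True))
    return paths
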