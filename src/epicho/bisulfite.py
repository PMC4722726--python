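"""Bisulfite conversion model, amplicon read alignment, and per-molecule
CpG methylation calling.

Chemistry modeled: bisulfite deaminates unmethylated cytosine to uracil
(read as thymine after PCR) while 5-methylcytosine is retained as
cytosine.  The model is top-strand only, as in targeted bisulfite PCR of
a single strand.  Each sequenced clone is one molecule; calls at each
CpG site are METH (C), UNMETH (T) or MISSING (anything else, or
uncovered).  Per-molecule conversion efficiency — the converted fraction
of non-CpG reference cytosines — is used as a QC filter (default 0.95).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .annotation import PromoterAnnotation

logger = logging.getLogger(__name__)

METH, UNMETH, MISSING = 1, 0, -1
_CALL_CHAR = {METH: "M", UNMETH: "U", MISSING: "."}
_CHAR_CALL = {v: k for k, v in _CALL_CHAR.items()}

MODES = ("endogenous", "mssi", "naked_dna")


def bisulfite_convert(
    sequence: str,
    methylated_positions: set[int] | list[int],
    failure_rate: float = 0.0,
    inappropriate_rate: float = 0.0,
    rng: np.random.Generator | None = None,
) -> str:
    """Apply bisulfite chemistry to a (sub)sequence.

    ``methylated_positions`` are 1-based positions of methylated Cs.
    Unmethylated C converts to T with probability ``1 - failure_rate``;
    a methylated C is inappropriately converted with probability
    ``inappropriate_rate``.  Non-C bases are untouched.
    """
    seq = sequence.upper()
    methylated = set(methylated_positions)
    for p in methylated:
        if not 1 <= p <= len(seq) or seq[p - 1] != "C":
            raise ValueError(f"methylated position {p} is not a C")
    if (failure_rate > 0 or inappropriate_rate > 0) and rng is None:
        raise ValueError("an rng is required when error rates are non-zero")

    out = list(seq)
    for i, base in enumerate(out):
        if base != "C":
            continue
        if (i + 1) in methylated:
            if inappropriate_rate > 0 and rng.random() < inappropriate_rate:
                out[i] = "T"
        else:
            if failure_rate > 0:
                if rng.random() >= failure_rate:
                    out[i] = "T"
            else:
                out[i] = "T"
    return "".join(out)


# --------------------------------------------------------------------------
# alignment
# --------------------------------------------------------------------------

@dataclass
class AlignedRead:
    """Mapping of read bases to 1-based reference positions (-1 = insertion)."""

    molecule_id: str
    ref_positions: np.ndarray       # int array, len(read)
    read: str
    identity: float
    gapped: bool

    def base_at(self, ref_pos: int) -> str | None:
        """Read base aligned to a reference position, None if uncovered."""
        hits = np.nonzero(self.ref_positions == ref_pos)[0]
        if len(hits) == 0:
            return None
        return self.read[hits[0]]


def _bisulfite_match(ref_base: str, read_base: str) -> bool:
    """Read T at a reference C is a legitimate converted match."""
    return read_base == ref_base or (ref_base == "C" and read_base == "T")


def _build_aligner() -> Align.PairwiseAligner:
    # reference alphabet uses 'c' for C so conversion (read T) scores as match
    alphabet = "ACGTNc"
    mat = substitution_matrices.Array(alphabet=alphabet, dims=2)
    for a in alphabet:
        for b in alphabet:
            mat[a, b] = -1.0
    for b in "ACGT":
        mat[b, b] = 1.0
    mat["c", "C"] = 1.0
    mat["c", "T"] = 1.0
    for b in alphabet:
        mat["N", b] = 0.0
        mat[b, "N"] = 0.0
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = mat
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -0.5
    return aligner


_ALIGNER = _build_aligner()


def align_read(
    read: str,
    annotation: PromoterAnnotation,
    molecule_id: str = "read",
    max_anchored_mismatch: float = 0.2,
    min_identity: float = 0.6,
) -> AlignedRead | None:
    """Position an amplicon read on the reference.

    First tries ungapped anchoring at the amplicon start; if the
    bisulfite-aware mismatch fraction exceeds ``max_anchored_mismatch``
    a global alignment (match +1, mismatch -1, gap open -2, gap extend
    -0.5, C/T equivalent at reference Cs) is used instead.  Reads whose
    final identity is below ``min_identity`` are rejected (returns
    ``None``, reason logged).
    """
    if annotation.amplicon is None:
        raise ValueError("annotation has no amplicon declared")
    read = read.upper()
    amp_start, amp_end = annotation.amplicon
    ref = annotation.sequence

    # --- ungapped anchor ---
    n = min(len(read), len(ref) - amp_start + 1)
    matches = mismatches = 0
    for i in range(n):
        rb, qb = ref[amp_start - 1 + i], read[i]
        if qb == "N" or rb == "N":
            continue
        if _bisulfite_match(rb, qb):
            matches += 1
        else:
            mismatches += 1
    compared = matches + mismatches
    mismatch_frac = mismatches / compared if compared else 1.0
    if compared and mismatch_frac <= max_anchored_mismatch:
        positions = np.arange(amp_start, amp_start + len(read))
        positions[n:] = -1
        identity = matches / compared
        return AlignedRead(molecule_id, positions, read, identity, gapped=False)

    # --- gapped fallback against the amplicon region ---
    amp_ref = ref[amp_start - 1 : amp_end].replace("C", "c")
    try:
        aln = _ALIGNER.align(amp_ref, read)[0]
    except Exception:  # no viable alignment path
        logger.info("read %s rejected: unalignable", molecule_id)
        return None
    positions = np.full(len(read), -1, dtype=int)
    matches = n_pairs = 0
    for (rs, re_), (qs, qe) in zip(*aln.aligned):
        for k in range(re_ - rs):
            ref_pos = amp_start + rs + k           # 1-based promoter coordinate
            positions[qs + k] = ref_pos
            n_pairs += 1
            rb, qb = ref[ref_pos - 1], read[qs + k]
            if qb == "N" or rb == "N":
                continue
            if _bisulfite_match(rb, qb):
                matches += 1
    # gap columns count against identity, so a heavily gapped stitch of
    # chance matches cannot pass the threshold
    n_columns = len(amp_ref) + len(read) - n_pairs
    identity = matches / n_columns if n_columns else 0.0
    if identity < min_identity:
        logger.info("read %s rejected: identity %.3f < %.2f",
                    molecule_id, identity, min_identity)
        return None
    return AlignedRead(molecule_id, positions, read, identity, gapped=True)


# --------------------------------------------------------------------------
# methylation calling
# --------------------------------------------------------------------------

@dataclass
class EpialleleMatrix:
    """Molecules x CpG-sites call matrix with assay mode.

    ``calls`` uses METH=1, UNMETH=0, MISSING=-1.  ``conversion_efficiency``
    is per molecule: the converted (T) fraction of aligned non-CpG
    reference-C positions; NaN when no such position is covered.
    """

    molecule_ids: list[str]
    cpg_positions: list[int]
    calls: np.ndarray
    mode: str
    conversion_efficiency: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.molecule_ids), len(self.cpg_positions)):
            raise ValueError("calls matrix shape does not match ids x positions")
        if self.conversion_efficiency is None:
            self.conversion_efficiency = np.full(len(self.molecule_ids), np.nan)
        if not np.isin(self.calls, [METH, UNMETH, MISSING]).all():
            raise ValueError("calls must be METH, UNMETH or MISSING")

    @property
    def n_molecules(self) -> int:
        return len(self.molecule_ids)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            [[_CALL_CHAR[c] for c in row] for row in self.calls],
            index=pd.Index(self.molecule_ids, name="molecule"),
            columns=[str(p) for p in self.cpg_positions],
        )
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path, mode: str) -> "EpialleleMatrix":
        df = pd.read_csv(path, index_col=0)
        calls = np.array([[_CHAR_CALL[v] for v in row] for row in df.to_numpy()],
                         dtype=np.int8)
        return cls(list(df.index), [int(c) for c in df.columns], calls, mode)


def call_methylation(
    reads: dict[str, str],
    annotation: PromoterAnnotation,
    mode: str,
    max_anchored_mismatch: float = 0.2,
    min_identity: float = 0.6,
) -> EpialleleMatrix:
    """Align reads and call METH/UNMETH/MISSING at every amplicon CpG.

    At each CpG C position: read C -> METH, read T -> UNMETH, any other
    base or no coverage -> MISSING.  Rejected reads are dropped (logged);
    at least one read must survive.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    cpg_positions = annotation.amplicon_cpg_positions()
    cpg_set = set(cpg_positions)
    amp_start, amp_end = annotation.amplicon
    noncpg_c = [p for p in range(amp_start, amp_end + 1)
                if annotation.sequence[p - 1] == "C" and p not in cpg_set]

    ids, rows, effs = [], [], []
    n_rejected = 0
    for mol_id, read in reads.items():
        aligned = align_read(read, annotation, mol_id,
                             max_anchored_mismatch, min_identity)
        if aligned is None:
            n_rejected += 1
            continue
        row = []
        for p in cpg_positions:
            base = aligned.base_at(p)
            if base == "C":
                row.append(METH)
            elif base == "T":
                row.append(UNMETH)
            else:
                row.append(MISSING)
        conv = tot = 0
        for p in noncpg_c:
            base = aligned.base_at(p)
            if base == "T":
                conv += 1
                tot += 1
            elif base == "C":
                tot += 1
        ids.append(mol_id)
        rows.append(row)
        effs.append(conv / tot if tot else np.nan)

    if not ids:
        raise ValueError("no reads survived alignment")
    if n_rejected:
        logger.warning("%d of %d reads rejected during alignment",
                       n_rejected, len(reads))
    matrix = EpialleleMatrix(ids, cpg_positions,
                             np.array(rows, dtype=np.int8), mode,
                             np.array(effs, dtype=float))
    all_missing = (matrix.calls == MISSING).all(axis=1)
    if all_missing.any():
        logger.warning("%d molecules have no callable CpG (retained, flagged)",
                       int(all_missing.sum()))
    return matrix


# --------------------------------------------------------------------------
# summaries
# --------------------------------------------------------------------------

def plot_lollipop(matrix: EpialleleMatrix, path: str | Path) -> None:
    """Lollipop-style epiallele plot: one row per molecule, one circle per
    CpG (filled = methylated, open = unmethylated, absent = missing)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n_mol, n_cpg = matrix.calls.shape
    fig, ax = plt.subplots(figsize=(max(4, n_cpg * 0.35), max(2, n_mol * 0.25)))
    xs = matrix.cpg_positions
    for i in range(n_mol):
        y = n_mol - i
        ax.hlines(y, xs[0], xs[-1], color="0.8", lw=0.8, zorder=1)
        for j, p in enumerate(xs):
            c = matrix.calls[i, j]
            if c == MISSING:
                continue
            ax.scatter(p, y, s=45, zorder=2, edgecolors="black",
                       facecolors="black" if c == METH else "white")
    ax.set_yticks(range(1, n_mol + 1),
                  labels=list(reversed(matrix.molecule_ids)), fontsize=6)
    ax.set_xlabel("promoter position (nt)")
    ax.set_title(f"epialleles ({matrix.mode} mode)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


@dataclass
class MethylationSummary:
    overall_pct: float
    per_site_pct: np.ndarray        # len == n CpG sites, NaN if uncallable
    per_molecule_pct: np.ndarray    # len == n retained molecules
    molecule_ids: list[str]
    n_excluded_low_conversion: int


def methylation_summary(
    matrix: EpialleleMatrix,
    filter_min_conversion: float = 0.95,
) -> MethylationSummary:
    """Methylation percentages over non-MISSING cells.

    Molecules whose bisulfite conversion efficiency falls below
    ``filter_min_conversion`` are excluded (incomplete conversion
    inflates apparent methylation).  Overall % = 100 x METH cells /
    (METH + UNMETH cells).
    """
    if matrix.mode != "endogenous":
        raise ValueError(
            f"methylation summary is defined for endogenous-mode matrices, got {matrix.mode!r}")
    eff = matrix.conversion_efficiency
    keep = ~(eff < filter_min_conversion)     # NaN efficiency is retained
    n_excluded = int((~keep).sum())
    if n_excluded:
        logger.warning("%d molecules excluded: conversion efficiency < %.2f",
                       n_excluded, filter_min_conversion)
    calls = matrix.calls[keep]
    ids = [m for m, k in zip(matrix.molecule_ids, keep) if k]

    meth = calls == METH
    unmeth = calls == UNMETH
    callable_total = meth.sum() + unmeth.sum()
    if callable_total == 0:
        raise ValueError("no callable (non-MISSING) cells after filtering")

    with np.errstate(invalid="ignore"):
        site_n = (meth | unmeth).sum(axis=0).astype(float)
        per_site = np.where(site_n > 0, 100.0 * meth.sum(axis=0) / site_n, np.nan)
        mol_n = (meth | unmeth).sum(axis=1).astype(float)
        per_mol = np.where(mol_n > 0, 100.0 * meth.sum(axis=1) / mol_n, np.nan)
    overall = 100.0 * meth.sum() / callable_total
    return MethylationSummary(float(overall), per_site, per_mol, ids, n_excluded)
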