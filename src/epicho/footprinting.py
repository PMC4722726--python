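"""Methyltransferase-accessibility footprinting.

An M.SssI-treated chromatin sample reports, per single molecule, which
CpGs were enzymatically accessible (methylated after the assay) and
which were protected (unmethylated), typically by a nucleosome: a run of
protected CpGs spanning roughly 147 bp is read as a nucleosome
footprint.  This module converts M.SssI-mode epiallele matrices into
protection maps, calls per-molecule footprints, and scores per-window
nucleosome occupancy.

Occupancy is reported with two definitions (the field uses both):

* CpG-call level (primary): 100 x protected calls / (protected +
  accessible calls) over all molecules at the window's CpGs.
* Molecule level: the fraction of molecules carrying a
  nucleosome-classified footprint over the window midpoint.  This is
  only fully observable when the sequenced amplicon covers enough of the
  window to satisfy the footprint span threshold.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .annotation import NucleosomeWindow, PromoterAnnotation
from .bisulfite import MISSING, METH, UNMETH, EpialleleMatrix

logger = logging.getLogger(__name__)

PROTECTED, ACCESSIBLE = 1, 0   # MISSING stays -1

DEFAULT_MIN_NUCLEOSOME_SPAN = 127   # bp; ~147 minus one CpG-spacing tolerance
DEFAULT_MIN_CPGS = 3


@dataclass
class ProtectionMap:
    """Per-molecule, per-CpG accessibility states from an M.SssI assay."""

    molecule_ids: list[str]
    cpg_positions: list[int]
    states: np.ndarray              # PROTECTED=1, ACCESSIBLE=0, MISSING=-1
    source_mode: str

    @property
    def n_molecules(self) -> int:
        return len(self.molecule_ids)


def to_protection_map(matrix: EpialleleMatrix) -> ProtectionMap:
    """Invert assay semantics: methylated = accessible, unmethylated =
    protected.  Refuses endogenous-mode matrices, where methylation has
    the opposite meaning."""
    if matrix.mode == "endogenous":
        raise ValueError(
            "endogenous-mode matrix: methylation does not report accessibility")
    states = np.full_like(matrix.calls, MISSING)
    states[matrix.calls == METH] = ACCESSIBLE
    states[matrix.calls == UNMETH] = PROTECTED
    return ProtectionMap(list(matrix.molecule_ids), list(matrix.cpg_positions),
                         states, matrix.mode)


@dataclass
class FootprintCall:
    molecule_id: str
    start: int                  # 1-based nt, run extended to flanking midpoints
    end: int
    n_protected_cpgs: int
    classification: str         # "nucleosome" | "subnucleosomal"

    @property
    def span_bp(self) -> int:
        return self.end - self.start + 1

    def contains(self, pos: float) -> bool:
        return self.start <= pos <= self.end


def _runs_of_protection(states_row: np.ndarray) -> list[list[int]]:
    """Maximal runs of protected CpG indices; MISSING bridges a run but
    contributes no protected evidence, ACCESSIBLE breaks it."""
    runs: list[list[int]] = []
    current: list[int] = []
    for j, s in enumerate(states_row):
        if s == PROTECTED:
            current.append(j)
        elif s == ACCESSIBLE:
            if current:
                runs.append(current)
                current = []
        # MISSING: run continues
    if current:
        runs.append(current)
    return runs


def call_footprints(
    pmap: ProtectionMap,
    annotation: PromoterAnnotation | None = None,
    min_nucleosome_span: int = DEFAULT_MIN_NUCLEOSOME_SPAN,
    min_cpgs: int = DEFAULT_MIN_CPGS,
) -> list[FootprintCall]:
    """Call protected footprints per molecule.

    A run's interval reaches from its first to its last protected CpG,
    extended to the midpoint toward the nearest flanking accessible CpG;
    at map edges it extends to the amplicon boundary (or the outermost
    CpG when no amplicon is declared).  Runs meeting both the span and
    the protected-CpG-count thresholds are classified "nucleosome",
    shorter ones "subnucleosomal".
    """
    if pmap.n_molecules < 1:
        raise ValueError("empty protection map")
    pos = np.asarray(pmap.cpg_positions)
    if annotation is not None and annotation.amplicon is not None:
        edge_lo, edge_hi = annotation.amplicon
    else:
        edge_lo, edge_hi = int(pos[0]), int(pos[-1])

    calls: list[FootprintCall] = []
    for mol_id, row in zip(pmap.molecule_ids, pmap.states):
        accessible_idx = np.nonzero(row == ACCESSIBLE)[0]
        for run in _runs_of_protection(row):
            first, last = run[0], run[-1]
            left_acc = accessible_idx[accessible_idx < first]
            right_acc = accessible_idx[accessible_idx > last]
            if len(left_acc):
                start = int(round((pos[left_acc[-1]] + pos[first]) / 2.0))
            else:
                start = edge_lo
            if len(right_acc):
                end = int(round((pos[last] + pos[right_acc[0]]) / 2.0))
            else:
                end = edge_hi
            span = end - start + 1
            cls = ("nucleosome"
                   if span >= min_nucleosome_span and len(run) >= min_cpgs
                   else "subnucleosomal")
            calls.append(FootprintCall(mol_id, start, end, len(run), cls))
    return calls


@dataclass
class OccupancyResult:
    window: str
    cpg_level_pct: float
    molecule_level_pct: float
    n_protected: int
    n_accessible: int
    n_molecules: int
    n_window_cpgs: int


def window_occupancy(
    pmap: ProtectionMap,
    window: NucleosomeWindow,
    annotation: PromoterAnnotation | None = None,
    min_nucleosome_span: int = DEFAULT_MIN_NUCLEOSOME_SPAN,
    min_cpgs: int = DEFAULT_MIN_CPGS,
) -> OccupancyResult:
    """Nucleosome occupancy of one window across all molecules.

    The CpG-call-level percentage is the primary statistic; the
    molecule-level alternative (fraction of molecules whose footprint
    over the window midpoint is nucleosome-classified) is reported
    alongside.
    """
    cols = [j for j, p in enumerate(pmap.cpg_positions)
            if window.start <= p <= window.end]
    if not cols:
        raise ValueError(f"window {window.name!r} contains no observed CpG site")
    if len(cols) < 2:
        logger.warning("window %s has <2 observed CpGs; footprints uncallable there",
                       window.name)
    sub = pmap.states[:, cols]
    n_prot = int((sub == PROTECTED).sum())
    n_acc = int((sub == ACCESSIBLE).sum())
    if n_prot + n_acc == 0:
        raise ValueError(f"window {window.name!r} has no non-MISSING calls")
    cpg_level = 100.0 * n_prot / (n_prot + n_acc)

    calls = call_footprints(pmap, annotation, min_nucleosome_span, min_cpgs)
    mid = window.midpoint
    occupied = {c.molecule_id for c in calls
                if c.classification == "nucleosome" and c.contains(mid)}
    mol_level = 100.0 * len(occupied) / pmap.n_molecules
    return OccupancyResult(window.name, cpg_level, mol_level,
                           n_prot, n_acc, pmap.n_molecules, len(cols))


def plot_protection_map(
    pmap: ProtectionMap,
    annotation: PromoterAnnotation | None = None,
    path: str | Path = "protection_map.png",
) -> None:
    """Single-molecule accessibility map: red = accessible (methylated by
    M.SssI), blue = protected, white = missing; annotated nucleosome
    windows are shaded."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    img = np.full(pmap.states.shape, 2.0)
    img[pmap.states == ACCESSIBLE] = 0.0
    img[pmap.states == PROTECTED] = 1.0
    cmap = ListedColormap(["#c0392b", "#2a6bb0", "white"])
    fig, ax = plt.subplots(figsize=(8, max(2, pmap.n_molecules * 0.2)))
    ax.imshow(img, aspect="auto", cmap=cmap, vmin=0, vmax=2,
              extent=(pmap.cpg_positions[0], pmap.cpg_positions[-1],
                      pmap.n_molecules, 0))
    if annotation is not None:
        for w in annotation.windows:
            ax.axvspan(w.start, w.end, color="0.5", alpha=0.15)
            ax.text(w.midpoint, -0.4, w.name, ha="center", fontsize=7)
    ax.set_xlabel("promoter position (nt)")
    ax.set_ylabel("molecule")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def naked_dna_efficiency(pmap: ProtectionMap, qc_threshold: float = 0.95) -> float:
    """M.SssI methylation efficiency (%) from a naked-DNA control map:
    the accessible fraction of non-MISSING calls.  Warns when the
    control falls below the QC threshold (default 95 %)."""
    n_acc = int((pmap.states == ACCESSIBLE).sum())
    n_prot = int((pmap.states == PROTECTED).sum())
    if n_acc + n_prot == 0:
        raise ValueError("empty or fully missing naked-DNA control map")
    eff = 100.0 * n_acc / (n_acc + n_prot)
    if eff < 100.0 * qc_threshold:
        warnings.warn(
            f"naked-DNA M.SssI efficiency {eff:.1f}% below QC threshold "
            f"{100 * qc_threshold:.0f}%", UserWarning, stacklevel=2)
    return eff
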