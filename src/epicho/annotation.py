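"""Promoter annotation: CpG sites, CpG islands, and named nucleosome windows.

Coordinates are 1-based inclusive throughout this package, matching the
convention used for the promoter landmarks (e.g. a nucleosome window
"Nuc853" spanning nt 853-999).  BED input/output converts to and from
0-based half-open coordinates at the file boundary.

CpG islands are detected with the classic Gardiner-Garden & Frommer
criteria (length >= 200 bp, GC fraction >= 0.50, observed/expected CpG
ratio >= 0.6) applied over a sliding window; the thresholds are exposed
as parameters.  ``N`` bases count toward region length but contribute
neither to GC content nor to CpG counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_VALID_BASES = frozenset("ACGTN")


@dataclass(frozen=True)
class CpGIsland:
    """A CpG-rich region (1-based inclusive coordinates)."""

    start: int
    end: int
    gc_fraction: float
    obs_exp_ratio: float

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class NucleosomeWindow:
    """A named candidate nucleosome position on the promoter.

    ``cpg_indices`` are indices into the annotation's ``cpg_positions``
    list for CpGs whose C falls inside [start, end].
    """

    name: str
    start: int
    end: int
    cpg_indices: list[int] = field(default_factory=list)

    @property
    def span(self) -> int:
        return self.end - self.start + 1

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass
class PromoterAnnotation:
    """Reference promoter sequence with CpG sites, islands and windows."""

    sequence: str
    cpg_positions: list[int]
    islands: list[CpGIsland] = field(default_factory=list)
    windows: list[NucleosomeWindow] = field(default_factory=list)
    amplicon: tuple[int, int] | None = None  # 1-based inclusive bisulfite amplicon

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        for p in self.cpg_positions:
            if self.sequence[p - 1 : p + 1] != "CG":
                raise ValueError(f"position {p} is not the C of a CpG")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def window(self, name: str) -> NucleosomeWindow:
        for w in self.windows:
            if w.name == name:
                return w
        raise KeyError(name)

    def amplicon_cpg_positions(self) -> list[int]:
        """CpG positions falling inside the declared amplicon."""
        if self.amplicon is None:
            raise ValueError("no amplicon declared on this annotation")
        lo, hi = self.amplicon
        return [p for p in self.cpg_positions if lo <= p <= hi]

    # ---- serialization -------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        payload = {
            "sequence": self.sequence,
            "cpg_positions": self.cpg_positions,
            "islands": [
                [i.start, i.end, i.gc_fraction, i.obs_exp_ratio] for i in self.islands
            ],
            "windows": [
                {"name": w.name, "start": w.start, "end": w.end, "cpg_indices": w.cpg_indices}
                for w in self.windows
            ],
            "amplicon": list(self.amplicon) if self.amplicon else None,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "PromoterAnnotation":
        d = json.loads(Path(path).read_text())
        ann = cls(
            sequence=d["sequence"],
            cpg_positions=list(d["cpg_positions"]),
            islands=[CpGIsland(*i) for i in d["islands"]],
            windows=[
                NucleosomeWindow(w["name"], w["start"], w["end"], list(w["cpg_indices"]))
                for w in d["windows"]
            ],
            amplicon=tuple(d["amplicon"]) if d.get("amplicon") else None,
        )
        return ann


# ---- operations --------------------------------------------------------


def _check_sequence(sequence: str) -> str:
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    bad = set(seq) - _VALID_BASES
    if bad:
        raise ValueError(f"invalid bases in sequence: {sorted(bad)}")
    return seq


def find_cpg_sites(sequence: str) -> list[int]:
    """Return sorted 1-based positions of the C of every CpG dinucleotide.

    ``N`` never matches, so "CN" / "NG" contribute no site.
    """
    seq = _check_sequence(sequence)
    return [i + 1 for i in range(len(seq) - 1) if seq[i] == "C" and seq[i + 1] == "G"]


def _region_stats(seq: str, start0: int, end0: int) -> tuple[float, float]:
    """GC fraction and CpG observed/expected for seq[start0:end0] (0-based)."""
    region = seq[start0:end0]
    length = len(region)
    n_c = region.count("C")
    n_g = region.count("G")
    n_cg = sum(1 for i in range(length - 1) if region[i] == "C" and region[i + 1] == "G")
    gc = (n_c + n_g) / length if length else 0.0
    obs_exp = (n_cg * length) / (n_c * n_g) if n_c and n_g else 0.0
    return gc, obs_exp


def find_cpg_islands(
    sequence: str,
    min_length: int = 200,
    min_gc: float = 0.50,
    min_obs_exp: float = 0.6,
    window: int = 100,
    step: int = 1,
) -> list[CpGIsland]:
    """Detect CpG islands by a sliding-window scan plus merge.

    Windows of ``window`` bp (advanced by ``step``) that satisfy the GC and
    observed/expected criteria are merged into maximal regions; a merged
    region is reported when it is at least ``min_length`` bp long and
    itself satisfies both criteria.
    """
    seq = _check_sequence(sequence)
    if len(seq) < window:
        raise ValueError(f"sequence shorter than scan window ({len(seq)} < {window})")

    hits: list[tuple[int, int]] = []  # 0-based half-open qualifying windows
    for s in range(0, len(seq) - window + 1, step):
        gc, oe = _region_stats(seq, s, s + window)
        if gc >= min_gc and oe >= min_obs_exp:
            if hits and s <= hits[-1][1]:
                hits[-1] = (hits[-1][0], s + window)
            else:
                hits.append((s, s + window))

    islands = []
    for s, e in hits:
        if e - s < min_length:
            continue
        gc, oe = _region_stats(seq, s, e)
        if gc >= min_gc and oe >= min_obs_exp:
            islands.append(CpGIsland(s + 1, e, round(gc, 4), round(oe, 4)))
    return islands


def define_windows(
    coords: list[tuple[str, int, int]],
    cpg_positions: list[int],
    sequence_length: int | None = None,
) -> list[NucleosomeWindow]:
    """Build named nucleosome windows (1-based inclusive) and annotate the
    CpG sites each one contains."""
    windows = []
    for name, start, end in coords:
        if start < 1 or end < start:
            raise ValueError(f"window {name!r}: invalid coordinates {start}-{end}")
        if sequence_length is not None and end > sequence_length:
            raise ValueError(f"window {name!r} extends past sequence end ({end} > {sequence_length})")
        idx = [i for i, p in enumerate(cpg_positions) if start <= p <= end]
        windows.append(NucleosomeWindow(name, start, end, idx))
    return windows


def annotate(
    sequence: str,
    window_coords: list[tuple[str, int, int]] | None = None,
    amplicon: tuple[int, int] | None = None,
    **island_kwargs,
) -> PromoterAnnotation:
    """Full annotation pass: CpG sites, islands, and optional windows."""
    seq = _check_sequence(sequence)
    cpgs = find_cpg_sites(seq)
    islands = find_cpg_islands(seq, **island_kwargs)
    windows = define_windows(window_coords or [], cpgs, len(seq))
    return PromoterAnnotation(seq, cpgs, islands, windows, amplicon)


# ---- file I/O ----------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: sequence} mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: dict[str, str], path: str | Path) -> None:
    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in records.items()]
    SeqIO.write(recs, str(path), "fasta")


def read_windows_bed(path: str | Path, cpg_positions: list[int]) -> list[NucleosomeWindow]:
    """Load nucleosome windows from BED (0-based half-open -> 1-based inclusive)."""
    bed = pd.read_csv(path, sep="\t", header=None, comment="#",
                      names=["chrom", "start", "end", "name"], usecols=range(4))
    coords = []
    for i, row in bed.iterrows():
        name = row["name"] if isinstance(row["name"], str) else f"win{i}"
        coords.append((name, int(row["start"]) + 1, int(row["end"])))
    return define_windows(coords, cpg_positions)


def write_windows_bed(windows: list[NucleosomeWindow], chrom: str, path: str | Path) -> None:
    with open(path, "w") as fh:
        for w in windows:
            fh.write(f"{chrom}\t{w.start - 1}\t{w.end}\t{w.name}\n")
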