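"""ChIP/input metaprofiles in fixed-width bins around transcription start sites.

Coordinates are 0-based half-open throughout (bedGraph/BED convention).
Positions not covered by any bedGraph interval have value 0.  Windows are
strand-oriented: bins run 5ʹ→3ʹ, so minus-strand windows are reversed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FormatError, InputError


class SignalTrack:
    """Piecewise-constant genomic signal (bedGraph semantics).

    Per chromosome, sorted non-overlapping half-open intervals with a value;
    range means are answered from a prefix integral of value × length.
    """

    def __init__(self, intervals: Mapping[str, Sequence[tuple[int, int, float]]]):
        self._chroms: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, ivals in intervals.items():
            ivals = sorted(ivals)
            starts = np.array([i[0] for i in ivals], dtype=np.int64)
            ends = np.array([i[1] for i in ivals], dtype=np.int64)
            values = np.array([i[2] for i in ivals], dtype=float)
            if np.any(starts >= ends):
                raise FormatError(f"{chrom}: interval with start >= end")
            if np.any(starts[1:] < ends[:-1]):
                raise FormatError(f"{chrom}: overlapping intervals")
            cum = np.concatenate([[0.0], np.cumsum(values * (ends - starts))])
            self._chroms[chrom] = (starts, ends, values, cum)

    @classmethod
    def from_bedgraph(cls, path: str | Path) -> "SignalTrack":
        table = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["chrom", "start", "end", "value"],
            comment="#",
            dtype={"chrom": str, "start": np.int64, "end": np.int64, "value": float},
        )
        grouped: dict[str, list[tuple[int, int, float]]] = {}
        for row in table.itertuples(index=False):
            grouped.setdefault(row.chrom, []).append((int(row.start), int(row.end), float(row.value)))
        return cls(grouped)

    def chromosomes(self) -> list[str]:
        return sorted(self._chroms)

    def _integral(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """∫ signal over [0, x) for each x (uncovered bases contribute 0)."""
        if chrom not in self._chroms:
            return np.zeros(len(positions))
        starts, ends, values, cum = self._chroms[chrom]
        x = np.asarray(positions, dtype=np.int64)
        full = np.searchsorted(ends, x, side="right")  # intervals fully left of x
        out = cum[full]
        # partial overlap of interval `full` when it starts before x
        has_next = full < len(starts)
        idx = np.flatnonzero(has_next)
        if idx.size:
            j = full[idx]
            partial = np.clip(x[idx] - starts[j], 0, ends[j] - starts[j])
            out[idx] = out[idx] + values[j] * partial
        return out

    def bin_means(self, chrom: str, start: int, end: int, n_bins: int) -> np.ndarray:
        """Mean signal in ``n_bins`` equal-width bins covering [start, end)."""
        if end <= start or (end - start) % n_bins != 0:
            raise InputError("window not divisible into the requested bins")
        edges = np.linspace(start, end, n_bins + 1).astype(np.int64)
        integrals = self._integral(chrom, edges)
        width = (end - start) // n_bins
        return np.diff(integrals) / width


@dataclass(frozen=True)
class TssAnnotation:
    gene_id: str
    chrom: str
    tss: int  # 0-based
    strand: str

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise InputError(f"{self.gene_id}: TSS must be >= 0")
        if self.strand not in ("+", "-"):
            raise InputError(f"{self.gene_id}: invalid strand {self.strand!r}")


def read_tss_bed(path: str | Path) -> list[TssAnnotation]:
    """Read BED6; TSS = start for '+' genes, end−1 for '−' genes."""
    table = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "name": str, "strand": str},
    )
    out = []
    for row in table.itertuples(index=False):
        tss = int(row.start) if row.strand == "+" else int(row.end) - 1
        out.append(TssAnnotation(gene_id=row.name, chrom=row.chrom, tss=tss, strand=row.strand))
    return out


@dataclass(frozen=True)
class MetaProfile:
    """Per-bin median ChIP/input ratio across genes, plus per-gene summaries."""

    bin_offsets: np.ndarray  # bin start offsets relative to TSS, 5'->3'
    bin_width: int
    median_ratio: np.ndarray
    gene_ratios: pd.DataFrame  # genes × bins
    gene_summary: pd.Series  # mean bin ratio within the window, per gene
    n_genes: int
    skipped_genes: tuple[str, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_start_offset": self.bin_offsets,
                "median_ratio": self.median_ratio,
                "n_genes": self.n_genes,
            }
        )


def ratio_metaprofile(
    chip: SignalTrack,
    input_track: SignalTrack,
    tss_set: Sequence[TssAnnotation],
    half_window: int = 4000,
    bin_width: int = 50,
    pseudocount: float = 1.0,
) -> MetaProfile:
    """Median ChIP/input ratio in fixed bins around TSSs, strand-oriented.

    Per gene and bin the ratio is (mean chip + pseudocount)/(mean input +
    pseudocount); the profile is the across-gene median per bin.  Genes whose
    window would extend below position 0 are skipped with a warning.
    """
    if half_window % bin_width != 0:
        raise InputError("half_window must be divisible by bin_width")
    if not tss_set:
        raise InputError("empty TSS set")
    n_bins = 2 * half_window // bin_width
    rows = {}
    skipped = []
    for gene in tss_set:
        lo = gene.tss - half_window
        hi = gene.tss + half_window
        if lo < 0:
            skipped.append(gene.gene_id)
            warnings.warn(
                f"gene {gene.gene_id}: window extends below position 0; skipped",
                stacklevel=2,
            )
            continue
        c = chip.bin_means(gene.chrom, lo, hi, n_bins)
        i = input_track.bin_means(gene.chrom, lo, hi, n_bins)
        ratio = (c + pseudocount) / (i + pseudocount)
        if gene.strand == "-":
            ratio = ratio[::-1]
        rows[gene.gene_id] = ratio
    if not rows:
        raise InputError("all genes skipped; no profile computed")
    gene_ratios = pd.DataFrame.from_dict(rows, orient="index")
    offsets = np.arange(-half_window, half_window, bin_width)
    gene_ratios.columns = offsets
    return MetaProfile(
        bin_offsets=offsets,
        bin_width=bin_width,
        median_ratio=gene_ratios.median(axis=0).to_numpy(),
        gene_ratios=gene_ratios,
        gene_summary=gene_ratios.mean(axis=1),
        n_genes=len(gene_ratios),
        skipped_genes=tuple(skipped),
    )


@dataclass(frozen=True)
class GenesetComparison:
    name: str
    fold: float  # median(A)/median(B)
    statistic: float
    p_value: float
    p_bh: float | None = None


def geneset_signal_compare(
    gene_summary: pd.Series,
    geneset_a: Iterable[str],
    geneset_b: Iterable[str],
    name: str = "A_vs_B",
) -> GenesetComparison:
    """Median-fold and two-sided Wilcoxon rank-sum between two gene sets'
    per-gene window summaries (mean bin ratio within the profiled window)."""
    a = [g for g in geneset_a if g in gene_summary.index]
    b = [g for g in geneset_b if g in gene_summary.index]
    if not a or not b:
        raise InputError("gene sets must be non-empty subsets of profiled genes")
    va = gene_summary.loc[a].to_numpy()
    vb = gene_summary.loc[b].to_numpy()
    if np.array_equal(np.sort(va), np.sort(vb)):
        stat, p = 0.0, 1.0
    else:
        stat, p = stats.ranksums(va, vb)
    med_b = float(np.median(vb))
    fold = float(np.median(va)) / med_b if med_b != 0 else float("inf")
    return GenesetComparison(name=name, fold=fold, statistic=float(stat), p_value=float(p))


def compare_genesets(
    gene_summary: pd.Series,
    comparisons: Mapping[str, tuple[Iterable[str], Iterable[str]]],
) -> list[GenesetComparison]:
    """Run a family of gene-set comparisons with BH correction across them."""
    results = [
        geneset_signal_compare(gene_summary, a, b, name=name)
        for name, (a, b) in comparisons.items()
    ]
    p_bh = stats.false_discovery_control([r.p_value for r in results], method="bh")
    return [
        GenesetComparison(
            name=r.name, fold=r.fold, statistic=r.statistic, p_value=r.p_value, p_bh=float(q)
        )
        for r, q in zip(results, p_bh)
    ]
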