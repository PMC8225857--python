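"""CDR3 self-reactivity motif scoring and group comparisons.

Two motif families are scored: amino-acid doublets at CDR3 positions 6 and 7
(position 1 = the conserved N-terminal cysteine), and cysteine near the CDR3
apex under an apex-out alignment (residues numbered outward from the loop
centre).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from scipy import stats

from .errors import InputError
from .repertoire_core import SampleClonotypeSet, TcrCatalogue

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class DoubletList:
    """A set of length-2 amino-acid motifs associated with self-reactivity."""

    doublets: frozenset[str]

    def __post_init__(self) -> None:
        for d in self.doublets:
            if len(d) != 2 or not set(d) <= AA_ALPHABET:
                raise InputError(f"invalid doublet {d!r}: need 2 standard amino acids")

    def __contains__(self, item: str) -> bool:
        return item in self.doublets

    def __len__(self) -> int:
        return len(self.doublets)

    @classmethod
    def from_file(cls, path: str | Path) -> "DoubletList":
        """Load a plain-text list, one doublet per line (blank lines skipped)."""
        lines = Path(path).read_text().split("\n")
        return cls(frozenset(s.strip().upper() for s in lines if s.strip()))


@dataclass(frozen=True)
class DoubletProportion:
    """Per-sample doublet proportion, or an exclusion flag for shallow samples."""

    value: float | None
    n_clonotypes: int
    n_with_doublet: int
    excluded: bool


@dataclass(frozen=True)
class MotifComparison:
    statistic: float
    p_value: float
    p_bonferroni: float
    test: str  # student_t_unpaired_two_sided | fisher_exact_two_sided
    n_comparisons: int
    table: tuple[tuple[int, int], tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        if self.n_comparisons < 1:
            raise InputError("n_comparisons must be >= 1")


def bonferroni(p: float, n_comparisons: int) -> float:
    return min(1.0, p * n_comparisons)


def doublet_at_6_7(cdr3_aa: str) -> str | None:
    """Return the residues at 1-based CDR3 positions 6 and 7, or None if too short."""
    if len(cdr3_aa) < 7:
        return None
    return cdr3_aa[5:7]


def doublet_proportion(
    sample: SampleClonotypeSet | Iterable[str],
    doublets: DoubletList,
    min_clones: int = 100,
) -> DoubletProportion:
    """Proportion of clonotypes whose position-6/7 doublet is in ``doublets``.

    Clonotypes too short to have positions 6/7 stay in the denominator.
    Samples with fewer than ``min_clones`` clonotypes are flagged excluded.
    """
    if len(doublets) == 0:
        raise InputError("doublet list is empty")
    cdr3s = sample.cdr3_sequences() if isinstance(sample, SampleClonotypeSet) else list(sample)
    n = len(cdr3s)
    hits = sum(1 for c in cdr3s if (d := doublet_at_6_7(c)) is not None and d in doublets)
    if n < min_clones:
        return DoubletProportion(value=None, n_clonotypes=n, n_with_doublet=hits, excluded=True)
    return DoubletProportion(value=hits / n, n_clonotypes=n, n_with_doublet=hits, excluded=False)


def apex_position(index: int, length: int) -> int:
    """Apex-out position of 0-based residue ``index`` in a CDR3 of ``length``.

    Odd length: the central residue is position 0.  Even length: the two
    central residues are positions 0 and +1.
    """
    return index - (length - 1) // 2


def has_central_cysteine(cdr3_aa: str, window: tuple[int, int] = (-2, 2)) -> bool:
    """True iff any residue with apex-out position inside ``window`` is 'C'."""
    if not cdr3_aa:
        raise InputError("cdr3_aa must be non-empty")
    lo, hi = window
    L = len(cdr3_aa)
    centre = (L - 1) // 2
    start = max(0, centre + lo)
    stop = min(L, centre + hi + 1)
    return "C" in cdr3_aa[start:stop]


def cysteine_counts(
    clonotypes: TcrCatalogue | SampleClonotypeSet | Iterable[str],
    window: tuple[int, int] = (-2, 2),
) -> tuple[int, int]:
    """(with central cysteine, without), each clonotype counted once."""
    if isinstance(clonotypes, (TcrCatalogue, SampleClonotypeSet)):
        cdr3s = clonotypes.cdr3_sequences()
    else:
        cdr3s = list(clonotypes)
    with_c = sum(1 for c in cdr3s if has_central_cysteine(c, window))
    return with_c, len(cdr3s) - with_c


def compare_cysteine_fisher(
    cat_a: TcrCatalogue,
    cat_b: TcrCatalogue,
    n_comparisons: int,
    window: tuple[int, int] = (-2, 2),
) -> MotifComparison:
    """Two-sided Fisher exact test on central-cysteine counts of two catalogues."""
    if len(cat_a) == 0 or len(cat_b) == 0:
        raise InputError("both catalogues must be non-empty")
    a_with, a_without = cysteine_counts(cat_a, window)
    b_with, b_without = cysteine_counts(cat_b, window)
    table = ((a_with, a_without), (b_with, b_without))
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return MotifComparison(
        statistic=float(odds),
        p_value=float(p),
        p_bonferroni=bonferroni(float(p), n_comparisons),
        test="fisher_exact_two_sided",
        n_comparisons=n_comparisons,
        table=table,
    )


def compare_doublet_ttest(
    props_a: Sequence[float],
    props_b: Sequence[float],
    n_comparisons: int,
) -> MotifComparison:
    """Unpaired two-sided Student's t (pooled variance) on per-sample proportions."""
    if len(props_a) < 2 or len(props_b) < 2:
        raise InputError("need at least 2 non-excluded samples per group")
    t, p = stats.ttest_ind(props_a, props_b, equal_var=True)
    # identical groups yield 0/0 -> nan; by convention no evidence of difference
    if t != t:
        t, p = 0.0, 1.0
    return MotifComparison(
        statistic=float(t),
        p_value=float(p),
        p_bonferroni=bonferroni(float(p), n_comparisons),
        test="student_t_unpaired_two_sided",
        n_comparisons=n_comparisons,
    )
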