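import itertools
import math
from pathlib import Path

import numpy as np
import pytest

from thymoselect.repertoire_core import ClonotypeRecord

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture
def data_dir() -> Path:
    return DATA_DIR


def make_record(
    cdr3="CAVSNLNTGKLIF",
    count=5,
    trav=("TRAV1",),
    traj="TRAJ33",
    sample="s1",
    mouse="m1",
    subset="wave1",
    genotype="control",
) -> ClonotypeRecord:
    return ClonotypeRecord(
        sample_id=sample,
        mouse_id=mouse,
        subset=subset,
        genotype=genotype,
        read_count=count,
        cdr3_aa=cdr3,
        trav_calls=tuple(trav) if not isinstance(trav, str) else (trav,),
        traj_call=traj,
    )


# ---------------------------------------------------------------------------
# independent oracles (never call package internals)
# ---------------------------------------------------------------------------

def enumeration_richness(abundances, m) -> float:
    """Exact mean number of distinct species over all C(n, m) subsets of the
    n individually-labelled clones."""
    labels = []
    for species, count in enumerate(abundances):
        labels.extend([species] * count)
    total = 0
    n_subsets = 0
    for subset in itertools.combinations(range(len(labels)), m):
        total += len({labels[i] for i in subset})
        n_subsets += 1
    return total / n_subsets


def fisher_two_sided_oracle(table) -> float:
    """Two-sided Fisher exact p by hypergeometric enumeration (exact ints)."""
    (a, b), (c, d) = table
    row1, row2, col1 = a + b, c + d, a + c
    n = row1 + row2

    def prob(x):
        return (
            math.comb(col1, x)
            * math.comb(n - col1, row1 - x)
            / math.comb(n, row1)
        )

    p_obs = prob(a)
    lo = max(0, col1 - row2)
    hi = min(col1, row1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))


def ttest_pooled_oracle(xs, ys):
    """Textbook unpaired two-sided Student's t with pooled variance."""
    from scipy.stats import t as t_dist

    xs, ys = np.asarray(xs, float), np.asarray(ys, float)
    nx, ny = len(xs), len(ys)
    sp2 = ((nx - 1) * xs.var(ddof=1) + (ny - 1) * ys.var(ddof=1)) / (nx + ny - 2)
    se = math.sqrt(sp2 * (1 / nx + 1 / ny))
    if se == 0:
        return 0.0, 1.0
    t = (xs.mean() - ys.mean()) / se
    p = 2 * t_dist.sf(abs(t), nx + ny - 2)
    return t, p


def bh_oracle(pvals):
    """Textbook Benjamini-Hochberg step-up adjustment."""
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj


def detectable_expectation_oracle(binary_matrix, n_draw):
    """Sum over genes of 1 - C(N-k_g, n)/C(N, n), exact rationals via comb."""
    N = binary_matrix.shape[0]
    k = binary_matrix.sum(axis=0)
    total = 0.0
    denom = math.comb(N, n_draw)
    for kg in k:
        miss = math.comb(N - int(kg), n_draw) / denom if N - kg >= n_draw else 0.0
        total += 1.0 - miss
    return total
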