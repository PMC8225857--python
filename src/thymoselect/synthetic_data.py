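"""Seeded generators for every input family, with planted parameters.

Every generator is a pure function of its config and seed: rerunning with
the same seed produces byte-identical files.  Truth records carry the
planted parameters so downstream estimates can be checked without
re-deriving constants.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError
from .repertoire_core import ClonotypeRecord
from .tra_breadth import GENE_CATEGORIES, CellCountMatrix
from .tss_profile import SignalTrack, TssAnnotation

AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: a small default doublet list used when none is supplied (planting only;
#: real analyses must supply their own list)
DEFAULT_DOUBLETS = (
    "GG", "GS", "SG", "AG", "GA", "WG", "GW", "RG", "GR", "LG",
    "GN", "NG", "QG", "GQ", "YG", "GY", "PG", "GP", "VG", "GV",
)


def _stream(seed: int, role: str) -> np.random.Generator:
    """One RNG stream per output role, derived by stable hashing."""
    return np.random.default_rng([seed, zlib.crc32(role.encode())])


def _law_probs(rng: np.random.Generator, k: int, law: Mapping[str, float]) -> np.ndarray:
    kind = law.get("kind", "lognormal")
    if kind == "lognormal":
        w = rng.lognormal(mean=0.0, sigma=float(law.get("sigma", 1.0)), size=k)
    elif kind == "power":
        ranks = np.arange(1, k + 1, dtype=float)
        w = ranks ** -float(law.get("alpha", 1.0))
        rng.shuffle(w)
    else:
        raise ConfigurationError(f"unknown abundance law {kind!r}")
    return w / w.sum()


# ---------------------------------------------------------------------------
# TCR repertoire simulation
# ---------------------------------------------------------------------------

@dataclass
class RepertoireSimConfig:
    n_clonotypes_true: int = 500
    abundance_law: dict = field(default_factory=lambda: {"kind": "lognormal", "sigma": 1.0})
    subsets: tuple[str, ...] = ("wave1", "CD4SP")
    genotypes: tuple[str, ...] = ("control", "mutant")
    n_mice: int = 3
    clones_per_mouse: int = 2000
    trav_pool: dict = field(
        default_factory=lambda: {
            **{f"TRAV{i}": "proximal" for i in (1, 2, 3, 4)},
            **{f"TRAV{i}": "distal" for i in (11, 12, 13, 14)},
        }
    )
    traj_pool: dict = field(
        default_factory=lambda: {
            "TRAJ56": "proximal", "TRAJ57": "proximal", "TRAJ58": "proximal",
            "TRAJ30": "medium", "TRAJ31": "medium", "TRAJ32": "medium",
            "TRAJ2": "distal", "TRAJ3": "distal", "TRAJ4": "distal",
        }
    )
    cdr3_length_min: int = 11
    cdr3_length_max: int = 17
    pi_doublet: float = 0.0
    pi_cys: float = 0.0
    doublet_list: tuple[str, ...] = DEFAULT_DOUBLETS
    sharing_fraction: float = 0.5
    singleton_error_rate: float = 0.0
    frac_nonfunctional: float = 0.0
    frac_ambiguous_v: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pi_doublet", "pi_cys", "sharing_fraction", "singleton_error_rate",
                     "frac_nonfunctional", "frac_ambiguous_v"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.clones_per_mouse < 1:
            raise ConfigurationError("clones_per_mouse must be >= 1")
        if self.cdr3_length_min < 7 or self.cdr3_length_max < self.cdr3_length_min:
            raise ConfigurationError("need 7 <= cdr3_length_min <= cdr3_length_max")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RepertoireSimConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


def _random_cdr3(
    rng: np.random.Generator,
    length: int,
    want_doublet: bool,
    want_cys: bool,
    doublets: Sequence[str],
    max_tries: int = 200,
) -> str:
    """Rejection-sample a CDR3 with the requested motif flags.

    Position 1 is the conserved 'C'; the last residue is 'F'.  The doublet
    flag controls membership of positions 6/7 in the supplied list; the
    cysteine flag controls 'C' within apex-out positions [-2, +2].
    """
    from .motif_selection import doublet_at_6_7, has_central_cysteine

    dl = set(doublets)
    for _ in range(max_tries):
        mid = rng.choice(list(AA20), size=length - 2)
        seq = "C" + "".join(mid) + "F"
        if want_doublet:
            seq = seq[:5] + doublets[rng.integers(len(doublets))] + seq[7:]
        elif doublet_at_6_7(seq) in dl:
            continue
        if has_central_cysteine(seq) != want_cys:
            continue
        return seq
    raise ConfigurationError(
        "could not satisfy motif flags; doublet list and cysteine target conflict"
    )


def _make_clonotype_pool(
    rng: np.random.Generator, size: int, cfg: RepertoireSimConfig, existing: set[str]
) -> list[tuple[str, str, str]]:
    travs = sorted(cfg.trav_pool)
    trajs = sorted(cfg.traj_pool)
    pool = []
    while len(pool) < size:
        want_d = rng.random() < cfg.pi_doublet
        want_c = rng.random() < cfg.pi_cys
        length = int(rng.integers(cfg.cdr3_length_min, cfg.cdr3_length_max + 1))
        cdr3 = _random_cdr3(rng, length, want_d, want_c, cfg.doublet_list)
        if cdr3 in existing:
            continue
        existing.add(cdr3)
        trav = travs[rng.integers(len(travs))]
        traj = trajs[rng.integers(len(trajs))]
        pool.append((trav, cdr3, traj))
    return pool


def simulate_repertoire(
    config: RepertoireSimConfig, out_dir: str | Path | None = None
) -> tuple[list[ClonotypeRecord], pd.DataFrame, dict]:
    """Generate per-sample clonotype records, sample metadata and truth.

    Each subset×genotype community holds ``n_clonotypes_true`` clonotypes:
    a shared core (fraction ``sharing_fraction``, common to all communities)
    plus community-private clonotypes.  Each mouse contributes one sample of
    ``clones_per_mouse`` clones drawn multinomially; the per-sample read
    count of a clonotype is its drawn clone count.
    """
    rng = _stream(config.seed, "repertoire")
    n_shared = int(round(config.sharing_fraction * config.n_clonotypes_true))
    seen_cdr3: set[str] = set()
    shared = _make_clonotype_pool(rng, n_shared, config, seen_cdr3)
    shared_w = _law_probs(rng, n_shared, config.abundance_law) if n_shared else np.array([])

    communities: dict[tuple[str, str], tuple[list, np.ndarray]] = {}
    for subset in config.subsets:
        for genotype in config.genotypes:
            n_priv = config.n_clonotypes_true - n_shared
            private = _make_clonotype_pool(rng, n_priv, config, seen_cdr3)
            priv_w = _law_probs(rng, n_priv, config.abundance_law) if n_priv else np.array([])
            clonos = shared + private
            w = np.concatenate([shared_w, priv_w])
            communities[(subset, genotype)] = (clonos, w / w.sum())

    records: list[ClonotypeRecord] = []
    meta_rows = []
    mouse_counter = 0
    for (subset, genotype), (clonos, probs) in communities.items():
        for _ in range(config.n_mice):
            mouse_counter += 1
            mouse_id = f"m{mouse_counter:03d}"
            sample_id = f"s_{subset}_{genotype}_{mouse_id}"
            counts = rng.multinomial(config.clones_per_mouse, probs)
            for idx in np.flatnonzero(counts):
                trav, cdr3, traj = clonos[idx]
                trav_calls = (trav,)
                if rng.random() < config.frac_ambiguous_v:
                    alt = sorted(config.trav_pool)[rng.integers(len(config.trav_pool))]
                    trav_calls = (trav, alt)
                if rng.random() < config.frac_nonfunctional:
                    pos = int(rng.integers(1, len(cdr3)))
                    cdr3 = cdr3[:pos] + "*" + cdr3[pos + 1:]
                records.append(
                    ClonotypeRecord(
                        sample_id=sample_id,
                        mouse_id=mouse_id,
                        subset=subset,
                        genotype=genotype,
                        read_count=int(counts[idx]),
                        cdr3_aa=cdr3,
                        trav_calls=trav_calls,
                        traj_call=traj,
                    )
                )
            # sequencing-error singletons: point-mutated copies at 1-2 reads
            n_err = rng.binomial(int(counts.sum()), config.singleton_error_rate)
            detected = np.flatnonzero(counts)
            for _ in range(n_err):
                trav, cdr3, traj = clonos[detected[rng.integers(len(detected))]]
                pos = int(rng.integers(1, len(cdr3) - 1))
                mutated = cdr3[:pos] + AA20[rng.integers(20)] + cdr3[pos + 1:]
                records.append(
                    ClonotypeRecord(
                        sample_id=sample_id,
                        mouse_id=mouse_id,
                        subset=subset,
                        genotype=genotype,
                        read_count=int(rng.integers(1, 3)),
                        cdr3_aa=mutated,
                        trav_calls=(trav,),
                        traj_call=traj,
                    )
                )
            meta_rows.append(
                {
                    "sample_id": sample_id,
                    "mouse_id": mouse_id,
                    "subset": subset,
                    "genotype": genotype,
                    "file": f"{sample_id}.tsv",
                }
            )
    metadata = pd.DataFrame(meta_rows)
    truth = {
        "seed": config.seed,
        "n_clonotypes_true": config.n_clonotypes_true,
        "n_shared": n_shared,
        "sharing_fraction": config.sharing_fraction,
        "pi_doublet": config.pi_doublet,
        "pi_cys": config.pi_cys,
        "communities": {
            f"{s}|{g}": {"richness_true": len(c[0])} for (s, g), c in communities.items()
        },
    }
    if out_dir is not None:
        _write_repertoire(records, metadata, truth, Path(out_dir))
    return records, metadata, truth


def _write_repertoire(
    records: Sequence[ClonotypeRecord], metadata: pd.DataFrame, truth: dict, out_dir: Path
) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    by_sample: dict[str, list[ClonotypeRecord]] = {}
    for r in records:
        by_sample.setdefault(r.sample_id, []).append(r)
    for sample_id, recs in by_sample.items():
        rows = [
            {
                "Count": r.read_count,
                "CDR3.amino.acid.sequence": r.cdr3_aa,
                "V.segments": ",".join(r.trav_calls),
                "J.segments": r.traj_call,
            }
            for r in recs
        ]
        pd.DataFrame(rows).to_csv(out_dir / f"{sample_id}.tsv", sep="\t", index=False)
    metadata.to_csv(out_dir / "metadata.tsv", sep="\t", index=False)
    (out_dir / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# single-cell count matrix simulation
# ---------------------------------------------------------------------------

@dataclass
class ScSimConfig:
    populations: dict = field(default_factory=lambda: {"control": 300})
    genes_per_category: dict = field(
        default_factory=lambda: {
            "aire_dependent": 100,
            "aire_enhanced": 100,
            "aire_independent_tra": 100,
            "other": 200,
        }
    )
    prevalence: dict = field(
        default_factory=lambda: {
            "aire_dependent": 0.02,
            "aire_enhanced": 0.05,
            "aire_independent_tra": 0.10,
            "other": 0.30,
        }
    )
    #: per-population multiplicative prevalence scaling (plants fold changes)
    population_scale: dict = field(default_factory=dict)
    mean_count: float = 3.0
    library_sigma: float = 0.3
    aire_prevalence: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for cat, n in self.genes_per_category.items():
            if cat not in GENE_CATEGORIES:
                raise ConfigurationError(f"unknown gene category {cat!r}")
            if n < 1:
                raise ConfigurationError(f"category {cat!r} has zero genes")
        for cat, p in self.prevalence.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"prevalence for {cat!r} must be in [0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScSimConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


def simulate_cell_matrix(
    config: ScSimConfig, out_dir: str | Path | None = None
) -> tuple[CellCountMatrix, dict]:
    """Bernoulli-prevalence expression with positive counts.

    Each cell expresses gene g independently with the planted per-category
    prevalence (scaled per population); expressed entries draw a positive
    count 1 + Poisson(mean_count × library factor).  An 'Aire' gene (category
    'other') with its own prevalence supports AIRE-positive cell selection.
    """
    rng = _stream(config.seed, "cells")
    gene_ids, categories, prevalences = ["Aire"], ["other"], [config.aire_prevalence]
    for cat in GENE_CATEGORIES:
        n = config.genes_per_category.get(cat, 0)
        for i in range(n):
            gene_ids.append(f"{cat}_g{i:04d}")
            categories.append(cat)
            prevalences.append(config.prevalence.get(cat, 0.1))
    prev = np.array(prevalences)

    cell_ids, pops = [], []
    for pop, n_cells in config.populations.items():
        for i in range(n_cells):
            cell_ids.append(f"{pop}_c{i:05d}")
            pops.append(pop)
    n_cells_total, n_genes = len(cell_ids), len(gene_ids)

    lib = rng.lognormal(mean=0.0, sigma=config.library_sigma, size=n_cells_total)
    dense = np.zeros((n_cells_total, n_genes), dtype=np.int64)
    row = 0
    for pop, n_cells in config.populations.items():
        scale = config.population_scale.get(pop, 1.0)
        p = np.clip(prev * scale, 0.0, 1.0)
        expressed = rng.random((n_cells, n_genes)) < p[None, :]
        lam = config.mean_count * lib[row:row + n_cells, None]
        counts = 1 + rng.poisson(np.broadcast_to(lam, (n_cells, n_genes)))
        dense[row:row + n_cells] = np.where(expressed, counts, 0)
        row += n_cells

    from scipy import sparse

    cell_meta = pd.DataFrame(
        {"population": pops, "aire_count": dense[:, 0]}, index=pd.Index(cell_ids, name="cell")
    )
    gene_meta = pd.DataFrame({"category": categories}, index=pd.Index(gene_ids, name="gene"))
    matrix = CellCountMatrix(
        counts=sparse.csr_matrix(dense), cell_meta=cell_meta, gene_meta=gene_meta
    )
    truth = {
        "seed": config.seed,
        "prevalence": dict(config.prevalence),
        "population_scale": {p: config.population_scale.get(p, 1.0) for p in config.populations},
        "aire_prevalence": config.aire_prevalence,
        "n_cells": dict(config.populations),
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        matrix.to_files(out_dir / "counts.mtx", out_dir / "genes.tsv", out_dir / "cells.tsv")
        (out_dir / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
    return matrix, truth


# ---------------------------------------------------------------------------
# ChIP/input track simulation
# ---------------------------------------------------------------------------

@dataclass
class ChipSimConfig:
    n_genes: int = 40
    n_enriched: int = 20
    fold: float = 3.0
    background: float = 1.0
    enrich_halfwidth: int = 4000
    half_window: int = 4000
    bin_width: int = 50
    margin: int = 500
    noise_sigma: float = 0.0  # lognormal sigma per bin, independent per track
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fold <= 0:
            raise ConfigurationError("fold must be > 0")
        if self.n_enriched > self.n_genes:
            raise ConfigurationError("n_enriched exceeds n_genes")
        if self.margin < 0:
            raise ConfigurationError("margin must be >= 0")

    @property
    def chrom_length(self) -> int:
        return 2 * (self.half_window + self.enrich_halfwidth) + 2 * self.margin

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ChipSimConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


def simulate_chip_tracks(
    config: ChipSimConfig, out_dir: str | Path | None = None
) -> tuple[SignalTrack, SignalTrack, list[TssAnnotation], dict]:
    """One gene per chromosome; chip = input × fold around enriched TSSs.

    With ``noise_sigma`` = 0 the tracks are exactly piecewise constant, so
    metaprofile bin medians equal the planted fold.  Noise draws are
    independent per bin and per track.
    """
    rng = _stream(config.seed, "chip")
    L = config.chrom_length
    tss = L // 2
    if tss - config.half_window < 0 or tss + config.half_window > L:
        raise ConfigurationError("profile window exceeds chromosome bounds")
    n_bins = L // config.bin_width
    chip_ivals: dict[str, list[tuple[int, int, float]]] = {}
    input_ivals: dict[str, list[tuple[int, int, float]]] = {}
    tss_list: list[TssAnnotation] = []
    truth_genes = {}
    for g in range(config.n_genes):
        chrom = f"chr_g{g:03d}"
        gene_id = f"gene{g:03d}"
        enriched = g < config.n_enriched
        strand = "+" if g % 2 == 0 else "-"
        base_in = config.background * _noise(rng, n_bins, config.noise_sigma)
        base_chip = config.background * _noise(rng, n_bins, config.noise_sigma)
        chip_rows, in_rows = [], []
        for b in range(n_bins):
            start = b * config.bin_width
            end = start + config.bin_width
            centre = (start + end) // 2
            fold = config.fold if enriched and abs(centre - tss) <= config.enrich_halfwidth else 1.0
            in_rows.append((start, end, float(base_in[b])))
            chip_rows.append((start, end, float(base_chip[b] * fold)))
        chip_ivals[chrom] = chip_rows
        input_ivals[chrom] = in_rows
        tss_list.append(TssAnnotation(gene_id=gene_id, chrom=chrom, tss=tss, strand=strand))
        truth_genes[gene_id] = {"enriched": enriched, "expected_fold": config.fold if enriched else 1.0}
    truth = {
        "seed": config.seed,
        "fold": config.fold,
        "n_enriched": config.n_enriched,
        "genes": truth_genes,
    }
    chip = SignalTrack(chip_ivals)
    input_track = SignalTrack(input_ivals)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        _write_bedgraph(chip_ivals, out_dir / "chip.bedgraph")
        _write_bedgraph(input_ivals, out_dir / "input.bedgraph")
        with open(out_dir / "tss.bed", "w") as fh:
            for t in tss_list:
                start = t.tss if t.strand == "+" else t.tss - 999
                end = t.tss + 1000 if t.strand == "+" else t.tss + 1
                fh.write(f"{t.chrom}\t{start}\t{end}\t{t.gene_id}\t0\t{t.strand}\n")
        (out_dir / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
    return chip, input_track, tss_list, truth


def _noise(rng: np.random.Generator, size: int, sigma: float) -> np.ndarray:
    if sigma == 0.0:
        return np.ones(size)
    return rng.lognormal(mean=0.0, sigma=sigma, size=size)


def _write_bedgraph(ivals: Mapping[str, list[tuple[int, int, float]]], path: Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(ivals):
            for start, end, value in ivals[chrom]:
                fh.write(f"{chrom}\t{start}\t{end}\t{value:.6g}\n")


def config_to_dict(cfg) -> dict:
    """Serializable view of any simulation config (for provenance sidecars)."""
    return dataclasses.asdict(cfg)
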