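"""Morisita-Horn overlap, segment usage and proximal/distal feature vectors."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError
from .repertoire_core import ClonotypeRecord, SampleClonotypeSet, TcrCatalogue

TRAV_ZONES = ("proximal", "distal")
TRAJ_ZONES = ("proximal", "medium", "distal")


def morisita_horn(x: Mapping[object, float], y: Mapping[object, float]) -> float:
    """Morisita-Horn overlap of two abundance mappings, in [0, 1].

    MH = 2 Σ x_i y_i / [(Σx_i²/X² + Σy_i²/Y²) · X · Y] over the union of
    keys, with X = Σx_i and Y = Σy_i; absent keys count as 0.
    """
    if not x or not y:
        raise InputError("abundance mappings must be non-empty")
    if any(v <= 0 for v in x.values()) or any(v <= 0 for v in y.values()):
        raise InputError("abundances must be positive")
    X = float(sum(x.values()))
    Y = float(sum(y.values()))
    cross = sum(v * y[k] for k, v in x.items() if k in y)
    sum_x2 = sum(v * v for v in x.values())
    sum_y2 = sum(v * v for v in y.values())
    denom = (sum_x2 / (X * X) + sum_y2 / (Y * Y)) * X * Y
    return float(2.0 * cross / denom)


def overlap_matrix(
    catalogues: Sequence[TcrCatalogue | Mapping[object, float]],
) -> np.ndarray:
    """Symmetric matrix of pairwise Morisita-Horn indices, diagonal = 1."""
    if len(catalogues) < 2:
        raise InputError("need at least 2 catalogues")
    maps = [c.abundance if isinstance(c, TcrCatalogue) else c for c in catalogues]
    k = len(maps)
    out = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            out[i, j] = out[j, i] = morisita_horn(maps[i], maps[j])
    return out


def segment_usage(
    clonotypes: SampleClonotypeSet | TcrCatalogue,
    records: Sequence[ClonotypeRecord] | None = None,
) -> dict[str, pd.Series]:
    """Relative Trav usage, CDR3-length distribution and (optionally) Traj usage.

    Each clonotype carries weight 1.  Traj is not part of the clonotype key,
    so Traj usage is computed from ``records`` when supplied (one unit per
    unique (trav, cdr3, traj) combination).
    """
    if isinstance(clonotypes, TcrCatalogue):
        keys = sorted(clonotypes.abundance)
    else:
        keys = sorted(clonotypes.clonotypes)
    if not keys:
        raise InputError("no clonotypes to tabulate")
    trav = pd.Series([k[0] for k in keys]).value_counts(normalize=True).sort_index()
    lengths = pd.Series([len(k[1]) for k in keys]).value_counts(normalize=True).sort_index()
    out = {"trav_usage": trav, "cdr3_length": lengths}
    if records is not None:
        combos = {(r.trav_primary, r.cdr3_aa, r.traj_call) for r in records}
        traj = pd.Series([c[2] for c in combos]).value_counts(normalize=True).sort_index()
        out["traj_usage"] = traj
    return out


@dataclass(frozen=True)
class ZoneMap:
    """Locus-position zone labels for Trav and Traj segments."""

    trav_zone: Mapping[str, str]
    traj_zone: Mapping[str, str]

    def __post_init__(self) -> None:
        for seg, z in self.trav_zone.items():
            if z not in TRAV_ZONES:
                raise ConfigurationError(f"Trav zone for {seg!r} must be in {TRAV_ZONES}, got {z!r}")
        for seg, z in self.traj_zone.items():
            if z not in TRAJ_ZONES:
                raise ConfigurationError(f"Traj zone for {seg!r} must be in {TRAJ_ZONES}, got {z!r}")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ZoneMap":
        """Two-column TSV: segment name, zone.  Trav vs Traj is inferred from
        the zone vocabulary ('medium' only exists for Traj) and segment name."""
        table = pd.read_csv(path, sep="\t", header=None, names=["segment", "zone"], dtype=str)
        trav, traj = {}, {}
        for seg, zone in zip(table["segment"], table["zone"]):
            target = traj if seg.upper().startswith("TRAJ") else trav
            target[seg] = zone
        return cls(trav_zone=trav, traj_zone=traj)


@dataclass(frozen=True)
class FeatureVector8:
    """Proximal/distal usage features over transcripts (records).

    The Traj triples are None when their Trav stratum is empty.
    """

    trav_prox_freq: float
    trav_dist_freq: float
    traj_within_trav_prox: tuple[float, float, float] | None  # (prox, med, dist)
    traj_within_trav_dist: tuple[float, float, float] | None

    def to_series(self) -> pd.Series:
        def unpack(t, stem):
            vals = t if t is not None else (np.nan, np.nan, np.nan)
            return {f"traj_{z}_within_{stem}": v for z, v in zip(("prox", "med", "dist"), vals)}

        data = {
            "trav_prox_freq": self.trav_prox_freq,
            "trav_dist_freq": self.trav_dist_freq,
        }
        data.update(unpack(self.traj_within_trav_prox, "trav_prox"))
        data.update(unpack(self.traj_within_trav_dist, "trav_dist"))
        return pd.Series(data)


def proximal_distal_features(
    records: Sequence[ClonotypeRecord],
    zones: ZoneMap,
    strict: bool = True,
) -> FeatureVector8:
    """The 8 proximal/distal usage frequencies, computed over transcripts.

    In strict mode a segment without a zone label raises; otherwise its
    transcripts are dropped from the tallies.
    """
    if not records:
        raise InputError("no records supplied")
    trav_tally = {z: 0 for z in TRAV_ZONES}
    traj_tally = {tz: {jz: 0 for jz in TRAJ_ZONES} for tz in TRAV_ZONES}
    for r in records:
        tz = zones.trav_zone.get(r.trav_primary)
        jz = zones.traj_zone.get(r.traj_call)
        if tz is None or jz is None:
            missing = r.trav_primary if tz is None else r.traj_call
            if strict:
                raise ConfigurationError(f"segment {missing!r} has no zone assignment")
            continue
        trav_tally[tz] += 1
        traj_tally[tz][jz] += 1
    total = sum(trav_tally.values())
    if total == 0:
        raise InputError("no records with zoned segments")

    def triple(tz: str) -> tuple[float, float, float] | None:
        stratum = sum(traj_tally[tz].values())
        if stratum == 0:
            return None
        return tuple(traj_tally[tz][jz] / stratum for jz in TRAJ_ZONES)

    return FeatureVector8(
        trav_prox_freq=trav_tally["proximal"] / total,
        trav_dist_freq=trav_tally["distal"] / total,
        traj_within_trav_prox=triple("proximal"),
        traj_within_trav_dist=triple("distal"),
    )
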