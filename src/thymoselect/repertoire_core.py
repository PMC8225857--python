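"""Clonotype table ingest, filtering, collapsing and catalogue assembly.

A *clonotype* is a unique combination of primary Trav segment and CDR3
amino-acid sequence.  Within a sample each clonotype is counted once; a
*TCR catalogue* pools the per-mouse clonotype sets of one subset×genotype
combination, with abundance equal to the number of mice in which the
clonotype was detected.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ConfigurationError, FormatError, InputError

SUBSETS = ("pre_selection", "wave1", "CD4SP", "CD8SP", "other")
GENOTYPES = ("control", "mutant", "other")

#: default column mapping for MIGEC-style clonotype tables
DEFAULT_COLUMNS = {
    "count": "Count",
    "cdr3": "CDR3.amino.acid.sequence",
    "v": "V.segments",
    "j": "J.segments",
}

#: characters marking non-functional CDR3s (stop codon / frameshift)
DEFAULT_SENTINELS = frozenset("*_")


@dataclass(frozen=True)
class ClonotypeRecord:
    """One sequenced TCRα chain observation within a sample."""

    sample_id: str
    mouse_id: str
    subset: str
    genotype: str
    read_count: int
    cdr3_aa: str
    trav_calls: tuple[str, ...]
    traj_call: str

    def __post_init__(self) -> None:
        if self.read_count < 0:
            raise InputError(f"read_count must be >= 0, got {self.read_count}")
        if not self.trav_calls:
            raise InputError("trav_calls must be non-empty")
        if not self.cdr3_aa:
            raise InputError("cdr3_aa must be non-empty")

    @property
    def trav_primary(self) -> str:
        return self.trav_calls[0]

    @property
    def is_ambiguous(self) -> bool:
        """True when the read aligned to more than one Trav paralog."""
        return len(self.trav_calls) > 1

    def is_functional(self, sentinels: frozenset[str] = DEFAULT_SENTINELS) -> bool:
        return not any(ch in sentinels for ch in self.cdr3_aa)


@dataclass(frozen=True)
class SampleClonotypeSet:
    """Clonotypes of one sample, each carried at most once."""

    sample_id: str
    mouse_id: str
    subset: str
    genotype: str
    clonotypes: frozenset[tuple[str, str]]

    def __len__(self) -> int:
        return len(self.clonotypes)

    def cdr3_sequences(self) -> list[str]:
        return [cdr3 for _, cdr3 in sorted(self.clonotypes)]


@dataclass(frozen=True)
class TcrCatalogue:
    """Pooled clonotypes for one subset×genotype; abundance = mice detected in."""

    subset: str
    genotype: str
    n_mice: int
    abundance: Mapping[tuple[str, str], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_mice < 1:
            raise InputError("n_mice must be >= 1")
        for key, a in self.abundance.items():
            if not 1 <= a <= self.n_mice:
                raise InputError(
                    f"abundance of {key} is {a}, outside [1, n_mice={self.n_mice}]"
                )

    def __len__(self) -> int:
        return len(self.abundance)

    def abundances(self) -> list[int]:
        return list(self.abundance.values())

    def cdr3_sequences(self) -> list[str]:
        return [cdr3 for _, cdr3 in sorted(self.abundance)]


def parse_clonotype_tables(
    paths: Sequence[str | Path],
    metadata: pd.DataFrame | str | Path,
    columns: Mapping[str, str] | None = None,
    v_delimiter: str = ",",
) -> list[ClonotypeRecord]:
    """Read MIGEC-style TSV clonotype tables into records.

    ``metadata`` maps each file to sample_id/mouse_id/subset/genotype via a
    ``file`` column (matched on basename).  Multi-valued V calls are split on
    ``v_delimiter`` preserving order (first = primary call).  CDR3 sequences
    are upper-cased on ingest.
    """
    cols = dict(DEFAULT_COLUMNS)
    if columns:
        cols.update(columns)

    if not isinstance(metadata, pd.DataFrame):
        metadata = pd.read_csv(metadata, sep="\t", dtype=str)
    required_meta = {"sample_id", "mouse_id", "subset", "genotype", "file"}
    missing = required_meta - set(metadata.columns)
    if missing:
        raise ConfigurationError(f"metadata missing columns: {sorted(missing)}")
    meta_by_file = {Path(f).name: row for f, row in zip(metadata["file"], metadata.to_dict("records"))}

    records: list[ClonotypeRecord] = []
    for path in paths:
        path = Path(path)
        meta = meta_by_file.get(path.name)
        if meta is None:
            raise ConfigurationError(f"no metadata entry for file {path.name!r}")
        table = pd.read_csv(path, sep="\t", dtype=str)
        for role in ("count", "cdr3", "v", "j"):
            if cols[role] not in table.columns:
                raise FormatError(
                    f"{path.name}: missing required column {cols[role]!r} (role: {role})"
                )
        for i, row in enumerate(table.to_dict("records"), start=2):
            raw_count = row[cols["count"]]
            try:
                count = int(raw_count)
            except (TypeError, ValueError):
                raise FormatError(
                    f"{path.name} line {i}: unparseable count {raw_count!r}"
                ) from None
            trav_calls = tuple(
                s.strip() for s in str(row[cols["v"]]).split(v_delimiter) if s.strip()
            )
            records.append(
                ClonotypeRecord(
                    sample_id=str(meta["sample_id"]),
                    mouse_id=str(meta["mouse_id"]),
                    subset=str(meta["subset"]),
                    genotype=str(meta["genotype"]),
                    read_count=count,
                    cdr3_aa=str(row[cols["cdr3"]]).upper(),
                    trav_calls=trav_calls,
                    traj_call=str(row[cols["j"]]),
                )
            )
    return records


def filter_records(
    records: Iterable[ClonotypeRecord],
    min_reads: int = 3,
    sentinels: frozenset[str] = DEFAULT_SENTINELS,
) -> list[ClonotypeRecord]:
    """Keep functional records detected at least ``min_reads`` times.

    Functional means the CDR3 carries none of the sentinel characters
    (default ``*`` for stop, ``_`` for frameshift).  Order is preserved.
    """
    if min_reads < 1:
        raise InputError(f"min_reads must be >= 1, got {min_reads}")
    return [
        r for r in records if r.is_functional(sentinels) and r.read_count >= min_reads
    ]


def collapse_to_clonotypes(
    records: Sequence[ClonotypeRecord],
    paralog_policy: str = "first_listed",
) -> SampleClonotypeSet:
    """Collapse one sample's records to its clonotype set.

    ``first_listed`` keys ambiguous reads by the first Trav paralog;
    ``exclude_ambiguous`` drops reads with more than one Trav call.
    Duplicate (trav, cdr3) pairs collapse to one entry regardless of reads.
    """
    if paralog_policy not in ("first_listed", "exclude_ambiguous"):
        raise InputError(f"unknown paralog_policy {paralog_policy!r}")
    if not records:
        raise InputError("cannot collapse an empty record list")
    sample_ids = {r.sample_id for r in records}
    if len(sample_ids) != 1:
        raise InputError(f"records span multiple samples: {sorted(sample_ids)}")
    first = records[0]
    pairs = set()
    for r in records:
        if paralog_policy == "exclude_ambiguous" and r.is_ambiguous:
            continue
        pairs.add((r.trav_primary, r.cdr3_aa))
    return SampleClonotypeSet(
        sample_id=first.sample_id,
        mouse_id=first.mouse_id,
        subset=first.subset,
        genotype=first.genotype,
        clonotypes=frozenset(pairs),
    )


def build_catalogue(samples: Sequence[SampleClonotypeSet]) -> TcrCatalogue:
    """Pool per-sample clonotype sets into a TCR catalogue.

    Samples from the same mouse are merged (set union) before counting, so
    each clonotype's abundance is the number of distinct mice it appears in.
    """
    if not samples:
        raise InputError("need at least one sample")
    keys = {(s.subset, s.genotype) for s in samples}
    if len(keys) != 1:
        raise InputError(f"samples span multiple subset×genotype combinations: {sorted(keys)}")
    subset, genotype = next(iter(keys))

    per_mouse: dict[str, set[tuple[str, str]]] = {}
    for s in samples:
        per_mouse.setdefault(s.mouse_id, set()).update(s.clonotypes)

    abundance: dict[tuple[str, str], int] = {}
    for clonoset in per_mouse.values():
        for key in clonoset:
            abundance[key] = abundance.get(key, 0) + 1
    return TcrCatalogue(
        subset=subset, genotype=genotype, n_mice=len(per_mouse), abundance=abundance
    )


def write_catalogue(catalogue: TcrCatalogue, out_prefix: str | Path) -> tuple[Path, Path]:
    """Write a catalogue as TSV plus a JSON sidecar with n_mice/provenance."""
    out_prefix = Path(out_prefix)
    tsv_path = out_prefix.with_suffix(".tsv")
    json_path = out_prefix.with_suffix(".json")
    rows = [
        {"trav": trav, "cdr3_aa": cdr3, "abundance": a}
        for (trav, cdr3), a in sorted(catalogue.abundance.items())
    ]
    pd.DataFrame(rows, columns=["trav", "cdr3_aa", "abundance"]).to_csv(
        tsv_path, sep="\t", index=False
    )
    json_path.write_text(
        json.dumps(
            {
                "subset": catalogue.subset,
                "genotype": catalogue.genotype,
                "n_mice": catalogue.n_mice,
                "n_clonotypes": len(catalogue),
            },
            indent=2,
        )
        + "\n"
    )
    return tsv_path, json_path


def read_catalogue(tsv_path: str | Path, json_path: str | Path | None = None) -> TcrCatalogue:
    """Read a catalogue written by :func:`write_catalogue`."""
    tsv_path = Path(tsv_path)
    if json_path is None:
        json_path = tsv_path.with_suffix(".json")
    meta = json.loads(Path(json_path).read_text())
    table = pd.read_csv(tsv_path, sep="\t", dtype={"trav": str, "cdr3_aa": str, "abundance": int})
    abundance = {
        (row.trav, row.cdr3_aa): int(row.abundance) for row in table.itertuples(index=False)
    }
    return TcrCatalogue(
        subset=meta["subset"],
        genotype=meta["genotype"],
        n_mice=int(meta["n_mice"]),
        abundance=abundance,
    )
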