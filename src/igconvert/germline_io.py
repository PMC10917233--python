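"""Sequence and table I/O, reference validation, and the coordinate system.

All coordinates exposed by this package are 1-based inclusive positions on
the ungapped functional V allele.  IMGT-gapped FASTA records (``.`` gap
characters) are accepted and degapped on load; a gapped->ungapped position
map is retained so region boundaries given on gapped coordinates can be
converted.
"""

from __future__ import annotations

import sys
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

VALID_REFERENCE_BASES = frozenset("ACGT")
VALID_READ_BASES = frozenset("ACGTN")

REGION_LABELS = ("FWR1", "CDR1", "FWR2", "CDR2", "FWR3", "CDR3")

#: Columns of the per-event TSV, in output order.
EVENT_TABLE_COLUMNS = [
    "sequence_id",
    "bird",
    "tissue",
    "isotype",
    "event_index",
    "min_start",
    "min_end",
    "max_start",
    "max_end",
    "donor",
    "levenshtein",
    "match_status",
    "flank5",
    "flank3",
    "aid_distance_5prime",
    "introduces_new_hotspot",
]


class FastaError(ValueError):
    """Raised on malformed FASTA input."""


@dataclass(frozen=True)
class NamedSequence:
    """A named, uppercase DNA sequence."""

    name: str
    seq: str

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("sequence name must be nonempty")
        if not self.seq:
            raise ValueError(f"sequence {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class ReferenceSet:
    """The functional V allele plus its pseudogene donor library.

    ``distances_kb`` optionally maps pseudogene names to their germline
    distance from the functional gene, in kilobases.
    """

    functional: NamedSequence
    pseudogenes: tuple[NamedSequence, ...]
    distances_kb: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if not self.pseudogenes:
            raise ValueError("reference set requires at least one pseudogene")
        names = [p.name for p in self.pseudogenes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate pseudogene names in reference set")
        if self.functional.name in names:
            raise ValueError(
                f"functional allele name {self.functional.name!r} collides "
                "with a pseudogene name"
            )
        if self.distances_kb is not None:
            for name, kb in self.distances_kb.items():
                if kb < 0:
                    raise ValueError(f"negative germline distance for {name!r}")

    @property
    def pseudogene_names(self) -> list[str]:
        return [p.name for p in self.pseudogenes]

    def pseudogene(self, name: str) -> NamedSequence:
        for p in self.pseudogenes:
            if p.name == name:
                return p
        raise KeyError(name)


@dataclass(frozen=True)
class Region:
    label: str
    start: int  # 1-based inclusive
    end: int


@dataclass(frozen=True)
class RegionMap:
    """Ordered FWR/CDR partition of the ungapped functional allele."""

    regions: tuple[Region, ...]
    functional_length: int

    def __post_init__(self) -> None:
        prev_end = 0
        for r in self.regions:
            if r.label not in REGION_LABELS:
                raise ValueError(f"unknown region label {r.label!r}")
            if not (1 <= r.start <= r.end <= self.functional_length):
                raise ValueError(f"region {r.label} out of bounds")
            if r.start <= prev_end:
                raise ValueError("regions must be ascending and non-overlapping")
            prev_end = r.end

    def region_of(self, position: int) -> str | None:
        """Region label covering a 1-based position, or None."""
        for r in self.regions:
            if r.start <= position <= r.end:
                return r.label
        return None


@dataclass
class RepertoireRecord:
    """One observed repertoire sequence plus optional metadata and events."""

    id: str
    seq: str
    bird: str | None = None
    tissue: str | None = None
    isotype: str | None = None
    events: list = field(default_factory=list)


def _clean_sequence(name: str, raw: str, *, allow_n: bool, degap: bool) -> str:
    seq = raw.upper().replace("U", "T")
    if degap:
        seq = seq.replace(".", "").replace("-", "")
    allowed = VALID_READ_BASES if allow_n else VALID_REFERENCE_BASES
    bad = set(seq) - allowed
    if bad:
        raise FastaError(
            f"sequence {name!r} contains invalid characters: "
            f"{', '.join(sorted(bad))}"
        )
    if not seq:
        raise FastaError(f"sequence {name!r} is empty after degapping")
    return seq


def read_fasta(
    path: str | Path, *, allow_n: bool = True, degap: bool = True
) -> list[NamedSequence]:
    """Read a FASTA file into validated :class:`NamedSequence` records.

    Sequences are uppercased, U is mapped to T, and (by default) IMGT gap
    dots and dashes are removed.  ``allow_n=False`` rejects N bases, as
    required for reference alleles.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FastaError(f"no FASTA records found in {path}")
    out: list[NamedSequence] = []
    seen: set[str] = set()
    for rec in records:
        name = rec.id
        if name in seen:
            raise FastaError(f"duplicate sequence name {name!r} in {path}")
        seen.add(name)
        out.append(
            NamedSequence(name, _clean_sequence(name, str(rec.seq), allow_n=allow_n, degap=degap))
        )
    return out


def gapped_to_ungapped_map(gapped_seq: str) -> dict[int, int]:
    """Map 1-based positions on an IMGT-gapped sequence to ungapped positions.

    Gap columns (``.`` or ``-``) are absent from the returned mapping.
    """
    mapping: dict[int, int] = {}
    ungapped = 0
    for i, ch in enumerate(gapped_seq, start=1):
        if ch not in ".-":
            ungapped += 1
            mapping[i] = ungapped
    return mapping


def write_fasta(sequences: Iterable[NamedSequence], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sequences:
            fh.write(f">{s.name}\n")
            for i in range(0, len(s.seq), 70):
                fh.write(s.seq[i : i + 70] + "\n")


def read_distances(path: str | Path, known_names: Sequence[str]) -> dict[str, float]:
    """Read a 2-column TSV (pseudogene name, distance in kb).

    Names absent from ``known_names`` produce a warning and are skipped;
    IMGT distance annotations are frequently incomplete, so a tolerant
    join is deliberate.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=["name", "kb"], comment="#")
    known = set(known_names)
    out: dict[str, float] = {}
    for _, row in df.iterrows():
        name = str(row["name"])
        if name not in known:
            warnings.warn(
                f"distance entry for unknown pseudogene {name!r} ignored",
                stacklevel=2,
            )
            continue
        out[name] = float(row["kb"])
    return out


def load_reference_set(
    functional_path: str | Path,
    pseudogene_path: str | Path,
    distances_path: str | Path | None = None,
    functional_name: str | None = None,
) -> ReferenceSet:
    """Load and validate the functional allele plus the pseudogene library.

    The functional FASTA must contain exactly one record unless
    ``functional_name`` selects one of several.  N bases are rejected in
    all reference sequences.
    """
    functional_records = read_fasta(functional_path, allow_n=False)
    if functional_name is not None:
        matches = [r for r in functional_records if r.name == functional_name]
        if not matches:
            raise ValueError(
                f"functional allele {functional_name!r} not found in {functional_path}"
            )
        functional = matches[0]
    elif len(functional_records) == 1:
        functional = functional_records[0]
    else:
        raise ValueError(
            f"{functional_path} contains {len(functional_records)} records; "
            "supply the functional allele name to disambiguate"
        )

    pseudogenes = tuple(read_fasta(pseudogene_path, allow_n=False))
    distances = None
    if distances_path is not None:
        distances = read_distances(distances_path, [p.name for p in pseudogenes])
    return ReferenceSet(functional=functional, pseudogenes=pseudogenes, distances_kb=distances)


def read_repertoire(
    path: str | Path, metadata_path: str | Path | None = None
) -> list[RepertoireRecord]:
    """Read repertoire sequences, optionally joining a metadata TSV on id.

    The metadata table may carry ``bird``, ``tissue`` and ``isotype``
    columns keyed on a ``sequence_id`` column.
    """
    seqs = read_fasta(path, allow_n=True)
    meta: dict[str, dict] = {}
    if metadata_path is not None:
        df = pd.read_csv(metadata_path, sep="\t", dtype=str)
        if "sequence_id" not in df.columns:
            raise ValueError("metadata table must have a 'sequence_id' column")
        for _, row in df.iterrows():
            meta[row["sequence_id"]] = row.to_dict()
    records = []
    for s in seqs:
        m = meta.get(s.name, {})
        records.append(
            RepertoireRecord(
                id=s.name,
                seq=s.seq,
                bird=m.get("bird"),
                tissue=m.get("tissue"),
                isotype=m.get("isotype"),
            )
        )
    return records


def events_to_frame(records: Iterable[RepertoireRecord]) -> pd.DataFrame:
    """Flatten annotated records into the canonical per-event table."""
    rows = []
    for rec in records:
        for i, ev in enumerate(rec.events):
            rows.append(
                {
                    "sequence_id": rec.id,
                    "bird": rec.bird,
                    "tissue": rec.tissue,
                    "isotype": rec.isotype,
                    "event_index": i,
                    "min_start": ev.min_start,
                    "min_end": ev.min_end,
                    "max_start": ev.max_start,
                    "max_end": ev.max_end,
                    "donor": ev.donor,
                    "levenshtein": ev.levenshtein,
                    "match_status": ev.match_status,
                    "flank5": ev.flank5,
                    "flank3": ev.flank3,
                    "aid_distance_5prime": ev.aid_distance_5prime,
                    "introduces_new_hotspot": ev.introduces_new_hotspot,
                }
            )
    return pd.DataFrame(rows, columns=EVENT_TABLE_COLUMNS)


def write_event_table(records: Iterable[RepertoireRecord], path: str | Path) -> None:
    """Write one TSV row per annotated event (1-based functional coords)."""
    events_to_frame(records).to_csv(path, sep="\t", index=False)


def read_event_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sequence_id": str})
    missing = set(EVENT_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"event table missing columns: {sorted(missing)}")
    return df


def warn(msg: str) -> None:
    print(f"[igconvert] warning: {msg}", file=sys.stderr)
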