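"""Sequence and metadata I/O, clone-label parsing and haplotype collapsing.

The substrate of every downstream statistic is an aligned multi-FASTA of
cloned amplicon sequences, one record per clone, whose record ids encode the
collection site, the host individual, the PCR replicate and a clone tag.
This module validates that substrate, turns it into typed records, and
collapses exact-duplicate sequences into a haplotype table.  Characters are
preserved verbatim (gaps and Ns included); how they are treated is decided by
each downstream statistic, not here.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AlignmentError, InputError

ALLOWED_CHARS = frozenset("ACGT-N")

__all__ = [
    "Alignment",
    "CloneRecord",
    "Haplotype",
    "HaplotypeTable",
    "HostMetaTable",
    "LabelScheme",
    "MlstReport",
    "read_alignment",
    "write_alignment",
    "parse_clone_labels",
    "format_clone_label",
    "collapse_haplotypes",
    "mlst_identity_check",
]


@dataclass(frozen=True)
class Alignment:
    """An aligned set of uppercase DNA sequences over {A,C,G,T,-,N}.

    All rows share the same length and ids are unique; both are enforced at
    construction time.
    """

    ids: tuple[str, ...]
    seqs: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise InputError("ids and seqs must have equal length")
        if not self.seqs:
            raise InputError("alignment must contain at least one record")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) != 1:
            raise AlignmentError(f"ragged alignment: row lengths {sorted(lengths)}")
        if next(iter(lengths)) == 0:
            raise AlignmentError("alignment length must be positive")
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise InputError(f"duplicate record ids: {dupes}")
        bad = set("".join(self.seqs)) - ALLOWED_CHARS
        if bad:
            raise AlignmentError(f"invalid characters in alignment: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.seqs[0])

    def __len__(self) -> int:
        return len(self.seqs)


def read_alignment(path: str | Path, format: str = "fasta") -> Alignment:
    """Read an aligned multi-record file, uppercasing sequences on the way in."""
    if format != "fasta":
        raise InputError(f"unsupported alignment format: {format!r}")
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise InputError(f"no records in {path}")
    return Alignment(
        ids=tuple(r.id for r in records),
        seqs=tuple(str(r.seq).upper() for r in records),
    )


def write_alignment(alignment: Alignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s), id=i, description="")
        for i, s in zip(alignment.ids, alignment.seqs)
    ]
    SeqIO.write(records, str(path), "fasta")


@dataclass(frozen=True)
class CloneRecord:
    """One cloned amplicon sequence tagged with its provenance."""

    clone_id: str
    individual_id: str
    site_code: str
    pcr_replicate: int
    sequence: str


@dataclass(frozen=True)
class LabelScheme:
    """How clone provenance is packed into a FASTA record id.

    Default: ``site|individual|replicate|clone`` with ``|`` as delimiter.  The
    replicate field may carry a non-numeric prefix (``r1`` parses as 1).
    """

    delimiter: str = "|"
    order: tuple[str, ...] = ("site", "individual", "replicate", "clone")

    def __post_init__(self) -> None:
        required = {"site", "individual", "replicate", "clone"}
        if set(self.order) != required:
            raise InputError(f"label scheme fields must be exactly {sorted(required)}")


def parse_clone_labels(
    alignment: Alignment, label_scheme: LabelScheme | None = None
) -> list[CloneRecord]:
    """Parse every record id into a :class:`CloneRecord` under the scheme."""
    scheme = label_scheme or LabelScheme()
    clones: list[CloneRecord] = []
    seen: set[tuple[str, int, str]] = set()
    for rec_id, seq in zip(alignment.ids, alignment.seqs):
        parts = rec_id.split(scheme.delimiter)
        if len(parts) != len(scheme.order):
            raise InputError(
                f"id {rec_id!r} has {len(parts)} fields, expected "
                f"{len(scheme.order)} under scheme {scheme.order}"
            )
        fields = dict(zip(scheme.order, parts))
        rep_digits = re.sub(r"^\D*", "", fields["replicate"])
        if not rep_digits.isdigit():
            raise InputError(f"id {rec_id!r}: replicate field {fields['replicate']!r} is not numeric")
        replicate = int(rep_digits)
        if replicate < 1:
            raise InputError(f"id {rec_id!r}: replicate must be >= 1")
        key = (fields["individual"], replicate, fields["clone"])
        if key in seen:
            raise InputError(f"duplicate (individual, replicate, clone) triple from id {rec_id!r}")
        seen.add(key)
        clones.append(
            CloneRecord(
                clone_id=fields["clone"],
                individual_id=fields["individual"],
                site_code=fields["site"],
                pcr_replicate=replicate,
                sequence=seq,
            )
        )
    return clones


def format_clone_label(clone: CloneRecord, label_scheme: LabelScheme | None = None) -> str:
    """Inverse of :func:`parse_clone_labels` for round-tripping clone sets."""
    scheme = label_scheme or LabelScheme()
    values = {
        "site": clone.site_code,
        "individual": clone.individual_id,
        "replicate": f"r{clone.pcr_replicate}",
        "clone": clone.clone_id,
    }
    return scheme.delimiter.join(values[f] for f in scheme.order)


def clones_to_alignment(clones: list[CloneRecord], label_scheme: LabelScheme | None = None) -> Alignment:
    return Alignment(
        ids=tuple(format_clone_label(c, label_scheme) for c in clones),
        seqs=tuple(c.sequence for c in clones),
    )


@dataclass(frozen=True)
class Haplotype:
    """A unique sequence with its multiplicity and carrier bookkeeping."""

    haplotype_id: str
    sequence: str
    count: int
    carrier_counts: dict[str, int] = field(compare=False)
    sites: frozenset[str] = field(compare=False)

    @property
    def carriers(self) -> frozenset[str]:
        return frozenset(self.carrier_counts)


@dataclass(frozen=True)
class HaplotypeTable:
    """Unique sequences with multiplicities; output of collapsing clone sets."""

    haplotypes: tuple[Haplotype, ...]

    def __post_init__(self) -> None:
        seqs = [h.sequence for h in self.haplotypes]
        if len(set(seqs)) != len(seqs):
            raise InputError("haplotype sequences must be pairwise distinct")

    def __len__(self) -> int:
        return len(self.haplotypes)

    def __iter__(self):
        return iter(self.haplotypes)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(h.haplotype_id for h in self.haplotypes)

    @property
    def sequences(self) -> tuple[str, ...]:
        return tuple(h.sequence for h in self.haplotypes)

    @property
    def counts(self) -> tuple[int, ...]:
        return tuple(h.count for h in self.haplotypes)

    @property
    def total_count(self) -> int:
        return sum(h.count for h in self.haplotypes)

    @property
    def alignment_length(self) -> int:
        return len(self.haplotypes[0].sequence) if self.haplotypes else 0

    def by_id(self, haplotype_id: str) -> Haplotype:
        for h in self.haplotypes:
            if h.haplotype_id == haplotype_id:
                return h
        raise KeyError(haplotype_id)

    def subset(self, ids: set[str] | frozenset[str]) -> "HaplotypeTable":
        return HaplotypeTable(tuple(h for h in self.haplotypes if h.haplotype_id in ids))

    def drop(self, ids: set[str] | frozenset[str]) -> "HaplotypeTable":
        return HaplotypeTable(tuple(h for h in self.haplotypes if h.haplotype_id not in ids))

    def to_alignment(self) -> Alignment:
        return Alignment(ids=self.ids, seqs=self.sequences)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "haplotype_id": self.ids,
                "count": self.counts,
                "n_carriers": [len(h.carriers) for h in self.haplotypes],
                "carriers": [",".join(sorted(h.carriers)) for h in self.haplotypes],
                "sites": [",".join(sorted(h.sites)) for h in self.haplotypes],
                "sequence": self.sequences,
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def write_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(h.sequence), id=h.haplotype_id, description=f"count={h.count}")
            for h in self.haplotypes
        ]
        SeqIO.write(records, str(path), "fasta")


def collapse_haplotypes(clones: list[CloneRecord], prefix: str = "H") -> HaplotypeTable:
    """Collapse clone records into unique haplotypes by exact string identity.

    Haplotype ids are deterministic: ordered by descending clone count, ties
    broken by lexicographic sequence.
    """
    if not clones:
        raise InputError("cannot collapse an empty clone set")
    lengths = {len(c.sequence) for c in clones}
    if len(lengths) != 1:
        raise AlignmentError(f"clone sequences have unequal lengths {sorted(lengths)}")
    buckets: dict[str, list[CloneRecord]] = {}
    for c in clones:
        buckets.setdefault(c.sequence, []).append(c)
    ordered = sorted(buckets.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    width = max(3, len(str(len(ordered))))
    haplotypes = []
    for idx, (seq, members) in enumerate(ordered, start=1):
        carrier_counts: dict[str, int] = {}
        for m in members:
            carrier_counts[m.individual_id] = carrier_counts.get(m.individual_id, 0) + 1
        haplotypes.append(
            Haplotype(
                haplotype_id=f"{prefix}{idx:0{width}d}",
                sequence=seq,
                count=len(members),
                carrier_counts=carrier_counts,
                sites=frozenset(m.site_code for m in members),
            )
        )
    return HaplotypeTable(tuple(haplotypes))


class HostMetaTable:
    """Per-individual host metadata: site, coordinates, mtDNA haplotype and
    haplogroup (North/South), contact-region flag, infection status and which
    symbiont groups the individual carries."""

    REQUIRED = (
        "individual_id",
        "site_code",
        "latitude",
        "longitude",
        "mtdna_haplotype",
        "mtdna_haplogroup",
        "mixed_region",
        "infected",
        "group1",
        "group2",
    )

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise InputError(f"host metadata missing columns: {missing}")
        if df["individual_id"].duplicated().any():
            dupes = sorted(df.loc[df["individual_id"].duplicated(), "individual_id"].unique())
            raise InputError(f"duplicate individuals in metadata: {dupes}")
        bad = set(df["mtdna_haplogroup"].unique()) - {"North", "South"}
        if bad:
            raise InputError(f"mtdna_haplogroup must be North/South, got {sorted(bad)}")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def individuals(self) -> set[str]:
        return set(self.df["individual_id"])

    def haplogroup_of(self) -> dict[str, str]:
        return dict(zip(self.df["individual_id"], self.df["mtdna_haplogroup"]))

    def site_of(self) -> dict[str, str]:
        return dict(zip(self.df["individual_id"], self.df["site_code"]))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "HostMetaTable":
        df = pd.read_csv(path, sep="\t")
        for col in ("mixed_region", "infected", "group1", "group2"):
            if col in df.columns and df[col].dtype == object:
                df[col] = df[col].map({"True": True, "False": False}).astype(bool)
        return cls(df)

    def write_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False, columns=list(self.REQUIRED))


@dataclass(frozen=True)
class MlstReport:
    """Clone-identity check per (individual, locus) for MLST libraries."""

    haplotype_counts: dict[tuple[str, str], int]
    flagged: frozenset[tuple[str, str]]
    consensus: dict[tuple[str, str], str]
    concatenated: dict[str, str]

    @property
    def all_identical(self) -> bool:
        return not self.flagged


def mlst_identity_check(per_locus_clones: dict[str, list[CloneRecord]]) -> MlstReport:
    """Check that all clones of each locus within an individual are identical.

    Groups with a single haplotype yield a consensus; individuals with a
    consensus at every locus get a concatenated sequence (loci in sorted
    order), ready for strain typing.
    """
    counts: dict[tuple[str, str], int] = {}
    flagged: set[tuple[str, str]] = set()
    consensus: dict[tuple[str, str], str] = {}
    loci = sorted(per_locus_clones)
    individuals: set[str] = set()
    for locus in loci:
        groups: dict[str, list[CloneRecord]] = {}
        for c in per_locus_clones[locus]:
            groups.setdefault(c.individual_id, []).append(c)
        for ind, members in groups.items():
            individuals.add(ind)
            uniq = sorted({m.sequence for m in members})
            counts[(ind, locus)] = len(uniq)
            if len(uniq) == 1:
                consensus[(ind, locus)] = uniq[0]
            else:
                flagged.add((ind, locus))
    concatenated = {}
    for ind in sorted(individuals):
        pieces = [consensus.get((ind, locus)) for locus in loci]
        if all(p is not None for p in pieces):
            concatenated[ind] = "".join(pieces)  # type: ignore[arg-type]
    return MlstReport(
        haplotype_counts=counts,
        flagged=frozenset(flagged),
        consensus=consensus,
        concatenated=concatenated,
    )
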