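"""Reference MGC protein database: gene-family nomenclature, data model, I/O.

The search targets are curated magnetosome proteins drawn from all taxonomic
groups where magnetotactic bacteria are known. Gene families follow the
field's nomenclature: ``mam`` (magnetosome membrane) genes, of which nine
(mamA, -B, -M, -K, -P, -Q, -E, -O, -I) occur in every known MGC; ``mms``
genes (magnetic-particle-membrane specific); ``mad`` genes (typical of
Deltaproteobacteria and Nitrospirae); and ``man`` genes (previously known
only from Nitrospirae). Each reference protein carries its source MGC, its
taxonomic group, and the magnetosome composition (magnetite/greigite) of its
source organism, so downstream modules can form labeled groups.

Non-MTB homologs (e.g. actin-like MamK homologs, TPR-like MamA homologs) are
stored in the same database with an ``is_homolog`` flag, recorded under the
marker family they mimic — marker evaluation treats markers and their decoys
jointly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

SEQUENCE_RE = re.compile(r"^[ACDEFGHIKLMNPQRSTVWYXBZ]+$")
VALID_COMPOSITIONS = ("magnetite", "greigite", "unknown")
CATEGORIES = ("mam", "mms", "mad", "man", "other")

#: The nine gene families present in all MGCs, in the order they are
#: conventionally listed (A, B, M, K, P, Q, E, O, I).
ESSENTIAL_FAMILY_NAMES = (
    "mamA", "mamB", "mamM", "mamK", "mamP", "mamQ", "mamE", "mamO", "mamI",
)

METADATA_COLUMNS = ("id", "family", "taxon_group", "source_mgc",
                    "composition_label", "is_homolog")


def family_category(name: str) -> str:
    """Category from the name prefix: mam/mms/mad/man, else ``other``."""
    for cat in CATEGORIES[:4]:
        if name.startswith(cat):
            return cat
    return "other"


@dataclass(frozen=True, order=True)
class GeneFamily:
    """A named MGC gene family (e.g. ``mamK``) with its derived category."""

    name: str
    category: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("gene family name must be non-empty")
        derived = family_category(self.name)
        if self.category and self.category != derived:
            raise ValueError(
                f"category {self.category!r} inconsistent with name {self.name!r}"
            )
        object.__setattr__(self, "category", derived)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


def essential_families() -> list[GeneFamily]:
    """The nine universal ``mam`` families, fixed order, database-independent."""
    return [GeneFamily(n) for n in ESSENTIAL_FAMILY_NAMES]


@dataclass
class ReferenceProtein:
    """One curated protein: family, provenance, composition label, sequence."""

    id: str
    family: GeneFamily
    taxon_group: str
    source_mgc: str
    composition_label: str
    sequence: str
    is_homolog: bool = False

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if self.composition_label not in VALID_COMPOSITIONS:
            raise ValueError(
                f"protein {self.id!r}: composition label "
                f"{self.composition_label!r} not in {VALID_COMPOSITIONS}"
            )
        if not self.taxon_group:
            raise ValueError(f"protein {self.id!r}: empty taxon_group")
        m = SEQUENCE_RE.match(self.sequence)
        if not m:
            bad = next(i for i, c in enumerate(self.sequence)
                       if not SEQUENCE_RE.match(c))
            raise ValueError(
                f"protein {self.id!r}: illegal residue "
                f"{self.sequence[bad]!r} at position {bad}"
            )


@dataclass
class ReferenceDatabase:
    """Curated marker proteins plus their flagged non-MTB homologs."""

    proteins: list[ReferenceProtein]
    homologs: list[ReferenceProtein] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for p in list(self.proteins) + list(self.homologs):
            if p.id in seen:
                raise ValueError(f"duplicate protein id {p.id!r}")
            seen.add(p.id)

    def __len__(self) -> int:
        return len(self.proteins) + len(self.homologs)

    @property
    def by_id(self) -> dict[str, ReferenceProtein]:
        return {p.id: p for p in self.proteins + self.homologs}

    def families(self) -> list[GeneFamily]:
        """Distinct marker families, sorted by name."""
        return sorted({p.family for p in self.proteins}, key=lambda f: f.name)

    def markers(self, family: GeneFamily | str | None = None) -> list[ReferenceProtein]:
        name = getattr(family, "name", family)
        return [p for p in self.proteins if name is None or p.family.name == name]

    def homologs_of(self, family: GeneFamily | str) -> list[ReferenceProtein]:
        name = getattr(family, "name", family)
        return [p for p in self.homologs if p.family.name == name]

    def subset(self, families) -> "ReferenceDatabase":
        names = {getattr(f, "name", f) for f in families}
        return ReferenceDatabase(
            proteins=[p for p in self.proteins if p.family.name in names],
            homologs=[p for p in self.homologs if p.family.name in names],
        )


def _parse_bool(x) -> bool:
    if isinstance(x, bool):
        return x
    s = str(x).strip().lower()
    if s in ("1", "true", "yes"):
        return True
    if s in ("0", "false", "no"):
        return False
    raise ValueError(f"cannot interpret {x!r} as a boolean is_homolog flag")


def load_reference_db(fasta_path: str | Path, metadata_path: str | Path) -> ReferenceDatabase:
    """Load and validate a reference database from protein FASTA plus a
    UTF-8 TSV metadata table with columns
    ``id family taxon_group source_mgc composition_label is_homolog``.

    Every FASTA record must have a metadata row and vice versa; duplicate
    ids, unknown composition labels, and illegal residues are hard errors.
    """
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        records[rec.id] = str(rec.seq)
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    missing_cols = set(METADATA_COLUMNS) - set(meta.columns)
    if missing_cols:
        raise ValueError(f"metadata table missing columns {sorted(missing_cols)}")
    if meta["id"].duplicated().any():
        dup = meta.loc[meta["id"].duplicated(), "id"].iloc[0]
        raise ValueError(f"duplicate metadata id {dup!r}")
    meta_ids = set(meta["id"])
    only_fasta = set(records) - meta_ids
    only_meta = meta_ids - set(records)
    if only_fasta or only_meta:
        raise ValueError(
            f"FASTA/metadata mismatch: missing from metadata {sorted(only_fasta)}, "
            f"missing from FASTA {sorted(only_meta)}"
        )
    proteins, homologs = [], []
    for row in meta.itertuples(index=False):
        p = ReferenceProtein(
            id=row.id,
            family=GeneFamily(row.family),
            taxon_group=row.taxon_group,
            source_mgc=row.source_mgc,
            composition_label=row.composition_label,
            sequence=records[row.id],
            is_homolog=_parse_bool(row.is_homolog),
        )
        (homologs if p.is_homolog else proteins).append(p)
    return ReferenceDatabase(proteins=proteins, homologs=homologs)


def write_reference_db(db: ReferenceDatabase, fasta_path: str | Path,
                       metadata_path: str | Path) -> None:
    """Write the database back to FASTA + TSV (round-trips with
    :func:`load_reference_db`)."""
    entries = list(db.proteins) + list(db.homologs)
    SeqIO.write(
        (SeqRecord(Seq(p.sequence), id=p.id, description="") for p in entries),
        str(fasta_path), "fasta",
    )
    rows = [
        {
            "id": p.id,
            "family": p.family.name,
            "taxon_group": p.taxon_group,
            "source_mgc": p.source_mgc,
            "composition_label": p.composition_label,
            "is_homolog": str(p.is_homolog).lower(),
        }
        for p in entries
    ]
    pd.DataFrame(rows, columns=list(METADATA_COLUMNS)).to_csv(
        metadata_path, sep="\t", index=False
    )
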