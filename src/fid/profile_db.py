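"""The species x enzyme fragment-profile database.

One record per species holds its extracted amplicon and the fragment
profile every panel enzyme produces from it.  Species whose amplicon
sequences are exactly identical are grouped — they are indistinguishable
under every enzyme by construction, so both views (records and duplicate
groups) are kept.  The database serializes to a greppable TSV (one row per
species x enzyme) with a JSON sidecar carrying sequences, the enzyme panel
and build metadata; the round trip is lossless.
"""

from __future__ import annotations

import json
import statistics
from dataclasses import dataclass, field
from pathlib import Path

from fid.insilico_pcr import (AmpliconRecord, PcrParams, PrimerPair,
                              DEFAULT_PRIMERS, extract_amplicon,
                              read_labelled_fasta)
from fid.restriction import Enzyme, FragmentProfile, digest

__all__ = [
    "SpeciesProfileSet", "ProfileDB", "build_profile_db", "dedupe_sequences",
    "write_db", "read_db", "length_summary", "LengthSummary",
]

FORMAT_VERSION = "1"

_TAXON_FIELDS = ("class_", "order", "family", "genus")


@dataclass
class SpeciesProfileSet:
    """One species: its amplicon plus a profile per enzyme."""

    species_label: str
    amplicon: AmpliconRecord
    profiles: dict[str, FragmentProfile]
    taxonomy: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for p in self.profiles.values():
            if p.amplicon_length != len(self.amplicon.sequence):
                raise ValueError(
                    f"{self.species_label}/{p.enzyme}: profile length "
                    f"{p.amplicon_length} != amplicon {len(self.amplicon.sequence)}")


@dataclass
class ProfileDB:
    records: list[SpeciesProfileSet]
    enzymes: list[Enzyme]
    duplicate_groups: list[frozenset[str]] = field(default_factory=list)
    skip_report: list[str] = field(default_factory=list)
    dropped_enzymes: list[str] = field(default_factory=list)

    @property
    def species(self) -> list[str]:
        return [r.species_label for r in self.records]

    @property
    def n_species(self) -> int:
        return len(self.records)

    def record(self, species_label: str) -> SpeciesProfileSet:
        for r in self.records:
            if r.species_label == species_label:
                return r
        raise KeyError(species_label)


def dedupe_sequences(records: list[SpeciesProfileSet]) -> list[frozenset[str]]:
    """Equivalence classes of exact amplicon-sequence identity (singletons omitted)."""
    by_seq: dict[str, list[str]] = {}
    for r in records:
        by_seq.setdefault(r.amplicon.sequence, []).append(r.species_label)
    groups = [frozenset(v) for v in by_seq.values() if len(v) > 1]
    groups.sort(key=lambda g: sorted(g))
    return groups


def build_profile_db(fasta, primers: PrimerPair | None = None,
                     pcr: PcrParams | None = None,
                     enzymes: list[Enzyme] | None = None,
                     separator: str = "|") -> ProfileDB:
    """Extract one amplicon per species from a FASTA file and digest it with a panel.

    When several records share a species label the first with a valid
    amplicon wins.  Species with no extractable amplicon go to the skip
    report; enzymes whose site occurs in no amplicon are dropped from the
    panel (they carry no information) and listed in ``dropped_enzymes``.
    """
    if enzymes is None:
        from fid.restriction import load_default_enzymes
        enzymes = load_default_enzymes()
    primers = primers or DEFAULT_PRIMERS
    pcr = pcr or PcrParams()

    amplicons: dict[str, AmpliconRecord] = {}
    seen_species: list[str] = []
    skip_report: list[str] = []
    n_records = 0
    for label, seq_id, seq in read_labelled_fasta(fasta, separator=separator):
        n_records += 1
        if label not in seen_species:
            seen_species.append(label)
        if label in amplicons:
            skip_report.append(
                f"{label}: extra record {seq_id} ignored (first valid amplicon kept)")
            continue
        amp = extract_amplicon(seq, primers, pcr,
                               species_label=label, seq_id=seq_id)
        if amp is not None:
            amplicons[label] = amp
    if n_records == 0:
        raise ValueError("empty FASTA: no records to build a database from")
    for label in seen_species:
        if label not in amplicons:
            skip_report.append(f"{label}: no amplicon found")

    # Drop enzymes that never cut anywhere in the database.
    cutting = [
        e for e in enzymes
        if any(len(digest(a, e).fragments) > 1 for a in amplicons.values())
    ]
    dropped = [e.name for e in enzymes if e not in cutting]

    records = [
        SpeciesProfileSet(
            species_label=label,
            amplicon=amp,
            profiles={e.name: digest(amp, e) for e in cutting},
        )
        for label, amp in amplicons.items()
    ]
    groups = dedupe_sequences(records)
    _assert_duplicate_profile_identity(records, groups)
    return ProfileDB(records=records, enzymes=cutting,
                     duplicate_groups=groups, skip_report=skip_report,
                     dropped_enzymes=dropped)


def _assert_duplicate_profile_identity(records, groups) -> None:
    by_label = {r.species_label: r for r in records}
    for g in groups:
        members = [by_label[s] for s in g]
        ref = members[0]
        for m in members[1:]:
            for name, prof in ref.profiles.items():
                if m.profiles[name].fragments != prof.fragments:
                    raise AssertionError(
                        f"identical sequences {sorted(g)} disagree under {name}")


@dataclass(frozen=True)
class LengthSummary:
    """Amplicon-length statistics over unique sequences."""

    n_unique_lengths: int
    median: float
    min_length: int
    min_label: str
    max_length: int
    max_label: str


def length_summary(db: ProfileDB) -> LengthSummary:
    """Summarize amplicon lengths over one representative per unique sequence."""
    if not db.records:
        raise ValueError("empty database")
    seen_seq: set[str] = set()
    reps = []
    for r in db.records:
        if r.amplicon.sequence not in seen_seq:
            seen_seq.add(r.amplicon.sequence)
            reps.append(r)
    lengths = [r.amplicon.length for r in reps]
    lo = min(reps, key=lambda r: (r.amplicon.length, r.species_label))
    hi = max(reps, key=lambda r: (r.amplicon.length, r.species_label))
    return LengthSummary(
        n_unique_lengths=len(set(lengths)),
        median=statistics.median(lengths),
        min_length=lo.amplicon.length, min_label=lo.species_label,
        max_length=hi.amplicon.length, max_label=hi.species_label,
    )


# ---------------------------------------------------------------------------
# serialization

def _sidecar_path(path) -> Path:
    return Path(str(path) + ".json")


def write_db(db: ProfileDB, path) -> None:
    """Write the profile TSV and its JSON sidecar (``<path>.json``)."""
    path = Path(path)
    lines = [f"# fid-profile-db v{FORMAT_VERSION}",
             "species\tclass\torder\tfamily\tgenus\tamplicon_length\tenzyme\tfragments"]
    for r in db.records:
        tax = [r.taxonomy.get(f, "") for f in _TAXON_FIELDS]
        for name in (e.name for e in db.enzymes):
            p = r.profiles[name]
            frags = ";".join(str(f) for f in p.fragments)
            lines.append("\t".join([r.species_label, *tax,
                                    str(r.amplicon.length), name, frags]))
    path.write_text("\n".join(lines) + "\n")

    side = {
        "format_version": FORMAT_VERSION,
        "enzymes": [
            {"name": e.name, "site": e.site, "cut_offset": e.cut_offset,
             "group": e.group}
            for e in db.enzymes
        ],
        "duplicate_groups": [sorted(g) for g in db.duplicate_groups],
        "skip_report": db.skip_report,
        "dropped_enzymes": db.dropped_enzymes,
        "amplicons": {
            r.species_label: {
                "seq_id": r.amplicon.seq_id,
                "sequence": r.amplicon.sequence,
                "length": r.amplicon.length,
                "flags": sorted(r.amplicon.extraction_flags),
                "alternate_lengths": list(r.amplicon.alternate_lengths),
                "taxonomy": r.taxonomy,
            }
            for r in db.records
        },
    }
    _sidecar_path(path).write_text(json.dumps(side, indent=1, sort_keys=True))


def read_db(path) -> ProfileDB:
    """Load a database written by :func:`write_db`; the round trip is exact."""
    path = Path(path)
    text = path.read_text().splitlines()
    if not text or not text[0].startswith("# fid-profile-db v"):
        raise ValueError(f"{path}: not a profile database (missing header)")
    version = text[0].rsplit("v", 1)[1]
    if version != FORMAT_VERSION:
        raise ValueError(f"{path}: format version {version!r} != {FORMAT_VERSION!r}")
    side = json.loads(_sidecar_path(path).read_text())
    enzymes = [Enzyme(**e) for e in side["enzymes"]]

    profiles: dict[str, dict[str, FragmentProfile]] = {}
    order: list[str] = []
    for lineno, line in enumerate(text[2:], start=3):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 8:
            raise ValueError(f"{path}:{lineno}: malformed row ({len(parts)} fields)")
        species, *_tax, length, enzyme, frags = parts
        fragments = tuple(int(x) for x in frags.split(";")) if frags else ()
        if species not in profiles:
            profiles[species] = {}
            order.append(species)
        profiles[species][enzyme] = FragmentProfile(
            enzyme=enzyme, fragments=fragments, amplicon_length=int(length))

    records = []
    for species in order:
        meta = side["amplicons"].get(species)
        if meta is None:
            raise ValueError(f"{path}: species {species!r} missing from sidecar")
        if len(profiles[species]) != len(enzymes):
            raise ValueError(f"{path}: species {species!r} has "
                             f"{len(profiles[species])} rows, expected {len(enzymes)}")
        amp = AmpliconRecord(
            species_label=species, seq_id=meta["seq_id"],
            sequence=meta["sequence"], length=meta["length"],
            extraction_flags=frozenset(meta["flags"]),
            alternate_lengths=tuple(meta["alternate_lengths"]),
        )
        records.append(SpeciesProfileSet(
            species_label=species, amplicon=amp, profiles=profiles[species],
            taxonomy=dict(meta.get("taxonomy", {}))))
    return ProfileDB(
        records=records, enzymes=enzymes,
        duplicate_groups=[frozenset(g) for g in side["duplicate_groups"]],
        skip_report=list(side["skip_report"]),
        dropped_enzymes=list(side["dropped_enzymes"]),
    )
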