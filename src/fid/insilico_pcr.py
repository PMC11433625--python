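"""Degenerate-primer matching and amplicon extraction.

Locates primer binding sites in arbitrary DNA with a bounded substitution
rate (cutadapt-style: errors / length of the matching part, partial overlap
allowed at sequence ends) and extracts the convergent primer-to-primer span
a PCR would amplify.  Extraction retries with a relaxed error rate and on
the reverse complement before giving up, and discards spans shorter than a
minimum product length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import floor
from typing import Iterator, Optional

from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import reverse_complement

__all__ = [
    "PrimerPair", "PcrParams", "PrimerMatch", "AmpliconRecord",
    "DEFAULT_PRIMERS", "find_primer_matches", "extract_amplicon",
    "read_labelled_fasta",
]

_IUPAC = {code: frozenset(bases) for code, bases in ambiguous_dna_values.items()}
_VALID_CODES = frozenset(_IUPAC) - {"X"}


def _check_alphabet(s: str, what: str) -> str:
    s = s.upper().replace("U", "T")
    bad = set(s) - _VALID_CODES
    if not s or bad:
        raise ValueError(f"{what} contains invalid characters {sorted(bad)!r}"
                         if bad else f"{what} is empty")
    return s


@dataclass(frozen=True)
class PrimerPair:
    """A forward/reverse primer pair, both written 5'->3'.

    The default pair targets the fungal ITS1-5.8S-ITS2 barcode region
    (primers conventionally named ITS1 and ITS4).
    """

    forward: str
    reverse: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "forward", _check_alphabet(self.forward, "forward primer"))
        object.__setattr__(self, "reverse", _check_alphabet(self.reverse, "reverse primer"))


#: ITS1 / ITS4 primer pair used to amplify the ITS1-5.8S-ITS2 region.
DEFAULT_PRIMERS = PrimerPair(forward="TCCGTAGGTGAACCTGCGG",
                             reverse="TCCTCCGCTTATTGATATGC")

#: Alternative ITS1 forward primer variant used in some wet-lab protocols.
ALT_FORWARD_PRIMER = "GTTTCCGTAGGTGAACTTGC"


@dataclass(frozen=True)
class PcrParams:
    """Tunables for primer matching and amplicon acceptance.

    max_error_rate
        Allowed mismatches divided by the length of the matching part.
    relaxed_error_rate
        Fallback rate tried when no amplicon is found at ``max_error_rate``.
    min_overlap
        Minimum primer/sequence overlap (nt) for a match to count;
        permits primers hanging off sequence ends.
    min_amplicon_len
        Products shorter than this are rejected.
    include_primers_in_length
        Whether the reported amplicon length covers both primer footprints
        (the experimentally measured PCR product does).
    max_passes
        Number of search rounds per orientation (cutadapt's ``-n``).
    """

    max_error_rate: float = 0.10
    relaxed_error_rate: float = 0.20
    min_overlap: int = 18
    min_amplicon_len: int = 200
    include_primers_in_length: bool = True
    max_passes: int = 2

    def __post_init__(self) -> None:
        if not (0 <= self.max_error_rate < 0.5 and 0 <= self.relaxed_error_rate < 0.5):
            raise ValueError("error rates must lie in [0, 0.5)")
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be positive")
        if self.min_amplicon_len < 1:
            raise ValueError("min_amplicon_len must be positive")


@dataclass(frozen=True)
class PrimerMatch:
    """One primer placement: 0-based half-open [start, end) on the given strand."""

    start: int
    end: int
    strand: str  # '+' or '-'
    n_errors: int
    which: str   # 'forward' or 'reverse'

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("start must precede end")


@dataclass
class AmpliconRecord:
    """A primer-delimited region in forward orientation.

    ``sequence`` always spans primer to primer inclusive; ``length`` is the
    PCR product size, including the primer footprints unless extraction was
    configured otherwise.  ``extraction_flags`` records which fallbacks fired
    (``relaxed_error``, ``reverse_complemented``).
    """

    species_label: str
    seq_id: str
    sequence: str
    length: int
    extraction_flags: frozenset = field(default_factory=frozenset)
    alternate_lengths: tuple = ()


def _base_matches(seq_base: str, primer_code: str) -> bool:
    # Sequence bases must be concrete; ambiguity in the genome never matches.
    return seq_base in _IUPAC.get(primer_code, frozenset())


def find_primer_matches(seq: str, primer: str, params: PcrParams | None = None,
                        error_rate: float | None = None,
                        which: str = "forward") -> list[PrimerMatch]:
    """Find all placements of ``primer`` on the + strand of ``seq``.

    A placement at offset ``o`` (possibly negative, or running past the
    sequence end) is reported when the overlapping part is at least
    ``min_overlap`` nt and its substitution count does not exceed
    ``floor(error_rate * overlap)``.  Matches are returned sorted by start.
    """
    params = params or PcrParams()
    rate = params.max_error_rate if error_rate is None else error_rate
    seq = _check_alphabet(seq, "sequence")
    primer = _check_alphabet(primer, "primer")
    lp, ls = len(primer), len(seq)
    min_ov = min(params.min_overlap, lp)

    matches: list[PrimerMatch] = []
    for o in range(-(lp - min_ov), ls - min_ov + 1):
        p_lo = max(0, -o)
        p_hi = min(lp, ls - o)
        overlap = p_hi - p_lo
        if overlap < min_ov:
            continue
        allowed = floor(rate * overlap)
        errors = 0
        for j in range(p_lo, p_hi):
            if not _base_matches(seq[o + j], primer[j]):
                errors += 1
                if errors > allowed:
                    break
        else:
            matches.append(PrimerMatch(start=o + p_lo, end=o + p_hi,
                                       strand="+", n_errors=errors,
                                       which=which))
    matches.sort(key=lambda m: (m.start, m.end))
    return matches


def _candidate_spans(seq: str, primers: PrimerPair, params: PcrParams,
                     rate: float) -> list[tuple[int, int]]:
    """All convergent (forward-start, reverse-end) spans meeting the length rule."""
    fwd = find_primer_matches(seq, primers.forward, params, error_rate=rate)
    rev_site = reverse_complement(primers.reverse)
    rev = find_primer_matches(seq, rev_site, params, error_rate=rate,
                              which="reverse")
    spans = []
    for f in fwd:
        for r in rev:
            if r.start >= f.end and r.end - f.start >= params.min_amplicon_len:
                spans.append((f.start, r.end))
    return spans


def extract_amplicon(seq: str, primers: PrimerPair | None = None,
                     params: PcrParams | None = None,
                     species_label: str = "", seq_id: str = "") -> Optional[AmpliconRecord]:
    """Extract the PCR product a convergent primer pair would yield.

    Tries, in order: the given strand at the standard error rate, the given
    strand at the relaxed rate, then the reverse complement at both rates
    (re-orienting the result forward).  Returns ``None`` when every pass
    fails.  With several valid spans the 5'-most, innermost one wins and a
    warning lists the alternate lengths.
    """
    primers = primers or DEFAULT_PRIMERS
    params = params or PcrParams()
    seq = _check_alphabet(seq, "sequence")

    passes = [
        (seq, params.max_error_rate, frozenset()),
        (seq, params.relaxed_error_rate, frozenset({"relaxed_error"})),
        (reverse_complement(seq), params.max_error_rate,
         frozenset({"reverse_complemented"})),
        (reverse_complement(seq), params.relaxed_error_rate,
         frozenset({"relaxed_error", "reverse_complemented"})),
    ]
    for oriented, rate, flags in passes:
        spans = _candidate_spans(oriented, primers, params, rate)
        if not spans:
            continue
        first_start = min(s for s, _ in spans)
        inner = [e for s, e in spans if s == first_start]
        end = min(inner)
        lengths = sorted({e - s for s, e in spans})
        if len(lengths) > 1:
            warnings.warn(
                f"{species_label or seq_id or 'sequence'}: multiple candidate "
                f"amplicons with lengths {lengths}; keeping the 5'-most "
                f"innermost span ({end - first_start} nt)",
                stacklevel=2,
            )
        sub = oriented[first_start:end]
        length = len(sub)
        if not params.include_primers_in_length:
            length -= len(primers.forward) + len(primers.reverse)
        return AmpliconRecord(
            species_label=species_label, seq_id=seq_id, sequence=sub,
            length=length, extraction_flags=flags,
            alternate_lengths=tuple(lengths) if len(lengths) > 1 else (),
        )
    return None


def read_labelled_fasta(path, separator: str = "|") -> Iterator[tuple[str, str, str]]:
    """Yield (species_label, seq_id, sequence) from a FASTA file.

    Record ids are parsed as ``species_label<separator>seq_id``; records
    without the separator use the whole id as both label and id.
    """
    from Bio import SeqIO

    for rec in SeqIO.parse(str(path), "fasta"):
        if separator in rec.id:
            label, _, seq_id = rec.id.partition(separator)
        else:
            label, seq_id = rec.id, rec.id
        yield label, seq_id, str(rec.seq).upper()
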