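"""Restriction enzymes and in-silico digestion.

An enzyme is a named recognition site (IUPAC-degenerate allowed) with a cut
offset inside the site.  Digestion finds every occurrence of every concrete
expansion of the site — overlapping occurrences all cut — and returns the
top-strand fragment lengths.  Sticky-end overhang asymmetry is ignored:
fragment length is the distance between consecutive top-strand cuts, which
is what a gel resolves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from itertools import product

from Bio.Data.IUPACData import ambiguous_dna_values

__all__ = [
    "Enzyme", "FragmentProfile", "parse_enzyme_table", "load_default_enzymes",
    "expand_iupac", "cut_positions", "digest", "collapse_site_isoschizomers",
]

_IUPAC = {code: bases for code, bases in ambiguous_dna_values.items() if code != "X"}


@dataclass(frozen=True)
class Enzyme:
    """A restriction endonuclease.

    ``site`` is the IUPAC recognition sequence; the cut falls between
    positions ``cut_offset - 1`` and ``cut_offset`` of the site on the top
    strand.  ``group`` optionally names a site-isoschizomer group such as
    "CfoI/HhaI/HinP1I".
    """

    name: str
    site: str
    cut_offset: int
    group: str | None = None

    def __post_init__(self) -> None:
        site = self.site.upper()
        if len(site) < 2:
            raise ValueError(f"{self.name}: recognition site must be >= 2 nt")
        bad = set(site) - set(_IUPAC)
        if bad:
            raise ValueError(f"{self.name}: illegal IUPAC codes {sorted(bad)!r}")
        if not (0 <= self.cut_offset <= len(site)):
            raise ValueError(
                f"{self.name}: cut offset {self.cut_offset} outside site of "
                f"length {len(site)}")
        object.__setattr__(self, "site", site)


@dataclass(frozen=True)
class FragmentProfile:
    """Fragment-length multiset one enzyme yields from one amplicon.

    Lengths are stored sorted descending; they always sum to the amplicon
    length (a digestion conserves every nucleotide).
    """

    enzyme: str
    fragments: tuple[int, ...]
    amplicon_length: int

    def __post_init__(self) -> None:
        frags = tuple(sorted(self.fragments, reverse=True))
        object.__setattr__(self, "fragments", frags)
        if sum(frags) != self.amplicon_length:
            raise ValueError(
                f"{self.enzyme}: fragments sum to {sum(frags)}, "
                f"amplicon is {self.amplicon_length} nt")
        if frags and frags[-1] < 1:
            raise ValueError(f"{self.enzyme}: zero-length fragment")

    @property
    def n_fragments(self) -> int:
        return len(self.fragments)


def parse_enzyme_table(text: str) -> list[Enzyme]:
    """Parse a tab-delimited enzyme table: ``name<TAB>site`` with ``^`` marking the cut.

    Slash-separated names ("CfoI/HhaI/HinP1I") are kept verbatim and also
    recorded as a site-isoschizomer group label.  Duplicate names, missing
    carets and illegal codes are rejected with the offending line number.
    """
    enzymes: list[Enzyme] = []
    seen: set[str] = set()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"line {lineno}: expected 'name<TAB>site'")
        name, marked = parts[0].strip(), parts[1].strip().upper()
        if "^" not in marked:
            raise ValueError(f"line {lineno} ({name}): no ^ cut marker in site")
        if marked.count("^") > 1:
            raise ValueError(f"line {lineno} ({name}): more than one ^ marker")
        offset = marked.index("^")
        site = marked.replace("^", "")
        if name in seen:
            raise ValueError(f"line {lineno}: duplicate enzyme name {name!r}")
        seen.add(name)
        group = name if "/" in name else None
        try:
            enzymes.append(Enzyme(name=name, site=site, cut_offset=offset, group=group))
        except ValueError as exc:
            raise ValueError(f"line {lineno}: {exc}") from exc
    return enzymes


def load_default_enzymes() -> list[Enzyme]:
    """Load the bundled starter table of common commercial enzymes."""
    text = resources.files("fid.data").joinpath("enzymes.tsv").read_text()
    return parse_enzyme_table(text)


def expand_iupac(site: str) -> set[str]:
    """Expand a degenerate site into the set of concrete DNA strings it denotes."""
    site = site.upper()
    bad = set(site) - set(_IUPAC)
    if bad:
        raise ValueError(f"illegal IUPAC codes {sorted(bad)!r}")
    return {"".join(p) for p in product(*(_IUPAC[c] for c in site))}


def cut_positions(seq: str, enzyme: Enzyme) -> list[int]:
    """Top-strand cut coordinates of ``enzyme`` on a concrete sequence.

    Every occurrence of every expansion of the recognition site cuts,
    overlapping occurrences included; identical coordinates are merged and
    cuts at the very ends (coordinate 0 or len) are dropped since they free
    no fragment.  Non-ACGT bases in the sequence never match a site.
    """
    seq = seq.upper()
    if set(seq) - {"A", "C", "G", "T"}:
        warnings.warn("sequence contains ambiguous bases; they never match "
                      "a recognition site", stacklevel=2)
    sites = expand_iupac(enzyme.site)
    k = len(enzyme.site)
    cuts = {
        s + enzyme.cut_offset
        for s in range(len(seq) - k + 1)
        if seq[s:s + k] in sites
    }
    return sorted(c for c in cuts if 0 < c < len(seq))


def digest(amplicon, enzyme: Enzyme) -> FragmentProfile:
    """Digest an amplicon (an AmpliconRecord or a plain sequence string).

    Fragments are the consecutive differences of ``[0, cuts..., length]``.
    """
    seq = amplicon if isinstance(amplicon, str) else amplicon.sequence
    cuts = cut_positions(seq, enzyme)
    bounds = [0, *cuts, len(seq)]
    frags = tuple(b - a for a, b in zip(bounds, bounds[1:]))
    return FragmentProfile(enzyme=enzyme.name, fragments=frags,
                           amplicon_length=len(seq))


def collapse_site_isoschizomers(enzymes: list[Enzyme]) -> list[Enzyme]:
    """Merge enzymes sharing a recognition site into one entry per site.

    Site-isoschizomers differ only in cut offset; the induced length shifts
    (a few bp) are below gel resolution, so a grouped panel treats them as
    one enzyme.  The merged entry keeps the first member's cut offset and a
    slash-joined group name.
    """
    by_site: dict[str, list[Enzyme]] = {}
    for e in enzymes:
        by_site.setdefault(e.site, []).append(e)
    out = []
    for site, members in by_site.items():
        if len(members) == 1:
            out.append(members[0])
        else:
            name = "/".join(m.name for m in members)
            out.append(Enzyme(name=name, site=site,
                              cut_offset=members[0].cut_offset, group=name))
    return out
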