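"""Discriminative power of enzymes, singly and in combination.

Two species are indistinguishable under an enzyme tuple when their joint
fragment profiles are identical (same multiset of lengths per enzyme).
A species counts as identifiable when its profile class is a singleton.
Adding an enzyme refines the partition, so identifiability is monotone in
the tuple.  The indistinguishability graph collects the species no single
panel enzyme can resolve, weighting each edge by the percentage of panel
enzymes under which the two species share a profile.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Iterable, Sequence

import networkx as nx

from fid.profile_db import ProfileDB

__all__ = [
    "EnzymeStats", "profile_key", "enzyme_stats", "combined_stats",
    "indistinguishability_graph", "rank_enzymes",
]


@dataclass(frozen=True)
class EnzymeStats:
    """Discrimination statistics for one enzyme or one ordered tuple."""

    enzymes: tuple[str, ...]
    n_profiles: int
    n_identifiable: int
    n_species: int

    @property
    def fraction_identifiable(self) -> float:
        return self.n_identifiable / self.n_species


def profile_key(record, enzymes: Sequence[str]) -> Hashable:
    """Canonical joint-profile key: per enzyme the sorted fragment multiset.

    Equal keys under a tuple of enzymes mean the species are
    indistinguishable by that tuple.
    """
    key = []
    for name in enzymes:
        if name not in record.profiles:
            raise KeyError(f"enzyme {name!r} absent from the profile set of "
                           f"{record.species_label!r}")
        key.append(record.profiles[name].fragments)
    return tuple(key)


def _partition(db: ProfileDB, enzymes: Sequence[str]) -> dict[Hashable, list[str]]:
    classes: dict[Hashable, list[str]] = {}
    for r in db.records:
        classes.setdefault(profile_key(r, enzymes), []).append(r.species_label)
    return classes


def _stats(db: ProfileDB, enzymes: tuple[str, ...]) -> EnzymeStats:
    classes = _partition(db, enzymes)
    singletons = sum(1 for v in classes.values() if len(v) == 1)
    return EnzymeStats(enzymes=enzymes, n_profiles=len(classes),
                       n_identifiable=singletons, n_species=db.n_species)


def enzyme_stats(db: ProfileDB, enzyme: str) -> EnzymeStats:
    """Profile and identifiability counts for a single enzyme."""
    return _stats(db, (enzyme,))


def combined_stats(db: ProfileDB, enzymes: Sequence[str]) -> EnzymeStats:
    """Counts on the joint key of an ordered enzyme tuple (2-5 enzymes)."""
    t = tuple(enzymes)
    if not 2 <= len(t) <= 5:
        raise ValueError("combined_stats expects 2 to 5 enzymes")
    if len(set(t)) != len(t):
        raise ValueError(f"repeated enzyme in tuple {t}")
    return _stats(db, t)


def indistinguishability_graph(db: ProfileDB,
                               panel: Iterable[str] | None = None,
                               restrict_to_unresolved: bool = True) -> nx.Graph:
    """Graph of species pairs that no single panel enzyme can tell apart.

    Nodes are the species never uniquely identifiable by any single enzyme
    of the panel (pass ``restrict_to_unresolved=False`` to keep every
    species with at least one collision).  An edge joins two species that
    share an identical profile under at least one enzyme and are never
    distinguishable; its ``weight`` is the percentage of panel enzymes
    under which the profiles coincide.
    """
    panel = list(panel) if panel is not None else [e.name for e in db.enzymes]
    if not panel:
        raise ValueError("empty enzyme panel")

    never_identifiable: set[str] = set(db.species)
    share_counts: dict[frozenset[str], int] = {}
    for enzyme in panel:
        classes = _partition(db, (enzyme,))
        for members in classes.values():
            if len(members) == 1:
                never_identifiable.discard(members[0])
            else:
                for i, a in enumerate(members):
                    for b in members[i + 1:]:
                        pair = frozenset((a, b))
                        share_counts[pair] = share_counts.get(pair, 0) + 1

    g = nx.Graph()
    if restrict_to_unresolved:
        g.add_nodes_from(sorted(never_identifiable))
        keep = never_identifiable
    else:
        keep = {s for pair in share_counts for s in pair}
        g.add_nodes_from(sorted(keep))
    for pair, count in share_counts.items():
        a, b = sorted(pair)
        if a in keep and b in keep:
            g.add_edge(a, b, weight=100.0 * count / len(panel))
    return g


def rank_enzymes(db: ProfileDB) -> list[EnzymeStats]:
    """All single-enzyme stats, best first.

    Sorted by species identified (desc), then by number of distinct
    profiles (desc), then alphabetically — a deterministic total order.
    """
    table = [enzyme_stats(db, e.name) for e in db.enzymes]
    table.sort(key=lambda s: (-s.n_identifiable, -s.n_profiles, s.enzymes[0]))
    return table
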