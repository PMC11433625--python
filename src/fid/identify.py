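"""Progressive species identification and discriminative enzyme-panel search.

Identification proceeds in stages.  Stage 0 keeps every database species
whose in-silico amplicon length is compatible with the measured amplicon
length under the calibrated error model.  Each subsequent stage takes one
measured restriction profile and keeps, among the survivors, the species
whose reference profile attains the maximum match score; ties keep all
tied species, and stage order matters.  A match score is the size of a
maximum one-to-one assignment between measured and reference fragments,
where a pair is compatible when the reference length falls inside the
permissive range of the measured length.

The combination search enumerates ordered enzyme tuples, pruned the way a
full search is infeasible on a large panel: first-stage candidates must
identify every query alone with a bounded number of co-selected species,
and later-stage candidates must improve precision by a minimum fraction
when paired with another enzyme.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import permutations
from statistics import median
from typing import Iterable, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import maximum_bipartite_matching

from fid.profile_db import ProfileDB
from fid.restriction import FragmentProfile
from fid.size_error import CalibrationModel, filter_detectable, permissive_range

__all__ = [
    "MeasuredProfile", "IdentificationResult", "ComboSearchConfig",
    "ComboRow", "ComboResult", "match_profile", "identify_species",
    "evaluate_identification", "search_combinations", "enzyme_frequency",
]


@dataclass(frozen=True)
class MeasuredProfile:
    """A gel-measured fragment profile for one enzyme."""

    enzyme: str
    fragments: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "fragments",
                           tuple(sorted(self.fragments, reverse=True)))


@dataclass
class Stage:
    name: str
    candidates: list[str]
    scores: dict[str, float] = field(default_factory=dict)


@dataclass
class IdentificationResult:
    """Trace of the candidate sets surviving each selection stage."""

    stages: list[Stage]
    final_candidates: set[str]
    truth: str | None = None

    @property
    def identified(self) -> bool | None:
        if self.truth is None:
            return None
        return self.truth in self.final_candidates

    @property
    def precision(self) -> int | None:
        """Number of species co-selected with the true one (lower is better)."""
        if not self.identified:
            return None
        return len(self.final_candidates) - 1


def _ranges(model: CalibrationModel, lengths: Sequence[float]):
    return [permissive_range(model, x) for x in lengths]


def _match_score(query_ranges, ref_fragments, score_mode: str,
                 reference_penalty: float) -> float:
    nq, nr = len(query_ranges), len(ref_fragments)
    if nq == 0 or nr == 0:
        return 0.0
    compat = np.array([[lo <= r <= hi for r in ref_fragments]
                       for lo, hi in query_ranges], dtype=bool)
    if score_mode == "containment":
        matched = int(compat.any(axis=1).sum())
    elif score_mode == "matching":
        m = maximum_bipartite_matching(csr_matrix(compat), perm_type="column")
        matched = int((m != -1).sum())
    else:
        raise ValueError(f"unknown score mode {score_mode!r}")
    return matched - reference_penalty * (nr - matched)


def match_profile(query: MeasuredProfile, reference: FragmentProfile,
                  model: CalibrationModel, score_mode: str = "matching",
                  reference_penalty: float = 0.0) -> float:
    """Score the agreement between a measured and a reference profile.

    The default score is the size of a maximum one-to-one matching on the
    interval-compatibility bipartite graph; ``score_mode='containment'``
    instead counts measured fragments with at least one compatible
    reference fragment.  ``reference_penalty`` subtracts that multiple of
    the unmatched reference fragments (off by default: faint bands are
    routinely missed on gels and should not count against a species).
    """
    qf = filter_detectable(query.fragments, model.min_detectable)
    rf = filter_detectable(reference.fragments, model.min_detectable)
    return _match_score(_ranges(model, qf), rf, score_mode, reference_penalty)


def identify_species(db: ProfileDB, measured_amplicon: float,
                     queries: Sequence[MeasuredProfile],
                     model: CalibrationModel, truth: str | None = None,
                     score_mode: str = "matching",
                     reference_penalty: float = 0.0) -> IdentificationResult:
    """Run the progressive selection pipeline for one isolate.

    Candidate sets can only shrink from stage to stage; an empty stage
    yields an empty final set (no backtracking).  Raises ``KeyError`` when
    a query names an enzyme outside the database panel.
    """
    panel = {e.name for e in db.enzymes}
    for q in queries:
        if q.enzyme not in panel:
            raise KeyError(f"query enzyme {q.enzyme!r} not in database panel")

    lo, hi = permissive_range(model, measured_amplicon)
    survivors = [r.species_label for r in db.records
                 if lo <= r.amplicon.length <= hi]
    stages = [Stage(name="amplicon_length", candidates=list(survivors))]

    by_label = {r.species_label: r for r in db.records}
    for q in queries:
        qf = filter_detectable(q.fragments, model.min_detectable)
        if not qf:
            warnings.warn(f"profile for {q.enzyme} has no detectable fragments; "
                          "stage skipped", stacklevel=2)
            continue
        if not survivors:
            stages.append(Stage(name=q.enzyme, candidates=[]))
            continue
        ranges = _ranges(model, qf)
        scores = {}
        for label in survivors:
            ref = filter_detectable(by_label[label].profiles[q.enzyme].fragments,
                                    model.min_detectable)
            scores[label] = _match_score(ranges, ref, score_mode,
                                         reference_penalty)
        best = max(scores.values())
        survivors = [s for s in survivors if scores[s] == best]
        stages.append(Stage(name=q.enzyme, candidates=list(survivors),
                            scores=scores))
    return IdentificationResult(stages=stages,
                                final_candidates=set(survivors), truth=truth)


@dataclass
class EvaluationReport:
    """Per-query outcomes plus the aggregate identification metrics."""

    per_query: "object"          # pandas DataFrame: truth, identified, precision
    pct_identified: float
    precision_min: float | None
    precision_median: float | None
    precision_max: float | None


def evaluate_identification(db: ProfileDB, labelled_queries, model,
                            **kwargs) -> EvaluationReport:
    """Score a truth-labelled query set.

    ``labelled_queries`` is an iterable of
    ``(truth_label, measured_amplicon, [MeasuredProfile, ...])`` triples.
    A query is identified when its true species is in the final candidate
    set; its precision is the number of co-selected species.
    """
    import pandas as pd

    rows = []
    for truth, amplicon, profiles in labelled_queries:
        res = identify_species(db, amplicon, profiles, model, truth=truth,
                               **kwargs)
        rows.append({"truth": truth, "identified": bool(res.identified),
                     "precision": res.precision,
                     "n_final": len(res.final_candidates)})
    df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("no queries supplied")
    precs = [r["precision"] for r in rows if r["precision"] is not None]
    return EvaluationReport(
        per_query=df,
        pct_identified=100.0 * df["identified"].mean(),
        precision_min=min(precs) if precs else None,
        precision_median=median(precs) if precs else None,
        precision_max=max(precs) if precs else None,
    )


# ---------------------------------------------------------------------------
# combination search

@dataclass(frozen=True)
class ComboSearchConfig:
    """Pruning thresholds and sampling sizes for the combination search.

    Defaults mirror a panel-scale screen: a first-stage enzyme must
    identify every query on its own with fewer than 50 co-selected
    species (at most 80 such enzymes kept), later stages draw from the
    enzymes whose pairing improves precision by at least 25% (at most 22
    kept), and tuples are evaluated on 100 sampled query species.
    """

    max_coselected_single: int = 50
    min_precision_improvement: float = 0.25
    first_stage_panel_size: int = 80
    later_stage_panel_size: int = 22
    n_query_species: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        for f in ("max_coselected_single", "first_stage_panel_size",
                  "later_stage_panel_size", "n_query_species"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")


@dataclass(frozen=True)
class ComboRow:
    enzymes: tuple[str, ...]
    pct_identified: float
    median_coselected: float | None
    n_precise: int


@dataclass
class ComboResult:
    rows: list[ComboRow]
    stage1_enzymes: list[str]
    later_enzymes: list[str]
    n_queries: int
    reason: str | None = None


def _tuple_metrics(db, model, queries, enzymes, **kwargs) -> ComboRow:
    identified = 0
    precise = 0
    coselected = []
    for truth, amplicon, profiles in queries:
        ordered = [profiles[e] for e in enzymes]
        res = identify_species(db, amplicon, ordered, model, truth=truth,
                               **kwargs)
        if res.identified:
            identified += 1
            coselected.append(res.precision)
            if res.precision == 0:
                precise += 1
    return ComboRow(
        enzymes=tuple(enzymes),
        pct_identified=100.0 * identified / len(queries),
        median_coselected=median(coselected) if coselected else None,
        n_precise=precise,
    )


def search_combinations(db: ProfileDB, model: CalibrationModel,
                        k_range: Iterable[int] = (2, 3, 4, 5),
                        config: ComboSearchConfig | None = None,
                        exhaustive: bool = False,
                        **kwargs) -> ComboResult:
    """Evaluate ordered enzyme tuples on sampled self-queries, with pruning.

    Queries are the in-silico amplicon lengths and profiles of
    ``config.n_query_species`` species sampled with the configured seed;
    the calibrated error model supplies the tolerance.  With
    ``exhaustive=True`` the pruning is bypassed and every ordered tuple
    of panel enzymes is evaluated (only feasible on small panels).
    """
    config = config or ComboSearchConfig()
    rng = np.random.default_rng(config.seed)
    panel = [e.name for e in db.enzymes]
    ks = sorted(set(k_range))
    if any(k < 2 or k > 5 for k in ks):
        raise ValueError("tuple sizes must lie in 2..5")

    labels = db.species
    n_q = min(config.n_query_species, len(labels))
    sampled = list(rng.choice(labels, size=n_q, replace=False))
    queries = []
    for label in sampled:
        rec = db.record(label)
        profiles = {e: MeasuredProfile(enzyme=e,
                                       fragments=rec.profiles[e].fragments)
                    for e in panel}
        queries.append((label, float(rec.amplicon.length), profiles))

    if exhaustive:
        rows = [_tuple_metrics(db, model, queries, combo, **kwargs)
                for k in ks for combo in permutations(panel, k)]
        rows.sort(key=_row_order)
        return ComboResult(rows=rows, stage1_enzymes=panel,
                           later_enzymes=panel, n_queries=n_q)

    # Stage 1: enzymes that identify every query alone, with bounded precision.
    single = {e: _tuple_metrics(db, model, queries, (e,), **kwargs)
              for e in panel}
    stage1 = [e for e, row in single.items()
              if row.pct_identified == 100.0
              and row.median_coselected is not None
              and row.median_coselected < config.max_coselected_single]
    stage1.sort(key=lambda e: (single[e].median_coselected, e))
    stage1 = stage1[:config.first_stage_panel_size]
    if not stage1:
        return ComboResult(rows=[], stage1_enzymes=[], later_enzymes=[],
                           n_queries=n_q,
                           reason="no enzyme passed the single-enzyme criteria")

    # Stage 2: enzymes whose pairing improves precision enough.
    pair_rows = {}
    precise_by_enzyme: dict[str, int] = {}
    improves: set[str] = set()
    for e1 in stage1:
        for e2 in panel:
            if e2 == e1:
                continue
            row = _tuple_metrics(db, model, queries, (e1, e2), **kwargs)
            pair_rows[(e1, e2)] = row
            if row.median_coselected is None:
                continue
            base = single[e2].median_coselected
            if base is not None and base > 0:
                improvement = (base - row.median_coselected) / base
                if improvement >= config.min_precision_improvement:
                    improves.add(e2)
            elif base == 0:
                improves.add(e2)  # already perfectly precise alone
            precise_by_enzyme[e2] = precise_by_enzyme.get(e2, 0) + row.n_precise
    later = sorted(improves,
                   key=lambda e: (-precise_by_enzyme.get(e, 0), e))
    later = later[:config.later_stage_panel_size]
    if not later:
        return ComboResult(rows=[], stage1_enzymes=stage1, later_enzymes=[],
                           n_queries=n_q,
                           reason="no enzyme passed the pairwise "
                                  "precision-improvement criterion")

    rows = []
    for k in ks:
        for first in stage1:
            rest_pool = [e for e in later if e != first]
            for rest in permutations(rest_pool, k - 1):
                combo = (first, *rest)
                if combo in pair_rows:
                    rows.append(pair_rows[combo])
                else:
                    rows.append(_tuple_metrics(db, model, queries, combo,
                                               **kwargs))
    rows.sort(key=_row_order)
    return ComboResult(rows=rows, stage1_enzymes=stage1, later_enzymes=later,
                       n_queries=n_q)


def _row_order(row: ComboRow):
    return (-row.n_precise, -row.pct_identified,
            row.median_coselected if row.median_coselected is not None
            else float("inf"),
            row.enzymes)


def enzyme_frequency(result: ComboResult | Sequence[ComboRow],
                     precise_only: bool = True) -> dict[str, float]:
    """Percentage of combinations containing each enzyme.

    With ``precise_only`` the count runs over the combinations that
    precisely identified at least one query species.  Over k-tuples the
    percentages sum to k x 100.
    """
    rows = result.rows if isinstance(result, ComboResult) else list(result)
    if precise_only:
        rows = [r for r in rows if r.n_precise > 0]
    if not rows:
        return {}
    counts: dict[str, int] = {}
    for r in rows:
        for e in r.enzymes:
            counts[e] = counts.get(e, 0) + 1
    return {e: 100.0 * c / len(rows) for e, c in sorted(counts.items())}
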