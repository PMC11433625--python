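# Methods

This note records the models, algorithms and design choices behind `fid`,
in the order the pipeline runs them.

## Primer matching and amplicon extraction

A primer placement is scored by Hamming distance only: a placement at
offset *o* is accepted when the overlap between primer and sequence is at
least `min_overlap` (default 18 nt, so primers may hang off sequence
ends) and the substitution count does not exceed
`floor(error_rate × overlap)`. Indels are deliberately out of scope —
the error model is "errors in the match divided by the length of the
matching part", and substitution-only matching makes the accepted set
easy to characterise and test against an exhaustive sliding-window scan.
IUPAC codes in the primer match their base sets; ambiguous bases in the
*genome* never match (conservative: an N is evidence of nothing).

Extraction searches for a convergent pair — a forward-primer match
followed by a match of the reverse complement of the reverse primer — and
returns the primer-to-primer span. Pass order: given strand at the
standard rate (default 0.10), given strand at the relaxed rate (0.20),
then the same two passes on the reverse complement with the result
re-oriented forward; flags on the record say which fallback fired.
Products shorter than `min_amplicon_len` (default 200 nt) are rejected in
every pass. When several convergent spans exist, the 5'-most, innermost
one wins and the alternates' lengths are attached to the record alongside
a warning; rDNA arrays carry many identical repeats, so the first repeat
is as good as any. Reported length includes both primer footprints by
default, because that is what the measured PCR product contains; a flag
excludes them. Coordinates are 0-based, half-open throughout.

## Digestion

Recognition sites are expanded over their IUPAC degeneracies and every
occurrence — overlapping ones included — contributes a cut at
`start + cut_offset` on the top strand; identical coordinates merge.
Fragment lengths are consecutive differences of `[0, cuts…, length]`, so
they always sum to the amplicon length (asserted at construction). Only
top-strand coordinates are modelled: sticky-end overhangs shift lengths
by at most a few bases, far below gel resolution. Site-isoschizomers
(same site, different offset) stay distinct by default;
`collapse_site_isoschizomers` merges them into one profile per site for
gel-resolution work. Enzymes whose site occurs in no database amplicon
are dropped from the panel at build time — they carry no information and
would only dilute panel-percentage statistics.

## Database and discrimination

The database keeps one record per species (first FASTA record with a
valid amplicon wins; the rest go to a skip report) and groups species
whose amplicon sequences are exactly identical — such species are
indistinguishable under every enzyme, which the build asserts. Length
statistics are computed over one representative per unique sequence.

A species is *identifiable* under an enzyme tuple when its joint
fragment-multiset key is a singleton class; this is the only reading
under which "profiles associated with a single species" is a count of
species. Adding an enzyme refines the partition, so identifiability is
monotone — a property the tests check exhaustively on all pairs. The
indistinguishability graph is restricted to species no single panel
enzyme identifies; edge weight is the percentage of retained panel
enzymes under which the two species share a profile (a flag widens the
node set to any species with at least one collision).

## Size-error calibration

Measured size is regressed on true size — the physical direction of the
noise — and the band is inverted for querying:

* `lm`: ordinary least squares; σ is the residual SD (ddof = 2).
* `varpow`: Var(εᵢ) = σ²·|μᵢ|^{2δ} with corr(εᵢ, εⱼ) = φ^{|rankᵢ−rankⱼ|}
  inside a lane, ranks being the migration order (descending size) —
  lanes are the only natural grouping in gel data. The likelihood is
  maximized by profiling β (iterated GLS given (δ, φ), weights from
  fitted means) and σ² (analytic), then running Nelder–Mead over
  (δ, atanh φ) from the origin. Starting at (0, 0) makes the `lm`
  solution the first iterate, so the fitted log-likelihood can never
  fall below the nested OLS one — an invariant rather than a hope.
  Convergence tolerance is 1e-8 on the log-likelihood; non-convergence
  raises with the last iterate attached.

The *permissive range* of a measured value m is the set of true sizes x
with |m − μ(x)| ≤ z·σ·|μ(x)|^δ, μ(x) = β₀ + β₁x, z the two-sided normal
quantile at the configured level (default 0.95 — the level is a modelling
choice, not an estimate). The band is inverted with Brent root-finding on
μ (closed form when δ = 0); the inversion assumes the half-width grows
sub-linearly (z·σ·δ·μ^{δ−1} < 1), which holds for any gel-realistic
parameters, and the lower endpoint clips near zero. Parameter uncertainty
is *not* propagated — the band is plug-in; with ~10³ calibration points
the sampling error of the fit is small against gel noise. Coverage of the
range equals the nominal level exactly when data come from the model,
which the tests confirm by simulation.

Fragments below `min_detectable` (default 100 nt) are excluded from both
query and reference sides during identification: such bands are invisible
or unquantifiable on agarose. In-silico discrimination keeps all
fragments — it describes sequences, not gels.

## Identification

Stage 0 keeps species whose in-silico amplicon length lies in the
permissive range of the measured amplicon length. Each later stage scores
survivors against one measured profile and keeps the argmax set; ties
keep everything — the output is a candidate set, not a forced call.
The score is the size of a maximum one-to-one matching between measured
and reference fragments, a pair being compatible when the reference
length falls in the measured length's permissive range (solved exactly as
bipartite matching; an exhaustive-assignment oracle checks it in tests).
A containment mode (count measured fragments with ≥ 1 compatible
reference) is available, as is an optional penalty per unmatched
reference fragment — off by default because faint bands routinely go
unseen on gels and should not count against a species. Empty stages yield
an empty final set without backtracking: an over-tight measurement is a
failed identification, not a licence to relax earlier decisions.
*Identification* means the true species is in the final set; *precision*
is the number of co-selected species (lower is better).

## Combination search

Ordered tuples of 2–5 enzymes are evaluated on self-queries of sampled
database species (in-silico lengths and profiles as inputs, the
calibrated model supplying tolerance). The full ordered space is
astronomically large (permutations of 5 from 143 exceed 55 billion), so
the search prunes: first-stage candidates must identify every query alone
with median co-selected species below a cap (default 50; at most 80
kept, best precision first), later-stage candidates must improve an
enzyme's precision by at least 25% when paired (at most 22 kept, ranked
by precise identifications in pairs). An `exhaustive` switch bypasses
pruning on small panels, and the tests require the pruned rows to match
the exhaustive ones exactly. Query sampling is seeded and recorded.

## Synthetic data

Genomes are `pad + forward primer + core + revcomp(reverse primer) +
pad`. Cores are first scrubbed of every planted enzyme's site
(mutate-and-rescan), then concrete site instances are inserted at
non-overlapping offsets; the assembled amplicon is re-scanned with a
naive matcher *local to the generator* and rejected unless the occurrence
set equals the planted one, so the truth table is exact and the check is
independent of the digestion code under test. Pads and primer
neighbourhoods are screened against near-matches of any primer
orientation so extraction has exactly one valid convergent pair. Primer
copies optionally carry up to two planted substitutions and genomes can
be emitted reverse-complemented, exercising the relaxed-rate and
reverse-complement fallbacks. Defaults (cores 200–1000 nt, pads
20–60 nt) put amplicons in the barcode-length range.

Calibration data and measured profiles apply the noise model exactly as
specified above; default noise parameters (β₀ = 2, β₁ = 0.97, σ = 1.5,
δ = 0.6, φ = 0.4, dropout < 100 nt) describe a realistic agarose gel with
mild size-dependent error and moderate lane correlation. What the
generator does **not** emulate: real ITS secondary structure, shared
evolutionary history between species (sequences are independent), copy-
number variation of the rDNA array, partial digestion, and gel artefacts
beyond the parametric noise (smiling, ladder misreads). Passing tests
therefore demonstrate algorithmic correctness and calibrated-noise
robustness, not performance on any particular real taxon set.

## Problem sizes and numerical choices

The test suite and acceptance script run at sizes chosen to make the
statistical assertions stable: 100-genome extraction closure, 10³
random digestion pairs, 50-species × all-enzyme-pairs refinement checks,
50 calibration replicates of 40 lanes × 8 bands, 10⁴ coverage draws,
and an 8-enzyme × 20-species exhaustive combination search. Tolerances:
median |δ̂ − δ| and |φ̂ − φ| below 0.15 at that calibration size, coverage
within ±2% of nominal, everything combinatorial exact. Ties are broken
deterministically everywhere (alphabetically last), and all randomness
flows from explicit seeds — no global generator state.

## Known limitations

* Substitution-only primer matching; indel-rich primer sites will be
  missed.
* Type IIS enzymes cutting outside their recognition site, methylation
  sensitivity and partial digestion are not modelled.
* The permissive range is a plug-in band; for very small calibration
  sets it will undercover.
* The bundled enzyme table is a starter panel of common commercial
  enzymes, not an exhaustive registry; users supply their own table for
  serious panel optimisation.
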