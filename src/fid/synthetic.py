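"""Synthetic genomes, calibration data and noisy gel measurements.

The generator plants primer binding sites and restriction sites into random
sequence so every downstream quantity — amplicon span, fragment lengths,
duplicate groups — is known exactly by construction.  Planted truth is
verified with a small naive scanner local to this module, so it stays
independent of the extraction and digestion code it is used to test.

Gel noise follows the calibration model: measured = beta0 + beta1*true +
eps with Var(eps) = sigma^2*|mu|^(2*delta) and AR(1) correlation along the
migration order; fragments below the dropout threshold vanish, as bands
under ~100 bp do on agarose gels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import floor, sqrt
from pathlib import Path

import numpy as np

from fid.insilico_pcr import DEFAULT_PRIMERS, PrimerPair
from fid.restriction import Enzyme, expand_iupac
from fid.identify import MeasuredProfile
from fid.size_error import CalibrationPoint

__all__ = [
    "SynthSpec", "NoiseSpec", "SpeciesTruth", "SyntheticDataset",
    "synth_genomes", "synth_calibration", "simulate_measured_profile",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class SynthSpec:
    """Layout of a synthetic genome set.

    Each genome is ``pad + forward primer + core + revcomp(reverse primer)
    + pad``; ``planted_enzymes`` fixes how many recognition sites of each
    enzyme the core carries.  ``duplicate_fraction`` of the species reuse
    an earlier species' amplicon verbatim (their pads differ), emulating
    distinct species with identical barcode sequences.  ``primer_mismatches``
    is the maximum number of substitutions planted into each primer copy
    (the actual count is drawn uniformly), and ``reverse_complement_fraction``
    of the genomes are emitted reverse-complemented.
    """

    n_species: int = 10
    core_length_range: tuple[int, int] = (200, 1000)
    planted_enzymes: tuple[tuple[Enzyme, int], ...] = ()
    pad_length_range: tuple[int, int] = (20, 60)
    duplicate_fraction: float = 0.0
    primer_mismatches: int = 0
    reverse_complement_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise ValueError("n_species must be positive")
        if not 0 <= self.duplicate_fraction < 1:
            raise ValueError("duplicate_fraction must lie in [0, 1)")
        for lo, hi in (self.core_length_range, self.pad_length_range):
            if lo < 1 or hi < lo:
                raise ValueError("length ranges must be positive and ordered")


@dataclass(frozen=True)
class NoiseSpec:
    """Gel measurement-noise parameters (defaults: a realistic agarose gel)."""

    beta0: float = 2.0
    beta1: float = 0.97
    sigma: float = 1.5
    delta: float = 0.6
    phi: float = 0.4
    dropout_below: float = 100.0

    def __post_init__(self) -> None:
        if not -1.0 < self.phi < 1.0:
            raise ValueError("|phi| must be < 1")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


@dataclass
class SpeciesTruth:
    """Exact planted layout for one species."""

    label: str
    amplicon: str
    length: int
    fragments: dict[str, tuple[int, ...]]
    duplicate_of: str | None = None


@dataclass
class SyntheticDataset:
    records: list[tuple[str, str]]          # (fasta id, genome sequence)
    truth: dict[str, SpeciesTruth]
    spec: SynthSpec = field(repr=False, default=None)

    @property
    def fasta_text(self) -> str:
        return "".join(f">{rid}\n{seq}\n" for rid, seq in self.records)

    def write_fasta(self, path) -> Path:
        path = Path(path)
        path.write_text(self.fasta_text)
        return path


# -- local naive scanner (independent of fid.restriction) -------------------

def _site_occurrences(seq: str, site: str) -> list[int]:
    concrete = expand_iupac(site)
    k = len(site)
    return [i for i in range(len(seq) - k + 1) if seq[i:i + k] in concrete]


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def _primer_clear(seq: str, primers: PrimerPair, allowed: set[int],
                  max_errors: int = 4, min_overlap: int = 18) -> bool:
    """True when no primer variant nearly matches outside the allowed offsets.

    Checks all full-length windows of the four primer orientations plus
    end-of-sequence partial overlaps down to ``min_overlap`` nt.
    """
    variants = {primers.forward, _revcomp(primers.forward),
                primers.reverse, _revcomp(primers.reverse)}
    for v in variants:
        k = len(v)
        for i in range(len(seq) - k + 1):
            if i in allowed:
                continue
            if _hamming(seq[i:i + k], v) <= max_errors:
                return False
        for ov in range(min_overlap, k):
            # primer hanging off the left or right end
            if _hamming(seq[:ov], v[k - ov:]) <= floor(0.2 * ov):
                return False
            if _hamming(seq[len(seq) - ov:], v[:ov]) <= floor(0.2 * ov):
                return False
    return True


def _random_seq(rng, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=n))


def _scrub_sites(rng, seq: str, sites: list[str], max_rounds: int = 200) -> str:
    """Mutate a sequence until it contains no occurrence of any listed site."""
    s = list(seq)
    for _ in range(max_rounds):
        hits = []
        text = "".join(s)
        for site in sites:
            hits.extend((i, len(site)) for i in _site_occurrences(text, site))
        if not hits:
            return text
        i, k = hits[0]
        j = i + int(rng.integers(0, k))
        choices = [b for b in _BASES if b != s[j]]
        s[j] = choices[int(rng.integers(0, 3))]
    raise RuntimeError("could not scrub planted sites from random core")


def _mutate(rng, seq: str, n_mut: int) -> str:
    if n_mut == 0:
        return seq
    s = list(seq)
    positions = rng.choice(len(s), size=min(n_mut, len(s)), replace=False)
    for j in positions:
        choices = [b for b in _BASES if b != s[j]]
        s[j] = choices[int(rng.integers(0, 3))]
    return "".join(s)


def _build_core(rng, spec: SynthSpec) -> tuple[str, dict[str, list[int]]]:
    """A random core with exactly the requested site occurrences planted."""
    site_strs = [e.site for e, _ in spec.planted_enzymes]
    lo, hi = spec.core_length_range
    for _ in range(200):
        n = int(rng.integers(lo, hi + 1))
        core = _scrub_sites(rng, _random_seq(rng, n), site_strs)
        slots: list[tuple[int, int]] = []   # occupied (start, end) spans
        placements: dict[str, list[int]] = {}
        ok = True
        for enzyme, count in spec.planted_enzymes:
            k = len(enzyme.site)
            placements[enzyme.name] = []
            for _ in range(count):
                for _attempt in range(100):
                    off = int(rng.integers(0, n - k + 1))
                    if all(off + k <= s or off >= e for s, e in slots):
                        break
                else:
                    ok = False
                    break
                slots.append((off, off + k))
                placements[enzyme.name].append(off)
                concrete = sorted(expand_iupac(enzyme.site))
                chosen = concrete[int(rng.integers(0, len(concrete)))]
                core = core[:off] + chosen + core[off + k:]
            if not ok:
                break
        if not ok:
            continue
        # insertion may have spawned extra occurrences spanning boundaries
        if all(sorted(_site_occurrences(core, e.site)) == sorted(placements[e.name])
               for e, _ in spec.planted_enzymes):
            return core, placements
    raise RuntimeError("could not plant the requested sites; core too short "
                       "or sites too dense")


def synth_genomes(spec: SynthSpec,
                  primers: PrimerPair = DEFAULT_PRIMERS) -> SyntheticDataset:
    """Generate genomes with planted primer and restriction sites plus exact truth.

    The truth table lists, per species, the amplicon sequence the primers
    delimit and the fragment lengths every planted enzyme produces,
    computed from the planted site offsets with the local naive scanner.
    Generation is deterministic in ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    records: list[tuple[str, str]] = []
    truth: dict[str, SpeciesTruth] = {}
    originals: list[str] = []

    for i in range(spec.n_species):
        label = f"sp{i:03d}"
        duplicate_of = None
        if originals and rng.random() < spec.duplicate_fraction:
            duplicate_of = originals[int(rng.integers(0, len(originals)))]
            amplicon = truth[duplicate_of].amplicon
        else:
            amplicon = None

        for _attempt in range(200):
            if amplicon is None:
                core, _ = _build_core(rng, spec)
                n_mut_f = int(rng.integers(0, spec.primer_mismatches + 1))
                n_mut_r = int(rng.integers(0, spec.primer_mismatches + 1))
                fwd = _mutate(rng, primers.forward, n_mut_f)
                rev_site = _mutate(rng, _revcomp(primers.reverse), n_mut_r)
                candidate_amp = fwd + core + rev_site
                # planted sites must survive assembly (primer junctions could
                # create or destroy occurrences)
                if not all(
                    len(_site_occurrences(candidate_amp, e.site)) == c
                    for e, c in spec.planted_enzymes
                ):
                    continue
            else:
                candidate_amp = amplicon

            lo, hi = spec.pad_length_range
            pad1 = _random_seq(rng, int(rng.integers(lo, hi + 1)))
            pad2 = _random_seq(rng, int(rng.integers(lo, hi + 1)))
            genome = pad1 + candidate_amp + pad2
            allowed = {len(pad1),
                       len(pad1) + len(candidate_amp) - len(primers.reverse)}
            if not _primer_clear(genome, primers, allowed):
                continue
            flipped = rng.random() < spec.reverse_complement_fraction
            if flipped:
                genome = _revcomp(genome)
            break
        else:
            raise RuntimeError(f"could not assemble a clean genome for {label}")

        amplicon = candidate_amp
        if duplicate_of is None:
            originals.append(label)
        fragments = {}
        for enzyme, _count in spec.planted_enzymes:
            cuts = sorted({o + enzyme.cut_offset
                           for o in _site_occurrences(amplicon, enzyme.site)}
                          - {0, len(amplicon)})
            bounds = [0, *cuts, len(amplicon)]
            fragments[enzyme.name] = tuple(
                sorted((b - a for a, b in zip(bounds, bounds[1:])),
                       reverse=True))
        truth[label] = SpeciesTruth(label=label, amplicon=amplicon,
                                    length=len(amplicon), fragments=fragments,
                                    duplicate_of=duplicate_of)
        records.append((f"{label}|synth{i:03d}", genome))
    return SyntheticDataset(records=records, truth=truth, spec=spec)


def _ar1_noise(rng, n: int, phi: float) -> np.ndarray:
    """AR(1) series with unit marginal variance."""
    z = rng.standard_normal(n)
    u = np.empty(n)
    u[0] = z[0]
    for i in range(1, n):
        u[i] = phi * u[i - 1] + sqrt(1.0 - phi * phi) * z[i]
    return u


def synth_calibration(noise: NoiseSpec, n_lanes: int = 40,
                      fragments_per_lane: int = 8, seed: int = 0,
                      size_range: tuple[float, float] = (100.0, 1000.0),
                      ) -> list[CalibrationPoint]:
    """Simulate a (expected, measured, lane, rank) calibration dataset.

    Within each lane, fragments are ordered by descending true size (the
    migration order) and their errors follow the AR(1), power-variance
    noise model.
    """
    rng = np.random.default_rng(seed)
    points: list[CalibrationPoint] = []
    for lane in range(n_lanes):
        x = np.sort(rng.uniform(*size_range, size=fragments_per_lane))[::-1]
        mu = noise.beta0 + noise.beta1 * x
        eps = noise.sigma * np.abs(mu) ** noise.delta * _ar1_noise(
            rng, fragments_per_lane, noise.phi)
        y = np.maximum(mu + eps, 1.0)
        for rank, (xi, yi) in enumerate(zip(x, y)):
            points.append(CalibrationPoint(expected=float(xi),
                                           measured=float(yi),
                                           lane_id=f"lane{lane:03d}",
                                           rank_in_lane=rank))
    return points


def simulate_measured_profile(true_fragments, noise: NoiseSpec,
                              seed: int | np.random.Generator = 0,
                              enzyme: str = "") -> MeasuredProfile:
    """Corrupt a true fragment profile the way a gel would.

    Fragments below ``noise.dropout_below`` vanish (undetectable bands);
    the rest acquire AR(1)-correlated, size-dependent measurement error in
    migration order.  ``true_fragments`` may be a FragmentProfile or any
    iterable of lengths.
    """
    if hasattr(true_fragments, "fragments"):
        enzyme = enzyme or true_fragments.enzyme
        true_fragments = true_fragments.fragments
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    kept = sorted((f for f in true_fragments if f >= noise.dropout_below),
                  reverse=True)
    if not kept:
        return MeasuredProfile(enzyme=enzyme, fragments=())
    x = np.array(kept, dtype=float)
    mu = noise.beta0 + noise.beta1 * x
    eps = noise.sigma * np.abs(mu) ** noise.delta * _ar1_noise(rng, len(x),
                                                               noise.phi)
    y = np.maximum(mu + eps, 1.0)
    return MeasuredProfile(enzyme=enzyme, fragments=tuple(float(v) for v in y))
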