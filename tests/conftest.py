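"""Shared fixtures: toy profile databases, enzyme panels, noise-free models."""

import numpy as np
import pytest

from fid import CalibrationModel, ProfileDB, SpeciesProfileSet
from fid.insilico_pcr import AmpliconRecord
from fid.restriction import Enzyme, FragmentProfile, load_default_enzymes


@pytest.fixture(scope="session")
def enzyme_map():
    return {e.name: e for e in load_default_enzymes()}


@pytest.fixture
def exact_model():
    """Identity calibration with zero noise: measured == true."""
    return CalibrationModel(kind="lm", beta0=0.0, beta1=1.0, sigma=0.0,
                            min_detectable=0.0)


def _seq_for(label: str, length: int) -> str:
    """A deterministic per-label sequence of the requested length."""
    import zlib

    rng = np.random.default_rng(zlib.crc32(label.encode()))
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


def make_toy_db(species_fragments: dict[str, dict[str, list[int]]],
                shared_sequences: dict[str, str] | None = None) -> ProfileDB:
    """Build a ProfileDB directly from fragment lists.

    ``species_fragments`` maps species -> enzyme -> fragment lengths (all
    enzymes must sum to the same amplicon length per species).
    ``shared_sequences`` maps a species to another whose amplicon sequence
    it copies verbatim (to exercise duplicate grouping).
    """
    shared_sequences = shared_sequences or {}
    enzyme_names = sorted({e for frag in species_fragments.values() for e in frag})
    seqs: dict[str, str] = {}
    records = []
    for label, by_enzyme in species_fragments.items():
        lengths = {sum(f) for f in by_enzyme.values()}
        assert len(lengths) == 1, f"{label}: inconsistent fragment sums"
        length = lengths.pop()
        if label in shared_sequences:
            seq = seqs[shared_sequences[label]]
            assert len(seq) == length
        else:
            seq = _seq_for(label, length)
        seqs[label] = seq
        amp = AmpliconRecord(species_label=label, seq_id=label, sequence=seq,
                             length=length)
        profiles = {
            e: FragmentProfile(enzyme=e, fragments=tuple(by_enzyme[e]),
                               amplicon_length=length)
            for e in enzyme_names
        }
        records.append(SpeciesProfileSet(species_label=label, amplicon=amp,
                                         profiles=profiles))
    enzymes = [Enzyme(name=e, site="NN", cut_offset=1) for e in enzyme_names]
    from fid.profile_db import dedupe_sequences
    return ProfileDB(records=records, enzymes=enzymes,
                     duplicate_groups=dedupe_sequences(records))


@pytest.fixture
def toy_db():
    """Three species; E1 merges A and B, E2 separates everything."""
    return make_toy_db({
        "A": {"E1": [100, 200], "E2": [120, 180]},
        "B": {"E1": [100, 200], "E2": [150, 150]},
        "C": {"E1": [300], "E2": [90, 210]},
    })


def random_toy_db(rng: np.random.Generator, n_species: int,
                  enzyme_names: list[str], amplicon_length: int = 600,
                  n_profiles_pool: int = 6) -> ProfileDB:
    """A db whose profiles are drawn from a small pool, forcing collisions."""
    pools = {}
    for e in enzyme_names:
        pool = []
        for _ in range(n_profiles_pool):
            n_cuts = int(rng.integers(0, 4))
            cuts = sorted(rng.choice(np.arange(1, amplicon_length),
                                     size=n_cuts, replace=False).tolist())
            bounds = [0, *cuts, amplicon_length]
            pool.append([b - a for a, b in zip(bounds, bounds[1:])])
        pools[e] = pool
    species = {
        f"sp{i:03d}": {e: pools[e][int(rng.integers(0, n_profiles_pool))]
                       for e in enzyme_names}
        for i in range(n_species)
    }
    return make_toy_db(species)
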