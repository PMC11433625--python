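"""Extract a primer-delimited amplicon from a genome and digest it.

Builds one synthetic genome with a planted ITS-style amplicon, recovers the
amplicon with the degenerate-primer scanner, and cuts it with HaeIII.
"""

from fid import extract_amplicon, digest
from fid.restriction import load_default_enzymes
from fid.synthetic import SynthSpec, synth_genomes

enzymes = {e.name: e for e in load_default_enzymes()}
spec = SynthSpec(n_species=1, planted_enzymes=((enzymes["HaeIII"], 2),),
                 seed=7)
dataset = synth_genomes(spec)
(rid, genome), truth = dataset.records[0], next(iter(dataset.truth.values()))

record = extract_amplicon(genome, species_label=truth.label)
profile = digest(record, enzymes["HaeIII"])

print(f"genome length: {len(genome)} nt")
print(f"amplicon length: {record.length} nt (planted: {truth.length})")
print(f"HaeIII fragments: {profile.fragments}")
# The two planted GGCC sites split the amplicon into three fragments whose
# lengths sum back to the amplicon length — nothing is lost in digestion.
assert sum(profile.fragments) == record.length
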