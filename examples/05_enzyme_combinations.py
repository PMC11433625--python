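"""Search enzyme combinations that pin a species down precisely.

On a small synthetic database the ordered pairs and triples of enzymes are
scored by how many self-queries they identify with zero co-selected
species; the pruned search matches an exhaustive one on this scale.
"""

import tempfile
from pathlib import Path

from fid import (CalibrationModel, ComboSearchConfig, build_profile_db,
                 enzyme_frequency, search_combinations)
from fid.restriction import load_default_enzymes
from fid.synthetic import SynthSpec, synth_genomes

enzymes = {e.name: e for e in load_default_enzymes()}
plant = tuple((enzymes[n], k) for n, k in
              [("HaeIII", 2), ("AluI", 1), ("RsaI", 2), ("HinfI", 1)])
dataset = synth_genomes(SynthSpec(n_species=25, planted_enzymes=plant,
                                  core_length_range=(300, 900), seed=9))
with tempfile.TemporaryDirectory() as tmp:
    db = build_profile_db(dataset.write_fasta(Path(tmp) / "g.fa"),
                          enzymes=[e for e, _ in plant])

model = CalibrationModel(kind="varpow", beta0=2.0, beta1=0.97, sigma=1.5,
                         delta=0.6, phi=0.4)
config = ComboSearchConfig(n_query_species=25, seed=4,
                           first_stage_panel_size=4, later_stage_panel_size=4)
result = search_combinations(db, model, k_range=(2, 3), config=config)

print(f"first-stage enzymes: {result.stage1_enzymes}")
print(f"later-stage enzymes: {result.later_enzymes}")
print(f"{len(result.rows)} ordered combinations evaluated on "
      f"{result.n_queries} query species; top five:")
for row in result.rows[:5]:
    print(f"  {'+'.join(row.enzymes):30s} identified {row.pct_identified:5.1f}%"
          f"  median co-selected {row.median_coselected}"
          f"  precise {row.n_precise}/{result.n_queries}")
# 'precise' counts queries whose final candidate set was exactly the true
# species; the frequency table shows which enzymes drive those successes.
for enzyme, pct in enzyme_frequency(result).items():
    print(f"  {enzyme}: in {pct:.0f}% of precise combinations")
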