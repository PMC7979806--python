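"""Cross-species conservation calling on a simulated ortholog family.

Diverges an ancestral protein to 25% identity while protecting a conserved
core, then calls which mutated positions are conserved — the same logic used
to ask whether a human ATM/ATR residue is identical in yeast Mec1/Tel1.
"""

from pikkmap import (
    AlignedPair,
    OrthologSpec,
    call_conserved,
    correspondence,
    global_align,
    map_residue,
    percent_identity,
    simulate_ortholog,
)
from pikkmap.synthetic import random_protein

human = random_protein(400, seed=1)
mutated_positions = [7, 40, 150, 200, 333]
ortho = simulate_ortholog(
    human,
    OrthologSpec(name="mec1_like", target_identity=0.25,
                 protected=frozenset([7, 200, 333]), seed=4),
)
pair = AlignedPair("human", ortho.name, ortho.row_ancestral, ortho.row_ortholog)
print(f"realized identity: {percent_identity(pair):.1f}% of alignment columns "
      f"(target 25%)")

calls = call_conserved(mutated_positions, human, {ortho.name: pair})
for c in calls:
    print(f"position {c.human_pos:>3} ({c.human_aa}): {c.status[ortho.name]:<12}"
          f" conserved={c.conserved}")
print("protected-core positions are always called conserved;")
print("the rest depend on where random substitutions landed")

# residue correspondence: map a position across a freshly computed alignment
short = global_align("ACDEFGHIK", "ACDFGHIK")
corr = correspondence(short)
print(f"after deleting E, position 5 (F) maps to partner position "
      f"{map_residue(corr, 5, 'a')}")
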