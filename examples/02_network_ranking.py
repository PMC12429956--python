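"""Which networks matter most for one disease group?

Ranks networks for a disease group by the disease-gene score SNG (how many
group disease genes fall in the network) and the drug score SND (how many
drug-disease pairs have a target there), then checks the top SNG network
against the generator's planted group structure.
"""

from netdrugmap import Phase, SynthConfig, generate_universe, group_score_table, top_k

universe, truth = generate_universe(SynthConfig(seed=1))
group = "Neu"  # nervous-system disease group

table = group_score_table(universe, group, phase=Phase.ALL)
print(f"group {group}: {table.total_sum} drug-disease pairs target any network\n")

print("top 5 networks by disease-gene score (SNG):")
for nid, score in top_k(table.sng, k=5, strict=True):
    in_pool = "planted" if nid in truth.group_pools[group] else "background"
    print(f"  {nid}: SNG={score}  SND={table.snd.get(nid, 0)}  [{in_pool}]")

best = top_k(table.sng, k=1, strict=True)[0][0]
print(f"\ntop network {best} is in the group's planted pool: "
      f"{best in truth.group_pools[group]}")
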