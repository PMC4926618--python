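"""Compare a molecular delimitation against morphospecies labels."""
from barcodiv import SimConfig, compare_partitions, sim_survey

survey = sim_survey(SimConfig(n_species=15, samples_per_species=4,
                              morph_lump=0.2, morph_split=0.1, seed=6))
cmp = compare_partitions(survey.true_partition, survey.morphospecies)
print(f"adjusted Rand index : {cmp.adjusted_rand:.3f}")
for cls, count in sorted(cmp.class_counts.items()):
    print(f"  {cls:<6}: {count}")
print()
print("'split' groups are morphospecies that lump several molecular")
print("species (sorting error or cryptic diversity); 'lump' groups are")
print("species that morphology split (e.g. polymorphism or dimorphism).")
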