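"""How fast does a large microbial population explore point mutations?

With N_e ~ 1e6 haploid individuals, a mutation rate of 5e-10 per bp per
division, and a 12-Mb genome, every base pair is hit somewhere in the
population every couple of thousand generations — so the mutational
neighborhood of the reference genome is explored nearly completely on
evolutionary timescales, and recurrent emergence of the same variant is
plausible rather than exotic.
"""

from remergence import exploration_timescales

est = exploration_timescales(n_e=1e6, mu=5e-10, genome_size=1.2e7)
print(f"mutations per genome per generation:     {est.muts_per_genome_per_gen:.1e}")
print(f"mutations population-wide per generation: {est.muts_per_population_per_gen:.1e}")
print(f"generations until a given bp is hit:      {est.generations_per_bp_hit:.1e}")
print(f"... for all three alternative bases:      {est.generations_all_three_alts:.1e}")
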