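"""Domain consensus, radical substitutions, and the longevity quotient.

A 54-position domain alignment is generated for two taxa with 5 species of
taxon A deviating radically (different physicochemical group) at position
19.  Deviation counting recovers the plan, and species carrying the deviant
residue are planted with a +17% higher median longevity quotient, which the
group comparison recovers.
"""

from evorate import (
    LqModel, PlannedDeviation, TraitModel, deviation_counts,
    generate_domain_alignment, generate_traits, residue_group_lq_compare,
)

plan = (PlannedDeviation(position=19, taxon="taxA", n_species=5, radical=True),)
aln, taxon_map, consensus = generate_domain_alignment(
    {"taxA": 30, "taxB": 24}, plan, n_positions=54, seed=3
)

for mode in ("all", "radical"):
    table = deviation_counts(aln, consensus, taxon_map, mode)
    print(f"{mode:8s} deviations at position 19: "
          f"taxA={table.counts['taxA'][18]}  taxB={table.counts['taxB'][18]}  "
          f"(conservative positions: taxA={table.conservative_positions['taxA']})")

deviant = next(seq[18] for _, seq in aln.entries if seq[18] != consensus[18])
carriers = {sp for sp, seq in aln.entries if seq[18] == deviant}
traits = generate_traits(
    {sp: 0.1 for sp in aln.species},
    TraitModel(mrls_noise_sd=1.0, lg_weight_noise_sd=0.1),
    seed=5,
    # tight spread: with only 5 carriers a wide LQ scatter would swamp the
    # planted shift in any single draw
    lq_model=LqModel(planted_percent_difference=17.0, spread_sd=0.05),
    lq_carriers=carriers,
)
res = residue_group_lq_compare(aln, 19, traits, residue=deviant)
print(f"\nresidue {deviant} at position 19: median LQ "
      f"{res.median_lq_in:.2f} (n={res.n_in}) vs {res.median_lq_out:.2f} "
      f"(n={res.n_out}) -> {res.percent_difference:+.1f}% (planted +17%)")
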