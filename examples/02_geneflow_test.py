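"""Shared-polymorphism LD test for gene flow (x = D_SS - D_SX).

For each species, x compares the linkage disequilibrium among shared
polymorphisms (D_SS) with the LD between shared and species-exclusive
polymorphisms (D_SX).  Introgressed variants are young and travel on a
common haplotype background, so the recipient species shows a large
positive x; significance comes from coalescent simulation of a
no-migration isolation null fitted to the locus.
"""

from introgrescan import default_study_design, simulate_study, geneflow_test, infer_direction

design = default_study_design()
dataset = simulate_study(design, seed=42)
meta = dataset.metadata
mel = meta.index[meta.species == "melpomene"].tolist()
tim = meta.index[meta.species == "timareta"].tolist()

for name in ("neutral_1", "colour"):
    aln = dataset.alignments[name]
    res = geneflow_test(aln, mel, tim, n_sims=999, seed=7,
                        recombination_rate=design.loci[0].params.rho)
    rec = infer_direction(res, labels=("melpomene", "timareta"))
    print(f"{name}: x_mel={res.x_pop1:+.3f} (p={res.p_pop1:.3f})  "
          f"x_tim={res.x_pop2:+.3f} (p={res.p_pop2:.3f})  recipient: {rec}")
# The colour locus names timareta as recipient with a small p.  Neutral
# loci carry weak real gene flow (2Nm = 0.1) and occasionally reach
# significance too, as unlinked markers did in real multi-locus surveys;
# only the colour locus does so consistently across seeds.
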