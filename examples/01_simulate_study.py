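"""Generate a study-like ddRAD dataset under the six-population demography.

The template encodes the point-estimate history (splits at 26,247 / 23,205 /
18,674 / 5,965 / 3,887 generations, admixture pulses into the Baltic deme)
and per-population sample sizes; the truth record written alongside the VCF
stores every generating parameter, so downstream estimates can be compared
with the values that produced the data.
"""

import powan

template = powan.StudyTemplate(n_loci=2000)   # the full template uses 20,000
geno, truth = powan.generate_vcf(template, seed=42, out_dir="scratch/study")

print(f"simulated {geno.n_sites} SNPs x {geno.n_samples} diploids "
      f"in {truth['n_loci']} loci")
for pop, idx in geno.pop_indices().items():
    print(f"  {pop}: {len(idx)} samples")
print("generating split times (generations):",
      {k: v for k, v in truth["params"].items() if k.startswith("t_")})
# Files written: scratch/study/{data.vcf, popmap.txt, truth.json}.
# SNP counts scale with n_loci; at 20,000 loci the dataset holds ~40k SNPs,
# the size regime of a real ddRAD study.
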