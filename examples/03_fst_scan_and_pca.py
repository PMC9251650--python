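"""Differentiation: pairwise F_ST with permutation tests, a 1-Mb windowed
scan with the mean + 3 SD outlier rule, and PCA with per-SNP eigenvector
correlations."""

import powan

geno, _ = powan.generate_vcf(powan.StudyTemplate(n_loci=3000), seed=7)

fst, pval = powan.pairwise_matrices(geno, n_perm=200, seed=1,
                                    populations=["NOR", "BAL", "LOM", "RTA"])
print("Weir & Cockerham F_ST:")
print(fst.round(3).to_string())
print("permutation p-values (200 permutations):")
print(pval.round(3).to_string(), "\n")

scan = powan.window_fst_scan(geno, "LOM", "RTA", window_bp=1_000_000,
                             min_snps=5)
n_out = int(scan.windows["outlier"].sum())
print(f"windowed scan: {len(scan.windows)} windows, mean F_ST "
      f"{scan.mean:.3f} (SD {scan.sd:.3f}), {n_out} outlier window(s)")
# Under the neutral generating model differentiation is genome-wide, so few
# or no windows exceed mean + 3 SD.

pca = powan.pca_with_snp_correlation(geno, n_components=4)
print("explained variance fractions:", pca.explained.round(3))
print("max |SNP-PC1 correlation|:", pca.snp_corr[:, 0].max().round(3))
# A genome-wide spread of moderate correlations (rather than a few extreme
# SNPs) indicates that the axis reflects genome-wide drift, not one region.
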