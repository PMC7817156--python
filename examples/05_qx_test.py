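"""Test for polygenic selection with the Qx statistic.

Qx measures overdispersion of trait-SNP allele frequencies across populations
relative to a neutral covariance built from genome-wide SNPs.  Under drift it
is chi-squared with (populations - 1) degrees of freedom; an empirical p is
also computed from random panels matched on minor-allele frequency (+-2%).
Running it on nested top-k panels (ranked by |effect|) shows whether the
signal is carried by a few large-effect SNPs.
"""

import paleoscore as ps
from paleoscore.qx import neutral_covariance, ordered_subset_scan

cfg = ps.make_preset("sweep-top", n_individuals=50, n_snps_null=6000, n_snps_trait=100)
data = ps.simulate_dataset(cfg, seed=6)

pool = data.population_freqs.loc[data.pool["snp_id"]]
cov = neutral_covariance(pool, min_snps=1000)
scan = ordered_subset_scan(
    data.effect_table, data.population_freqs, pool, cov,
    k_list=[5, 30, 100], drop_top=[5], b=2000, seed=7,
)
print(scan[["subset", "qx", "m_snps", "chi2_p", "empirical_p"]].to_string(index=False))
print("\n-> selection acts on the top-5 effects only: the top-5 panel is highly")
print("   significant, the full panel dilutes the signal, and removing the top 5")
print("   leaves a panel compatible with drift.")
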