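"""Generate a synthetic ancient-DNA study and look at what it contains.

Three source populations (hunter-gatherer-, Early-Farmer- and Steppe-like)
drift apart from a common ancestor and mix over the last 15,000 years; dated
pseudohaploid individuals are sampled along the transect with coverage-driven
missingness.  The 'sweep-top' preset puts directional selection on the light
alleles of the five largest-effect trait SNPs.
"""

import paleoscore as ps

cfg = ps.make_preset("sweep-top", n_individuals=200, n_snps_null=3000, n_snps_trait=80)
data = ps.simulate_dataset(cfg, seed=1)

m = data.matrix
print(f"samples: {m.n_samples}, SNPs: {m.n_snps} "
      f"({len(data.effect_table)} trait + {len(data.pool)} null)")
print(f"overall missing-call rate: {m.missing_mask().mean():.2f} "
      "(each call dropped with probability exp(-coverage))")
print(f"date range: {data.meta['date_bp'].max():.0f} - "
      f"{data.meta['date_bp'].min():.0f} years BP")
print(f"selected SNPs (largest |beta|, light allele favoured): {data.selected_snp_ids}")
print("\nmean ancestry fraction by epoch (rows sum to 1):")
data.meta["epoch"] = (data.meta["date_bp"] // 5000 * 5000).astype(int)
print(data.q.merge(data.meta, on="sample_id")
      .groupby("epoch")[["hunter_gatherer", "early_farmer", "steppe"]]
      .mean().round(2))
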