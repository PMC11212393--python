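"""Call allele-specific-binding (ASB) sites from per-animal allelic counts.

Each animal's ref/alt read counts at a heterozygous site are tested with the
1-df chi-square statistic (ref-alt)^2 / (ref+alt). A site is kept when at
least 5% of animals show imbalance at p < 0.05 and the site is biallelic;
counts are then aggregated over the imbalanced animals into one phenotype
y = alt/(ref+alt) - 0.5 per site.

Run:  python examples/02_call_asb.py
"""

from asbqtl.asb import build_asb_sites, chi2_asb_test, sites_to_frame
from asbqtl.simulate import SyntheticConfig, simulate_study

# the per-animal test on a clearly imbalanced and a balanced count pair
for ref, alt in [(30, 10), (20, 20)]:
    stat, p = chi2_asb_test(ref, alt)
    print(f"ref={ref:3d} alt={alt:3d}  chi2={stat:6.3f}  p={p:.4g}")

study = simulate_study(SyntheticConfig(n_chromosomes=1, chrom_length=250_000,
                                       n_peaks=60, n_cows=12,
                                       n_offpeak_snps=150, seed=7))

# restrict to sites under peaks, as the pipeline does
under = study.truth[study.truth.under_peak]
keys = set(zip(under.chrom, under.pos))
counts = study.counts[[k in keys for k in zip(study.counts.chrom,
                                              study.counts.pos)]]

sites, audit = build_asb_sites(counts, study.genome.chroms)
print("\nfilter audit:")
for k, v in sorted(audit.items()):
    print(f"  {k}: {v}")

df = sites_to_frame(sites)
print(f"\n{len(df)} ASB sites; first rows:")
print(df.head(5).to_string(index=False))
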