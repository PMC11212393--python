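"""Generate a small synthetic ASB study and look at what it contains.

The generator writes everything a real study would provide: a genome FASTA,
per-sample ChIP-seq peak calls, per-animal allelic read counts at
heterozygous sites, an independent validation cohort, and annotation files
(eQTL / aseQTL site lists, conserved-element BED). A truth table records
which sites are causal and their true allelic shift delta.

Run:  python examples/01_simulate_study.py
"""

from pathlib import Path

from asbqtl.simulate import SyntheticConfig, simulate_study

cfg = SyntheticConfig(n_chromosomes=1, chrom_length=250_000, n_peaks=60,
                      n_cows=12, n_offpeak_snps=150, seed=7)
study = simulate_study(cfg)

outdir = Path("example_output/study")
study.write(outdir)
print(f"study written to {outdir}/")
for p in sorted(outdir.rglob("*")):
    if p.is_file():
        print(f"  {p.relative_to(outdir)}")

truth = study.truth
print(f"\n{len(truth)} heterozygous sites; "
      f"{truth.under_peak.sum()} under peaks; "
      f"{truth.is_causal.sum()} causal")
causal = truth[truth.is_causal]
print("true allelic shift |delta| of causal sites: "
      f"min={causal.true_delta.abs().min():.3f} "
      f"max={causal.true_delta.abs().max():.3f}")
print("\nfirst counts rows:")
print(study.counts.head(5).to_string(index=False))
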