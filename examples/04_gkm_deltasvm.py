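"""Train the gapped k-mer classifier and score variants with deltaSVM.

Consensus peak sequences (positives) are separated from GC-matched background
segments (negatives) by a linear max-margin classifier over gapped 6-of-10-mer
counts. A variant's deltaSVM is the summed alt-minus-ref score of the ten
10-bp windows covering it in its 19-bp context.

Run:  python examples/04_gkm_deltasvm.py
"""

import numpy as np
import pandas as pd

from asbqtl.gkm import (
    GkmConfig,
    consensus_peaks,
    cross_validate,
    delta_svm_table,
    fetch_sequences,
    null_sequences,
    train,
)
from asbqtl._util import substream
from asbqtl.asb import build_asb_sites
from asbqtl.simulate import SyntheticConfig, simulate_study

study = simulate_study(SyntheticConfig(n_chromosomes=1, chrom_length=250_000,
                                       n_peaks=60, n_cows=12,
                                       n_offpeak_snps=150, seed=7))
genome = study.genome.chroms
cfg = GkmConfig(seed=7)

sample_peaks = study.genome.sample_peaks
cons = consensus_peaks(sample_peaks, config=cfg)
print(f"{cons.shape[0]} consensus peaks from "
      f"{sample_peaks.sample_id.nunique()} samples")

neg = null_sequences(genome, cons, cfg, rng=substream(7, "nullseqs"))
pos_seqs = fetch_sequences(genome, cons)
neg_seqs = fetch_sequences(genome, neg)
model = train(pos_seqs, neg_seqs, cfg)
print(f"trained on {model.n_pos} positives / {model.n_neg} negatives "
      f"({model.method} route)")

cv = cross_validate(pos_seqs, neg_seqs, cfg)
print("\n5-fold cross-validation:")
print(cv.to_string(index=False))

under = study.truth[study.truth.under_peak]
keys = set(zip(under.chrom, under.pos))
counts = study.counts[[k in keys for k in zip(study.counts.chrom,
                                              study.counts.pos)]]
sites, _ = build_asb_sites(counts, genome)
scores = delta_svm_table(model, sites, genome)
merged = scores.merge(study.truth[["site_id", "true_delta"]], on="site_id")
merged = merged.dropna()
r = np.corrcoef(merged.true_delta, merged.delta_svm)[0, 1]
print(f"\ndeltaSVM vs true allelic shift over {len(merged)} sites: r = {r:.2f}")
print(merged.reindex(merged.delta_svm.abs()
                     .sort_values(ascending=False).index).head(5)
      .to_string(index=False))
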