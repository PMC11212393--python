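"""Predict allelic imbalance from flanking sequence with neighborhood BLUP.

Sites sharing the same ordered (ref, alt) genotype and at least 7 of 10 flank
bases form a site's training neighborhood. The neighborhood mean effect is
shrunk toward zero with weights 4N / (4N sigma_s^2 + 1) and ridge 1/sigma_u^2;
the variance pair is chosen by maximizing the correlation between observed
phenotypes and leave-one-out predictions over a fixed grid.

Run:  python examples/03_blup_neighborhoods.py
"""

import numpy as np

from asbqtl.asb import build_asb_sites
from asbqtl.blup import build_neighborhoods, grid_search, predict_all
from asbqtl.simulate import SyntheticConfig, simulate_study

study = simulate_study(SyntheticConfig(n_chromosomes=1, chrom_length=250_000,
                                       n_peaks=60, n_cows=12,
                                       n_offpeak_snps=150, seed=7))
under = study.truth[study.truth.under_peak]
keys = set(zip(under.chrom, under.pos))
counts = study.counts[[k in keys for k in zip(study.counts.chrom,
                                              study.counts.pos)]]
sites, _ = build_asb_sites(counts, study.genome.chroms)

nbhds = build_neighborhoods(sites)
sizes = np.array([nb.n_members for nb in nbhds])
print(f"{len(sites)} sites; median neighborhood size = {np.median(sizes):.0f}; "
      f"{(sizes == 0).sum()} sites with no neighbors")

best, table = grid_search(sites, neighborhoods=nbhds)
print(f"\ngrid search best: sigma_s2={best.sigma_s2} sigma_u2={best.sigma_u2}")
print(table.sort_values('r', ascending=False).head(5).to_string(index=False))

preds = predict_all(sites, best, neighborhoods=nbhds)
merged = preds.merge(study.truth[["site_id", "true_delta", "is_causal"]],
                     on="site_id")
covered = merged[merged.is_causal & (merged.n_neighbors >= 5)]
acc = (np.sign(covered.u_hat) == np.sign(covered.true_delta)).mean()
print(f"\nsign(u_hat) matches sign(true delta) at {acc:.2f} "
      f"of {len(covered)} well-covered causal sites")
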