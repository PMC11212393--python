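"""Allele-specific-binding calls, site filtering, aggregation, phenotypes.

A heterozygous site under a ChIP-seq peak shows ASB when reads mapping to the
two alleles are significantly unbalanced. The per-animal test statistic is
x = (ref - alt)^2 / N, chi-squared with 1 df under the balanced null (it is
the score test of p = 0.5 for alt ~ Binomial(N, p)). Sites are retained if
they are biallelic SNPs showing ASB in at least a minimum fraction of
animals; read counts are then aggregated across the ASB-significant animals
and the site phenotype is y = alt/N - 0.5, zero under perfect balance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from asbqtl._util import InputError

#: Per-animal tests require at least this many reads; below it the animal
#: contributes neither to significance calls nor to the animal-fraction
#: denominator.
MIN_READS_PER_COW = 10


@dataclass
class AsbSite:
    """One aggregated ASB site with its phenotype and flanking context."""

    site_id: str
    chrom: str
    pos: int                # 1-based
    ref_allele: str
    alt_allele: str
    agg_ref: int
    agg_alt: int
    n_cows_asb: int
    flank5: str = ""
    flank3: str = ""
    monoallelic: bool = False

    @property
    def N(self) -> int:
        return self.agg_ref + self.agg_alt

    @property
    def y(self) -> float:
        return self.agg_alt / self.N - 0.5


def chi2_asb_test(ref_count, alt_count):
    """Allelic-imbalance test: statistic (ref-alt)^2/N, 1-df upper tail.

    Accepts scalars or arrays; returns (statistic, p_value).
    """
    ref = np.asarray(ref_count, dtype=float)
    alt = np.asarray(alt_count, dtype=float)
    n = ref + alt
    if np.any(n <= 0):
        raise InputError("chi2_asb_test undefined for N = 0")
    stat = (ref - alt) ** 2 / n
    p = stats.chi2.sf(stat, df=1)
    if np.ndim(ref_count) == 0 and np.ndim(alt_count) == 0:
        return float(stat), float(p)
    return stat, p


def _per_cow_flags(records: pd.DataFrame, p_threshold: float) -> pd.DataFrame:
    """Annotate each record with testability and per-animal significance."""
    rec = records.copy()
    n = rec.ref_count + rec.alt_count
    rec["tested"] = n >= MIN_READS_PER_COW
    rec["sig"] = False
    t = rec.tested.to_numpy()
    if t.any():
        stat = (rec.ref_count[t] - rec.alt_count[t]) ** 2 / n[t]
        rec.loc[t, "sig"] = stats.chi2.sf(stat, df=1) < p_threshold
    return rec


def filter_sites(records: pd.DataFrame, n_cows: int | None = None,
                 p_threshold: float = 0.05, min_cow_fraction: float = 0.05
                 ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the three exclusion rules and return retained records + audit.

    A site is retained iff it is a biallelic SNP (one ref and one alt base
    across all records) and at least ceil(min_cow_fraction * n_cows) animals
    show per-animal imbalance at p < p_threshold. The audit dict mirrors the
    bookkeeping a study summary table reports: totals and removals per rule.
    """
    cols = ["sample_id", "chrom", "pos", "ref", "alt", "ref_count", "alt_count"]
    audit = {"sites_total": 0, "removed_non_asb": 0, "removed_low_cow_fraction": 0,
             "removed_not_biallelic": 0, "sites_retained": 0}
    if len(records) == 0:
        return records.iloc[0:0], audit
    missing = set(cols) - set(records.columns)
    if missing:
        raise InputError(f"counts table missing columns: {sorted(missing)}")
    if n_cows is None:
        n_cows = records.sample_id.nunique()

    rec = _per_cow_flags(records, p_threshold)
    grouped = rec.groupby(["chrom", "pos"], sort=True)
    audit["sites_total"] = grouped.ngroups
    min_sig = int(np.ceil(min_cow_fraction * n_cows))

    keep_keys = []
    for key, grp in grouped:
        n_sig = int(grp.sig.sum())
        if n_sig == 0:
            audit["removed_non_asb"] += 1
            continue
        if n_sig < min_sig:
            audit["removed_low_cow_fraction"] += 1
            continue
        if grp.ref.nunique() != 1 or grp.alt.nunique() != 1 \
                or grp.ref.iat[0] == grp.alt.iat[0]:
            audit["removed_not_biallelic"] += 1
            continue
        keep_keys.append(key)

    audit["sites_retained"] = len(keep_keys)
    if not keep_keys:
        return rec.iloc[0:0], audit
    idx = pd.MultiIndex.from_tuples(keep_keys, names=["chrom", "pos"])
    retained = rec.set_index(["chrom", "pos"]).loc[idx].reset_index()
    return retained, audit


def aggregate(site_records: pd.DataFrame, significant_only: bool = True) -> AsbSite:
    """Aggregate one retained site's counts across animals into an AsbSite.

    By default only ASB-significant animals' reads are summed (the reads that
    carry the imbalance signal); ``significant_only=False`` sums every tested
    heterozygous animal for sensitivity analysis.
    """
    grp = site_records
    if "sig" not in grp.columns:
        grp = _per_cow_flags(grp, 0.05)
    use = grp[grp.sig] if significant_only else grp[grp.tested]
    agg_ref = int(use.ref_count.sum())
    agg_alt = int(use.alt_count.sum())
    if agg_ref + agg_alt == 0:
        raise InputError("aggregation produced zero total reads")
    return AsbSite(
        site_id=f"{grp.chrom.iat[0]}:{grp.pos.iat[0]}",
        chrom=str(grp.chrom.iat[0]),
        pos=int(grp.pos.iat[0]),
        ref_allele=str(grp.ref.iat[0]),
        alt_allele=str(grp.alt.iat[0]),
        agg_ref=agg_ref,
        agg_alt=agg_alt,
        n_cows_asb=int(grp.sig.sum()),
        monoallelic=(agg_ref == 0 or agg_alt == 0),
    )


def extract_flanks(genome: Mapping[str, str], chrom: str, pos: int,
                   flank: int = 5) -> tuple[str, str]:
    """Uppercase plus-strand flanks immediately up/downstream of a 1-based site.

    Raises InputError when the flank runs off the contig or contains N; the
    caller excludes such sites with a warning.
    """
    seq = genome[chrom]
    if pos - flank < 1 or pos + flank > len(seq):
        raise InputError(f"{chrom}:{pos}: insufficient flank")
    left = str(seq[pos - 1 - flank:pos - 1]).upper()
    right = str(seq[pos:pos + flank]).upper()
    if "N" in left or "N" in right:
        raise InputError(f"{chrom}:{pos}: flank contains N")
    return left, right


def build_asb_sites(records: pd.DataFrame, genome: Mapping[str, str],
                    n_cows: int | None = None, p_threshold: float = 0.05,
                    min_cow_fraction: float = 0.05, significant_only: bool = True
                    ) -> tuple[list[AsbSite], dict[str, int]]:
    """Filter, aggregate and flank-annotate every retained site."""
    retained, audit = filter_sites(records, n_cows=n_cows,
                                   p_threshold=p_threshold,
                                   min_cow_fraction=min_cow_fraction)
    sites: list[AsbSite] = []
    skipped = 0
    if len(retained):
        for _, grp in retained.groupby(["chrom", "pos"], sort=True):
            site = aggregate(grp, significant_only=significant_only)
            try:
                site.flank5, site.flank3 = extract_flanks(genome, site.chrom, site.pos)
            except InputError:
                skipped += 1
                continue
            sites.append(site)
    audit["removed_bad_flank"] = skipped
    audit["sites_with_flanks"] = len(sites)
    return sites, audit


def sites_to_frame(sites: list[AsbSite]) -> pd.DataFrame:
    return pd.DataFrame({
        "site_id": [s.site_id for s in sites],
        "chrom": [s.chrom for s in sites],
        "pos": [s.pos for s in sites],
        "ref_allele": [s.ref_allele for s in sites],
        "alt_allele": [s.alt_allele for s in sites],
        "agg_ref": [s.agg_ref for s in sites],
        "agg_alt": [s.agg_alt for s in sites],
        "N": [s.N for s in sites],
        "y": [s.y for s in sites],
        "n_cows_asb": [s.n_cows_asb for s in sites],
        "flank5": [s.flank5 for s in sites],
        "flank3": [s.flank3 for s in sites],
        "monoallelic": [s.monoallelic for s in sites],
    })
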