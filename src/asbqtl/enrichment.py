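"""Four-category functional-enrichment validation of candidate asbQTL.

Every SNP in the study falls in exactly one category per prediction method:
(1) candidate asbQTL, (2) non-causal ASB (ASB sites not selected as
candidates), (3) non-ASB variants under a peak, (4) SNPs not under a peak.
For each functional annotation (independent-cohort ASB, eQTL, aseQTL,
conserved elements) the proportion of annotated sites per category is
compared between adjacent categories with a 1-df chi-square test; a pair is
flagged enriched when p < alpha and the earlier category's proportion is the
greater one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from asbqtl._util import InputError
from asbqtl.asb import MIN_READS_PER_COW, chi2_asb_test
from asbqtl.combine import two_by_two_chi2

CATEGORY_ORDER = ("candidate_asbqtl", "noncausal_asb", "non_asb_under_peak",
                  "not_under_peak")


@dataclass
class AnnotationSets:
    """Named annotation memberships: exact (chrom, pos) site sets plus a
    half-open interval set for conserved elements. Alleles are ignored."""

    validation_asb: set[tuple[str, int]] = field(default_factory=set)
    eqtl: set[tuple[str, int]] = field(default_factory=set)
    aseqtl: set[tuple[str, int]] = field(default_factory=set)
    conserved: dict[str, np.ndarray] = field(default_factory=dict)  # chrom -> (n,2) 0-based

    def names(self) -> list[str]:
        return ["validation_asb", "eqtl", "aseqtl", "conserved"]

    def contains(self, name: str, chrom: str, pos: int) -> bool:
        """Membership of a 1-based site position."""
        if name == "conserved":
            iv = self.conserved.get(chrom)
            if iv is None or len(iv) == 0:
                return False
            p0 = pos - 1
            return bool(((iv[:, 0] <= p0) & (p0 < iv[:, 1])).any())
        return (chrom, pos) in getattr(self, name)

    @staticmethod
    def from_files(validation_sites: str | Path | None = None,
                   eqtl_sites: str | Path | None = None,
                   aseqtl_sites: str | Path | None = None,
                   conserved_bed: str | Path | None = None) -> "AnnotationSets":
        def read_sites(path):
            if path is None:
                return set()
            df = pd.read_csv(path, sep="\t")
            return set(zip(df.chrom.astype(str), df.pos.astype(int)))

        conserved: dict[str, np.ndarray] = {}
        if conserved_bed is not None:
            bed = pd.read_csv(conserved_bed, sep="\t", header=None,
                              names=["chrom", "start", "end"], usecols=[0, 1, 2])
            for chrom, grp in bed.groupby("chrom"):
                conserved[str(chrom)] = grp[["start", "end"]].to_numpy()
        return AnnotationSets(validation_asb=read_sites(validation_sites),
                              eqtl=read_sites(eqtl_sites),
                              aseqtl=read_sites(aseqtl_sites),
                              conserved=conserved)


def validation_asb_sites(validation_counts: pd.DataFrame, p_threshold: float = 0.01,
                         min_cows: int = 1) -> set[tuple[str, int]]:
    """Sites showing allelic imbalance (p < p_threshold) in at least
    ``min_cows`` animals of the independent cohort."""
    rec = validation_counts.copy()
    n = rec.ref_count + rec.alt_count
    rec = rec[n >= MIN_READS_PER_COW]
    if len(rec) == 0:
        return set()
    _, p = chi2_asb_test(rec.ref_count.to_numpy(), rec.alt_count.to_numpy())
    rec = rec.assign(sig=p < p_threshold)
    hits = rec.groupby(["chrom", "pos"]).sig.sum()
    hits = hits[hits >= min_cows]
    return {(str(c), int(p)) for c, p in hits.index}


def categorize(all_snps: pd.DataFrame, asb_site_ids: set[str],
               candidate_site_ids: set[str]) -> pd.Series:
    """One category label per SNP for one method's candidate set.

    ``all_snps`` needs site_id and under_peak columns. Candidates must be a
    subset of the ASB sites, and ASB sites must lie under peaks.
    """
    if not candidate_site_ids <= asb_site_ids:
        raise InputError("candidate sites must be a subset of ASB sites")
    ids = all_snps.site_id
    under = all_snps.under_peak.to_numpy(bool)
    is_asb = ids.isin(asb_site_ids).to_numpy()
    if np.any(is_asb & ~under):
        raise InputError("ASB sites must be under peaks")
    is_cand = ids.isin(candidate_site_ids).to_numpy()
    labels = np.where(
        is_cand, "candidate_asbqtl",
        np.where(is_asb, "noncausal_asb",
                 np.where(under, "non_asb_under_peak", "not_under_peak")))
    return pd.Series(labels, index=all_snps.index, name="category")


def annotate_and_tabulate(all_snps: pd.DataFrame, labels: pd.Series,
                          annotations: AnnotationSets) -> pd.DataFrame:
    """Per category x annotation: member count, annotated count, proportion.

    Empty categories report NaN proportions (missing, not zero).
    """
    rows = []
    member = {name: np.array([annotations.contains(name, c, p)
                              for c, p in zip(all_snps.chrom, all_snps.pos)])
              for name in annotations.names()}
    for cat in CATEGORY_ORDER:
        mask = (labels == cat).to_numpy()
        n = int(mask.sum())
        for name in annotations.names():
            k = int(member[name][mask].sum()) if n else 0
            rows.append((cat, name, n, k, k / n if n else np.nan))
    return pd.DataFrame(rows, columns=["category", "annotation", "n_sites",
                                       "n_annotated", "proportion"])


def sequential_tests(table: pd.DataFrame, alpha: float = 0.01) -> pd.DataFrame:
    """Chi-square comparison of each category against the next in the fixed
    order, per annotation; flagged iff p < alpha and the earlier category's
    proportion is greater. Tests with a zero margin are skipped with a note."""
    rows = []
    for name, grp in table.groupby("annotation", sort=False):
        grp = grp.set_index("category").reindex(CATEGORY_ORDER)
        for first, second in zip(CATEGORY_ORDER[:-1], CATEGORY_ORDER[1:]):
            r1, r2 = grp.loc[first], grp.loc[second]
            if r1.n_sites == 0 or r2.n_sites == 0:
                rows.append((first, second, name, np.nan, np.nan, False,
                             "skipped: empty category"))
                continue
            a, b = int(r1.n_annotated), int(r1.n_sites - r1.n_annotated)
            c, d = int(r2.n_annotated), int(r2.n_sites - r2.n_annotated)
            if (a + c) == 0 or (b + d) == 0:
                rows.append((first, second, name, np.nan, np.nan, False,
                             "skipped: zero margin"))
                continue
            stat, p = two_by_two_chi2(a, b, c, d)
            flagged = bool(p < alpha and r1.proportion > r2.proportion)
            rows.append((first, second, name, stat, p, flagged, ""))
    return pd.DataFrame(rows, columns=["category", "next_category", "annotation",
                                       "chi2", "p_value", "flagged", "note"])
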