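"""Synthetic ASB study generator with known causal effects.

Emulates the data a ChIP-seq allele-specific-binding (ASB) analysis consumes:
a small genome with binding motifs planted inside peak regions, per-sample
peak calls with significance scores, heterozygous sites whose alternate
alleles perturb motif strength, per-animal allelic read counts, an independent
validation cohort, and functional-annotation site sets with controllable
overlap with the causal sites.

The allelic effect is defined directly on the alternate-read probability:
alt reads ~ Binomial(N, 0.5 + delta). Causal sites sit inside motif
instances and their delta is the allele's motif-weight difference scaled so
that the strongest possible perturbation equals ``effect_scale``; every
non-causal site has delta = 0. This makes downstream parameter recovery
exactly interpretable on the phenotype scale y = alt/N - 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from asbqtl._util import ConfigError, substream

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: Dominant-base probabilities of the default planted motif, interleaved so
#: that the plantable central offsets carry a spread of information content
#: (and hence a spread of allelic effect sizes).
_DEFAULT_MOTIF_PROBS = (
    0.62, 0.93, 0.68, 0.88, 0.73, 0.95, 0.78,
    0.83, 0.64, 0.90, 0.70, 0.86, 0.75, 0.80,
)
_DEFAULT_MOTIF_CONSENSUS = "TGACTCATGCGTCA"


def default_motif() -> np.ndarray:
    """Width-14 probability matrix over A,C,G,T for the default motif."""
    w = len(_DEFAULT_MOTIF_PROBS)
    pwm = np.empty((w, 4))
    for j, (p, cons) in enumerate(zip(_DEFAULT_MOTIF_PROBS, _DEFAULT_MOTIF_CONSENSUS)):
        pwm[j] = (1.0 - p) / 3.0
        pwm[j, BASE_INDEX[cons]] = p
    return pwm


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic study.

    Defaults describe the reference desk-scale study: a 2 x 1 Mb genome with
    500 peaks, ~4 heterozygous sites per peak (30% causal with allelic shifts
    |delta| in roughly [0.12, 0.30]), 20 animals at mean depth 30, and an
    independent 3-animal validation cohort.
    """

    n_chromosomes: int = 2
    chrom_length: int = 1_000_000
    n_peaks: int = 500
    peak_length_range: tuple[int, int] = (150, 400)
    motif: np.ndarray = field(default_factory=default_motif)
    n_cows: int = 20
    mean_depth_per_cow: float = 30.0
    depth_dispersion: float = 0.3
    n_het_per_peak: int = 4
    frac_causal_sites: float = 0.3
    effect_scale: float = 0.3
    n_offpeak_snps: int = 1000
    n_validation_cows: int = 3
    annotation_overlap: float = 0.8
    annotation_base_rate: float = 0.1
    gc_content: float = 0.45
    frac_sig_peaks: float = 0.6     # fraction of peaks whose -log10 P > 200
    frac_shared_peaks: float = 0.9  # fraction of peaks present in >=50% of samples
    allelic_overdispersion: float = 0.0  # beta-binomial hook, off by default
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_chromosomes", "chrom_length", "n_peaks", "n_cows",
                     "n_validation_cows", "n_het_per_peak"):
            if getattr(self, name) < 0 or (name not in ("n_peaks",) and getattr(self, name) == 0):
                raise ConfigError(f"{name} must be positive (n_peaks may be zero)")
        lo, hi = self.peak_length_range
        if not (0 < lo <= hi <= 2000):
            raise ConfigError("peak lengths must be in (0, 2000]")
        if not 0.0 <= self.frac_causal_sites <= 1.0:
            raise ConfigError("frac_causal_sites must be in [0, 1]")
        if not 0.0 < self.effect_scale < 0.5:
            raise ConfigError("effect_scale must be in (0, 0.5)")
        if not 0.0 < self.gc_content < 1.0:
            raise ConfigError("gc_content must be in (0, 1)")
        self.motif = np.asarray(self.motif, dtype=float)
        if self.motif.ndim != 2 or self.motif.shape[1] != 4:
            raise ConfigError("motif must be a (width, 4) probability matrix")
        if not np.allclose(self.motif.sum(axis=1), 1.0, atol=1e-6):
            raise ConfigError("motif rows must sum to 1")
        if self.motif.shape[0] > lo:
            raise ConfigError("motif wider than the shortest peak")


@dataclass
class Genome:
    """Chromosome sequences plus peak and motif-instance bookkeeping."""

    chroms: dict[str, str]
    peaks: pd.DataFrame          # peak_id, chrom, start, end (0-based half-open)
    sample_peaks: pd.DataFrame   # sample_id, chrom, start, end, neglog10p
    motif_instances: pd.DataFrame  # peak_id, chrom, start (0-based)


@dataclass
class SyntheticStudy:
    config: SyntheticConfig
    genome: Genome
    truth: pd.DataFrame
    counts: pd.DataFrame
    validation_counts: pd.DataFrame

    def write(self, outdir: str | Path) -> None:
        write_study(self, outdir)


def motif_log_weights(pwm: np.ndarray) -> np.ndarray:
    """Per-position log2 enrichment over background; the allelic effect of a
    ref->alt substitution is proportional to the weight difference."""
    return np.log2(pwm / 0.25)


def _codes_to_str(codes: np.ndarray) -> str:
    return "".join(BASES[c] for c in codes)


def generate_genome(config: SyntheticConfig) -> Genome:
    """Draw i.i.d. chromosomes, place non-overlapping peaks, plant motifs,
    and emit per-sample peak calls with -log10 P scores."""
    rng = substream(config.seed, "genome")
    gc = config.gc_content
    base_p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])

    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    chrom_codes = {
        name: rng.choice(4, size=config.chrom_length, p=base_p).astype(np.int8)
        for name in chrom_names
    }

    lo, hi = config.peak_length_range
    margin = 20  # keep peaks clear of chromosome ends so flanks always exist
    lengths = rng.integers(lo, hi + 1, size=config.n_peaks)
    # Round-robin assignment of peaks to chromosomes.
    chrom_of = np.array([i % config.n_chromosomes for i in range(config.n_peaks)])
    peak_rows = []
    for ci, name in enumerate(chrom_names):
        idx = np.flatnonzero(chrom_of == ci)
        ls = lengths[idx]
        usable = config.chrom_length - 2 * margin
        slack = usable - int(ls.sum()) - len(idx)  # >=1 bp gap between peaks
        if slack < 0:
            raise ConfigError(
                f"cannot place {len(idx)} peaks totalling {ls.sum()} bp on a "
                f"{config.chrom_length} bp chromosome"
            )
        gaps = np.sort(rng.integers(0, slack + 1, size=len(idx)))
        starts = margin + gaps + np.concatenate(([0], np.cumsum(ls[:-1] + 1)))
        for pid_local, (s, l) in enumerate(zip(starts, ls)):
            peak_rows.append((name, int(s), int(s + l)))
    peaks = pd.DataFrame(peak_rows, columns=["chrom", "start", "end"])
    peaks = peaks.sort_values(["chrom", "start"]).reset_index(drop=True)
    peaks.insert(0, "peak_id", [f"peak{i:04d}" for i in range(len(peaks))])

    # Plant >=1 motif instance per peak (about one per 300 bp).
    w = config.motif.shape[0]
    inst_rows = []
    for row in peaks.itertuples():
        length = row.end - row.start
        n_inst = max(1, length // 300)
        placed: list[int] = []
        # first instance summit-centered (binding sites concentrate at the
        # peak center); any additional instances uniform within the peak
        center = (row.start + row.end - w) // 2
        lo_c = max(row.start, center - 40)
        hi_c = min(row.end - w, center + 40)
        placed.append(int(rng.integers(lo_c, hi_c + 1)))
        attempts = 0
        while len(placed) < n_inst and attempts < 50 * n_inst:
            attempts += 1
            s = int(rng.integers(row.start, row.end - w + 1))
            if all(abs(s - q) >= w for q in placed):
                placed.append(s)
        for s in placed:
            sampled = np.array(
                [rng.choice(4, p=config.motif[j]) for j in range(w)], dtype=np.int8
            )
            chrom_codes[row.chrom][s:s + w] = sampled
            inst_rows.append((row.peak_id, row.chrom, s))
    motif_instances = pd.DataFrame(inst_rows, columns=["peak_id", "chrom", "start"])

    sample_peaks = _draw_sample_peaks(peaks, config, rng)
    chroms = {name: _codes_to_str(codes) for name, codes in chrom_codes.items()}
    return Genome(chroms=chroms, peaks=peaks, sample_peaks=sample_peaks,
                  motif_instances=motif_instances)


def _draw_sample_peaks(peaks: pd.DataFrame, config: SyntheticConfig,
                       rng: np.random.Generator) -> pd.DataFrame:
    """Per-sample peak calls: a configurable fraction of peaks score above
    -log10 P = 200 and a configurable fraction recur in >=50% of samples."""
    n = len(peaks)
    strong = rng.random(n) < config.frac_sig_peaks
    shared = rng.random(n) < config.frac_shared_peaks
    rows = []
    for s in range(config.n_cows):
        sample = f"cow{s + 1:02d}"
        present = rng.random(n) < np.where(shared, 0.9, 0.3)
        score = np.where(strong, rng.uniform(210, 300, n), rng.uniform(20, 190, n))
        jit_s = rng.integers(-10, 11, n)
        jit_e = rng.integers(-10, 11, n)
        for i in np.flatnonzero(present):
            rows.append((
                sample, peaks.chrom.iat[i],
                max(0, int(peaks.start.iat[i] + jit_s[i])),
                int(peaks.end.iat[i] + jit_e[i]),
                float(score[i]),
            ))
    return pd.DataFrame(rows, columns=["sample_id", "chrom", "start", "end", "neglog10p"])


def plant_variants(genome: Genome, config: SyntheticConfig) -> pd.DataFrame:
    """Place heterozygous sites and assign their true allelic shifts.

    Causal sites land inside motif instances at offsets where both 5-bp
    flanks stay within the motif; delta = effect_scale * (w_alt - w_ref) /
    max|w difference|, so an allele swap at the most informative position
    shifts the alt-read probability by the full effect_scale. Non-causal
    under-peak sites and off-peak SNPs carry delta = 0.
    """
    rng = substream(config.seed, "variants")
    pwm = config.motif
    w = pwm.shape[0]
    lo, _ = config.peak_length_range
    if w > lo:
        raise ConfigError("motif wider than the shortest peak")
    weights = motif_log_weights(pwm)
    max_diff = float((weights.max(axis=1) - weights.min(axis=1)).max())
    offsets = np.arange(5, w - 5)  # both 5-bp flanks inside the motif
    if offsets.size == 0:
        raise ConfigError("motif too narrow to host flank-contained causal sites")
    dominant = pwm.argmax(axis=1)

    inst_by_peak = {pid: grp for pid, grp in genome.motif_instances.groupby("peak_id")}
    used: set[tuple[str, int]] = set()
    rows = []

    def genome_base(chrom: str, pos0: int) -> str:
        return genome.chroms[chrom][pos0]

    for peak in genome.peaks.itertuples():
        insts = inst_by_peak.get(peak.peak_id)
        for _ in range(config.n_het_per_peak):
            causal = bool(rng.random() < config.frac_causal_sites) and insts is not None
            if causal:
                inst = insts.iloc[int(rng.integers(len(insts)))]
                off = int(offsets[int(rng.integers(offsets.size))])
                pos0 = int(inst.start) + off
                if (peak.chrom, pos0) in used:
                    continue
                ref = genome_base(peak.chrom, pos0)
                ri = BASE_INDEX[ref]
                if ri == dominant[off]:
                    minors = [b for b in range(4) if b != ri]
                    ai = int(minors[int(rng.integers(3))])
                else:
                    ai = int(dominant[off])
                delta = config.effect_scale * float(weights[off, ai] - weights[off, ri]) / max_diff
            else:
                # place outside motif instances so a delta=0 site never sits
                # on an informative motif position
                for _try in range(100):
                    pos0 = int(rng.integers(peak.start, peak.end))
                    inside = insts is not None and bool(
                        ((insts.start <= pos0) & (pos0 < insts.start + w)).any()
                    )
                    if not inside and (peak.chrom, pos0) not in used:
                        break
                else:
                    continue
                ref = genome_base(peak.chrom, pos0)
                ri = BASE_INDEX[ref]
                minors = [b for b in range(4) if b != ri]
                ai = int(minors[int(rng.integers(3))])
                delta = 0.0
            used.add((peak.chrom, pos0))
            rows.append((peak.chrom, pos0 + 1, ref, BASES[ai], delta, causal, True))

    # off-peak SNPs
    peak_iv = {c: grp[["start", "end"]].to_numpy() for c, grp in genome.peaks.groupby("chrom")}
    chrom_names = list(genome.chroms)
    n_placed = 0
    while n_placed < config.n_offpeak_snps:
        chrom = chrom_names[int(rng.integers(len(chrom_names)))]
        pos0 = int(rng.integers(10, len(genome.chroms[chrom]) - 10))
        iv = peak_iv.get(chrom)
        if iv is not None and bool(((iv[:, 0] <= pos0) & (pos0 < iv[:, 1])).any()):
            continue
        if (chrom, pos0) in used:
            continue
        used.add((chrom, pos0))
        ref = genome_base(chrom, pos0)
        minors = [b for b in range(4) if b != BASE_INDEX[ref]]
        rows.append((chrom, pos0 + 1, ref, BASES[int(minors[int(rng.integers(3))])],
                     0.0, False, False))
        n_placed += 1

    truth = pd.DataFrame(rows, columns=["chrom", "pos", "ref_allele", "alt_allele",
                                        "true_delta", "is_causal", "under_peak"])
    truth = truth.sort_values(["chrom", "pos"]).reset_index(drop=True)
    truth.insert(0, "site_id", truth.chrom + ":" + truth.pos.astype(str))

    causal = truth.is_causal.to_numpy()
    anno_rng = substream(config.seed, "annotations")
    for col in ("in_eqtl", "in_aseqtl", "in_conserved"):
        p = np.where(causal, config.annotation_overlap, config.annotation_base_rate)
        truth[col] = anno_rng.random(len(truth)) < p
    return truth


def _depth_matrix(n_sites: int, n_cows: int, config: SyntheticConfig,
                  rng: np.random.Generator) -> np.ndarray:
    m = config.mean_depth_per_cow
    if config.depth_dispersion > 0:
        n = 1.0 / config.depth_dispersion
        p = n / (n + m)
        return rng.negative_binomial(n, p, size=(n_sites, n_cows))
    return rng.poisson(m, size=(n_sites, n_cows))


def _draw_cohort(truth: pd.DataFrame, n_cows: int, prefix: str,
                 config: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    n_sites = len(truth)
    depth = _depth_matrix(n_sites, n_cows, config, rng)
    p_alt = 0.5 + truth.true_delta.to_numpy()[:, None]
    if config.allelic_overdispersion > 0:
        # beta-binomial allelic noise around 0.5 + delta
        conc = 1.0 / config.allelic_overdispersion
        p_alt = rng.beta(np.clip(p_alt, 1e-9, None) * conc,
                         np.clip(1 - p_alt, 1e-9, None) * conc,
                         size=(n_sites, n_cows))
        alt = rng.binomial(depth, p_alt)
    else:
        alt = rng.binomial(depth, np.broadcast_to(p_alt, (n_sites, n_cows)))
    ref = depth - alt
    cows = [f"{prefix}{c + 1:02d}" for c in range(n_cows)]
    frames = []
    for ci, cow in enumerate(cows):
        frames.append(pd.DataFrame({
            "sample_id": cow,
            "chrom": truth.chrom,
            "pos": truth.pos,
            "ref": truth.ref_allele,
            "alt": truth.alt_allele,
            "ref_count": ref[:, ci],
            "alt_count": alt[:, ci],
        }))
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["sample_id", "chrom", "pos"]).reset_index(drop=True)


def simulate_counts(truth: pd.DataFrame, config: SyntheticConfig
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cow allelic read counts for the main and validation cohorts.

    Total depth per cow and site is negative-binomial (mean
    ``mean_depth_per_cow``, variance m + d*m^2); alternate reads are
    Binomial(N, 0.5 + true_delta). The validation cohort is drawn from an
    independent stream.
    """
    if config.mean_depth_per_cow <= 0:
        raise ConfigError("mean_depth_per_cow must be > 0 (all-zero counts)")
    counts = _draw_cohort(truth, config.n_cows, "cow",
                          config, substream(config.seed, "counts"))
    validation = _draw_cohort(truth, config.n_validation_cows, "valcow",
                              config, substream(config.seed, "validation"))
    return counts, validation


def simulate_study(config: SyntheticConfig) -> SyntheticStudy:
    """Generate the full synthetic study: genome, truth, both cohorts."""
    genome = generate_genome(config)
    truth = plant_variants(genome, config)
    counts, validation = simulate_counts(truth, config)
    return SyntheticStudy(config=config, genome=genome, truth=truth,
                          counts=counts, validation_counts=validation)


# ---------------------------------------------------------------------------
# writers

def write_fasta(chroms: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in chroms.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_study(study: SyntheticStudy, outdir: str | Path) -> None:
    """Serialize every study component as plain text (FASTA/narrowPeak/TSV/BED)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(study.genome.chroms, out / "genome.fa")
    study.genome.peaks.to_csv(out / "peaks.tsv", sep="\t", index=False)

    peak_dir = out / "sample_peaks"
    peak_dir.mkdir(exist_ok=True)
    for sample, grp in study.genome.sample_peaks.groupby("sample_id"):
        with open(peak_dir / f"{sample}.narrowPeak", "w") as fh:
            for i, r in enumerate(grp.itertuples()):
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{sample}_pk{i}\t0\t.\t"
                         f"0\t{r.neglog10p:.3f}\t-1\t-1\n")

    study.truth.to_csv(out / "truth.tsv", sep="\t", index=False,
                       float_format="%.6g")
    study.counts.to_csv(out / "counts.tsv", sep="\t", index=False)
    study.validation_counts.to_csv(out / "validation_counts.tsv", sep="\t", index=False)

    truth = study.truth
    for name, col in (("eqtl", "in_eqtl"), ("aseqtl", "in_aseqtl")):
        sub = truth[truth[col]]
        sub[["chrom", "pos"]].to_csv(out / f"{name}.sites", sep="\t", index=False)
    cons = truth[truth.in_conserved]
    with open(out / "conserved.bed", "w") as fh:
        for r in cons.itertuples():
            start = max(0, r.pos - 4)  # small conserved element around the site
            fh.write(f"{r.chrom}\t{start}\t{r.pos + 3}\n")


def scaled_config(base: SyntheticConfig | None = None, **overrides) -> SyntheticConfig:
    """Convenience for small test-scale configs derived from the defaults."""
    cfg = base or SyntheticConfig()
    return replace(cfg, **overrides)
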