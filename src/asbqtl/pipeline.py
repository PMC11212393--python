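"""End-to-end orchestration: simulate -> call ASB -> gkm -> BLUP -> combine -> enrich.

Every stage reads its inputs from, and writes its outputs to, the run
directory, so any stage can be re-run in isolation and ``run_all`` equals the
composition of stages. All randomness flows from one root seed through named
substreams, and floating-point output formatting is fixed, so a rerun with
the same configuration is byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from asbqtl import asb, blup as blup_mod, combine as combine_mod
from asbqtl import enrichment as enrich_mod
from asbqtl import gkm as gkm_mod
from asbqtl._util import InputError, substream
from asbqtl.asb import AsbSite
from asbqtl.gkm import GkmConfig, GkmModel
from asbqtl.simulate import SyntheticConfig, simulate_study

_FLOAT_FMT = "%.10g"

STAGES = ("simulate", "call-asb", "train-gkm", "delta-svm", "blup",
          "combine", "enrich", "report")


@dataclass
class RunConfig:
    """One declarative configuration for a full run.

    ``mode="simulate"`` generates the study from ``synthetic``; in
    ``mode="real"`` the input paths must point at existing files.
    """

    outdir: str | Path = "asbqtl_run"
    mode: str = "simulate"
    seed: int = 0
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    gkm: GkmConfig = field(default_factory=GkmConfig)
    p_threshold: float = 0.05
    min_cow_fraction: float = 0.05
    aggregate_significant_only: bool = True
    min_flank_matches: int = 7
    grid_s: tuple[float, ...] = blup_mod.DEFAULT_GRID_S
    grid_u: tuple[float, ...] = blup_mod.DEFAULT_GRID_U
    n_top: int = 1000
    scale_n_top: bool = True        # cap at 10% of sites for small runs
    cv_max_per_class: int = 250     # subsample cap for the CV metric stage
    enrichment_alpha: float = 0.01
    # real-data inputs
    counts_path: str | None = None
    sample_peaks_dir: str | None = None
    genome_fasta: str | None = None
    validation_counts_path: str | None = None
    eqtl_sites: str | None = None
    aseqtl_sites: str | None = None
    conserved_bed: str | None = None

    def __post_init__(self) -> None:
        # the root seed propagates to every stochastic stage
        self.synthetic = replace(self.synthetic, seed=self.seed)
        self.gkm = replace(self.gkm, seed=self.seed)

    @staticmethod
    def from_yaml(path: str | Path, **overrides) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        syn = SyntheticConfig(**raw.pop("synthetic", {}))
        gk = GkmConfig(**raw.pop("gkm", {}))
        for key in ("grid_s", "grid_u", "peak_length_range"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return RunConfig(synthetic=syn, gkm=gk, **raw)


# ---------------------------------------------------------------------------
# run-directory helpers

def _data_dir(cfg: RunConfig) -> Path:
    return Path(cfg.outdir) / "data"


def _require(path: Path) -> Path:
    if not path.exists():
        raise InputError(f"required input not found: {path}")
    return path


def _required_path(value: str | None, what: str) -> Path:
    if not value:
        raise InputError(f"real-data mode needs {what} to be configured")
    return _require(Path(value))


def load_genome(cfg: RunConfig) -> dict[str, str]:
    if cfg.mode == "simulate":
        fasta = _require(_data_dir(cfg) / "genome.fa")
    else:
        fasta = _required_path(cfg.genome_fasta, "genome_fasta")
    import pyfaidx

    fa = pyfaidx.Fasta(str(fasta))
    return {name: str(fa[name][:]) for name in fa.keys()}


def _load_counts(cfg: RunConfig) -> pd.DataFrame:
    if cfg.mode == "simulate":
        path = _require(_data_dir(cfg) / "counts.tsv")
    else:
        path = _required_path(cfg.counts_path, "counts_path")
    return pd.read_csv(path, sep="\t")


def read_narrowpeak(path: str | Path, sample_id: str | None = None) -> pd.DataFrame:
    """BED6+4 peak calls; column 8 carries the -log10 P value."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "name", "score", "strand",
                            "signal", "neglog10p", "qvalue", "peak"])
    df["sample_id"] = sample_id or Path(path).stem
    return df[["sample_id", "chrom", "start", "end", "neglog10p"]]


def _load_sample_peaks(cfg: RunConfig) -> pd.DataFrame:
    if cfg.mode == "simulate":
        peak_dir = _require(_data_dir(cfg) / "sample_peaks")
    else:
        peak_dir = _required_path(cfg.sample_peaks_dir, "sample_peaks_dir")
    frames = [read_narrowpeak(p) for p in sorted(peak_dir.glob("*.narrowPeak"))]
    if not frames:
        raise InputError(f"no .narrowPeak files in {peak_dir}")
    return pd.concat(frames, ignore_index=True)


def _peak_intervals(cfg: RunConfig) -> pd.DataFrame:
    if cfg.mode == "simulate":
        return pd.read_csv(_require(_data_dir(cfg) / "peaks.tsv"), sep="\t")
    # real-data mode: union of consensus regions as the peak footprint
    out = Path(cfg.outdir) / "consensus_peaks.tsv"
    if out.exists():
        return pd.read_csv(out, sep="\t")
    return gkm_mod.consensus_peaks(_load_sample_peaks(cfg), config=cfg.gkm)


def under_peak_flags(sites: pd.DataFrame, peaks: pd.DataFrame) -> np.ndarray:
    """True where a 1-based site position overlaps a 0-based half-open peak."""
    flags = np.zeros(len(sites), dtype=bool)
    for chrom, grp in peaks.groupby("chrom"):
        starts = grp.start.to_numpy()
        ends = grp.end.to_numpy()
        order = np.argsort(starts)
        starts, ends = starts[order], ends[order]
        mask = (sites.chrom == chrom).to_numpy()
        p0 = sites.pos.to_numpy()[mask] - 1
        idx = np.searchsorted(starts, p0, side="right") - 1
        ok = idx >= 0
        ok[ok] = p0[ok] < ends[idx[ok]]
        flags[np.flatnonzero(mask)] = ok
    return flags


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def _sites_from_frame(df: pd.DataFrame) -> list[AsbSite]:
    return [AsbSite(site_id=r.site_id, chrom=str(r.chrom), pos=int(r.pos),
                    ref_allele=r.ref_allele, alt_allele=r.alt_allele,
                    agg_ref=int(r.agg_ref), agg_alt=int(r.agg_alt),
                    n_cows_asb=int(r.n_cows_asb), flank5=r.flank5,
                    flank3=r.flank3, monoallelic=bool(r.monoallelic))
            for r in df.itertuples()]


def _checkpoint(cfg: RunConfig, stage: str) -> None:
    path = Path(cfg.outdir) / "checkpoint.json"
    done = []
    if path.exists():
        done = json.loads(path.read_text()).get("completed", [])
    if stage not in done:
        done.append(stage)
    path.write_text(json.dumps({"completed": done}, indent=0) + "\n")


# ---------------------------------------------------------------------------
# stages

def stage_simulate(cfg: RunConfig) -> None:
    if cfg.mode != "simulate":
        return
    study = simulate_study(cfg.synthetic)
    study.write(_data_dir(cfg))
    _checkpoint(cfg, "simulate")


def stage_call_asb(cfg: RunConfig) -> None:
    out = Path(cfg.outdir)
    counts = _load_counts(cfg)
    genome = load_genome(cfg)
    peaks = _peak_intervals(cfg)
    site_pos = counts[["chrom", "pos"]].drop_duplicates().reset_index(drop=True)
    site_pos["under"] = under_peak_flags(site_pos, peaks)
    under = set(zip(site_pos.chrom[site_pos.under], site_pos.pos[site_pos.under]))
    keyed = list(zip(counts.chrom, counts.pos))
    counts_under = counts[[k in under for k in keyed]]
    sites, audit = asb.build_asb_sites(
        counts_under, genome,
        p_threshold=cfg.p_threshold, min_cow_fraction=cfg.min_cow_fraction,
        significant_only=cfg.aggregate_significant_only)
    _write(asb.sites_to_frame(sites), out / "asb_sites.tsv")
    audit_df = pd.DataFrame(sorted(audit.items()), columns=["metric", "count"])
    _write(audit_df, out / "asb_audit.tsv")
    _checkpoint(cfg, "call-asb")


def _center_crop(seq: str, crop: int | None) -> str:
    if crop is None or len(seq) <= crop:
        return seq
    off = (len(seq) - crop) // 2
    return seq[off:off + crop]


def stage_train_gkm(cfg: RunConfig) -> None:
    out = Path(cfg.outdir)
    genome = load_genome(cfg)
    sample_peaks = _load_sample_peaks(cfg)
    cons = gkm_mod.consensus_peaks(sample_peaks, config=cfg.gkm)
    _write(cons, out / "consensus_peaks.tsv")
    if cfg.gkm.max_train_pos is not None and len(cons) > cfg.gkm.max_train_pos:
        rng = substream(cfg.seed, "train-subsample")
        keep = np.sort(rng.permutation(len(cons))[:cfg.gkm.max_train_pos])
        train_pos = cons.iloc[keep].reset_index(drop=True)
    else:
        train_pos = cons
    neg = gkm_mod.null_sequences(genome, train_pos, cfg.gkm,
                                 rng=substream(cfg.seed, "nullseqs"))
    crop = cfg.gkm.train_crop_bp
    pos_seqs = [_center_crop(s, crop)
                for s in gkm_mod.fetch_sequences(genome, train_pos)]
    neg_seqs = [_center_crop(s, crop)
                for s in gkm_mod.fetch_sequences(genome, neg)]
    _write_fasta_list(pos_seqs, out / "training_pos.fa", "pos")
    _write_fasta_list(neg_seqs, out / "training_neg.fa", "neg")

    model = gkm_mod.train(pos_seqs, neg_seqs, cfg.gkm)
    np.save(out / "gkm_weights.npy", model.weights)
    meta = {"format_version": 1, "word_length": cfg.gkm.word_length,
            "informative_columns": cfg.gkm.informative_columns,
            "C": cfg.gkm.C, "include_revcomp": cfg.gkm.include_revcomp,
            "intercept": model.intercept, "n_pos": model.n_pos,
            "n_neg": model.n_neg, "method": model.method}
    (out / "gkm_model.json").write_text(json.dumps(meta, indent=1, sort_keys=True) + "\n")

    # CV metrics on a (deterministically) subsampled training set
    rng = substream(cfg.seed, "cv-subsample")
    p_idx = rng.permutation(len(pos_seqs))[:cfg.cv_max_per_class]
    n_idx = rng.permutation(len(neg_seqs))[:cfg.cv_max_per_class * cfg.gkm.neg_ratio]
    cv = gkm_mod.cross_validate([pos_seqs[i] for i in sorted(p_idx)],
                                [neg_seqs[i] for i in sorted(n_idx)], cfg.gkm)
    _write(cv, out / "cv_metrics.tsv")
    _checkpoint(cfg, "train-gkm")


def _write_fasta_list(seqs: Sequence[str], path: Path, prefix: str) -> None:
    with open(path, "w") as fh:
        for i, s in enumerate(seqs):
            fh.write(f">{prefix}{i}\n{s}\n")


def load_model(cfg: RunConfig) -> GkmModel:
    out = Path(cfg.outdir)
    meta = json.loads(_require(out / "gkm_model.json").read_text())
    weights = np.load(_require(out / "gkm_weights.npy"))
    gconf = replace(cfg.gkm, word_length=meta["word_length"],
                    informative_columns=meta["informative_columns"],
                    include_revcomp=meta["include_revcomp"])
    return GkmModel(config=gconf, weights=weights, intercept=meta["intercept"],
                    n_pos=meta["n_pos"], n_neg=meta["n_neg"],
                    method=meta["method"])


def stage_delta_svm(cfg: RunConfig) -> None:
    out = Path(cfg.outdir)
    genome = load_genome(cfg)
    model = load_model(cfg)
    sites_df = pd.read_csv(_require(out / "asb_sites.tsv"), sep="\t")
    sites = _sites_from_frame(sites_df)
    _write(gkm_mod.delta_svm_table(model, sites, genome), out / "delta_svm.tsv")
    _checkpoint(cfg, "delta-svm")


def stage_blup(cfg: RunConfig) -> None:
    out = Path(cfg.outdir)
    sites_df = pd.read_csv(_require(out / "asb_sites.tsv"), sep="\t")
    sites = _sites_from_frame(sites_df)
    nbhds = blup_mod.build_neighborhoods(sites, min_matches=cfg.min_flank_matches)
    best, table = blup_mod.grid_search(sites, cfg.grid_s, cfg.grid_u,
                                       neighborhoods=nbhds)
    _write(table, out / "grid_search.tsv")
    preds = blup_mod.predict_all(sites, best, neighborhoods=nbhds)
    _write(preds, out / "blup_predictions.tsv")
    (out / "blup_params.json").write_text(json.dumps(
        {"sigma_s2": best.sigma_s2, "sigma_u2": best.sigma_u2}) + "\n")
    _checkpoint(cfg, "blup")


def stage_combine(cfg: RunConfig) -> None:
    out = Path(cfg.outdir)
    sites = pd.read_csv(_require(out / "asb_sites.tsv"), sep="\t")
    u = pd.read_csv(_require(out / "blup_predictions.tsv"), sep="\t")
    d = pd.read_csv(_require(out / "delta_svm.tsv"), sep="\t")
    rec = sites[["site_id", "chrom", "pos", "y"]].rename(columns={"y": "y_observed"})
    rec = rec.merge(u[["site_id", "u_hat"]], on="site_id")
    rec = rec.merge(d, on="site_id")

    fit = combine_mod.fit_mlr(rec)
    _write(fit.to_frame(), out / "mlr_fit.tsv")
    rec["mlr_score"] = fit.predict(rec.u_hat, rec.delta_svm)
    _write(rec, out / "predictions.tsv")

    scored = rec[rec.y_observed != 0].dropna(subset=["u_hat", "delta_svm"])
    n_top = (combine_mod.default_n_top(len(scored), cfg.n_top)
             if cfg.scale_n_top else cfg.n_top)
    methods = {"gkmsvm": "delta_svm", "blup": "u_hat", "mlr": "mlr_score"}
    acc_rows = []
    cand_sets = {}
    for method, col in methods.items():
        cand = combine_mod.select_candidates(scored, n_top=n_top, score_col=col)
        cand_sets[method] = cand
        _write(cand, out / f"candidates_{method}.tsv")
        acc_rows.append((method, n_top,
                         combine_mod.direction_accuracy(cand, score_col=col)))
    acc = pd.DataFrame(acc_rows, columns=["method", "n_candidates", "accuracy"])
    chi2, p = combine_mod.compare_accuracies(
        acc.loc[acc.method == "blup", "accuracy"].iat[0],
        acc.loc[acc.method == "gkmsvm", "accuracy"].iat[0], n_top, n_top)
    acc["blup_vs_gkmsvm_chi2"] = chi2
    acc["blup_vs_gkmsvm_p"] = p
    _write(acc, out / "accuracy_summary.tsv")
    _checkpoint(cfg, "combine")


def _all_snps(cfg: RunConfig) -> pd.DataFrame:
    if cfg.mode == "simulate":
        truth = pd.read_csv(_require(_data_dir(cfg) / "truth.tsv"), sep="\t")
        return truth[["site_id", "chrom", "pos", "under_peak"]]
    counts = _load_counts(cfg)
    snps = counts[["chrom", "pos"]].drop_duplicates().reset_index(drop=True)
    snps.insert(0, "site_id", snps.chrom.astype(str) + ":" + snps.pos.astype(str))
    snps["under_peak"] = under_peak_flags(snps, _peak_intervals(cfg))
    return snps


def _annotations(cfg: RunConfig) -> enrich_mod.AnnotationSets:
    if cfg.mode == "simulate":
        d = _data_dir(cfg)
        ann = enrich_mod.AnnotationSets.from_files(
            eqtl_sites=d / "eqtl.sites", aseqtl_sites=d / "aseqtl.sites",
            conserved_bed=d / "conserved.bed")
        vpath = d / "validation_counts.tsv"
    else:
        ann = enrich_mod.AnnotationSets.from_files(
            eqtl_sites=cfg.eqtl_sites, aseqtl_sites=cfg.aseqtl_sites,
            conserved_bed=cfg.conserved_bed)
        vpath = Path(cfg.validation_counts_path) if cfg.validation_counts_path else None
    if vpath is not None and Path(vpath).exists():
        vcounts = pd.read_csv(vpath, sep="\t")
        ann.validation_asb = enrich_mod.validation_asb_sites(vcounts)
    return ann


def stage_enrich(cfg: RunConfig) -> None:
    out = Path(cfg.outdir)
    all_snps = _all_snps(cfg)
    sites = pd.read_csv(_require(out / "asb_sites.tsv"), sep="\t")
    asb_ids = set(sites.site_id)
    ann = _annotations(cfg)
    tables, tests = [], []
    for method in ("mlr", "gkmsvm", "blup"):
        cand = pd.read_csv(_require(out / f"candidates_{method}.tsv"), sep="\t")
        labels = enrich_mod.categorize(all_snps, asb_ids, set(cand.site_id))
        table = enrich_mod.annotate_and_tabulate(all_snps, labels, ann)
        table.insert(0, "method", method)
        tables.append(table)
        t = enrich_mod.sequential_tests(table, alpha=cfg.enrichment_alpha)
        t.insert(0, "method", method)
        tests.append(t)
    _write(pd.concat(tables, ignore_index=True), out / "enrichment_table.tsv")
    _write(pd.concat(tests, ignore_index=True), out / "enrichment_tests.tsv")
    _checkpoint(cfg, "enrich")


def stage_report(cfg: RunConfig) -> None:
    """One flat key/value summary of the run's headline numbers."""
    out = Path(cfg.outdir)
    rows: list[tuple[str, object]] = []
    audit = pd.read_csv(out / "asb_audit.tsv", sep="\t")
    rows += [(f"asb.{r.metric}", r["count"]) for _, r in audit.iterrows()]
    grid = pd.read_csv(out / "grid_search.tsv", sep="\t")
    best = grid.loc[grid.r.idxmax()]
    rows += [("blup.best_sigma_s2", best.sigma_s2),
             ("blup.best_sigma_u2", best.sigma_u2),
             ("blup.best_r", best.r)]
    cv = pd.read_csv(out / "cv_metrics.tsv", sep="\t")
    mean = cv[cv.fold == "mean"].iloc[0]
    rows += [("gkm.cv_auroc", mean.auroc), ("gkm.cv_auprc", mean.auprc)]
    mlr = pd.read_csv(out / "mlr_fit.tsv", sep="\t")
    for _, r in mlr.iterrows():
        rows += [(f"mlr.{r.term}.estimate", r.estimate),
                 (f"mlr.{r.term}.p", r.p_value)]
    rows.append(("mlr.adjusted_r2", mlr.adjusted_r2.iat[0]))
    acc = pd.read_csv(out / "accuracy_summary.tsv", sep="\t")
    for _, r in acc.iterrows():
        rows.append((f"accuracy.{r.method}", r.accuracy))
    tests = pd.read_csv(out / "enrichment_tests.tsv", sep="\t")
    rows.append(("enrichment.n_flagged", int(tests.flagged.sum())))
    _write(pd.DataFrame(rows, columns=["metric", "value"]), out / "report.tsv")
    _checkpoint(cfg, "report")


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "call-asb": stage_call_asb,
    "train-gkm": stage_train_gkm,
    "delta-svm": stage_delta_svm,
    "blup": stage_blup,
    "combine": stage_combine,
    "enrich": stage_enrich,
    "report": stage_report,
}


def run_stage(cfg: RunConfig, stage: str) -> None:
    if stage not in _STAGE_FUNCS:
        raise InputError(f"unknown stage {stage!r}; choose from {STAGES}")
    Path(cfg.outdir).mkdir(parents=True, exist_ok=True)
    _STAGE_FUNCS[stage](cfg)


def run_all(cfg: RunConfig) -> Path:
    """Execute every stage in order; returns the run directory."""
    for stage in STAGES:
        run_stage(cfg, stage)
    return Path(cfg.outdir)
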