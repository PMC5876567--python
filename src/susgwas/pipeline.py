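"""End-to-end orchestration: QC -> relatedness/outliers -> ROH/FROH ->
segment sharing + permutation -> GWAS + haplotypes, with per-stage artifacts
and a consolidated run report."""

from __future__ import annotations

import logging
import os
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from susgwas import assoc_gwas, marker_qc, relatedness, roh_inbreeding, segment_sharing
from susgwas.assoc_gwas import ASSOC_P_THRESHOLD
from susgwas.genotype_io import PHENO_CASE, PHENO_CONTROL, GenotypeData, read_ped_map
from susgwas.marker_qc import QcThresholds
from susgwas.roh_inbreeding import RohParams, SWINE_GENOME_KB
from susgwas.segment_sharing import SharingParams

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Every stage parameter, with the screen's standard defaults."""

    ped_path: str = ""
    map_path: str = ""
    out_dir: str = "susgwas_out"
    qc: QcThresholds = field(default_factory=QcThresholds)
    roh: RohParams = field(default_factory=RohParams)
    sharing: SharingParams = field(default_factory=SharingParams)
    ld_window_snps: int = 50
    ld_step_snps: int = 5
    mds_dims: int = 2
    outlier_sd: float = 4.0
    outlier_override: list[str] | None = None
    n_permutations: int = 10_000
    assoc_threshold: float = ASSOC_P_THRESHOLD
    genome_length_kb: float = SWINE_GENOME_KB
    hap_markers: list[str] | None = None
    seed: int = 1

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "qc" in kwargs:
            kwargs["qc"] = QcThresholds(**kwargs["qc"])
        if "roh" in kwargs:
            kwargs["roh"] = RohParams(**kwargs["roh"])
        if "sharing" in kwargs:
            kwargs["sharing"] = SharingParams(**kwargs["sharing"])
        return cls(**kwargs)


@dataclass
class RunReport:
    """Headline numbers and per-stage attrition for one pipeline run."""

    n_samples_in: int = 0
    n_markers_in: int = 0
    n_samples_qc: int = 0
    n_markers_qc: int = 0
    n_outliers_removed: int = 0
    n_samples_analysis: int = 0
    n_cases: int = 0
    n_controls: int = 0
    n_markers_pruned: int = 0
    pruned_per_chromosome: dict = field(default_factory=dict)
    mean_pi_hat: float = float("nan")
    lambda_gc: float = float("nan")
    froh_mean_cases: float = float("nan")
    froh_mean_controls: float = float("nan")
    froh_t: float = float("nan")
    froh_p: float = float("nan")
    n_roh_segments: int = 0
    n_shared_segments: int = 0
    min_chrom_sharing_p: float = float("nan")
    min_chrom_sharing_chrom: str = ""
    n_assoc_significant: int = 0
    top_assoc_snp: str = ""
    top_assoc_p: float = float("nan")
    stage_seconds: dict = field(default_factory=dict)
    config_echo: dict = field(default_factory=dict)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def summary(self) -> str:
        lines = [
            f"samples: {self.n_samples_in} in -> {self.n_samples_qc} after QC -> "
            f"{self.n_samples_analysis} after outlier removal "
            f"({self.n_cases} cases / {self.n_controls} controls)",
            f"markers: {self.n_markers_in} in -> {self.n_markers_qc} after QC; "
            f"{self.n_markers_pruned} after LD pruning",
            f"mean PI_HAT (analysis set): {self.mean_pi_hat:.3f}",
            f"lambda_GC: {self.lambda_gc:.3f}",
            f"FROH cases {self.froh_mean_cases:.4f} vs controls "
            f"{self.froh_mean_controls:.4f} (t = {self.froh_t:.2f}, p = {self.froh_p:.3g})",
            f"sharing: {self.n_shared_segments} segments; best chromosome "
            f"{self.min_chrom_sharing_chrom} (p = {self.min_chrom_sharing_p:.4g})",
            f"GWAS: {self.n_assoc_significant} markers below "
            f"p = {self.config_echo.get('assoc_threshold', ASSOC_P_THRESHOLD):g}; "
            f"top {self.top_assoc_snp} (p = {self.top_assoc_p:.3g})",
        ]
        return "\n".join(lines)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage


def run_pipeline(
    config: PipelineConfig, data: GenotypeData | None = None
) -> RunReport:
    """Run all stages in order, writing per-stage TSVs under ``out_dir``.

    ``data`` may be passed directly (e.g. a simulated dataset); otherwise
    the configured PED/MAP is read.  Identical config + input + seed gives
    identical outputs.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    report = RunReport()
    report.config_echo = {
        "seed": config.seed,
        "n_permutations": config.n_permutations,
        "assoc_threshold": config.assoc_threshold,
        "genome_length_kb": config.genome_length_kb,
    }

    def stage(name):
        class _Ctx:
            def __enter__(self_):
                self_.t0 = time.perf_counter()
                logger.info("stage %s started", name)
                return self_

            def __exit__(self_, exc_type, exc, tb):
                report.stage_seconds[name] = round(time.perf_counter() - self_.t0, 3)
                if exc is not None:
                    raise StageError(name, exc) from exc
                logger.info("stage %s done in %.2fs", name, report.stage_seconds[name])
        return _Ctx()

    with stage("load"):
        if data is None:
            data = read_ped_map(config.ped_path, config.map_path)
        report.n_samples_in = data.n_samples
        report.n_markers_in = data.n_markers

    with stage("qc"):
        qc_data, qc_report = marker_qc.filter_markers(data, config.qc)
        qc_report.to_tsv(os.path.join(config.out_dir, "qc_removed.tsv"))
        with open(os.path.join(config.out_dir, "qc_summary.txt"), "w") as fh:
            fh.write(qc_report.summary() + "\n")
        report.n_samples_qc = qc_data.n_samples
        report.n_markers_qc = qc_data.n_markers

    with stage("ld_prune"):
        kept = marker_qc.ld_prune(
            qc_data, config.ld_window_snps, config.ld_step_snps, config.qc.ld_r2_max
        )
        kept_set = set(kept)
        pruned = qc_data.subset(
            marker_idx=[j for j, s in enumerate(qc_data.marker_ids) if s in kept_set]
        )

    with stage("relatedness"):
        dist = relatedness.ibs_distance_matrix(pruned)
        proj = relatedness.classical_mds(dist, k=config.mds_dims)
        proj.to_frame().to_csv(
            os.path.join(config.out_dir, "mds_coords.tsv"), sep="\t", index=False
        )
        outliers = relatedness.flag_background_outliers(
            proj, config.outlier_sd, config.outlier_override
        )
        with open(os.path.join(config.out_dir, "outliers.txt"), "w") as fh:
            fh.write("\n".join(outliers) + ("\n" if outliers else ""))
        report.n_outliers_removed = len(outliers)
        keep_idx = [
            i for i, iid in enumerate(qc_data.sample_ids) if iid not in set(outliers)
        ]
        analysis = qc_data.subset(sample_idx=keep_idx).set_minor_allele_first()
        pruned = pruned.subset(sample_idx=keep_idx)
        report.n_samples_analysis = analysis.n_samples
        report.n_cases = int(analysis.case_mask().sum())
        report.n_controls = int(analysis.control_mask().sum())
        if report.n_cases == 0 or report.n_controls == 0:
            raise ValueError("analysis set has a single phenotype class")
        ibd = relatedness.ibd_pi_hat(pruned)
        ibd.to_csv(os.path.join(config.out_dir, "ibd.tsv"), sep="\t", index=False)
        report.mean_pi_hat = float(ibd["pi_hat"].mean())
        counts = pruned.autosomal().markers["chrom"].value_counts()
        report.pruned_per_chromosome = {str(k): int(v) for k, v in counts.items()}
        report.n_markers_pruned = int(counts.sum())

    with stage("roh"):
        segments = roh_inbreeding.detect_roh(analysis, config.roh)
        roh_inbreeding.segments_table(segments).to_csv(
            os.path.join(config.out_dir, "roh_segments.tsv"), sep="\t", index=False
        )
        froh = roh_inbreeding.froh_table(
            segments, analysis.sample_ids, config.genome_length_kb
        )
        froh = froh.merge(
            analysis.samples[["iid", "phenotype"]], on="iid", how="left"
        )
        froh.to_csv(os.path.join(config.out_dir, "froh.tsv"), sep="\t", index=False)
        report.n_roh_segments = len(segments)
        fc = froh.loc[froh["phenotype"] == PHENO_CASE, "froh"].to_numpy()
        fu = froh.loc[froh["phenotype"] == PHENO_CONTROL, "froh"].to_numpy()
        mc, mu, t, p = roh_inbreeding.froh_group_test(fc, fu)
        report.froh_mean_cases = mc
        report.froh_mean_controls = mu
        report.froh_t = t
        report.froh_p = p

    with stage("sharing"):
        shared = segment_sharing.detect_shared_segments(pruned, config.sharing)
        segment_sharing.segments_table(shared).to_csv(
            os.path.join(config.out_dir, "shared_segments.tsv"), sep="\t", index=False
        )
        grid = segment_sharing.marker_grid(pruned)
        pheno = dict(zip(pruned.sample_ids, pruned.phenotypes()))
        perm = segment_sharing.permutation_pvalues(
            shared, pheno, grid, config.n_permutations, config.seed
        )
        perm.to_frame().to_csv(
            os.path.join(config.out_dir, "sharing_permutation.tsv"),
            sep="\t",
            index=False,
        )
        report.n_shared_segments = len(shared)
        if len(perm.chrom_min_p):
            best = perm.chrom_min_p.sort_values("p").iloc[0]
            report.min_chrom_sharing_p = float(best["p"])
            report.min_chrom_sharing_chrom = str(best["chrom"])

    with stage("assoc"):
        scan = assoc_gwas.gwas_scan(analysis)
        betas = []
        labels = (analysis.phenotypes() == PHENO_CASE).astype(float)
        for j in range(analysis.n_markers):
            try:
                eff = assoc_gwas.logistic_effect(analysis.calls[:, j], labels)
                betas.append((eff.beta, eff.se, eff.p, eff.separation))
            except ValueError:
                betas.append((np.nan, np.nan, np.nan, False))
        scan[["beta", "beta_se", "beta_p"]] = pd.DataFrame(
            [(b, s, p) for b, s, p, _ in betas]
        )
        scan["separation"] = [sep for *_, sep in betas]
        scan.to_csv(os.path.join(config.out_dir, "assoc.tsv"), sep="\t", index=False)
        finite = scan.dropna(subset=["chi2"])
        infl = assoc_gwas.genomic_inflation(finite["chi2"].to_numpy())
        report.lambda_gc = infl.lambda_gc
        assoc_gwas.qq_points(finite["p"].to_numpy()).to_csv(
            os.path.join(config.out_dir, "qq.tsv"), sep="\t", index=False
        )
        sig = finite[finite["p"] < config.assoc_threshold]
        report.n_assoc_significant = len(sig)
        if len(finite):
            top = finite.sort_values("p").iloc[0]
            report.top_assoc_snp = str(top["snp"])
            report.top_assoc_p = float(top["p"])
        hap_markers = config.hap_markers
        if hap_markers is None and 2 <= len(sig) and len(set(sig["chrom"])) >= 1:
            # default: top markers sharing the top marker's chromosome
            top_chrom = finite.sort_values("p").iloc[0]["chrom"]
            same = sig[sig["chrom"] == top_chrom].sort_values("p")["snp"].tolist()
            hap_markers = same[:3] if len(same) >= 2 else None
        if hap_markers:
            hap = assoc_gwas.haplotype_assoc(analysis, list(hap_markers))
            hap.to_frame().to_csv(
                os.path.join(config.out_dir, "haplotypes.tsv"), sep="\t", index=False
            )

    report.to_yaml(os.path.join(config.out_dir, "report.yaml"))
    return report
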