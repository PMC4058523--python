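"""End-to-end orchestration: config, stage order, outputs, determinism.

Stage order: outlier detection (miRNA and mRNA) → inverse-correlation
screen → subnetwork construction → exclusivity Z-score nomination →
evaluation (ROC + clustering).  Every stage's output can be written as TSV
and re-read, so partial reruns are cheap; all randomness flows from the one
master seed through a fixed per-stage derivation, and two runs with the
same config produce byte-identical TSV outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import correlation, data_io, evaluation, lsoss, scoring, simulate, subnetwork

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage hard error, tagged with the failing stage's name."""


# stage name -> offset mixed into the master seed
_STAGE_OFFSETS = {
    "simulate-cohort": 0,
    "simulate-network": 1,
    "mirna-outliers": 2,
    "gene-outliers": 3,
    "alpha-null": 4,
}


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage child seed (< 2^31) from the master seed."""
    ss = np.random.SeedSequence([int(master_seed), _STAGE_OFFSETS[stage]])
    return int(ss.generate_state(1)[0] % (2 ** 31 - 1))


@dataclass
class SimulateSpec:
    """Synthetic-cohort block of a run config (defaults = study conditions)."""

    n_mirna: int = 100
    n_gene: int = 500
    n_control: int = 6
    n_case: int = 19
    noise_sd: float = 1.0
    n_extra_edges: int = 500
    n_rich: int = 4
    exclusive_per_rich: int = 6
    n_heavy_pairs: int = 3
    shared_per_pair: int = 10
    planted_effect: float = 3.0
    outlier_fraction: float = 0.6
    slope: float = 2.0
    shared_slope: float = 1.4
    partner_correlation: float = 0.45

    def make_truth(self) -> simulate.GroundTruth:
        return simulate.default_truth(
            n_mirna=self.n_mirna,
            n_gene=self.n_gene,
            n_rich=self.n_rich,
            exclusive_per_rich=self.exclusive_per_rich,
            n_heavy_pairs=self.n_heavy_pairs,
            shared_per_pair=self.shared_per_pair,
            planted_effect=self.planted_effect,
            outlier_fraction=self.outlier_fraction,
            slope=self.slope,
            shared_slope=self.shared_slope,
            partner_correlation=self.partner_correlation,
        )


@dataclass
class RunConfig:
    """Flat, human-editable run configuration.

    Either the four input paths or a ``simulate`` block must be given.
    Defaults follow the published thresholds where stated (rho <= −0.6,
    correlation p < 0.05, Z >= 0.3, alpha > 1, alpha p < 0.05) and the
    package defaults documented in docs/methods.md otherwise.
    """

    seed: int = 0
    out_dir: str | None = None
    # inputs: files ...
    mirna_path: str | None = None
    gene_path: str | None = None
    annotation_path: str | None = None
    network_path: str | None = None
    # ... or simulation
    simulate: SimulateSpec | None = None
    # transforms / thresholds
    log_transform: bool = True
    pseudocount: float = 1.0
    lsoss_q: float | None = None
    lsoss_top_n: int | None = None
    lsoss_top_frac: float | None = 0.5
    n_perm: int = 999
    rho_cutoff: float = -0.6
    corr_p_cutoff: float = 0.05
    corr_sample_mode: str = "all-paired"
    z_cutoff: float = 0.3
    alpha_min: int = 1
    alpha_p_cutoff: float = 0.05
    # output options
    make_plots: bool = False
    write_graphml: bool = False

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        def fail(msg):
            raise PipelineError(f"stage config: {msg}")

        if not isinstance(self.seed, int) or not 0 <= self.seed < 2 ** 31:
            fail(f"seed must be an integer in [0, 2^31), got {self.seed!r}")
        paths = [self.mirna_path, self.gene_path, self.annotation_path,
                 self.network_path]
        if self.simulate is None:
            if any(p is None for p in paths):
                fail("either a simulate block or all four input paths are required")
        elif any(p is not None for p in paths):
            fail("give either input paths or a simulate block, not both")
        if self.pseudocount < 0:
            fail("pseudocount must be nonnegative")
        if self.lsoss_q is not None and not 0 < self.lsoss_q <= 1:
            fail(f"lsoss_q must be in (0, 1], got {self.lsoss_q}")
        if self.lsoss_top_n is not None and self.lsoss_top_n < 1:
            fail("lsoss_top_n must be a positive integer")
        if self.lsoss_top_frac is not None and not 0 < self.lsoss_top_frac <= 1:
            fail(f"lsoss_top_frac must be in (0, 1], got {self.lsoss_top_frac}")
        if self.n_perm < 0:
            fail("n_perm must be >= 0")
        if self.n_perm == 0 and self.lsoss_q is not None:
            fail("n_perm = 0 cannot support a q-value outlier gate")
        if not -1.0 <= self.rho_cutoff <= 0.0:
            fail(f"rho_cutoff must be in [-1, 0], got {self.rho_cutoff}")
        if not 0 < self.corr_p_cutoff <= 1:
            fail(f"corr_p_cutoff must be in (0, 1], got {self.corr_p_cutoff}")
        if self.corr_sample_mode not in correlation.SAMPLE_MODES:
            fail(f"corr_sample_mode must be one of {correlation.SAMPLE_MODES}")
        if not 0.0 <= self.z_cutoff <= 1.0:
            fail(f"z_cutoff must be in [0, 1], got {self.z_cutoff}")
        if self.alpha_min < 0:
            fail("alpha_min must be >= 0")
        if not 0 < self.alpha_p_cutoff <= 1:
            fail(f"alpha_p_cutoff must be in (0, 1], got {self.alpha_p_cutoff}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise PipelineError(f"stage config: unknown config keys {sorted(unknown)}")
        sim = d.get("simulate")
        if isinstance(sim, dict):
            sim_known = {f.name for f in dataclasses.fields(SimulateSpec)}
            sim_unknown = set(sim) - sim_known
            if sim_unknown:
                raise PipelineError(
                    f"stage config: unknown simulate keys {sorted(sim_unknown)}"
                )
            d["simulate"] = SimulateSpec(**sim)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if not isinstance(d, dict):
            raise PipelineError("stage config: config file must hold a mapping")
        return cls.from_dict(d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass
class PipelineResult:
    config: dict
    counts: dict
    mirna_results: list = field(default_factory=list)
    gene_results: list = field(default_factory=list)
    mirna_selected: list = field(default_factory=list)
    gene_selected: list = field(default_factory=list)
    pairs: object = None  # DataFrame
    network: object = None  # RegulatorySubnetwork
    scores: object = None  # DataFrame with p_alpha + is_candidate
    candidates: object = None  # DataFrame subset
    roc_results: list = field(default_factory=list)
    clustering: object = None
    truth: object = None  # GroundTruth when simulated
    cohort: object = None  # Cohort when simulated
    out_dir: str | None = None


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with stage name and cause."""

    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is None:
                logger.info("stage %s: done in %.2fs", name, dt)
                return False
            if isinstance(exc, PipelineError):
                return False
            raise PipelineError(f"stage {name}: {exc}") from exc

    return _Ctx()


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Execute all stages; returns in-memory results and (optionally) writes
    every stage output plus ``run_summary.json`` under ``cfg.out_dir``."""
    counts: dict = {}
    truth = cohort = None
    out = Path(cfg.out_dir) if cfg.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    with _stage("load-inputs"):
        if cfg.simulate is not None:
            truth = cfg.simulate.make_truth()
            cohort = simulate.generate_cohort(
                truth,
                n_control=cfg.simulate.n_control,
                n_case=cfg.simulate.n_case,
                noise_sd=cfg.simulate.noise_sd,
                seed=stage_seed(cfg.seed, "simulate-cohort"),
            )
            mirna_em, gene_em, ann = cohort.mirna, cohort.genes, cohort.annotation
            reference = simulate.generate_reference_network(
                truth,
                n_extra_edges=cfg.simulate.n_extra_edges,
                seed=stage_seed(cfg.seed, "simulate-network"),
            )
            if out:
                inp = out / "inputs"
                inp.mkdir(exist_ok=True)
                data_io.write_expression(mirna_em, inp / "mirna_expression.tsv")
                data_io.write_expression(gene_em, inp / "gene_expression.tsv")
                data_io.write_annotation(ann, inp / "sample_annotation.tsv")
                data_io.write_edge_list(reference, inp / "reference_network.tsv")
                simulate.write_truth(truth, inp / "truth.tsv")
        else:
            mirna_em = data_io.read_expression(cfg.mirna_path, "miRNA")
            gene_em = data_io.read_expression(cfg.gene_path, "mRNA")
            ann = data_io.read_annotation(cfg.annotation_path)
            reference = data_io.read_edge_list(cfg.network_path)
            if cfg.log_transform:
                mirna_em = data_io.log_transform(mirna_em, cfg.pseudocount)
                gene_em = data_io.log_transform(gene_em, cfg.pseudocount)
        counts["mirna_features"] = mirna_em.n_features
        counts["gene_features"] = gene_em.n_features
        counts["samples_mirna"] = mirna_em.n_samples
        counts["samples_gene"] = gene_em.n_samples
        counts["reference_edges"] = len(reference)

    with _stage("outliers"):
        mirna_results = lsoss.lsoss_scan(
            mirna_em, ann, n_perm=cfg.n_perm, seed=stage_seed(cfg.seed, "mirna-outliers")
        )
        gene_results = lsoss.lsoss_scan(
            gene_em, ann, n_perm=cfg.n_perm, seed=stage_seed(cfg.seed, "gene-outliers")
        )
        mirna_sel = lsoss.select_outliers(
            mirna_results, q_cutoff=cfg.lsoss_q, top_n=cfg.lsoss_top_n,
            top_frac=cfg.lsoss_top_frac,
        )
        gene_sel = lsoss.select_outliers(
            gene_results, q_cutoff=cfg.lsoss_q, top_n=cfg.lsoss_top_n,
            top_frac=cfg.lsoss_top_frac,
        )
        counts["mirna_outliers"] = len(mirna_sel)
        counts["gene_outliers"] = len(gene_sel)
        if out:
            lsoss.write_outlier_table(mirna_results, out / "mirna_outliers.tsv")
            lsoss.write_outlier_table(gene_results, out / "gene_outliers.tsv")

    with _stage("correlate"):
        pairs = correlation.screen_pairs(
            mirna_sel, gene_sel, mirna_em, gene_em, ann,
            rho_cutoff=cfg.rho_cutoff,
            p_cutoff=cfg.corr_p_cutoff,
            sample_mode=cfg.corr_sample_mode,
        )
        counts["pairs_tested"] = pairs.attrs.get("n_tested", 0)
        counts["pairs_retained"] = len(pairs)
        if out:
            correlation.write_pairs(pairs, out / "inverse_pairs.tsv")

    with _stage("network"):
        net = subnetwork.build_subnetwork(pairs, reference)
        counts.update({f"subnetwork_{k}": v for k, v in net.summary().items()})
        if out:
            subnetwork.write_subnetwork(net, out / "subnetwork_edges.tsv")
            if cfg.write_graphml:
                subnetwork.write_graphml(net, out / "subnetwork.graphml")

    with _stage("score"):
        if net.n_edges > 0:
            scores = scoring.score_mirnas(net)
            p_alpha = scoring.alpha_significance(
                net, n_perm=max(cfg.n_perm, 1), seed=stage_seed(cfg.seed, "alpha-null")
            )
            scores["p_alpha"] = scores["mirna_id"].map(p_alpha)
            scores = scoring.nominate(
                scores,
                z_cutoff=cfg.z_cutoff,
                alpha_min=cfg.alpha_min,
                p_cutoff=cfg.alpha_p_cutoff,
            )
        else:
            import pandas as pd

            scores = pd.DataFrame(
                columns=["mirna_id", "alpha", "beta", "z", "p_alpha", "is_candidate"]
            )
        candidates = scores[scores["is_candidate"].astype(bool)].reset_index(drop=True) \
            if len(scores) else scores
        counts["candidates"] = len(candidates)
        if out:
            scoring.write_scores(scores, out / "mirna_scores.tsv")

    with _stage("evaluate"):
        direction_of = {r.feature_id: r.direction for r in mirna_results}
        labels = ann.labels_for(mirna_em.sample_ids)
        roc_results = []
        for mid in list(candidates["mirna_id"]) if len(candidates) else []:
            roc_results.append(
                evaluation.evaluate_roc(
                    mirna_em.data.loc[mid].to_numpy(dtype=float),
                    labels,
                    direction=direction_of.get(mid, "up"),
                    mirna_id=mid,
                )
            )
        clustering = None
        if len(candidates) >= 2:
            cand_em = data_io.ExpressionMatrix(
                mirna_em.data.loc[list(candidates["mirna_id"])],
                feature_kind="miRNA",
                log_scale=mirna_em.log_scale,
            )
            clustering = evaluation.cluster_samples(cand_em, ann)
            counts["clustering_agreement"] = clustering.agreement
        else:
            logger.warning("evaluate: fewer than 2 candidates, clustering skipped")
        if out:
            evaluation.report(
                candidates if len(candidates) else scores,
                roc_results,
                clustering,
                out,
                expr=(cand_em if len(candidates) >= 2 else None),
                ann=ann,
                make_plots=cfg.make_plots,
            )

    # stage-count monotonicity: candidates ⊆ subnetwork miRNAs ⊆ outlier miRNAs
    cand_set = set(candidates["mirna_id"]) if len(candidates) else set()
    outlier_set = {r.feature_id for r in mirna_sel}
    if not cand_set <= net.mirnas:
        raise PipelineError("stage invariant: candidates not a subset of subnetwork miRNAs")
    if not net.mirnas <= outlier_set:
        raise PipelineError("stage invariant: subnetwork miRNAs not a subset of outliers")

    result = PipelineResult(
        config=cfg.to_dict(),
        counts=counts,
        mirna_results=mirna_results,
        gene_results=gene_results,
        mirna_selected=mirna_sel,
        gene_selected=gene_sel,
        pairs=pairs,
        network=net,
        scores=scores,
        candidates=candidates,
        roc_results=roc_results,
        clustering=clustering,
        truth=truth,
        cohort=cohort,
        out_dir=str(out) if out else None,
    )
    if out:
        cfg_echo = {k: v for k, v in result.config.items() if k != "out_dir"}
        summary = {
            "config": cfg_echo,
            "counts": {k: (round(v, 6) if isinstance(v, float) else v)
                       for k, v in counts.items()},
            "candidates": sorted(cand_set),
        }
        (out / "run_summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True) + "\n"
        )
    return result
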