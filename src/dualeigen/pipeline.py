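"""End-to-end dual eigen-analysis driven by a single config.

The workflow chains: simulate (or load) the expression profile -> SVD of
the pooled profile and of the control-only profile -> sign anchoring ->
component matching and endogenous/exogenous classification -> per-component
factor associations -> two-end Wilcoxon enrichment of the gene eigenvectors
-> optional motif/loading association.  Every run writes its resolved
configuration beside the outputs and is byte-reproducible from
(inputs, config, seed).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as deio
from .dual import associate_all, classify_components, match_components
from .eigen import compute_svd, contribution_percentages, fix_signs
from .enrichment import enrich_collection, results_frame
from .motif import PWM, base_association, scan_pwm_affinity
from .profiles import ExpressionProfile
from .simulate import (
    SimulationSpec,
    generate_genesets,
    generate_profile,
    generate_promoters,
)

log = logging.getLogger("dualeigen")


@dataclass
class PipelineConfig:
    """All stage parameters of one dual eigen-analysis run."""

    seed: int = 0
    outdir: str = "dualeigen_out"

    # inputs; None -> simulate with `simulation`
    expression_tsv: str | None = None
    attributes_tsv: str | None = None
    gmt: str | None = None
    promoters_fasta: str | None = None
    pfm: str | None = None

    simulation: dict = field(default_factory=dict)

    centering: str = "gene"
    anchor: str = "week"
    top_k: int = 3
    min_match_similarity: float = 0.3
    sim_threshold: float = 0.6
    alpha: float = 0.05

    run_enrichment: bool = True
    min_set_size: int = 5
    n_null_sets: int = 100

    run_motif: bool = True
    n_perm: int = 999
    promoter_length: int = 200
    planted_consensus: str = "AGGTCA"
    null_consensus: str = "CCGGAA"

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)


@dataclass
class DualEigenReport:
    pooled: object
    control: object
    matches: list
    associations: list
    components: pd.DataFrame
    enrichment: dict
    motif: pd.DataFrame | None
    truth: object | None
    outdir: Path


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


@_stage("inputs")
def _load_inputs(config: PipelineConfig):
    if config.expression_tsv:
        profile = deio.read_expression_tsv(config.expression_tsv, config.attributes_tsv)
        return profile, None
    spec = SimulationSpec(**{"seed": config.seed, **config.simulation})
    return generate_profile(spec)


def run_dual_eigen(config: PipelineConfig) -> DualEigenReport:
    """Execute the full dual eigen-analysis and write the report bundle."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_log(outdir)
    log.info("seed=%d centering=%s top_k=%d", config.seed, config.centering, config.top_k)

    profile, truth = _load_inputs(config)
    attrs = profile.attributes
    if attrs is None:
        raise RuntimeError("pipeline stage 'inputs' failed: attribute table required")

    pooled = _stage("svd-pooled")(compute_svd)(profile, config.centering)
    pooled = fix_signs(pooled, attrs, config.anchor)
    control_profile = profile.control_only()
    control = _stage("svd-control")(compute_svd)(control_profile, config.centering)
    control = fix_signs(control, control_profile.attributes, config.anchor)

    matches = _stage("match")(match_components)(
        pooled, control, config.top_k, config.min_match_similarity
    )
    associations = _stage("associate")(associate_all)(pooled, attrs, config.top_k)
    matches = classify_components(
        matches, associations, config.sim_threshold, config.alpha
    )

    components = _components_table(pooled, matches, associations)

    enrichment: dict[int, pd.DataFrame] = {}
    if config.run_enrichment:
        collection = _gene_sets(config, profile, truth)
        if collection is not None:
            for m in matches:
                u = pooled.gene_loadings(m.pooled_index)
                res = _stage("enrichment")(enrich_collection)(
                    u, collection, config.min_set_size
                )
                enrichment[m.pooled_index] = results_frame(res)

    motif_table = None
    if config.run_motif:
        motif_table = _stage("motif")(_run_motif)(config, profile, truth, pooled, matches)

    _write_outputs(config, outdir, profile, truth, pooled, control,
                   components, enrichment, motif_table)
    return DualEigenReport(pooled, control, matches, associations, components,
                           enrichment, motif_table, truth, outdir)


def _setup_log(outdir: Path) -> None:
    log.setLevel(logging.INFO)
    log.handlers = [h for h in log.handlers if not isinstance(h, logging.FileHandler)]
    if not any(isinstance(h, logging.StreamHandler) for h in log.handlers):
        log.addHandler(logging.StreamHandler())
    fh = logging.FileHandler(outdir / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    import numpy, scipy, pandas  # noqa: PLC0415
    log.info("versions numpy=%s scipy=%s pandas=%s",
             numpy.__version__, scipy.__version__, pandas.__version__)


def _components_table(pooled, matches, associations) -> pd.DataFrame:
    cum = contribution_percentages(pooled.rho)
    p_by = {}
    for a in associations:
        p_by.setdefault(a.component_index, {})[a.factor] = a.p_value
    rows = []
    for m in matches:
        k = m.pooled_index
        row = {
            "component": k + 1,
            "rho": pooled.rho[k],
            "cumulative_pct": cum[k],
            "matched_control_component": "" if m.control_index is None else m.control_index + 1,
            "similarity": m.similarity,
            "classification": m.classification,
        }
        for factor, p in sorted(p_by.get(k, {}).items()):
            row[f"p_{factor}"] = p
        rows.append(row)
    return pd.DataFrame(rows)


def _gene_sets(config, profile, truth):
    if config.gmt:
        return deio.read_gmt(config.gmt, profile.genes)
    if truth is not None:
        return generate_genesets(truth, n_null_sets=config.n_null_sets,
                                 seed=config.seed + 1)
    return None


def _run_motif(config, profile, truth, pooled, matches):
    """Affinity scan + running-sum association of each motif with each component."""
    if config.promoters_fasta:
        promoters = deio.read_promoters_fasta(config.promoters_fasta)
        pwms = deio.read_jaspar_pfm(config.pfm) if config.pfm else []
        if not pwms:
            return None
    elif truth is not None:
        planted = PWM.from_consensus("planted", config.planted_consensus)
        null = PWM.from_consensus("null", config.null_consensus)
        promoters = generate_promoters(
            truth, planted, promoter_length=config.promoter_length,
            seed=config.seed + 2,
        )
        pwms = [planted, null]
    else:
        return None

    rows = []
    for pwm in pwms:
        affinity = scan_pwm_affinity(promoters, pwm)
        for m in matches:
            u = pooled.gene_loadings(m.pooled_index)
            res = base_association(u, affinity, n_perm=config.n_perm,
                                   seed=config.seed + 3 + m.pooled_index)
            rows.append({
                "motif": pwm.name,
                "component": m.pooled_index + 1,
                "score": res.score,
                "end": res.end,
                "p_value": res.p_value,
            })
    table = pd.DataFrame(rows)
    n_motifs = len(pwms)
    table["p_bonferroni"] = np.minimum(1.0, table["p_value"] * n_motifs)
    return table


def _write_outputs(config, outdir, profile, truth, pooled, control,
                   components, enrichment, motif_table) -> None:
    config.to_yaml(outdir / "config.resolved.yaml")
    if config.expression_tsv is None:
        deio.write_expression_tsv(profile, outdir / "expression.tsv")
        deio.write_attributes_tsv(profile, outdir / "attributes.tsv")
    if truth is not None:
        deio.write_ground_truth(truth, outdir / "ground_truth.json")
    deio.write_decomposition(pooled, outdir / "pooled")
    deio.write_decomposition(control, outdir / "control")
    components.to_csv(outdir / "components.tsv", sep="\t", index=False,
                      float_format=deio.FLOAT_FMT)
    for k in range(pooled.n_components):
        v = pooled.sample_loadings(k).sort_values()
        table = pd.DataFrame({"loading": v})
        if profile.attributes is not None:
            table = table.join(profile.attributes)
        table.to_csv(outdir / f"sample_loadings.component{k + 1}.tsv", sep="\t",
                     index_label="sample_id", float_format=deio.FLOAT_FMT)
    for k, frame in enrichment.items():
        frame.to_csv(outdir / f"enrichment.component{k + 1}.tsv", sep="\t",
                     index=False, float_format=deio.FLOAT_FMT)
    if motif_table is not None:
        motif_table.to_csv(outdir / "motif_association.tsv", sep="\t", index=False,
                           float_format=deio.FLOAT_FMT)
    log.info("report written to %s", outdir)
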