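"""End-to-end orchestration: binding map -> DE -> enrichment -> sponge null.

The enrichment stage joins the DE stage's downregulated gene list to the
binding summaries by gene name; genes absent from the binding table count as
unbound (the report states this).  Every stage logs its parameters; the final
JSON report embeds the exact configuration and SHA-256 digests of all inputs
so a run is auditable and reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import diff_expression as de_mod
from . import enrichment as enr_mod
from . import promoter_binding as pb
from . import sponge as sp
from .energy import EnergyParams, default_params, load_params

log = logging.getLogger("tfmir")

__all__ = ["PipelineConfig", "StageError", "run_all"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    promoters: str
    clusters: str
    matrix: str
    design: str
    transcript: str
    mirs: str
    out_dir: str
    alpha: float = 0.05
    bed0: bool = False
    min_overlap_bp: int = 1
    bh_correction: bool = False
    universe_kind: str = "promoter"  # or "gene"
    n_shuffles: int = 100
    seed: int = 0
    energy_params: str | None = None
    utr3: tuple[int, int] | None = None  # 0-based half-open
    both_orientations: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.universe_kind not in {"promoter", "gene"}:
            raise ValueError("universe_kind must be 'promoter' or 'gene'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if raw.get("utr3") is not None:
            raw["utr3"] = tuple(raw["utr3"])
        return cls(**raw)

    def check_inputs(self) -> None:
        for name in ("promoters", "clusters", "matrix", "design", "transcript", "mirs"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"input file for {name!r} not found: {p}")


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _binding_stage(config: PipelineConfig, out: Path) -> tuple[dict, dict[str, bool], list]:
    dialect = "bed0" if config.bed0 else "1based"
    promoters = pb.read_promoters(config.promoters, dialect=dialect)
    clusters = pb.read_clusters(config.clusters)
    log.info(
        "map-binding: %d promoters, %d clusters, min_overlap_bp=%d",
        len(promoters), len(clusters), config.min_overlap_bp,
    )
    assignment = pb.intersect(promoters, clusters, min_overlap_bp=config.min_overlap_bp)
    summaries = [pb.summarize_binding(p, assignment[p.promoter_id]) for p in promoters]
    pb.write_binding_table(promoters, summaries, out / "binding_table.tsv")
    counts = pb.write_classification_json(summaries, out / "binding_counts.json")
    gene_bound: dict[str, bool] = {}
    for s in summaries:
        for g in s.mir_genes:
            gene_bound[g] = gene_bound.get(g, False) or s.bound
    return counts, gene_bound, summaries


def _de_stage(config: PipelineConfig, out: Path):
    matrix = de_mod.read_expression(config.matrix, config.design)
    log.info("de: %d probes x %d samples, alpha=%g", *matrix.values.shape, config.alpha)
    normalized = de_mod.quantile_normalize(matrix)
    results = de_mod.call_de(
        normalized, alpha=config.alpha, bh_correction=config.bh_correction
    )
    de_mod.de_table(results).to_csv(out / "de_table.tsv", sep="\t", index=False)
    counts = {
        "down_in_kd": sum(r.direction == "down_in_kd" for r in results),
        "up_in_kd": sum(r.direction == "up_in_kd" for r in results),
        "ns": sum(r.direction == "ns" for r in results),
    }
    with open(out / "de_counts.json", "w") as fh:
        json.dump(counts, fh, indent=2)
    return results, counts


def _enrichment_stage(
    config: PipelineConfig, gene_bound: dict[str, bool], summaries, de_results
) -> dict:
    down_genes = {r.gene_id for r in de_results if r.direction == "down_in_kd"}
    if config.universe_kind == "gene":
        universe = {r.gene_id for r in de_results} | set(gene_bound)
        bound = {g for g, b in gene_bound.items() if b}
        selected = down_genes & universe
        selected_bound = down_genes & bound
        inp = enr_mod.EnrichmentInput(
            len(universe), len(bound), len(selected), len(selected_bound)
        )
    else:  # promoter-level units
        n_bound = sum(s.bound for s in summaries)
        sel = [s for s in summaries if down_genes & set(s.mir_genes)]
        inp = enr_mod.EnrichmentInput(
            len(summaries), n_bound, len(sel), sum(s.bound for s in sel)
        )
    p_analytic = enr_mod.hypergeom_tail(inp)
    p_empirical = enr_mod.permutation_enrichment(inp, iters=100_000, seed=config.seed)
    frac_full, frac_round = (
        enr_mod.bound_fraction(inp) if inp.n_selected else (float("nan"), 0)
    )
    log.info("enrich: counts=%s p=%.3g", inp, p_analytic)
    return {
        "universe_kind": config.universe_kind,
        "join": "by gene name; genes absent from the binding table count as unbound",
        "counts": dataclasses.asdict(inp),
        "p_analytic": p_analytic,
        "p_empirical": p_empirical,
        "bound_fraction_pct": frac_full,
        "bound_fraction_pct_rounded": frac_round,
    }


def _sponge_stage(config: PipelineConfig, out: Path) -> dict:
    transcripts = sp.read_fasta(config.transcript, "transcript")
    if len(transcripts) != 1:
        raise ValueError(f"expected exactly one transcript, got {len(transcripts)}")
    transcript = transcripts[0]
    mirs = sp.read_fasta(config.mirs, "mir")
    if config.both_orientations:
        mirs = mirs + [sp.reverse_complement(m) for m in mirs]
    params = load_params(config.energy_params) if config.energy_params else default_params()
    log.info(
        "sponge: transcript %d nt, %d miRs, %d shuffles, seed=%d",
        len(transcript), len(mirs), config.n_shuffles, config.seed,
    )
    results = sp.run_sponge_null(
        transcript, config.utr3, mirs, params,
        n_shuffles=config.n_shuffles, seed=config.seed,
    )
    sites = []
    for m in mirs:
        hit = sp.best_site(transcript, m, params)
        if hit is not None:
            sites.append(
                {
                    "mir": m.name,
                    "window": list(hit.transcript_window),
                    "delta_g": hit.delta_g,
                    "n_pairs": hit.n_pairs,
                }
            )
    with open(out / "sponge_sites.json", "w") as fh:
        json.dump(sites, fh, indent=2)
    return {
        region: {
            "true_score": r.true_score,
            "null_mean": sum(r.null_scores) / len(r.null_scores),
            "empirical_p": r.empirical_p,
            "z_score": r.z_score,
            "n_shuffles": r.n_shuffles,
        }
        for region, r in results.items()
    }


def run_all(config: PipelineConfig) -> dict:
    """Run every stage and write ``report.json`` into the output directory.

    On stage failure a ``report.json.partial`` marker is left behind and a
    StageError naming the stage is raised.
    """
    config.check_inputs()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    marker = out / "report.json.partial"
    marker.touch()
    digests = {
        name: _sha256(getattr(config, name))
        for name in ("promoters", "clusters", "matrix", "design", "transcript", "mirs")
    }
    report: dict = {
        "config": dataclasses.asdict(config),
        "input_digests": digests,
    }
    stage = "map-binding"
    try:
        counts, gene_bound, summaries = _binding_stage(config, out)
        report["binding_counts"] = counts
        stage = "de"
        de_results, de_counts = _de_stage(config, out)
        report["de_counts"] = de_counts
        stage = "enrich"
        report["enrichment"] = _enrichment_stage(config, gene_bound, summaries, de_results)
        stage = "sponge"
        report["sponge"] = _sponge_stage(config, out)
    except Exception as exc:
        raise StageError(stage, exc) from exc
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    marker.unlink()
    return report
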