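"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators emulate the study's data at configurable scale: a promoter
map with a controlled fraction of TF-bound promoters and scored binding
clusters; a two-condition (knockdown vs control) probe-level expression
matrix with planted log2 effects and Gaussian noise; and a long transcript
carrying planted miR-complementary sites at controlled fidelity, biased into
a designated 3'UTR.  Every generator is a pure function of its config
(including the seed), so regenerated bundles are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .diff_expression import CONTROL, KNOCKDOWN, ExpressionMatrix
from .promoter_binding import BindingCluster, GenomicInterval, PromoterRecord
from .sponge import RnaSequence

__all__ = [
    "SyntheticConfig",
    "gen_binding_landscape",
    "gen_expression",
    "gen_coupled_study",
    "gen_sponge_instance",
    "write_bundle",
]

_BASES = np.array(["A", "C", "G", "U"])


@dataclass(frozen=True)
class SyntheticConfig:
    """All generator knobs.

    Defaults mirror the study's scale: 781 promoters of which ~20.5% are
    bound (160/781), 17.5% of bound promoters driving 2-6-gene pre-miR
    clusters (28/160), cluster scores uniform on [100, 1000], a 4.3-kb
    transcript, three biological replicates per condition, and a 7:1
    down:up split among planted expression effects (63:9).
    """

    seed: int = 0
    # binding landscape
    n_promoters: int = 781
    cluster_gene_fraction: float = 0.175
    bound_fraction: float = 160 / 781
    score_range: tuple[int, int] = (100, 1000)
    score_values: tuple[int, ...] | None = None  # empirical alternative
    genome_length: int = 50_000_000
    # expression matrix (2 probes per gene)
    n_probes: int = 1562
    de_fraction: float = 72 / 781
    de_down_fraction: float = 63 / 72
    bound_down_fraction: float = 38 / 63  # coupled study: down genes on bound promoters
    log2_effect: float = 2.0
    noise_sd: float = 0.5
    replicates_per_condition: int = 3
    # sponge instance
    transcript_length: int = 4300
    background_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    n_mirs: int = 9
    mir_length: int = 22
    planted_sites_per_mir: int = 1
    site_mutation_rate: float = 0.0
    utr3_fraction: float = 0.3
    utr3_site_bias: float = 0.7

    def __post_init__(self) -> None:
        for name in (
            "cluster_gene_fraction",
            "bound_fraction",
            "de_fraction",
            "de_down_fraction",
            "bound_down_fraction",
            "site_mutation_rate",
            "utr3_fraction",
            "utr3_site_bias",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        comp = np.asarray(self.background_composition, dtype=float)
        if comp.shape != (4,) or abs(comp.sum() - 1.0) > 1e-9 or (comp < 0).any():
            raise ValueError("background_composition must be 4 probabilities summing to 1")
        for name in (
            "n_promoters",
            "genome_length",
            "n_probes",
            "replicates_per_condition",
            "transcript_length",
            "n_mirs",
            "mir_length",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_sd < 0 or self.planted_sites_per_mir < 0:
            raise ValueError("noise_sd and planted_sites_per_mir must be >= 0")

    def replace(self, **kwargs) -> "SyntheticConfig":
        return dataclasses.replace(self, **kwargs)


def _rng(config: SyntheticConfig, stream: int) -> np.random.Generator:
    # distinct deterministic stream per generator
    return np.random.default_rng([config.seed, stream])


def gen_binding_landscape(
    config: SyntheticConfig,
) -> tuple[list[PromoterRecord], list[BindingCluster], dict[str, bool]]:
    """Non-overlapping promoters plus clusters placed only on bound promoters.

    Bound promoters (probability ``bound_fraction``) receive 1-5 overlapping
    clusters scored from the configured distribution; promoters are separated
    by >= 1 kb so clusters never spill onto a neighbour.  Returns the records,
    the clusters, and the per-promoter truth flag.
    """
    rng = _rng(config, 1)
    n = config.n_promoters
    margin = 500  # clusters may extend this far beyond their promoter
    lengths = rng.integers(1000, 8000, size=n)
    gaps = rng.integers(2 * margin + 100, 5000, size=n)
    if int(lengths.sum() + gaps.sum()) > config.genome_length:
        raise ValueError("genome too short to place promoters without overlap")
    promoters: list[PromoterRecord] = []
    clusters: list[BindingCluster] = []
    truth: dict[str, bool] = {}
    pos = 0
    gene_no = 0
    for i in range(n):
        pos += int(gaps[i])
        start, end = pos, pos + int(lengths[i])
        pos = end
        if rng.random() < config.cluster_gene_fraction:
            k = int(rng.integers(2, 7))
        else:
            k = 1
        genes = tuple(f"miR-s{gene_no + j + 1:04d}" for j in range(k))
        gene_no += k
        pid = f"prom{i:05d}"
        promoters.append(
            PromoterRecord(pid, GenomicInterval("chr1", start, end), genes)
        )
        bound = bool(rng.random() < config.bound_fraction)
        truth[pid] = bound
        if bound:
            for _ in range(int(rng.integers(1, 6))):
                width = int(rng.integers(100, 401))
                lo = max(0, start - min(margin, width - 1))
                c_start = int(rng.integers(lo, end))  # guarantees >=1 bp overlap
                if config.score_values is not None:
                    score = int(rng.choice(config.score_values))
                else:
                    score = int(rng.integers(config.score_range[0], config.score_range[1] + 1))
                clusters.append(
                    BindingCluster(GenomicInterval("chr1", c_start, c_start + width), score)
                )
    return promoters, clusters, truth


def _build_matrix(
    config: SyntheticConfig,
    genes: list[str],
    labels: np.ndarray,
    rng: np.random.Generator,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Materialize a probe-level intensity matrix for given per-gene labels."""
    n_genes = len(genes)
    reps = config.replicates_per_condition
    effects = np.where(
        labels == "down", -config.log2_effect,
        np.where(labels == "up", config.log2_effect, 0.0),
    )
    baseline = rng.uniform(6.0, 12.0, size=n_genes)
    samples = [f"KD{i + 1}" for i in range(reps)] + [f"CTRL{i + 1}" for i in range(reps)]
    condition = pd.Series(
        [KNOCKDOWN] * reps + [CONTROL] * reps, index=samples, name="condition"
    )
    probe_ids = []
    gene_ids = []
    rows = []
    for g in range(n_genes):
        for p in range(2):
            probe_ids.append(f"probe{g:05d}_{p}")
            gene_ids.append(genes[g])
            log2_vals = (
                baseline[g]
                + effects[g] * (condition.values == KNOCKDOWN)
                + rng.normal(0.0, config.noise_sd, size=2 * reps)
            )
            rows.append(2.0**log2_vals)
    values = pd.DataFrame(np.vstack(rows), index=probe_ids, columns=samples)
    matrix = ExpressionMatrix(
        values=values, gene_ids=pd.Series(gene_ids, index=probe_ids), condition=condition
    )
    truth = pd.DataFrame({"gene": genes, "label": labels, "effect": effects})
    return matrix, truth


def gen_expression(
    config: SyntheticConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Two-condition intensity matrix with planted log2 effects.

    Each gene gets two probes (to exercise the probe-collapse rule).  Log2
    intensities are baseline + condition effect + N(0, noise_sd); a
    ``de_fraction`` of genes carry an effect of magnitude ``log2_effect``
    (knockdown minus control), negative for the ``de_down_fraction`` split.
    Returns the matrix (linear-scale intensities) and a truth table with
    columns gene / label in {down, up, null} / effect.
    """
    rng = _rng(config, 2)
    n_genes = max(1, config.n_probes // 2)
    genes = [f"miR-s{i + 1:04d}" for i in range(n_genes)]
    labels = np.array(["null"] * n_genes, dtype=object)
    n_de = int(round(config.de_fraction * n_genes))
    if n_de:
        de_idx = rng.choice(n_genes, size=n_de, replace=False)
        n_down = int(round(config.de_down_fraction * n_de))
        labels[de_idx[:n_down]] = "down"
        labels[de_idx[n_down:]] = "up"
    return _build_matrix(config, genes, labels, rng)


def gen_coupled_study(
    config: SyntheticConfig,
) -> tuple[list[PromoterRecord], list[BindingCluster], dict[str, bool], ExpressionMatrix, pd.DataFrame]:
    """Binding landscape plus an expression matrix whose truth is coupled to it.

    The expression universe is the lead gene of every promoter, so the
    DE->binding join operates on promoter-level units.  Planted downregulated
    genes are drawn preferentially from bound promoters: a fraction
    ``bound_down_fraction`` of the ``de_down_fraction * de_fraction *
    n_promoters`` down genes sit on bound promoters (the remainder on unbound
    ones), planting a binding/downregulation enrichment of known strength;
    upregulated genes are drawn from the leftover pool uniformly.
    """
    promoters, clusters, bind_truth = gen_binding_landscape(config)
    rng = _rng(config, 4)
    lead = [p.mir_genes[0] for p in promoters]
    bound_lead = [g for g, p in zip(lead, promoters) if bind_truth[p.promoter_id]]
    unbound_lead = [g for g, p in zip(lead, promoters) if not bind_truth[p.promoter_id]]
    n_de = int(round(config.de_fraction * len(lead)))
    n_down = int(round(config.de_down_fraction * n_de))
    n_up = n_de - n_down
    n_down_bound = min(int(round(config.bound_down_fraction * n_down)), len(bound_lead))
    n_down_unbound = min(n_down - n_down_bound, len(unbound_lead))
    down = set(rng.choice(bound_lead, size=n_down_bound, replace=False)) | set(
        rng.choice(unbound_lead, size=n_down_unbound, replace=False)
    )
    pool = [g for g in lead if g not in down]
    up = set(rng.choice(pool, size=min(n_up, len(pool)), replace=False))
    labels = np.array(
        ["down" if g in down else "up" if g in up else "null" for g in lead],
        dtype=object,
    )
    matrix, de_truth = _build_matrix(config, lead, labels, rng)
    return promoters, clusters, bind_truth, matrix, de_truth


_RC = {"A": "U", "U": "A", "C": "G", "G": "C"}


def gen_sponge_instance(
    config: SyntheticConfig,
    mirs: Sequence[RnaSequence] | None = None,
) -> tuple[RnaSequence, tuple[int, int], list[RnaSequence], list[dict]]:
    """A transcript with planted miR-complementary sites and its 3'UTR.

    Background bases are i.i.d. from ``background_composition``.  For each miR
    (generated when not supplied), ``planted_sites_per_mir`` full-length
    reverse-complement sites are written into the background without overlap,
    each base independently mutated with ``site_mutation_rate``; a fraction
    ``utr3_site_bias`` of sites is placed inside the 3'UTR (the final
    ``utr3_fraction`` of the transcript).  Returns (transcript, utr3 interval,
    miRs, truth site list).
    """
    rng = _rng(config, 3)
    L = config.transcript_length
    if mirs is None:
        mirs = [
            RnaSequence(
                f"mir-s{i + 1}",
                "".join(rng.choice(_BASES, size=config.mir_length)),
                "mir",
            )
            for i in range(config.n_mirs)
        ]
    else:
        mirs = list(mirs)
    total_site_len = sum(len(m) for m in mirs) * config.planted_sites_per_mir
    if total_site_len > L:
        raise ValueError("transcript too short for the requested planted sites")
    comp = np.asarray(config.background_composition, dtype=float)
    bases = rng.choice(_BASES, size=L, p=comp)
    utr3 = (int(round((1.0 - config.utr3_fraction) * L)), L)
    occupied = np.zeros(L, dtype=bool)
    truth: list[dict] = []
    for mir in mirs:
        site_rc = "".join(_RC[b] for b in reversed(mir.bases))
        w = len(site_rc)
        for _ in range(config.planted_sites_per_mir):
            placed = False
            for _attempt in range(10_000):
                if rng.random() < config.utr3_site_bias and utr3[1] - utr3[0] >= w:
                    start = int(rng.integers(utr3[0], utr3[1] - w + 1))
                else:
                    start = int(rng.integers(0, L - w + 1))
                if not occupied[start : start + w].any():
                    placed = True
                    break
            if not placed:
                raise ValueError("could not place planted sites without overlap")
            occupied[start : start + w] = True
            site = [
                str(rng.choice(_BASES)) if rng.random() < config.site_mutation_rate else b
                for b in site_rc
            ]
            bases[start : start + w] = site
            truth.append({"mir": mir.name, "start": start, "end": start + w})
    transcript = RnaSequence("synthetic_transcript", "".join(bases), "transcript")
    return transcript, utr3, mirs, truth


def write_bundle(config: SyntheticConfig, out_dir: str | Path) -> dict[str, str]:
    """Emit the full synthetic input bundle (tables, FASTA, design, truth JSON)."""
    from .sponge import write_fasta

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    promoters, clusters, bind_truth, matrix, de_truth = gen_coupled_study(config)
    transcript, utr3, mirs, site_truth = gen_sponge_instance(config)

    paths = {
        "promoters": str(out / "promoters.tsv"),
        "clusters": str(out / "clusters.bed"),
        "matrix": str(out / "expression.tsv"),
        "design": str(out / "design.tsv"),
        "transcript": str(out / "transcript.fa"),
        "mirs": str(out / "mirs.fa"),
        "truth": str(out / "truth.json"),
    }
    with open(paths["promoters"], "w") as fh:
        fh.write("chrom\tstart\tend\tgenes\n")
        for p in promoters:
            iv = p.interval
            fh.write(f"{iv.chrom}\t{iv.start + 1}\t{iv.end}\t{','.join(p.mir_genes)}\n")
    with open(paths["clusters"], "w") as fh:
        for c in clusters:
            iv = c.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{c.score}\n")
    mat = matrix.values.copy()
    mat.insert(0, "gene_id", matrix.gene_ids)
    mat.index.name = "probe_id"
    mat.to_csv(paths["matrix"], sep="\t")
    with open(paths["design"], "w") as fh:
        fh.write("sample\tcondition\n")
        for s, c in matrix.condition.items():
            fh.write(f"{s}\t{c}\n")
    write_fasta([transcript], paths["transcript"])
    write_fasta(mirs, paths["mirs"])
    truth = {
        "config": dataclasses.asdict(config),
        "bound_promoters": bind_truth,
        "de_genes": de_truth.to_dict(orient="records"),
        "utr3": list(utr3),
        "planted_sites": site_truth,
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=2)
        fh.write("\n")
    return paths
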