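"""End-to-end orchestration: SE calling -> motif scanning -> CRC network ->
differential signal -> co-occupancy, with a machine-readable JSON report.

Inputs come either from files (PipelineConfig path fields) or from the
synthetic generator (``simulate: {seed: ...}`` in the config).  Reruns with
identical inputs and seed reproduce the report bit-exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import yaml

from . import cooccupancy as co
from . import diffsignal as ds
from . import io as cio
from . import motifs as mo
from . import network as net
from . import se_caller as se
from .intervals import GenomicInterval, filter_atac, intersect
from .sequences import FastaGenome
from .simulate import SimSpec, simulate, simulate_knockdown

__all__ = ["PipelineConfig", "PipelineError", "run_all"]

logger = logging.getLogger("crckit.pipeline")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """All stage inputs and parameters; defaults follow the documented
    ROSE/pipeline defaults."""

    outdir: str = "crc_out"
    seed: int = 0
    # synthetic mode: generate inputs instead of reading them
    simulate: bool = False
    simulate_knockdown: bool = True
    # input paths (file mode)
    peaks: Optional[str] = None          # H3K27ac constituent peaks BED
    coverage: Optional[str] = None       # H3K27ac bedGraph
    control: Optional[str] = None
    genome: Optional[str] = None         # FASTA
    annotation: Optional[str] = None
    atac: Optional[str] = None
    motifs: Optional[str] = None         # MEME text
    expression: Optional[str] = None
    counts: Optional[str] = None
    design: Optional[str] = None
    kd_coverage: Optional[str] = None
    kd_peaks: Optional[str] = None
    h3k4me1: Optional[str] = None
    h3k27me3: Optional[str] = None
    tf_peaks: dict = field(default_factory=dict)  # name -> BED path
    # stage parameters
    stitch_distance: int = se.DEFAULT_STITCH_DISTANCE
    tss_exclude: Optional[int] = None
    se_gene_window: int = se.DEFAULT_SE_GENE_WINDOW
    min_pileup: float = 40.0
    tpm_min: float = net.DEFAULT_TPM_THRESHOLD
    motif_pvalue: float = mo.DEFAULT_P_THRESHOLD
    lfc: float = ds.DEFAULT_LFC_MIN
    fdr: float = ds.DEFAULT_FDR_MAX
    kd_fold: float = 0.25

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise PipelineError("config", f"unknown config keys {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _round(x, nd=6):
    if isinstance(x, float):
        return round(x, nd)
    return x


def _require(cfg: PipelineConfig, stage: str, *fields: str) -> None:
    for f in fields:
        val = getattr(cfg, f)
        if val is None:
            raise PipelineError(stage, f"missing required input path {f!r}")
        if not Path(val).exists():
            raise PipelineError(stage, f"input {f!r} not found at {val}")


def _load_inputs(cfg: PipelineConfig, outdir: Path) -> dict[str, Any]:
    if cfg.simulate:
        logger.info("simulate: generating synthetic dataset (seed=%d)", cfg.seed)
        dataset = simulate(SimSpec(seed=cfg.seed, kd_fold=cfg.kd_fold))
        kd = simulate_knockdown(dataset) if cfg.simulate_knockdown else None
        sim_dir = outdir / "simulated_inputs"
        dataset.write(sim_dir)
        bundle = {
            "h3k27ac_peaks": dataset.h3k27ac_peaks,
            "h3k27ac_cov": dataset.coverage["h3k27ac"],
            "control_cov": None,
            "genome": dataset.genome,
            "annotation": dataset.annotation,
            "atac_peaks": dataset.atac_peaks,
            "pwms": dataset.pwms,
            "expression": dataset.expression,
            "tf_peaks": dataset.tf_peaks,
            "h3k4me1": dataset.coverage["h3k4me1"],
            "h3k27me3": dataset.coverage["h3k27me3"],
            "truth": dataset.truth,
        }
        if kd is not None:
            bundle.update(
                {
                    "kd_peaks": kd.h3k27ac_peaks,
                    "kd_cov": kd.coverage["h3k27ac"],
                    "counts": kd.counts,
                    "design": kd.design,
                }
            )
        else:
            bundle.update({"kd_peaks": None, "kd_cov": None,
                           "counts": None, "design": None})
        return bundle

    _require(cfg, "load", "peaks", "coverage", "annotation")
    bundle: dict[str, Any] = {
        "h3k27ac_peaks": cio.read_bed(cfg.peaks, pileup_from_score=False),
        "h3k27ac_cov": cio.read_bedgraph(cfg.coverage),
        "control_cov": cio.read_bedgraph(cfg.control) if cfg.control else None,
        "annotation": cio.read_annotation(cfg.annotation),
        "genome": None,
        "atac_peaks": None,
        "pwms": None,
        "expression": None,
        "tf_peaks": {},
        "kd_peaks": None,
        "kd_cov": None,
        "counts": None,
        "design": None,
        "h3k4me1": None,
        "h3k27me3": None,
        "truth": None,
    }
    if cfg.atac:
        _require(cfg, "load", "atac")
        bundle["atac_peaks"] = cio.read_bed(cfg.atac, pileup_from_score=True,
                                            summit_from_extra=True)
    if cfg.motifs:
        _require(cfg, "load", "motifs", "genome", "expression")
        bundle["pwms"] = mo.read_meme(cfg.motifs)
        bundle["genome"] = FastaGenome(cfg.genome)
        bundle["expression"] = cio.read_expression(cfg.expression)
    if cfg.counts:
        _require(cfg, "load", "counts", "design")
        bundle["counts"] = cio.read_counts(cfg.counts)
        bundle["design"] = cio.read_design(cfg.design)
    if cfg.kd_coverage:
        _require(cfg, "load", "kd_coverage", "kd_peaks")
        bundle["kd_cov"] = cio.read_bedgraph(cfg.kd_coverage)
        bundle["kd_peaks"] = cio.read_bed(cfg.kd_peaks)
    if cfg.h3k4me1:
        bundle["h3k4me1"] = cio.read_bedgraph(cfg.h3k4me1)
    if cfg.h3k27me3:
        bundle["h3k27me3"] = cio.read_bedgraph(cfg.h3k27me3)
    for name, path in sorted(cfg.tf_peaks.items()):
        if not Path(path).exists():
            raise PipelineError("load", f"TF peak file for {name} not found at {path}")
        bundle["tf_peaks"][name] = cio.read_bed(path)
    return bundle


def _search_regions(atac_peaks, ranking) -> tuple[list[GenomicInterval], dict]:
    """ATAC-within-SE overlap segments, named and mapped to SE ids."""
    se_spans = [
        GenomicInterval(e.span.chrom, e.span.start, e.span.end,
                        name=e.enhancer_id)
        for e in ranking.supers
    ]
    regions, region_se = [], {}
    for a, s, _ in intersect(atac_peaks, se_spans):
        iv = a.interval
        start = max(iv.start, s.start)
        end = min(iv.end, s.end)
        name = f"{s.name}|{iv.name or iv.start}"
        regions.append(GenomicInterval(iv.chrom, start, end, name=name))
        region_se[name] = s.name
    return regions, region_se


def _write_se_table(path, ranking) -> None:
    rows = [
        (
            e.span.chrom, e.span.start, e.span.end, e.n_constituents,
            round(e.signal, 4), e.rank, int(e.is_super),
        )
        for e in ranking.enhancers
    ]
    pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "n_constituents", "signal", "rank",
                 "is_super"],
    ).to_csv(path, sep="\t", index=False)


def run_all(cfg: PipelineConfig) -> dict:
    """Run every configured stage; artifacts under cfg.outdir, report dict
    returned and written as report.json."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logger.info("parameters: %s", json.dumps(asdict(cfg), sort_keys=True))
    report: dict[str, Any] = {"parameters": asdict(cfg)}
    stage = "load"
    try:
        bundle = _load_inputs(cfg, outdir)

        stage = "call-se"
        logger.info("call-se: stitching at %d bp", cfg.stitch_distance)
        tss_excl = (
            (bundle["annotation"], cfg.tss_exclude) if cfg.tss_exclude else None
        )
        ranking = se.call_super_enhancers(
            bundle["h3k27ac_peaks"], bundle["h3k27ac_cov"],
            bundle["control_cov"], cfg.stitch_distance, tss_excl,
        )
        _write_se_table(outdir / "enhancer_table.tsv", ranking)
        cio.write_bed(
            outdir / "super_enhancers.bed",
            [e.span for e in ranking.supers],
        )
        se_genes = se.assign_se_genes(
            ranking, bundle["annotation"], cfg.se_gene_window
        )
        with open(outdir / "se_genes.tsv", "w") as fh:
            fh.write("se_id\tgenes\n")
            for se_id in sorted(se_genes):
                fh.write(
                    f"{se_id}\t{','.join(g.symbol for g in se_genes[se_id])}\n"
                )
        report["super_enhancers"] = {
            "n_enhancers": len(ranking.enhancers),
            "n_super": ranking.n_super,
            "cutoff_signal": _round(ranking.cutoff_signal, 4),
        }

        crc_result = None
        if bundle["atac_peaks"] is not None and bundle["pwms"] is not None:
            stage = "scan"
            atac_kept = filter_atac(bundle["atac_peaks"], cfg.min_pileup)
            regions, region_se = _search_regions(atac_kept, ranking)
            logger.info(
                "scan: %d ATAC-in-SE regions x %d PWMs", len(regions),
                len(bundle["pwms"]),
            )
            hits = mo.scan(
                regions, bundle["genome"], bundle["pwms"],
                p_threshold=cfg.motif_pvalue,
            )
            with open(outdir / "motif_hits.bed", "w") as fh:
                for h in hits:
                    fh.write(
                        f"{h.region.chrom}\t{h.genomic_start}\t"
                        f"{h.genomic_start + 1}\t{h.pwm_name}\t"
                        f"{h.score:.4f}\t{h.strand}\t{h.pvalue:.3e}\t"
                        f"{h.region.name}\n"
                    )
            report["motif_scan"] = {
                "n_regions": len(regions),
                "n_hits": len(hits),
            }

            stage = "build-crc"
            tf_nodes = []
            se_gene_symbols = {
                se_id: [g.symbol for g in genes]
                for se_id, genes in se_genes.items()
            }
            tf_syms = sorted(
                {g.symbol for g in bundle["annotation"] if g.is_tf}
            )
            for sym in tf_syms:
                prox = frozenset(
                    se_id for se_id, syms in se_gene_symbols.items()
                    if sym in syms
                )
                tpm = float(bundle["expression"].get(sym, 0.0))
                tf_nodes.append(net.TFNode(symbol=sym, tpm=tpm,
                                           proximal_ses=prox))
            network = net.build_network(
                tf_nodes, se_gene_symbols, hits, region_se_ids=region_se,
                tpm_threshold=cfg.tpm_min,
            )
            deg = net.degrees(network)
            cliques = net.enumerate_cliques(network)
            ces = net.clique_enrichment(cliques)
            deg.to_csv(outdir / "node_table.tsv", sep="\t")
            with open(outdir / "cliques.json", "w") as fh:
                json.dump([list(c) for c in cliques], fh, indent=1)
                fh.write("\n")
            crc_result = net.CRCResult(cliques=cliques, degrees=deg, ces=ces)
            report["crc"] = {
                "n_nodes": int(deg.shape[0]),
                "n_edges": network.graph.number_of_edges(),
                "cliques": [list(c) for c in cliques],
                "ces": {k: _round(v, 4) for k, v in ces.items()},
                "degrees": {
                    sym: {
                        "in": int(r.in_degree),
                        "out": int(r.out_degree),
                        "total": int(r.total_degree),
                    }
                    for sym, r in deg.iterrows()
                },
            }

        if bundle["counts"] is not None:
            stage = "diff"
            logger.info("diff: testing %d regions", len(bundle["counts"]))
            res = ds.test_differential(
                bundle["counts"], bundle["design"], lfc_min=cfg.lfc,
                fdr_max=cfg.fdr,
            )
            res.to_csv(outdir / "differential.tsv", sep="\t",
                       float_format="%.6g")
            sig = res[res["significant"]]
            report["differential"] = {
                "n_tested": int(res["pvalue"].notna().sum()),
                "n_significant": int(len(sig)),
                "n_down": int((sig["log2FC"] < 0).sum()),
                "n_up": int((sig["log2FC"] > 0).sum()),
            }

        if bundle["kd_cov"] is not None and bundle["kd_peaks"] is not None:
            stage = "transitions"
            ranking_kd = se.call_super_enhancers(
                bundle["kd_peaks"], bundle["kd_cov"], None,
                cfg.stitch_distance, tss_excl,
            )
            trans = ds.classify_enhancer_transitions(
                ranking, ranking_kd, bundle["h3k4me1"], bundle["h3k27me3"],
            )
            trans.to_csv(outdir / "transitions.tsv", sep="\t",
                         float_format="%.6g")
            label_counts = trans["label"].value_counts().to_dict()
            report["knockdown"] = {
                "n_super_wt": ranking.n_super,
                "n_super_kd": ranking_kd.n_super,
                "transitions": {k: int(v) for k, v in sorted(label_counts.items())},
                "n_se_reduced_or_lost": int(
                    (
                        trans["wt_is_super"]
                        & (trans["reduced"] | (trans["label"] == "SE->TE"))
                    ).sum()
                ),
            }

        if len(bundle["tf_peaks"]) >= 2:
            stage = "cooccupancy"
            # co-occupancy is read on the core TFs: the largest CRC clique
            # when one was found, otherwise every supplied peak set
            core = bundle["tf_peaks"]
            if crc_result is not None and crc_result.cliques:
                members = [t for t in crc_result.cliques[0] if t in core]
                if len(members) >= 2:
                    core = {t: core[t] for t in members}
            classes = co.venn(core)
            bound, fractions = co.se_cobinding(ranking.supers, core)
            hs = co.hotspots(core, annotation=bundle["annotation"])
            cio.write_bed(outdir / "hotspots.bed",
                          [h.region for h in hs])
            report["cooccupancy"] = {
                "core_tfs": sorted(core),
                "classes": {
                    "+".join(sorted(c.membership)): c.count for c in classes
                },
                "se_cobinding": {k: _round(v, 4) for k, v in fractions.items()},
                "n_hotspots": len(hs),
            }

        stage = "report"
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True, default=str)
            fh.write("\n")
        logger.info("report written to %s", outdir / "report.json")
        return report
    except PipelineError:
        (outdir / f"FAILED.{stage}").write_text("stage failed\n")
        raise
    except Exception as exc:
        (outdir / f"FAILED.{stage}").write_text(f"{exc}\n")
        raise PipelineError(stage, str(exc)) from exc
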