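"""Shared fixtures: a small simulated dataset and a 20-seed study.

The study fixture runs the full inference chain (simulate -> SE calling ->
ATAC-constrained motif scan -> network/cliques -> knockdown -> transition
labels) once per seed and is shared by the recovery tests.
"""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from crckit import motifs as mo
from crckit import network as net
from crckit.diffsignal import classify_enhancer_transitions
from crckit.intervals import GenomicInterval, filter_atac, intersect
from crckit.se_caller import assign_se_genes, call_super_enhancers
from crckit.simulate import SimSpec, simulate, simulate_knockdown

STUDY_SEEDS = list(range(101, 121))  # 20 seeds


def build_search_regions(atac_peaks, ranking):
    """ATAC-within-SE overlap segments named per SE (shared helper)."""
    se_spans = [
        GenomicInterval(e.span.chrom, e.span.start, e.span.end,
                        name=e.enhancer_id)
        for e in ranking.supers
    ]
    regions, region_se = [], {}
    for a, s, _ in intersect(atac_peaks, se_spans):
        iv = a.interval
        name = f"{s.name}|{iv.name or iv.start}"
        regions.append(
            GenomicInterval(iv.chrom, max(iv.start, s.start),
                            min(iv.end, s.end), name=name)
        )
        region_se[name] = s.name
    return regions, region_se


def run_crc_inference(dataset, ranking):
    """Scan ATAC-in-SE regions and build the TF network from a dataset."""
    se_genes = assign_se_genes(ranking, dataset.annotation)
    atac = filter_atac(dataset.atac_peaks)
    regions, region_se = build_search_regions(atac, ranking)
    hits = mo.scan(regions, dataset.genome, dataset.pwms)
    se_gene_symbols = {
        sid: [g.symbol for g in genes] for sid, genes in se_genes.items()
    }
    tf_syms = sorted({g.symbol for g in dataset.annotation if g.is_tf})
    nodes = [
        net.TFNode(
            symbol=sym,
            tpm=float(dataset.expression.get(sym, 0.0)),
            proximal_ses=frozenset(
                sid for sid, syms in se_gene_symbols.items() if sym in syms
            ),
        )
        for sym in tf_syms
    ]
    network = net.build_network(nodes, se_gene_symbols, hits,
                                region_se_ids=region_se)
    return network, net.enumerate_cliques(network), hits


@pytest.fixture(scope="session")
def dataset():
    """One default synthetic dataset (seed 11)."""
    return simulate(SimSpec(seed=11))


@pytest.fixture(scope="session")
def kd_dataset(dataset):
    return simulate_knockdown(dataset)


@pytest.fixture(scope="session")
def study():
    """Per-seed recovery results over the 20 study seeds."""
    results = []
    for seed in STUDY_SEEDS:
        ds = simulate(SimSpec(seed=seed))
        kd = simulate_knockdown(ds)
        ranking = call_super_enhancers(ds.h3k27ac_peaks,
                                       ds.coverage["h3k27ac"])
        ranking_kd = call_super_enhancers(kd.h3k27ac_peaks,
                                          kd.coverage["h3k27ac"])
        planted = {(d["start"], d["end"]) for d in ds.truth["planted_ses"]}
        called = {(e.span.start, e.span.end) for e in ranking.supers}
        jaccard = len(planted & called) / len(planted | called)

        network, cliques, _ = run_crc_inference(ds, ranking)
        triad = tuple(sorted(ds.truth["clique"]))

        trans = classify_enhancer_transitions(
            ranking, ranking_kd, kd.coverage["h3k4me1"],
            kd.coverage["h3k27me3"],
        )
        targeted = trans[trans["wt_is_super"]]
        untargeted = trans[~trans["wt_is_super"]]
        results.append(
            {
                "seed": seed,
                "jaccard": jaccard,
                "n_planted": len(planted),
                "n_super_wt": ranking.n_super,
                "n_super_kd": ranking_kd.n_super,
                "clique_found": triad in cliques,
                "cliques": cliques,
                "degrees": net.degrees(network),
                "triad": triad,
                "frac_targeted_lost_or_reduced": float(
                    ((targeted["label"] == "SE->TE") | targeted["reduced"]).mean()
                ),
                "frac_untargeted_changed": float(
                    ((untargeted["label"] != "TE->TE") | untargeted["reduced"]).mean()
                ),
            }
        )
    return results
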