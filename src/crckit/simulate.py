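"""Synthetic epigenome with a planted core regulatory circuitry.

The generator emulates the data structure of an H3K27ac/ATAC/TF-ChIP study
of a stem-cell population: 500 enhancer loci on one chromosome, of which 20
are super-enhancers (clusters of 3-6 constituents within stitch distance)
and 480 are isolated typical-enhancer constituents.  SE total signals sit
on a jittered linear grid far above the log-normal TE background, so the
ranked-signal curve shows the canonical hockey stick and the tangent
slope-1 cutoff separates the planted SEs exactly.  Three TFs (PAX6, RUNX1,
SMAD3) form the planted auto-regulatory clique: each member's consensus
word is planted, inside ATAC peaks, in its own SE and in the SEs of the
other two.  A simulated knockdown of the master TF scales H3K27ac coverage
and counts over all bound-SE constituents.

Everything is drawn from a single seeded generator: identical seeds give
byte-identical outputs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace as dc_replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .coverage import Coverage
from .intervals import GeneAnnotation, GenomicInterval, Peak
from .io import write_annotation, write_bed, write_bedgraph
from .motifs import PWM, write_meme
from .sequences import BASES, InMemoryGenome

__all__ = ["SimSpec", "SimulatedDataset", "simulate", "simulate_knockdown"]

CLIQUE_TFS = ("PAX6", "RUNX1", "SMAD3")
# SE-assigned background TFs: TP63 auto-regulates (planted self word) and is
# fed by RUNX1; KLF5 exchanges words with TP63 but lacks a self edge; GRHL2
# has an SE but is expressed below the admission threshold.  FOSL2 and EHF
# are expressed TFs without a proximal SE.
BACKGROUND_SE_TFS = ("TP63", "KLF5", "GRHL2")
NON_SE_TFS = ("FOSL2", "EHF")
ALL_TFS = CLIQUE_TFS + BACKGROUND_SE_TFS + NON_SE_TFS

TF_TPM = {
    "PAX6": 150.0,
    "RUNX1": 80.0,
    "SMAD3": 200.0,
    "TP63": 120.0,
    "KLF5": 60.0,
    "GRHL2": 5.0,
    "FOSL2": 40.0,
    "EHF": 30.0,
}

# grid rank (0 = weakest SE) per TF-proximal SE
TF_SE_GRID_RANK = {
    "PAX6": 10,
    "RUNX1": 13,
    "SMAD3": 16,
    "TP63": 7,
    "KLF5": 5,
    "GRHL2": 3,
}


@dataclass(frozen=True)
class SimSpec:
    """Parameters of the synthetic epigenome.

    Signal units are coverage x bp, matching the SE caller's quantifier.
    The SE grid bounds and the TE amplitude model are chosen so that the
    rank-curve inflection cutoff calls exactly the planted SEs in the
    wild type while a fold-0.25 knockdown drops the weakest scaled SE
    into the TE tail (see docs/methods.md).
    """

    seed: int
    chrom: str = "chr1"
    chrom_size: Optional[int] = None  # None -> sized to fit the layout
    n_se: int = 20
    n_te: int = 480
    clique_members: tuple[str, ...] = CLIQUE_TFS
    # TE constituents: amplitude ~ LogNormal(log te_amp_median, te_amp_sigma)
    te_amp_median: float = 10.0
    te_amp_sigma: float = 0.25
    te_width_mean: float = 1100.0
    te_width_sd: float = 100.0
    # SE total signal: linear grid between the bounds, x U(0.95, 1.05) jitter
    se_signal_min: float = 1.1e5
    se_signal_max: float = 2.6e7
    se_constituents_min: int = 3
    se_constituents_max: int = 6
    # ATAC peaks nested in constituents
    atac_width: int = 260
    atac_pileup_median: float = 90.0
    atac_pileup_sigma: float = 0.3
    te_atac_rate: float = 0.5
    n_background_atac: int = 150
    # NB count model over stitched loci (mean = signal / count_scale)
    count_scale: float = 100.0
    nb_dispersion: float = 0.1
    n_replicates: int = 2
    # knockdown
    kd_target: str = "RUNX1"
    kd_fold: float = 0.25
    # TF ChIP layout
    cobind_rate: float = 0.6  # PAX6/SMAD3 binding rate at non-clique SEs
    n_unique_tf_peaks: int = 30
    motif_width: int = 8
    motif_consensus_prob: float = 0.88

    def __post_init__(self) -> None:
        if not set(self.clique_members) <= set(ALL_TFS):
            raise ValueError("clique members must be among the simulated TFs")
        if self.se_signal_min >= self.se_signal_max:
            raise ValueError("se_signal_min must be < se_signal_max")


@dataclass
class SimulatedDataset:
    spec: SimSpec
    genome: InMemoryGenome
    chrom_sizes: dict[str, int]
    annotation: list[GeneAnnotation]
    h3k27ac_peaks: list[Peak]  # constituent peaks; score = amplitude
    coverage: dict[str, Coverage]  # h3k27ac, h3k4me1, h3k27me3
    atac_peaks: list[Peak]
    tf_peaks: dict[str, list[Peak]]
    pwms: list[PWM]
    expression: pd.Series
    counts: pd.DataFrame
    design: pd.DataFrame
    truth: dict
    is_knockdown: bool = False

    def write(self, outdir) -> dict[str, Path]:
        """Emit the dataset in standard text formats; returns path map."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}

        def _p(key, name):
            paths[key] = outdir / name
            return paths[key]

        self.genome.write_fasta(_p("genome", "genome.fa"))
        write_annotation(_p("annotation", "annotation.tsv"), self.annotation)
        write_bed(_p("h3k27ac_peaks", "h3k27ac_peaks.bed"), self.h3k27ac_peaks)
        for track, cov in self.coverage.items():
            write_bedgraph(_p(track, f"{track}.bedgraph"), cov)
        write_bed(_p("atac_peaks", "atac_peaks.bed"), self.atac_peaks)
        for tf, peaks in self.tf_peaks.items():
            write_bed(_p(f"tf_{tf}", f"tf_{tf}.bed"), peaks)
        write_meme(_p("motifs", "motifs.meme"), self.pwms)
        expr = self.expression.rename("tpm").reset_index()
        expr.columns = ["symbol", "tpm"]
        expr.to_csv(_p("expression", "expression.tsv"), sep="\t", index=False,
                    float_format="%.4f")
        self.counts.to_csv(_p("counts", "counts.tsv"), sep="\t")
        self.design.to_csv(_p("design", "design.tsv"), sep="\t", index=False)
        with open(_p("truth", "truth.json"), "w") as fh:
            json.dump(self.truth, fh, indent=1, sort_keys=True)
            fh.write("\n")
        return paths


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    n = 1.0 / dispersion
    p = n / (n + np.asarray(mean, dtype=float))
    return rng.negative_binomial(n, p)


def _make_pwms(rng: np.random.Generator, spec: SimSpec) -> tuple[list[PWM], dict[str, str]]:
    pwms, consensus = [], {}
    for tf in ALL_TFS:
        w = spec.motif_width + int(rng.integers(0, 3))  # widths 8-10
        cons_idx = rng.integers(0, 4, size=w)
        probs = np.full((w, 4), (1 - spec.motif_consensus_prob) / 3)
        probs[np.arange(w), cons_idx] = spec.motif_consensus_prob
        pwm = PWM(name=tf, probs=probs)
        pwms.append(pwm)
        consensus[tf] = "".join(BASES[i] for i in cons_idx)
    return pwms, consensus


def simulate(spec: SimSpec) -> SimulatedDataset:
    """Generate the wild-type dataset plus its ground-truth manifest."""
    rng = np.random.default_rng(spec.seed)
    n_loci = spec.n_se + spec.n_te
    chrom = spec.chrom

    pwms, consensus = _make_pwms(rng, spec)

    # ----- layout: which loci are SEs, which carry TF genes -----
    tf_slot_positions = np.linspace(40, n_loci - 40, num=len(ALL_TFS)).astype(int)
    slot_tfs = list(ALL_TFS)
    rng.shuffle(slot_tfs)
    tf_slots = dict(zip(slot_tfs, tf_slot_positions))  # tf -> layout index

    tf_se = {tf: r for tf, r in TF_SE_GRID_RANK.items() if r < spec.n_se}
    se_slots = {tf_slots[tf] for tf in tf_se}  # TF SE loci
    free = [i for i in range(n_loci) if i not in set(tf_slots.values())]
    extra = rng.choice(len(free), size=spec.n_se - len(se_slots), replace=False)
    se_slots |= {free[i] for i in sorted(extra)}

    # grid rank per SE slot: TF SEs get fixed ranks, the rest in layout order
    slot_rank: dict[int, int] = {tf_slots[tf]: rank for tf, rank in tf_se.items()}
    free_ranks = [r for r in range(spec.n_se) if r not in set(slot_rank.values())]
    for slot, rank in zip(
        sorted(s for s in se_slots if s not in slot_rank), free_ranks
    ):
        slot_rank[slot] = rank

    delta = (spec.se_signal_max - spec.se_signal_min) / max(spec.n_se - 1, 1)
    grid = spec.se_signal_min + delta * np.arange(spec.n_se)
    grid = grid * rng.uniform(0.95, 1.05, size=spec.n_se)

    # ----- walk the chromosome laying down loci -----
    cursor = 6000
    h3k27ac_peaks: list[Peak] = []
    atac_peaks: list[Peak] = []
    annotation: list[GeneAnnotation] = []
    expr_rows: list[tuple[str, float]] = []
    locus_spans: list[GenomicInterval] = []
    locus_is_se: list[bool] = []
    locus_signal: list[float] = []
    se_records: list[dict] = []
    planted_words: list[dict] = []  # {tf, start, strand, se_gene}
    word_sites: dict[str, list[int]] = {tf: [] for tf in ALL_TFS}
    se_atac_by_slot: dict[int, list[Peak]] = {}
    se_constituents_by_slot: dict[int, list[Peak]] = {}

    slot_tf_lookup = {v: k for k, v in tf_slots.items()}

    for slot in range(n_loci):
        locus_start = cursor
        constituents: list[tuple[int, int, float]] = []  # start, end, amp
        local_atac: list[Peak] = []
        if slot in se_slots:
            rank = slot_rank[slot]
            total = float(grid[rank])
            n_con = int(
                rng.integers(spec.se_constituents_min, spec.se_constituents_max + 1)
            )
            shares = rng.dirichlet(np.full(n_con, 4.0))
            for k in range(n_con):
                width = int(rng.integers(900, 1500))
                amp = shares[k] * total / width
                constituents.append((cursor, cursor + width, amp))
                # one ATAC peak nested in each constituent
                a_start = cursor + int(rng.integers(80, width - spec.atac_width - 80))
                pileup = float(
                    rng.lognormal(math.log(spec.atac_pileup_median),
                                  spec.atac_pileup_sigma)
                )
                local_atac.append(
                    Peak(
                        interval=GenomicInterval(
                            chrom, a_start, a_start + spec.atac_width,
                            name=f"atac_se{rank}_c{k}",
                        ),
                        summit_offset=spec.atac_width // 2,
                        pileup=round(pileup, 2),
                    )
                )
                cursor += width
                if k < n_con - 1:
                    cursor += int(rng.integers(2000, 6000))
        else:
            width = int(
                np.clip(rng.normal(spec.te_width_mean, spec.te_width_sd), 700, 1500)
            )
            amp = float(
                rng.lognormal(math.log(spec.te_amp_median), spec.te_amp_sigma)
            )
            constituents.append((cursor, cursor + width, amp))
            if rng.random() < spec.te_atac_rate:
                a_start = cursor + int(rng.integers(50, width - 320))
                pileup = float(rng.lognormal(math.log(45.0), 0.5))
                local_atac.append(
                    Peak(
                        interval=GenomicInterval(chrom, a_start, a_start + 300,
                                                 name=f"atac_te{slot}"),
                        summit_offset=150,
                        pileup=round(pileup, 2),
                    )
                )
            cursor += width

        span = GenomicInterval(chrom, locus_start, cursor)
        locus_spans.append(span)
        locus_is_se.append(slot in se_slots)
        total_signal = sum((e - s) * a for s, e, a in constituents)
        locus_signal.append(total_signal)

        con_peaks = [
            Peak(
                interval=GenomicInterval(chrom, s, e, name=f"k27ac_{slot}_{j}",
                                         score=round(a, 4)),
            )
            for j, (s, e, a) in enumerate(constituents)
        ]
        h3k27ac_peaks.extend(con_peaks)
        atac_peaks.extend(local_atac)
        if slot in se_slots:
            se_atac_by_slot[slot] = local_atac
            se_constituents_by_slot[slot] = con_peaks
            se_records.append(
                {
                    "slot": slot,
                    "grid_rank": slot_rank[slot],
                    "chrom": chrom,
                    "start": locus_start,
                    "end": cursor,
                    "signal": round(total_signal, 2),
                    "tf": slot_tf_lookup.get(slot, ""),
                }
            )

        # one gene per locus, TSS just upstream
        tss = locus_start - int(rng.integers(1500, 4000))
        tf = slot_tf_lookup.get(slot)
        if tf is not None:
            gene_id, symbol, is_tf = tf, tf, True
            tpm = TF_TPM[tf]
        else:
            gene_id = symbol = f"G{slot:04d}"
            is_tf = False
            tpm = float(rng.lognormal(math.log(20.0), 1.0))
        annotation.append(
            GeneAnnotation(gene_id=gene_id, symbol=symbol, chrom=chrom,
                           tss=tss, strand="+", is_tf=is_tf)
        )
        expr_rows.append((symbol, round(tpm, 4)))

        cursor += int(rng.integers(15000, 22000))

    genome_size = cursor + 20000
    if spec.chrom_size is not None:
        if spec.chrom_size < genome_size:
            raise ValueError(
                f"chrom_size {spec.chrom_size} too small for the requested "
                f"loci (need >= {genome_size})"
            )
        genome_size = spec.chrom_size

    # ----- genome sequence with planted words -----
    seq_idx = rng.integers(0, 4, size=genome_size, dtype=np.int8)

    def plant(word: str, pos: int, tf: str, se_tf: str) -> None:
        for i, b in enumerate(word):
            seq_idx[pos + i] = BASES.index(b)
        planted_words.append(
            {"tf": tf, "chrom": chrom, "start": pos, "strand": "+",
             "se_gene": se_tf}
        )
        word_sites[tf].append(pos)

    def plant_set(atac: Peak, tfs: list[str], se_tf: str) -> None:
        pos = atac.interval.start + 20
        for tf in tfs:
            word = consensus[tf]
            plant(word, pos, tf, se_tf)
            pos += len(word) + 6

    clique = tuple(sorted(spec.clique_members))
    for member in clique:
        slot = tf_slots[member]
        atac = se_atac_by_slot[slot]
        plant_set(atac[0], list(clique), member)
        if len(atac) > 1:  # duplicate placements for robustness to filters
            plant_set(atac[1], list(clique), member)
    # TP63 self-loop + RUNX1 feed; TP63/KLF5 exchange without KLF5 self
    plant_set(se_atac_by_slot[tf_slots["TP63"]][0], ["TP63", "RUNX1", "KLF5"],
              "TP63")
    plant_set(se_atac_by_slot[tf_slots["KLF5"]][0], ["TP63"], "KLF5")
    plant_set(se_atac_by_slot[tf_slots["GRHL2"]][0], ["PAX6"], "GRHL2")

    base_bytes = np.frombuffer(BASES.encode("ascii"), dtype=np.uint8)
    genome = InMemoryGenome(
        {chrom: base_bytes[seq_idx].tobytes().decode("ascii")}
    )

    # background ATAC peaks in intergenic space
    for i in range(spec.n_background_atac):
        pos = int(rng.integers(0, genome_size - 400))
        pileup = float(rng.lognormal(math.log(30.0), 0.6))
        atac_peaks.append(
            Peak(
                interval=GenomicInterval(chrom, pos, pos + 300, name=f"atac_bg{i}"),
                summit_offset=150,
                pileup=round(pileup, 2),
            )
        )
    atac_peaks.sort(key=lambda p: p.interval.start)

    # ----- TF ChIP peaks -----
    tf_peaks: dict[str, list[Peak]] = {tf: [] for tf in ALL_TFS}
    half_peak = 120

    def add_tf_peak(tf: str, center: int) -> None:
        tf_peaks[tf].append(
            Peak(
                interval=GenomicInterval(
                    chrom, max(0, center - half_peak), center + half_peak,
                    name=f"{tf}_pk{len(tf_peaks[tf])}",
                ),
                summit_offset=half_peak,
            )
        )

    for tf in ALL_TFS:
        for pos in word_sites[tf]:
            add_tf_peak(tf, pos + len(consensus[tf]) // 2)

    kd_bound_slots: list[int] = []
    cobinders = [t for t in clique if t != spec.kd_target][:2]
    for rec in se_records:
        slot = rec["slot"]
        con0 = se_constituents_by_slot[slot][0].interval
        center = con0.midpoint
        is_clique_se = rec["tf"] in clique
        if spec.kd_target in ALL_TFS:
            kd_bound_slots.append(slot)
            if not is_clique_se:
                add_tf_peak(spec.kd_target, center)
        for tf in cobinders:
            if not is_clique_se and rng.random() < spec.cobind_rate:
                add_tf_peak(tf, center + int(rng.integers(-40, 40)))
    for tf in ALL_TFS:
        for _ in range(spec.n_unique_tf_peaks):
            pos = int(rng.integers(200, genome_size - 200))
            add_tf_peak(tf, pos)
        tf_peaks[tf].sort(key=lambda p: p.interval.start)

    # ----- coverage tracks -----
    k27_records = [
        (p.interval.chrom, p.interval.start, p.interval.end, p.interval.score)
        for p in h3k27ac_peaks
    ]
    k4_records = [
        (p.interval.chrom, p.interval.start, p.interval.end,
         round(8.0 * float(rng.uniform(0.8, 1.2)), 4))
        for p in h3k27ac_peaks
    ]
    k27me3_records = []
    last_end = -1
    for pos in sorted(int(rng.integers(0, genome_size - 2500)) for _ in range(40)):
        if pos >= last_end:  # drop blocks that would overlap the previous one
            k27me3_records.append((chrom, pos, pos + 2000, 5.0))
            last_end = pos + 2000
    coverage = {
        "h3k27ac": Coverage.from_records(k27_records),
        "h3k4me1": Coverage.from_records(k4_records),
        "h3k27me3": Coverage.from_records(sorted(k27me3_records)),
    }

    # ----- NB counts over stitched loci (wild-type replicates) -----
    region_ids = [
        f"{s.chrom}:{s.start}-{s.end}" for s in locus_spans
    ]
    mu = np.array(locus_signal) / spec.count_scale
    counts = {}
    for r in range(spec.n_replicates):
        counts[f"wt_rep{r + 1}"] = _nb_draw(rng, mu, spec.nb_dispersion)
    counts_df = pd.DataFrame(counts, index=region_ids)
    counts_df.index.name = "region"
    design = pd.DataFrame(
        {
            "sample": list(counts),
            "condition": ["wt"] * spec.n_replicates,
            "replicate": list(range(1, spec.n_replicates + 1)),
        }
    )

    expression = (
        pd.DataFrame(expr_rows, columns=["symbol", "tpm"])
        .set_index("symbol")["tpm"]
    )

    truth = {
        "seed": spec.seed,
        "chrom": chrom,
        "chrom_size": genome_size,
        "n_se_planted": spec.n_se,
        "n_te": spec.n_te,
        "planted_ses": se_records,
        "clique": list(clique),
        "tf_se_slots": {tf: int(s) for tf, s in tf_slots.items()
                        if tf in TF_SE_GRID_RANK},
        "planted_words": planted_words,
        "kd": {
            "target": spec.kd_target,
            "fold": spec.kd_fold,
            "bound_se_slots": kd_bound_slots,
        },
        "locus_is_se": [bool(b) for b in locus_is_se],
        "locus_signals": [round(float(s), 2) for s in locus_signal],
    }

    return SimulatedDataset(
        spec=spec,
        genome=genome,
        chrom_sizes={chrom: genome_size},
        annotation=annotation,
        h3k27ac_peaks=h3k27ac_peaks,
        coverage=coverage,
        atac_peaks=atac_peaks,
        tf_peaks=tf_peaks,
        pwms=pwms,
        expression=expression,
        counts=counts_df,
        design=design,
        truth=truth,
    )


def simulate_knockdown(
    dataset: SimulatedDataset,
    tf: Optional[str] = None,
    fold: Optional[float] = None,
) -> SimulatedDataset:
    """Perturb the dataset by a TF knockdown.

    H3K27ac coverage, constituent amplitudes and NB counts over the SE
    constituents bound by ``tf`` (per the truth manifest) are scaled by
    ``fold``; H3K4me1 and H3K27me3 are untouched.  Knockdown replicate
    counts are appended to the count matrix and the truth manifest gains
    the affected regions.
    """
    spec = dataset.spec
    tf = tf if tf is not None else spec.kd_target
    fold = fold if fold is not None else spec.kd_fold
    if tf not in ALL_TFS:
        raise ValueError(f"unknown TF {tf!r}")
    if tf != dataset.truth["kd"]["target"]:
        raise ValueError(
            f"truth manifest records binding for {dataset.truth['kd']['target']!r}, "
            f"not {tf!r}"
        )
    bound_slots = set(dataset.truth["kd"]["bound_se_slots"])
    if not bound_slots:
        raise ValueError(f"{tf} is not bound to any SE in this dataset")
    rng = np.random.default_rng([spec.seed, 7919])

    # SE slots are identified by the k27ac peak names k27ac_<slot>_<j>
    def peak_slot(p: Peak) -> int:
        return int(p.interval.name.split("_")[1])

    affected = [
        p.interval for p in dataset.h3k27ac_peaks if peak_slot(p) in bound_slots
    ]
    new_k27_records = []
    new_peaks = []
    for p in dataset.h3k27ac_peaks:
        iv = p.interval
        amp = iv.score
        if peak_slot(p) in bound_slots:
            amp = round(amp * fold, 4)
        new_peaks.append(
            Peak(interval=dc_replace(iv, score=amp), summit_offset=p.summit_offset,
                 pileup=p.pileup, extras=p.extras)
        )
        new_k27_records.append((iv.chrom, iv.start, iv.end, amp))

    coverage = dict(dataset.coverage)
    coverage["h3k27ac"] = Coverage.from_records(new_k27_records)

    is_se = dataset.truth["locus_is_se"]
    signals = np.array(dataset.truth["locus_signals"], dtype=float)
    region_ids = list(dataset.counts.index)
    mu = signals / spec.count_scale
    kd_scale = np.array(
        [fold if (is_se[i] and i in bound_slots) else 1.0
         for i in range(len(region_ids))]
    )
    counts = dataset.counts.copy()
    for r in range(spec.n_replicates):
        counts[f"kd_rep{r + 1}"] = _nb_draw(rng, mu * kd_scale, spec.nb_dispersion)
    design = pd.concat(
        [
            dataset.design,
            pd.DataFrame(
                {
                    "sample": [f"kd_rep{r + 1}" for r in range(spec.n_replicates)],
                    "condition": ["kd"] * spec.n_replicates,
                    "replicate": list(range(1, spec.n_replicates + 1)),
                }
            ),
        ],
        ignore_index=True,
    )

    truth = json.loads(json.dumps(dataset.truth))
    truth["kd"]["fold"] = fold
    truth["kd"]["affected_regions"] = [
        {"chrom": iv.chrom, "start": iv.start, "end": iv.end, "fold": fold}
        for iv in affected
    ]
    truth["kd"]["targeted_se_slots"] = sorted(
        s for s in bound_slots if is_se[s]
    )

    return SimulatedDataset(
        spec=spec,
        genome=dataset.genome,
        chrom_sizes=dataset.chrom_sizes,
        annotation=dataset.annotation,
        h3k27ac_peaks=new_peaks,
        coverage=coverage,
        atac_peaks=dataset.atac_peaks,
        tf_peaks=dataset.tf_peaks,
        pwms=dataset.pwms,
        expression=dataset.expression,
        counts=counts,
        design=design,
        truth=truth,
        is_knockdown=True,
    )
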