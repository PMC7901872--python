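"""Config-driven orchestration: simulate -> tracks -> profiles -> enhancers.

The pipeline is deterministic given its config: every stage derives its RNG
stream from the config seed, outputs carry no timestamps, and the manifest
records a parameter hash so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import chemistry, enhancers as enh_mod, genome as gen_mod, promoters, tracks
from .genome import KLF_MOTIF, ParameterError

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    mode: str = "bismapr"
    seed: int = 1
    # genome / annotation
    n_chroms: int = 1
    chrom_len: int = 800_000
    gc: float = 0.42
    n_genes: int = 40
    divergent_fraction: float = 0.75
    expressed_fraction: float = 0.8
    n_bidirectional_pairs: int = 3
    bidirectional_span: int = 300
    n_enhancers_per_group: int = 10
    enhancer_skew: float = 0.4
    enhancer_len: int = 1000
    placement_pad: int = 2500
    motif_consensus: str = KLF_MOTIF.consensus
    # chemistry
    p_conv: float = 0.95
    rnase_efficiency: float = 0.9
    ssdna_free_fraction: float = 0.1
    depth_scale: float = 1.0
    background_rate: float = 0.2
    # tracks
    bin_size: int = 5
    blacklist: str = ""
    # analysis
    log2_threshold: float = 1.5
    pseudocount: float = 0.1
    bidirectional_max_span: int = 1000
    gc_window: int = 100
    gc_step: int = 10
    kmeans_k: int = 4
    matrix_window: int = 2000

    def __post_init__(self):
        if self.mode not in chemistry.MODES:
            raise ParameterError(f"mode must be one of {chemistry.MODES}")
        for name in ("bin_size", "log2_threshold", "bidirectional_max_span",
                     "gc_window", "gc_step", "kmeans_k", "matrix_window"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for f in dataclasses.fields(self):
                v = getattr(self, f.name)
                if isinstance(v, str):
                    fh.write(f'{f.name} = "{v}"\n')
                else:
                    fh.write(f"{f.name} = {v}\n")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - names
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def param_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def simulate_world(cfg: PipelineConfig):
    """Genome + genes + bidirectional pairs + enhancers + truth loci."""
    g = gen_mod.simulate_genome(cfg.n_chroms, cfg.chrom_len, cfg.gc,
                                seed=cfg.seed)
    genes, loci = gen_mod.annotate_genes(
        g, cfg.n_genes, cfg.divergent_fraction, cfg.expressed_fraction,
        seed=cfg.seed + 11, ssdna_free_fraction=cfg.ssdna_free_fraction)
    pairs, pair_loci = gen_mod.plant_bidirectional_pairs(
        g, genes, cfg.n_bidirectional_pairs, cfg.bidirectional_span,
        seed=cfg.seed + 12, ssdna_free_fraction=cfg.ssdna_free_fraction,
        pad=cfg.placement_pad)
    for gm, gp in pairs:
        genes.extend((gm, gp))
    loci.extend(pair_loci)
    motif = gen_mod.MotifModel(cfg.motif_consensus, name="planted")
    g, enhancers, enh_loci = gen_mod.plant_enhancers(
        g, (cfg.n_enhancers_per_group,) * 4, motif, cfg.enhancer_skew,
        seed=cfg.seed + 13, genes=genes, gc=cfg.gc,
        enhancer_len=cfg.enhancer_len, pad=cfg.placement_pad,
        ssdna_free_fraction=cfg.ssdna_free_fraction)
    loci.extend(enh_loci)
    return g, genes, loci, enhancers, pairs


def run_pipeline(cfg: PipelineConfig, outdir) -> dict:
    """Run all stages, write every artifact under ``outdir``, return manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config_hash": cfg.param_hash(), "seed": cfg.seed,
                "mode": cfg.mode, "stages": [], "outputs": {}}

    def stage(name):
        t0 = time.perf_counter()
        logger.info("stage %s ...", name)
        manifest["stages"].append(name)
        return t0

    def done(name, t0):
        logger.info("stage %s done in %.2fs", name, time.perf_counter() - t0)

    # --- simulate ---------------------------------------------------------
    t0 = stage("simulate")
    g, genes, loci, enhancers, pairs = simulate_world(cfg)
    gen_mod.write_fasta(g, out / "genome.fa")
    gen_mod.write_genes_bed(genes, out / "genes.bed")
    gen_mod.write_loci_bed(loci, out / "truth_loci.bed")
    gen_mod.write_enhancers_bed(enhancers, out / "enhancers.bed")
    gen_mod.write_expression_tsv(genes, out / "expression.tsv")
    done("simulate", t0)

    # --- chemistry --------------------------------------------------------
    t0 = stage("chemistry")
    records = chemistry.run_chemistry(
        g, loci, cfg.mode, p_conv=cfg.p_conv,
        rnase_efficiency=cfg.rnase_efficiency,
        background_rate=cfg.background_rate, depth_scale=cfg.depth_scale,
        seed=cfg.seed + 21)
    chemistry.write_sam(records, g.lengths, out / "library.sam")
    chemistry.write_truth_tsv(records, out / "library_truth.tsv")
    done("chemistry", t0)

    # --- tracks -----------------------------------------------------------
    t0 = stage("tracks")
    blacklist = (tracks.read_bed_intervals(cfg.blacklist)
                 if cfg.blacklist else None)
    track = tracks.build_tracks(records, g.lengths, cfg.bin_size, blacklist)
    tracks.write_bedgraph(track.forward, cfg.bin_size, out / "forward.bedgraph")
    tracks.write_bedgraph(track.reverse, cfg.bin_size, out / "reverse.bedgraph")
    tracks.write_bedgraph(tracks.composite_track(track), cfg.bin_size,
                          out / "composite.bedgraph")
    done("tracks", t0)

    # --- profiles ---------------------------------------------------------
    t0 = stage("profiles")
    expr = promoters.load_expression_tsv(out / "expression.tsv")
    expressed = promoters.expressed_genes(expr)
    active = [gn for gn in genes if gn.gene_id in expressed]
    table = promoters.promoter_density_table(
        track, active, half_window=cfg.matrix_window // 2,
        log2_threshold=cfg.log2_threshold, pseudocount=cfg.pseudocount)
    table.to_csv(out / "tss_classification.tsv", sep="\t",
                 float_format="%.4f")
    anchors = promoters.tss_anchors(active)
    fwd_m = promoters.reference_point_matrix(
        track.forward, cfg.bin_size, anchors, cfg.matrix_window,
        cfg.matrix_window)
    rev_m = promoters.reference_point_matrix(
        track.reverse, cfg.bin_size, anchors, cfg.matrix_window,
        cfg.matrix_window)
    profile = promoters.strandedness_profile(fwd_m, rev_m)
    np.savetxt(out / "strandedness_profile.tsv",
               np.column_stack([fwd_m.bin_centers, profile]),
               fmt="%.6g", delimiter="\t", header="offset\tstrandedness",
               comments="")
    bidir = promoters.find_bidirectional_promoters(
        genes, cfg.bidirectional_max_span, expressed)
    with open(out / "bidirectional_promoters.tsv", "w") as fh:
        fh.write("minus_gene\tplus_gene\tchrom\tspan\n")
        for gm, gp, span in bidir:
            fh.write(f"{gm.gene_id}\t{gp.gene_id}\t{gm.chrom}\t{span}\n")
    done("profiles", t0)

    # --- enhancers --------------------------------------------------------
    t0 = stage("enhancers")
    fwd_e, rev_e = enh_mod.enhancer_matrix(track, enhancers, window=1000)
    grouping = enh_mod.cluster_enhancers(fwd_e, rev_e, k=cfg.kmeans_k,
                                         seed=cfg.seed)
    motif = gen_mod.MotifModel(cfg.motif_consensus, name="planted")
    skew_by_id, offset_by_id = {}, {}
    for e in enhancers:
        seq = g.seq(e.chrom)[e.start:e.end]
        skew_by_id[e.enh_id] = float(np.mean(enh_mod.gc_skew(
            seq, cfg.gc_window, cfg.gc_step)))
        hits = enh_mod.scan_motif(seq, motif)
        if hits:
            offset_by_id[e.enh_id] = hits[0][0]
    table = enh_mod.grouping_table(grouping, enhancers, skew_by_id,
                                   offset_by_id)
    table.to_csv(out / "enhancer_groups.tsv", sep="\t", float_format="%.4f")
    with open(out / "enhancer_groups.bed", "w") as fh:
        by_id = {e.enh_id: e for e in enhancers}
        for eid, lab in zip(grouping.ids, grouping.labels):
            e = by_id[eid]
            fh.write(f"{e.chrom}\t{e.start}\t{e.end}\tgroup{lab}\t0\t.\n")
    # overlap of recovered high-signal groups (1-2) with planted
    # unidirectional truth, as a hypergeometric enrichment report
    truth_uni = {e.enh_id for e in enhancers if e.truth_group in (1, 2)}
    called = set(grouping.members(1)) | set(grouping.members(2))
    res = enh_mod.hypergeom_enrichment(
        len(enhancers), len(truth_uni), len(called),
        len(truth_uni & called))
    with open(out / "enrichment.tsv", "w") as fh:
        fh.write("population\tsuccesses\tdraws\toverlap\tfold\tp\n")
        fh.write(f"{res.population}\t{res.successes}\t{res.draws}\t"
                 f"{res.overlap}\t{res.fold:.4f}\t{res.p:.4g}\n")
    done("enhancers", t0)

    for p in sorted(out.iterdir()):
        if p.name != "manifest.json" and p.is_file():
            manifest["outputs"][p.name] = _sha256(p)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


FIXTURE_SCALES = {
    "tiny": dict(n_chroms=1, chrom_len=100_000, n_genes=6,
                 n_bidirectional_pairs=2, n_enhancers_per_group=2,
                 enhancer_len=600, placement_pad=1000),
    "demo": dict(n_chroms=2, chrom_len=1_000_000, n_genes=140,
                 n_bidirectional_pairs=10, n_enhancers_per_group=15,
                 placement_pad=2000),
}


def make_fixtures(scale: str, seed: int, outdir) -> PipelineConfig:
    """Write a self-contained synthetic input set (genome, annotation,
    truth, library) at 'tiny' or 'demo' scale."""
    if scale not in FIXTURE_SCALES:
        raise ParameterError(f"scale must be one of {sorted(FIXTURE_SCALES)}")
    cfg = PipelineConfig(seed=seed, **FIXTURE_SCALES[scale])
    run_pipeline(cfg, outdir)
    cfg.to_file(Path(outdir) / "config.toml")
    return cfg


def setup_logging(verbose: bool = True) -> None:
    logging.basicConfig(stream=sys.stderr,
                        level=logging.INFO if verbose else logging.WARNING,
                        format="%(levelname)s %(name)s: %(message)s")
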