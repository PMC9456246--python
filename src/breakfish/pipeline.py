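"""End-to-end pipelines tying segmentation, metrics and statistics together.

``analyze_stack`` runs the per-stack detection chain (despeckle →
nucleus detection → per-nucleus locus/territory detection → pairing →
distances → QC).  ``run_fish_pipeline`` pools cells across conditions,
derives the break threshold from the control condition and computes the
break-calling and territory statistics.  ``run_fourc_pipeline`` runs
the full 4C chain (digest → demux → map → count → mask → merge →
profile → trans fraction → enrichment).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import allele_metrics as am
from . import break_stats as bs
from . import fourc as fc
from . import segmentation as seg
from .config import FishRunConfig, RunConfig
from .stack import VoxelStack

log = logging.getLogger("breakfish")

__all__ = ["analyze_stack", "run_fish_pipeline", "run_fourc_pipeline", "FishRunResult"]


def analyze_stack(
    channels: dict[str, VoxelStack],
    config: FishRunConfig,
    cell_id_offset: int = 0,
) -> list[am.CellRecord]:
    """Detect and measure every cell in one multi-channel stack."""
    s = config.segmentation
    dna = seg.despeckle(channels["dna"])
    probe1 = seg.despeckle(channels["probe1"])
    probe2 = seg.despeckle(channels["probe2"])
    paint = seg.despeckle(channels["paint"])
    spacing = dna.spacing

    det_cfg = seg.NucleusDetectConfig(
        stop_fraction=s.stop_fraction,
        init_radius=s.init_radius_vox,
        beta=s.beta,
        min_voxels=s.nucleus_min_vox,
        max_voxels=s.nucleus_max_vox,
    )
    nuclei = seg.detect_nuclei(dna, det_cfg)
    log.info("detected %d nuclei", len(nuclei))

    cells: list[am.CellRecord] = []
    for i, nucleus in enumerate(nuclei):
        cell = am.CellRecord(cell_id=cell_id_offset + i, nucleus=nucleus)
        objs1 = seg.size_filter(
            seg.detect_objects(probe1, nucleus, "locus", s.locus_top_k, s.connectivity, i),
            s.locus_min_vox, s.locus_max_vox,
        )
        objs2 = seg.size_filter(
            seg.detect_objects(probe2, nucleus, "locus", s.locus_top_k, s.connectivity, i),
            s.locus_min_vox, s.locus_max_vox,
        )
        terrs = seg.size_filter(
            seg.detect_objects(paint, nucleus, "territory", s.territory_top_k, s.connectivity, i),
            s.territory_min_vox, s.territory_max_vox,
        )
        cell.loci1 = [am.weighted_centroid(o, spacing, "probe1") for o in objs1]
        cell.loci2 = [am.weighted_centroid(o, spacing, "probe2") for o in objs2]
        cell.territories = terrs
        pairs, _ = am.pair_loci(cell.loci1, cell.loci2)
        for l1, l2 in pairs:
            pair = am.AllelePair(locus1=l1, locus2=l2, cell_id=cell.cell_id)
            pair.pair_distance = am.pair_distance(pair)
            if terrs:
                pair.territory_dist1 = am.nearest_territory_distance(l1, terrs, spacing)
                pair.territory_dist2 = am.nearest_territory_distance(l2, terrs, spacing)
            cell.pairs.append(pair)
        cells.append(am.qc_cell(cell, config.cutoff_nm))
    return cells


@dataclass
class FishRunResult:
    """Pooled per-cell measurements plus the derived break statistics."""

    cells: pd.DataFrame  # one row per retained allele pair
    threshold_nm: float = float("nan")
    stats: dict = field(default_factory=dict)

    def scatter_table(self) -> pd.DataFrame:
        """Per-locus (pair distance, signed territory distance) table."""
        rows = []
        for _, r in self.cells.iterrows():
            for probe, td in (("probe1", r.territory_dist1_nm), ("probe2", r.territory_dist2_nm)):
                rows.append((r.condition, r.cell_id, r.pair_index, probe, r.pair_distance_nm, td))
        return pd.DataFrame(
            rows,
            columns=["condition", "cell_id", "pair_index", "probe", "pair_distance_nm", "territory_dist_nm"],
        )

    def histogram_table(self, bin_nm: float = 100.0) -> pd.DataFrame:
        """Binned pairwise-distance counts per condition."""
        d = self.cells
        upper = max(d.pair_distance_nm.max(), bin_nm)
        bins = np.arange(0, upper + bin_nm, bin_nm)
        out = []
        for cond, grp in d.groupby("condition"):
            counts, edges = np.histogram(grp.pair_distance_nm, bins=bins)
            for lo, hi, c in zip(edges[:-1], edges[1:], counts):
                out.append((cond, lo, hi, int(c)))
        return pd.DataFrame(out, columns=["condition", "bin_lo_nm", "bin_hi_nm", "count"])


def _cells_to_frame(cells: list[am.CellRecord], condition: str) -> pd.DataFrame:
    rows = []
    for cell in cells:
        if not cell.qc_pass:
            rows.append(
                dict(condition=condition, cell_id=cell.cell_id, qc_pass=False,
                     qc_reason=cell.qc_reason, pair_index=-1,
                     pair_distance_nm=np.nan, territory_dist1_nm=np.nan,
                     territory_dist2_nm=np.nan,
                     x1=np.nan, y1=np.nan, z1=np.nan, x2=np.nan, y2=np.nan, z2=np.nan)
            )
            continue
        for k, p in enumerate(cell.pairs):
            rows.append(
                dict(condition=condition, cell_id=cell.cell_id, qc_pass=True,
                     qc_reason="", pair_index=k,
                     pair_distance_nm=p.pair_distance,
                     territory_dist1_nm=p.territory_dist1,
                     territory_dist2_nm=p.territory_dist2,
                     x1=p.locus1.position[0], y1=p.locus1.position[1], z1=p.locus1.position[2],
                     x2=p.locus2.position[0], y2=p.locus2.position[1], z2=p.locus2.position[2])
            )
    return pd.DataFrame(rows)


def run_fish_pipeline(
    stack_sets: list[tuple[str, dict[str, VoxelStack]]],
    config: RunConfig,
    outdir: str | Path | None = None,
    control_condition: str = "control",
) -> FishRunResult:
    """Run the full FISH quantification over labelled stacks.

    ``stack_sets`` is a list of ``(condition, channels)`` pairs.  The
    break threshold is the ``quantile_q`` quantile of control pair
    distances; every condition is then classified against it.  An
    allele is scored outside the territory when either of its signals
    has a positive signed territory distance.
    """
    fish = config.fish
    frames = []
    offset = 0
    for condition, channels in stack_sets:
        cells = analyze_stack(channels, fish, cell_id_offset=offset)
        offset += len(cells)
        frames.append(_cells_to_frame(cells, condition))
    table = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    retained = table[table.qc_pass].copy() if len(table) else table

    result = FishRunResult(cells=retained)
    stats: dict = {"n_cells_total": int(table.cell_id.nunique()) if len(table) else 0,
                   "n_cells_qc": int(retained.cell_id.nunique()) if len(retained) else 0,
                   "conditions": {}}
    control = retained[retained.condition == control_condition] if len(retained) else retained
    if len(control) >= 10:
        threshold = bs.broken_threshold(control.pair_distance_nm.to_numpy(), fish.quantile_q)
        result.threshold_nm = threshold
        retained["broken"] = retained.pair_distance_nm > threshold
        for cond, grp in retained.groupby("condition"):
            calls = bs.classify_broken(grp.pair_distance_nm.to_numpy(), threshold)
            tail = bs.tail_test(calls.broken_fraction, len(grp), fish.k_sigma)
            stats["conditions"][cond] = {
                "n_alleles": int(len(grp)),
                "broken_fraction": calls.broken_fraction,
                "tail_margin": tail.margin,
                "tail_significant": tail.significant,
            }
        # territory association among treated alleles: broken vs intact
        treated = retained[retained.condition != control_condition]
        if len(treated):
            outside = (treated.territory_dist1_nm > 0) | (treated.territory_dist2_nm > 0)
            tab = np.array(
                [
                    [int((outside & treated.broken).sum()), int((~outside & treated.broken).sum())],
                    [int((outside & ~treated.broken).sum()), int((~outside & ~treated.broken).sum())],
                ]
            )
            if tab.sum(axis=1).min() > 0 and tab.sum(axis=0).min() > 0:
                chi2, p, fold = bs.territory_association(tab)
                stats["territory_association"] = {
                    "table": tab.tolist(), "chi2": chi2, "p": p, "fold": fold,
                }
        stats["threshold_nm"] = threshold
    result.stats = stats

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(outdir / "cells.csv", index=False)
        result.scatter_table().to_csv(outdir / "scatter.csv", index=False)
        result.histogram_table().to_csv(outdir / "histogram.csv", index=False)
        (outdir / "stats.json").write_text(json.dumps(stats, indent=1, default=float))
        manifest = {"config_hash": config.digest_hash(), "seed": config.seed,
                    "config": config.model_dump()}
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return result


def run_fourc_pipeline(
    genome: dict[str, str],
    replicate_reads: list[list[tuple[str, str]]],
    anchors: list[fc.AnchorSpec],
    config: RunConfig,
    genes: pd.DataFrame | None = None,
    partners: list[str] | None = None,
    outdir: str | Path | None = None,
) -> dict:
    """Run the 4C chain for one anchor over all replicates.

    Returns a dict with the fragment map, per-replicate and merged
    signals, replicate correlation, window profiles, trans fraction and
    (when ``genes``/``partners`` are supplied) the partner-enrichment
    test.
    """
    cfg = config.fourc
    anchor = anchors[0]
    fragments = fc.digest_genome(genome, cfg.site, cfg.cut_offset)
    rep_signals = []
    parse_logs = []
    map_logs = []
    for reads in replicate_reads:
        parsed = fc.parse_reads(reads, anchors, cfg.site, cfg.include_site)
        mapped, map_log = fc.map_exact(parsed.captured[anchor.anchor_id], genome, cfg.map_min_len)
        signals, sig_log = fc.fragment_signal(mapped, fragments, cfg.end_tolerance)
        if cfg.mask_flank >= 0:
            signals = fc.mask_bait(signals, anchor.bait_chrom, anchor.bait_fragment_index, cfg.mask_flank)
        rep_signals.append(signals)
        parse_logs.append(
            {"classified": parsed.n_classified, "no_site": parsed.n_no_site,
             "unknown_anchor": parsed.n_unknown_anchor, "ambiguous": parsed.n_ambiguous}
        )
        map_logs.append({**map_log, **sig_log})

    n_assigned = [sum(s.raw for s in sig) for sig in rep_signals]
    if len(rep_signals) > 1 and min(n_assigned) > 0:
        merged, r = fc.normalize_and_merge(rep_signals, cfg.scale, cfg.window)
    else:
        merged, r = rep_signals[0], 1.0
    profile = fc.window_profile(merged, cfg.window)
    results: dict = {
        "fragments": fragments,
        "replicate_signals": rep_signals,
        "merged_signals": merged,
        "replicate_r": r,
        "profile": profile,
        "parse_logs": parse_logs,
        "map_logs": map_logs,
    }
    bearing = [s for s in merged if s.raw >= 1]
    if bearing:
        results["trans_fraction"] = fc.trans_fraction(merged, anchor.bait_chrom)
    else:
        log.warning("no contact-bearing fragments; profiles are empty")
    if genes is not None and partners:
        u, p, gene_table = fc.partner_enrichment(
            merged, genes, partners, anchor.bait_chrom, window=cfg.window
        )
        results["enrichment"] = {"U": u, "p": p}
        results["gene_table"] = gene_table

    if outdir is not None:
        from .io import write_bed_fragments, write_bedgraph

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_bed_fragments(fragments, outdir / "fragments.bed")
        write_bedgraph(profile, outdir / f"{anchor.anchor_id}_profile.bedGraph", anchor.anchor_id)
        sig_df = pd.DataFrame(
            [(s.fragment.chrom, s.fragment.start, s.fragment.end, s.raw, s.normalized) for s in merged],
            columns=["chrom", "start", "end", "raw", "normalized"],
        )
        sig_df.to_csv(outdir / "fragment_signal.tsv", sep="\t", index=False)
        stats = {
            "replicate_r": r,
            "trans_fraction": results.get("trans_fraction"),
            "enrichment": results.get("enrichment"),
            "parse_logs": parse_logs,
            "map_logs": map_logs,
            "config_hash": config.digest_hash(),
            "seed": config.seed,
        }
        (outdir / "stats.json").write_text(json.dumps(stats, indent=1, default=float))
    return results
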