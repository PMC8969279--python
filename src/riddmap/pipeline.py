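"""End-to-end discovery pipeline: simulate/load -> flatten -> DEU -> change-point
-> stem-loop calls, with standard-format outputs and a run-metadata record.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, annotation, changepoint, deu, io, simulate, stemloop

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Thresholds, paths, and the simulation block for one discovery run."""

    # input paths (ignored when simulate_block is set)
    gtf: str | None = None
    fasta: str | None = None
    counts: str | None = None
    # simulation block
    simulate_block: dict | None = None
    # thresholds
    fdr_max: float = 0.05
    fc_max: float = -2.0
    min_delta: float = 1.0
    min_5p_sig_fraction: float = 0.5
    max_3p_depletion: float = 0.5
    min_stem: int = 4
    loop_range: tuple[int, int] = (4, 12)
    fold_window: int = 30
    window_pad: int = 100
    max_gap: int = 200
    override: tuple[str, ...] = ()
    seed: int = 0
    outdir: str = "riddmap_out"


@dataclass
class DiscoveryResult:
    models: list
    matrix: simulate.ExonCountMatrix
    deu_results: pd.DataFrame
    candidates: pd.DataFrame
    profiles: dict
    windows: list
    calls: list
    site_groups: list
    truth: simulate.SimTruth | None = None
    tallies: dict = field(default_factory=dict)


def _load_inputs(config: PipelineConfig):
    if config.simulate_block is not None:
        blk = dict(config.simulate_block)
        blk.setdefault("seed", config.seed)
        models, truth, matrix = simulate.simulate_experiment(**blk)
        return models, matrix, truth
    for name in ("gtf", "fasta", "counts"):
        path = getattr(config, name)
        if path is None or not Path(path).exists():
            raise FileNotFoundError(f"[input] required {name} file missing: {path}")
    models = io.read_gtf(config.gtf)
    models = io.attach_sequences(models, io.read_transcript_fasta(config.fasta))
    counts, gene_ids = io.read_counts_tsv(config.counts)
    bins = annotation.flatten_gene_models(models)
    counts = counts.loc[[b.bin_id for b in bins]]
    conditions = {
        s: ("mock" if s.startswith("mock") else "ire1") for s in counts.columns
    }
    matrix = simulate.ExonCountMatrix(counts=counts, conditions=conditions, bins=bins)
    return models, matrix, None


def run_discovery(config: PipelineConfig) -> DiscoveryResult:
    """Run the full discovery chain and write its outputs to ``config.outdir``."""
    t0 = time.time()
    models, matrix, truth = _load_inputs(config)
    tx_by_gene = {m.gene_id: m for m in models}

    results = deu.run_deu(matrix)
    candidates = deu.select_candidates(
        results, fdr_max=config.fdr_max, fc_max=config.fc_max, override=config.override
    )

    profiles, windows = {}, []
    ordered_bins_by_gene = {}
    for gene in candidates["gene_id"]:
        if gene not in tx_by_gene:
            continue
        t = tx_by_gene[gene]
        gbins = annotation.order_bins(
            [b for b in matrix.bins if not b.ambiguous and gene in b.gene_ids], t.strand
        )
        ordered_bins_by_gene[gene] = gbins
        prof = changepoint.build_profile(results, gene, fdr_threshold=config.fdr_max)
        if len(prof.values) < 2:
            profiles[gene] = prof
            continue
        prof = changepoint.classify_xbp1_like(
            prof,
            min_delta=config.min_delta,
            min_5p_sig_fraction=config.min_5p_sig_fraction,
            max_3p_depletion=config.max_3p_depletion,
        )
        profiles[gene] = prof
        if prof.xbp1_like:
            lo, hi = changepoint.cleavage_window(prof, gbins, t, pad=config.window_pad)
            windows.append((gene, t.transcript_id, (lo, hi)))

    sequences = {m.transcript_id: m.sequence for m in models if m.sequence}
    calls = stemloop.call_sites(
        windows,
        sequences,
        window=config.fold_window,
        min_stem=config.min_stem,
        loop_range=config.loop_range,
    )
    groups = stemloop.pair_sites(calls, max_gap=config.max_gap) if calls else []

    tallies = {
        "bins_total": len(matrix.bins),
        "bins_tested": int(results["testable"].sum()),
        "candidates": int(len(candidates)),
        "xbp1_like_genes": int(sum(p.xbp1_like for p in profiles.values())),
        "site_calls": len(calls),
        "site_groups": len(groups),
        "elapsed_s": round(time.time() - t0, 3),
    }
    result = DiscoveryResult(
        models=models,
        matrix=matrix,
        deu_results=results,
        candidates=candidates,
        profiles=profiles,
        windows=windows,
        calls=calls,
        site_groups=groups,
        truth=truth,
        tallies=tallies,
    )
    _write_outputs(config, result)
    return result


def _write_outputs(config: PipelineConfig, res: DiscoveryResult) -> None:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    res.deu_results.to_csv(outdir / "deu_results.tsv", sep="\t", index=False)
    res.candidates.to_csv(outdir / "candidates.tsv", sep="\t")
    io.write_counts_tsv(res.matrix.counts, res.matrix.gene_ids, outdir / "counts.tsv")
    io.write_bins_tsv(res.matrix.bins, outdir / "bins.tsv")
    io.write_gtf(res.models, outdir / "models.gtf")
    if all(m.sequence for m in res.models):
        io.write_transcript_fasta(res.models, outdir / "transcripts.fa")
    if res.truth is not None:
        io.write_json(res.truth.to_dict(), outdir / "truth.json")

    prof_rows = []
    for gene, p in res.profiles.items():
        for i, (v, s) in enumerate(zip(p.values, p.significant), start=1):
            prof_rows.append(
                dict(
                    gene_id=gene, rank_5to3=i, log2_usage_fc=v, significant=bool(s),
                    changepoint=p.changepoint, depth_delta=p.depth_delta,
                    xbp1_like=p.xbp1_like,
                )
            )
    pd.DataFrame(prof_rows).to_csv(outdir / "profiles.tsv", sep="\t", index=False)

    with open(outdir / "windows.bed", "w") as fh:
        for gene, tx, (lo, hi) in res.windows:
            p = res.profiles[gene]
            score = int(np.clip(-p.depth_delta * 100, 0, 1000))
            # BED6: chrom = transcript id, 0-based half-open
            fh.write(f"{tx}\t{lo - 1}\t{hi}\t{gene}\t{score}\t+\n")

    with open(outdir / "calls.tsv", "w") as fh:
        fh.write(
            "gene_id\ttranscript_id\tconsensus_start\tcleavage_after\tenergy\t"
            "stem_len\tloop_len\tin_window\tgroup_id\n"
        )
        for c in res.calls:
            fh.write(
                f"{c.gene_id}\t{c.transcript_id}\t{c.consensus_start}\t{c.cleavage_after}\t"
                f"{c.hairpin.energy}\t{c.hairpin.stem_len}\t{c.hairpin.loop_len}\t"
                f"{int(c.in_window)}\t{c.group_id}\n"
            )

    seqs = {m.transcript_id: m.sequence for m in res.models if m.sequence}
    with open(outdir / "structures.txt", "w") as fh:
        for c in res.calls:
            lo, hi = c.hairpin.span
            seq = seqs.get(c.transcript_id, "")
            fh.write(f">{c.transcript_id} {lo}-{hi} cleavage_after={c.cleavage_after}\n")
            fh.write(f"{seq[lo - 1:hi]}\n{c.hairpin.structure}\n")

    meta = {
        "version": __version__,
        "seed": config.seed,
        "config": {k: v for k, v in asdict(config).items()},
        "tallies": res.tallies,
    }
    with open(outdir / "run_metadata.json", "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
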