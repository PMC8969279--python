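import numpy as np
import pytest

from riddmap import annotation, deu, pipeline, simulate


@pytest.fixture(scope="session")
def recovery_run(tmp_path_factory):
    """One full discovery run under the parameter-recovery study conditions:
    200 genes, 20 planted targets, cleavage efficiency 0.9, depth 1e6,
    dispersion 0.05, 3 mock vs 3 IRE1-treated replicates, fixed seed."""
    out = tmp_path_factory.mktemp("recovery")
    cfg = pipeline.PipelineConfig(
        simulate_block=dict(n_genes=200, n_targets=20, epsilon=0.9, depth=1e6),
        seed=7,
        outdir=str(out),
    )
    return pipeline.run_discovery(cfg)


@pytest.fixture(scope="session")
def null_deu_results():
    """DEU results on a null simulation (no cleavage targets)."""
    _models, _truth, matrix = simulate.simulate_experiment(
        n_genes=100, n_targets=0, epsilon=0.0, depth=1e6, dispersion=0.05, seed=11
    )
    return deu.run_deu(matrix)


def true_bin_index(gene_id, cut_pos, matrix_bins, transcript):
    """1-based 5'->3' rank of the bin containing a transcript coordinate."""
    gbins = annotation.order_bins(
        [b for b in matrix_bins if not b.ambiguous and gene_id in b.gene_ids],
        transcript.strand,
    )
    for i, b in enumerate(gbins, start=1):
        t1 = annotation.genomic_to_transcript(transcript, b.start)
        t2 = annotation.genomic_to_transcript(transcript, b.end - 1)
        if min(t1, t2) <= cut_pos <= max(t1, t2):
            return i
    return None


def random_locus(rng, max_genes=3, max_tx=3, max_exons=4, span=10_000):
    """Random multi-isoform toy locus on one chromosome (for oracle tests)."""
    models = []
    n_genes = int(rng.integers(1, max_genes + 1))
    for g in range(n_genes):
        strand = "+" if rng.random() < 0.5 else "-"
        for t in range(int(rng.integers(1, max_tx + 1))):
            n_ex = int(rng.integers(1, max_exons + 1))
            cuts = np.sort(rng.choice(span, size=2 * n_ex, replace=False))
            exons = tuple((int(cuts[2 * i]), int(cuts[2 * i + 1])) for i in range(n_ex))
            models.append(
                annotation.TranscriptModel(
                    gene_id=f"g{g}",
                    transcript_id=f"g{g}t{t}",
                    chrom="chrL",
                    strand=strand,
                    exons=exons,
                )
            )
    return models
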