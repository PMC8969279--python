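"""Synthetic transcriptomes and exon-count matrices under the poly(A)-selection
read-loss model.

The generator emulates the in vitro IRE1 cleavage experiment: total RNA is
incubated with (or without) recombinant IRE1, poly(A)-selected, and sequenced.
Because only the polyadenylated 3' cleavage product survives library
preparation, a transcript cleaved with efficiency ``epsilon`` loses a fraction
``epsilon`` of its molecules' coverage over every position 5' of the cut,
while coverage 3' of the cut is unchanged.  Replicate noise is negative
binomial with variance mu + alpha * mu**2 (alpha = 0 degenerates to Poisson).

Cleavage sites are planted as XBP1-like hairpins: a perfect-complement stem
flanking a loop that carries the CUGCAG consensus, substituted (never
inserted) into the transcript sequence so coordinates stay stable.  The
recorded ground-truth cleavage position is the transcript coordinate of the
guanine at consensus position 3 (CUG|CAG), 3' of which IRE1 cleaves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import (
    ExonBin,
    TranscriptModel,
    flatten_gene_models,
    genomic_to_transcript,
    transcript_to_genomic,
)

__all__ = [
    "GeneTruth",
    "SimTruth",
    "ExonCountMatrix",
    "simulate_transcriptome",
    "plant_cleavage_hairpin",
    "simulate_counts",
]

CONSENSUS = "CUGCAG"
# offset of the scissile guanine within the consensus (CUG|CAG), 0-based
CONSENSUS_G_OFFSET = 2


@dataclass
class GeneTruth:
    """Ground truth for one gene in a simulation."""

    is_target: bool = False
    cleavage_positions: tuple[int, ...] = ()
    epsilon: float = 0.0

    def __post_init__(self) -> None:
        if not self.is_target and (self.epsilon != 0.0 or self.cleavage_positions):
            raise ValueError("non-targets must have epsilon 0 and no cleavage positions")
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError("epsilon must be in [0, 1]")


@dataclass
class SimTruth:
    """Full ground-truth record of a simulation run."""

    seed: int
    dispersion: float = 0.05
    genes: dict[str, GeneTruth] = field(default_factory=dict)
    library_sizes: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "dispersion": self.dispersion,
            "library_sizes": self.library_sizes,
            "genes": {
                g: {
                    "is_target": t.is_target,
                    "cleavage_positions": list(t.cleavage_positions),
                    "epsilon": t.epsilon,
                }
                for g, t in self.genes.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimTruth":
        truth = cls(seed=d["seed"], dispersion=d["dispersion"])
        truth.library_sizes = dict(d.get("library_sizes", {}))
        for g, t in d["genes"].items():
            truth.genes[g] = GeneTruth(
                is_target=t["is_target"],
                cleavage_positions=tuple(t["cleavage_positions"]),
                epsilon=t["epsilon"],
            )
        return truth


@dataclass
class ExonCountMatrix:
    """Exon-bin counts by sample, with condition labels.

    ``counts`` is a bins x samples integer DataFrame (index = bin_id);
    ``conditions`` maps sample -> {"mock", "ire1"}.
    """

    counts: pd.DataFrame
    conditions: dict[str, str]
    bins: list[ExonBin]
    gene_ids: pd.Series = None  # per-bin "+"-joined gene ids

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        for s in self.counts.columns:
            if s not in self.conditions:
                raise ValueError(f"sample {s} has no condition label")
            if self.conditions[s] not in ("mock", "ire1"):
                raise ValueError(f"unknown condition {self.conditions[s]!r}")
        for cond in ("mock", "ire1"):
            if sum(1 for c in self.conditions.values() if c == cond) < 2:
                raise ValueError(f"need >= 2 replicates per condition, too few {cond}")
        if self.gene_ids is None:
            self.gene_ids = pd.Series(
                ["+".join(b.gene_ids) for b in self.bins], index=self.counts.index
            )

    def samples_of(self, condition: str) -> list[str]:
        return [s for s in self.counts.columns if self.conditions[s] == condition]


def simulate_transcriptome(
    n_genes: int,
    exons_per_gene: tuple[int, int] = (4, 8),
    exon_len: tuple[int, int] = (80, 200),
    gc: float = 0.5,
    seed: int = 0,
) -> list[TranscriptModel]:
    """Generate single-isoform gene models with random spliced sequences.

    Each gene lives on its own chromosome with intron gaps of 50-200 nt and a
    random strand.  Sequences are i.i.d. nucleotides with the requested GC
    fraction.  Deterministic for a fixed seed.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if exons_per_gene[0] > exons_per_gene[1] or exons_per_gene[0] < 1:
        raise ValueError(f"invalid exons_per_gene range {exons_per_gene}")
    if exon_len[0] > exon_len[1] or exon_len[0] < 1:
        raise ValueError(f"invalid exon_len range {exon_len}")
    if not 0 < gc < 1:
        raise ValueError("gc must be in (0, 1)")

    rng = np.random.default_rng(seed)
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    alphabet = np.array(list("ACGU"))
    models = []
    for i in range(n_genes):
        n_ex = int(rng.integers(exons_per_gene[0], exons_per_gene[1] + 1))
        lens = rng.integers(exon_len[0], exon_len[1] + 1, size=n_ex)
        gaps = rng.integers(50, 201, size=n_ex)
        exons = []
        pos = int(gaps[0])
        for L, gap in zip(lens, gaps):
            exons.append((pos, pos + int(L)))
            pos += int(L) + int(gap)
        strand = "+" if rng.random() < 0.5 else "-"
        seq = "".join(rng.choice(alphabet, size=int(lens.sum()), p=probs))
        models.append(
            TranscriptModel(
                gene_id=f"G{i:04d}",
                transcript_id=f"T{i:04d}",
                chrom=f"chr{i:04d}",
                strand=strand,
                exons=tuple(exons),
                sequence=seq,
            )
        )
    return models


def plant_cleavage_hairpin(
    t: TranscriptModel,
    position: int,
    stem_len: int = 6,
    loop: str = "ACUGCAG",
) -> tuple[TranscriptModel, int]:
    """Substitute an XBP1-like hairpin so the consensus guanine sits at *position*.

    The planted window is ``G``*stem_len + loop + ``C``*stem_len — a perfect
    G-C stem flanking the loop, which must contain exactly one CUGCAG.  The
    sequence length is unchanged.  Returns the modified transcript and the
    recorded cleavage position (== *position*, the transcript coordinate of
    the guanine at consensus position 3).
    """
    if t.sequence is None:
        raise ValueError("transcript has no sequence to plant into")
    if loop.count(CONSENSUS) != 1:
        raise ValueError("loop must contain exactly one CUGCAG")
    loop_idx = loop.index(CONSENSUS)
    window = "G" * stem_len + loop + "C" * stem_len
    g_offset = stem_len + loop_idx + CONSENSUS_G_OFFSET  # 0-based within window
    start0 = (position - 1) - g_offset
    if start0 < 0 or start0 + len(window) > t.length:
        raise ValueError(
            f"hairpin window at position {position} does not fit inside "
            f"transcript of length {t.length}"
        )
    seq = t.sequence[:start0] + window + t.sequence[start0 + len(window):]
    return t.with_sequence(seq), position


def _bin_transcript_interval(b: ExonBin, t: TranscriptModel) -> tuple[int, int]:
    """1-based inclusive transcript interval covered by a genomic bin."""
    a = genomic_to_transcript(t, b.start)
    c = genomic_to_transcript(t, b.end - 1)
    return (a, c) if a <= c else (c, a)


def expected_bin_means(
    models: list[TranscriptModel],
    bins: list[ExonBin],
    truth: SimTruth,
    depth: float,
    abundances: np.ndarray,
    carryover: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin expected counts for a unit-library-size mock and IRE1 sample.

    Mock mean of bin i of gene g is lambda_g * pi_gi (gene abundance times
    within-gene bin weight, proportional to bin length), scaled so the mock
    means sum to *depth*.  The treated mean multiplies the fraction of a bin
    5' of the (3'-most) cleavage position by ``(1 - eps) + eps * carryover``.
    """
    by_gene = {m.gene_id: m for m in models}
    lam = {m.gene_id: abundances[i] for i, m in enumerate(models)}
    gene_len = {m.gene_id: m.length for m in models}

    base = np.empty(len(bins))
    scale = np.ones(len(bins))
    for i, b in enumerate(bins):
        g = b.gene_ids[0] if len(b.gene_ids) == 1 else None
        if g is None:
            # ambiguous bin: sum contributions of each member gene
            base[i] = sum(lam[x] * b.length / gene_len[x] for x in b.gene_ids)
            continue
        if g not in truth.genes:
            raise KeyError(f"no truth entry for gene {g}")
        base[i] = lam[g] * b.length / gene_len[g]
        gt = truth.genes[g]
        if gt.is_target and gt.cleavage_positions:
            t = by_gene[g]
            cut = max(gt.cleavage_positions)  # 3'-most cut survives selection
            t1, t2 = _bin_transcript_interval(b, t)
            n5 = max(0, min(t2, cut) - t1 + 1)
            frac5 = n5 / b.length
            retain = (1.0 - gt.epsilon) + gt.epsilon * carryover
            scale[i] = frac5 * retain + (1.0 - frac5)
    base *= depth / base.sum()
    return base, base * scale


def simulate_counts(
    models: list[TranscriptModel],
    truth: SimTruth,
    n_mock: int = 3,
    n_ire1: int = 3,
    depth: float = 1e6,
    seed: int = 0,
    carryover: float = 0.0,
    abundance_meanlog: float = 4.0,
    abundance_sdlog: float = 1.0,
    library_size_sdlog: float = 0.1,
    bins: list[ExonBin] | None = None,
) -> ExonCountMatrix:
    """Draw replicate exon-bin counts for mock and IRE1-treated samples.

    Gene abundances are log-normal (meanlog 4, sdlog 1 by default); library
    size factors are log-normal around 1 and recorded in *truth*.  Counts are
    NB(mean, alpha) with alpha = ``truth.dispersion`` (Poisson when 0).
    """
    if n_mock < 2 or n_ire1 < 2:
        raise ValueError("need >= 2 replicates per condition")
    for m in models:
        if m.gene_id not in truth.genes:
            raise KeyError(f"no truth entry for gene {m.gene_id}")
    rng = np.random.default_rng(seed)
    if bins is None:
        bins = flatten_gene_models(models)
    abundances = rng.lognormal(abundance_meanlog, abundance_sdlog, size=len(models))
    mu_mock, mu_ire1 = expected_bin_means(models, bins, truth, depth, abundances, carryover)

    samples = [f"mock_{j + 1}" for j in range(n_mock)] + [
        f"ire1_{j + 1}" for j in range(n_ire1)
    ]
    conditions = {s: ("mock" if s.startswith("mock") else "ire1") for s in samples}
    sizes = rng.lognormal(0.0, library_size_sdlog, size=len(samples))
    sizes /= np.exp(np.mean(np.log(sizes)))  # geometric mean 1
    truth.library_sizes = {s: float(z) for s, z in zip(samples, sizes)}

    alpha = truth.dispersion
    cols = {}
    for s, z in zip(samples, sizes):
        mu = z * (mu_mock if conditions[s] == "mock" else mu_ire1)
        if alpha == 0.0:
            cols[s] = rng.poisson(mu)
        else:
            r = 1.0 / alpha
            p = r / (r + mu)
            cols[s] = rng.negative_binomial(r, p)
    counts = pd.DataFrame(cols, index=[b.bin_id for b in bins])
    return ExonCountMatrix(counts=counts, conditions=conditions, bins=bins)


def simulate_experiment(
    n_genes: int = 200,
    n_targets: int = 20,
    epsilon: float = 0.9,
    depth: float = 1e6,
    dispersion: float = 0.05,
    n_mock: int = 3,
    n_ire1: int = 3,
    seed: int = 0,
    stem_len: int = 6,
    loop: str = "ACUGCAG",
    **transcriptome_kwargs,
) -> tuple[list[TranscriptModel], SimTruth, ExonCountMatrix]:
    """Full study simulation: transcriptome, planted targets, count matrix.

    ``n_targets`` genes are chosen at random; each gets one XBP1-like hairpin
    planted in the middle 30-70% of its transcript and is cleaved with
    efficiency *epsilon*.  Seeds for the sub-steps are derived from *seed*.
    """
    rng = np.random.default_rng(seed)
    sub = rng.integers(0, 2**31 - 1, size=3)
    models = simulate_transcriptome(n_genes, seed=int(sub[0]), **transcriptome_kwargs)
    truth = SimTruth(seed=seed, dispersion=dispersion)
    target_idx = set(rng.choice(n_genes, size=n_targets, replace=False).tolist())
    planted = []
    for i, m in enumerate(models):
        if i in target_idx:
            lo = max(int(0.3 * m.length), 40)
            hi = min(int(0.7 * m.length), m.length - 40)
            pos = int(rng.integers(lo, hi + 1))
            m, recorded = plant_cleavage_hairpin(m, pos, stem_len=stem_len, loop=loop)
            truth.genes[m.gene_id] = GeneTruth(
                is_target=True, cleavage_positions=(recorded,), epsilon=epsilon
            )
        else:
            truth.genes[m.gene_id] = GeneTruth()
        planted.append(m)
    matrix = simulate_counts(
        planted, truth, n_mock=n_mock, n_ire1=n_ire1, depth=depth, seed=int(sub[1])
    )
    return planted, truth, matrix
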