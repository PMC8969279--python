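"""Per-bin differential exon usage: NB likelihood-ratio test, signed fold
change, BH-FDR, and candidate selection.

The test contrasts each exon bin against the rest of its gene.  For every
sample the pair (bin count, rest-of-gene count) is modelled with negative
binomial means

    null:        log mu[sample, part] = a_sample + b * 1[part = bin]
    alternative: log mu[sample, part] = a_sample + b * 1[part = bin]
                                        + c * 1[part = bin, condition = ire1]

with a plug-in dispersion alpha shared between both fits.  The statistic is
LR = 2 * (l1 - l0), referred to chi-square with 1 df.  Per-sample intercepts
absorb sequencing depth, so the test itself needs no explicit normalisation;
size factors are used to compute usage fractions and fold changes.

Fold change is the usage odds ratio reported in the signed +/- convention
with |fc| >= 1: fc < 0 means the bin's usage is lower in IRE1-treated
samples, so a selection rule of FDR < 0.05 and FC < -2 keeps bins with at
least a two-fold usage loss after cleavage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

from .annotation import ExonBin, order_bins
from .simulate import ExonCountMatrix

__all__ = [
    "size_factors",
    "estimate_dispersions",
    "test_bin",
    "fold_change",
    "run_deu",
    "select_candidates",
]

log = logging.getLogger(__name__)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (geometric-mean pseudo-reference).

    Computed over bins with all-positive counts and normalised to geometric
    mean 1.  Falls back to total-count ratios (with a warning) when no bin is
    positive in every sample.
    """
    if not (counts.values > 0).any():
        raise ValueError("count matrix is all zero; cannot compute size factors")
    positive = counts[(counts > 0).all(axis=1)]
    if len(positive) == 0:
        log.warning("no all-positive bin; falling back to total-count size factors")
        factors = counts.sum(axis=0).astype(float)
    else:
        logref = np.log(positive).mean(axis=1)
        factors = np.exp(np.log(positive).sub(logref, axis=0).median(axis=0))
    factors /= np.exp(np.mean(np.log(factors)))
    return factors


def estimate_dispersions(matrix: ExonCountMatrix, sf: pd.Series | None = None) -> pd.Series:
    """Method-of-moments NB dispersion per bin, shrunk toward the gene mean.

    On size-factor-normalised counts, within each condition
    alpha_hat = max(0, (s2 - mean) / mean**2); the per-bin estimate (averaged
    over conditions) is then shrunk halfway toward the mean dispersion of the
    bin's gene.
    """
    if sf is None:
        sf = size_factors(matrix.counts)
    norm = matrix.counts / sf
    raw = pd.Series(0.0, index=matrix.counts.index)
    for cond in ("mock", "ire1"):
        sub = norm[matrix.samples_of(cond)]
        mu = sub.mean(axis=1)
        s2 = sub.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = (s2 - mu) / mu**2
        raw += np.clip(a.fillna(0.0), 0.0, None)
    raw /= 2.0
    gene_mean = raw.groupby(matrix.gene_ids).transform("mean")
    return 0.5 * raw + 0.5 * gene_mean


def _nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    if alpha == 0.0:
        return float(np.sum(y * np.log(mu) - mu - special.gammaln(y + 1)))
    r = 1.0 / alpha
    return float(
        np.sum(
            special.gammaln(y + r)
            - special.gammaln(r)
            - special.gammaln(y + 1)
            + r * np.log(r / (r + mu))
            + y * np.log(mu / (r + mu))
        )
    )


def _fit_nb_glm(
    y: np.ndarray, design: np.ndarray, alpha: float, beta0: np.ndarray
) -> tuple[float, np.ndarray]:
    """Maximise the NB log-likelihood with mean exp(design @ beta), fixed alpha."""
    r = 1.0 / alpha

    def negll_grad(beta):
        mu = np.exp(design @ beta)
        ll = _nb_loglik(y, mu, alpha)
        dldeta = y - mu * (r + y) / (r + mu)
        return -ll, -(design.T @ dldeta)

    res = optimize.minimize(negll_grad, beta0, jac=True, method="L-BFGS-B")
    return -float(res.fun), res.x


def _poisson_fits(y_bin, y_rest, conditions):
    """Closed-form Poisson MLE means for null and alternative models.

    With per-sample intercepts, the fitted null mean for the bin part is
    N_j * T_bin / N, and the alternative replaces the global bin share by the
    per-condition share — the iterative-proportional-fitting solution of the
    log-linear model.
    """
    N_j = y_bin + y_rest
    share0 = y_bin.sum() / N_j.sum()
    mu0_bin = N_j * share0
    mu1_bin = np.empty_like(mu0_bin, dtype=float)
    for cond in ("mock", "ire1"):
        sel = conditions == cond
        share = y_bin[sel].sum() / N_j[sel].sum() if N_j[sel].sum() > 0 else 0.0
        mu1_bin[sel] = N_j[sel] * share
    return N_j, mu0_bin, mu1_bin


def _usages(y_bin, y_rest, conditions, sf):
    """Bin-vs-gene usage fractions per condition, pseudocount 0.5 when degenerate."""
    out = {}
    for cond in ("mock", "ire1"):
        sel = conditions == cond
        nb = np.sum(y_bin[sel] / sf[sel])
        nr = np.sum(y_rest[sel] / sf[sel])
        if nb == 0 or nr == 0:
            log.debug("degenerate usage; applying pseudocount 0.5")
            nb = np.sum((y_bin[sel] + 0.5) / sf[sel])
            nr = np.sum((y_rest[sel] + 0.5) / sf[sel])
        out[cond] = nb / (nb + nr)
    return out["mock"], out["ire1"]


def _count_fold_change(y_bin: np.ndarray, conditions: np.ndarray, sf: np.ndarray) -> float:
    """Signed treated/mock ratio of normalised bin counts (|fc| >= 1).

    Unlike the usage odds ratio, this reads out absolute coverage of the bin:
    a bin 3' of a cleavage site keeps its coverage and has count_fc near +/-1
    even though its *usage* rises.  Exon-usage depletion profiles are built
    from this quantity.  Pseudocount 0.5 guards all-zero conditions.
    """
    means = {}
    for cond in ("mock", "ire1"):
        sel = conditions == cond
        means[cond] = np.mean(y_bin[sel] / sf[sel])
    if means["mock"] == 0 or means["ire1"] == 0:
        for cond in ("mock", "ire1"):
            sel = conditions == cond
            means[cond] = np.mean((y_bin[sel] + 0.5) / sf[sel])
    r = means["ire1"] / means["mock"]
    return r if r >= 1 else -1.0 / r


@dataclass
class BinTestResult:
    lr_stat: float
    p: float
    usage_mock: float
    usage_ire1: float
    testable: bool = True


def test_bin(
    y_bin: np.ndarray,
    y_rest: np.ndarray,
    conditions: np.ndarray,
    alpha: float,
    sf: np.ndarray,
) -> BinTestResult:
    """LR test for a condition x (bin vs rest-of-gene) interaction.

    Parameters
    ----------
    y_bin, y_rest : arrays of per-sample counts for the bin and for the sum
        of the gene's other bins.
    conditions : array of "mock"/"ire1" labels, >= 2 samples each.
    alpha : fixed NB dispersion (0 -> Poisson).
    sf : size factors (used for usage fractions only).
    """
    y_bin = np.asarray(y_bin, dtype=float)
    y_rest = np.asarray(y_rest, dtype=float)
    conditions = np.asarray(conditions)
    sf = np.asarray(sf, dtype=float)
    for cond in ("mock", "ire1"):
        if np.sum(conditions == cond) < 2:
            raise ValueError(f"need >= 2 {cond} samples")

    um, ui = _usages(y_bin, y_rest, conditions, sf)
    if y_bin.sum() == 0:
        return BinTestResult(0.0, 1.0, um, ui)

    n = len(y_bin)
    N_j, mu0_bin_pois, mu1_bin_pois = _poisson_fits(y_bin, y_rest, conditions)
    y = np.concatenate([y_bin, y_rest])

    if alpha == 0.0:
        # Poisson MLEs are closed form; LR reduces to the collapsed-table G test
        mu_rest0 = N_j - mu0_bin_pois
        mu_rest1 = N_j - mu1_bin_pois
        ll0 = _nb_loglik(y, np.concatenate([mu0_bin_pois, mu_rest0]).clip(1e-12), 0.0)
        ll1 = _nb_loglik(y, np.concatenate([mu1_bin_pois, mu_rest1]).clip(1e-12), 0.0)
    else:
        # design rows: samples x (bin part), then samples x (rest part)
        ident = np.eye(n)
        sample_cols = np.vstack([ident, ident])
        part_col = np.concatenate([np.ones(n), np.zeros(n)])[:, None]
        inter_col = np.concatenate([(conditions == "ire1").astype(float), np.zeros(n)])[
            :, None
        ]
        X0 = np.hstack([sample_cols, part_col])
        X1 = np.hstack([sample_cols, part_col, inter_col])
        # warm start from the Poisson solution
        mu_rest0 = (N_j - mu0_bin_pois).clip(1e-8)
        a0 = np.log(mu_rest0)
        b0 = np.log(mu0_bin_pois.clip(1e-8)).mean() - a0.mean()
        beta0 = np.concatenate([a0, [b0]])
        ll0, fit0 = _fit_nb_glm(y, X0, alpha, beta0)
        ll1, _ = _fit_nb_glm(y, X1, alpha, np.concatenate([fit0, [0.0]]))

    lr = max(0.0, 2.0 * (ll1 - ll0))
    p = float(stats.chi2.sf(lr, df=1))
    return BinTestResult(lr, p, um, ui)


def fold_change(usage_mock: float, usage_ire1: float) -> float:
    """Signed usage odds ratio with |fc| >= 1.

    r = [u_ire1/(1-u_ire1)] / [u_mock/(1-u_mock)]; fc = r if r >= 1 else -1/r.
    """
    if not (0 < usage_mock < 1 and 0 < usage_ire1 < 1):
        raise ValueError("usages must lie strictly in (0, 1)")
    r = (usage_ire1 / (1 - usage_ire1)) / (usage_mock / (1 - usage_mock))
    return r if r >= 1 else -1.0 / r


def run_deu(
    matrix: ExonCountMatrix,
    sf: pd.Series | None = None,
    dispersions: pd.Series | None = None,
) -> pd.DataFrame:
    """Test every unambiguous bin of every multi-bin gene; BH-adjust p-values.

    Ambiguous bins (shared between genes) stay in the output flagged
    ``ambiguous`` and untested; single-bin genes are flagged untestable.
    Returns a DataFrame with one row per bin: lr_stat, p, fdr, fc,
    usage_mock, usage_ire1, rank_5to3, testable, ambiguous.
    """
    if sf is None:
        sf = size_factors(matrix.counts)
    if dispersions is None:
        dispersions = estimate_dispersions(matrix, sf)
    conditions = np.array([matrix.conditions[s] for s in matrix.counts.columns])
    sf_arr = sf.loc[matrix.counts.columns].to_numpy()

    bin_by_id = {b.bin_id: b for b in matrix.bins}
    unamb = [b for b in matrix.bins if not b.ambiguous]
    by_gene: dict[str, list[ExonBin]] = {}
    for b in unamb:
        by_gene.setdefault(b.gene_ids[0], []).append(b)

    rows = []
    for gene, gbins in by_gene.items():
        strand = gbins[0].strand
        ordered = order_bins(gbins, strand)
        gcounts = matrix.counts.loc[[b.bin_id for b in ordered]].to_numpy(dtype=float)
        total = gcounts.sum(axis=0)
        testable_gene = len(ordered) >= 2
        for i, b in enumerate(ordered):
            row = {
                "bin_id": b.bin_id,
                "gene_id": gene,
                "rank_5to3": b.rank_5to3,
                "ambiguous": False,
            }
            if not testable_gene:
                row.update(
                    lr_stat=np.nan, p=np.nan, fc=np.nan,
                    usage_mock=np.nan, usage_ire1=np.nan, testable=False,
                )
            else:
                y_bin = gcounts[i]
                y_rest = total - y_bin
                res = test_bin(y_bin, y_rest, conditions, float(dispersions[b.bin_id]), sf_arr)
                fc = fold_change(res.usage_mock, res.usage_ire1)
                row.update(
                    lr_stat=res.lr_stat, p=res.p, fc=fc,
                    count_fc=_count_fold_change(y_bin, conditions, sf_arr),
                    usage_mock=res.usage_mock, usage_ire1=res.usage_ire1, testable=True,
                )
            rows.append(row)
    for b in matrix.bins:
        if b.ambiguous:
            rows.append(
                dict(
                    bin_id=b.bin_id, gene_id="+".join(b.gene_ids), rank_5to3=None,
                    ambiguous=True, lr_stat=np.nan, p=np.nan, fc=np.nan,
                    usage_mock=np.nan, usage_ire1=np.nan, testable=False,
                )
            )
    df = pd.DataFrame(rows)
    df["fdr"] = np.nan
    tested = df["p"].notna()
    if tested.any():
        df.loc[tested, "fdr"] = multipletests(df.loc[tested, "p"], method="fdr_bh")[1]
    return df


def select_candidates(
    results: pd.DataFrame,
    fdr_max: float = 0.05,
    fc_max: float = -2.0,
    override: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Rank candidate genes by their most-negative bin fold change.

    Keeps unambiguous, testable bins with fdr < fdr_max and fc < fc_max
    (strict inequalities); a gene enters once, ranked by its most-negative
    bin fc.  Genes on *override* are appended regardless of fold change and
    flagged — mirroring the manual inclusion of biologically interesting
    genes that miss the fold-change cut.
    """
    usable = results[results["testable"] & ~results["ambiguous"]].copy()
    hits = usable[(usable["fdr"] < fdr_max) & (usable["fc"] < fc_max)]
    per_gene = (
        hits.groupby("gene_id")["fc"].min().sort_values().rename("best_fc").reset_index()
    )
    per_gene["override"] = False
    extra = []
    selected = set(per_gene["gene_id"])
    for g in override:
        if g in selected:
            continue
        gene_rows = usable[usable["gene_id"] == g]
        best = gene_rows["fc"].min() if len(gene_rows) else np.nan
        extra.append({"gene_id": g, "best_fc": best, "override": True})
    if extra:
        per_gene = pd.concat([per_gene, pd.DataFrame(extra)], ignore_index=True)
    per_gene.index = pd.RangeIndex(1, len(per_gene) + 1, name="rank")
    return per_gene
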