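"""Statistical evaluation of coupling scores against measured metabolites.

Scores are the independent variable, measured metabolite ln fold changes
the dependent one.  Beyond the parametric Pearson test this module
provides the label-shuffling permutation test (gene labels are permuted
*before* score recomputation, so the null preserves the network topology
and the fold-change distribution), a robustness resampling against
mRNA-protein slope variability, Benjamini-Hochberg FDR selection, an
exact binomial test on the fraction of positive correlations, and the
paired Wilcoxon comparison of score variants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .coccoa_engine import DirectedBipartiteGraph, build_graph, score_degree_n
from .expression_mapping import filter_significant, reaction_deltas
from .model_io import CoccoaError, ExpressionTable, MetabolicNetwork

__all__ = [
    "CorrelationResult",
    "RobustnessResult",
    "correlate",
    "permutation_test",
    "robustness_resampling",
    "fdr_select",
    "sign_fraction_test",
    "compare_score_variants",
]


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation between scores and measured fold changes."""

    n: int
    r: float
    p: float
    permutation_p: float | None = None
    status: str = "ok"  # ok | insufficient data | undefined

    @property
    def r2(self) -> float:
        return self.r * self.r if self.r == self.r else float("nan")

    @property
    def slope_sign(self) -> int:
        if self.r != self.r or self.r == 0:
            return 0
        return 1 if self.r > 0 else -1

    @property
    def ok(self) -> bool:
        return self.status == "ok"


def correlate(scores: Sequence[float], metabolite_lnfc: Sequence[float]) -> CorrelationResult:
    """Pearson r with two-sided parametric P for slope = 0.

    Fewer than 3 pairs gives an "insufficient data" result; a
    zero-variance vector gives an "undefined" result (r is NaN) — neither
    raises.
    """
    x = np.asarray(scores, dtype=float)
    y = np.asarray(metabolite_lnfc, dtype=float)
    if x.shape != y.shape:
        raise CoccoaError("score and metabolite vectors differ in length")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise CoccoaError("non-finite values in correlation input")
    n = len(x)
    if n < 3:
        return CorrelationResult(n=n, r=float("nan"), p=float("nan"), status="insufficient data")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(n=n, r=float("nan"), p=float("nan"), status="undefined")
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(n=n, r=float(r), p=float(p))


def _pipeline_scores(
    network: MetabolicNetwork,
    expr: ExpressionTable,
    metabolites: Sequence[str],
    alpha: float,
    d_up: int,
    d_down: int,
    measured: Mapping[str, float] | None,
    currency,
) -> dict[str, float]:
    """Recompute scores from a (possibly permuted/rescaled) expression table."""
    filtered = filter_significant(expr, alpha) if alpha < 1 else expr
    deltas = reaction_deltas(network, filtered)
    kwargs = {} if currency is None else {"currency": currency}
    graph = build_graph(network, deltas, **kwargs)
    out: dict[str, float] = {}
    for met in metabolites:
        s = score_degree_n(met, graph, d_up, d_down, measured)
        if s is not None:
            out[met] = s.score
    return out


def _shuffle_gene_labels(expr: ExpressionTable, rng: np.random.Generator) -> ExpressionTable:
    df = expr.data.copy()
    perm = rng.permutation(len(df))
    for col in ("log2fc", "pvalue", "lnfc"):
        df[col] = df[col].to_numpy()[perm]
    return ExpressionTable(df, expr.reference)


def permutation_test(
    metabolites: Sequence[str],
    network: MetabolicNetwork,
    expr: ExpressionTable,
    metabolite_lnfc: Mapping[str, float],
    n_perm: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
    d_up: int = 1,
    d_down: int = 0,
    measured: Mapping[str, float] | None = None,
    currency=None,
    smoothed: bool = False,
) -> CorrelationResult:
    """Gene-label permutation test of the score-metabolite correlation.

    Gene labels are shuffled without replacement before each score
    recomputation; the permutation P-value is the fraction of permuted
    squared correlations exceeding the observed one (raw estimator, per
    the original protocol; ``smoothed`` switches to (k+1)/(n+1), which
    cannot return zero).  Permutations in which fewer than 3 metabolites
    retain a score count as non-exceeding.
    """
    if n_perm < 100:
        raise CoccoaError("n_perm must be at least 100")
    rng = np.random.default_rng(seed)
    observed_scores = _pipeline_scores(
        network, expr, metabolites, alpha, d_up, d_down, measured, currency
    )
    mets = sorted(m for m in observed_scores if m in metabolite_lnfc)
    obs = correlate([observed_scores[m] for m in mets], [metabolite_lnfc[m] for m in mets])
    if not obs.ok:
        return CorrelationResult(obs.n, obs.r, obs.p, permutation_p=1.0, status=obs.status)
    obs_r2 = obs.r2
    exceed = 0
    any_defined = False
    for _ in range(n_perm):
        shuffled = _shuffle_gene_labels(expr, rng)
        perm_scores = _pipeline_scores(
            network, shuffled, metabolites, alpha, d_up, d_down, measured, currency
        )
        pm = sorted(m for m in perm_scores if m in metabolite_lnfc)
        res = correlate([perm_scores[m] for m in pm], [metabolite_lnfc[m] for m in pm])
        if res.ok:
            any_defined = True
            if res.r2 > obs_r2:
                exceed += 1
    if not any_defined:
        perm_p = 1.0
    elif smoothed:
        perm_p = (exceed + 1) / (n_perm + 1)
    else:
        perm_p = exceed / n_perm
    return CorrelationResult(obs.n, obs.r, obs.p, permutation_p=perm_p)


@dataclass(frozen=True)
class RobustnessResult:
    """Outcome of the mRNA-protein slope resampling."""

    n_simulations: int
    fraction_significant: float
    slope_mean: float
    slope_sd: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_significant <= 1.0:
            raise CoccoaError("fraction must lie in [0, 1]")


def robustness_resampling(
    metabolites: Sequence[str],
    network: MetabolicNetwork,
    expr: ExpressionTable,
    metabolite_lnfc: Mapping[str, float],
    slope_mean: float = 1.0,
    slope_sd: float = 0.3,
    n_sim: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
    transcript_alpha: float = 0.05,
    d_up: int = 1,
    d_down: int = 0,
    currency=None,
) -> RobustnessResult:
    """Fraction of slope-perturbed re-analyses that stay significant.

    Each simulation rescales every gene's ln-ratio by its own correction
    factor drawn from N(slope_mean, slope_sd) — modelling gene-to-gene
    variability of the mRNA-to-protein fold-change slope — recomputes the
    degree-1 scores and the parametric correlation, and counts the
    simulations with P <= alpha.  With slope_sd = 0 every simulation
    reproduces the unperturbed analysis (scaled by slope_mean).
    """
    if slope_sd < 0:
        raise CoccoaError("slope_sd must be non-negative")
    if n_sim < 100:
        raise CoccoaError("n_sim must be at least 100")
    rng = np.random.default_rng(seed)
    n_sig = 0
    for _ in range(n_sim):
        df = expr.data.copy()
        factors = rng.normal(slope_mean, slope_sd, size=len(df))
        df["lnfc"] = df["lnfc"].to_numpy() * factors
        df["log2fc"] = df["lnfc"] / math.log(2)
        sim_expr = ExpressionTable(df, expr.reference)
        scores = _pipeline_scores(
            network, sim_expr, metabolites, transcript_alpha, d_up, d_down, None, currency
        )
        mets = sorted(m for m in scores if m in metabolite_lnfc)
        res = correlate([scores[m] for m in mets], [metabolite_lnfc[m] for m in mets])
        if res.ok and res.p <= alpha:
            n_sig += 1
    return RobustnessResult(
        n_simulations=n_sim,
        fraction_significant=n_sig / n_sim,
        slope_mean=slope_mean,
        slope_sd=slope_sd,
    )


def fdr_select(pvalues: Sequence[float], q: float = 0.10) -> list[int]:
    """Benjamini-Hochberg step-up selection at FDR level ``q``.

    Returns the indices of the selected hypotheses (empty when none
    pass).
    """
    if not 0 < q < 1:
        raise CoccoaError("q must lie in (0, 1)")
    p = np.asarray(pvalues, dtype=float)
    if len(p) == 0:
        return []
    reject, _, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return [int(i) for i in np.flatnonzero(reject)]


def sign_fraction_test(
    correlations: Sequence[CorrelationResult] | Sequence[float], null_p: float = 0.5
) -> tuple[float, float]:
    """(fraction positive, two-sided exact binomial P) over correlation signs.

    Accepts either :class:`CorrelationResult` objects or raw r values;
    every entry must have a defined sign.
    """
    signs = []
    for c in correlations:
        r = c.r if isinstance(c, CorrelationResult) else float(c)
        if r != r or r == 0:
            raise CoccoaError("correlation without a defined sign")
        signs.append(1 if r > 0 else -1)
    if not signs:
        raise CoccoaError("no correlations supplied")
    k = sum(1 for s in signs if s > 0)
    n = len(signs)
    res = sps.binomtest(k, n, null_p, alternative="two-sided")
    return k / n, float(res.pvalue)


def compare_score_variants(
    r_with: Sequence[float], r_without: Sequence[float]
) -> tuple[float, float]:
    """Paired Wilcoxon signed-rank test between two per-metabolite r sets.

    Used to ask whether including measured neighbor-metabolite ratios
    improves the per-metabolite correlations; pairs are the same
    metabolites under the two scoring modes.  Returns (median difference,
    two-sided P).
    """
    a = np.asarray(r_with, dtype=float)
    b = np.asarray(r_without, dtype=float)
    if a.shape != b.shape or len(a) < 3:
        raise CoccoaError("need >= 3 paired correlation coefficients")
    stat = sps.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided")
    return float(np.median(a - b)), float(stat.pvalue)
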