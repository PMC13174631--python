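"""Subpopulation-resolved interpretation of bulk depletion signals.

Bulk depletion in a mixed population is a composite of its
subpopulations' fitness effects. If subpopulation ``k`` starts at
fraction ``f_k`` and carries a per-doubling log2 fitness effect ``s_k``,
the bulk per-doubling depletion over ``T`` doublings is

    beta_bulk = (1/T) * log2( sum_k f_k * 2**(s_k * T) )

which always lies between min(s) and max(s) and converges to max(s) as
T grows: the least-depleting ("limiting") subpopulation dominates the
aggregate signal because it outgrows the others.

The leave-one-out framework asks, per gene, how well expression can be
inferred from depletion: each organoid is held out in turn, expression
is regressed on beta across the remaining organoids, and the held-out
organoid's observed values — bulk and per-subpopulation — are compared
against the prediction. The subpopulation with the smallest residual is
the "winning subpopulation"; a G-test of independence then asks whether
winners coincide with the lowest-expressing subpopulations more often
than chance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

__all__ = [
    "composite_beta",
    "limiting_subpop",
    "loo_fit",
    "loo_fit_all",
    "subpop_residuals",
    "r2_compare",
    "winner_frequency",
    "gtest_independence",
    "winner_lowexpr_association",
    "LOOResult",
    "WinnerSummary",
]

_LN2 = np.log(2.0)


def _validate_mixture(f, s) -> tuple[np.ndarray, np.ndarray]:
    f = np.asarray(f, dtype=float)
    s = np.asarray(s, dtype=float)
    if f.shape != s.shape or f.ndim != 1 or f.size == 0:
        raise ValueError("f and s must be equal-length nonempty vectors")
    if np.any(f <= 0):
        raise ValueError("all fractions must be > 0 (drop absent subpopulations)")
    if abs(f.sum() - 1.0) > 1e-9:
        raise ValueError(f"fractions sum to {f.sum()!r}, expected 1")
    return f, s


def composite_beta(f, s, T: float) -> float:
    """Bulk per-doubling depletion of a mixture of exponentially growing clones.

    ``beta = (1/T) * log2(sum_k f_k * 2**(s_k * T))``; computed in log
    space so extreme ``s*T`` products cannot overflow.
    """
    f, s = _validate_mixture(f, s)
    if T <= 0:
        raise ValueError("T must be > 0")
    return float(logsumexp(np.log(f) + s * T * _LN2) / (T * _LN2))


def limiting_subpop(f, s) -> tuple[float, list[int]]:
    """Asymptotic bulk beta and the index (or tied indices) of the limiting clone.

    As T grows, composite depletion converges to max(s): the resistant
    subpopulation limits how much aggregate depletion can be observed.
    """
    f, s = _validate_mixture(f, s)
    top = float(s.max())
    return top, [int(i) for i in np.flatnonzero(s == top)]


# ---------------------------------------------------------------------------
# leave-one-out expression-from-depletion framework
# ---------------------------------------------------------------------------


def loo_fit(
    beta_table: pd.DataFrame,
    bulk_expression: pd.DataFrame,
    gene: str,
    min_train: int = 4,
) -> pd.DataFrame:
    """Leave-one-organoid-out linear prediction of expression from beta.

    For each held-out organoid, expression is regressed on beta (ordinary
    least squares) over the remaining organoids and the held-out
    organoid's expression is predicted from its own beta. Returns a table
    (gene, organoid, beta, x_bulk, x_hat, res_bulk, n_train); its
    ``attrs["degenerate"]`` flag is set when beta is constant across every
    training fold, in which case the table is empty.
    """
    sub = beta_table[beta_table["gene"] == gene]
    orgs = [o for o in sub["organoid"] if o in bulk_expression.columns]
    if len(orgs) < min_train + 1:
        raise ValueError(
            f"gene {gene!r} screened in {len(orgs)} organoids; need >= {min_train + 1}"
        )
    b = sub.set_index("organoid").loc[orgs, "beta"].to_numpy(dtype=float)
    x = bulk_expression.loc[gene, orgs].to_numpy(dtype=float)
    rows = []
    degenerate = False
    for i, org in enumerate(orgs):
        mask = np.arange(len(orgs)) != i
        if np.ptp(b[mask]) == 0:
            degenerate = True
            continue
        slope, intercept = np.polyfit(b[mask], x[mask], 1)
        x_hat = intercept + slope * b[i]
        rows.append((gene, org, b[i], x[i], x_hat, abs(x[i] - x_hat), int(mask.sum())))
    out = pd.DataFrame(
        rows, columns=["gene", "organoid", "beta", "x_bulk", "x_hat", "res_bulk", "n_train"]
    )
    out.attrs["degenerate"] = degenerate and out.empty
    return out


def loo_fit_all(
    beta_table: pd.DataFrame,
    bulk_expression: pd.DataFrame,
    min_train: int = 4,
) -> pd.DataFrame:
    """Run :func:`loo_fit` for every eligible gene; degenerate genes are skipped."""
    frames = []
    for gene in beta_table["gene"].unique():
        if gene not in bulk_expression.index:
            continue
        try:
            res = loo_fit(beta_table, bulk_expression, gene, min_train=min_train)
        except ValueError:
            continue
        if res.attrs.get("degenerate"):
            warnings.warn(f"gene {gene!r}: beta constant across training organoids; skipped")
            continue
        frames.append(res)
    if not frames:
        raise ValueError("no gene produced a non-degenerate leave-one-out fit")
    return pd.concat(frames, ignore_index=True)


@dataclass
class LOOResult:
    """Leave-one-out outcome: per-(gene, organoid) summary plus residual detail."""

    summary: pd.DataFrame  # gene, organoid, beta, x_hat, x_bulk, res_bulk,
    #                        winner, res_winner, improvement, n_train, n_subpops
    residuals: pd.DataFrame  # gene, organoid, subpopulation, x_sub, residual, cell_fraction


def subpop_residuals(
    loo_predictions: pd.DataFrame,
    subpop_expression: pd.DataFrame,
) -> LOOResult:
    """Score each subpopulation's observed expression against the LOO prediction.

    ``subpop_expression`` is long-form (gene, organoid, subpopulation,
    mean_expr, cell_fraction). The winner is the subpopulation with the
    smallest absolute residual |x_sub - x_hat|; ties go to the larger
    cell fraction, then the lexicographically smaller label. The
    proportional improvement is (res_bulk - res_winner) / res_bulk when
    res_bulk > 0 (NaN otherwise); it is negative when bulk beats every
    subpopulation.
    """
    sub = subpop_expression.set_index(["gene", "organoid"]).sort_index()
    sum_rows, res_rows = [], []
    for row in loo_predictions.itertuples(index=False):
        try:
            grp = sub.loc[(row.gene, row.organoid)]
        except KeyError:
            continue
        if isinstance(grp, pd.Series):
            grp = grp.to_frame().T
        resid = (grp["mean_expr"].astype(float) - row.x_hat).abs()
        order = pd.DataFrame(
            {
                "subpopulation": grp["subpopulation"].astype(str),
                "residual": resid.to_numpy(),
                "cell_fraction": grp["cell_fraction"].astype(float).to_numpy(),
            }
        ).sort_values(
            ["residual", "cell_fraction", "subpopulation"],
            ascending=[True, False, True],
        )
        winner = order.iloc[0]
        improvement = (
            (row.res_bulk - winner["residual"]) / row.res_bulk
            if row.res_bulk > 0
            else np.nan
        )
        sum_rows.append(
            (
                row.gene,
                row.organoid,
                row.beta,
                row.x_hat,
                row.x_bulk,
                row.res_bulk,
                winner["subpopulation"],
                winner["residual"],
                improvement,
                row.n_train,
                len(order),
            )
        )
        means = grp.set_index(grp["subpopulation"].astype(str))["mean_expr"].astype(float)
        for r in order.itertuples(index=False):
            res_rows.append(
                (
                    row.gene,
                    row.organoid,
                    r.subpopulation,
                    float(means.loc[r.subpopulation]),
                    r.residual,
                    r.cell_fraction,
                )
            )
    summary = pd.DataFrame(
        sum_rows,
        columns=[
            "gene",
            "organoid",
            "beta",
            "x_hat",
            "x_bulk",
            "res_bulk",
            "winner",
            "res_winner",
            "improvement",
            "n_train",
            "n_subpops",
        ],
    )
    residuals = pd.DataFrame(
        res_rows,
        columns=["gene", "organoid", "subpopulation", "x_sub", "residual", "cell_fraction"],
    )
    return LOOResult(summary=summary, residuals=residuals)


def r2_compare(loo_result: LOOResult, min_holdouts: int = 3) -> pd.DataFrame:
    """Per-gene proportion of variance explained, bulk vs subpopulation-resolved.

    R2_bulk uses bulk observations and bulk residuals; R2_sub substitutes
    the winning subpopulation's observed values (and residuals). Either
    may be negative; zero observation variance sets an undefined flag.
    """
    rows = []
    res = loo_result.residuals.set_index(["gene", "organoid", "subpopulation"])
    for gene, sub in loo_result.summary.groupby("gene", sort=False):
        if len(sub) < min_holdouts:
            continue
        x_win = np.array(
            [
                res.loc[(gene, r.organoid, r.winner), "x_sub"]
                for r in sub.itertuples(index=False)
            ],
            dtype=float,
        )

        def _r2(obs: np.ndarray, resid: np.ndarray) -> float:
            ss_tot = float(np.sum((obs - obs.mean()) ** 2))
            return 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else np.nan

        r2_bulk = _r2(sub["x_bulk"].to_numpy(float), sub["res_bulk"].to_numpy(float))
        r2_sub = _r2(x_win, sub["res_winner"].to_numpy(float))
        rows.append((gene, len(sub), r2_bulk, r2_sub, not np.isfinite(r2_bulk) or not np.isfinite(r2_sub)))
    return pd.DataFrame(
        rows, columns=["gene", "n_holdouts", "r2_bulk", "r2_sub", "undefined"]
    )


def winner_frequency(loo_result: LOOResult, organoid: str) -> pd.Series:
    """Fraction of genes each subpopulation wins within one organoid."""
    sub = loo_result.summary[loo_result.summary["organoid"] == organoid]
    if sub.empty:
        raise ValueError(f"no winners recorded for organoid {organoid!r}")
    return sub["winner"].value_counts(normalize=True).rename("frequency")


# ---------------------------------------------------------------------------
# G-test and winner/low-expressor association
# ---------------------------------------------------------------------------


def gtest_independence(contingency) -> tuple[float, int, float]:
    """Likelihood-ratio (G) test of independence on a contingency table.

    ``G = 2 * sum O * ln(O/E)`` over cells with O > 0, expected counts
    from the margins, df = (rows-1)(cols-1), p from the chi-square upper
    tail. Zero-margin rows/columns are dropped with a warning first.
    """
    obs = np.asarray(contingency, dtype=float)
    if obs.ndim != 2:
        raise ValueError("contingency must be 2-dimensional")
    if np.any(obs < 0) or np.any(obs != np.round(obs)):
        raise ValueError("contingency must hold nonnegative integers")
    keep_r = obs.sum(axis=1) > 0
    keep_c = obs.sum(axis=0) > 0
    if not keep_r.all() or not keep_c.all():
        warnings.warn("dropping zero-margin rows/columns before the G-test")
        obs = obs[keep_r][:, keep_c]
    if obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("need at least a 2x2 table with positive margins")
    total = obs.sum()
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / total
    mask = obs > 0
    g = 2.0 * float(np.sum(obs[mask] * np.log(obs[mask] / expected[mask])))
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return g, df, float(stats.chi2.sf(g, df))


@dataclass
class WinnerSummary:
    """Association between winning and lowest-expressing subpopulations."""

    per_organoid: pd.DataFrame  # organoid, n_genes, n_subpops, match_rate,
    #                             binom_p, G, df, g_p
    contingency: dict[str, pd.DataFrame]
    frequencies: dict[str, pd.Series]
    pooled_match_rate: float
    pooled_binom_p: float


def winner_lowexpr_association(
    loo_result: LOOResult,
    subpop_expression: pd.DataFrame,
) -> WinnerSummary:
    """Test whether winners coincide with lowest-expressing subpopulations.

    Per organoid: the lowest-expressing subpopulation per gene is the
    argmin of mean expression (ties to the smaller cell fraction, then
    label); a winner x lowest-expressor contingency table over genes
    feeds :func:`gtest_independence`, and the match rate is tested
    against a 1/K null with an exact one-sided binomial test. Organoids
    with a single subpopulation are excluded with a warning. A pooled
    match rate across organoids with equal K is reported alongside.
    """
    lowest = (
        subpop_expression.sort_values(
            ["gene", "organoid", "mean_expr", "cell_fraction", "subpopulation"],
            ascending=[True, True, True, True, True],
        )
        .groupby(["gene", "organoid"], sort=False)
        .first()["subpopulation"]
    )
    rows, tables, freqs = [], {}, {}
    match_tot = n_tot = 0
    ks = set()
    for org, sub in loo_result.summary.groupby("organoid", sort=False):
        k = int(sub["n_subpops"].iloc[0])
        if k < 2:
            warnings.warn(f"organoid {org!r} has a single subpopulation; excluded")
            continue
        low = np.array([lowest.loc[(g, org)] for g in sub["gene"]], dtype=object)
        win = sub["winner"].to_numpy(dtype=object)
        table = pd.crosstab(
            pd.Series(win, name="winner"), pd.Series(low, name="lowest_expressor")
        )
        tables[org] = table
        freqs[org] = sub["winner"].value_counts(normalize=True).rename("frequency")
        try:
            g, df, g_p = gtest_independence(table.to_numpy())
        except ValueError:
            g, df, g_p = np.nan, 0, np.nan
        matches = int((win == low).sum())
        binom_p = stats.binomtest(matches, len(sub), 1.0 / k, alternative="greater").pvalue
        rows.append((org, len(sub), k, matches / len(sub), binom_p, g, df, g_p))
        match_tot += matches
        n_tot += len(sub)
        ks.add(k)
    if not rows:
        raise ValueError("no organoid with >= 2 subpopulations")
    if len(ks) == 1 and n_tot > 0:
        pooled_p = stats.binomtest(
            match_tot, n_tot, 1.0 / ks.pop(), alternative="greater"
        ).pvalue
    else:
        pooled_p = np.nan
    return WinnerSummary(
        per_organoid=pd.DataFrame(
            rows,
            columns=[
                "organoid",
                "n_genes",
                "n_subpops",
                "match_rate",
                "binom_p",
                "G",
                "df",
                "g_p",
            ],
        ),
        contingency=tables,
        frequencies=freqs,
        pooled_match_rate=match_tot / n_tot if n_tot else np.nan,
        pooled_binom_p=float(pooled_p),
    )
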