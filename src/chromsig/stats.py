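"""Permutation statistics, chi-square proportion tests and expression models.

The central test asks whether a target gene set (e.g. PAR genes) has a
different chromatin-signature composition than a reference pool (e.g.
autosomal genes): the observed Pearson chi-square statistic of the target's
signature counts against the pool's proportions is compared with the same
statistic for many random subsamples of the pool of the target's size.
Matching modes remove covariate confounding: TE_PREVALENCE forces every
subsample to contain exactly the target's number of TE-overlapping genes;
EXPRESSION_WINDOW restricts the pool to genes whose expression lies within
25% of the target's median before subsampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from chromsig.signatures import GeneSignatureTable

DEFAULT_N_PERM = 100_000
EXPRESSION_WINDOW_FRACTION = 0.25


def fraction_percent(count: int, total: int, ndigits: int = 3) -> float:
    """Percentage of a count over a total, rounded to a printed precision."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * count / total, ndigits)


# ---------------------------------------------------------------------------
# Chi-square statistic
# ---------------------------------------------------------------------------

def chi_square_stat(observed_counts, expected_proportions) -> float:
    """Pearson chi-square of observed category counts against expected
    proportions: sum (O_c - E_c)^2 / E_c with E_c = N p_c.

    Categories with expected 0 and observed 0 are dropped; expected 0 with
    observed > 0 makes the statistic infinite.
    """
    obs = np.asarray(observed_counts, dtype=float)
    p = np.asarray(expected_proportions, dtype=float)
    if obs.shape != p.shape:
        raise ValueError("category sets differ")
    if (obs < 0).any():
        raise ValueError("negative counts")
    if not np.isclose(p.sum(), 1.0, atol=1e-9):
        raise ValueError("expected proportions must sum to 1")
    n = obs.sum()
    exp = n * p
    keep = ~((exp == 0) & (obs == 0))
    obs, exp = obs[keep], exp[keep]
    if ((exp == 0) & (obs > 0)).any():
        return float("inf")
    return float(((obs - exp) ** 2 / exp).sum())


# ---------------------------------------------------------------------------
# Matched subsampling permutation test
# ---------------------------------------------------------------------------

@dataclass
class PermutationResult:
    observed_statistic: float
    n_exceeding: int              # null draws >= observed
    n_perm: int
    p_value: float
    matching: str
    seed: int
    null_draws: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "observed_statistic": self.observed_statistic,
            "n_exceeding": self.n_exceeding,
            "n_perm": self.n_perm,
            "p_value": self.p_value,
            "matching": self.matching,
            "seed": self.seed,
        }])


def _signature_codes(sig_table: GeneSignatureTable) -> pd.Series:
    return sig_table.table.set_index("gene_id")["signature"]


def _category_counts(labels: pd.Series, categories: list[str]) -> np.ndarray:
    vc = labels.value_counts()
    return vc.reindex(categories, fill_value=0).to_numpy(dtype=np.int64)


def _null_statistics_mvh(
    strata_counts: list[np.ndarray],
    strata_sizes: list[int],
    pool_counts: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
    reference: str = "leave_out",
) -> np.ndarray:
    """Null chi-square draws: per stratum, a multivariate-hypergeometric draw
    of signature counts (identical in law to drawing that many genes without
    replacement from the stratum); strata sum to one subsample.

    With ``reference='leave_out'`` each draw is scored against the signature
    proportions of the pool genes NOT in the draw — mirroring the observed
    statistic, where the target is disjoint from the pool whose proportions
    it is compared to.  ``'full_pool'`` scores draws against the full pool's
    proportions, which understates the null variance (the draw is part of
    the pool) and makes the test anticonservative.
    """
    n_cat = len(pool_counts)
    draws = np.zeros((n_perm, n_cat), dtype=np.int64)
    for counts, size in zip(strata_counts, strata_sizes):
        if size == 0:
            continue
        draws += rng.multivariate_hypergeometric(counts, size, size=n_perm)
    n = draws.sum(axis=1, keepdims=True).astype(float)
    if reference == "leave_out":
        remaining = pool_counts[None, :] - draws
        props = remaining / remaining.sum(axis=1, keepdims=True)
    elif reference == "full_pool":
        props = np.broadcast_to((pool_counts / pool_counts.sum())[None, :],
                                draws.shape)
    else:
        raise ValueError(f"unknown null reference {reference!r}")
    exp = n * props
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(exp > 0, (draws - exp) ** 2 / np.where(exp > 0, exp, 1.0), 0.0)
        bad = (exp == 0) & (draws > 0)
    stats = terms.sum(axis=1)
    stats[bad.any(axis=1)] = np.inf
    return stats


def matched_permutation_test(
    target_genes,
    pool_genes,
    signatures: GeneSignatureTable,
    n_perm: int = DEFAULT_N_PERM,
    matching: str = "NONE",
    covariates: pd.DataFrame | None = None,
    seed: int = 0,
    keep_null: bool = False,
    null_reference: str = "leave_out",
) -> PermutationResult:
    """Covariate-matched subsampling test of signature composition.

    ``covariates`` is indexed by gene_id; TE_PREVALENCE matching needs a
    boolean ``te_overlap`` column, EXPRESSION_WINDOW a numeric ``expression``
    column.  The observed statistic is the chi-square of the target's
    signature counts against the full pool's proportions; each of ``n_perm``
    null draws subsamples |target| genes from the (matched) pool and computes
    the same statistic.  Empirical p = (#draws >= observed + 1) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    target = list(target_genes)
    pool = list(pool_genes)
    if set(target) & set(pool):
        raise ValueError("target and pool gene sets must be disjoint")
    sigs = _signature_codes(signatures)
    missing = (set(target) | set(pool)) - set(sigs.index)
    if missing:
        raise ValueError(f"genes missing from signature table: {sorted(missing)[:5]}")
    categories = sorted(set(sigs.loc[target]) | set(sigs.loc[pool]),
                        key=lambda s: int(s[1:]))
    pool_counts = _category_counts(sigs.loc[pool], categories)
    pool_props = pool_counts / pool_counts.sum()
    observed = chi_square_stat(_category_counts(sigs.loc[target], categories), pool_props)

    matching = matching.upper()
    if matching == "NONE":
        strata = [(pool, len(target))]
    elif matching == "TE_PREVALENCE":
        te = covariates["te_overlap"].astype(bool)
        t_te = int(te.reindex(target).sum())
        pool_te = [g for g in pool if te.get(g, False)]
        pool_nonte = [g for g in pool if not te.get(g, False)]
        need_non = len(target) - t_te
        if len(pool_te) < t_te or len(pool_nonte) < need_non:
            raise ValueError(
                f"TE matching infeasible: need {t_te} TE / {need_non} non-TE pool "
                f"genes, have {len(pool_te)} / {len(pool_nonte)}")
        strata = [(pool_te, t_te), (pool_nonte, need_non)]
    elif matching == "EXPRESSION_WINDOW":
        expr = covariates["expression"]
        med = float(expr.reindex(target).median())
        lo, hi = (1 - EXPRESSION_WINDOW_FRACTION) * med, (1 + EXPRESSION_WINDOW_FRACTION) * med
        window_pool = [g for g in pool if lo <= expr.get(g, np.nan) <= hi]
        if len(window_pool) < len(target):
            raise ValueError(
                f"expression matching infeasible: window [{lo:.3g}, {hi:.3g}] holds "
                f"{len(window_pool)} pool genes, target has {len(target)}")
        strata = [(window_pool, len(target))]
    else:
        raise ValueError(f"unknown matching mode {matching!r}")

    rng = np.random.default_rng(seed)
    strata_counts = [_category_counts(sigs.loc[genes], categories) for genes, _ in strata]
    strata_sizes = [size for _, size in strata]
    null = _null_statistics_mvh(strata_counts, strata_sizes, pool_counts,
                                n_perm, rng, reference=null_reference)
    b = int((null >= observed).sum())
    return PermutationResult(
        observed_statistic=observed,
        n_exceeding=b,
        n_perm=n_perm,
        p_value=(b + 1) / (n_perm + 1),
        matching=matching,
        seed=seed,
        null_draws=null if keep_null else None,
    )


def draw_matched_subsample(
    target_genes, pool_genes, covariates: pd.DataFrame | None,
    matching: str, rng: np.random.Generator,
) -> list[str]:
    """One gene-level matched draw (audit path; the test itself draws
    category counts, which is equivalent in distribution)."""
    target = list(target_genes)
    pool = list(pool_genes)
    matching = matching.upper()
    if matching == "TE_PREVALENCE":
        te = covariates["te_overlap"].astype(bool)
        t_te = int(te.reindex(target).sum())
        pool_te = [g for g in pool if te.get(g, False)]
        pool_nonte = [g for g in pool if not te.get(g, False)]
        pick = list(rng.choice(pool_te, size=t_te, replace=False))
        pick += list(rng.choice(pool_nonte, size=len(target) - t_te, replace=False))
        return pick
    if matching == "EXPRESSION_WINDOW":
        expr = covariates["expression"]
        med = float(expr.reindex(target).median())
        lo, hi = (1 - EXPRESSION_WINDOW_FRACTION) * med, (1 + EXPRESSION_WINDOW_FRACTION) * med
        pool = [g for g in pool if lo <= expr.get(g, np.nan) <= hi]
    return list(rng.choice(pool, size=len(target), replace=False))


# ---------------------------------------------------------------------------
# Signature x location expression model
# ---------------------------------------------------------------------------

@dataclass
class ModelFit:
    coefficients: pd.DataFrame  # term, estimate, std_error, p_value, estimable
    n_obs: int
    r_squared: float


def signature_expression_model(
    log_expression: pd.Series,
    signatures: pd.Series,
    location: pd.Series,
    reference_signature: str = "S1",
) -> ModelFit:
    """OLS of log2(TPM+1) on signature, location and their interaction.

    Signature indicators use ``reference_signature`` as the baseline
    (absorbed in the intercept); location is a binary autosome/PAR indicator.
    Interaction terms that cannot be estimated because a signature occurs
    only on one location are reported with ``estimable = False`` rather than
    silently dropped.
    """
    df = pd.DataFrame({
        "y": log_expression, "signature": signatures, "location": location,
    }).dropna()
    levels = [s for s in df["signature"].unique()]
    if len(levels) < 2:
        raise ValueError("need at least 2 signature levels")
    small = df["signature"].value_counts()
    drop = list(small.index[small < 2])
    if drop:
        import warnings
        warnings.warn(f"dropping signature levels with < 2 genes: {drop}")
        df = df[~df["signature"].isin(drop)]
    if reference_signature not in set(df["signature"]):
        raise ValueError(f"reference level {reference_signature!r} absent from data")

    sig_levels = sorted(set(df["signature"]) - {reference_signature},
                        key=lambda s: int(s[1:]))
    loc_levels = sorted(set(df["location"]))
    ref_loc = loc_levels[0]
    cols: dict[str, np.ndarray] = {"Intercept": np.ones(len(df))}
    for s in sig_levels:
        cols[f"signature[{s}]"] = (df["signature"] == s).to_numpy(float)
    for l in loc_levels[1:]:
        cols[f"location[{l}]"] = (df["location"] == l).to_numpy(float)
    for s in sig_levels:
        for l in loc_levels[1:]:
            cols[f"signature[{s}]:location[{l}]"] = (
                ((df["signature"] == s) & (df["location"] == l)).to_numpy(float))

    X = np.column_stack(list(cols.values()))
    names = list(cols)
    # detect aliased columns by incremental rank
    keep: list[int] = []
    rank = 0
    for j in range(X.shape[1]):
        r = np.linalg.matrix_rank(X[:, keep + [j]])
        if r > rank:
            keep.append(j)
            rank = r
    fit = sm.OLS(df["y"].to_numpy(), X[:, keep]).fit()
    rows = []
    kept_names = [names[j] for j in keep]
    for name in names:
        if name in kept_names:
            i = kept_names.index(name)
            rows.append((name, fit.params[i], fit.bse[i], fit.pvalues[i], True))
        else:
            rows.append((name, np.nan, np.nan, np.nan, False))
    coef = pd.DataFrame(rows, columns=["term", "estimate", "std_error",
                                       "p_value", "estimable"])
    return ModelFit(coefficients=coef, n_obs=len(df), r_squared=float(fit.rsquared))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]
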