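"""Permutation-calibrated evaluation of subtype assignments.

A subtype solution is scored two ways: differential survival between
subtypes (K-group log-rank test) and enrichment of clinical covariates
within subtypes (Kruskal-Wallis for numeric labels, Pearson chi-square for
categorical ones). Because asymptotic p-values are unreliable when some
clusters are small, chi-square-type statistics are calibrated by permuting
the cluster labels:

* log-rank: an initial batch of min(max(10 / p_asymptotic, 1e4), 1e6)
  permutations, then batches of 1e5 until both ends of the 95% CI for the
  p-value are within 10% of the estimate and the interval does not cross
  0.05;
* clinical enrichment: batches of 1e3 until the 95% CI does not cross
  0.05, up to 1e5 permutations.

The empirical p-value uses the (1 + b) / (1 + n) estimator, so it can
never be exactly zero. A Friedman rank test compares methods across
datasets, and Kaplan-Meier curves summarize per-subtype survival.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "PermutationResult",
    "EnrichmentReport",
    "logrank_statistic",
    "permutation_pvalue_logrank",
    "initial_logrank_batch",
    "kruskal_wallis",
    "chi_square_enrichment",
    "permutation_pvalue_enrichment",
    "enrichment_count",
    "friedman_compare",
    "km_estimate",
]


@dataclass
class PermutationResult:
    """Empirical p-value with its binomial 95% CI and stopping reason."""

    p_hat: float
    ci_low: float
    ci_high: float
    n_perm: int
    stopped_by: str  # ci_within_10pct | ci_clear_of_05 | max_iterations
    statistic: float

    def as_dict(self) -> dict:
        return {
            "p_hat": self.p_hat,
            "ci": [self.ci_low, self.ci_high],
            "n_perm": self.n_perm,
            "stopped_by": self.stopped_by,
            "statistic": self.statistic,
        }


@dataclass
class EnrichmentReport:
    """Per-clinical-label test results and the count of significant labels."""

    entries: dict[str, dict] = field(default_factory=dict)
    n_significant: int = 0
    alpha: float = 0.05


# ---------------------------------------------------------------------------
# log-rank


def _codes(labels) -> tuple[np.ndarray, int]:
    codes, uniques = pd.factorize(np.asarray(labels))
    if (codes < 0).any():
        raise ValueError("labels contain missing values")
    return codes, len(uniques)


def _check_survival(time, event) -> tuple[np.ndarray, np.ndarray]:
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if np.any(time < 0):
        raise ValueError("survival times must be nonnegative")
    if event.sum() == 0:
        raise ValueError("log-rank statistic undefined: every observation is censored")
    return time, event


def logrank_statistic(time, event, labels) -> tuple[float, int, float]:
    """K-group log-rank chi-square, its df = K - 1, and the asymptotic p.

    Observed-minus-expected event counts are accumulated over the distinct
    event times with the hypergeometric variance of the conditional
    permutation distribution at each risk set.
    """
    time, event = _check_survival(time, event)
    codes, k = _codes(labels)
    if k < 2:
        raise ValueError("need at least two groups")

    event_times = np.unique(time[event == 1])
    o_minus_e = np.zeros(k)
    var = np.zeros((k, k))
    for t in event_times:
        at_risk = time >= t
        n_t = at_risk.sum()
        d_t = int(((time == t) & (event == 1)).sum())
        n_gt = np.bincount(codes[at_risk], minlength=k).astype(float)
        d_gt = np.bincount(codes[(time == t) & (event == 1)], minlength=k).astype(float)
        p_g = n_gt / n_t
        o_minus_e += d_gt - d_t * p_g
        if n_t > 1:
            c = d_t * (n_t - d_t) / (n_t - 1)
            var += c * (np.diag(p_g) - np.outer(p_g, p_g))

    u = o_minus_e[:-1]
    v = var[:-1, :-1]
    chi2 = float(u @ np.linalg.pinv(v) @ u)
    df = k - 1
    return chi2, df, float(stats.chi2.sf(chi2, df))


def _batch_logrank_chi2(prep: dict, labels_batch: np.ndarray) -> np.ndarray:
    """Log-rank chi-square for a B x N batch of label vectors (codes 0..K-1).

    Everything that does not depend on the labels (risk-set sizes, event
    counts per distinct event time) is precomputed in ``prep``.
    """
    k = prep["k"]
    order = prep["order"]
    first = prep["first"]  # first sorted index of each distinct event time
    last = prep["last"]  # last sorted index of each distinct event time
    d_t = prep["d_t"]  # total events at each distinct event time
    n_t = prep["n_t"]  # total at risk at each distinct event time
    e_sorted = prep["e_sorted"]
    c_t = prep["c_t"]  # d_t (n_t - d_t) / (n_t - 1)

    ls = labels_batch[:, order]
    b, n = ls.shape
    t = len(first)

    p = np.empty((b, t, k))
    o = np.empty((b, k))
    for g in range(k):
        m = ls == g
        suffix = np.cumsum(m[:, ::-1], axis=1)[:, ::-1]  # at-risk count of group g
        p[:, :, g] = suffix[:, first] / n_t
        me_cum = np.cumsum(m * e_sorted, axis=1)
        d_g = me_cum[:, last]
        d_g[:, 1:] -= me_cum[:, last[:-1]]
        o[:, g] = d_g.sum(axis=1)

    e = np.einsum("t,btg->bg", d_t, p)
    vd = np.einsum("t,btg->bg", c_t, p)
    v = -np.einsum("t,btg,bth->bgh", c_t, p, p)
    v[:, np.arange(k), np.arange(k)] += vd

    u = (o - e)[:, :-1]
    vsub = v[:, :-1, :-1]
    sol = (np.linalg.pinv(vsub) @ u[:, :, None])[:, :, 0]
    return np.einsum("bi,bi->b", u, sol)


def _prep_logrank(time: np.ndarray, event: np.ndarray, k: int) -> dict:
    order = np.argsort(time, kind="stable")
    t_sorted = time[order]
    e_sorted = event[order].astype(float)
    ut = np.unique(t_sorted[e_sorted == 1])
    first = np.searchsorted(t_sorted, ut, side="left")
    last = np.searchsorted(t_sorted, ut, side="right") - 1
    n = len(time)
    n_t = (n - first).astype(float)
    # total events at each distinct event time
    e_cum = np.cumsum(e_sorted)
    d_t = e_cum[last].copy()
    d_t[1:] -= e_cum[last[:-1]]
    with np.errstate(divide="ignore", invalid="ignore"):
        c_t = np.where(n_t > 1, d_t * (n_t - d_t) / np.maximum(n_t - 1, 1), 0.0)
    return {
        "k": k,
        "order": order,
        "first": first,
        "last": last,
        "d_t": d_t,
        "n_t": n_t,
        "e_sorted": e_sorted,
        "c_t": c_t,
    }


def _binomial_ci(p_hat: float, n: int, z: float = 1.959963984540054) -> tuple[float, float]:
    """95% CI for the permutation p-value.

    Wald interval by default; Wilson when the tail count is small
    (p_hat * n < 5), where Wald is unreliable.
    """
    if p_hat * n < 5:
        denom = 1 + z * z / n
        center = (p_hat + z * z / (2 * n)) / denom
        half = z / denom * np.sqrt(p_hat * (1 - p_hat) / n + z * z / (4 * n * n))
    else:
        center = p_hat
        half = z * np.sqrt(p_hat * (1 - p_hat) / n)
    return max(0.0, center - half), min(1.0, center + half)


def initial_logrank_batch(p_asymptotic: float) -> int:
    """Size of the first permutation batch: min(max(10/p, 1e4), 1e6)."""
    with np.errstate(divide="ignore"):
        target = np.inf if p_asymptotic == 0 else 10.0 / p_asymptotic
    return int(np.ceil(min(max(target, 1e4), 1e6) - 1e-9))


def _ci_stop_logrank(p_hat: float, lo: float, hi: float) -> bool:
    within = abs(lo - p_hat) <= 0.1 * p_hat and abs(hi - p_hat) <= 0.1 * p_hat
    clear = lo > 0.05 or hi < 0.05
    return within and clear


def permutation_pvalue_logrank(
    time,
    event,
    labels,
    seed: int | None = 0,
    max_perm: int = 1_000_000,
    chunk: int = 2_000,
) -> PermutationResult:
    """Permutation-calibrated log-rank p-value with adaptive stopping.

    The initial batch size follows min(max(10 / p_asymptotic, 1e4), 1e6);
    further batches of 1e5 are added until both ends of the 95% CI are
    within 10% of the estimate and the interval is clear of 0.05, or
    ``max_perm`` permutations have been spent.
    """
    time, event = _check_survival(time, event)
    codes, k = _codes(labels)
    if k < 2:
        raise ValueError("need at least two groups")
    chi2_obs, _, p_asym = logrank_statistic(time, event, codes)
    prep = _prep_logrank(time, event, k)
    rng = np.random.default_rng(seed)

    def run(n_todo: int) -> int:
        exceed = 0
        done = 0
        while done < n_todo:
            b = min(chunk, n_todo - done)
            batch = rng.permuted(np.broadcast_to(codes, (b, len(codes))).copy(), axis=1)
            stat = _batch_logrank_chi2(prep, batch)
            exceed += int((stat >= chi2_obs - 1e-12).sum())
            done += b
        return exceed

    n_perm = min(initial_logrank_batch(p_asym), max_perm)
    b_exceed = run(n_perm)
    p_hat = (1 + b_exceed) / (1 + n_perm)
    lo, hi = _binomial_ci(p_hat, n_perm)
    stopped = "ci_within_10pct" if _ci_stop_logrank(p_hat, lo, hi) else ""

    while not stopped:
        if n_perm >= max_perm:
            stopped = "max_iterations"
            break
        extra = min(100_000, max_perm - n_perm)
        b_exceed += run(extra)
        n_perm += extra
        p_hat = (1 + b_exceed) / (1 + n_perm)
        lo, hi = _binomial_ci(p_hat, n_perm)
        if _ci_stop_logrank(p_hat, lo, hi):
            stopped = "ci_within_10pct"
    return PermutationResult(p_hat, lo, hi, n_perm, stopped, chi2_obs)


# ---------------------------------------------------------------------------
# clinical enrichment


def kruskal_wallis(values, labels) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p-value.

    Missing values are dropped (together with their labels). If every
    remaining value is identical the test is vacuous: H = 0, p = 1.
    """
    values = np.asarray(values, dtype=float)
    codes, k = _codes(labels)
    keep = np.isfinite(values)
    values, codes = values[keep], codes[keep]
    groups = [values[codes == g] for g in np.unique(codes)]
    groups = [g for g in groups if len(g)]
    if len(groups) < 2:
        raise ValueError("need at least two non-empty groups")
    if np.unique(values).size < 2:
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def chi_square_enrichment(categories, labels) -> tuple[float, float]:
    """Pearson chi-square of the label x category contingency table.

    No continuity correction; df = (r - 1)(c - 1). Missing categories are
    dropped; a degenerate table (fewer than two non-empty rows or columns)
    is an error.
    """
    cat = pd.Series(np.asarray(categories, dtype=object))
    lab = pd.Series(np.asarray(labels, dtype=object))
    keep = cat.notna() & lab.notna()
    table = pd.crosstab(lab[keep], cat[keep]).to_numpy()
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("degenerate contingency table: need >= 2 rows and columns")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def permutation_pvalue_enrichment(
    statistic,
    data,
    labels,
    seed: int | None = 0,
    batch: int = 1_000,
    max_perm: int = 100_000,
) -> PermutationResult:
    """Permutation p-value for an enrichment statistic.

    ``statistic(data, labels) -> float`` is recomputed under label
    permutations in batches (default 1e3) until the 95% CI for the p-value
    does not cross 0.05, up to ``max_perm`` (default 1e5) permutations.
    """
    labels = np.asarray(labels)
    obs = statistic(data, labels)
    rng = np.random.default_rng(seed)
    n_perm = 0
    b_exceed = 0
    while True:
        for _ in range(batch):
            perm = rng.permutation(labels)
            if statistic(data, perm) >= obs - 1e-12:
                b_exceed += 1
        n_perm += batch
        p_hat = (1 + b_exceed) / (1 + n_perm)
        lo, hi = _binomial_ci(p_hat, n_perm)
        if lo > 0.05 or hi < 0.05:
            return PermutationResult(p_hat, lo, hi, n_perm, "ci_clear_of_05", float(obs))
        if n_perm >= max_perm:
            return PermutationResult(p_hat, lo, hi, n_perm, "max_iterations", float(obs))


def enrichment_count(clinical, labels, alpha: float = 0.05, seed: int | None = 0, permute: bool = True) -> EnrichmentReport:
    """Test every clinical label against the clustering; count significant ones.

    Numeric labels get the Kruskal-Wallis test (asymptotic p); categorical
    labels get the chi-square test, permutation-calibrated when ``permute``
    is on. Labels with a single observed level are skipped with a warning.
    """
    report = EnrichmentReport(alpha=alpha)
    labels = np.asarray(labels)
    table = clinical.labels if hasattr(clinical, "labels") else pd.DataFrame(clinical)
    if table.shape[1] == 0:
        raise ValueError("no clinical labels to test")
    rng = np.random.default_rng(seed)
    for name in table.columns:
        col = table[name]
        present = col.notna().to_numpy()
        if pd.unique(col[present]).size < 2:
            warnings.warn(f"clinical label {name!r} has a single level; skipped", stacklevel=2)
            continue
        entry: dict = {}
        try:
            if pd.api.types.is_numeric_dtype(col):
                entry["test"] = "kruskal_wallis"
                h, p = kruskal_wallis(col.to_numpy(dtype=float), labels)
                entry["statistic"], entry["p"] = h, p
            else:
                entry["test"] = "chi_square"
                sub_seed = int(rng.integers(2**31 - 1))
                if permute:
                    perm = permutation_pvalue_enrichment(
                        lambda d, l: chi_square_enrichment(d, l)[0],
                        col.to_numpy(dtype=object),
                        labels,
                        seed=sub_seed,
                    )
                    entry["statistic"], entry["p"] = perm.statistic, perm.p_hat
                    entry["permutation"] = perm.as_dict()
                else:
                    chi2, p = chi_square_enrichment(col.to_numpy(dtype=object), labels)
                    entry["statistic"], entry["p"] = chi2, p
        except ValueError as exc:
            warnings.warn(f"clinical label {name!r} skipped: {exc}", stacklevel=2)
            continue
        report.entries[name] = entry
    report.n_significant = sum(e["p"] < alpha for e in report.entries.values())
    return report


# ---------------------------------------------------------------------------
# cross-method comparison and survival curves


def friedman_compare(score_matrix) -> tuple[float, float, np.ndarray]:
    """Friedman rank test across datasets (rows) and methods (columns).

    Ranks are assigned within each dataset with average ties; returns the
    tie-corrected chi-square, its p-value (df = methods - 1) and the mean
    rank of each method.
    """
    scores = np.asarray(score_matrix, dtype=float)
    if scores.ndim != 2 or scores.shape[0] < 2 or scores.shape[1] < 2:
        raise ValueError("need >= 2 datasets and >= 2 methods")
    if not np.all(np.isfinite(scores)):
        raise ValueError("score matrix has missing cells")
    n, k = scores.shape
    ranks = np.apply_along_axis(stats.rankdata, 1, scores)
    mean_ranks = ranks.mean(axis=0)
    center = (k + 1) / 2.0
    ss_treat = n * np.sum((mean_ranks - center) ** 2)
    ss_err = np.sum((ranks - center) ** 2) / (n * (k - 1))
    chi2 = 0.0 if ss_err == 0 else float(ss_treat / ss_err)
    return chi2, float(stats.chi2.sf(chi2, k - 1)), mean_ranks


def km_estimate(time, event, labels) -> dict:
    """Kaplan-Meier product-limit curve per group.

    Returns {group: (times, survival)} with each curve starting at
    (0, 1) and non-increasing.
    """
    from lifelines import KaplanMeierFitter

    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    labels = np.asarray(labels)
    curves = {}
    for g in pd.unique(labels):
        mask = labels == g
        if mask.sum() == 0:
            raise ValueError(f"empty group {g!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(time[mask], event[mask])
        sf = kmf.survival_function_
        curves[g] = (sf.index.to_numpy(dtype=float), sf.iloc[:, 0].to_numpy(dtype=float))
    return curves
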