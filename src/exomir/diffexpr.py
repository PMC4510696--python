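"""Count matrices, normalization, negative-binomial enrichment testing,
seven-way set partitions, and sample-relationship summaries.

The differential test is a self-contained NB procedure: per-miRNA two-sided
p-values come from a sum-conditioned exact NB test when the total count is
small (the conditional distribution of one group's sum given the grand total
under independence of NB group sums), otherwise from a Wald test on log2
group means with NB variance. Dispersions are method-of-moments estimates
with a local-regression mean trend, floored conservatively at the trend.
This is behaviourally similar to, but not numerically identical with,
classical count-based DE packages.

Enrichment calls use |log2 fold change| >= 1 and Benjamini-Hochberg
FDR <= 0.001, both boundaries inclusive.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .mapanno import AnnotatedRead

EXACT_TEST_MAX_TOTAL = 5000
PSEUDOCOUNT = 0.5


# ---------------------------------------------------------------------------
# counting and normalization


def build_counts(annotated_by_sample: dict[str, list[AnnotatedRead]]) -> pd.DataFrame:
    """Weighted miRNA x sample count matrix from annotated reads."""
    cols = {}
    for sample, annotated in annotated_by_sample.items():
        acc: dict[str, float] = {}
        for a in annotated:
            if a.category == "miRNA" and a.mature_id:
                acc[a.mature_id] = acc.get(a.mature_id, 0.0) + a.weight
        cols[sample] = acc
    df = pd.DataFrame(cols).fillna(0.0).sort_index()
    df.index.name = "mirna"
    return df


def rpm_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Scale each sample column to one million."""
    sums = counts.sum(axis=0)
    zero = sums[sums <= 0]
    if len(zero):
        raise ValueError(f"zero-count sample(s): {list(zero.index)}")
    return counts * (1e6 / sums)


def tmm_factors(
    counts: pd.DataFrame,
    ref_sample: str | None = None,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors.

    Per sample, the factor is 2 to the weighted mean of log2 count ratios
    against a reference sample, after discarding the most extreme ``trim_m``
    of M values and ``trim_a`` of A values on each side; weights are inverse
    asymptotic (delta-method binomial) variances. Genes with a zero in either
    sample are excluded. Factors are scaled to geometric mean 1, so the
    effective library size of a sample is libsize x factor.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    lib = counts.sum(axis=0).astype(float)
    if ref_sample is None:
        # reference: sample whose 75th count percentile (scaled) is closest to the mean
        uq = counts.apply(lambda c: np.percentile(c[c > 0], 75) if (c > 0).any() else 0.0)
        uq = uq / lib
        ref_sample = (uq - uq.mean()).abs().idxmin()
    ref = counts[ref_sample].to_numpy(float)
    nref = lib[ref_sample]
    logf = {}
    for s in counts.columns:
        if s == ref_sample:
            logf[s] = 0.0
            continue
        obs = counts[s].to_numpy(float)
        nobs = lib[s]
        ok = (obs > 0) & (ref > 0)
        if ok.sum() < 10:
            logf[s] = np.log2(nobs / nref) * 0  # fall back: pure library-size ratio
            import warnings

            warnings.warn(f"fewer than 10 usable genes for {s}; using library-size ratio")
            continue
        o, r = obs[ok], ref[ok]
        m = np.log2(o / nobs) - np.log2(r / nref)
        a = 0.5 * (np.log2(o / nobs) + np.log2(r / nref))
        v = (nobs - o) / (nobs * o) + (nref - r) / (nref * r)
        n = len(m)
        lo_m = int(np.floor(n * trim_m)) + 1
        hi_m = n + 1 - lo_m
        lo_a = int(np.floor(n * trim_a)) + 1
        hi_a = n + 1 - lo_a
        rank_m = stats.rankdata(m)
        rank_a = stats.rankdata(a)
        keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
        if keep.sum() == 0:
            logf[s] = 0.0
            continue
        f = np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep])
        logf[s] = f if np.isfinite(f) else 0.0
    factors = pd.Series({s: 2.0 ** f for s, f in logf.items()})[counts.columns]
    return factors / stats.gmean(factors)


def normalized_counts(counts: pd.DataFrame, method: str = "tmm") -> pd.DataFrame:
    """Counts scaled to a common effective library size (mean library)."""
    lib = counts.sum(axis=0)
    if method == "rpm":
        eff = lib.astype(float)
    elif method == "tmm":
        eff = lib * tmm_factors(counts)
    else:
        raise ValueError(method)
    return counts * (eff.mean() / eff)


# ---------------------------------------------------------------------------
# dispersion and testing


def estimate_dispersion(
    counts: pd.DataFrame,
    groups: pd.Series | dict[str, str],
    method: str = "pooled",
    trend: bool = True,
) -> pd.Series:
    """Per-miRNA NB dispersion alpha (var = mu + alpha mu^2).

    Method-of-moments gene-wise estimates on normalized counts using
    within-group deviations, either pooled across conditions or per condition
    (then maximized). A lowess mean-dispersion trend on the log-mean scale
    supplies a floor: the final alpha is max(gene-wise, trend).
    """
    groups = pd.Series(groups)[counts.columns]
    norm = normalized_counts(counts)
    levels = groups.unique()
    if not any((groups == g).sum() >= 2 for g in levels):
        raise ValueError("no replicated group; supply a fixed dispersion instead")

    mu = norm.mean(axis=1)
    if method == "pooled":
        ss = pd.Series(0.0, index=norm.index)
        dof = 0
        for g in levels:
            sub = norm.loc[:, groups[groups == g].index]
            if sub.shape[1] >= 2:
                ss += ((sub.sub(sub.mean(axis=1), axis=0)) ** 2).sum(axis=1)
                dof += sub.shape[1] - 1
        s2 = ss / dof
        gene = ((s2 - mu) / mu**2).clip(lower=0.0).fillna(0.0)
    elif method == "per-condition":
        per = []
        for g in levels:
            sub = norm.loc[:, groups[groups == g].index]
            if sub.shape[1] < 2:
                continue
            mg = sub.mean(axis=1)
            s2 = sub.var(axis=1, ddof=1)
            per.append(((s2 - mg) / mg**2).clip(lower=0.0).fillna(0.0))
        gene = pd.concat(per, axis=1).max(axis=1)
    else:
        raise ValueError(method)

    gene[mu <= 0] = 0.0
    if not trend:
        return gene
    ok = mu > 0
    if ok.sum() >= 10:
        fit = lowess(gene[ok].to_numpy(), np.log10(mu[ok].to_numpy()),
                     frac=0.5, return_sorted=True)
        trend_vals = np.interp(np.log10(mu[ok].to_numpy()), fit[:, 0], fit[:, 1])
        trend_series = pd.Series(0.0, index=gene.index)
        trend_series[ok] = np.clip(trend_vals, 0.0, None)
        return pd.concat([gene, trend_series], axis=1).max(axis=1)
    return gene


def _exact_nb_pvalue(ka: float, kb: float, n1: int, n2: int, alpha: float) -> float:
    """Two-sided sum-conditioned exact test on group-summed counts.

    Group sums are NB (size n/alpha); conditioning on the grand total S gives
    the two-sided p as the probability mass of outcomes no more likely than
    the observed split.
    """
    ka, kb = int(round(ka)), int(round(kb))
    s = ka + kb
    if s == 0:
        return 1.0
    a = np.arange(s + 1)
    mu = s / (n1 + n2)
    if alpha <= 0:
        # Poisson group sums -> binomial conditional
        logp = stats.binom.logpmf(a, s, n1 / (n1 + n2))
    else:
        r1, r2 = n1 / alpha, n2 / alpha
        m1, m2 = n1 * mu, n2 * mu
        logp = (stats.nbinom.logpmf(a, r1, r1 / (r1 + m1))
                + stats.nbinom.logpmf(s - a, r2, r2 / (r2 + m2)))
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    return float(min(1.0, p[p <= p[ka] * (1 + 1e-12)].sum()))


def _wald_pvalue(mean_a, mean_b, n1, n2, alpha):
    va = (mean_a + alpha * mean_a**2) / n1
    vb = (mean_b + alpha * mean_b**2) / n2
    la, lb = np.log2(mean_a + PSEUDOCOUNT), np.log2(mean_b + PSEUDOCOUNT)
    se = np.sqrt(va / ((mean_a + PSEUDOCOUNT) * np.log(2)) ** 2
                 + vb / ((mean_b + PSEUDOCOUNT) * np.log(2)) ** 2)
    if se == 0:
        return 1.0
    z = (la - lb) / se
    return float(2 * stats.norm.sf(abs(z)))


def nb_test(
    counts: pd.DataFrame,
    groups: pd.Series | dict[str, str],
    dispersions: pd.Series | float,
    contrast: tuple[str, str] | None = None,
    normalize: str = "tmm",
) -> pd.DataFrame:
    """Two-group NB test per miRNA.

    ``contrast=(numerator, denominator)`` names the group levels; log2 fold
    change is numerator over denominator on normalized means with a 0.5
    pseudocount. Returns a frame with log2_fold_change, base means,
    dispersion, p_value and BH fdr; all-zero miRNAs are reported untested
    (NaN p).
    """
    groups = pd.Series(groups)[counts.columns]
    levels = list(pd.unique(groups))
    if contrast is None:
        if len(levels) != 2:
            raise ValueError("need exactly two groups or an explicit contrast")
        contrast = (levels[0], levels[1])
    ga = groups[groups == contrast[0]].index
    gb = groups[groups == contrast[1]].index
    norm = normalized_counts(counts[list(ga) + list(gb)], method=normalize) \
        if normalize else counts[list(ga) + list(gb)].astype(float)
    if isinstance(dispersions, (int, float)):
        dispersions = pd.Series(float(dispersions), index=counts.index)

    rows = []
    for mirna in counts.index:
        xa = norm.loc[mirna, ga].to_numpy(float)
        xb = norm.loc[mirna, gb].to_numpy(float)
        mean_a, mean_b = xa.mean(), xb.mean()
        alpha = float(dispersions.get(mirna, 0.0))
        lfc = np.log2((mean_a + PSEUDOCOUNT) / (mean_b + PSEUDOCOUNT))
        if mean_a == 0 and mean_b == 0:
            p = np.nan
        else:
            ka, kb = xa.sum(), xb.sum()
            if ka + kb <= EXACT_TEST_MAX_TOTAL:
                p = _exact_nb_pvalue(ka, kb, len(xa), len(xb), alpha)
            else:
                p = _wald_pvalue(mean_a, mean_b, len(xa), len(xb), alpha)
        rows.append(dict(mirna=mirna, mean_a=mean_a, mean_b=mean_b,
                         base_mean=(mean_a + mean_b) / 2, log2_fold_change=lfc,
                         dispersion=alpha, p_value=p))
    res = pd.DataFrame(rows).set_index("mirna")
    tested = res.p_value.notna()
    fdr = pd.Series(np.nan, index=res.index)
    if tested.any():
        fdr[tested] = multipletests(res.p_value[tested], method="fdr_bh")[1]
    res["fdr"] = fdr
    return res


def call_enriched(
    results: pd.DataFrame, lfc_min: float = 1.0, fdr_max: float = 0.001
) -> pd.Series:
    """Enrichment calls (boundary-inclusive on both thresholds).

    Positive log2 fold change means enriched in the contrast numerator
    (by convention the exosome compartment)."""
    call = pd.Series("not-called", index=results.index)
    sig = (results.log2_fold_change.abs() >= lfc_min) & (results.fdr <= fdr_max)
    call[sig & (results.log2_fold_change > 0)] = "exosome-enriched"
    call[sig & (results.log2_fold_change < 0)] = "cell-enriched"
    return call


# ---------------------------------------------------------------------------
# seven-way set partition


@dataclass
class CategoryPartition:
    """Disjoint seven-region partition of three named enriched sets."""

    lines: tuple[str, str, str]
    regions: dict[frozenset, set]

    def count(self, *lines: str) -> int:
        return len(self.regions.get(frozenset(lines), set()))

    def counts(self) -> dict[str, int]:
        out = {}
        for key, members in self.regions.items():
            out[" & ".join(sorted(key))] = len(members)
        return out

    def all_members(self) -> set:
        return set().union(*self.regions.values()) if self.regions else set()


def partition_sets(sets_by_line: dict[str, set]) -> CategoryPartition:
    """Standard 7-region partition (uniques, pairwise-only, triple)."""
    if len(sets_by_line) != 3:
        raise ValueError("exactly three named sets required")
    lines = tuple(sets_by_line)
    a, b, c = (sets_by_line[x] for x in lines)
    regions = {
        frozenset([lines[0]]): a - b - c,
        frozenset([lines[1]]): b - a - c,
        frozenset([lines[2]]): c - a - b,
        frozenset([lines[0], lines[1]]): (a & b) - c,
        frozenset([lines[0], lines[2]]): (a & c) - b,
        frozenset([lines[1], lines[2]]): (b & c) - a,
        frozenset(lines): a & b & c,
    }
    return CategoryPartition(lines, regions)


_FIXTURE_LINES = ("DKO-1", "DKs-8", "DLD-1")
_FIXTURE_CATEGORIES = {
    "DKO-1": frozenset(["DKO-1"]),
    "DKs-8": frozenset(["DKs-8"]),
    "DLD-1": frozenset(["DLD-1"]),
    "DKO-1 and DKs-8": frozenset(["DKO-1", "DKs-8"]),
    "DKO-1 and DLD-1": frozenset(["DKO-1", "DLD-1"]),
    "DLD-1 and DKs-8": frozenset(["DLD-1", "DKs-8"]),
    "DKO-1, DLD-1 and DKs-8": frozenset(["DKO-1", "DKs-8", "DLD-1"]),
}


def parse_category_table(source: str | Path) -> CategoryPartition:
    """Parse a packaged category-block TSV (category<TAB>mirna rows under a
    header line) into a CategoryPartition. Duplicate names within a block and
    unknown block headers are rejected with the offending line number."""
    if isinstance(source, Path) or (isinstance(source, str) and "\t" not in source
                                    and "\n" not in source):
        text = Path(source).read_text()
    else:
        text = source
    regions: dict[frozenset, set] = {k: set() for k in _FIXTURE_CATEGORIES.values()}
    lines = text.splitlines()
    if not lines or lines[0].strip() != "category\tmirna":
        raise ValueError("line 1: expected header 'category<TAB>mirna'")
    for i, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        try:
            cat, name = line.split("\t")
        except ValueError:
            raise ValueError(f"line {i}: malformed row {line!r}") from None
        if cat not in _FIXTURE_CATEGORIES:
            raise ValueError(f"line {i}: unknown category block {cat!r}")
        region = regions[_FIXTURE_CATEGORIES[cat]]
        if name in region:
            raise ValueError(f"line {i}: duplicate miRNA {name!r} in block {cat!r}")
        region.add(name)
    return CategoryPartition(_FIXTURE_LINES, regions)


# ---------------------------------------------------------------------------
# sample relationships


def spearman_matrix(expr: pd.DataFrame, pairs: list[tuple[str, str]] | None = None) -> pd.DataFrame:
    """Symmetric Spearman correlation matrix over sample columns (average
    ranks for ties); constant columns yield NaN entries."""
    if expr.shape[0] < 3:
        raise ValueError("need at least 3 miRNAs")
    cols = expr.columns
    mat = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    todo = pairs or [(a, b) for i, a in enumerate(cols) for b in cols[i + 1:]]
    for a, b in todo:
        x, y = expr[a], expr[b]
        if x.nunique() <= 1 or y.nunique() <= 1:
            r = np.nan
        else:
            r = stats.spearmanr(x, y).statistic
        mat.loc[a, b] = mat.loc[b, a] = r
    return mat


def pca(
    expr: pd.DataFrame,
    log_transform: bool = True,
    pseudocount: float = 1.0,
    n_components: int | None = None,
) -> tuple[pd.DataFrame, np.ndarray, pd.DataFrame]:
    """PCA of samples (columns) over miRNA features.

    Returns (scores, explained_variance_fractions, loadings). The matrix is optionally
    log2(x+pseudocount)-transformed, feature-centered, then decomposed by
    SVD; each component's sign is fixed so its largest-magnitude loading is
    positive.
    """
    if expr.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    x = np.log2(expr.to_numpy(float) + pseudocount) if log_transform else expr.to_numpy(float)
    x = x - x.mean(axis=1, keepdims=True)  # center each miRNA across samples
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    k_max = min(x.shape)
    k = min(n_components or k_max, k_max)
    if n_components and n_components > k_max:
        import warnings

        warnings.warn(f"only {k_max} components available; truncating")
    for j in range(k):
        i = np.argmax(np.abs(u[:, j]))
        if u[i, j] < 0:
            u[:, j] *= -1
            vt[j, :] *= -1
    scores = pd.DataFrame(
        (vt[:k].T * s[:k]), index=expr.columns,
        columns=[f"PC{j + 1}" for j in range(k)],
    )
    var = s**2
    explained = (var / var.sum())[:k] if var.sum() > 0 else np.zeros(k)
    loadings = pd.DataFrame(u[:, :k], index=expr.index,
                            columns=[f"PC{j + 1}" for j in range(k)])
    return scores, explained, loadings
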