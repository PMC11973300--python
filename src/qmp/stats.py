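"""Statistical surface: filtering, paired tests, multiplicity correction,
fold changes, alpha-diversity, generalized UniFrac and PERMANOVA.

Univariate tests delegate to scipy/statsmodels; generalized UniFrac and
the seeded-permutation PERMANOVA are implemented here (the generalized
form with branch weights (p+q)^alpha interpolates between unweighted and
weighted UniFrac and is not available in scikit-bio).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from skbio import TreeNode
from statsmodels.stats.multitest import multipletests

from qmp.tables_io import ValidationError

logger = logging.getLogger("qmp")


# ---------------------------------------------------------------------------
# taxon filtering


def filter_taxa(rel: pd.DataFrame, groups: dict[str, list[str]],
                prevalence_min: float = 0.30,
                relab_min: float = 0.0025) -> list[str]:
    """Taxa worth testing: prevalent in at least one group AND non-trivially
    abundant in at least one sample.

    A taxon is kept iff (i) in some group the proportion of positive
    samples is >= ``prevalence_min`` and (ii) some sample has relative
    abundance >= ``relab_min``. Boundary values are retained.
    """
    for g, samples in groups.items():
        if len(samples) == 0:
            raise ValidationError(f"group {g!r} is empty")
    kept = []
    for taxon in rel.columns:
        col = rel[taxon]
        prevalent = any(
            (col.loc[s] > 0).mean() >= prevalence_min
            for s in (groups[g] for g in groups)
        )
        abundant = (col >= relab_min).any()
        if prevalent and abundant:
            kept.append(taxon)
    return kept


# ---------------------------------------------------------------------------
# univariate tests


def wilcoxon_signed_rank(x, y) -> tuple[float, float]:
    """Two-sided paired Wilcoxon signed-rank test.

    Zero differences are dropped; with no non-zero differences the test is
    degenerate and p = 1. The exact null distribution is used for n <= 25
    non-zero tie-free differences, the normal approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    d = x - y
    d = d[d != 0]
    n = len(d)
    if n == 0:
        logger.warning("all paired differences are zero; p = 1")
        return 0.0, 1.0
    ties = len(np.unique(np.abs(d))) < n
    method = "exact" if (n <= 25 and not ties) else "approx"
    res = scipy.stats.wilcoxon(d, method=method)
    return float(res.statistic), float(res.pvalue)


def fisher_exact(table) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2x2 contingency table."""
    table = np.asarray(table, dtype=int)
    if (table < 0).any():
        raise ValidationError("contingency table entries must be non-negative")
    odds, p = scipy.stats.fisher_exact(table, alternative="two-sided")
    return float(odds), float(p)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fold_change(before_central: float, after_central: float) -> float:
    """Later/earlier ratio of central abundances; NaN when undefined."""
    if before_central <= 0:
        return float("nan")
    return after_central / before_central


# ---------------------------------------------------------------------------
# alpha diversity


def richness(fractions, detection_min: float = 0.0) -> int:
    """Number of taxa detected above ``detection_min`` (default: any
    positive abundance)."""
    f = np.asarray(fractions, dtype=float)
    if detection_min > 0:
        return int((f >= detection_min).sum())
    return int((f > 0).sum())


def shannon_effective(fractions) -> float:
    """exp(Shannon entropy): the effective number of equally common taxa."""
    f = np.asarray(fractions, dtype=float)
    f = f[f > 0]
    return float(np.exp(-np.sum(f * np.log(f))))


# ---------------------------------------------------------------------------
# generalized UniFrac


def _branch_matrix(tree: TreeNode, taxon_ids) -> tuple[np.ndarray, np.ndarray]:
    """(branch lengths, leaf-membership indicator) for every non-root node.

    Row j of the indicator marks which taxa descend through branch j, so
    subtree proportions are a single matrix product with the abundance
    matrix.
    """
    taxon_pos = {t: i for i, t in enumerate(taxon_ids)}
    lengths, members = [], []
    for node in tree.postorder(include_self=False):
        length = node.length if node.length is not None else 0.0
        if length < 0 or not np.isfinite(length):
            raise ValidationError("tree has negative or non-finite branch length")
        ind = np.zeros(len(taxon_ids))
        for tip in node.tips(include_self=True):
            if tip.name in taxon_pos:
                ind[taxon_pos[tip.name]] = 1.0
        lengths.append(length)
        members.append(ind)
    return np.asarray(lengths), np.asarray(members)


def _check_on_tree(tree: TreeNode, abund: pd.DataFrame) -> None:
    leaves = {t.name for t in tree.tips()}
    present = abund.columns[(abund > 0).any(axis=0)]
    missing = [t for t in present if t not in leaves]
    if missing:
        raise ValidationError(
            f"abundant taxa missing from tree: {missing[:10]}"
        )


def generalized_unifrac(tree: TreeNode, sample_p, sample_q,
                        alpha: float = 0.5) -> float:
    """Generalized UniFrac distance between two communities.

    d = sum_b L_b (p+q)^alpha |p-q|/(p+q) / sum_b L_b (p+q)^alpha over
    branches with p+q > 0, where p, q are the per-sample proportions of
    leaves descending through branch b. alpha=1 recovers a weighted
    UniFrac normalization; alpha=0 weights all occupied branches equally.
    """
    abund = pd.DataFrame([sample_p, sample_q])
    abund = abund.div(abund.sum(axis=1), axis=0)
    _check_on_tree(tree, abund)
    lengths, members = _branch_matrix(tree, list(abund.columns))
    props = abund.values @ members.T  # 2 x branches
    p, q = props[0], props[1]
    tot = p + q
    occupied = tot > 0
    w = lengths[occupied] * tot[occupied] ** alpha
    denom = w.sum()
    if denom == 0:
        return 0.0
    num = (w * np.abs(p[occupied] - q[occupied]) / tot[occupied]).sum()
    return float(num / denom)


def unifrac_distance_matrix(tree: TreeNode, abund: pd.DataFrame,
                            alpha: float = 0.5) -> pd.DataFrame:
    """All-pairs generalized UniFrac over a samples x taxa table."""
    rel = abund.div(abund.sum(axis=1), axis=0)
    _check_on_tree(tree, rel)
    lengths, members = _branch_matrix(tree, list(rel.columns))
    props = rel.values @ members.T  # samples x branches
    n = props.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p, q = props[i], props[j]
            tot = p + q
            occ = tot > 0
            w = lengths[occ] * tot[occ] ** alpha
            denom = w.sum()
            d = 0.0 if denom == 0 else float(
                (w * np.abs(p[occ] - q[occ]) / tot[occ]).sum() / denom)
            out[i, j] = out[j, i] = d
    return pd.DataFrame(out, index=rel.index, columns=rel.index)


# ---------------------------------------------------------------------------
# PERMANOVA


@dataclass
class PermanovaResult:
    pseudo_f: float
    r_squared: float
    p_value: float
    n_permutations: int


def _sums_of_squares(d2: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    n = d2.shape[0]
    sst = d2.sum() / (2 * n)
    ssw = 0.0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        ssw += d2[np.ix_(idx, idx)].sum() / (2 * len(idx))
    return sst, ssw


def _pseudo_f(d2: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    n = d2.shape[0]
    k = len(np.unique(labels))
    sst, ssw = _sums_of_squares(d2, labels)
    ssb = sst - ssw
    f = (ssb / (k - 1)) / (ssw / (n - k)) if ssw > 0 else np.inf
    r2 = ssb / sst if sst > 0 else 0.0
    return f, r2


def permanova(dist: pd.DataFrame, groups: pd.Series, n_perm: int = 999,
              seed: int | None = None) -> PermanovaResult:
    """Permutational multivariate ANOVA on a distance matrix.

    Pseudo-F from between/within sums of squared distances; the p-value
    counts label permutations with F* >= F, with the observed labelling
    included: p = (hits + 1) / (n_perm + 1). Labels are permuted freely
    (no strata). ``seed`` makes the permutation stream reproducible.
    """
    samples = list(dist.index)
    labels = np.asarray(groups.reindex(samples))
    counts = pd.Series(labels).value_counts()
    if len(counts) < 2:
        raise ValidationError("PERMANOVA needs at least two groups")
    if (counts < 2).any():
        raise ValidationError(
            f"group {counts.idxmin()!r} has fewer than 2 samples"
        )
    d = dist.values
    if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0):
        raise ValidationError("distance matrix must be symmetric with zero diagonal")
    d2 = d ** 2
    f_obs, r2 = _pseudo_f(d2, labels)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        f_perm, _ = _pseudo_f(d2, rng.permutation(labels))
        if f_perm >= f_obs - 1e-12:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return PermanovaResult(float(f_obs), float(r2), float(p), n_perm)


def pairwise_permanova(dist: pd.DataFrame, groups: pd.Series,
                       n_perm: int = 999, seed: int | None = None) -> pd.DataFrame:
    """PERMANOVA on every pair of groups, with BH correction across pairs."""
    rng = np.random.default_rng(seed)
    levels = sorted(groups.unique())
    rows = []
    for i, a in enumerate(levels):
        for b in levels[i + 1:]:
            keep = groups[groups.isin([a, b])].index
            keep = [s for s in dist.index if s in set(keep)]
            sub = dist.loc[keep, keep]
            res = permanova(sub, groups[keep], n_perm=n_perm,
                            seed=int(rng.integers(2 ** 31)))
            rows.append({"group_a": a, "group_b": b, "pseudo_F": res.pseudo_f,
                         "R2": res.r_squared, "p": res.p_value})
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].values)
    return out


# ---------------------------------------------------------------------------
# differential abundance over a study design


def paired_taxon_tests(abund: pd.DataFrame, pairs: pd.DataFrame,
                       comparison: str, unit: str) -> pd.DataFrame:
    """Per-taxon paired Wilcoxon tests between two timepoints.

    ``pairs`` maps each subject to its sample at the earlier and later
    timepoint. Fold change is the ratio of group means (later/earlier);
    q-values are BH-adjusted within this (comparison, unit) family.
    """
    rows = []
    before = abund.loc[pairs["sample_t0"]]
    after = abund.loc[pairs["sample_t1"]]
    for taxon in abund.columns:
        x, y = before[taxon].values, after[taxon].values
        stat, p = wilcoxon_signed_rank(y, x)
        fc = fold_change(float(np.mean(x)), float(np.mean(y)))
        rows.append({"taxon": taxon, "comparison": comparison, "unit": unit,
                     "test": "wilcoxon_signed_rank", "statistic": stat,
                     "p": p, "fold_change": fc})
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].values)
    out["significant_p"] = out["p"] <= 0.05
    out["significant_q"] = out["q"] <= 0.05
    return out


def prevalence_fisher_tests(abund: pd.DataFrame, groups: dict[str, list[str]],
                            comparison: str, unit: str) -> pd.DataFrame:
    """Per-taxon presence/absence Fisher's exact test between two groups.

    The 2x2 table counts samples positive/negative for the taxon in each
    group — a prevalence reading of "pairwise Fisher's exact".
    """
    (ga, sa), (gb, sb) = list(groups.items())
    rows = []
    for taxon in abund.columns:
        pos_a = int((abund.loc[sa, taxon] > 0).sum())
        pos_b = int((abund.loc[sb, taxon] > 0).sum())
        table = [[pos_a, len(sa) - pos_a], [pos_b, len(sb) - pos_b]]
        odds, p = fisher_exact(table)
        rows.append({"taxon": taxon, "comparison": comparison, "unit": unit,
                     "test": "fisher_exact_prevalence", "statistic": odds,
                     "p": p})
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].values)
    return out
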