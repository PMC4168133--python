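"""Count-based differential expression for pooled small-RNA libraries.

Expression is normalized to reads per million (NE = count / library total x
1e6). Each pairwise library comparison runs three tests on raw counts -- the
Audic-Claverie exact test, Fisher's exact test and the 2x2 chi-squared test --
with a Bonferroni correction over the miRNAs actually tested in the pair.
A miRNA is called up- or down-regulated when the adjusted p-value is below
alpha and |log2 fold change| of the NE ratio exceeds the cutoff; a miRNA with
zero NE in one library of a pair is sex-specific to the other and is not
tested; a miRNA with NE below 1 in all three libraries is filtered out
entirely. The module also provides the 2^(-ddCt) relative-quantification
calculus used for qPCR validation against a 5.8S rRNA reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln, logsumexp

from .simlib import GROUPS

TEST_POLICIES = ("ac", "fisher", "chi2", "consensus")


@dataclass
class ExpressionMatrix:
    """miRNA x library table of raw counts and normalized expression."""

    counts: pd.DataFrame  # integer counts, columns are library names
    ne: pd.DataFrame      # reads-per-million, same shape
    totals: pd.Series     # per-library normalization totals

    @property
    def libraries(self) -> list[str]:
        return list(self.counts.columns)


def normalize(counts: pd.DataFrame, totals: pd.Series | None = None) -> ExpressionMatrix:
    """Reads-per-million normalization: NE = count / total * 1e6.

    When ``totals`` is omitted, each library's total is its summed miRNA
    count, in which case every NE column sums to exactly 1e6.
    """
    counts = counts.astype(np.int64)
    if totals is None:
        totals = counts.sum(axis=0)
    totals = pd.Series(totals).reindex(counts.columns)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise ValueError(f"non-positive normalization total for {bad}")
    ne = counts / totals * 1e6
    return ExpressionMatrix(counts=counts, ne=ne, totals=totals)


def expression_from_annotation(annotated: pd.DataFrame,
                               groups: tuple[str, ...] = GROUPS,
                               norm_total: str = "mirna") -> ExpressionMatrix:
    """Build the miRNA expression matrix from an annotated tag table.

    miRNA rows are keyed by ``best_hit`` (conserved ids or novel tags);
    counts of tags assigned to the same miRNA are summed. ``norm_total``
    selects the normalization denominator: ``'mirna'`` (summed miRNA counts,
    the default governing the DE analysis) or ``'clean'`` (all clean reads).
    """
    if norm_total not in ("mirna", "clean"):
        raise ValueError("norm_total must be 'mirna' or 'clean'")
    mir_cats = ("conserved_miRNA_genome", "conserved_miRNA_hairpin", "novel_miRNA")
    sub = annotated[annotated["category"].isin(mir_cats)]
    cols = [f"count_{g}" for g in groups]
    counts = sub.groupby("best_hit")[cols].sum()
    counts.columns = list(groups)
    counts.index.name = "mirna"
    if norm_total == "mirna":
        totals = None
    else:
        totals = annotated[cols].sum()
        totals.index = list(groups)
    return normalize(counts, totals)


# ---------------------------------------------------------------------------
# the three tests

def _ac_log_pmf(k: np.ndarray, x: int, N1: float, N2: float) -> np.ndarray:
    """log p(k|x) = k log(N2/N1) + log (x+k)!/(x! k!) - (x+k+1) log(1+N2/N1)."""
    r = N2 / N1
    return (k * np.log(r) + gammaln(x + k + 1) - gammaln(x + 1) - gammaln(k + 1)
            - (x + k + 1) * np.log1p(r))


def audic_claverie_p(x: int, y: int, N1: float, N2: float) -> float:
    """Two-sided Audic-Claverie p-value for counts x, y in libraries of
    sizes N1, N2.

    The conditional distribution of the second count given the first is
    p(y|x) = (N2/N1)^y (x+y)! / (x! y! (1+N2/N1)^(x+y+1)); the two-sided
    p-value doubles the smaller tail, capped at 1. Computed in log space;
    the upper tail falls back to direct summation when 1 - lower-CDF loses
    precision.
    """
    if x < 0 or y < 0:
        raise ValueError("counts must be non-negative")
    if N1 <= 0 or N2 <= 0:
        raise ValueError("library totals must be positive")
    ks = np.arange(0, y + 1)
    log_pmf = _ac_log_pmf(ks, x, N1, N2)
    lower = float(np.exp(log_pmf).sum())            # P(K <= y)
    below = lower - float(np.exp(log_pmf[-1]))      # P(K < y)
    upper = 1.0 - below                             # P(K >= y)
    if upper < 1e-12:
        # catastrophic cancellation: sum the upper tail directly, in
        # log space and chunks (terms may underflow float range entirely)
        log_sum = -np.inf
        k, chunk = y, 512
        while True:
            kk = np.arange(k, k + chunk)
            lp = _ac_log_pmf(kk, x, N1, N2)
            log_sum = np.logaddexp(log_sum, logsumexp(lp))
            k += chunk
            if lp.max() < max(log_sum - 40.0, -800.0):
                break
        upper = float(np.exp(log_sum))
    # floor at a representable positive value: p is a tail mass, never 0
    return float(max(min(1.0, 2.0 * min(lower, upper)), 1e-300))


def contingency_tests(x: int, y: int, N1: int, N2: int,
                      continuity: bool = False) -> tuple[float, float]:
    """Fisher exact (two-sided, point-probability rule) and 2x2 chi-squared
    p-values for the table [[x, N1-x], [y, N2-y]]."""
    if x > N1 or y > N2:
        raise ValueError("count exceeds its library total")
    table = np.array([[x, N1 - x], [y, N2 - y]])
    # two-sided Fisher by the point-probability rule, vectorised over the
    # hypergeometric support (scipy's generic path is prohibitively slow for
    # the large counts a deep library produces)
    n = x + y
    lo, hi = max(0, n - N2), min(n, N1)
    ks = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(ks, N1 + N2, N1, n)
    p_obs = stats.hypergeom.pmf(x, N1 + N2, N1, n)
    p_fisher = float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-9)].sum()))
    if table.sum() == 0 or (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        p_chi2 = 1.0
    else:
        p_chi2 = float(stats.chi2_contingency(table, correction=continuity)[1])
    return p_fisher, p_chi2


# ---------------------------------------------------------------------------
# call rules

STATUSES = ("up", "down", "not_significant", "specific_A", "specific_B", "filtered")


def call_de(
    em: ExpressionMatrix,
    pair: tuple[str, str],
    alpha: float = 0.05,
    lfc: float = 1.0,
    test_policy: str = "ac",
    ne_filter: float = 1.0,
) -> pd.DataFrame:
    """Differential-expression calls for one library pair (A, B).

    Rows with NE below ``ne_filter`` in every library are ``filtered`` and
    excluded from testing and from the Bonferroni family. Rows with zero NE
    in exactly one member of the pair are ``specific_A``/``specific_B`` and
    are not tested. Remaining rows are tested per ``test_policy`` ('ac' =
    Audic-Claverie, 'fisher', 'chi2', or 'consensus' = the maximum of the
    three p-values); the working p-value is Bonferroni-multiplied by the
    number of tested rows. Status is ``up``/``down`` when the adjusted p is
    below ``alpha`` and log2(NE_A/NE_B) exceeds ``lfc`` in magnitude.
    """
    if test_policy not in TEST_POLICIES:
        raise ValueError(f"unknown test_policy {test_policy!r}")
    a, b = pair
    if a not in em.libraries or b not in em.libraries:
        raise KeyError(f"pair {pair} not in matrix libraries {em.libraries}")
    N1, N2 = float(em.totals[a]), float(em.totals[b])
    filtered_mask = (em.ne < ne_filter).all(axis=1)

    rows = []
    for mid in em.counts.index:
        x, y = int(em.counts.at[mid, a]), int(em.counts.at[mid, b])
        nea, neb = float(em.ne.at[mid, a]), float(em.ne.at[mid, b])
        row = dict(mirna=mid, count_A=x, count_B=y, ne_A=nea, ne_B=neb,
                   log2fc=np.nan, p_ac=np.nan, p_fisher=np.nan,
                   p_chi2=np.nan, p_adjusted=np.nan)
        if filtered_mask[mid]:
            row["status"] = "filtered"
        elif nea == 0 and neb == 0:
            row["status"] = "filtered"
        elif neb == 0:
            row["status"] = "specific_A"
        elif nea == 0:
            row["status"] = "specific_B"
        else:
            row["log2fc"] = np.log2(nea / neb)
            row["p_ac"] = audic_claverie_p(x, y, N1, N2)
            row["p_fisher"], row["p_chi2"] = contingency_tests(
                x, y, int(N1), int(N2))
            row["status"] = "tested"
        rows.append(row)
    df = pd.DataFrame(rows).set_index("mirna")

    tested = df["status"] == "tested"
    n_tests = int(tested.sum())
    policy_p = {
        "ac": df["p_ac"],
        "fisher": df["p_fisher"],
        "chi2": df["p_chi2"],
        "consensus": df[["p_ac", "p_fisher", "p_chi2"]].max(axis=1),
    }[test_policy]
    df.loc[tested, "p_adjusted"] = np.minimum(1.0, policy_p[tested] * n_tests)

    sig = tested & (df["p_adjusted"] < alpha)
    df.loc[tested, "status"] = "not_significant"
    df.loc[sig & (df["log2fc"] > lfc), "status"] = "up"
    df.loc[sig & (df["log2fc"] < -lfc), "status"] = "down"

    # abundance tiers from each library's mean copy number over the matrix
    for col, lib in (("tier_A", a), ("tier_B", b)):
        mean = float(em.counts[lib].mean())
        cnt = df["count_A"] if col == "tier_A" else df["count_B"]
        df[col] = [abundance_tier(c, mean) if mean > 0 else "Low" for c in cnt]
    return df


def plot_values(em: ExpressionMatrix, pair: tuple[str, str],
                zero_value: float = 0.01) -> pd.DataFrame:
    """NE pairs for log-scale scatter plotting, zeros replaced by 0.01.

    The replacement applies only to the returned plotting table; the
    expression matrix is left untouched.
    """
    a, b = pair
    out = em.ne[[a, b]].copy()
    out[out == 0] = zero_value
    return out


def abundance_tier(count: float, mean: float) -> str:
    """Expression tier of a raw read count against the dataset mean copy.

    High: above the mean. Middle: above 10 and at most the mean. Low: at
    most 10 reads. Boundary counts (exactly 10, exactly the mean) are
    assigned to the lower tier.
    """
    if mean <= 0:
        raise ValueError("dataset mean copy must be positive")
    if count > mean:
        return "High"
    if count > 10:
        return "Middle"
    return "Low"


# ---------------------------------------------------------------------------
# qPCR relative quantification

def ddct(ct_target_treated: float, ct_ref_treated: float,
         ct_target_control: float, ct_ref_control: float) -> float:
    """Relative quantity by the 2^(-ddCt) method.

    dCt = Ct(target) - Ct(reference) within each condition; ddCt is the
    treated-minus-control difference; RQ = 2^(-ddCt), so the control-vs-
    itself ratio is 1 by construction.
    """
    for v in (ct_target_treated, ct_ref_treated, ct_target_control, ct_ref_control):
        if not np.isfinite(v) or v <= 0:
            raise ValueError("Ct values must be finite and positive")
    d_treated = ct_target_treated - ct_ref_treated
    d_control = ct_target_control - ct_ref_control
    return float(2.0 ** (-(d_treated - d_control)))


def welch_t(group_a, group_b) -> tuple[float, float]:
    """Two-sided Welch t-test (unequal variances)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two observations")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)
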