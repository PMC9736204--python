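"""Group comparison statistics and the combined CNA + mutation matrix.

Contains the exact two-sided Fisher test used for gene- and region-level
group comparisons (hypergeometric tail summation in log space), an exact /
asymptotic Mann-Whitney U for burden comparisons, Kaplan-Meier and log-rank
survival summaries, the favorable/adverse prognosis dichotomy, and the
oncoprint-style gene x sample alteration matrix that integrates gene-level
copy-number calls with selected mutations.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from statsmodels.stats.multitest import multipletests

from .variants import VariantCandidate

__all__ = [
    "fisher_exact_two_sided",
    "benjamini_hochberg",
    "mann_whitney_u",
    "km_curve",
    "logrank_test",
    "assign_prognosis_group",
    "gene_level_cna",
    "AlterationMatrix",
    "build_alteration_matrix",
    "compare_mutation_frequencies",
    "GroupComparisonRow",
]

STATUSES = ("none", "mutation", "gain", "loss", "mutation_gain", "mutation_loss")
MUTATED_STATUSES = frozenset({"mutation", "mutation_gain", "mutation_loss"})


# ---------------------------------------------------------------------------
# elementary tests
# ---------------------------------------------------------------------------

def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Sums, over all tables with the observed margins, the hypergeometric
    probabilities not exceeding the observed table's probability (relative
    tolerance 1e-12 on the comparison). Computed with log-factorials; an
    all-zero table returns 1 by convention.
    """
    for x in (a, b, c, d):
        if x < 0 or x != int(x):
            raise ValueError("table entries must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    n = a + b + c + d
    if n == 0:
        return 1.0
    row1 = a + b
    col1 = a + c
    lo = max(0, col1 - (n - row1))
    hi = min(row1, col1)
    lgamma = math.lgamma

    def log_p(x: int) -> float:
        # hypergeometric pmf: C(row1, x) C(n-row1, col1-x) / C(n, col1)
        return (
            lgamma(row1 + 1)
            - lgamma(x + 1)
            - lgamma(row1 - x + 1)
            + lgamma(n - row1 + 1)
            - lgamma(col1 - x + 1)
            - lgamma(n - row1 - col1 + x + 1)
            - (lgamma(n + 1) - lgamma(col1 + 1) - lgamma(n - col1 + 1))
        )

    log_obs = log_p(a)
    cutoff = log_obs + math.log1p(1e-12)  # relative tolerance on the pmf comparison
    total = 0.0
    for x in range(lo, hi + 1):
        lp = log_p(x)
        if lp <= cutoff:
            total += math.exp(lp)
    return min(total, 1.0)


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted q-values (via statsmodels)."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def mann_whitney_u(x: Sequence[float], y: Sequence[float]):
    """Mann-Whitney U with a two-sided p-value.

    For m + n <= 12 the p-value is exact, by enumeration of all C(m+n, m)
    group assignments of the pooled values (ties handled naturally); larger
    samples use the normal approximation with tie and continuity corrections.
    Returns ``(U, p)`` where U counts (x_i > y_j) pairs plus half-ties.
    """
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    m, n = len(x), len(y)
    if m == 0 or n == 0:
        raise ValueError("both samples must be non-empty")

    def u_stat(xs, ys):
        u = 0.0
        for xi in xs:
            for yj in ys:
                if xi > yj:
                    u += 1.0
                elif xi == yj:
                    u += 0.5
        return u

    u_obs = u_stat(x, y)
    if m + n <= 12:
        pooled = x + y
        center = m * n / 2.0
        dev_obs = abs(u_obs - center)
        count = 0
        total = 0
        for idx in itertools.combinations(range(m + n), m):
            idx_set = set(idx)
            xs = [pooled[i] for i in idx]
            ys = [pooled[i] for i in range(m + n) if i not in idx_set]
            total += 1
            if abs(u_stat(xs, ys) - center) >= dev_obs - 1e-12:
                count += 1
        return u_obs, count / total
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return u_obs, float(res.pvalue)


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

def km_curve(times: Sequence[float], events: Sequence[bool]) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimate.

    Returns a DataFrame with columns ``time`` and ``survival`` (one row per
    observed time, censored entries reduce the risk set without a step).
    """
    times = np.asarray(list(times), dtype=float)
    events = np.asarray(list(events), dtype=bool)
    if times.size == 0:
        raise ValueError("empty survival input")
    if np.any(times <= 0):
        raise ValueError("survival times must be strictly positive")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_
    return pd.DataFrame(
        {"time": sf.index.to_numpy(dtype=float), "survival": sf.iloc[:, 0].to_numpy()}
    )


def logrank_test(groups: Sequence[tuple]):
    """Log-rank test across >= 2 groups of ``(times, events)`` pairs.

    Returns ``(chi2, p)`` with k-1 degrees of freedom for k groups.
    """
    if len(groups) < 2:
        raise ValueError("log-rank test needs at least two groups")
    all_times, all_events, labels = [], [], []
    for gi, (times, events) in enumerate(groups):
        for t, e in zip(times, events):
            all_times.append(float(t))
            all_events.append(bool(e))
            labels.append(gi)
    res = multivariate_logrank_test(all_times, labels, all_events)
    return float(res.test_statistic), float(res.p_value)


def assign_prognosis_group(
    first_course_response: str, relapse: bool
) -> str:
    """Favorable iff complete response to first-course chemotherapy and no relapse."""
    if first_course_response is None or relapse is None:
        raise ValueError("response and relapse must be resolved")
    if first_course_response not in ("CR", "PR", "other"):
        raise ValueError(f"unknown response {first_course_response!r}")
    return "favorable" if (first_course_response == "CR" and not relapse) else "adverse"


# ---------------------------------------------------------------------------
# combined alteration matrix
# ---------------------------------------------------------------------------

def gene_level_cna(
    calls: pd.DataFrame, gene_map: Mapping[str, tuple]
) -> pd.DataFrame:
    """Collapse segment-level calls to per-gene per-sample gain/loss/none.

    A gene takes the call of the segment class (gain/loss/neutral) covering
    the strict majority (> 50%) of its span; uncovered span counts as
    neutral, and ties or exact 50/50 splits resolve to ``none``. ``gene_map``
    maps gene name -> (chrom, start, end) in 0-based half-open coordinates.
    Returns a long DataFrame with columns ``sample``, ``gene``, ``call``.
    """
    rows = []
    by_sample = dict(tuple(calls.groupby("sample", sort=True)))
    for sample, seg in by_sample.items():
        seg_by_chrom = dict(tuple(seg.groupby("chrom", sort=False)))
        for gene, (chrom, gstart, gend) in gene_map.items():
            span = gend - gstart
            if span <= 0:
                raise ValueError(f"gene {gene} has empty interval")
            covered = {"gain": 0, "loss": 0, "neutral": 0}
            sub = seg_by_chrom.get(chrom)
            if sub is not None:
                s = np.maximum(sub["start"].to_numpy(), gstart)
                e = np.minimum(sub["end"].to_numpy(), gend)
                ov = np.maximum(e - s, 0)
                for call_label, length in zip(sub["call"], ov):
                    covered[call_label] += int(length)
            # uncovered span counts as neutral
            covered["neutral"] = span - covered["gain"] - covered["loss"]
            call = "none"
            if covered["gain"] * 2 > span and covered["gain"] > covered["loss"]:
                call = "gain"
            elif covered["loss"] * 2 > span and covered["loss"] > covered["gain"]:
                call = "loss"
            rows.append({"sample": sample, "gene": gene, "call": call})
    return pd.DataFrame(rows)


@dataclass
class AlterationMatrix:
    """Gene x sample status matrix with per-sample group labels."""

    status: pd.DataFrame  # index genes, columns samples, values in STATUSES
    groups: pd.Series  # index samples -> group label

    def gene_counts(self, group: Optional[str] = None) -> pd.DataFrame:
        """Per-gene counts of each status (optionally within one group)."""
        df = self.status
        if group is not None:
            df = df.loc[:, self.groups[self.groups == group].index]
        counts = {s: (df == s).sum(axis=1) for s in STATUSES}
        return pd.DataFrame(counts)

    def mutated_cases(self, gene: str, group: Optional[str] = None):
        """Case ids whose status for ``gene`` includes a mutation component."""
        row = self.status.loc[gene]
        if group is not None:
            row = row[self.groups[self.groups == group].index]
        return [s for s, v in row.items() if v in MUTATED_STATUSES]


def build_alteration_matrix(
    selected_mutations: Iterable[VariantCandidate],
    gene_cna: pd.DataFrame,
    panel: Sequence[str],
    samples: Sequence[str],
    groups: Optional[Mapping[str, str]] = None,
) -> AlterationMatrix:
    """Combine selected mutations and gene-level CNA calls into one matrix.

    Cell values: ``none``, ``mutation``, ``gain``, ``loss``,
    ``mutation_gain``, ``mutation_loss``. Duplicate mutation rows for one
    (gene, sample) pair collapse into a single mutation component.
    """
    samples = list(samples)
    status = pd.DataFrame("none", index=list(panel), columns=samples, dtype=object)
    cna_lookup: dict = {}
    if gene_cna is not None and len(gene_cna):
        for _, r in gene_cna.iterrows():
            cna_lookup[(r["gene"], r["sample"])] = r["call"]
    mutated = set()
    for m in selected_mutations:
        if m.gene in status.index and m.sample_id in samples:
            mutated.add((m.gene, m.sample_id))
    for gene in status.index:
        for sample in samples:
            cna = cna_lookup.get((gene, sample), "none")
            has_mut = (gene, sample) in mutated
            if has_mut and cna == "gain":
                v = "mutation_gain"
            elif has_mut and cna == "loss":
                v = "mutation_loss"
            elif has_mut:
                v = "mutation"
            elif cna in ("gain", "loss"):
                v = cna
            else:
                v = "none"
            status.at[gene, sample] = v
    group_series = pd.Series(
        {s: (groups or {}).get(s, "") for s in samples}, name="group"
    )
    return AlterationMatrix(status=status, groups=group_series)


@dataclass(frozen=True)
class GroupComparisonRow:
    feature: str
    count_a: int
    size_a: int
    count_b: int
    size_b: int
    odds_ratio: float
    p_two_sided: float
    q_bh: float = float("nan")


def compare_mutation_frequencies(
    matrix: AlterationMatrix, group_a: str, group_b: str
) -> pd.DataFrame:
    """Per-gene Fisher comparison of mutated-case fractions between two groups.

    A case counts as mutated for a gene when its matrix status contains a
    mutation component. Raw two-sided Fisher p is primary; BH q accompanies
    it. Rows are sorted by (p, gene).
    """
    samples_a = list(matrix.groups[matrix.groups == group_a].index)
    samples_b = list(matrix.groups[matrix.groups == group_b].index)
    if not samples_a or not samples_b:
        raise ValueError("both groups must be non-empty")
    if set(samples_a) & set(samples_b):
        raise ValueError("groups must be disjoint")
    rows = []
    for gene in matrix.status.index:
        row = matrix.status.loc[gene]
        ca = sum(row[s] in MUTATED_STATUSES for s in samples_a)
        cb = sum(row[s] in MUTATED_STATUSES for s in samples_b)
        na, nb = len(samples_a), len(samples_b)
        p = fisher_exact_two_sided(ca, na - ca, cb, nb - cb)
        denom = ca * (nb - cb)
        num = cb * (na - ca)
        odds = float("inf") if num == 0 and denom > 0 else (
            float("nan") if num == 0 else denom / num
        )
        rows.append(
            {
                "gene": gene,
                "count_a": ca,
                "size_a": na,
                "freq_a": ca / na,
                "count_b": cb,
                "size_b": nb,
                "freq_b": cb / nb,
                "odds_ratio": odds,
                "p": p,
            }
        )
    df = pd.DataFrame(rows)
    df["q_bh"] = benjamini_hochberg(df["p"])
    return df.sort_values(["p", "gene"], kind="stable").reset_index(drop=True)
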