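"""Cross-locality parallel candidates and their statistics.

A SNP enters the parallel set when it is an RDA outlier in every locality
with the same assigned predictor and the same correlation sign — a natural
multiplicity control, since a three-way coincidence of axis extremeness,
predictor and sign is vanishingly rare under neutrality. The module also
provides the exact multi-set intersection test (iterated hypergeometric
folding, as in SuperExactTest) and the settler-versus-survivor
allele-proportion chi-square.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2, hypergeom

from selmort.cohort import MISSING
from selmort.gea import RdaScan


@dataclass
class ParallelSet:
    """SNPs flagged in all localities with matching predictor and sign."""

    members: pd.DataFrame  # snp -> predictor, sign, per-locality r
    dropped: pd.DataFrame  # snp -> reason (absent / predictor mismatch / sign mismatch)
    localities: list[str]


def intersect_parallel(scans: dict[str, RdaScan] | dict[str, pd.DataFrame]) -> ParallelSet:
    """Intersect per-locality candidate tables into the parallel set.

    ``scans`` maps locality name to an :class:`~selmort.gea.RdaScan` (its
    ``outliers`` table is used) or directly to a candidate DataFrame indexed
    by SNP with ``predictor`` and ``sign`` columns. The result is invariant
    to locality order.
    """
    if len(scans) < 2:
        raise ValueError("need candidate tables from at least two localities")
    localities = sorted(scans)
    tables = {}
    for loc in localities:
        t = scans[loc]
        tables[loc] = t.outliers if isinstance(t, RdaScan) else t

    all_snps = sorted(set().union(*(set(t.index) for t in tables.values())))
    member_rows, dropped_rows = [], []
    for snp in all_snps:
        present = [loc for loc in localities if snp in tables[loc].index]
        if len(present) < len(localities):
            dropped_rows.append((snp, "absent"))
            continue
        preds = {tables[loc].loc[snp, "predictor"] for loc in localities}
        if len(preds) > 1:
            dropped_rows.append((snp, "predictor mismatch"))
            continue
        signs = {int(tables[loc].loc[snp, "sign"]) for loc in localities}
        if len(signs) > 1:
            dropped_rows.append((snp, "sign mismatch"))
            continue
        row = {"predictor": preds.pop(), "sign": signs.pop()}
        for loc in localities:
            row[f"r_{loc}"] = float(tables[loc].loc[snp, "r"])
        member_rows.append((snp, row))
    members = pd.DataFrame(
        [r for _, r in member_rows],
        index=pd.Index([s for s, _ in member_rows], name="snp"),
    )
    if members.empty:
        members = pd.DataFrame(
            columns=["predictor", "sign"] + [f"r_{loc}" for loc in localities]
        )
        members.index.name = "snp"
    dropped = pd.DataFrame(dropped_rows, columns=["snp", "reason"]).set_index("snp")
    return ParallelSet(members=members, dropped=dropped, localities=localities)


# ---------------------------------------------------------------------- #
# exact multi-set intersection test


@dataclass
class IntersectionTest:
    category: tuple
    set_sizes: tuple[int, ...]
    background: int
    observed: int
    p_value: float
    pmf: np.ndarray  # exact distribution of the intersection size


def multiset_intersection_test(
    set_sizes, background: int, observed: int, category: tuple = ()
) -> IntersectionTest:
    """Exact tail probability of a k-way overlap of uniform random subsets.

    For independent uniform subsets A_1..A_k of a background of size N, the
    intersection size is distributed by iterated hypergeometric folding:
    |A_1 ∩ A_2| ~ Hypergeom(N, n_1, n_2) and, conditional on a running
    intersection of size m, folding in A_i gives Hypergeom(N, m, n_i).
    Returns P(|∩ A_i| >= observed) and the full exact distribution.
    """
    sizes = tuple(int(s) for s in set_sizes)
    n = int(background)
    if len(sizes) < 2:
        raise ValueError("need at least two sets")
    if any(s < 0 or s > n for s in sizes):
        raise ValueError("set sizes must lie in [0, background]")
    if observed < 0 or observed > min(sizes):
        raise ValueError(
            f"impossible overlap {observed} for set sizes {sizes}"
        )
    m_max = min(sizes[0], sizes[1])
    support = np.arange(m_max + 1)
    pmf = hypergeom.pmf(support, n, sizes[0], sizes[1])
    for size in sizes[2:]:
        # fold: P(next = j) = sum_m P(m) * Hypergeom(j; N, m, size)
        new_max = min(m_max, size)
        new_support = np.arange(new_max + 1)
        fold = hypergeom.pmf(new_support[:, None], n, support[None, :], size)
        pmf = fold @ pmf
        m_max, support = new_max, new_support
    pmf = np.clip(pmf, 0.0, None)
    p = float(min(1.0, pmf[observed:].sum()))
    return IntersectionTest(
        category=category,
        set_sizes=sizes,
        background=n,
        observed=int(observed),
        p_value=p,
        pmf=pmf,
    )


# ---------------------------------------------------------------------- #
# allele-frequency-change chi-square


@dataclass
class AlleleFreqTest:
    snp: str
    table: np.ndarray  # 2x2 counts: rows (ref, alt), cols (settler, survivor)
    statistic: float
    p_value: float
    expected: np.ndarray
    low_expected: bool
    applicable: bool
    reason: str = ""


def allele_counts(calls: np.ndarray) -> tuple[int, int]:
    """(ref, alt) allele copies from 0/1/2 codes, ignoring missing calls."""
    called = calls[calls != MISSING]
    alt = int(called.sum())
    return 2 * called.size - alt, alt


def allele_freq_change_test(
    settler_counts: tuple[int, int],
    survivor_counts: tuple[int, int],
    snp: str = "",
) -> AlleleFreqTest:
    """Pearson chi-square (no continuity correction) on the 2x2 allele table.

    Counts are (ref, alt) allele copies per age group — two per homozygote,
    one per heterozygote. A zero row or column margin makes the statistic
    undefined and the test is returned as not applicable with the reason.
    """
    obs = np.array([settler_counts, survivor_counts], dtype=float).T  # (allele, group)
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    total = obs.sum()
    if (row == 0).any() or (col == 0).any() or total == 0:
        return AlleleFreqTest(
            snp=snp,
            table=obs,
            statistic=float("nan"),
            p_value=float("nan"),
            expected=np.full_like(obs, np.nan),
            low_expected=False,
            applicable=False,
            reason="zero margin in the allele-count table",
        )
    expected = np.outer(row, col) / total
    stat = float(((obs - expected) ** 2 / expected).sum())
    p = float(chi2.sf(stat, df=1))
    return AlleleFreqTest(
        snp=snp,
        table=obs,
        statistic=stat,
        p_value=p,
        expected=expected,
        low_expected=bool((expected < 5).any()),
        applicable=True,
    )


# ---------------------------------------------------------------------- #
# predictor-combination categorization


def associated_predictors(
    parallel: ParallelSet,
    corr_by_locality: dict[str, pd.DataFrame],
    runner_up: float = 0.9,
) -> pd.Series:
    """Predictor set per parallel SNP (assigned plus near-tied predictors).

    A SNP is associated with every predictor whose |r| reaches ``runner_up``
    times the assigned predictor's |r| in every locality, with a consistent
    sign across localities. Returns a Series of frozensets indexed by SNP.
    """
    out = {}
    common = set.intersection(
        *(set(c.columns) for c in corr_by_locality.values())
    )
    for snp, row in parallel.members.iterrows():
        assigned = row["predictor"]
        assoc = {assigned}
        for q in sorted(common):
            if q == assigned:
                continue
            ok = True
            signs = set()
            for loc in parallel.localities:
                corr = corr_by_locality[loc]
                if snp not in corr.index:
                    ok = False
                    break
                r_q = corr.loc[snp, q]
                r_a = corr.loc[snp, assigned]
                if abs(r_q) < runner_up * abs(r_a):
                    ok = False
                    break
                signs.add(int(np.sign(r_q)))
            if ok and len(signs) == 1:
                assoc.add(q)
        out[snp] = frozenset(assoc)
    return pd.Series(out, dtype=object)


def categorize_by_predictor(
    parallel: ParallelSet,
    corr_by_locality: dict[str, pd.DataFrame] | None = None,
    runner_up: float = 0.9,
) -> pd.DataFrame:
    """Group parallel SNPs by their exact predictor combination.

    Each SNP contributes to exactly one combination category (its full set
    of associated predictors). Every observed combination is tested with
    :func:`multiset_intersection_test` against the per-predictor candidate
    counts over the parallel-set background (SuperExactTest semantics: the
    observed statistic for a combination is the number of SNPs associated
    with at least that combination).
    """
    if parallel.members.empty:
        return pd.DataFrame(
            columns=["predictors", "n_snps", "observed_superset", "p_value"]
        )
    if corr_by_locality is None:
        assoc = pd.Series(
            {s: frozenset({p}) for s, p in parallel.members["predictor"].items()},
            dtype=object,
        )
    else:
        assoc = associated_predictors(parallel, corr_by_locality, runner_up)
    background = len(assoc)
    per_pred: dict[str, set] = {}
    for snp, preds in assoc.items():
        for q in preds:
            per_pred.setdefault(q, set()).add(snp)
    rows = []
    for combo in sorted({tuple(sorted(v)) for v in assoc}, key=lambda c: (len(c), c)):
        exact = int(sum(1 for v in assoc if tuple(sorted(v)) == combo))
        superset = int(sum(1 for v in assoc if set(combo) <= v))
        if len(combo) >= 2:
            test = multiset_intersection_test(
                [len(per_pred[q]) for q in combo],
                background,
                superset,
                category=combo,
            )
            p = test.p_value
        else:
            p = float("nan")  # a singleton category has no intersection test
        rows.append((combo, exact, superset, p))
    return pd.DataFrame(
        rows, columns=["predictors", "n_snps", "observed_superset", "p_value"]
    )
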