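"""One-way ANOVA with Tukey HSD post hoc and compact-letter display."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["AnovaResult", "anova_oneway", "tukey_letters"]


@dataclass
class AnovaResult:
    groups: list[str]
    means: np.ndarray
    ses: np.ndarray                # standard errors of the group means
    ns: np.ndarray
    F: float
    p: float
    tukey_p: np.ndarray            # pairwise p-value matrix, group order
    letters: list[str] | None = None


def anova_oneway(values: np.ndarray, groups: np.ndarray) -> AnovaResult:
    """Classical equal-variance one-way ANOVA plus Tukey HSD p-values.

    F = MS_between / MS_within; the p-value comes from the F distribution
    and pairwise comparisons from the studentized range distribution.
    """
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    names = list(dict.fromkeys(groups.tolist()))
    if len(names) < 2:
        raise ValueError("at least two groups required")
    samples = [values[groups == g] for g in names]
    ns = np.array([len(s) for s in samples])
    if (ns < 2).any():
        small = names[int(np.argmin(ns))]
        raise ValueError(f"group {small!r} has fewer than 2 observations")

    means = np.array([s.mean() for s in samples])
    grand = values.mean()
    n_total = len(values)
    k = len(names)
    ss_between = float((ns * (means - grand) ** 2).sum())
    ss_within = float(sum(((s - m) ** 2).sum() for s, m in zip(samples, means)))
    df_b, df_w = k - 1, n_total - k
    ms_w = ss_within / df_w
    if ms_w == 0:
        F = 0.0 if ss_between == 0 else float("inf")
        p = 1.0 if ss_between == 0 else 0.0
    else:
        F = (ss_between / df_b) / ms_w
        p = float(sps.f.sf(F, df_b, df_w))

    # Tukey-Kramer: q_ij = |mean_i - mean_j| / sqrt(MSw/2 (1/n_i + 1/n_j)),
    # referred to the studentized range distribution with k groups, df_w
    tukey_p = np.ones((k, k))
    if ms_w > 0:
        iu, ju = np.triu_indices(k, 1)
        q = np.abs(means[iu] - means[ju]) / np.sqrt(
            ms_w / 2 * (1 / ns[iu] + 1 / ns[ju])
        )
        pq = sps.studentized_range.sf(q, k, df_w)
        tukey_p[iu, ju] = tukey_p[ju, iu] = pq
    else:
        off = ~np.eye(k, dtype=bool)
        distinct = np.abs(means[:, None] - means[None, :]) > 0
        tukey_p[off & distinct] = 0.0

    ses = np.array([s.std(ddof=1) / np.sqrt(len(s)) for s in samples])
    return AnovaResult(
        groups=names, means=means, ses=ses, ns=ns,
        F=float(F), p=p, tukey_p=tukey_p,
    )


def tukey_letters(result: AnovaResult, alpha: float = 0.05) -> dict[str, str]:
    """Compact-letter display via the insert-and-absorb algorithm.

    Groups sharing a letter are not significantly different at ``alpha``;
    letters are assigned in descending-mean order so "a" marks the
    largest mean.  The letters are also stored on ``result``.
    """
    order = np.argsort(-result.means, kind="stable")
    names = [result.groups[i] for i in order]
    k = len(names)
    sig = {
        (a, b)
        for a in range(k)
        for b in range(a + 1, k)
        if result.tukey_p[order[a], order[b]] < alpha
    }

    columns: list[set[int]] = [set(range(k))]
    for i, j in sorted(sig):
        for col in [c for c in columns if i in c and j in c]:
            columns.remove(col)
            columns.extend([col - {j}, col - {i}])
        # absorb: keep only maximal, distinct sets
        maximal = []
        for c in columns:
            if not any(c < d for d in columns) and c not in maximal:
                maximal.append(c)
        columns = maximal
    # order columns by their highest-mean member for stable lettering
    columns.sort(key=min)

    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {name: "" for name in names}
    for li, col in enumerate(columns):
        for i in sorted(col):
            letters[names[i]] += alphabet[li]
    result.letters = [letters[g] for g in result.groups]
    return letters
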