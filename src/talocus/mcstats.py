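"""Monte Carlo one-way ANOVA and a Monte Carlo Tukey-style pairwise test.

Significance is assessed by recomputing the statistic over uniformly random
label shuffles that preserve group sizes, with the add-one p-value convention
p = (1 + #{null >= observed}) / (1 + iterations), which never returns zero.
The pairwise test controls the family-wise error by comparing each observed
studentized mean difference to the null distribution of the *maximum*
studentized difference over all pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb, sqrt
from typing import Callable, Sequence

import numpy as np

_CHUNK = 2000  # permutation rows held in memory at once


@dataclass
class GroupedData:
    """Numeric observations with group labels (values reordered group-wise)."""

    values: np.ndarray
    labels: list[str]
    groups: list[str] = field(init=False)
    sizes: np.ndarray = field(init=False)

    def __init__(self, values: Sequence[float], labels: Sequence[str]):
        values = np.asarray(values, dtype=float)
        labels = list(labels)
        if len(values) != len(labels):
            raise ValueError("values and labels differ in length")
        groups = sorted(set(labels))
        if len(groups) < 2:
            raise ValueError("need at least two groups")
        order = np.argsort([groups.index(l) for l in labels], kind="stable")
        self.values = values[order]
        self.labels = [labels[i] for i in order]
        self.groups = groups
        self.sizes = np.array([self.labels.count(g) for g in groups])
        if (self.sizes < 2).any():
            raise ValueError("every group needs at least two observations")

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def k(self) -> int:
        return len(self.groups)

    def group_values(self) -> list[np.ndarray]:
        out = []
        ofs = 0
        for sz in self.sizes:
            out.append(self.values[ofs:ofs + sz])
            ofs += sz
        return out

    def _bounds(self) -> list[tuple[int, int]]:
        ofs = 0
        bounds = []
        for sz in self.sizes:
            bounds.append((ofs, ofs + int(sz)))
            ofs += int(sz)
        return bounds


def _sums_to_f(sums: np.ndarray, sizes: np.ndarray, sst: float,
               grand: float, n: int, k: int) -> np.ndarray:
    ssb = (sums ** 2 / sizes).sum(axis=-1) - grand ** 2 / n
    ssw = sst - ssb
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / (k - 1)) / (ssw / (n - k))
    return f


def f_statistic(data: GroupedData) -> float:
    """Classic one-way F = between-group MS / within-group MS."""
    v = data.values
    sst = float(((v - v.mean()) ** 2).sum())
    if sst == 0:
        raise ValueError("total variance is zero; F undefined")
    sums = np.array([g.sum() for g in data.group_values()])
    ssb = float((sums ** 2 / data.sizes).sum() - v.sum() ** 2 / data.n)
    ssw = sst - ssb
    if ssw <= 1e-12:
        raise ValueError("within-group variance is zero; F undefined")
    return (ssb / (data.k - 1)) / (ssw / (data.n - data.k))


@dataclass
class GroupComparison:
    """Observed statistic, Monte Carlo null and p-values of one comparison."""

    observed_f: float
    null_f: np.ndarray
    p_global: float
    pairwise: dict[tuple[str, str], tuple[float, float]] | None
    iterations: int
    seed: int | None


def _null_group_sums(data: GroupedData, iterations: int,
                     rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """(iterations, k) group sums and (iterations,) within-SS under shuffling."""
    v = data.values
    bounds = data._bounds()
    sst = float(((v - v.mean()) ** 2).sum())
    grand = float(v.sum())
    sums_all = np.empty((iterations, data.k))
    done = 0
    while done < iterations:
        rows = min(_CHUNK, iterations - done)
        perms = rng.permuted(np.tile(v, (rows, 1)), axis=1)
        for gi, (lo, hi) in enumerate(bounds):
            sums_all[done:done + rows, gi] = perms[:, lo:hi].sum(axis=1)
        done += rows
    ssb = (sums_all ** 2 / data.sizes).sum(axis=1) - grand ** 2 / data.n
    ssw = sst - ssb
    return sums_all, ssw


def mc_anova(data: GroupedData, iterations: int = 10_000,
             seed: int | None = None) -> GroupComparison:
    """Permutation one-way ANOVA: shuffle labels, recompute F, add-one p."""
    f_obs = f_statistic(data)
    rng = np.random.default_rng(seed)
    v = data.values
    sst = float(((v - v.mean()) ** 2).sum())
    grand = float(v.sum())
    sums, ssw = _null_group_sums(data, iterations, rng)
    ssb = (sums ** 2 / data.sizes).sum(axis=1) - grand ** 2 / data.n
    with np.errstate(divide="ignore", invalid="ignore"):
        null_f = (ssb / (data.k - 1)) / (ssw / (data.n - data.k))
    null_f = np.nan_to_num(null_f, nan=np.inf)
    p = (1 + int((null_f >= f_obs - 1e-12).sum())) / (1 + iterations)
    return GroupComparison(f_obs, null_f, p, None, iterations, seed)


def _pairwise_q(means: np.ndarray, msw, sizes: np.ndarray
                ) -> np.ndarray:
    """Studentized mean differences q_ij for all pairs (last axis)."""
    k = sizes.shape[0]
    pairs = list(combinations(range(k), 2))
    out = np.empty(means.shape[:-1] + (len(pairs),))
    for pi, (i, j) in enumerate(pairs):
        se = np.sqrt(msw * (1.0 / sizes[i] + 1.0 / sizes[j]) / 2.0)
        out[..., pi] = np.abs(means[..., i] - means[..., j]) / se
    return out


def mc_tukey(data: GroupedData, iterations: int = 10_000,
             seed: int | None = None) -> dict[tuple[str, str], tuple[float, float]]:
    """Pairwise studentized mean differences against a max-statistic null.

    For each shuffle, the maximum q over all pairs is recorded; each observed
    pair q is compared to that single null distribution (family-wise control).
    Returns {(group_i, group_j): (q_observed, p)}.
    """
    f_statistic(data)  # raises on degenerate data
    rng = np.random.default_rng(seed)
    v = data.values
    means_obs = np.array([g.mean() for g in data.group_values()])
    msw_obs = _msw(data)
    q_obs = _pairwise_q(means_obs, msw_obs, data.sizes)

    sums, ssw = _null_group_sums(data, iterations, rng)
    means = sums / data.sizes
    msw = np.maximum(ssw / (data.n - data.k), 1e-300)
    q_null = _pairwise_q(means, msw, data.sizes)
    max_null = q_null.max(axis=1)

    out = {}
    for pi, (i, j) in enumerate(combinations(range(data.k), 2)):
        p = (1 + int((max_null >= q_obs[pi] - 1e-12).sum())) / (1 + iterations)
        out[(data.groups[i], data.groups[j])] = (float(q_obs[pi]), p)
    return out


def _msw(data: GroupedData) -> float:
    ssw = sum(float(((g - g.mean()) ** 2).sum()) for g in data.group_values())
    return ssw / (data.n - data.k)


def mc_anova_tukey(data: GroupedData, iterations: int = 10_000,
                   seed: int | None = None) -> GroupComparison:
    """Convenience wrapper: global permutation ANOVA plus pairwise table."""
    cmp_ = mc_anova(data, iterations=iterations, seed=seed)
    cmp_.pairwise = mc_tukey(data, iterations=iterations, seed=seed)
    return cmp_


def exhaustive_permutation_p(data: GroupedData,
                             statistic: Callable[[list[np.ndarray]], float],
                             max_permutations: int = 1_000_000) -> float:
    """Exact permutation p over all distinct group-size-preserving assignments.

    ``statistic`` receives the per-group value arrays.  The observed labeling
    is one of the enumerated assignments, so p = #{stat >= observed} / total
    is never zero.
    """
    sizes = [int(s) for s in data.sizes]
    n = data.n
    total = 1
    rem = n
    for s in sizes:
        total *= comb(rem, s)
        rem -= s
    if total > max_permutations:
        raise ValueError(f"{total} assignments exceed the {max_permutations} guard")
    obs = statistic(data.group_values())
    v = data.values
    count = 0

    def recurse(remaining: tuple[int, ...], gi: int, chosen: list[np.ndarray]):
        nonlocal count
        if gi == len(sizes) - 1:
            groups = chosen + [v[list(remaining)]]
            if statistic(groups) >= obs - 1e-12:
                count += 1
            return
        for idx in combinations(remaining, sizes[gi]):
            rest = tuple(x for x in remaining if x not in set(idx))
            recurse(rest, gi + 1, chosen + [v[list(idx)]])

    recurse(tuple(range(n)), 0, [])
    return count / total


def f_from_groups(groups: list[np.ndarray]) -> float:
    """F statistic from per-group arrays (for use with the exhaustive oracle)."""
    all_v = np.concatenate(groups)
    sst = float(((all_v - all_v.mean()) ** 2).sum())
    ssb = sum(len(g) * (g.mean() - all_v.mean()) ** 2 for g in groups)
    ssw = sst - ssb
    n, k = len(all_v), len(groups)
    if ssw <= 1e-12:
        return np.inf
    return float((ssb / (k - 1)) / (ssw / (n - k)))


def abs_mean_difference(groups: list[np.ndarray]) -> float:
    """|mean(group1) - mean(group2)| (two-group exhaustive-oracle statistic)."""
    if len(groups) != 2:
        raise ValueError("statistic defined for two groups")
    return float(abs(groups[0].mean() - groups[1].mean()))


def max_studentized_difference(groups: list[np.ndarray]) -> float:
    """Maximum pairwise studentized mean difference (Tukey-style statistic)."""
    all_v = np.concatenate(groups)
    n, k = len(all_v), len(groups)
    ssw = sum(float(((g - g.mean()) ** 2).sum()) for g in groups)
    msw = ssw / (n - k)
    if msw <= 0:
        return np.inf
    best = 0.0
    for g1, g2 in combinations(groups, 2):
        q = abs(g1.mean() - g2.mean()) / sqrt(msw * (1 / len(g1) + 1 / len(g2)) / 2)
        best = max(best, q)
    return best
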