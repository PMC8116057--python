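"""Enrichment and association statistics for shifted loci.

Includes the permutation test for protein-domain-family enrichment
among significantly shifted loci (domains shuffled between tested loci,
19,999 permutations by default), the Yates-corrected 2x2 chi-square
association test, the hypergeometric overlap test, the Welch t-test for
group differences, and maximal-overlap assignment of sliding-window
metrics (e.g. synteny diversity) to loci.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .emd import bh_adjust
from .read_io import ValidationError


@dataclass(frozen=True)
class DomainAssignment:
    locus_id: str
    domain_family_id: str
    count: int = 1

    def __post_init__(self):
        if self.count < 1:
            raise ValidationError("domain assignment count must be >= 1")


def domain_enrichment(
    assignments: Sequence[DomainAssignment],
    tested_loci: Iterable[str],
    significant_loci: Iterable[str],
    n_perm: int = 19999,
    rng: np.random.Generator | None = None,
    method: str = "montecarlo",
    max_exhaustive: int = 200_000,
) -> pd.DataFrame:
    """Permutation test for domain-family enrichment among significant loci.

    The observed statistic per family is the number of significant loci
    carrying at least one domain of the family.  Under the null, domain
    assignments are shuffled between tested loci by applying a random
    bijection of loci to the whole assignment table, which preserves the
    assignment multiset (and per-locus domain counts).  p-values use the
    (1 + exceedances) / (1 + draws) convention and are BH-corrected
    across families.

    ``method='exhaustive'`` enumerates, per family, every placement of
    the family's loci among the tested loci (all subsets of the same
    cardinality) — feasible only for small inputs and used for exact
    verification.
    """
    tested = sorted(set(tested_loci))
    significant = set(significant_loci)
    if not significant <= set(tested):
        raise ValidationError("significant loci must be a subset of tested loci")
    for a in assignments:
        if a.locus_id not in set(tested):
            raise ValidationError(f"assignment for untested locus {a.locus_id}")
    families = sorted({a.domain_family_id for a in assignments})
    fam_idx = {f: i for i, f in enumerate(families)}
    loc_idx = {l: i for i, l in enumerate(tested)}
    m = len(tested)
    presence = np.zeros((len(families), m), dtype=bool)
    for a in assignments:
        presence[fam_idx[a.domain_family_id], loc_idx[a.locus_id]] = True
    sig_mask = np.array([l in significant for l in tested])
    observed = presence.astype(np.int64) @ sig_mask.astype(np.int64)

    if method == "exhaustive":
        pvals = np.ones(len(families))
        for i in range(len(families)):
            k = int(presence[i].sum())
            n_place = comb(m, k)
            if n_place > max_exhaustive:
                raise ValidationError("exhaustive enumeration too large; use montecarlo")
            exceed = 0
            for subset in combinations(range(m), k):
                if np.sum(sig_mask[list(subset)]) >= observed[i]:
                    exceed += 1
            pvals[i] = (1 + exceed) / (n_place + 1)
    else:
        rng = rng or np.random.default_rng()
        exceed = np.zeros(len(families), dtype=int)
        chunk = 2000
        done = 0
        while done < n_perm:
            size = min(chunk, n_perm - done)
            perms = np.empty((size, m), dtype=bool)
            for j in range(size):
                perms[j] = sig_mask[rng.permutation(m)]
            stats = presence.astype(np.int64) @ perms.T.astype(np.int64)  # families x perms
            exceed += (stats >= observed[:, None]).sum(axis=1)
            done += size
        pvals = (1 + exceed) / (n_perm + 1)

    frame = pd.DataFrame({
        "domain_family_id": families,
        "observed_overlap": observed.astype(int),
        "permutation_p": pvals,
    })
    frame["fdr"] = bh_adjust(frame["permutation_p"]) if len(frame) else []
    return frame


def two_by_two_association(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-square with Yates continuity correction on the 2x2
    table [[a, b], [c, d]]; df = 1."""
    table = np.array([[a, b], [c, d]], dtype=float)
    if np.any(table < 0):
        raise ValidationError("counts must be non-negative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValidationError("both margins of the 2x2 table must be positive")
    res = scipy.stats.chi2_contingency(table, correction=True)
    return float(res.statistic), float(res.pvalue)


def hypergeometric_overlap(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k) of observing an
    overlap of at least ``k`` between a set of size ``K`` and a set of
    size ``n`` drawn from a universe of ``N``."""
    if not (0 <= k <= min(K, n) and K <= N and n <= N):
        raise ValidationError("infeasible hypergeometric counts")
    return float(scipy.stats.hypergeom.sf(k - 1, N, K, n))


def group_mean_difference(values, group) -> tuple[float, float]:
    """Welch two-sample t-test (two-sided) between flagged and unflagged
    loci."""
    values = np.asarray(values, float)
    group = np.asarray(group, bool)
    if values.shape != group.shape:
        raise ValidationError("values and group flags must align")
    if not np.all(np.isfinite(values)):
        raise ValidationError("non-finite metric values")
    x, y = values[group], values[~group]
    if x.size < 2 or y.size < 2:
        raise ValidationError("each group needs at least 2 values")
    res = scipy.stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def assign_windowed_metric(
    loci: Sequence, windows: Sequence[tuple],
) -> tuple[pd.Series, list[str]]:
    """Assign to each locus the metric of the sliding window with the
    largest overlap (ties: smaller-coordinate window).

    ``windows`` are (chrom, start, end, value) tuples, e.g. 5-kb synteny
    diversity windows.  Loci with no overlapping window get NaN and are
    listed separately.
    """
    values = {}
    missing = []
    for locus in loci:
        best = None
        for chrom, start, end, value in sorted(windows, key=lambda w: (w[0], w[1], w[2])):
            if chrom != locus.chrom:
                continue
            ov = min(end, locus.end) - max(start, locus.start)
            if ov > 0 and (best is None or ov > best[0]):
                best = (ov, value)
        if best is None:
            values[locus.locus_id] = np.nan
            missing.append(locus.locus_id)
        else:
            values[locus.locus_id] = best[1]
    return pd.Series(values, name="window_metric"), missing
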