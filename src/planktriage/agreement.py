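"""Human-vs-machine abundance agreement statistics.

Long-term plankton monitoring produces, for each sample, a per-category
abundance table (thousand specimens per m² of water column, categories being
species or developmental stages).  When a machine pipeline replaces part of
the manual counting, the two observers must be compared as *methods*:

* paired permutation test on the L1 distance between the two estimate
  vectors (sign-flip null on per-category differences),
* Wilcoxon signed-rank test on the paired differences,
* Mann-Whitney rank-sum test (the monitoring program's historical criterion
  for between-sample differences, significance below p = 0.05),
* Pearson correlation between the two estimate series,
* Bland-Altman analysis in log2 space with limits at +/- 2 SD,
* and a simple category breakdown: fractions where the machine agrees,
  undercounts, or overcounts.

Counts are converted to areal abundance with the net geometry: a conical
(Juday) net of known mouth diameter samples a cylinder of water, so
specimens per m² = count / (counted fraction × mouth area).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "PairedAbundanceTable",
    "BlandAltman",
    "AgreementReport",
    "summarize_mean_sd",
    "permutation_test_l1",
    "wilcoxon_signed_rank",
    "mann_whitney_u",
    "pearson_r",
    "bland_altman_log2",
    "category_breakdown",
    "counts_to_areal",
    "compute_agreement",
    "NET_MOUTH_DIAMETER_M",
]

#: Mouth diameter of the monitoring program's plankton net, metres.
NET_MOUTH_DIAMETER_M = 0.375


@dataclass(frozen=True)
class PairedAbundanceTable:
    """Per-category abundance from two observers for one sample.

    ``human`` and ``machine`` are in thousand specimens per m², >= 0,
    aligned with ``categories``.
    """

    categories: tuple[str, ...]
    human: np.ndarray
    machine: np.ndarray

    def __post_init__(self) -> None:
        human = np.asarray(self.human, dtype=np.float64)
        machine = np.asarray(self.machine, dtype=np.float64)
        object.__setattr__(self, "human", human)
        object.__setattr__(self, "machine", machine)
        object.__setattr__(self, "categories", tuple(self.categories))
        n = len(self.categories)
        if n < 1:
            raise ValueError("table must have at least one category")
        if human.shape != (n,) or machine.shape != (n,):
            raise ValueError("human/machine must align with categories")
        if len(set(self.categories)) != n:
            raise ValueError("duplicate category names")
        if (human < 0).any() or (machine < 0).any():
            raise ValueError("negative abundance")

    def __len__(self) -> int:
        return len(self.categories)


def summarize_mean_sd(values) -> tuple[float, float]:
    """Arithmetic mean and sample SD (n-1 denominator); needs n >= 2."""
    arr = np.asarray(values, dtype=np.float64)
    if arr.size < 2:
        raise ValueError("need at least two values for mean +/- SD")
    return float(arr.mean()), float(arr.std(ddof=1))


def counts_to_areal(
    raw_count: float,
    counted_fraction: float = 1.0,
    net_mouth_diameter_m: float = NET_MOUTH_DIAMETER_M,
) -> float:
    """Convert a (sub)sample count to thousand specimens per m².

    ``counted_fraction`` is the fraction of the concentrated sample actually
    examined under the microscope (in (0, 1]); the net mouth area
    ``pi * (d/2)^2`` is the sampled water-column cross-section.
    """
    if not (0.0 < counted_fraction <= 1.0):
        raise ValueError("counted_fraction must be in (0, 1]")
    if net_mouth_diameter_m <= 0:
        raise ValueError("net mouth diameter must be positive")
    if raw_count < 0:
        raise ValueError("raw count must be >= 0")
    area = math.pi * (net_mouth_diameter_m / 2.0) ** 2
    return (raw_count / counted_fraction) / area / 1000.0


# --------------------------------------------------------------------------
# tests


def _sign_matrix(n: int) -> np.ndarray:
    """All 2^n sign patterns as a (2^n, n) array of +/-1."""
    bits = (np.arange(2**n)[:, None] >> np.arange(n)[None, :]) & 1
    return 1.0 - 2.0 * bits


def permutation_test_l1(
    table: PairedAbundanceTable, n_perm: int = 9999, seed: int | None = None
) -> float:
    """Paired sign-flip permutation test on the L1 distance, two-sided.

    The statistic is ``T = |sum_i (h_i - m_i)|``.  The naive per-category
    ``sum |h_i - m_i|`` is invariant under within-pair swaps and therefore
    degenerate as a permutation statistic; the signed-sum reading is the
    non-degenerate one, with the null generated by independent sign flips
    of the per-category differences (observer exchangeability within each
    category).

    For n <= 12 categories all 2^n flips are enumerated and the p-value is
    the exact tail fraction ``#{T* >= T} / 2^n``; otherwise ``n_perm``
    seeded random flips are drawn and the add-one convention
    ``(1 + #{T* >= T}) / (1 + n_perm)`` applies.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    d = table.human - table.machine
    t_obs = abs(float(d.sum()))
    if np.all(d == 0):
        return 1.0
    n = len(d)
    tol = 1e-12 * max(1.0, t_obs)
    if n <= 12:
        t_null = np.abs(_sign_matrix(n) @ d)
        return float(np.mean(t_null >= t_obs - tol))
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    t_null = np.abs(signs @ d)
    return float((1 + np.sum(t_null >= t_obs - tol)) / (1 + n_perm))


def wilcoxon_signed_rank(
    table: PairedAbundanceTable, zero_method: str = "drop"
) -> float:
    """Two-sided Wilcoxon signed-rank test on per-category differences.

    Zero differences are dropped by default (Wilcoxon's original
    convention); ``zero_method="pratt"`` ranks them but excludes them from
    the statistic.  The exact null distribution (all sign assignments over
    midranks, so ties are handled) is enumerated for n <= 15 nonzero
    differences; above that scipy's normal approximation with continuity
    correction is used.
    """
    if zero_method not in ("drop", "pratt"):
        raise ValueError("zero_method must be 'drop' or 'pratt'")
    d = table.human - table.machine
    nz = d != 0
    if not nz.any():
        raise ValueError("all differences are zero; signed-rank test undefined")
    if zero_method == "drop":
        d_used = d[nz]
        ranks = stats.rankdata(np.abs(d_used))
    else:  # pratt: rank zeros too, then discard them from the statistic
        ranks_all = stats.rankdata(np.abs(d))
        d_used = d[nz]
        ranks = ranks_all[nz]
    n = len(d_used)
    w_plus = float(ranks[d_used > 0].sum())
    if n <= 15:
        # enumerate W+ over all sign assignments: rank contributes iff sign is +
        masks = ((np.arange(2**n)[:, None] >> np.arange(n)[None, :]) & 1).astype(float)
        w_null = masks @ ranks
        mu = ranks.sum() / 2.0
        dev = abs(w_plus - mu)
        p = float(np.mean(np.abs(w_null - mu) >= dev - 1e-12))
        return min(1.0, p)
    res = stats.wilcoxon(
        d_used, correction=True, alternative="two-sided", method="approx"
    )
    return float(res.pvalue)


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney rank-sum test; returns ``(U, p)``.

    Exact null distribution when ``n*m <= 64`` and the pooled sample is
    tie-free; normal approximation with tie correction otherwise.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    tie_free = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (x.size * y.size <= 64 and tie_free) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def pearson_r(table: PairedAbundanceTable) -> float:
    """Product-moment correlation between the two estimate series."""
    h, m = table.human, table.machine
    if len(h) < 3:
        raise ValueError("need at least three categories for a correlation")
    if h.std() == 0 or m.std() == 0:
        raise ValueError("zero variance in one of the series")
    return float(stats.pearsonr(h, m).statistic)


@dataclass(frozen=True)
class BlandAltman:
    """Bland-Altman analysis of two observers in log2 space.

    Per category with both values positive: x = mean of log2 estimates,
    y = log2(human) - log2(machine).  ``bias`` is the mean of y and the
    limits of agreement are ``bias +/- 2 * SD(y)`` (exactly 2).  Categories
    with a zero in either observer are excluded and listed: a pseudocount
    would silently dominate the limits for rare taxa.
    """

    categories: tuple[str, ...]
    mean_log2: np.ndarray
    diff_log2: np.ndarray
    bias: float
    sd: float
    lower: float
    upper: float
    excluded: tuple[str, ...]


def bland_altman_log2(table: PairedAbundanceTable) -> BlandAltman:
    usable = (table.human > 0) & (table.machine > 0)
    if usable.sum() < 2:
        raise ValueError("need at least two categories with positive values in both observers")
    h = table.human[usable]
    m = table.machine[usable]
    cats = tuple(c for c, u in zip(table.categories, usable) if u)
    excluded = tuple(c for c, u in zip(table.categories, usable) if not u)
    x = (np.log2(h) + np.log2(m)) / 2.0
    y = np.log2(h) - np.log2(m)
    bias = float(y.mean())
    sd = float(y.std(ddof=1))
    return BlandAltman(
        categories=cats,
        mean_log2=x,
        diff_log2=y,
        bias=bias,
        sd=sd,
        lower=bias - 2.0 * sd,
        upper=bias + 2.0 * sd,
        excluded=excluded,
    )


def category_breakdown(
    table: PairedAbundanceTable, tol: float = 0.0
) -> tuple[float, float, float]:
    """Fractions of categories (equal, machine_lower, machine_higher).

    ``equal`` means |h - m| <= tol (tol in raw abundance units, default 0);
    the three fractions sum to 1.
    """
    h, m = table.human, table.machine
    n = len(table)
    equal = float(np.sum(np.abs(h - m) <= tol)) / n
    lower = float(np.sum(m < h - tol)) / n
    higher = float(np.sum(m > h + tol)) / n
    return equal, lower, higher


@dataclass
class AgreementReport:
    """The full agreement bundle for one paired table."""

    human_mean_sd: tuple[float, float]
    machine_mean_sd: tuple[float, float]
    perm_p: float
    wilcoxon_p: float | None
    mannwhitney_u: float
    mannwhitney_p: float
    pearson_r: float
    bland_altman: BlandAltman
    breakdown: tuple[float, float, float]
    n_categories: int
    notes: tuple[str, ...] = ()


def compute_agreement(
    table: PairedAbundanceTable, n_perm: int = 9999, seed: int | None = None
) -> AgreementReport:
    """Compute every agreement statistic for one paired table."""
    notes: list[str] = []
    try:
        wil = wilcoxon_signed_rank(table)
    except ValueError as exc:
        wil = None
        notes.append(f"wilcoxon: {exc}")
    u_stat, u_p = mann_whitney_u(table.human, table.machine)
    return AgreementReport(
        human_mean_sd=summarize_mean_sd(table.human),
        machine_mean_sd=summarize_mean_sd(table.machine),
        perm_p=permutation_test_l1(table, n_perm=n_perm, seed=seed),
        wilcoxon_p=wil,
        mannwhitney_u=u_stat,
        mannwhitney_p=u_p,
        pearson_r=pearson_r(table),
        bland_altman=bland_altman_log2(table),
        breakdown=category_breakdown(table),
        n_categories=len(table),
        notes=tuple(notes),
    )
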