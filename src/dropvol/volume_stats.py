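"""Droplet-volume statistics and the bottom-up uncertainty budget.

Droplet volumes are obtained from area-equivalent diameters assuming the
droplets are (nearly) perfect spheres, V = (pi/6) d^3.  Per-well summaries
average per-droplet volumes (not the volume of the mean diameter — the cube
is convex, so the two differ by Jensen's inequality and the per-droplet mean
is the physically meaningful one).  Group screening uses iterative two-sided
Grubbs tests; group comparison uses one-way ANOVA with Tukey HSD; and the
measurement uncertainty is assembled bottom-up from the ANOVA mean squares:

    u_r   = sqrt(MS_within) / sqrt(n)                       (repeatability)
    u_ip1 = sqrt((MS_between - MS_within) / (n N))          if MS_between > MS_within
    u_ip2 = sqrt(MS_within/n) * (2 / (N (n-1)))^(1/4) / sqrt(N)   otherwise
    u_c   = sqrt(u_r^2 + u_ip^2),   U = k * u_c

with n replicates per experiment, N experiments, and a coverage factor k
(default 2.1, ~95% confidence given the effective degrees of freedom).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "droplet_volume",
    "diameter_from_volume",
    "WellVolumeSummary",
    "summarize_well",
    "OutlierScreenResult",
    "grubbs_critical",
    "grubbs_screen",
    "AnovaResult",
    "anova_oneway",
    "tukey_pairwise",
    "UncertaintyBudget",
    "uncertainty_budget_from_ms",
    "uncertainty_budget",
    "relative_sd",
]

_UM3_PER_NL = 1e6  # 1 nL = 1e6 um^3


def droplet_volume(diameter_um):
    """Sphere volume in nL from a diameter in um: (pi/6) d^3 / 1e6.

    Accepts scalars or arrays; negative diameters raise.
    """
    d = np.asarray(diameter_um, dtype=float)
    if np.any(d < 0):
        raise ValueError("diameter must be non-negative")
    v = (np.pi / 6.0) * d**3 / _UM3_PER_NL
    return float(v) if np.isscalar(diameter_um) else v


def diameter_from_volume(volume_nl):
    """Inverse of :func:`droplet_volume`: d = (6e6 V / pi)^(1/3) in um."""
    v = np.asarray(volume_nl, dtype=float)
    if np.any(v < 0):
        raise ValueError("volume must be non-negative")
    d = np.cbrt(6.0 * _UM3_PER_NL * v / np.pi)
    return float(d) if np.isscalar(volume_nl) else d


@dataclass
class WellVolumeSummary:
    """Per-well aggregate of accepted droplets (one row of a per-day volume summary)."""

    well: str
    cartridge: str
    day: int
    n_droplets: int
    mean_diameter_um: float
    sd_diameter_um: float
    mean_volume_nl: float
    sd_volume_nl: float
    single_droplet: bool = False  # SD reported as 0 because n = 1


def summarize_well(records, well: str = "", cartridge: str = "", day: int = 0) -> WellVolumeSummary:
    """Summarise one well: mean/SD of diameters and of per-droplet volumes.

    ``records`` is either an iterable of objects with a ``diameter_um``
    attribute (accepted droplet records) or a plain sequence of diameters in
    um.  Volumes are computed per droplet and then averaged; SDs are sample
    SDs (ddof=1).  A single-droplet well reports SD 0 with a flag.
    """
    items = list(records)
    if not items:
        raise ValueError("summarize_well needs at least one droplet")
    if hasattr(items[0], "diameter_um"):
        d = np.array([r.diameter_um for r in items], dtype=float)
    else:
        d = np.asarray(items, dtype=float)
    v = droplet_volume(d)
    single = d.size == 1
    return WellVolumeSummary(
        well=well,
        cartridge=cartridge,
        day=day,
        n_droplets=int(d.size),
        mean_diameter_um=float(d.mean()),
        sd_diameter_um=0.0 if single else float(d.std(ddof=1)),
        mean_volume_nl=float(v.mean()),
        sd_volume_nl=0.0 if single else float(v.std(ddof=1)),
        single_droplet=single,
    )


# ---------------------------------------------------------------------------
# Grubbs outlier screening
# ---------------------------------------------------------------------------

def grubbs_critical(n: int, alpha: float = 0.05) -> float:
    """Two-sided Grubbs critical value for sample size n at level alpha.

    G_crit = (n-1)/sqrt(n) * sqrt(t^2 / (n - 2 + t^2)) with
    t = t_{alpha/(2n), n-2} (upper quantile).
    """
    if n < 3:
        raise ValueError("Grubbs test needs n >= 3")
    t = stats.t.ppf(1 - alpha / (2 * n), n - 2)
    return (n - 1) / math.sqrt(n) * math.sqrt(t * t / (n - 2 + t * t))


@dataclass
class OutlierScreenResult:
    """Outcome of an iterative two-sided Grubbs screen."""

    values: np.ndarray
    labels: list
    alpha: float
    outliers: list = field(default_factory=list)  # (label, value, G, G_crit)
    kept_mask: np.ndarray | None = None

    @property
    def kept_values(self) -> np.ndarray:
        return self.values[self.kept_mask]

    @property
    def outlier_labels(self) -> list:
        return [o[0] for o in self.outliers]


def grubbs_screen(values: Sequence[float], alpha: float = 0.05, labels=None) -> OutlierScreenResult:
    """Iterative two-sided Grubbs screen: flag the largest studentised
    deviation, remove it, repeat until no flag (or fewer than 3 values remain).

    Flagged values are meant to be excluded from downstream budgets.  An
    all-identical sample has zero spread and yields no outliers.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("Grubbs screen needs at least 3 values")
    if labels is None:
        labels = list(range(x.size))
    labels = list(labels)
    if len(labels) != x.size:
        raise ValueError("labels must match values in length")

    result = OutlierScreenResult(values=x, labels=labels, alpha=alpha)
    kept = np.ones(x.size, dtype=bool)
    while kept.sum() >= 3:
        sub = x[kept]
        s = sub.std(ddof=1)
        if s == 0:
            break
        dev = np.abs(sub - sub.mean())
        i_local = int(np.argmax(dev))
        g = dev[i_local] / s
        g_crit = grubbs_critical(int(kept.sum()), alpha)
        if g <= g_crit:
            break
        i_global = np.flatnonzero(kept)[i_local]
        result.outliers.append((labels[i_global], float(x[i_global]), float(g), float(g_crit)))
        kept[i_global] = False
    result.kept_mask = kept
    return result


# ---------------------------------------------------------------------------
# One-way ANOVA and Tukey HSD
# ---------------------------------------------------------------------------

@dataclass
class AnovaResult:
    ms_within: float
    ms_between: float
    f_statistic: float
    p_value: float
    df_between: int
    df_within: int
    group_sizes: list


def _as_groups(groups) -> tuple[list, list[np.ndarray]]:
    if isinstance(groups, Mapping):
        names = list(groups.keys())
        arrays = [np.asarray(groups[k], dtype=float) for k in names]
    else:
        arrays = [np.asarray(g, dtype=float) for g in groups]
        names = list(range(len(arrays)))
    return names, arrays


def anova_oneway(groups) -> AnovaResult:
    """Standard one-way decomposition exposing the mean squares.

    ``groups`` is a mapping name -> values or a sequence of value sequences;
    balanced or unbalanced.  The mean squares feed the uncertainty budget.
    """
    _, arrays = _as_groups(groups)
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs at least 2 values")
    all_values = np.concatenate(arrays)
    grand = all_values.mean()
    n_total = all_values.size
    k = len(arrays)
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_b, df_w = k - 1, n_total - k
    ms_b, ms_w = ss_between / df_b, ss_within / df_w
    if ms_w == 0:
        f = math.inf if ms_b > 0 else 0.0
        p = 0.0 if ms_b > 0 else 1.0
    else:
        f = ms_b / ms_w
        p = float(stats.f.sf(f, df_b, df_w))
    return AnovaResult(
        ms_within=float(ms_w),
        ms_between=float(ms_b),
        f_statistic=float(f),
        p_value=p,
        df_between=df_b,
        df_within=df_w,
        group_sizes=[int(a.size) for a in arrays],
    )


def tukey_pairwise(groups, alpha: float = 0.05):
    """All pairwise comparisons with studentised-range (Tukey HSD) adjustment.

    Returns a pandas DataFrame with columns group1, group2, diff, p_adj,
    significant.
    """
    import pandas as pd

    names, arrays = _as_groups(groups)
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs at least 2 values")
    res = stats.tukey_hsd(*arrays)
    rows = []
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            p = float(res.pvalue[i, j])
            rows.append(
                {
                    "group1": names[i],
                    "group2": names[j],
                    "diff": float(arrays[i].mean() - arrays[j].mean()),
                    "p_adj": p,
                    "significant": p < alpha,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Bottom-up uncertainty budget
# ---------------------------------------------------------------------------

@dataclass
class UncertaintyBudget:
    """Variance-component uncertainty budget for a mean droplet volume.

    ``branch`` records which intermediate-precision formula applied:
    "ip1" when MS_between > MS_within (a real between-experiment component),
    "ip2" otherwise (intermediate precision bounded from the within scatter).
    """

    ms_within: float
    ms_between: float
    n: float
    N: int
    u_r: float
    u_ip: float
    branch: str
    u_c: float
    k: float
    U: float


def uncertainty_budget_from_ms(
    ms_within: float,
    ms_between: float,
    n: float,
    N: int,
    k: float = 2.1,
) -> UncertaintyBudget:
    """Evaluate the budget from given ANOVA mean squares.

    n is the number of replicates per experiment (may be fractional: the
    harmonic mean is used for unbalanced designs), N the number of
    experiments.  Branch rule is strict: ip1 iff MS_between > MS_within.
    """
    if n < 2:
        raise ValueError("need n >= 2 replicates per experiment")
    if N < 2:
        raise ValueError("need N >= 2 experiments")
    if ms_within < 0 or ms_between < 0:
        raise ValueError("mean squares must be non-negative")
    u_r = math.sqrt(ms_within) / math.sqrt(n)
    if ms_between > ms_within:
        branch = "ip1"
        u_ip = math.sqrt((ms_between - ms_within) / (n * N))
    else:
        branch = "ip2"
        u_ip = math.sqrt(ms_within / n) * (2.0 / (N * (n - 1))) ** 0.25 / math.sqrt(N)
    u_c = math.hypot(u_r, u_ip)
    return UncertaintyBudget(
        ms_within=ms_within,
        ms_between=ms_between,
        n=n,
        N=N,
        u_r=u_r,
        u_ip=u_ip,
        branch=branch,
        u_c=u_c,
        k=k,
        U=k * u_c,
    )


def uncertainty_budget(groups, k: float = 2.1, n: float | None = None) -> UncertaintyBudget:
    """Budget computed from grouped measurements (groups = experiments).

    Runs the one-way ANOVA and evaluates the budget with N = number of
    groups and n = replicates per group (harmonic mean when unbalanced,
    unless given explicitly).
    """
    res = anova_oneway(groups)
    sizes = np.asarray(res.group_sizes, dtype=float)
    if n is None:
        n = float(sizes.size / (1.0 / sizes).sum())  # harmonic mean
    return uncertainty_budget_from_ms(res.ms_within, res.ms_between, n, len(sizes), k=k)


def relative_sd(values: Sequence[float]) -> float:
    """Relative standard deviation in percent: 100 * sample SD / mean."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    mean = x.mean()
    if mean == 0:
        raise ValueError("mean is zero; RSD undefined")
    return 100.0 * x.std(ddof=1) / mean
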