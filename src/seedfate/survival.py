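"""Seed bank survival: the retained-times-stained product and its aggregation.

Seed bank survival for a group of packets is

    survival = pl * ps

where ``pl`` is the proportion of recovered seeds that were retained
(intact) and ``ps`` is the staining rate — the proportion of assayed
retained seeds showing any tetrazolium stain, used as the viability
estimate.  Survival is computed per elementary stratum (species x cohort
x microhabitat x burial duration) from pooled counts, then averaged
*unweighted* across strata for any coarser report.  The alternative path
— multiplying stratum-averaged pl by stratum-averaged ps — is also
exposed because the two disagree in general (a product of means is not
the mean of products); the stratum-mean path is the headline number.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._round import round_half_up
from .packet_model import PacketRecord
from .pool_accounting import summarize_pools
from .schema import STRATUM_KEYS


@dataclass(frozen=True)
class SurvivalEstimate:
    """Survival of one group: pl, ps, their product, and sample sizes.

    For aggregated estimates (means across strata) ``pl`` and ``ps`` hold
    the unweighted means of the component rates and ``survival`` the mean
    of the component survivals, so ``survival != pl * ps`` in general;
    ``aggregated`` marks such rows and ``n_strata`` counts the components.
    """

    group: Mapping[str, object]
    pl: float | None
    ps: float | None
    survival: float
    n_recovered: int = 0
    n_retained: int = 0
    n_assayed: int = 0
    aggregated: bool = False
    n_strata: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.survival <= 1.0:
            raise ValueError(f"survival must be in [0, 1], got {self.survival}")

    @property
    def survival_pct(self) -> float:
        return 100.0 * self.survival


def survival_estimate(pl: float, ps: float) -> float:
    """The survival product pl * ps; pure, deterministic, domain-checked."""
    for name, value in (("pl", pl), ("ps", ps)):
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"{name} must be a proportion in [0, 1], got {value}")
    return pl * ps


def estimate_from_counts(
    group: Mapping[str, object],
    n_recovered: int,
    n_retained: int,
    n_assayed: int,
    n_stained: int,
) -> SurvivalEstimate:
    """Survival from pooled counts of one stratum.

    ``pl`` uses recovered seeds as the denominator (unrecovered seeds are
    excluded everywhere); a stratum with nothing assayed has undefined
    ``ps`` and is reported with ``ps = None`` and survival 0 only when
    ``pl`` is 0.
    """
    if n_recovered == 0:
        raise ValueError(f"group {dict(group)}: no recovered seeds")
    pl = n_retained / n_recovered
    if n_assayed == 0:
        if n_retained == 0:
            return SurvivalEstimate(group, pl, None, 0.0, n_recovered, 0, 0)
        raise ValueError(
            f"group {dict(group)}: retained seeds present but none assayed; "
            "staining rate undefined"
        )
    ps = n_stained / n_assayed
    return SurvivalEstimate(
        group, pl, ps, pl * ps, n_recovered, n_retained, n_assayed
    )


def stratum_survival(
    records: Sequence[PacketRecord],
    grouping: Sequence[str] = STRATUM_KEYS,
) -> list[SurvivalEstimate]:
    """Survival per elementary stratum from pooled packet counts."""
    estimates = []
    for summary in summarize_pools(records, grouping):
        estimates.append(
            estimate_from_counts(
                summary.group,
                n_recovered=summary.expended_F + summary.retained_C,
                n_retained=summary.retained_C,
                n_assayed=summary.n_assayed,
                n_stained=summary.retained_live_D,
            )
        )
    return estimates


def aggregate_survival(
    estimates: Sequence[SurvivalEstimate],
    over: Sequence[str],
) -> list[SurvivalEstimate]:
    """Unweighted mean of group survivals across the labels in ``over``.

    The remaining labels define the output groups.  Order of the input
    does not affect the result.  ``pl``/``ps`` of an aggregate are the
    unweighted means of the defined component rates.
    """
    if not estimates:
        raise ValueError("aggregate_survival requires at least one estimate")
    buckets: dict[tuple, list[SurvivalEstimate]] = {}
    for est in estimates:
        key = tuple(sorted((k, v) for k, v in est.group.items() if k not in over))
        buckets.setdefault(key, []).append(est)
    out = []
    for key in sorted(buckets, key=str):
        # canonical member order makes the float means order-invariant
        members = sorted(buckets[key], key=lambda m: str(sorted(m.group.items())))
        pls = [m.pl for m in members if m.pl is not None]
        pss = [m.ps for m in members if m.ps is not None]
        out.append(
            SurvivalEstimate(
                group=dict(key),
                pl=float(np.mean(pls)) if pls else None,
                ps=float(np.mean(pss)) if pss else None,
                survival=float(np.mean([m.survival for m in members])),
                n_recovered=sum(m.n_recovered for m in members),
                n_retained=sum(m.n_retained for m in members),
                n_assayed=sum(m.n_assayed for m in members),
                aggregated=True,
                n_strata=sum(m.n_strata for m in members),
            )
        )
    return out


def product_of_means(estimates: Sequence[SurvivalEstimate]) -> float:
    """mean(pl) * mean(ps) across groups — the pooled-average survival path.

    Differs from the headline mean-of-products in general; reported
    alongside it for transparency.
    """
    pls = [e.pl for e in estimates if e.pl is not None]
    pss = [e.ps for e in estimates if e.ps is not None]
    if not pls or not pss:
        raise ValueError("need defined pl and ps values")
    return float(np.mean(pls)) * float(np.mean(pss))


def survival_decline(s_year1: float, s_year2: float) -> float:
    """Percent decline in survival between two burial durations.

    ``(s1 - s2) / s1 * 100`` on like-scaled inputs (both proportions or
    both percentages).  Undefined for zero first-season survival.
    """
    if s_year1 <= 0:
        raise ValueError("decline undefined: first-season survival is zero")
    return (s_year1 - s_year2) / s_year1 * 100.0


def bootstrap_survival_ci(
    records: Sequence[PacketRecord],
    grouping: Sequence[str] = STRATUM_KEYS,
    n_resamples: int = 2000,
    level: float = 0.95,
    seed: int | None = None,
) -> pd.DataFrame:
    """Percentile bootstrap CI for stratum survival, resampling packets.

    Survival is a product of two binomial proportions with a dependent
    subsampled denominator, so no textbook interval applies directly;
    this nonparametric interval is an extension of the point estimator,
    not part of the survival definition itself.
    """
    rng = np.random.default_rng(seed)
    rows = []
    from .packet_model import records_to_frame

    frame = records_to_frame(records)
    for key, g in frame.groupby(list(grouping), sort=True):
        labels = dict(zip(grouping, key if isinstance(key, tuple) else (key,)))
        counts = g[["n_expended", "n_retained", "n_assayed", "n_stained"]].to_numpy()
        n = len(counts)
        idx = rng.integers(0, n, size=(n_resamples, n))
        draws = counts[idx]  # (resamples, packets, 4)
        sums = draws.sum(axis=1).astype(float)
        recovered = sums[:, 0] + sums[:, 1]
        with np.errstate(invalid="ignore", divide="ignore"):
            pl = np.where(recovered > 0, sums[:, 1] / recovered, np.nan)
            ps = np.where(sums[:, 2] > 0, sums[:, 3] / sums[:, 2], np.nan)
        surv = pl * ps
        surv = surv[np.isfinite(surv)]
        alpha = (1.0 - level) / 2.0
        point = estimate_from_counts(
            labels,
            int(counts[:, 0].sum() + counts[:, 1].sum()),
            int(counts[:, 1].sum()),
            int(counts[:, 2].sum()),
            int(counts[:, 3].sum()),
        )
        rows.append(
            {
                **labels,
                "survival": point.survival,
                "ci_low": float(np.quantile(surv, alpha)) if len(surv) else np.nan,
                "ci_high": float(np.quantile(surv, 1 - alpha)) if len(surv) else np.nan,
                "n_resamples": n_resamples,
                "method": "percentile bootstrap over packets",
            }
        )
    return pd.DataFrame(rows)


def estimates_to_frame(
    estimates: Sequence[SurvivalEstimate], decimals: int | None = None
) -> pd.DataFrame:
    """Tidy frame of survival estimates; optional report-time rounding."""
    rows = []
    for est in estimates:
        row = dict(est.group)
        row.update(
            pl=est.pl,
            ps=est.ps,
            survival=est.survival,
            survival_pct=est.survival_pct,
            n_recovered=est.n_recovered,
            n_retained=est.n_retained,
            n_assayed=est.n_assayed,
            aggregated=est.aggregated,
            n_strata=est.n_strata,
        )
        if decimals is not None:
            row["survival_pct"] = round_half_up(row["survival_pct"], decimals)
        rows.append(row)
    return pd.DataFrame(rows)
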