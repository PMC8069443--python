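"""Per-animal total-yield tables and the protocol comparison statistics.

The analysis chain: build, for every animal and trait (milk, FCM, fat,
protein), the 210-day total under each calculation method — Wood fits on
protocols A/B/C integrated over the lactation, and the ICAR
test-interval total on the monthly control series — then, per group,
screen test-day distributions with Shapiro-Wilk, run a one-way
fixed-effects GLM with calculation method as the sole effect, and
compare every non-reference method to the full-schedule Wood fit (A)
with Dunnett's many-to-one test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import standards
from .protocols import (
    DAYS_PER_MONTH,
    HORIZON_DAYS,
    RecordingProtocol,
    standard_protocols,
)
from .wood import fit_wood, total_yield_daily_sum, total_yield_wood

__all__ = [
    "TRAIT_ORDER",
    "METHOD_ORDER",
    "per_animal_totals",
    "normality_screen",
    "one_way_glm",
    "dunnett_vs_reference",
    "compare_protocols",
    "comparison_report",
    "GlmResult",
    "DunnettComparison",
]

TRAIT_ORDER = ("milk", "fcm", "fat", "protein")
METHOD_ORDER = ("A", "ICAR", "B", "C")


def _trait_series(grp: pd.DataFrame) -> dict:
    """Daily-yield series (g/day) per trait from one animal's records."""
    milk = grp["milk_g"].to_numpy(dtype=float)
    return {
        "milk": milk,
        "fcm": standards.fcm_3_5(milk, grp["fat_pct"].to_numpy(dtype=float)),
        "fat": standards.constituent_daily_yield(
            milk, grp["fat_pct"].to_numpy(dtype=float)
        ),
        "protein": standards.constituent_daily_yield(
            milk, grp["protein_pct"].to_numpy(dtype=float)
        ),
    }


def per_animal_totals(
    records: pd.DataFrame,
    protocols: dict | None = None,
    traits=TRAIT_ORDER,
    *,
    totals_mode: str = "integral",
    icar_edges: str = "include",
    icar_start_dim: int = 3,
    horizon_days: int = HORIZON_DAYS,
    include_icar: bool = True,
) -> tuple[pd.DataFrame, list]:
    """Total-yield table: one row per animal x trait x method (kg).

    Wood methods: fit the curve to the protocol's test days and
    integrate over [0, horizon] (``totals_mode="integral"``, closed
    form) or sum predicted daily yields over days 1..horizon
    (``totals_mode="daily_sum"``).  ICAR: test-interval method on the
    monthly control series (DIM 30, 60, ..., 210 taken from the grid).

    Animals whose fit fails a protocol (non-convergence, or b <= -1
    making the integral divergent) contribute no row for that method;
    the failures list records (animal_id, trait, method, reason).
    """
    if totals_mode not in ("integral", "daily_sum"):
        raise ValueError(f"unknown totals_mode {totals_mode!r}")
    if protocols is None:
        protocols = standard_protocols()
    icar_dims = np.arange(DAYS_PER_MONTH, horizon_days + 1, DAYS_PER_MONTH)

    rows, failures = [], []
    for (animal_id, breed), grp in records.groupby(
        ["animal_id", "breed"], sort=False
    ):
        grp = grp.sort_values("dim")
        dims = grp["dim"].to_numpy(dtype=float)
        series = _trait_series(grp)
        for trait in traits:
            y = series[trait]
            for name, proto in protocols.items():
                mask = np.isin(dims, np.asarray(proto.dims, dtype=float))
                try:
                    fit = fit_wood(dims[mask], y[mask], trait=trait)
                    if not fit.converged:
                        raise RuntimeError(f"fit did not converge: {fit.message}")
                    if totals_mode == "integral":
                        total = total_yield_wood(fit.params, 0, horizon_days)
                    else:
                        total = total_yield_daily_sum(fit.params, horizon_days)
                except (ValueError, RuntimeError) as exc:
                    failures.append((animal_id, trait, name, str(exc)))
                    continue
                rows.append((animal_id, breed, trait, name, total))
            if include_icar:
                icar_mask = np.isin(dims, icar_dims)
                total = standards.icar_total(
                    dims[icar_mask],
                    y[icar_mask],
                    start_dim=icar_start_dim,
                    end_dim=horizon_days,
                    edges=icar_edges,
                )
                rows.append((animal_id, breed, trait, "ICAR", total))

    totals = pd.DataFrame(
        rows, columns=["animal_id", "breed", "trait", "method", "total_kg"]
    )
    return totals, failures


def normality_screen(records: pd.DataFrame, min_n: int = 3) -> pd.DataFrame:
    """Shapiro-Wilk W and p per breed x test day x trait.

    Purely descriptive: results are reported, nothing downstream is
    gated on them.  Cells with fewer than ``min_n`` observations or zero
    variance are skipped (flagged in the ``skipped`` column).
    """
    rows = []
    for (breed, dim), grp in records.groupby(["breed", "dim"]):
        series = _trait_series(grp)
        for trait in TRAIT_ORDER:
            x = series[trait]
            if x.size < min_n or np.ptp(x) == 0:
                rows.append((breed, dim, trait, x.size, np.nan, np.nan, True))
                continue
            w, p = sps.shapiro(x)
            rows.append((breed, dim, trait, x.size, float(w), float(p), False))
    return pd.DataFrame(
        rows, columns=["breed", "dim", "trait", "n", "W", "p", "skipped"]
    )


@dataclass(frozen=True)
class GlmResult:
    """One-way fixed-effects ANOVA summary for method groups."""

    f: float
    p: float
    df_between: int
    df_within: int
    mse: float
    lsmeans: dict
    sem: float


def one_way_glm(groups: dict) -> GlmResult:
    """One-way ANOVA of totals on calculation method.

    ``groups`` maps method name -> array of per-animal totals.  LSMeans
    are the group means (the design is balanced: every animal appears
    once per method).  SEM is the pooled ``sqrt(MSE / n)`` with n the
    harmonic-mean group size.
    """
    names = list(groups)
    arrays = [np.asarray(groups[g], dtype=float) for g in names]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    n_tot = sum(a.size for a in arrays)
    grand = sum(a.sum() for a in arrays) / n_tot
    ssb = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ssw = sum(float(np.sum((a - a.mean()) ** 2)) for a in arrays)
    dfb, dfw = len(arrays) - 1, n_tot - len(arrays)
    if ssw == 0:
        raise ValueError("zero within-group variance in every group")
    mse = ssw / dfw
    f = (ssb / dfb) / mse
    p = float(sps.f.sf(f, dfb, dfw))
    n_harm = len(arrays) / sum(1 / a.size for a in arrays)
    return GlmResult(
        f=float(f),
        p=p,
        df_between=dfb,
        df_within=dfw,
        mse=mse,
        lsmeans={g: float(a.mean()) for g, a in zip(names, arrays)},
        sem=math.sqrt(mse / n_harm),
    )


@dataclass(frozen=True)
class DunnettComparison:
    """One treatment-vs-control contrast of Dunnett's test."""

    diff: float
    statistic: float
    p_raw: float
    p_adj: float
    sig_class: str


def _sig_class(p: float) -> str:
    return "**" if p < 0.01 else "*" if p < 0.05 else "n.s."


def dunnett_vs_reference(
    groups: dict, reference: str = "A", rng=None
) -> dict:
    """Dunnett many-to-one comparisons of each method against the reference.

    The m contrasts share the control group, so under the null their t
    statistics follow an equicorrelated multivariate t (correlation 1/2
    under balance); family-wise adjusted p-values come from that joint
    distribution (scipy's implementation).  With a single contrast the
    procedure reduces exactly to the pooled two-sample t-test, computed
    here in closed form.  Two-sided throughout; adjusted p is floored at
    the unadjusted pooled-t p, which it can never undercut in theory.
    """
    if reference not in groups:
        raise ValueError(f"reference group {reference!r} missing")
    control = np.asarray(groups[reference], dtype=float)
    treat_names = [g for g in groups if g != reference]
    if not treat_names:
        raise ValueError("need at least one non-reference group")
    treats = [np.asarray(groups[g], dtype=float) for g in treat_names]

    all_arrays = [control] + treats
    n_tot = sum(a.size for a in all_arrays)
    k = len(all_arrays)
    dfw = n_tot - k
    mse = sum(float(np.sum((a - a.mean()) ** 2)) for a in all_arrays) / dfw

    t_stats = np.array(
        [
            (a.mean() - control.mean())
            / math.sqrt(mse * (1 / a.size + 1 / control.size))
            for a in treats
        ]
    )
    p_raw = 2 * sps.t.sf(np.abs(t_stats), dfw)

    if len(treats) == 1:
        p_adj = p_raw.copy()
    else:
        res = sps.dunnett(
            *treats, control=control, random_state=np.random.default_rng(rng)
        )
        p_adj = np.maximum(res.pvalue, p_raw)

    return {
        g: DunnettComparison(
            diff=float(a.mean() - control.mean()),
            statistic=float(t),
            p_raw=float(pr),
            p_adj=float(pa),
            sig_class=_sig_class(pa),
        )
        for g, a, t, pr, pa in zip(treat_names, treats, t_stats, p_raw, p_adj)
    }


def compare_protocols(
    totals: pd.DataFrame,
    reference: str = "A",
    by=("breed", "trait"),
    rng=None,
) -> pd.DataFrame:
    """GLM + Dunnett per group (default per breed x trait).

    Returns one row per group x method with the LSMean (kg), pooled SEM
    (kg), Dunnett-adjusted p vs the reference and its significance class
    (* p<0.05, ** p<0.01).  The reference row carries no p-value.
    Passing ``by=("trait",)`` pools breeds, i.e. the GLM with method as
    the only effect.
    """
    by = list(by)
    out = []
    rng = np.random.default_rng(rng)
    for keys, grp in totals.groupby(by, sort=False):
        keys = keys if isinstance(keys, tuple) else (keys,)
        methods = [m for m in METHOD_ORDER if m in set(grp["method"])]
        groups = {
            m: grp.loc[grp["method"] == m, "total_kg"].to_numpy() for m in methods
        }
        glm = one_way_glm(groups)
        dunn = dunnett_vs_reference(groups, reference=reference, rng=rng)
        for m in methods:
            cmp_ = dunn.get(m)
            out.append(
                dict(zip(by, keys))
                | {
                    "method": m,
                    "n": groups[m].size,
                    "lsmean_kg": glm.lsmeans[m],
                    "sem_kg": glm.sem,
                    "anova_f": glm.f,
                    "anova_p": glm.p,
                    "p_adj": cmp_.p_adj if cmp_ else np.nan,
                    "sig_class": cmp_.sig_class if cmp_ else "",
                }
            )
    return pd.DataFrame(out)


def comparison_report(comparison: pd.DataFrame) -> tuple[pd.DataFrame, str]:
    """Wide report: per trait block, per breed row, methods across.

    Returns (wide DataFrame, aligned-text rendering).  Columns: the
    reference LSMean, then each comparison method's LSMean with its
    significance class, then the pooled SEM — one row per breed x trait.
    """
    wide_rows = []
    for trait in [t for t in TRAIT_ORDER if t in set(comparison["trait"])]:
        tr = comparison[comparison["trait"] == trait]
        for breed in tr["breed"].unique():
            sub = tr[tr["breed"] == breed].set_index("method")
            row = {"trait": trait, "breed": breed}
            for m in METHOD_ORDER:
                if m not in sub.index:
                    continue
                row[m] = round(float(sub.loc[m, "lsmean_kg"]), 2)
                if sub.loc[m, "sig_class"]:
                    row[f"{m}_sig"] = sub.loc[m, "sig_class"]
            row["SEM"] = round(float(sub["sem_kg"].iloc[0]), 2)
            wide_rows.append(row)
    wide = pd.DataFrame(wide_rows)

    lines = []
    for trait in wide["trait"].unique():
        lines.append(f"== {trait} (total kg, LSMeans; * p<0.05, ** p<0.01 vs A) ==")
        block = wide[wide["trait"] == trait]
        for _, r in block.iterrows():
            parts = [f"{r['breed']:<18}"]
            for m in METHOD_ORDER:
                if m in r and not pd.isna(r[m]):
                    sig = r.get(f"{m}_sig", "")
                    sig = "" if pd.isna(sig) else sig
                    parts.append(f"{m}={r[m]:>8.2f} {sig:<4}")
            parts.append(f"SEM={r['SEM']:.2f}")
            lines.append("  ".join(parts))
        lines.append("")
    return wide, "\n".join(lines)
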