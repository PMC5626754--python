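"""Split-plot (mixed-design) statistics.

Implements the group x time-region x spectral-component analysis natively:

* :func:`mixed_anova` — one between-subject factor plus one or two
  fully-crossed within-subject factors, each within effect tested against
  its own effect-by-subject error stratum; no sphericity correction;
* :func:`oneway_within_region` — the per-region model (one within factor);
* :func:`oneway_anova` — classical one-way between-groups ANOVA;
* :func:`fisher_lsd` — unadjusted pairwise comparisons on the ANOVA error
  mean square, plus Cohen's d;
* :func:`run_paper_analysis` — the full reporting bundle.

Sums of squares
---------------
The design is balanced within subjects but the between factor may be
unbalanced.  Group comparisons use group sizes directly; within-subject
main effects use unweighted (across groups) cell means, i.e. the standard
Type-III treatment for a one-between split plot.  With balanced groups all
conventions coincide.  Degrees of freedom are the classical split-plot
values: a within effect with ``q`` numerator df is tested on
``(q, q * (N - k))`` where ``k`` is the number of groups.
"""

from __future__ import annotations

import itertools
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.linalg import helmert

__all__ = [
    "mixed_anova",
    "oneway_within_region",
    "oneway_anova",
    "fisher_lsd",
    "cohens_d",
    "run_paper_analysis",
]


def _contrasts(n_levels: int) -> np.ndarray:
    """Orthonormal contrast matrix (n_levels x n_levels-1), columns _|_ 1."""
    if n_levels < 2:
        return np.zeros((max(n_levels, 1), 0))
    return helmert(n_levels).T


def _pivot_cells(
    data: pd.DataFrame,
    dv: str,
    subject: str,
    between: str,
    within: Sequence[str],
) -> Tuple[np.ndarray, np.ndarray, list, list[list]]:
    """Return (Y[N, n_cells], group labels[N], group levels, within levels).

    Cells are ordered by the cartesian product of the sorted within-factor
    levels (first factor slowest).  Raises on incomplete or duplicated
    within-cells.
    """
    for col in (dv, subject, between, *within):
        if col not in data.columns:
            raise ValueError(f"column {col!r} missing from data")
    levels = [sorted(data[w].unique()) for w in within]
    pivot = data.pivot_table(
        index=[subject, between],
        columns=list(within),
        values=dv,
        aggfunc="count",
    )
    if pivot.isna().any().any():
        raise ValueError("incomplete within-subject cells")
    if (pivot != 1).any().any():
        raise ValueError("duplicated subject x within-cell observations")
    wide = data.pivot_table(
        index=[subject, between], columns=list(within), values=dv, aggfunc="mean"
    )
    # order columns as the cartesian product of sorted levels
    cols = list(itertools.product(*levels)) if len(within) > 1 else levels[0]
    wide = wide[cols]
    groups = wide.index.get_level_values(between).to_numpy()
    group_levels = sorted(pd.unique(groups))
    if len(group_levels) < 2:
        raise ValueError("between factor needs at least 2 levels")
    counts = pd.Series(groups).value_counts()
    if counts.min() < 2:
        raise ValueError("every group needs at least 2 subjects")
    return wide.to_numpy(dtype=float), groups, group_levels, levels


def _within_effect_sums(
    Y: np.ndarray,
    groups: np.ndarray,
    group_levels: list,
    K: np.ndarray,
    mult: float,
) -> Tuple[float, float, float]:
    """(SS_effect, SS_group_interaction, SS_error) for one within effect."""
    n_g = np.array([(groups == g).sum() for g in group_levels], dtype=float)
    N = Y.shape[0]
    k = len(group_levels)
    Z = Y @ K  # (N, q) contrast scores
    Zg = np.stack([Z[groups == g].mean(axis=0) for g in group_levels])
    Zu = Zg.mean(axis=0)  # unweighted across groups
    Zw = (n_g[:, None] * Zg).sum(axis=0) / N  # weighted grand
    n_h = k / (1.0 / n_g).sum()  # harmonic mean group size
    ss_effect = mult * k * n_h * float(Zu @ Zu)
    ss_inter = mult * float((n_g[:, None] * (Zg - Zw) ** 2).sum())
    ss_error = 0.0
    for i, g in enumerate(group_levels):
        resid = Z[groups == g] - Zg[i]
        ss_error += float((resid**2).sum())
    ss_error *= mult
    return ss_effect, ss_inter, ss_error


def _f_row(effect, ss, df1, ss_err, df2, stratum) -> dict:
    ms = ss / df1
    ms_err = ss_err / df2
    F = ms / ms_err if ms_err > 0 else np.inf
    p = float(sps.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
    return {
        "effect": effect,
        "df_num": int(df1),
        "df_den": int(df2),
        "F": float(F),
        "p": p,
        "ss_effect": float(ss),
        "ms_error": float(ms_err),
        "error_stratum": stratum,
    }


def mixed_anova(
    data: pd.DataFrame,
    dv: str = "amplitude",
    subject: str = "subject_id",
    between: str = "group",
    within: Sequence[str] = ("region", "component"),
) -> pd.DataFrame:
    """Split-plot ANOVA with one between and one or two within factors.

    Returns a table with one row per effect (between main effect, every
    within effect, and each group interaction), columns ``effect, df_num,
    df_den, F, p, ss_effect, ms_error, error_stratum``.
    """
    within = list(within)
    if not 1 <= len(within) <= 2:
        raise ValueError("mixed_anova supports 1 or 2 within factors")
    Y, groups, group_levels, levels = _pivot_cells(
        data, dv, subject, between, within
    )
    N = Y.shape[0]
    k = len(group_levels)
    n_cells = Y.shape[1]
    n_g = np.array([(groups == g).sum() for g in group_levels], dtype=float)

    rows = []
    # --- between-subject stratum -----------------------------------------
    m_s = Y.mean(axis=1)
    Mg = np.array([m_s[groups == g].mean() for g in group_levels])
    W = (n_g * Mg).sum() / N
    ss_group = n_cells * float((n_g * (Mg - W) ** 2).sum())
    ss_subj = n_cells * sum(
        float(((m_s[groups == g] - Mg[i]) ** 2).sum())
        for i, g in enumerate(group_levels)
    )
    rows.append(
        _f_row(between, ss_group, k - 1, ss_subj, N - k, "subjects_within_groups")
    )

    # --- within-subject strata -------------------------------------------
    sizes = [len(lv) for lv in levels]
    Ms = [_contrasts(s) for s in sizes]
    Js = [np.full((s, 1), 1.0 / s) for s in sizes]

    def kron_for(subset: Tuple[int, ...]) -> Tuple[np.ndarray, float, int]:
        mats = []
        mult = 1.0
        q = 1
        for i, s in enumerate(sizes):
            if i in subset:
                mats.append(Ms[i])
                q *= s - 1
            else:
                mats.append(Js[i])
                mult *= s
        K = mats[0]
        for m in mats[1:]:
            K = np.kron(K, m)
        return K, mult, q

    subsets = [(0,)] if len(within) == 1 else [(0,), (1,), (0, 1)]
    for subset in subsets:
        K, mult, q = kron_for(subset)
        if q == 0:  # degenerate (single-level) within factor: no effect rows
            continue
        ss_eff, ss_int, ss_err = _within_effect_sums(
            Y, groups, group_levels, K, mult
        )
        name = " x ".join(within[i] for i in subset)
        stratum = f"{name} x subjects_within_groups"
        df_err = q * (N - k)
        rows.append(_f_row(name, ss_eff, q, ss_err, df_err, stratum))
        rows.append(
            _f_row(f"{between} x {name}", ss_int, (k - 1) * q, ss_err, df_err, stratum)
        )
    return pd.DataFrame(rows)


def oneway_within_region(
    data: pd.DataFrame,
    dv: str = "amplitude",
    subject: str = "subject_id",
    between: str = "group",
    within: str = "component",
) -> pd.DataFrame:
    """Per-region model: group between, one within factor."""
    return mixed_anova(data, dv=dv, subject=subject, between=between, within=[within])


def oneway_anova(values: np.ndarray, groups: np.ndarray) -> dict:
    """Classical one-way between-groups ANOVA on per-subject scalars."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    group_levels = sorted(pd.unique(groups))
    if len(group_levels) < 2:
        raise ValueError("need at least 2 groups")
    N = values.size
    k = len(group_levels)
    grand = values.mean()
    ss_between = ss_within = 0.0
    for g in group_levels:
        x = values[groups == g]
        if x.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 subjects")
        ss_between += x.size * (x.mean() - grand) ** 2
        ss_within += float(((x - x.mean()) ** 2).sum())
    df1, df2 = k - 1, N - k
    ms_between = ss_between / df1
    ms_within = ss_within / df2
    F = ms_between / ms_within if ms_within > 0 else np.inf
    p = float(sps.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
    return {
        "effect": "group",
        "df_num": df1,
        "df_den": df2,
        "F": float(F),
        "p": p,
        "ms_error": float(ms_within),
    }


def cohens_d(x: np.ndarray, y: np.ndarray) -> float:
    """Standardized mean difference with (n-1)-weighted pooled SD.

    No small-sample correction is applied.  Raises when the pooled SD is
    zero (degenerate samples).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs n >= 2")
    nx, ny = x.size, y.size
    pooled_var = (
        (nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)
    ) / (nx + ny - 2)
    if pooled_var <= 0:
        raise ValueError("pooled standard deviation is zero")
    return float((x.mean() - y.mean()) / np.sqrt(pooled_var))


def fisher_lsd(
    values: np.ndarray,
    groups: np.ndarray,
    ms_error: Optional[float] = None,
    df_error: Optional[int] = None,
) -> pd.DataFrame:
    """Fisher LSD pairwise comparisons on per-subject scalar responses.

    ``t = (m_i - m_j) / sqrt(MSe * (1/n_i + 1/n_j))`` with the supplied
    error mean square and df (defaults: the one-way within-groups MSE).
    Two-sided p, no multiplicity correction; Cohen's d from the raw group
    samples.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    group_levels = sorted(pd.unique(groups))
    if ms_error is None or df_error is None:
        ctx = oneway_anova(values, groups)
        ms_error = ctx["ms_error"] if ms_error is None else ms_error
        df_error = ctx["df_den"] if df_error is None else df_error
    if ms_error <= 0:
        raise ValueError("error mean square must be positive")
    rows = []
    for gi, gj in itertools.combinations(group_levels, 2):
        x = values[groups == gi]
        y = values[groups == gj]
        diff = float(x.mean() - y.mean())
        se = float(np.sqrt(ms_error * (1.0 / x.size + 1.0 / y.size)))
        t = diff / se
        p = float(2.0 * sps.t.sf(abs(t), df_error))
        rows.append(
            {
                "group_a": gi,
                "group_b": gj,
                "mean_diff": diff,
                "t": float(t),
                "df": int(df_error),
                "p": p,
                "cohens_d": cohens_d(x, y),
            }
        )
    return pd.DataFrame(rows)


# components entering each stage of the reporting bundle
GLOBAL_COMPONENTS = ("f0_amp", "f1_mean", "non_f1_mean", "mean_h")
CONSONANT_COMPONENTS = ("f0_amp", "mean_h")
VOWEL_COMPONENTS = ("f0_amp", "f1_mean", "non_f1_mean")


def _melt(features: pd.DataFrame, components: Sequence[str]) -> pd.DataFrame:
    long = features.melt(
        id_vars=["subject_id", "group", "region"],
        value_vars=list(components),
        var_name="component",
        value_name="amplitude",
    )
    return long


def _stage(
    long: pd.DataFrame,
    within: Sequence[str],
    alpha: float,
    posthoc_always: bool,
) -> dict:
    table = mixed_anova(long, within=within)
    group_row = table.loc[table["effect"] == "group"].iloc[0]
    out = {"anova": table.to_dict(orient="records"), "posthoc": None}
    if posthoc_always or group_row["p"] < alpha:
        # LSD on subject means across within cells; MS_subj rescaled to the
        # subject-mean scale (divide by the number of within cells)
        n_cells = int(
            long.groupby("subject_id", observed=True).size().iloc[0]
        )
        subj = (
            long.groupby(["subject_id", "group"], observed=True)["amplitude"]
            .mean()
            .reset_index()
        )
        out["posthoc"] = fisher_lsd(
            subj["amplitude"].to_numpy(),
            subj["group"].to_numpy(),
            ms_error=float(group_row["ms_error"]) / n_cells,
            df_error=int(group_row["df_den"]),
        ).to_dict(orient="records")
    return out


def run_paper_analysis(
    features: pd.DataFrame,
    alpha: float = 0.05,
    posthoc_always: bool = False,
) -> dict:
    """Full statistical report on a long (subject x region) feature table.

    Stages: (1) global group x region x component model on the four-band
    table; (2) consonant model on {F0, harmonic mean}; (3) vowel model on
    {F0, F1 mean, non-F1 mean}; (4) per-component one-way group ANOVAs per
    region, with Fisher LSD + Cohen's d wherever the omnibus group effect
    has ``p < alpha`` (or always with ``posthoc_always``).
    """
    required = {"subject_id", "group", "region", *GLOBAL_COMPONENTS}
    missing = required - set(features.columns)
    if missing:
        raise ValueError(f"features table missing columns {sorted(missing)}")
    if features["group"].nunique() < 2:
        raise ValueError("between factor needs >= 2 groups")
    regions = set(features["region"].unique())
    if regions != {"consonant", "vowel"}:
        raise ValueError(f"expected consonant+vowel regions, got {sorted(regions)}")

    results: dict = {
        "n_subjects": int(features["subject_id"].nunique()),
        "groups": features.groupby("group", observed=True)["subject_id"]
        .nunique()
        .to_dict(),
        "alpha": alpha,
    }
    try:
        results["global"] = _stage(
            _melt(features, GLOBAL_COMPONENTS),
            ("region", "component"),
            alpha,
            posthoc_always,
        )
    except ValueError as err:
        raise ValueError(f"global model: {err}") from err

    for region, comps in (
        ("consonant", CONSONANT_COMPONENTS),
        ("vowel", VOWEL_COMPONENTS),
    ):
        sub = features.loc[features["region"] == region]
        try:
            results[region] = _stage(
                _melt(sub, comps), ("component",), alpha, posthoc_always
            )
        except ValueError as err:
            raise ValueError(f"{region} model: {err}") from err

        per_component = {}
        for comp in comps:
            vals = sub[comp].to_numpy()
            grp = sub["group"].to_numpy()
            res = oneway_anova(vals, grp)
            entry = {"anova": res, "posthoc": None}
            if posthoc_always or res["p"] < alpha:
                entry["posthoc"] = fisher_lsd(
                    vals, grp, ms_error=res["ms_error"], df_error=res["df_den"]
                ).to_dict(orient="records")
            per_component[comp] = entry
        results[f"{region}_per_component"] = per_component
    return results
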