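"""Three-group statistics: ANOVA, LSD post hoc, FDR, partial correlations.

The inference stage compares OCD, UFDR and HC groups on (a) the three
temporal-dynamics indices, and (b) per-state connectivity strength for every
component pair (family size m = N(N-1)/2 per state, 741 for 39 components),
with Benjamini-Hochberg FDR within each family.  Within the patient group,
partial correlations between temporal properties and symptom scales (Y-BOCS,
OCI-R) control for depression (BDI), anxiety (STAI state and trait) and
education.  Summary-statistic ANOVA and Pearson chi-square reproduce
demographics-table tests from printed means +- SD and contingency counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .clustering import StateModel
from .windows import WindowedFNC

DEFAULT_COVARIATES = ("bdi", "stai_state", "stai_trait", "education_years")
TEMPORAL_OUTCOMES = ("fw_state1", "fw_state2", "dt_state1", "dt_state2", "n_transitions")
SYMPTOM_SCALES = ("ybocs_total", "ocir")


def subject_state_connectivity(
    fnc: WindowedFNC,
    model: StateModel,
    aggregation: str = "mean",
) -> np.ndarray:
    """Per-subject, per-state connectivity profile: (S, K, P) array.

    Entry [s, k, :] aggregates subject s's Fisher-z vectors over the windows
    assigned to state k+1 (mean by default, median optionally); NaN where the
    subject never visits the state.
    """
    if aggregation not in ("mean", "median"):
        raise ValueError("aggregation must be 'mean' or 'median'")
    agg = np.mean if aggregation == "mean" else np.median
    S, W, P = fnc.values.shape
    if model.labels.shape != (S, W):
        raise ValueError("state labels not aligned with windowed connectivity")
    out = np.full((S, model.k, P), np.nan)
    for s in range(S):
        for k in range(model.k):
            mask = model.labels[s] == k + 1
            if mask.any():
                out[s, k] = agg(fnc.values[s, mask], axis=0)
    return out


def oneway_anova(groups: Sequence[np.ndarray]):
    """One-way fixed-effects ANOVA; accepts (n_g,) or (n_g, m) per group.

    Returns ``(F, p, (df_between, df_within))`` with F and p scalars or
    length-m arrays.  Vectorized so a 741-pair family is a single call.
    """
    groups = [np.atleast_1d(np.asarray(g, dtype=float)) for g in groups]
    if len(groups) < 2 or any(g.shape[0] < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    ns = np.asarray([g.shape[0] for g in groups])
    n, G = ns.sum(), len(groups)
    means = np.stack([g.mean(axis=0) for g in groups])
    allv = np.concatenate(groups, axis=0)
    grand = allv.mean(axis=0)
    ssb = (ns[:, None] if means.ndim > 1 else ns) * (means - grand) ** 2
    ssb = ssb.sum(axis=0)
    ssw = sum(((g - m) ** 2).sum(axis=0) for g, m in zip(groups, means))
    dfb, dfw = G - 1, n - G
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / dfb) / (ssw / dfw)
    if np.any(~np.isfinite(F)):
        raise ValueError("zero pooled within-group variance")
    p = stats.f.sf(F, dfb, dfw)
    return F, p, (dfb, dfw)


def anova_from_summary(
    means: Sequence[float], sds: Sequence[float], ns: Sequence[int]
) -> tuple[float, float]:
    """One-way ANOVA reconstructed from printed group means, SDs and sizes."""
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    ns = np.asarray(ns)
    if np.any(ns < 2) or np.any(sds < 0):
        raise ValueError("need n >= 2 and sd >= 0 per group")
    n, G = ns.sum(), len(ns)
    grand = (ns * means).sum() / n
    ssb = (ns * (means - grand) ** 2).sum()
    ssw = ((ns - 1) * sds**2).sum()
    if ssw == 0:
        if np.allclose(means, means[0]):
            raise ValueError("all SDs zero with equal means: F undefined")
        return np.inf, 0.0
    F = (ssb / (G - 1)) / (ssw / (n - G))
    return float(F), float(stats.f.sf(F, G - 1, n - G))


def lsd_posthoc(groups: Sequence[np.ndarray], labels: Sequence[str] | None = None):
    """Fisher's LSD: pairwise t using pooled within-group variance, df = n - G.

    Returns ``{(label_a, label_b): (t, p)}``; t and p are arrays for
    multi-outcome input.  p-values are unadjusted, as the procedure defines.
    """
    groups = [np.atleast_1d(np.asarray(g, dtype=float)) for g in groups]
    ns = np.asarray([g.shape[0] for g in groups])
    n, G = ns.sum(), len(groups)
    if labels is None:
        labels = [f"g{i + 1}" for i in range(G)]
    means = [g.mean(axis=0) for g in groups]
    ssw = sum(((g - m) ** 2).sum(axis=0) for g, m in zip(groups, means))
    msw = ssw / (n - G)
    out = {}
    for i in range(G):
        for j in range(i + 1, G):
            se = np.sqrt(msw * (1.0 / ns[i] + 1.0 / ns[j]))
            with np.errstate(divide="ignore", invalid="ignore"):
                t = (means[i] - means[j]) / se
            t = np.where(se == 0, 0.0, t) if np.ndim(t) else (0.0 if se == 0 else t)
            p = 2 * stats.t.sf(np.abs(t), n - G)
            out[(labels[i], labels[j])] = (t, p)
    return out


def bh_fdr(pvals: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (adjusted p, rejection mask at level q)."""
    pvals = np.asarray(pvals, dtype=float)
    if np.any((pvals < 0) | (pvals > 1) | ~np.isfinite(pvals)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(pvals, alpha=q, method="fdr_bh")
    return p_adj, reject


def chi_square(table: np.ndarray) -> tuple[float, float, int]:
    """Pearson chi-square of independence on a G x C contingency table."""
    table = np.asarray(table, dtype=float)
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("contingency table has a zero margin")
    res = stats.chi2_contingency(table, correction=False)
    return float(res.statistic), float(res.pvalue), int(res.dof)


def partial_correlation(
    x: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
) -> tuple[float, float]:
    """Pearson correlation of x and y after residualizing both on covariates.

    Covariates enter a least-squares fit with intercept; p comes from the t
    distribution with df = n - n_covariates - 2.  An empty covariate set
    reduces to the plain Pearson correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if covariates is None or (hasattr(covariates, "size") and np.asarray(covariates).size == 0):
        Z = np.ones((n, 1))
        ncov = 0
    else:
        covariates = np.asarray(covariates, dtype=float)
        if covariates.ndim == 1:
            covariates = covariates[:, None]
        Z = np.column_stack([np.ones(n), covariates])
        ncov = covariates.shape[1]
        if np.linalg.matrix_rank(Z) < Z.shape[1]:
            raise ValueError("rank-deficient covariate matrix")
    if n <= ncov + 2:
        raise ValueError("too few observations for the covariate set")
    rx = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
    ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
    # a variable fully explained by the covariates has no residual to
    # correlate; report 0 rather than the correlation of rounding noise
    if (rx**2).sum() <= 1e-24 * max((x**2).sum(), 1.0) or (
        ry**2
    ).sum() <= 1e-24 * max((y**2).sum(), 1.0):
        return 0.0, 1.0
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    r = float(np.clip((rx * ry).sum() / denom, -1.0, 1.0))
    df = n - ncov - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r**2))
    p = float(2 * stats.t.sf(abs(t), df)) if abs(r) < 1 else 0.0
    return r, p


@dataclass
class GroupAnalysisResult:
    temporal: pd.DataFrame
    connectivity: dict[int, pd.DataFrame]
    clinical: pd.DataFrame
    exclusions: dict[int, int]
    q: float
    warnings_: list[str] = field(default_factory=list)


def run_group_analysis(
    metrics: pd.DataFrame,
    profiles: np.ndarray | None,
    manifest: pd.DataFrame,
    q: float = 0.05,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    group_order: Sequence[str] = ("OCD", "UFDR", "HC"),
    patient_group: str = "OCD",
    pair_ids: Sequence[tuple[str, str]] | None = None,
) -> GroupAnalysisResult:
    """Full inference stage over a cohort's metrics and state profiles.

    * temporal indices: one-way ANOVA + LSD over all subjects, BH within the
      five-outcome family;
    * per-state connectivity: ANOVA + LSD per pair with BH at family size
      m = P, subjects missing the state excluded listwise (counts reported),
      a family skipped with a warning when any group retains < 2 subjects;
    * clinical: partial correlations (metric x symptom scale) within the
      patient group, BH across that family.
    """
    df = metrics.merge(manifest, on="subject_id")
    groups_present = [g for g in group_order if (df["group"] == g).any()]
    warn_list: list[str] = []

    # --- temporal indices -------------------------------------------------
    rows = []
    all_outcomes = [c for c in TEMPORAL_OUTCOMES if c in df.columns]
    # outcomes with zero pooled within-group variance cannot be tested
    outcome_cols = []
    for c in all_outcomes:
        pooled = sum(
            ((df.loc[df["group"] == g, c].to_numpy(float)
              - df.loc[df["group"] == g, c].mean()) ** 2).sum()
            for g in groups_present
        )
        if pooled > 0:
            outcome_cols.append(c)
        else:
            msg = f"outcome {c}: zero within-group variance, ANOVA skipped"
            warnings.warn(msg)
            warn_list.append(msg)
    by_group = [df.loc[df["group"] == g, outcome_cols].to_numpy(float) for g in groups_present]
    if outcome_cols:
        F, p, (dfb, dfw) = oneway_anova(by_group)
        posthoc = lsd_posthoc(by_group, groups_present)
        p_adj, rej = bh_fdr(np.atleast_1d(p), q)
    else:
        F = p = p_adj = rej = np.empty(0)
        posthoc = {}
        dfb = dfw = 0
    for i, c in enumerate(outcome_cols):
        row = {
            "outcome": c,
            "F": np.atleast_1d(F)[i],
            "p": np.atleast_1d(p)[i],
            "p_fdr": p_adj[i],
            "reject": bool(rej[i]),
            "df1": dfb,
            "df2": dfw,
        }
        for g, arr in zip(groups_present, by_group):
            row[f"mean_{g}"] = arr[:, i].mean()
            row[f"sd_{g}"] = arr[:, i].std(ddof=1)
        for (a, b), (t, pp) in posthoc.items():
            row[f"t_{a}_vs_{b}"] = np.atleast_1d(t)[i]
            row[f"p_{a}_vs_{b}"] = np.atleast_1d(pp)[i]
        rows.append(row)
    temporal = pd.DataFrame(
        rows, columns=None if rows else ["outcome", "F", "p", "p_fdr", "reject", "df1", "df2"]
    )

    # --- per-state connectivity -------------------------------------------
    connectivity: dict[int, pd.DataFrame] = {}
    exclusions: dict[int, int] = {}
    if profiles is not None:
        S, K, P = profiles.shape
        group_arr = df.set_index("subject_id").loc[metrics["subject_id"], "group"].to_numpy()
        for k in range(K):
            prof = profiles[:, k, :]
            present = ~np.isnan(prof).any(axis=1)
            exclusions[k + 1] = int((~present).sum())
            sub = [prof[present & (group_arr == g)] for g in groups_present]
            if any(len(a) < 2 for a in sub):
                msg = f"state {k + 1}: a group has < 2 subjects, family skipped"
                warnings.warn(msg)
                warn_list.append(msg)
                continue
            F, p, (dfb, dfw) = oneway_anova(sub)
            p_adj, rej = bh_fdr(p, q)
            posthoc = lsd_posthoc(sub, groups_present)
            tab = {
                "pair": (
                    [f"{a}|{b}" for a, b in pair_ids]
                    if pair_ids is not None
                    else np.arange(P)
                ),
                "F": F,
                "p": p,
                "p_fdr": p_adj,
                "reject": rej,
            }
            for (a, b), (t, pp) in posthoc.items():
                tab[f"t_{a}_vs_{b}"] = t
                tab[f"p_{a}_vs_{b}"] = pp
            connectivity[k + 1] = pd.DataFrame(tab)

    # --- clinical partial correlations within the patient group -----------
    pat = df[df["group"] == patient_group]
    crows = []
    if len(pat) <= len(covariates) + 2:
        msg = (
            f"patient group n={len(pat)} too small for "
            f"{len(covariates)} covariates, clinical correlations skipped"
        )
        warnings.warn(msg)
        warn_list.append(msg)
    else:
        Z = pat.loc[:, list(covariates)].to_numpy(float) if len(covariates) else None
        for metric in outcome_cols:
            for scale in SYMPTOM_SCALES:
                if scale not in pat.columns:
                    continue
                r, pp = partial_correlation(
                    pat[metric].to_numpy(float), pat[scale].to_numpy(float), Z
                )
                crows.append({"metric": metric, "scale": scale, "r": r, "p": pp})
    clinical = pd.DataFrame(crows, columns=["metric", "scale", "r", "p"])
    if len(clinical):
        p_adj, rej = bh_fdr(clinical["p"].to_numpy(), q)
        clinical["p_fdr"] = p_adj
        clinical["reject"] = rej
    else:
        clinical["p_fdr"] = pd.Series(dtype=float)
        clinical["reject"] = pd.Series(dtype=bool)

    return GroupAnalysisResult(temporal, connectivity, clinical, exclusions, q, warn_list)
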