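"""Repeated-measures statistics on absorption-factor tables.

The design is a subject-by-treatment (split-plot) layout: each wing set
is a subject, the preparation (or preparation group) it belongs to is
the between-subjects factor, and the analysis band is the
within-subject factor.  The battery comprises

* a one-way ANOVA on the subjects' marginal means across bands
  (the between-subjects test);
* Mauchly's sphericity test on the pooled within-group covariance of
  the band measures, with the Greenhouse-Geisser epsilon;
* the within-subject repeated-measures ANOVA (band main effect and
  between x band interaction), optionally with Greenhouse-Geisser
  corrected — possibly non-integer — degrees of freedom;
* Tukey-Kramer studentized-range pairwise comparisons, either on the
  marginal means or separately per band with each band's own one-way
  error term (no extra multiplicity correction across bands).

Everything assumes a balanced design (equal sets per level, complete
band grids); Tukey-Kramer additionally handles unequal group sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .types import Band, RMDataset


@dataclass
class RMFit:
    """Fitted subject-by-treatment summary of a balanced design."""

    between: str                       # "preparation" | "group"
    levels: list[str]
    bands_hz: np.ndarray
    subjects: pd.DataFrame             # columns: subject, level, marginal_mean
    data_wide: pd.DataFrame            # index subject, columns band, values alpha
    subject_levels: pd.Series          # level per subject (aligned to data_wide)
    cell_means: pd.DataFrame           # index level, columns band
    pooled_cov: np.ndarray             # pooled within-level covariance (k x k)
    n_per_level: dict[str, int]

    @property
    def n_subjects(self) -> int:
        return len(self.data_wide)

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    @property
    def n_bands(self) -> int:
        return len(self.bands_hz)


@dataclass(frozen=True)
class AnovaResult:
    """One F test, with (possibly corrected, non-integer) dfs."""

    effect: str
    F: float
    df1: float
    df2: float
    p: float
    epsilon: float = 1.0


def fit_rm(dataset: RMDataset, between: str = "preparation") -> RMFit:
    """Summarise a balanced long table into the quantities the tests need.

    Raises on an unbalanced design, identifying the offending cell, and
    requires at least two subjects per between-level (else the pooled
    covariance is undefined).
    """
    if between not in ("preparation", "group"):
        raise ValueError("between must be 'preparation' or 'group'")
    df = dataset.data
    bands = np.sort(df["fc_hz"].unique())
    wide = df.pivot_table(
        index=["set_id"], columns="fc_hz", values="alpha", aggfunc="first"
    ).reindex(columns=bands)
    if wide.isna().any().any():
        bad = wide[wide.isna().any(axis=1)].index[0]
        raise ValueError(f"unbalanced design: subject {bad!r} misses a band")
    level_of = df.groupby("set_id")[between].first().reindex(wide.index)

    counts = level_of.value_counts()
    if (counts < 2).any():
        bad = counts[counts < 2].index[0]
        raise ValueError(f"level {bad!r} has fewer than 2 subjects")

    levels = sorted(counts.index)
    cell_means = (
        df.groupby([between, "fc_hz"])["alpha"].mean().unstack().reindex(
            index=levels, columns=bands
        )
    )
    k = len(bands)
    pooled = np.zeros((k, k))
    dof = 0
    for lev in levels:
        X = wide[level_of == lev].to_numpy()
        pooled += (len(X) - 1) * np.cov(X, rowvar=False)
        dof += len(X) - 1
    pooled /= dof

    subjects = pd.DataFrame(
        {
            "subject": wide.index,
            "level": level_of.values,
            "marginal_mean": wide.mean(axis=1).values,
        }
    )
    return RMFit(
        between=between,
        levels=levels,
        bands_hz=bands,
        subjects=subjects,
        data_wide=wide,
        subject_levels=level_of,
        cell_means=cell_means,
        pooled_cov=pooled,
        n_per_level={lev: int(counts[lev]) for lev in levels},
    )


def between_anova(fit: RMFit) -> AnovaResult:
    """One-way ANOVA on the subjects' marginal means across bands."""
    if fit.n_levels < 2:
        raise ValueError("need at least 2 between-levels")
    y = fit.subjects["marginal_mean"].to_numpy()
    labels = fit.subjects["level"].to_numpy()
    grand = y.mean()
    ss_b = sum(
        (labels == lev).sum() * (y[labels == lev].mean() - grand) ** 2
        for lev in fit.levels
    )
    ss_w = sum(
        ((y[labels == lev] - y[labels == lev].mean()) ** 2).sum()
        for lev in fit.levels
    )
    df1 = fit.n_levels - 1
    df2 = fit.n_subjects - fit.n_levels
    F = (ss_b / df1) / (ss_w / df2)
    return AnovaResult(
        effect=fit.between, F=float(F), df1=df1, df2=df2,
        p=float(sps.f.sf(F, df1, df2)),
    )


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal contrast matrix (Helmert, normalised)."""
    C = np.zeros((k - 1, k))
    for i in range(k - 1):
        C[i, : i + 1] = 1.0
        C[i, i + 1] = -(i + 1.0)
        C[i] /= np.linalg.norm(C[i])
    return C


def sphericity(fit: RMFit) -> tuple[float, float, float]:
    """Mauchly's test and the Greenhouse-Geisser epsilon.

    Returns ``(chi2, p, epsilon)``.  Both are computed from the pooled
    within-level covariance projected onto orthonormal contrasts of the
    band measures; the chi-square approximation uses the pooled error
    degrees of freedom ``d = N - g``.
    """
    k = fit.n_bands
    if k < 2:
        raise ValueError("need at least 2 within-levels")
    d = fit.n_subjects - fit.n_levels
    C = _orthonormal_contrasts(k)
    A = C @ fit.pooled_cov @ C.T
    eigs = np.linalg.eigvalsh(A)
    if eigs[0] <= 1e-14 * max(eigs[-1], 1e-300):
        raise ValueError(
            "singular within-subject covariance: need more subjects than "
            "bands, or reduce the band set"
        )
    p_dim = k - 1
    W = np.prod(eigs) / (eigs.mean()) ** p_dim
    f_corr = 1.0 - (2.0 * p_dim**2 + p_dim + 2.0) / (6.0 * p_dim * d)
    chi2 = -f_corr * d * np.log(W)
    df_chi = k * (k - 1) / 2.0 - 1.0
    p = float(sps.chi2.sf(chi2, df_chi))
    gg = eigs.sum() ** 2 / (p_dim * (eigs**2).sum())
    gg = float(np.clip(gg, 1.0 / p_dim, 1.0))
    return float(chi2), p, gg


def within_anova(
    fit: RMFit, correction: str = "greenhouse_geisser"
) -> list[AnovaResult]:
    """Band main effect and between x band interaction F tests.

    Balanced split-plot decomposition with the subject-by-band residual
    as the error term.  Under ``greenhouse_geisser`` the p-values use
    epsilon-deflated (non-integer) degrees of freedom.
    """
    if correction not in ("none", "greenhouse_geisser"):
        raise ValueError(f"unknown correction {correction!r}")
    Y = fit.data_wide.to_numpy()
    labels = fit.subject_levels.to_numpy()
    N, k = Y.shape
    g = fit.n_levels
    grand = Y.mean()
    band_means = Y.mean(axis=0)
    subj_means = Y.mean(axis=1)

    ss_band = N * ((band_means - grand) ** 2).sum()
    ss_inter = 0.0
    ss_err = 0.0
    for lev in fit.levels:
        sel = labels == lev
        X = Y[sel]
        n = sel.sum()
        lev_band = X.mean(axis=0)
        lev_mean = X.mean()
        ss_inter += n * ((lev_band - band_means - lev_mean + grand) ** 2).sum()
        resid = X - lev_band[None, :] - X.mean(axis=1)[:, None] + lev_mean
        ss_err += (resid**2).sum()

    df_band = k - 1
    df_inter = (g - 1) * (k - 1)
    df_err = (N - g) * (k - 1)
    ms_err = ss_err / df_err

    eps = 1.0
    if correction == "greenhouse_geisser":
        _, _, eps = sphericity(fit)

    effects = [("band", ss_band, df_band)]
    if g > 1:
        effects.append((f"{fit.between} x band", ss_inter, df_inter))
    out = []
    for effect, ss, df1 in effects:
        F = (ss / df1) / ms_err
        p = float(sps.f.sf(F, eps * df1, eps * df_err))
        out.append(
            AnovaResult(effect=effect, F=float(F), df1=df1, df2=df_err,
                        p=p, epsilon=eps)
        )
    return out


def tukey_kramer(
    dataset: RMDataset,
    between: str = "preparation",
    at_band: Band | float | None = None,
) -> pd.DataFrame:
    """Studentized-range pairwise comparisons between levels.

    ``at_band=None`` compares subject marginal means across bands
    (one value per subject); passing a band (or its centre frequency in
    Hz) compares that band's values with the band's own one-way error
    term.  The Kramer adjustment handles unequal group sizes.  Returns
    a table with columns level_a, level_b, mean_diff, q, p.
    """
    fit = fit_rm(dataset, between)
    if at_band is None:
        y = fit.subjects["marginal_mean"].to_numpy()
        labels = fit.subjects["level"].to_numpy()
    else:
        fc = at_band.fc if isinstance(at_band, Band) else float(at_band)
        match = np.isclose(fit.bands_hz, fc)
        if not match.any():
            raise ValueError(f"band {fc} Hz not present in the dataset")
        y = fit.data_wide.iloc[:, int(np.argmax(match))].to_numpy()
        labels = fit.subject_levels.to_numpy()

    g = fit.n_levels
    if g < 2:
        raise ValueError("need at least 2 levels")
    means = {lev: y[labels == lev].mean() for lev in fit.levels}
    ns = {lev: int((labels == lev).sum()) for lev in fit.levels}
    df_err = len(y) - g
    mse = sum(
        ((y[labels == lev] - means[lev]) ** 2).sum() for lev in fit.levels
    ) / df_err

    rows = []
    for a, b in combinations(fit.levels, 2):
        diff = means[a] - means[b]
        se = np.sqrt(mse / 2.0 * (1.0 / ns[a] + 1.0 / ns[b]))
        q = abs(diff) / se if se > 0 else 0.0
        p = float(sps.studentized_range.sf(q, g, df_err)) if q > 0 else 1.0
        rows.append(
            {"level_a": a, "level_b": b, "mean_diff": float(diff),
             "q": float(q), "p": min(p, 1.0)}
        )
    return pd.DataFrame(rows)


def significance_marker(p: float) -> str:
    """The three-tier marker convention: *, **, *** at 0.05/0.01/0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""
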