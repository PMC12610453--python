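"""Delta-Ct normalization and two-group differential expression.

Per-sample normalization subtracts the arithmetic mean Ct of the detected
housekeeping references; group effects are summarized as the difference of
group-mean delta-Ct (ddCt), reported as log2 fold regulation = -ddCt so that
positive values mean up-regulation in the first-named group. Inference is a
Welch two-sample t-test per assay with Benjamini-Hochberg adjustment across
the tested assays of a contrast, and a dual significance filter
|log2 fold regulation| > 1 and FDR < 0.05.

The Welch statistic and the BH step-up are implemented directly (not delegated
to scipy/statsmodels) so the test suite can verify them against those
libraries as independent references.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from mirpanel.panel_io import DE_COLUMNS, CtTable, SampleMeta

DEFAULT_LFC_THRESHOLD = 1.0
DEFAULT_FDR_THRESHOLD = 0.05


@dataclass
class DeltaCtTable:
    """Normalized delta-Ct values for target assays only.

    ``dct`` is samples x target assays; NaN marks undetected cells. Relative
    expression 2**-dct is derived, never stored.
    """

    dct: pd.DataFrame

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(self.dct.index)

    @property
    def target_assay_ids(self) -> tuple[str, ...]:
        return tuple(self.dct.columns)

    @property
    def rel_expr(self) -> pd.DataFrame:
        return 2.0 ** (-self.dct)


@dataclass(frozen=True)
class Contrast:
    """Two disjoint sample groups; group A is the reported-up direction."""

    name: str
    group_a_ids: tuple[str, ...]
    group_b_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        a, b = set(self.group_a_ids), set(self.group_b_ids)
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"contrast {self.name!r}: each group needs >=2 samples")
        if a & b:
            raise ValueError(f"contrast {self.name!r}: groups overlap: {sorted(a & b)}")
        object.__setattr__(self, "group_a_ids", tuple(self.group_a_ids))
        object.__setattr__(self, "group_b_ids", tuple(self.group_b_ids))


def normalize_delta_ct(ct_table: CtTable) -> DeltaCtTable:
    """delta-Ct = target Ct minus the mean of detected housekeeping Cts.

    Undetected target cells propagate as NaN; a sample with no detected
    housekeeping assay is an error (there is nothing to normalize against).
    """
    layout = ct_table.layout
    if not layout.housekeeping_assays:
        raise ValueError("layout has no housekeeping assays")
    frame = ct_table.to_frame()
    det = pd.DataFrame(
        ct_table.detected, index=frame.index, columns=frame.columns
    )

    hk = frame[list(layout.housekeeping_assays)]
    hk_det = det[list(layout.housekeeping_assays)]
    n_det = hk_det.sum(axis=1)
    dead = n_det[n_det == 0].index.tolist()
    if dead:
        raise ValueError(f"no detected housekeeping assay for samples: {dead}")
    hk_mean = hk.where(hk_det).mean(axis=1)

    targets = list(layout.target_assays)
    dct = frame[targets].where(det[targets]).sub(hk_mean, axis=0)
    return DeltaCtTable(dct=dct)


def welch_test(a: Sequence[float], b: Sequence[float]) -> tuple[float, float, float]:
    """Welch's two-sample t-test: returns (t, Satterthwaite df, two-sided p).

    Degenerate inputs follow fixed conventions: identical constant groups give
    p = 1; constant groups with different means give p = 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError(f"welch_test needs >=2 values per group (got {na}, {nb})")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    diff = a.mean() - b.mean()
    if va == 0.0 and vb == 0.0:
        df = float(na + nb - 2)
        if diff == 0.0:
            return 0.0, df, 1.0
        return math.copysign(math.inf, diff), df, 0.0
    qa, qb = va / na, vb / nb
    t = diff / math.sqrt(qa + qb)
    df = (qa + qb) ** 2 / (qa**2 / (na - 1) + qb**2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(min(p, 1.0))


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Monotone non-decreasing in rank after the reverse cumulative minimum,
    capped at 1; tied raw p-values receive identical adjusted values.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj


def run_contrast(
    dct: DeltaCtTable,
    contrast: Contrast,
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
    fdr_threshold: float = DEFAULT_FDR_THRESHOLD,
) -> pd.DataFrame:
    """Per-assay ddCt, fold regulation, Welch p, BH FDR and significance flag.

    Assays with fewer than 2 non-missing values in either group are reported
    with ``tested = False`` and excluded from the BH family, so the
    multiplicity m equals the number of assays actually tested.
    """
    missing = (set(contrast.group_a_ids) | set(contrast.group_b_ids)) - set(
        dct.sample_ids
    )
    if missing:
        raise ValueError(f"contrast samples absent from delta-Ct table: {sorted(missing)}")

    a_frame = dct.dct.loc[list(contrast.group_a_ids)]
    b_frame = dct.dct.loc[list(contrast.group_b_ids)]

    rows = []
    for assay in dct.target_assay_ids:
        a = a_frame[assay].to_numpy(dtype=float)
        b = b_frame[assay].to_numpy(dtype=float)
        a, b = a[~np.isnan(a)], b[~np.isnan(b)]
        if a.size < 2 or b.size < 2:
            rows.append(
                dict(
                    mirna=assay, mean_dct_a=np.nan, mean_dct_b=np.nan, ddct=np.nan,
                    log2_fold_reg=np.nan, fold_reg=np.nan, t_stat=np.nan,
                    welch_df=np.nan, p=np.nan, fdr=np.nan,
                    significant=False, tested=False,
                )
            )
            continue
        t, df, p = welch_test(a, b)
        ddct = float(a.mean() - b.mean())
        rows.append(
            dict(
                mirna=assay, mean_dct_a=float(a.mean()), mean_dct_b=float(b.mean()),
                ddct=ddct, log2_fold_reg=-ddct, fold_reg=float(2.0**-ddct),
                t_stat=t, welch_df=df, p=p, fdr=np.nan,
                significant=False, tested=True,
            )
        )
    de = pd.DataFrame(rows, columns=list(DE_COLUMNS))
    tested = de["tested"].to_numpy()
    if tested.any():
        de.loc[tested, "fdr"] = bh_adjust(de.loc[tested, "p"].to_numpy())
        de["significant"] = (
            tested
            & (de["fdr"] < fdr_threshold)
            & (de["log2_fold_reg"].abs() > lfc_threshold)
        )
    return de


def _grade_dummies(grades: Sequence[str]) -> pd.DataFrame:
    # Unordered categorical coding, first level dropped as reference.
    cat = pd.Categorical([str(g) for g in grades])
    return pd.get_dummies(pd.Series(cat), prefix="grade", drop_first=True).astype(float)


def covariate_adjustment(
    dct: DeltaCtTable,
    meta: Sequence[SampleMeta],
    mirnas: Iterable[str],
    contrast: Contrast | None = None,
    covariates: Sequence[str] = ("age", "bmi", "grade"),
) -> pd.DataFrame:
    """OLS of delta-Ct on group plus clinical covariates, per selected miRNA.

    Returns one row per miRNA with the group coefficient re-oriented to the
    fold-regulation scale (``group_log2_fold_reg`` = -group coefficient, so
    positive means up in group A), its standard error, and normal-theory
    p-values for the group term and each covariate.
    """
    by_id = {m.sample_id: m for m in meta}
    if contrast is None:
        a_ids = tuple(m.sample_id for m in meta if m.group == "cancer")
        b_ids = tuple(m.sample_id for m in meta if m.group == "healthy")
        contrast = Contrast("cancer_vs_healthy", a_ids, b_ids)
    samples = list(contrast.group_a_ids) + list(contrast.group_b_ids)
    for s in samples:
        if s not in by_id:
            raise ValueError(f"sample {s!r} missing from metadata")
        rec = by_id[s]
        for cov in covariates:
            if getattr(rec, cov) is None:
                raise ValueError(f"sample {s!r}: covariate {cov!r} is missing")

    design = pd.DataFrame(index=samples)
    design["intercept"] = 1.0
    design["group"] = [1.0 if s in set(contrast.group_a_ids) else 0.0 for s in samples]
    for cov in covariates:
        if cov == "grade":
            dummies = _grade_dummies([by_id[s].grade for s in samples])
            dummies.index = samples
            if dummies.shape[1] == 0:
                raise ValueError(
                    "rank-deficient design: column 'grade' is constant"
                )
            design = pd.concat([design, dummies], axis=1)
        else:
            design[cov] = [float(getattr(by_id[s], cov)) for s in samples]

    X = design.to_numpy(dtype=float)
    rank = 0
    collinear = []
    for j, col in enumerate(design.columns):
        r = np.linalg.matrix_rank(X[:, : j + 1])
        if r == rank:
            collinear.append(col)
        rank = r
    if collinear:
        raise ValueError(f"rank-deficient design: collinear columns {collinear}")

    import statsmodels.api as sm

    rows = []
    for mirna in mirnas:
        if mirna not in dct.dct.columns:
            raise KeyError(f"unknown assay {mirna!r}")
        y = dct.dct.loc[samples, mirna].to_numpy(dtype=float)
        if np.any(np.isnan(y)):
            keep = ~np.isnan(y)
            fit = sm.OLS(y[keep], X[keep]).fit()
        else:
            fit = sm.OLS(y, X).fit()
        idx = list(design.columns).index("group")
        row = dict(
            mirna=mirna,
            group_coef_dct=float(fit.params[idx]),
            group_log2_fold_reg=float(-fit.params[idx]),
            group_se=float(fit.bse[idx]),
            group_p=float(fit.pvalues[idx]),
        )
        for j, col in enumerate(design.columns):
            if col in ("intercept", "group"):
                continue
            row[f"p_{col}"] = float(fit.pvalues[j])
        rows.append(row)
    return pd.DataFrame(rows)
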