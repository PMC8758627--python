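"""mtDNA copy-number estimation and covariate adjustment.

Three assay paths produce a raw copy-number metric:

* **array** — the median mitochondrial probe intensity over homozygous
  mitochondrial SNPs, then stepwise removal of technical components
  (principal components or surrogate variables of the nuclear probes);
* **wgs/wes** — the ratio of mitochondrial reads to total aligned reads;
* **qPCR** — ΔCt corrected either by a linear mixed model (pipetting order
  fixed, plate random) or by per-plate calibrator samples.

Array estimates can be calibrated against a sequencing-derived metric on an
overlap subset, cell-count covariates are chosen by cross-validated forward
selection, and the final metric is the standardized residual (mean 0, sd 1)
after covariate regression.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.decomposition import PCA
from sklearn.model_selection import KFold

logger = logging.getLogger(__name__)

__all__ = [
    "MtcnMetric",
    "technical_components",
    "raw_mtcn_from_probes",
    "stepwise_component_adjust",
    "mtcn_from_read_counts",
    "mtcn_from_qpcr",
    "calibrate_array_to_wes",
    "select_cell_count_covariates",
    "exclude_cell_count_outliers",
    "standardize_residuals",
]


@dataclass
class MtcnMetric:
    """Per-sample raw and covariate-adjusted copy-number values.

    ``adjusted`` is on the standardized-residual scale: mean 0, sd 1 over
    non-missing samples.
    """

    raw: pd.Series
    adjusted: pd.Series
    assay: str
    covariates_used: list[str]

    def __post_init__(self) -> None:
        ok = self.adjusted.dropna()
        if len(ok) > 1:
            if abs(ok.mean()) > 1e-8 or abs(ok.std(ddof=1) - 1.0) > 1e-6:
                raise ValueError("adjusted metric is not standardized")


def technical_components(nuclear_intensities: pd.DataFrame,
                         n_components: int = 10) -> pd.DataFrame:
    """Principal components of nuclear probe intensities.

    Captures technical artifacts (DNA input quantity/quality, hybridisation
    efficiency, batch) that also contaminate the mitochondrial probes.
    Components are ordered by variance explained.
    """
    n_components = min(n_components, *nuclear_intensities.shape)
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(nuclear_intensities.to_numpy())
    return pd.DataFrame(scores, index=nuclear_intensities.index,
                        columns=[f"PC{j + 1}" for j in range(n_components)])


def raw_mtcn_from_probes(intensities: pd.DataFrame,
                         homozygous_mask: pd.DataFrame) -> pd.Series:
    """Median mitochondrial probe intensity over homozygous probes.

    Samples with no homozygous probe are returned missing with a warning.
    """
    if intensities.shape != homozygous_mask.shape:
        raise ValueError("intensities and mask shapes differ")
    vals = intensities.to_numpy(dtype=float).copy()
    vals[~homozygous_mask.to_numpy(dtype=bool)] = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        med = np.nanmedian(vals, axis=1)
    n_missing = int(np.isnan(med).sum())
    if n_missing:
        logger.warning("%d samples have no homozygous mitochondrial probe; "
                       "raw metric set missing", n_missing)
    return pd.Series(med, index=intensities.index, name="raw_mtcn")


def stepwise_component_adjust(
    raw_metric: pd.Series,
    components: pd.DataFrame | None,
    alpha: float = 0.05,
) -> tuple[pd.Series, int]:
    """Regress out leading technical components chosen stepwise.

    Components are added in order; inclusion stops at the first component
    whose added term is not significant at ``alpha`` (t-test).  Returns the
    residuals (centered) and the number of components used.
    """
    y = raw_metric.dropna()
    if components is None or components.shape[1] == 0:
        logger.warning("no technical components supplied; returning centered metric")
        out = raw_metric - y.mean()
        return out, 0
    comp = components.loc[y.index]
    k = 0
    for j in range(comp.shape[1]):
        X = sm.add_constant(comp.iloc[:, :j + 1].to_numpy())
        fit = sm.OLS(y.to_numpy(), X).fit()
        if fit.pvalues[-1] < alpha:
            k = j + 1
        else:
            break
    if k == 0:
        resid = y - y.mean()
    else:
        X = sm.add_constant(comp.iloc[:, :k].to_numpy())
        resid = pd.Series(sm.OLS(y.to_numpy(), X).fit().resid, index=y.index)
    return resid.reindex(raw_metric.index), k


def mtcn_from_read_counts(mt_reads, total_reads) -> pd.Series:
    """Ratio of mitochondrial reads to total aligned reads.

    Zero total reads yields a missing value with a warning.
    """
    mt = pd.Series(mt_reads, dtype=float)
    tot = pd.Series(total_reads, dtype=float)
    ratio = mt / tot.where(tot > 0)
    if (tot <= 0).any():
        logger.warning("%d samples with zero total reads set missing",
                       int((tot <= 0).sum()))
    return ratio.rename("raw_mtcn")


def _delta_ct(plate_data: pd.DataFrame) -> pd.DataFrame:
    df = plate_data.copy()
    df["delta_ct"] = df["mt_ct"] - df["nuclear_ct"]
    return df


def mtcn_from_qpcr(plate_data: pd.DataFrame,
                   design: str = "fixed_order_random_plate") -> pd.Series:
    """Corrected per-sample ΔCt from a qPCR plate table.

    ``fixed_order_random_plate``
        Linear mixed model (REML): pipetting order as fixed effect, plate as
        random intercept; returns per-sample mean residual ΔCt.  Falls back
        to plate-mean centering followed by order regression if the mixed
        model does not converge.
    ``calibrator``
        Subtracts each plate's mean calibrator deviation from ΔCt; plates
        without calibrators are flagged and their samples set missing.

    Note the sign: ΔCt *decreases* with copy number, so downstream users
    typically negate this metric before covariate adjustment.
    """
    required = {"sample_id", "plate", "order", "mt_ct", "nuclear_ct"}
    missing_cols = required - set(plate_data.columns)
    if missing_cols:
        raise ValueError(f"plate table missing columns: {sorted(missing_cols)}")
    df = _delta_ct(plate_data)
    if (df[["mt_ct", "nuclear_ct"]] <= 0).any().any():
        raise ValueError("Ct values must be positive")

    if design == "calibrator":
        if "is_calibrator" not in df.columns:
            raise ValueError("calibrator design needs an is_calibrator column")
        cal = df[df["is_calibrator"]]
        grand = cal["delta_ct"].mean()
        per_plate = cal.groupby("plate")["delta_ct"].mean() - grand
        samples = df[~df["is_calibrator"]].copy()
        factor = samples["plate"].map(per_plate)
        bad_plates = factor.isna()
        if bad_plates.any():
            logger.warning("plates without calibrators: %s",
                           sorted(samples.loc[bad_plates, "plate"].unique()))
        samples["corrected"] = samples["delta_ct"] - factor
        return samples.groupby("sample_id")["corrected"].mean().rename("raw_mtcn")

    if design != "fixed_order_random_plate":
        raise ValueError(f"unknown qPCR design {design!r}")
    samples = df[~df.get("is_calibrator", pd.Series(False, index=df.index))].copy()
    grp = samples.groupby("sample_id")

    # The pipetting-order slope is the plate-fixed-effect OLS estimate on
    # replicate rows (biology is independent of order, so it only adds
    # noise).  The plate random intercept is then fit on sample-level means:
    # fitting it on replicate rows would misread the replicate correlation
    # as plate variance and shrink real between-sample signal into the
    # plate BLUPs.
    by_plate = samples.groupby("plate")
    x_dev = samples["order"] - by_plate["order"].transform("mean")
    y_dev = samples["delta_ct"] - by_plate["delta_ct"].transform("mean")
    sxx = float(x_dev @ x_dev)
    slope = float(x_dev @ y_dev) / sxx if sxx > 0 else None

    level = grp.agg(delta_ct=("delta_ct", "mean"), order=("order", "mean"),
                    plate=("plate", "first"))
    if slope is not None:
        y = (level["delta_ct"] - slope * level["order"]).to_numpy()
        X = np.ones((len(level), 1))
    else:  # no order variation: intercept-only sample-level model
        y = level["delta_ct"].to_numpy()
        X = np.ones((len(level), 1))
    resid = None
    if level["plate"].nunique() > 1:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.MixedLM(y, X, groups=level["plate"].to_numpy()
                                 ).fit(reml=True)
            resid = y - np.asarray(fit.fittedvalues)  # removes plate BLUPs
        except Exception:  # pragma: no cover - degenerate plates
            logger.warning("mixed model failed; using two-step fallback")
    if resid is None:
        centered = level["delta_ct"] - level.groupby("plate")["delta_ct"].transform("mean")
        resid = sm.OLS(centered.to_numpy(),
                       sm.add_constant(level["order"].to_numpy())).fit().resid
    return pd.Series(resid, index=level.index, name="raw_mtcn")


def calibrate_array_to_wes(
    array_metric: pd.Series,
    wes_metric: pd.Series,
    min_overlap: int = 30,
) -> tuple[pd.Series, dict[str, float]]:
    """Regress a sequencing metric on the array metric over the overlap.

    The fitted line maps array values onto the sequencing scale for every
    sample with array data, mirroring calibration of a full-cohort array
    metric against a sequencing metric available on a subset.

    Returns (predictions for all array samples, fit dict with slope/intercept).
    """
    overlap = array_metric.dropna().index.intersection(wes_metric.dropna().index)
    if len(overlap) == 0:
        raise ValueError("no overlapping samples between array and sequencing metrics")
    if len(overlap) < min_overlap:
        raise ValueError(f"overlap {len(overlap)} below minimum {min_overlap}")
    X = sm.add_constant(array_metric.loc[overlap].to_numpy())
    fit = sm.OLS(wes_metric.loc[overlap].to_numpy(), X).fit()
    intercept, slope = fit.params
    pred = intercept + slope * array_metric
    return pred.rename("calibrated_mtcn"), {
        "slope": float(slope), "intercept": float(intercept),
        "r2": float(fit.rsquared), "n_overlap": int(len(overlap)),
    }


def select_cell_count_covariates(
    metric: pd.Series,
    cell_counts: pd.DataFrame,
    n_folds: int = 10,
    epsilon: float = 1e-4,
    seed: int = 0,
) -> list[str]:
    """Forward selection of cell-count covariates by cross-validated R².

    A candidate is retained when it raises the mean out-of-fold R² of the
    metric-on-cell-counts regression by more than ``epsilon``.  Deterministic
    for a fixed fold seed.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    idx = metric.dropna().index.intersection(cell_counts.dropna().index)
    if len(idx) < n_folds:
        raise ValueError("fewer samples than folds")
    y = metric.loc[idx].to_numpy()
    X_all = cell_counts.loc[idx]
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    splits = list(kf.split(y))

    def cv_r2(cols: list[str]) -> float:
        if not cols:
            return 0.0
        X = X_all[cols].to_numpy()
        scores = []
        for tr, te in splits:
            Xtr = sm.add_constant(X[tr], has_constant="add")
            Xte = sm.add_constant(X[te], has_constant="add")
            fit = sm.OLS(y[tr], Xtr).fit()
            pred = Xte @ fit.params
            ss_res = np.sum((y[te] - pred) ** 2)
            ss_tot = np.sum((y[te] - y[tr].mean()) ** 2)
            scores.append(1.0 - ss_res / ss_tot)
        return float(np.mean(scores))

    selected: list[str] = []
    best = 0.0
    remaining = list(X_all.columns)
    while remaining:
        gains = [(cv_r2(selected + [c]), c) for c in remaining]
        score, cand = max(gains)
        if score - best > epsilon:
            selected.append(cand)
            remaining.remove(cand)
            best = score
        else:
            break
    return selected


def exclude_cell_count_outliers(cell_counts: pd.DataFrame,
                                k: float = 5.0) -> pd.Index:
    """Samples within median ± k·IQR on every cell type.

    Extreme counts can mark active infection or malignancy, so such samples
    are dropped before association analysis.
    """
    med = cell_counts.median()
    iqr = cell_counts.quantile(0.75) - cell_counts.quantile(0.25)
    lo, hi = med - k * iqr, med + k * iqr
    ok = ((cell_counts >= lo) & (cell_counts <= hi)).all(axis=1)
    return cell_counts.index[ok]


def standardize_residuals(metric: pd.Series,
                          covariates: pd.DataFrame | None = None,
                          assay: str = "array") -> MtcnMetric:
    """Standardized residuals (mean 0, sd 1) after covariate regression.

    Collinear covariate columns are dropped with a warning; an exactly
    fitting covariate set (all residuals zero) is rejected as degenerate.
    """
    y = metric.dropna()
    if covariates is None or covariates.shape[1] == 0:
        cov_used: list[str] = []
        X = np.ones((len(y), 1))
    else:
        cov = covariates.loc[y.index].copy()
        # drop collinear columns (QR-based rank check, greedy)
        keep: list[str] = []
        for c in cov.columns:
            trial = cov[keep + [c]].to_numpy(dtype=float)
            trial = np.column_stack([np.ones(len(trial)), trial])
            if np.linalg.matrix_rank(trial) == trial.shape[1]:
                keep.append(c)
            else:
                logger.warning("dropping collinear covariate %r", c)
        cov_used = keep
        X = sm.add_constant(cov[keep].to_numpy(dtype=float))
    resid = sm.OLS(y.to_numpy(), X).fit().resid
    sd = resid.std(ddof=1)
    if not np.isfinite(sd) or sd < 1e-12:
        raise ValueError("degenerate residuals: metric is exactly linear in covariates")
    adjusted = pd.Series(resid / sd, index=y.index).reindex(metric.index)
    # guard against floating-point drift in the standardization
    ok = adjusted.dropna()
    adjusted = (adjusted - ok.mean()) / ok.std(ddof=1)
    return MtcnMetric(raw=metric, adjusted=adjusted, assay=assay,
                      covariates_used=cov_used)
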