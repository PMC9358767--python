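"""Specimen-level scaling statistics: PCA carapace dimensions, log-log
allometric regressions with 95% CIs, and Poisson scute-count regression.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .morpho import PBA_SENTINEL

#: dimensional expectations of slopes vs surface area
ISOMETRY_REFERENCES = {
    "length": 0.5, "height": 0.5, "width": 0.5,
    "median_scute_volume": 1.5, "median_scute_pba": 1.0,
    "median_scute_thickness": 0.5, "median_scute_width": 0.5,
}


@dataclass
class AllometryFit:
    slope: float
    intercept: float
    ci_low: float
    ci_high: float
    model: str  # loglog_ols | poisson_glm
    isometry_reference: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("fit needs n >= 3")
        if not self.ci_low <= self.slope <= self.ci_high:
            raise ValueError("confidence interval does not bracket the slope")

    def classify(self) -> str:
        """'isometric' if the CI contains the reference, else the
        direction of allometry."""
        if self.ci_low <= self.isometry_reference <= self.ci_high:
            return "isometric"
        return "positive allometry" if self.slope > self.isometry_reference \
            else "negative allometry"

    def to_dict(self) -> dict:
        return asdict(self)


def carapace_dimensions(centers: np.ndarray) -> tuple[float, float, float]:
    """(length, height, width) as PC-score ranges of the scute centers.

    Covariance PCA of the N x 3 coordinates; dimension k is the range
    (max - min) of scores on PC k, with PC1 the longest axis.  Each
    PC's largest-magnitude loading is made positive (ranges are
    sign-invariant; this only fixes reported orientation).
    """
    pts = np.asarray(centers, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 4:
        raise ValueError("need >= 4 points of shape (N, 3)")
    centered = pts - pts.mean(axis=0)
    cov = np.cov(centered.T)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if evals[-1] <= 0 or evals[0] / max(evals[-1], 1e-300) > 1e12:
        raise ValueError("centers are (near-)collinear; axes undefined")
    for k in range(3):
        if evecs[np.argmax(np.abs(evecs[:, k])), k] < 0:
            evecs[:, k] = -evecs[:, k]
    if evals[0] / evals[1] < 1.01 or evals[1] / evals[2] < 1.01:
        warnings.warn("axis identity ambiguous: near-equal PCA eigenvalues")
    scores = centered @ evecs
    dims = scores.max(axis=0) - scores.min(axis=0)
    return float(dims[0]), float(dims[1]), float(dims[2])


def fit_loglog(x, y, isometry_reference: float = 0.5) -> AllometryFit:
    """OLS of ln(y) on ln(x) with a t-based 95% CI on the slope."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need matched x/y with n >= 3")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("log-log fit requires strictly positive values")
    res = sm.OLS(np.log(y), sm.add_constant(np.log(x))).fit()
    ci = res.conf_int(alpha=0.05)
    return AllometryFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        ci_low=float(min(ci[1])),
        ci_high=float(max(ci[1])),
        model="loglog_ols",
        isometry_reference=isometry_reference,
        n=len(x),
    )


def fit_scute_count(counts, sa_values, sa_unit: str = "cm2") -> AllometryFit:
    """Poisson GLM (log link) of scute count on untransformed SA.

    Reports the exponentiated slope exp(beta1) with an exponentiated
    Wald 95% CI.  ``sa_values`` are mm^2; the covariate is converted to
    ``sa_unit`` first (slope magnitude depends on the unit).
    """
    counts = np.asarray(counts)
    sa = np.asarray(sa_values, dtype=float)
    if len(counts) != len(sa) or len(counts) < 3:
        raise ValueError("need matched counts/SA with n >= 3")
    if not np.all(counts == np.round(counts)) or np.any(counts <= 0):
        raise ValueError("counts must be positive integers")
    if sa_unit == "cm2":
        sa = sa / 100.0
    elif sa_unit != "mm2":
        raise ValueError(f"unknown SA unit: {sa_unit}")
    res = sm.GLM(
        counts.astype(float), sm.add_constant(sa), family=sm.families.Poisson()
    ).fit()
    beta1 = float(res.params[1])
    se = float(res.bse[1])
    z = 1.959963984540054  # N(0,1) 97.5% quantile
    return AllometryFit(
        slope=float(np.exp(beta1)),
        intercept=float(res.params[0]),
        ci_low=float(np.exp(beta1 - z * se)),
        ci_high=float(np.exp(beta1 + z * se)),
        model="poisson_glm",
        isometry_reference=1.0,
        n=len(counts),
    )


# --------------------------------------------------------------- series

_MEDIAN_COLS = {
    "median_scute_volume": "median_scute_volume_mm3",
    "median_scute_pba": "median_scute_pba_mm2",
    "median_scute_thickness": "median_scute_thickness_mm",
    "median_scute_width": "median_scute_width_mm",
}
_DIM_COLS = {"length": "length_mm", "height": "height_mm", "width": "width_mm"}

_NORM_COLS = ["volume_norm", "pba_norm", "thickness_norm", "width_norm",
              "gaussK_norm", "meanH_norm"]


def series_table(per_specimen: list[dict]) -> pd.DataFrame:
    """Build the per-specimen summary table from stats frames.

    Each entry: {"specimen", "stats" (scute frame), "sa_mm2",
    "length_mm", "height_mm", "width_mm"}.  Medians exclude PBA
    sentinels; a specimen with no valid PBA gets NaN there (dropped
    from the PBA fit with a warning downstream).
    """
    rows = []
    for entry in per_specimen:
        st = entry["stats"]
        pba = st.loc[st["pba_mm2"] != PBA_SENTINEL, "pba_mm2"]
        if pba.empty:
            warnings.warn(
                f"specimen {entry['specimen']}: no valid PBA; excluded from PBA fit"
            )
        rows.append(
            {
                "specimen": entry["specimen"],
                "sa_mm2": entry["sa_mm2"],
                "length_mm": entry["length_mm"],
                "height_mm": entry["height_mm"],
                "width_mm": entry["width_mm"],
                "median_scute_volume_mm3": float(st["volume_mm3"].median()),
                "median_scute_pba_mm2": float(pba.median()) if not pba.empty
                    else np.nan,
                "median_scute_thickness_mm": float(st["thickness_mm"].median()),
                "median_scute_width_mm": float(st["width_mm"].median()),
                "n_scutes": int(len(st)),
            }
        )
    return pd.DataFrame(rows).sort_values("sa_mm2").reset_index(drop=True)


def fit_series(table: pd.DataFrame, sa_unit: str = "cm2") -> dict[str, AllometryFit]:
    """All scaling fits for a per-specimen table: 7 log-log + 1 Poisson."""
    if len(table) < 3:
        raise ValueError("need >= 3 specimens")
    sa = table["sa_mm2"].to_numpy()
    fits: dict[str, AllometryFit] = {}
    for name, col in {**_DIM_COLS, **_MEDIAN_COLS}.items():
        y = table[col].to_numpy(dtype=float)
        ok = np.isfinite(y)
        if ok.sum() < len(y):
            warnings.warn(f"{name}: {int((~ok).sum())} specimen(s) dropped")
        fits[name] = fit_loglog(sa[ok], y[ok], ISOMETRY_REFERENCES[name])
    fits["n_scutes"] = fit_scute_count(
        table["n_scutes"].to_numpy(), sa, sa_unit=sa_unit
    )
    return fits


def five_number_summary(values) -> dict[str, float]:
    """min, Q1, median, Q3, max with linearly interpolated quartiles."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) == 0:
        return {k: np.nan for k in ("min", "q1", "median", "q3", "max")}
    q1, med, q3 = np.percentile(v, [25, 50, 75], method="linear")
    return {"min": float(v.min()), "q1": float(q1), "median": float(med),
            "q3": float(q3), "max": float(v.max())}


def summarize_series(
    per_specimen: list[dict], sa_unit: str = "cm2"
) -> tuple[pd.DataFrame, dict[str, AllometryFit], pd.DataFrame]:
    """Series table, all scaling fits, and per-specimen five-number
    summaries of every normalized variable (boxplot data).

    ``per_specimen`` entries must carry normalized stats frames (the
    ``*_norm`` columns from ``morpho.normalize_stats``).
    """
    table = series_table(per_specimen)
    fits = fit_series(table, sa_unit=sa_unit)
    box_rows = []
    for entry in sorted(per_specimen, key=lambda e: e["sa_mm2"]):
        st = entry["stats"]
        for col in _NORM_COLS:
            if col not in st.columns:
                continue
            row = {"specimen": entry["specimen"], "sa_mm2": entry["sa_mm2"],
                   "variable": col}
            row.update(five_number_summary(st[col]))
            box_rows.append(row)
    return table, fits, pd.DataFrame(box_rows)
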