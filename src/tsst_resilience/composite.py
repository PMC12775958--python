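"""PCA integration of reactivity/recovery features and the resilience index.

Two three-variable principal component analyses (cortisol, blood pressure,
heart rate) summarize stress reactivity (the AUCi features) and recovery
(the raw levels at the recovery occasion). Features are transformed toward
normality first (log, or a scaled inverse-hyperbolic-sine when values can
be negative), PCA suitability is screened with the Kaiser-Meyer-Olkin
index, Bartlett's sphericity test and the correlation-matrix determinant,
and the leading component scores are standardized to T-scores (mean 50,
SD 10). The resilience index is the negated geometric mean of the two
T-scores:

    index = -sqrt(T_reactivity * T_recovery)

so that a higher (less negative) index means lower reactivity and/or
faster return to baseline, i.e. more resilient physiological responding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TransformSpec",
    "PcaResult",
    "DEFAULT_TRANSFORMS",
    "assess_normality",
    "apply_transform",
    "pca_suitability",
    "fit_pca_component",
    "to_t_scores",
    "resilience_index",
    "compute_composites",
]

REACTIVITY_FEATURES = ("cortisol_auci", "map_auci", "hr_auci")
RECOVERY_FEATURES = ("cortisol_recovery", "map_recovery", "hr_recovery")

# Default transform per feature: AUCi values that can be negative take the
# scaled inverse hyperbolic sine; strictly positive, right-skewed features
# take the log; heart-rate recovery needs none.
DEFAULT_TRANSFORMS = {
    "cortisol_auci": "asinh_scaled",
    "map_auci": "log",
    "hr_auci": "asinh_scaled",
    "cortisol_recovery": "log",
    "map_recovery": "log",
    "hr_recovery": "none",
}


@dataclass
class TransformSpec:
    """Normalizing transform for one feature column."""

    variable: str
    transform: str = "none"  # none | log | asinh_scaled
    scaling_constant: float | None = None
    fallback_applied: bool = False

    def __post_init__(self) -> None:
        if self.transform not in {"none", "log", "asinh_scaled"}:
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.transform == "asinh_scaled" and self.scaling_constant is not None:
            if self.scaling_constant <= 0:
                raise ValueError("scaling_constant must be positive")


@dataclass
class PcaResult:
    """Leading-component summary of a 3-variable correlation PCA."""

    loadings: np.ndarray
    eigenvalues: np.ndarray
    n_components_retained: int
    variance_explained: float
    kmo: float
    bartlett_chi2: float
    bartlett_df: int
    bartlett_p: float
    determinant: float
    scores: np.ndarray
    variables: tuple = ()
    transforms: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "variables": list(self.variables),
            "loadings": self.loadings.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "n_components_retained": self.n_components_retained,
            "variance_explained": self.variance_explained,
            "kmo": self.kmo,
            "bartlett_chi2": self.bartlett_chi2,
            "bartlett_df": self.bartlett_df,
            "bartlett_p": self.bartlett_p,
            "determinant": self.determinant,
            "transforms": [
                {
                    "variable": t.variable,
                    "transform": t.transform,
                    "scaling_constant": t.scaling_constant,
                    "fallback_applied": t.fallback_applied,
                }
                for t in self.transforms
            ],
        }


def assess_normality(values) -> dict:
    """Sample skewness and Shapiro-Wilk p; flag when a transform is needed.

    A feature is flagged for transformation when its skewness exceeds 3 or
    the Shapiro-Wilk test rejects normality at p < .05. Constant input has
    undefined skewness; it is reported as 0 with ``degenerate=True``.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 3:
        raise ValueError("need at least 3 finite values")
    if np.ptp(x) == 0.0:
        return {
            "skewness": 0.0,
            "shapiro_p": np.nan,
            "transform_needed": False,
            "degenerate": True,
        }
    skew = float(stats.skew(x, bias=False))  # adjusted Fisher-Pearson
    shapiro_p = float(stats.shapiro(x).pvalue)
    return {
        "skewness": skew,
        "shapiro_p": shapiro_p,
        "transform_needed": bool(skew > 3 or shapiro_p < 0.05),
        "degenerate": False,
    }


def apply_transform(values, spec: TransformSpec) -> tuple[np.ndarray, TransformSpec]:
    """Apply ``spec`` to ``values``; returns the data and the resolved spec.

    ``log`` is the natural logarithm and requires strictly positive input;
    ``asinh_scaled`` computes ``asinh(x / c)`` with ``c`` the median
    absolute value (resolved from the data when not fixed in the spec).
    """
    x = np.asarray(values, dtype=float)
    if spec.transform == "none":
        return x.copy(), spec
    if spec.transform == "log":
        if np.any(x <= 0):
            raise ValueError(
                f"{spec.variable}: log transform requires positive values; "
                "use asinh_scaled for sign-changing features"
            )
        return np.log(x), spec
    c = spec.scaling_constant
    if c is None:
        c = float(np.median(np.abs(x)))
    if c <= 0:
        raise ValueError(f"{spec.variable}: median absolute value must be positive")
    resolved = TransformSpec(spec.variable, "asinh_scaled", c)
    return np.arcsinh(x / c), resolved


def pca_suitability(matrix) -> dict:
    """KMO index, Bartlett sphericity test and correlation determinant.

    Bartlett's chi-square is ``-(n - 1 - (2p + 5)/6) * ln|R|`` on
    ``p(p-1)/2`` degrees of freedom; the KMO index compares squared
    correlations against squared partial correlations (anti-image).
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a 2-D matrix with >= 2 columns")
    n, p = X.shape
    if n <= 10:
        raise ValueError("need more than 10 rows")
    if np.isnan(X).any():
        raise ValueError("matrix must be complete")
    R = np.corrcoef(X, rowvar=False)
    det = float(np.linalg.det(R))
    if det <= 1e-12:
        raise ValueError("correlation matrix is singular")
    inv = np.linalg.inv(R)
    d = np.sqrt(np.diag(inv))
    partial = -inv / np.outer(d, d)
    off = ~np.eye(p, dtype=bool)
    r2 = np.sum(R[off] ** 2)
    q2 = np.sum(partial[off] ** 2)
    kmo = float(r2 / (r2 + q2))
    chi2 = float(-(n - 1 - (2 * p + 5) / 6.0) * np.log(det))
    df = p * (p - 1) // 2
    pval = float(stats.chi2.sf(chi2, df))
    return {
        "kmo": kmo,
        "bartlett_chi2": chi2,
        "bartlett_df": df,
        "bartlett_p": pval,
        "determinant": det,
    }


def fit_pca_component(matrix, variables=(), transforms=()) -> PcaResult:
    """Correlation-matrix PCA, returning the (oriented) leading component.

    Components with eigenvalue > 1 are retained (count reported); the
    leading eigenvector is oriented so its loadings are non-negative overall
    (sign flipped when the loading sum is negative), loadings are reported
    as eigenvector * sqrt(eigenvalue), and scores are unit-variance:
    standardized data projected on eigenvector / sqrt(eigenvalue).
    """
    X = np.asarray(matrix, dtype=float)
    suit = pca_suitability(X)
    R = np.corrcoef(X, rowvar=False)
    eigval, eigvec = np.linalg.eigh(R)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    v = eigvec[:, 0]
    if v.sum() < 0:
        v = -v
    lead = float(eigval[0])
    retained = int(np.sum(eigval > 1.0))
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    scores = Z @ (v / np.sqrt(lead))
    return PcaResult(
        loadings=v * np.sqrt(lead),
        eigenvalues=eigval,
        n_components_retained=retained,
        variance_explained=lead / X.shape[1],
        scores=scores,
        variables=tuple(variables),
        transforms=list(transforms),
        **suit,
    )


def to_t_scores(scores) -> np.ndarray:
    """Standardize to T-scores: mean 50, SD 10 (sample SD, n-1)."""
    x = np.asarray(scores, dtype=float)
    sd = x.std(ddof=1)
    if not sd > 0:
        raise ValueError("scores have zero variance")
    return 50.0 + 10.0 * (x - x.mean()) / sd


def resilience_index(reactivity_t, recovery_t):
    """Resilience index: ``-sqrt(reactivity_t * recovery_t)``.

    Both arguments must be strictly positive (T-scores are, short of a
    5-SD outlier); the function is symmetric and strictly decreasing in
    each argument — higher reactivity or slower recovery lowers the index.
    """
    a = np.asarray(reactivity_t, dtype=float)
    b = np.asarray(recovery_t, dtype=float)
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError(
            "resilience_index requires positive T-scores; the geometric "
            "mean is undefined at non-positive values"
        )
    out = -np.sqrt(a * b)
    return float(out) if out.ndim == 0 else out


def _resolve_transforms(frame, feature_names, overrides):
    """Apply the configured transform per feature, validated on the data.

    The transform choice is data-driven, as when normality is checked
    feature by feature before a PCA: a log-assigned feature falls back to
    the scaled inverse hyperbolic sine when it contains non-positive
    values, or when the asinh-transformed column is closer to symmetric
    than the log-transformed one (log of a near-zero area otherwise
    manufactures an extreme negative outlier). The fallback is recorded on
    the resolved spec, never applied silently.
    """
    data = np.empty((len(frame), len(feature_names)))
    specs = []
    for j, name in enumerate(feature_names):
        kind = (overrides or {}).get(name, DEFAULT_TRANSFORMS.get(name, "none"))
        x = frame[name].to_numpy(dtype=float)
        fallback = False
        if kind == "log":
            if np.any(x <= 0):
                fallback = True
            else:
                skew_log = abs(stats.skew(np.log(x), bias=False))
                c = np.median(np.abs(x))
                skew_asinh = abs(stats.skew(np.arcsinh(x / c), bias=False))
                fallback = skew_asinh < skew_log
        if fallback:
            kind = "asinh_scaled"
        values, spec = apply_transform(x, TransformSpec(name, kind))
        spec.fallback_applied = fallback
        data[:, j] = values
        specs.append(spec)
    return data, specs


def compute_composites(
    features: pd.DataFrame,
    transform_overrides: dict | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Run both PCAs and assemble the per-participant composite scores.

    Returns ``(composites, report)`` where composites has columns
    participant_id / reactivity_t / recovery_t / resilience_index and the
    report carries both :class:`PcaResult` objects plus normality
    diagnostics of the raw and transformed features.
    """
    needed = set(REACTIVITY_FEATURES) | set(RECOVERY_FEATURES)
    missing = needed - set(features.columns)
    if missing:
        raise ValueError(f"feature table lacks columns {sorted(missing)}")

    report = {"normality_raw": {}, "normality_transformed": {}}
    results = {}
    for block, names in (
        ("reactivity", REACTIVITY_FEATURES),
        ("recovery", RECOVERY_FEATURES),
    ):
        data, specs = _resolve_transforms(features, names, transform_overrides)
        for j, name in enumerate(names):
            report["normality_raw"][name] = assess_normality(features[name])
            report["normality_transformed"][name] = assess_normality(data[:, j])
        results[block] = fit_pca_component(data, names, specs)

    reactivity_t = to_t_scores(results["reactivity"].scores)
    recovery_t = to_t_scores(results["recovery"].scores)
    composites = pd.DataFrame(
        {
            "participant_id": features["participant_id"].to_numpy(),
            "reactivity_t": reactivity_t,
            "recovery_t": recovery_t,
            "resilience_index": resilience_index(reactivity_t, recovery_t),
        }
    )
    report["reactivity"] = results["reactivity"]
    report["recovery"] = results["recovery"]
    return composites, report
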