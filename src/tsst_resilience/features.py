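"""Per-participant reactivity, recovery and peak features.

From raw trajectories this module computes mean arterial pressure, peak
values over the protocol-defined windows, area under the curve with respect
to increase (AUCi), recovery levels, the cortisol responder classification,
and K-nearest-neighbour imputation of sparse missingness.

Window conventions follow the laboratory protocol: the cortisol peak and
AUCi use the post-rest samples T1..T6 only (the arrival sample is excluded);
the HR peak window is baseline plus the three TSST phases; the MAP peak
window is the three TSST phases only. Recovery is the raw level at the last
cortisol sample (T6) or at the cardio recovery phase.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PhysioTrajectory",
    "RESPONDER_THRESHOLD",
    "mean_arterial_pressure",
    "peak_value",
    "auc_increase",
    "recovery_value",
    "classify_responder",
    "knn_impute",
    "compute_features",
    "feature_table_from_arrays",
]

#: non-responders show a peak rise of < 15.5 % over baseline
RESPONDER_THRESHOLD = 0.155

CORTISOL_WINDOW = ("T1", "T2", "T3", "T4", "T5", "T6")
HR_PEAK_WINDOW = ("baseline", "preparation", "speech", "calculation")
MAP_PEAK_WINDOW = ("preparation", "speech", "calculation")


@dataclass
class PhysioTrajectory:
    """One participant x one modality time series.

    ``times`` are minutes from baseline (strictly increasing), ``values``
    are ng/ml (cortisol), mm Hg (MAP) or BPM (HR), and ``phase_labels`` is
    the parallel list of protocol phases.
    """

    participant_id: object
    modality: str
    times: np.ndarray
    values: np.ndarray
    phase_labels: tuple

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.phase_labels = tuple(self.phase_labels)
        if self.modality not in {"cortisol", "MAP", "HR"}:
            raise ValueError(f"unknown modality {self.modality!r}")
        if not (self.times.size == self.values.size == len(self.phase_labels)):
            raise ValueError("times, values and phase_labels must align")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")
        if self.modality == "cortisol" and np.any(self.values <= 0):
            raise ValueError("cortisol values must be strictly positive")

    def window(self, labels) -> tuple[np.ndarray, np.ndarray]:
        labels = set(labels)
        keep = np.array([lab in labels for lab in self.phase_labels])
        return self.times[keep], self.values[keep]


def mean_arterial_pressure(sbp, dbp):
    """MAP = DBP + (SBP - DBP) / 3, in mm Hg.

    Accepts scalars or arrays; a systolic reading below the diastolic one is
    rejected as physiologically implausible.
    """
    sbp = np.asarray(sbp, dtype=float)
    dbp = np.asarray(dbp, dtype=float)
    if np.any(dbp <= 0) or np.any(sbp < dbp):
        raise ValueError("require sbp >= dbp > 0")
    out = dbp + (sbp - dbp) / 3.0
    return float(out) if out.ndim == 0 else out


def peak_value(trajectory: PhysioTrajectory, window) -> tuple[float, float]:
    """Maximum value over the labelled window, ties broken to earliest time.

    Returns ``(value, time)``.
    """
    window = tuple(window)
    if not window:
        raise ValueError("window must be non-empty")
    missing = set(window) - set(trajectory.phase_labels)
    if missing:
        raise ValueError(f"window labels absent from trajectory: {sorted(missing)}")
    t, v = trajectory.window(window)
    i = int(np.argmax(v))  # argmax returns the first maximum: earliest time
    return float(v[i]), float(t[i])


def auc_increase(times, values) -> float:
    """Area under the curve with respect to increase (AUCi).

    Trapezoidal area of the series minus the baseline rectangle:
    ``sum((v[i+1]+v[i])/2 * (t[i+1]-t[i])) - v[0] * (t[-1]-t[0])``.
    The first point is the baseline; the result may be negative when the
    series runs mostly below baseline.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.size < 2 or t.size != v.size:
        raise ValueError("need >= 2 aligned (time, value) points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    total = float(np.trapezoid(v, t))
    return total - float(v[0]) * float(t[-1] - t[0])


def recovery_value(trajectory: PhysioTrajectory) -> float:
    """Raw level at the recovery point (T6 for cortisol, 'recovery' else)."""
    label = "T6" if trajectory.modality == "cortisol" else "recovery"
    if label not in trajectory.phase_labels:
        raise ValueError(f"trajectory lacks a {label!r} point")
    i = trajectory.phase_labels.index(label)
    return float(trajectory.values[i])


def classify_responder(baseline, peak_post) -> bool | np.ndarray:
    """Cortisol responder rule.

    Non-responders exhibit a peak rise of strictly less than 15.5 % over
    their baseline: responder iff ``(peak_post - baseline)/baseline >=
    0.155`` (equality counts as responding). ``peak_post`` is the maximum
    over the post-baseline samples T2..T6.
    """
    b = np.asarray(baseline, dtype=float)
    p = np.asarray(peak_post, dtype=float)
    if np.any(b <= 0):
        raise ValueError("baseline must be positive")
    out = (p - b) / b >= RESPONDER_THRESHOLD
    return bool(out) if out.ndim == 0 else out


def knn_impute(table: pd.DataFrame, k: int = 5) -> pd.DataFrame:
    """Complete ``table`` by K-nearest-neighbour imputation.

    Each missing cell is replaced by the mean of its variable over the
    ``k`` nearest fully observed rows, with distance the standardized
    Euclidean distance over the variables observed in the incomplete row.
    Observed cells are never altered. Rows with every value missing are
    rejected; intended for the sparse (< 5 %) missingness this protocol
    produces.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    X = table.to_numpy(dtype=float)
    miss = np.isnan(X)
    if not miss.any():
        return table.copy()
    if miss.mean() >= 0.05:
        raise ValueError("missing fraction must be < 5 %")
    if miss.all(axis=1).any():
        raise ValueError("a row with all values missing cannot be imputed")
    complete = ~miss.any(axis=1)
    if complete.sum() < 1:
        raise ValueError("KNN imputation needs at least one complete row")
    kk = min(k, int(complete.sum()))
    donors = X[complete]
    col_sd = np.nanstd(X, axis=0, ddof=1)
    col_sd[~np.isfinite(col_sd) | (col_sd == 0)] = 1.0
    out = X.copy()
    for i in np.where(miss.any(axis=1))[0]:
        obs = ~miss[i]
        d = np.sqrt(
            np.mean(((donors[:, obs] - X[i, obs]) / col_sd[obs]) ** 2, axis=1)
        )
        nearest = np.argsort(d, kind="stable")[:kk]
        out[i, miss[i]] = donors[nearest][:, miss[i]].mean(axis=0)
    result = table.copy()
    result.iloc[:, :] = out
    return result


def _auci_matrix(values: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Row-wise AUCi for a matrix of series sharing one time grid."""
    total = np.trapezoid(values, grid, axis=1)
    return total - values[:, 0] * (grid[-1] - grid[0])


def feature_table_from_arrays(
    cortisol: np.ndarray,
    map_values: np.ndarray,
    hr_values: np.ndarray,
    cortisol_grid,
    cardio_grid,
    *,
    arrival_included: bool | None = None,
    include_cardio_recovery_in_auci: bool = True,
    participant_ids=None,
) -> pd.DataFrame:
    """Vectorized feature extraction from aligned value matrices.

    ``cortisol`` is (n, 7) over arrival + T1..T6, or (n, 6) over T1..T6;
    the arrival sample is dropped from every feature. When
    ``arrival_included`` is None it is inferred from the grid: a leading
    grid point at negative time (before the T1 baseline at 0) is treated as
    the arrival sample. ``map_values``/``hr_values`` are (n, 5) over the
    five cardio phases. This is the array-level core behind
    :func:`compute_features`.
    """
    cortisol = np.asarray(cortisol, dtype=float)
    map_values = np.asarray(map_values, dtype=float)
    hr_values = np.asarray(hr_values, dtype=float)
    grid_c = np.asarray(cortisol_grid, dtype=float)
    grid_k = np.asarray(cardio_grid, dtype=float)
    if cortisol.shape[1] != grid_c.size:
        raise ValueError("cortisol matrix does not match its grid")
    if arrival_included is None:
        arrival_included = grid_c[0] < 0
    if arrival_included:
        cortisol = cortisol[:, 1:]
        grid_c = grid_c[1:]
    if map_values.shape[1] != grid_k.size or hr_values.shape[1] != grid_k.size:
        raise ValueError("cardio matrices do not match the cardio grid")

    n = cortisol.shape[0]
    if participant_ids is None:
        participant_ids = np.arange(1, n + 1)

    cardio_cols = slice(None) if include_cardio_recovery_in_auci else slice(0, -1)
    grid_cardio = grid_k[cardio_cols]

    peak_post = cortisol[:, 1:].max(axis=1)
    baseline = cortisol[:, 0]
    return pd.DataFrame(
        {
            "participant_id": participant_ids,
            "cortisol_auci": _auci_matrix(cortisol, grid_c),
            "cortisol_recovery": cortisol[:, -1],
            "cortisol_peak": cortisol.max(axis=1),
            "cortisol_baseline": baseline,
            "map_auci": _auci_matrix(map_values[:, cardio_cols], grid_cardio),
            "map_recovery": map_values[:, -1],
            "map_peak": map_values[:, 1:4].max(axis=1),
            "map_baseline": map_values[:, 0],
            "hr_auci": _auci_matrix(hr_values[:, cardio_cols], grid_cardio),
            "hr_recovery": hr_values[:, -1],
            "hr_peak": hr_values[:, 0:4].max(axis=1),
            "hr_baseline": hr_values[:, 0],
            "responder": classify_responder(baseline, peak_post),
        }
    )


def _pivot(physio: pd.DataFrame, modality: str, labels) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    sub = physio[physio["modality"] == modality]
    if sub.empty:
        raise ValueError(f"no rows for modality {modality!r}")
    wide = sub.pivot_table(
        index="participant_id", columns="phase_label", values="value", sort=True
    )
    missing = [lab for lab in labels if lab not in wide.columns]
    if missing:
        raise ValueError(f"{modality}: missing phases {missing}")
    wide = wide[list(labels)]
    times = (
        sub.drop_duplicates("phase_label").set_index("phase_label")["time_min"]
    )
    grid = times.reindex(list(labels)).to_numpy(dtype=float)
    return wide.index.to_numpy(), wide.to_numpy(dtype=float), grid


def compute_features(
    physio: pd.DataFrame,
    *,
    knn_k: int = 5,
    include_cardio_recovery_in_auci: bool = True,
) -> pd.DataFrame:
    """Feature rows from a long physio table.

    The table must carry columns participant_id / modality / phase_label /
    time_min / value with modalities cortisol plus either MAP or SBP+DBP,
    and HR. SBP/DBP rows are converted to MAP. Sparse missingness is
    completed by KNN imputation on the participant x (modality, phase)
    matrix before any feature is computed.
    """
    required = {"participant_id", "modality", "phase_label", "time_min", "value"}
    if not required.issubset(physio.columns):
        raise ValueError(f"physio table must have columns {sorted(required)}")
    physio = physio.copy()
    mods = set(physio["modality"].unique())
    if "MAP" not in mods:
        if not {"SBP", "DBP"}.issubset(mods):
            raise ValueError("need MAP rows or SBP+DBP rows")
        sbp = physio[physio["modality"] == "SBP"].set_index(
            ["participant_id", "phase_label"]
        )
        dbp = physio[physio["modality"] == "DBP"].set_index(
            ["participant_id", "phase_label"]
        )
        both = ~(sbp["value"].isna() | dbp["value"].reindex(sbp.index).isna())
        map_rows = sbp.reset_index()
        map_rows["modality"] = "MAP"
        dbp_vals = dbp["value"].reindex(sbp.index).to_numpy()
        vals = np.where(
            both.to_numpy(),
            dbp_vals + (sbp["value"].to_numpy() - dbp_vals) / 3.0,
            np.nan,
        )
        map_rows["value"] = vals
        physio = pd.concat(
            [physio[~physio["modality"].isin(["SBP", "DBP"])], map_rows],
            ignore_index=True,
        )

    cortisol_labels = ("arrival",) + CORTISOL_WINDOW
    have_arrival = (
        (physio["modality"] == "cortisol") & (physio["phase_label"] == "arrival")
    ).any()
    if not have_arrival:
        cortisol_labels = CORTISOL_WINDOW
    pid_c, cort, grid_c = _pivot(physio, "cortisol", cortisol_labels)
    pid_m, mapm, grid_k = _pivot(physio, "MAP", CARDIO_LABELS_ORDER)
    pid_h, hrm, grid_k2 = _pivot(physio, "HR", CARDIO_LABELS_ORDER)
    if not (np.array_equal(pid_c, pid_m) and np.array_equal(pid_c, pid_h)):
        raise ValueError("participants differ across modalities")

    blocks = np.hstack([cort, mapm, hrm])
    if np.isnan(blocks).any():
        cols = pd.DataFrame(blocks)
        blocks = knn_impute(cols, k=knn_k).to_numpy()
    nc, nm = cort.shape[1], mapm.shape[1]
    cort, mapm, hrm = blocks[:, :nc], blocks[:, nc : nc + nm], blocks[:, nc + nm :]

    return feature_table_from_arrays(
        cort,
        mapm,
        hrm,
        grid_c,
        grid_k,
        arrival_included=have_arrival,
        include_cardio_recovery_in_auci=include_cardio_recovery_in_auci,
        participant_ids=pid_c,
    )


CARDIO_LABELS_ORDER = ("baseline", "preparation", "speech", "calculation", "recovery")
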