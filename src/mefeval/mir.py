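"""Milk mid-infrared (MIR) spectral preprocessing and CH4 phenotype edits.

Raw FOSS spectra carry 1,060 absorbance "pins".  Three informative regions
(pins 260-402, 442-472 and 701-767, 1-based closed ranges) are retained,
giving 241 points.  Within each laboratory, principal-component score drift
over time defines homogeneous subsets; each subset is standardized to a
reference by a per-pin affine map, screened for outliers by Mahalanobis
distance in the retained component space (chi-squared test, P < 0.001), and
smoothed with a third-order Savitzky-Golay filter of width 11.

Daily CH4 records (g/d) are averaged by calendar week (>= 2 daily values),
edited at |3.5| SD, restricted to first lactation and 5-305 days in milk,
and matched to the nearest processed spectrum within 11 days of the week
midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass


import numpy as np
import pandas as pd
from scipy.signal import savgol_filter
from scipy.stats import chi2
from sklearn.decomposition import PCA

RAW_PIN_COUNT = 1060
#: 1-based closed FOSS pin ranges retained for prediction.
PIN_RANGES = ((260, 402), (442, 472), (701, 767))
N_SELECTED = sum(hi - lo + 1 for lo, hi in PIN_RANGES)  # 241

DIM_EDIT_WINDOW = (5, 305)
WEEKLY_MIN_DAILY = 2
SD_EDIT = 3.5
MATCH_MAX_DAYS = 11


def select_informative_pins(raw: np.ndarray) -> np.ndarray:
    """Concatenate the retained pin ranges (order preserved) -> 241 points."""
    raw = np.asarray(raw, dtype=float)
    n = raw.shape[-1]
    if n < PIN_RANGES[-1][1]:
        raise ValueError(f"raw spectrum has {n} pins; need at least {PIN_RANGES[-1][1]}")
    pieces = [raw[..., lo - 1:hi] for lo, hi in PIN_RANGES]
    return np.concatenate(pieces, axis=-1)


def selected_pin_indices() -> np.ndarray:
    """0-based raw-pin indices of the 241 retained points."""
    return np.concatenate([np.arange(lo - 1, hi) for lo, hi in PIN_RANGES])


# ---------------------------------------------------------------------------
# homogeneous subsets and standardization
# ---------------------------------------------------------------------------

def detect_homogeneous_subsets(
    spectra: np.ndarray,
    dates: np.ndarray,
    variance_threshold: float = 0.01,
    window: int = 30,
    shift_sd: float = 3.0,
) -> np.ndarray:
    """Split a laboratory's time axis into spectrally homogeneous subsets.

    Principal components of the scaled spectra explaining more than
    ``variance_threshold`` of variance are monitored over time; a shift of
    the running mean of any monitored score (two-window z statistic above
    ``shift_sd``) marks a changepoint.  Returns a subset id per spectrum
    (0, 1, ... in time order).
    """
    spectra = np.asarray(spectra, dtype=float)
    dates = np.asarray(dates)
    n = len(spectra)
    if n < 2:
        import warnings

        warnings.warn("fewer than 2 spectra: a single subset is assumed")
        return np.zeros(n, dtype=int)
    order = np.argsort(dates, kind="stable")
    sd = spectra.std(axis=0)
    if np.all(sd == 0):  # identical spectra throughout
        return np.zeros(n, dtype=int)
    sd[sd == 0] = 1.0
    scaled = (spectra - spectra.mean(axis=0)) / sd
    k = min(n, scaled.shape[1], 10)
    pca = PCA(n_components=k)
    scores = pca.fit_transform(scaled)
    keep = pca.explained_variance_ratio_ > variance_threshold
    if not np.any(keep):
        return np.zeros(n, dtype=int)
    scores = scores[:, keep][order]

    w = min(window, n // 2)
    breaks = []
    if w >= 2:
        for comp in scores.T:
            for i in range(w, n - w + 1):
                left = comp[i - w:i]
                right = comp[i:i + w]
                pooled = np.sqrt((left.var(ddof=1) + right.var(ddof=1)) / w)
                if pooled == 0:
                    continue
                z = abs(right.mean() - left.mean()) / pooled
                if z > shift_sd:
                    breaks.append(i)
    subset_sorted = np.zeros(n, dtype=int)
    if breaks:
        # merge nearby candidate breakpoints into changepoints
        breaks = np.sort(np.unique(breaks))
        groups = [[breaks[0]]]
        for b in breaks[1:]:
            if b - groups[-1][-1] <= w:
                groups[-1].append(b)
            else:
                groups.append([b])
        cuts = [int(np.median(g)) for g in groups]
        for c in cuts:
            subset_sorted[c:] += 1
    out = np.zeros(n, dtype=int)
    out[order] = subset_sorted
    return out


@dataclass
class StandardizationMap:
    """Per-pin affine map aligning a subset to the reference statistics."""

    slope: np.ndarray
    offset: np.ndarray

    def apply(self, spectra: np.ndarray) -> np.ndarray:
        return spectra * self.slope + self.offset


def standardize_subset(
    spectra: np.ndarray,
    reference_mean: np.ndarray,
    reference_sd: np.ndarray,
) -> tuple[np.ndarray, StandardizationMap]:
    """Align subset per-pin mean and SD to the reference laboratory/period."""
    spectra = np.asarray(spectra, dtype=float)
    mu = spectra.mean(axis=0)
    sd = spectra.std(axis=0)
    slope = np.ones_like(mu)
    ok = sd > 0
    if not np.all(ok):
        import warnings

        warnings.warn("zero-variance pins standardized by offset only")
    slope[ok] = np.asarray(reference_sd, float)[ok] / sd[ok]
    offset = np.asarray(reference_mean, float) - slope * mu
    m = StandardizationMap(slope=slope, offset=offset)
    return m.apply(spectra), m


def mahalanobis_qc(
    spectra: np.ndarray,
    variance_threshold: float = 0.01,
    p_value: float = 0.001,
) -> np.ndarray:
    """QC flags: True = keep, False = outlier.

    Distances are computed in the space of principal components explaining
    more than ``variance_threshold`` of variance; a spectrum is flagged when
    its squared Mahalanobis distance exceeds the chi-squared quantile at
    ``p_value`` with df = number of retained components.
    """
    x = np.asarray(spectra, dtype=float)
    n, p = x.shape
    k_max = min(n - 1, p)
    if k_max < 1:
        raise ValueError("need at least 2 spectra for QC")
    pca = PCA(n_components=k_max)
    scores = pca.fit_transform(x)
    keep = pca.explained_variance_ratio_ > variance_threshold
    if not np.any(keep):
        keep[0] = True
    s = scores[:, keep]
    cov = np.cov(s, rowvar=False)
    cov = np.atleast_2d(cov)
    try:
        cinv = np.linalg.inv(cov)
    except np.linalg.LinAlgError:
        import warnings

        warnings.warn("singular score covariance: using pseudo-inverse")
        cinv = np.linalg.pinv(cov)
    d2 = np.einsum("ni,ij,nj->n", s, cinv, s)
    crit = chi2.ppf(1.0 - p_value, df=s.shape[1])
    return d2 <= crit


def savitzky_golay(spectrum: np.ndarray, order: int = 3, width: int = 11) -> np.ndarray:
    """Savitzky-Golay smoothing with shrink-window edge handling.

    Interior points use the standard filter; near the ends the polynomial is
    fitted on the available (asymmetric, shrunken) window rather than padded
    data, so no values are fabricated beyond the spectrum.
    """
    x = np.asarray(spectrum, dtype=float)
    if width % 2 == 0 or width <= order:
        raise ValueError("width must be odd and greater than the polynomial order")
    n = x.shape[-1]
    if n < width:
        raise ValueError(f"spectrum length {n} shorter than filter width {width}")
    out = savgol_filter(x, width, order, axis=-1)
    h = width // 2
    idx = np.arange(n)
    for i in list(range(h)) + list(range(n - h, n)):
        lo, hi = max(0, i - h), min(n, i + h + 1)
        t = idx[lo:hi] - i
        coeffs = np.polynomial.polynomial.polyfit(t, np.moveaxis(x[..., lo:hi], -1, 0), order)
        out[..., i] = coeffs[0]
    return out


# ---------------------------------------------------------------------------
# weekly CH4 phenotype
# ---------------------------------------------------------------------------

def weekly_aggregate_and_edit(
    daily: pd.DataFrame,
    sd_edit: float = SD_EDIT,
    min_daily: int = WEEKLY_MIN_DAILY,
    dim_window: tuple = DIM_EDIT_WINDOW,
    edit_level: str = "weekly",
) -> pd.DataFrame:
    """Weekly CH4 means with the standard edits.

    ``daily`` columns: animal, date (datetime64), ch4, dim, lactation.
    Weeks are ISO calendar weeks of the measurement dates; the week midpoint
    is the median measurement date.  Records outside first lactation or the
    DIM window are dropped, weeks need >= ``min_daily`` daily values, and
    weekly means beyond ``sd_edit`` SD of the weekly-mean distribution are
    removed (set ``edit_level='daily'`` to apply the SD edit to daily values
    before averaging instead).
    """
    d = daily.copy()
    d["date"] = pd.to_datetime(d["date"])
    d = d[(d["lactation"] == 1) & (d["dim"] >= dim_window[0]) & (d["dim"] <= dim_window[1])]
    if edit_level == "daily" and len(d):
        mu, sd = d["ch4"].mean(), d["ch4"].std(ddof=1)
        if sd > 0:
            d = d[np.abs(d["ch4"] - mu) <= sd_edit * sd]
    iso = d["date"].dt.isocalendar()
    d["week"] = iso.year.astype(str) + "-W" + iso.week.astype(str).str.zfill(2)
    grp = d.groupby(["animal", "week"])
    weekly = grp.agg(
        ch4=("ch4", "mean"),
        n_daily=("ch4", "size"),
        midpoint=("date", "median"),
        dim_mid=("dim", "median"),
    ).reset_index()
    weekly = weekly[weekly["n_daily"] >= min_daily]
    weekly = weekly[
        (weekly["dim_mid"] >= dim_window[0]) & (weekly["dim_mid"] <= dim_window[1])
    ]
    if edit_level == "weekly" and len(weekly) > 1:
        mu, sd = weekly["ch4"].mean(), weekly["ch4"].std(ddof=1)
        if sd > 0:
            weekly = weekly[np.abs(weekly["ch4"] - mu) <= sd_edit * sd]
    return weekly.reset_index(drop=True)


def match_weekly_to_spectrum(
    weekly: pd.DataFrame,
    spectra_index: pd.DataFrame,
    max_days: int = MATCH_MAX_DAYS,
) -> pd.DataFrame:
    """Attach the nearest same-animal spectrum within ``max_days`` of the
    week midpoint (ties go to the earlier date); unmatched weeks get
    spectrum_id = -1."""
    out = weekly.copy()
    out["spectrum_id"] = -1
    out["match_days"] = np.nan
    spec = spectra_index.copy()
    spec["date"] = pd.to_datetime(spec["date"])
    by_animal = dict(tuple(spec.groupby("animal")))
    for i, row in out.iterrows():
        cand = by_animal.get(row["animal"])
        if cand is None:
            continue
        dist = (cand["date"] - pd.to_datetime(row["midpoint"])).dt.days
        absd = dist.abs()
        best = absd.min()
        if best > max_days:
            continue
        ties = cand[absd == best]
        chosen = ties.sort_values("date").iloc[0]
        out.loc[i, "spectrum_id"] = chosen["spectrum_id"]
        out.loc[i, "match_days"] = best
    return out


def prediction_metrics(predicted: np.ndarray, observed: np.ndarray) -> dict:
    """Pearson correlation (r) and RMSE of CH4 predictions."""
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape or p.size < 3:
        raise ValueError("need matching vectors of length >= 3")
    rmse = float(np.sqrt(np.mean((p - o) ** 2)))
    if p.std() == 0 or o.std() == 0:
        return {"r": np.nan, "rmse": rmse, "degenerate": True}
    r = float(np.corrcoef(p, o)[0, 1])
    return {"r": r, "rmse": rmse, "degenerate": False}
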