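"""ToF-SIMS peak-table lipidomics: TIC normalization, PCA, PLS-DA/VIP, fold changes.

The module consumes peak tables (m/z labelled ion intensities per spectrum,
as produced by vendor peak-picking software) and compares two classes of
spectra — e.g. normal vs cancer cell samples. Intensities are normalized to
the total ion count (TIC) of each spectrum; class structure is explored by
PCA, discriminant ions ranked by PLS-DA VIP scores, and composition shifts
quantified as fold changes of class means with bootstrap confidence
intervals. Saturation analysis forms per-spectrum MUFA/SFA and PUFA/SFA
ratios before the class comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

__all__ = [
    "PeakTable",
    "PLSDAModel",
    "PCAResult",
    "tic_normalize",
    "pca_scores",
    "plsda_vip",
    "fold_changes",
    "saturation_ratios",
]


@dataclass
class PeakTable:
    """m/z peak intensities per spectrum.

    ``intensities`` is a DataFrame with one row per spectrum and one column
    per peak (columns are m/z values as floats or strings). ``tic`` is the
    per-spectrum total ion count used for normalization; when absent the row
    sum of the listed peaks is used as a proxy. ``names`` optionally maps
    peak column -> assignment (e.g. ``264.2 -> "SM"``).
    """

    intensities: pd.DataFrame
    tic: pd.Series | None = None
    names: Mapping = field(default_factory=dict)
    polarity: str = "negative"
    normalized: bool = False

    def __post_init__(self) -> None:
        if (self.intensities.to_numpy() < 0).any():
            raise ValueError("intensities must be non-negative")
        if self.tic is not None:
            self.tic = self.tic.reindex(self.intensities.index)

    @property
    def n_spectra(self) -> int:
        return len(self.intensities)

    @property
    def peaks(self) -> list:
        return list(self.intensities.columns)


@dataclass
class PCAResult:
    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_ratio: np.ndarray
    ellipses: dict = field(default_factory=dict)
    rank_deficient: bool = False


@dataclass
class PLSDAModel:
    """PLS1 discriminant model with VIP scores.

    ``weights`` (p x A) are the normalized NIPALS weight vectors, ``scores``
    (n x A) the X-scores, ``ssy`` the per-component explained sum of squares
    of the class response. ``vip`` satisfies mean(vip**2) == 1.
    """

    weights: np.ndarray
    scores: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    ssy: np.ndarray
    vip: pd.Series
    classes: tuple
    vip_threshold: float = 1.0

    @property
    def discriminant_peaks(self) -> list:
        return list(self.vip.index[self.vip > self.vip_threshold])


def tic_normalize(table: PeakTable) -> PeakTable:
    """Divide each spectrum's peaks by its total ion count.

    Spectra with zero (or missing) TIC are rejected with a warning; the
    remaining spectra are unaffected. The returned table is flagged
    ``normalized`` and retains the original TIC as metadata so that
    re-normalizing is a no-op only if the stored TIC is reused.
    """
    tic = table.tic if table.tic is not None else table.intensities.sum(axis=1)
    bad = ~(tic > 0)
    if bad.any():
        warnings.warn(f"rejecting {int(bad.sum())} spectra with zero TIC")
    keep = table.intensities.loc[~bad]
    norm = keep.div(tic[~bad], axis=0)
    return PeakTable(intensities=norm, tic=tic[~bad], names=dict(table.names),
                     polarity=table.polarity, normalized=True)


def _design(table: PeakTable, autoscale: bool) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    x = table.intensities.to_numpy(dtype=float)
    mu = x.mean(axis=0)
    xc = x - mu
    if autoscale:
        sd = x.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        xc = xc / sd
    else:
        sd = np.ones(x.shape[1])
    return xc, mu, sd


def pca_scores(table: PeakTable, labels: Sequence | None = None,
               n_components: int = 2, autoscale: bool = False,
               ellipse_level: float = 0.95) -> PCAResult:
    """Column-centred PCA of a peak table with per-class confidence ellipses.

    Ellipses are the 2-D normal quantile at ``ellipse_level`` on each class's
    score covariance: the dict maps ``label -> (centre, half_axes, angle_rad)``
    with half-axes along the principal directions of the class covariance.
    """
    if table.n_spectra < 3 or len(table.peaks) < 2:
        raise ValueError("need at least 3 spectra and 2 peaks")
    xc, _, _ = _design(table, autoscale)
    rank = np.linalg.matrix_rank(xc)
    ncomp = min(n_components, rank) if rank >= 1 else 1
    pca = PCA(n_components=ncomp)
    scores = pca.fit_transform(xc)
    res = PCAResult(
        scores=pd.DataFrame(scores, index=table.intensities.index,
                            columns=[f"PC{i+1}" for i in range(ncomp)]),
        loadings=pd.DataFrame(pca.components_.T, index=table.peaks,
                              columns=[f"PC{i+1}" for i in range(ncomp)]),
        explained_variance_ratio=pca.explained_variance_ratio_,
        rank_deficient=ncomp < n_components,
    )
    if labels is not None and ncomp >= 2:
        labels = np.asarray(labels)
        q = stats.chi2.ppf(ellipse_level, df=2)
        for lab in np.unique(labels):
            pts = scores[labels == lab][:, :2]
            if pts.shape[0] < 3:
                continue
            cov = np.cov(pts.T)
            evals, evecs = np.linalg.eigh(cov)
            order = np.argsort(evals)[::-1]
            evals, evecs = evals[order], evecs[:, order]
            res.ellipses[lab] = (
                pts.mean(axis=0),
                np.sqrt(np.maximum(evals, 0) * q),
                float(np.arctan2(evecs[1, 0], evecs[0, 0])),
            )
    return res


def plsda_vip(table: PeakTable, labels: Sequence, n_components: int = 2,
              autoscale: bool = True, vip_threshold: float = 1.0) -> PLSDAModel:
    """NIPALS PLS1 discriminant analysis with Variable Importance in Projection.

    X is autoscaled (unit variance) by default and y is the +/-1 class coding,
    centred. VIP of peak j over A components is

    ``VIP_j = sqrt( p * sum_a [ SSY_a * (w_ja / ||w_a||)^2 ] / sum_a SSY_a )``

    with ``SSY_a = q_a^2 t_a' t_a`` the response variance captured by
    component a. The mean of squared VIP over peaks is identically 1.
    """
    labels = np.asarray(labels)
    classes = tuple(pd.unique(labels))
    if len(classes) != 2:
        raise ValueError(f"exactly two classes required, got {len(classes)}")
    n, p = table.intensities.shape
    a_max = min(n - 1, p)
    ncomp = min(n_components, a_max)
    x, _, _ = _design(table, autoscale)
    y = np.where(labels == classes[0], 1.0, -1.0)
    y = y - y.mean()

    w_all = np.zeros((p, ncomp))
    t_all = np.zeros((n, ncomp))
    p_all = np.zeros((p, ncomp))
    q_all = np.zeros(ncomp)
    ssy = np.zeros(ncomp)
    xr, yr = x.copy(), y.copy()
    for a in range(ncomp):
        w = xr.T @ yr
        nw = np.linalg.norm(w)
        if nw == 0:
            ncomp = a
            break
        w /= nw
        t = xr @ w
        tt = float(t @ t)
        if tt == 0:
            ncomp = a
            break
        pl = xr.T @ t / tt
        q = float(yr @ t) / tt
        xr = xr - np.outer(t, pl)
        yr = yr - q * t
        w_all[:, a], t_all[:, a], p_all[:, a], q_all[a] = w, t, pl, q
        ssy[a] = q**2 * tt
    w_all, t_all, p_all = w_all[:, :ncomp], t_all[:, :ncomp], p_all[:, :ncomp]
    q_all, ssy = q_all[:ncomp], ssy[:ncomp]

    denom = ssy.sum()
    if denom <= 0:
        raise ValueError("response variance is zero; labels may be constant")
    vip = np.sqrt(p * (w_all**2 @ ssy) / denom)
    return PLSDAModel(
        weights=w_all, scores=t_all, x_loadings=p_all, y_loadings=q_all,
        ssy=ssy,
        vip=pd.Series(vip, index=table.peaks, name="VIP"),
        classes=classes, vip_threshold=vip_threshold,
    )


def _class_split(table: PeakTable, labels: Sequence) -> tuple:
    labels = np.asarray(labels)
    classes = pd.unique(labels)
    if len(classes) != 2:
        raise ValueError("exactly two classes required")
    x = table.intensities.to_numpy(dtype=float)
    return x[labels == classes[0]], x[labels == classes[1]], tuple(classes)


def _bootstrap_ratio(num: np.ndarray, den: np.ndarray, n_boot: int,
                     rng: np.random.Generator) -> tuple[float, float]:
    """Percentile CI of mean(num-resample)/mean(den-resample)."""
    i = rng.integers(0, num.shape[0], size=(n_boot, num.shape[0]))
    j = rng.integers(0, den.shape[0], size=(n_boot, den.shape[0]))
    r_num = num[i].mean(axis=1)
    r_den = den[j].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = r_num / r_den
    lo, hi = np.nanpercentile(ratios, [2.5, 97.5])
    return float(lo), float(hi)


def fold_changes(table: PeakTable, labels: Sequence,
                 peaks: Sequence | None = None,
                 groups: Mapping[str, Sequence] | None = None,
                 n_boot: int = 2000, seed: int = 0) -> pd.DataFrame:
    """Ratios of class means of TIC-normalized intensities, with bootstrap CIs.

    The ratio reported is ``mean(class_1) / mean(class_2)`` in the order the
    classes first appear in ``labels``. ``groups`` sums peak sets (e.g. all
    SFA fragments) per spectrum before comparing. A zero denominator mean
    yields an infinite ratio, flagged in the ``finite`` column. CIs are 95%
    percentile bootstrap over spectra (default 2000 resamples, seeded).
    """
    if not table.normalized:
        table = tic_normalize(table)
    xa, xb, classes = _class_split(table, labels)
    if xa.shape[0] < 1 or xb.shape[0] < 1:
        raise ValueError("both classes must be non-empty")
    cols = list(table.intensities.columns)
    targets: list[tuple[str, np.ndarray, np.ndarray]] = []
    for pk in (peaks if peaks is not None else cols):
        ix = cols.index(pk)
        targets.append((str(pk), xa[:, ix], xb[:, ix]))
    for gname, members in (groups or {}).items():
        ixs = [cols.index(m) for m in members]
        targets.append((gname, xa[:, ixs].sum(axis=1), xb[:, ixs].sum(axis=1)))

    rng = np.random.default_rng(seed)
    rows = []
    for name, a, b in targets:
        mb = b.mean()
        ratio = np.inf if mb == 0 else a.mean() / mb
        lo, hi = _bootstrap_ratio(a, b, n_boot, rng)
        rows.append({"peak": name, "class_num": classes[0],
                     "class_den": classes[1], "ratio": ratio,
                     "ci_low": lo, "ci_high": hi,
                     "finite": bool(np.isfinite(ratio))})
    return pd.DataFrame(rows).set_index("peak")


def saturation_ratios(table: PeakTable, labels: Sequence,
                      sfa: Sequence, mufa: Sequence, pufa: Sequence,
                      n_boot: int = 2000, seed: int = 0) -> pd.DataFrame:
    """Class comparison of per-spectrum unsaturation ratios.

    For each spectrum the MUFA and PUFA peak sums are normalized to the SFA
    sum; the class ratio of those per-spectrum quantities is then reported
    with bootstrap CIs, mirroring fatty-acid saturation analysis where
    unsaturated signal is referenced to saturated signal per sample.
    """
    if not table.normalized:
        table = tic_normalize(table)
    xa, xb, classes = _class_split(table, labels)
    cols = list(table.intensities.columns)

    def per_spectrum(x: np.ndarray, members: Sequence) -> np.ndarray:
        ixs = [cols.index(m) for m in members]
        return x[:, ixs].sum(axis=1)

    rng = np.random.default_rng(seed)
    rows = []
    for name, members in (("MUFA/SFA", mufa), ("PUFA/SFA", pufa)):
        ra = per_spectrum(xa, members) / per_spectrum(xa, sfa)
        rb = per_spectrum(xb, members) / per_spectrum(xb, sfa)
        ratio = np.inf if rb.mean() == 0 else ra.mean() / rb.mean()
        lo, hi = _bootstrap_ratio(ra, rb, n_boot, rng)
        rows.append({"quantity": name, "class_num": classes[0],
                     "class_den": classes[1],
                     "mean_num": float(ra.mean()), "mean_den": float(rb.mean()),
                     "ratio": ratio, "ci_low": lo, "ci_high": hi})
    return pd.DataFrame(rows).set_index("quantity")
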