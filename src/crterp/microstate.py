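"""Topographic pattern analysis (microstates).

Global field power, modified K-means segmentation of group ERPs into
template maps, meta-criterion selection of the number of maps,
back-fitting of templates to individual ERPs via spatial correlation,
global explained variance (GEV), and the Map x Condition rmANOVA on
GEV values.

Conventions: a scalp map is a vector over electrodes; maps are
average-referenced and templates unit L2 norm.  Spatial correlation is
the Pearson correlation of two maps across electrodes.  In
polarity-sensitive mode (the default for evoked data) assignment uses
the signed correlation; polarity-invariant mode uses |r| and
eigenvector-based template updates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import EpochedERP

__all__ = [
    "TemplateMapSet",
    "Segmentation",
    "GEVTable",
    "gfp",
    "spatial_correlation",
    "group_concatenate",
    "segment_kmeans",
    "select_k_metacriterion",
    "fit_templates",
    "build_gev_table",
    "gev_anova",
]


@dataclass
class TemplateMapSet:
    """k unit-norm, average-referenced template scalp maps (k x channels)."""

    maps: np.ndarray
    polarity: str = "sensitive"

    def __post_init__(self) -> None:
        self.maps = np.atleast_2d(np.asarray(self.maps, dtype=float))
        self.maps = self.maps - self.maps.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(self.maps, axis=1)
        if np.any(norms == 0):
            raise ValueError("zero template map")
        self.maps = self.maps / norms[:, None]

    @property
    def k(self) -> int:
        return self.maps.shape[0]


@dataclass
class Segmentation:
    """Per-timepoint labeling of a map series by template index."""

    labels: np.ndarray          # time -> template index, -1 = unassigned
    gev_total: float
    gfp: np.ndarray
    n_reseeds: int = 0


@dataclass
class GEVTable:
    """Tidy per-(subject, condition, window, template) GEV fractions."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        need = {"subject", "condition", "window", "map", "gev"}
        if len(self.table) and not need.issubset(self.table.columns):
            raise ValueError(f"GEV table needs columns {sorted(need)}")


# ---------------------------------------------------------------------------

def gfp(erp: np.ndarray) -> np.ndarray:
    """Global field power: per-sample standard deviation across channels
    of the average-referenced map."""
    v = np.asarray(erp, dtype=float)
    if v.shape[-2] < 2:
        raise ValueError("GFP needs at least 2 channels")
    v = v - v.mean(axis=-2, keepdims=True)
    return np.sqrt((v ** 2).mean(axis=-2))


def spatial_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation of two scalp maps across electrodes."""
    a = np.asarray(a, float) - np.mean(a)
    b = np.asarray(b, float) - np.mean(b)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def group_concatenate(erps: EpochedERP, post_stimulus_only: bool = True) -> np.ndarray:
    """Group-average ERPs of every condition concatenated along time
    (channels x (n_conditions * n_samples)).

    By default only post-stimulus samples enter (segmentation of the
    0..550 ms period); the pre-stimulus baseline carries no stable
    topography and would only feed noise maps to the clustering.
    """
    ga = np.nanmean(erps.data, axis=0)  # cond x chan x time
    if post_stimulus_only:
        sel = erps.times_ms() >= 0
        ga = ga[:, :, sel]
    return np.concatenate(list(ga), axis=-1)


# ---------------------------------------------------------------------------
# modified K-means

def _corr_to_templates(maps_c: np.ndarray, norms: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Correlation of each centered map (channels x T) with each unit
    template (k x channels); returns k x T."""
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (t @ maps_c) / norms[None, :]
    return np.where(np.isfinite(r), r, 0.0)


def _kmeans_once(
    maps_c: np.ndarray,
    norms: np.ndarray,
    g: np.ndarray,
    k: int,
    polarity: str,
    rng: np.random.Generator,
    max_iter: int = 200,
) -> tuple[np.ndarray, np.ndarray, int]:
    n_ch, n_t = maps_c.shape
    valid = norms > 0
    cand = np.flatnonzero(valid)
    init = rng.choice(cand, size=k, replace=False)
    t = maps_c[:, init].T.copy()
    t /= np.linalg.norm(t, axis=1, keepdims=True)
    labels = np.full(n_t, -1, dtype=int)
    n_reseeds = 0
    for _ in range(max_iter):
        r = _corr_to_templates(maps_c, norms, t)
        score = np.abs(r) if polarity == "invariant" else r
        new = np.where(valid, score.argmax(axis=0), -1)
        if np.array_equal(new, labels):
            break
        labels = new
        for j in range(k):
            sel = labels == j
            if not sel.any():
                labels[rng.choice(cand)] = j
                sel = labels == j
                n_reseeds += 1
            x = maps_c[:, sel]
            if polarity == "invariant":
                s = x @ x.T
                w, v = np.linalg.eigh(s)
                tj = v[:, -1]
            else:
                tj = x.sum(axis=1)
            nrm = np.linalg.norm(tj)
            t[j] = tj / nrm if nrm > 0 else t[j]
    return t, labels, n_reseeds


def _gev_of_labeling(
    maps_c: np.ndarray, norms: np.ndarray, g: np.ndarray,
    t: np.ndarray, labels: np.ndarray, polarity: str,
) -> float:
    r = _corr_to_templates(maps_c, norms, t)
    idx = np.clip(labels, 0, None)
    r_sel = r[idx, np.arange(maps_c.shape[1])]
    r_sel = np.where(labels >= 0, r_sel, 0.0)
    denom = (g ** 2).sum()
    if denom == 0:
        return 0.0
    return float(((g * r_sel) ** 2).sum() / denom)


def segment_kmeans(
    group_erps: np.ndarray,
    k: int,
    n_restarts: int = 100,
    polarity: str = "sensitive",
    seed: int = 0,
) -> tuple[TemplateMapSet, Segmentation]:
    """Modified K-means segmentation of a map series.

    Parameters
    ----------
    group_erps : (channels, T) ndarray
        Usually the condition group-averages concatenated along time
        (:func:`group_concatenate`).
    k : int
        Number of template maps.
    n_restarts : int
        Random restarts; the labeling with the highest total GEV wins.
    polarity : {"sensitive", "invariant"}
        Signed-correlation assignment with mean updates, or
        |correlation| assignment with eigenvector updates.

    Returns
    -------
    (TemplateMapSet, Segmentation)
    """
    v = np.asarray(group_erps, dtype=float)
    if v.ndim != 2:
        raise ValueError("group_erps must be channels x time")
    n_ch, n_t = v.shape
    if not 1 <= k <= n_t:
        raise ValueError(f"k={k} must be in [1, {n_t}]")
    if polarity not in ("sensitive", "invariant"):
        raise ValueError(f"unknown polarity mode {polarity!r}")
    maps_c = v - v.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(maps_c, axis=0)
    g = gfp(v)
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_restarts):
        t, labels, n_reseeds = _kmeans_once(maps_c, norms, g, k, polarity, rng)
        score = _gev_of_labeling(maps_c, norms, g, t, labels, polarity)
        if best is None or score > best[0]:
            best = (score, t, labels, n_reseeds)
    score, t, labels, n_reseeds = best
    return (
        TemplateMapSet(t, polarity=polarity),
        Segmentation(labels, score, g, n_reseeds),
    )


# ---------------------------------------------------------------------------
# meta-criterion for the number of maps

def select_k_metacriterion(
    group_erps: np.ndarray,
    k_range,
    seed: int = 0,
    n_restarts: int = 50,
    polarity: str = "sensitive",
) -> tuple[int, pd.DataFrame]:
    """Choose the number of template maps by a meta-criterion.

    Four criteria are computed per k — the predictive-residual
    cross-validation criterion (argmin), the Krzanowski-Lai index
    (argmax, guarded against the flattened tail of the dispersion
    curve), the explained-variance elbow (the k most above the chord of the
    total-GEV curve), and the dispersion elbow (same rule on the
    within-cluster dispersion W(k)).  The chosen k is the median of the per-criterion
    optima; fractional medians round down (ties favor the smaller k).

    Returns the chosen k and the per-k criterion table.
    """
    ks = sorted(int(k) for k in k_range)
    if not ks:
        raise ValueError("empty k_range")
    if len(ks) == 1:
        return ks[0], pd.DataFrame({"k": ks})
    v = np.asarray(group_erps, dtype=float)
    n_ch, n_t = v.shape
    maps_c = v - v.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(maps_c, axis=0)
    g = gfp(v)
    denom = (g ** 2).sum()

    rows = []
    seg_cache = {}
    rng = np.random.default_rng(seed)
    for k in ks:
        tset, seg = segment_kmeans(v, k, n_restarts=n_restarts, polarity=polarity,
                                   seed=int(rng.integers(2 ** 31 - 1)))
        seg_cache[k] = (tset, seg)
        r = _corr_to_templates(maps_c, norms, tset.maps)
        idx = np.clip(seg.labels, 0, None)
        r_sel = r[idx, np.arange(n_t)]
        resid = (g ** 2) * (1.0 - r_sel ** 2)      # unexplained variance per sample
        w = float(resid.sum())
        sigma2 = w / (n_t * (n_ch - 1))
        cv = sigma2 * ((n_ch - 1) / max(n_ch - 1 - k, 1)) ** 2
        rows.append({"k": k, "gev_total": seg.gev_total, "W": w, "cv": cv})
    tab = pd.DataFrame(rows)

    # Krzanowski-Lai on the dispersion curve; a KL ratio whose
    # denominator drop is negligible (< 5% of the largest drop) marks a
    # flattened curve beyond the true k and is excluded
    kl = np.full(len(ks), np.nan)
    wvals = tab["W"].to_numpy()
    diff = np.full(len(ks), np.nan)
    for i in range(1, len(ks)):
        diff[i] = (ks[i - 1] ** (2.0 / n_ch)) * wvals[i - 1] - (ks[i] ** (2.0 / n_ch)) * wvals[i]
    dmax = np.nanmax(np.abs(diff)) if np.isfinite(diff).any() else 0.0
    for i in range(1, len(ks) - 1):
        if np.isfinite(diff[i + 1]) and abs(diff[i + 1]) > 0.05 * dmax:
            kl[i] = abs(diff[i] / diff[i + 1])
    tab["kl"] = kl

    # explained-variance elbow: the k most above the chord joining the
    # ends of the GEV curve (max-distance-to-chord elbow rule)
    gev = tab["gev_total"].to_numpy()
    ka = np.asarray(ks, float)
    chord = gev[0] + (gev[-1] - gev[0]) * (ka - ka[0]) / (ka[-1] - ka[0])
    curv = gev - chord
    curv[[0, -1]] = np.nan
    tab["elbow"] = curv

    # dispersion elbow: same rule on the within-cluster dispersion W(k)
    wchord = wvals[0] + (wvals[-1] - wvals[0]) * (ka - ka[0]) / (ka[-1] - ka[0])
    wcurv = wchord - wvals
    wcurv[[0, -1]] = np.nan
    tab["dispersion"] = wcurv

    optima = [ks[int(np.nanargmin(tab["cv"]))]]
    if np.isfinite(kl).any():
        optima.append(ks[int(np.nanargmax(kl))])
    if np.isfinite(curv).any():
        optima.append(ks[int(np.nanargmax(curv))])
    if np.isfinite(wcurv).any():
        optima.append(ks[int(np.nanargmax(wcurv))])
    chosen = int(np.floor(np.median(optima)))
    chosen = min(ks, key=lambda k: (abs(k - chosen), k))  # snap to k_range
    tab.attrs["optima"] = optima
    return chosen, tab


# ---------------------------------------------------------------------------
# back-fitting and GEV

def fit_templates(
    templates: TemplateMapSet,
    erp: np.ndarray,
    window: slice | np.ndarray | None = None,
) -> np.ndarray:
    """Back-fit templates to an individual ERP; per-template GEV.

    Each time point (within ``window``, an index array or slice over the
    time axis) is labeled with the template of maximal spatial
    correlation (absolute correlation in polarity-invariant mode);
    GEV_k = sum_{t labeled k} (GFP(t) r_k(t))^2 / sum_t GFP(t)^2.
    """
    v = np.asarray(erp, dtype=float)
    if window is not None:
        v = v[:, window]
    maps_c = v - v.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(maps_c, axis=0)
    g = gfp(v)
    denom = (g ** 2).sum()
    if denom == 0:
        warnings.warn("zero-GFP window: GEV undefined, returning zeros")
        return np.zeros(templates.k)
    r = _corr_to_templates(maps_c, norms, templates.maps)
    score = np.abs(r) if templates.polarity == "invariant" else r
    labels = score.argmax(axis=0)
    gev = np.zeros(templates.k)
    contrib = (g * r[labels, np.arange(v.shape[1])]) ** 2
    for k in range(templates.k):
        gev[k] = contrib[labels == k].sum() / denom
    return gev


def build_gev_table(
    erps: EpochedERP,
    templates: TemplateMapSet,
    windows: dict[str, tuple[float, float]],
) -> GEVTable:
    """Per-(subject, condition, window, template) GEV fractions."""
    rows = []
    for wname, wms in windows.items():
        ts = erps.time_indices(wms)
        for s in range(erps.n_subjects):
            for ci, cond in enumerate(erps.conditions):
                gev = fit_templates(templates, erps.data[s, ci], window=ts)
                for k in range(templates.k):
                    rows.append(
                        {"subject": s, "condition": cond, "window": wname,
                         "map": k, "gev": gev[k]}
                    )
    return GEVTable(pd.DataFrame(rows))


def gev_anova(
    table: GEVTable,
    window: str,
    maps: list[int] | None = None,
) -> dict:
    """Two-way (Map x Condition) repeated-measures ANOVA on GEV.

    Returns per-effect F, Greenhouse-Geisser-corrected dfs and p, and
    partial eta squared, plus per-map post hoc paired t-tests between
    conditions.
    """
    import pingouin as pg

    df = table.table
    df = df[df["window"] == window]
    if maps is not None:
        df = df[df["map"].isin(maps)]
    if df.empty:
        raise ValueError(f"no GEV entries for window {window!r} / maps {maps}")
    n_subj = df["subject"].nunique()
    if n_subj < 2:
        raise ValueError("need at least 2 subjects for a within-subject ANOVA")
    counts = df.groupby(["subject"]).size()
    if counts.nunique() != 1:
        raise ValueError("incomplete GEV table: unbalanced cells across subjects")

    aov = pg.rm_anova(data=df, dv="gev", within=["map", "condition"],
                      subject="subject", detailed=True, effsize="np2")
    effects = {}
    for _, row in aov.iterrows():
        name = row["Source"].replace(" * ", "_x_").lower()
        eps = float(row["eps"]) if np.isfinite(row.get("eps", np.nan)) else 1.0
        p = np.nan
        for key in ("p_GG_corr", "p-GG-corr", "p_unc", "p-unc"):
            if key in row.index and np.isfinite(row[key]):
                p = row[key]
                break
        effects[name] = {
            "F": float(row["F"]),
            "df_num": float(row["ddof1"]) * eps,
            "df_den": float(row["ddof2"]) * eps,
            "p": float(p),
            "epsilon": eps,
            "partial_eta_sq": float(row["np2"]),
        }

    import scipy.stats

    posthoc = []
    conds = sorted(df["condition"].unique())
    for m in sorted(df["map"].unique()):
        sub = df[df["map"] == m].pivot_table(index="subject", columns="condition",
                                             values="gev")
        for i in range(len(conds)):
            for j in range(i + 1, len(conds)):
                t, p = scipy.stats.ttest_rel(sub[conds[i]], sub[conds[j]])
                posthoc.append({"map": int(m), "pair": (conds[i], conds[j]),
                                "t": float(t), "p": float(p)})
    return {"effects": effects, "posthoc": posthoc}
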