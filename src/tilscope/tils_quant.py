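"""Stromal TILs counting, per-HPF grading and inter-rater agreement.

Counts are taken inside square windows of one high-power-field (HPF,
400x objective) area placed over stromal tissue; per-HPF counts are graded
low / moderate / high at the <100 / 100-300 / >300 cells-per-HPF
thresholds (both boundaries belong to "moderate").  Agreement between
raters (or between the pipeline and raters) is quantified with:

* ICC(A,1) — single-measures intraclass correlation under a two-way
  random-effects model for absolute agreement, with an exact
  F-distribution 95% CI (McGraw & Wong);
* Cohen's kappa for pairwise categorical grading, Fleiss' kappa for
  overall multi-rater agreement (bootstrap percentile CIs);
* Bland-Altman mean bias and 95% limits of agreement (bias +/- 1.96 SD).

ICC strengths follow Cicchetti (1994): <0.40 poor, 0.40-0.59 fair,
0.60-0.74 good, >=0.75 excellent.  Kappa strengths follow Landis & Koch
(1977): <=0 poor, 0-0.20 slight, 0.21-0.40 fair, 0.41-0.60 moderate,
0.61-0.80 substantial, 0.81-1.00 almost perfect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats

from .io_annotations import BinaryMask

__all__ = [
    "GradeThresholds",
    "HPFSpec",
    "RatingsMatrix",
    "IccResult",
    "KappaResult",
    "BlandAltmanResult",
    "AgreementReport",
    "stromal_mask",
    "count_in_fields",
    "grade",
    "icc_absolute",
    "cohens_kappa",
    "fleiss_kappa",
    "bland_altman",
    "agreement_report",
    "icc_strength",
    "kappa_strength",
]


@dataclass
class GradeThresholds:
    """Cells-per-HPF grade boundaries; 100 and 300 grade as 'moderate'."""

    low_max: float = 100.0
    high_min: float = 300.0

    def __post_init__(self):
        if not 0 < self.low_max <= self.high_min:
            raise ValueError("need 0 < low_max <= high_min")


@dataclass
class HPFSpec:
    """One 400x high-power field; 0.237 mm^2 is the standard FN22 eyepiece
    field area.  mpp is that of the image the boxes live in."""

    field_area_mm2: float = 0.237
    mpp: float = 1.0

    def __post_init__(self):
        if self.field_area_mm2 <= 0 or self.mpp <= 0:
            raise ValueError("field area and mpp must be positive")

    @property
    def side_px(self) -> float:
        return np.sqrt(self.field_area_mm2) * 1000.0 / self.mpp


@dataclass
class RatingsMatrix:
    """n_subjects x k_raters values (continuous counts or categorical)."""

    values: np.ndarray
    rater_names: list[str] | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("ratings must be a 2-D matrix")
        n, k = self.values.shape
        if n < 2 or k < 2:
            raise ValueError("need >= 2 subjects and >= 2 raters")
        if self.values.dtype.kind in "fc" and not np.isfinite(
                self.values.astype(float)).all():
            raise ValueError("ratings must not contain missing values")
        if self.rater_names is None:
            self.rater_names = [f"rater{j}" for j in range(k)]


@dataclass
class IccResult:
    estimate: float
    ci_low: float
    ci_high: float
    strength: str = ""


@dataclass
class KappaResult:
    estimate: float
    ci_low: float
    ci_high: float
    degenerate: bool = False
    strength: str = ""


@dataclass
class BlandAltmanResult:
    bias: float
    loa_low: float
    loa_high: float
    differences: np.ndarray


@dataclass
class AgreementReport:
    icc: IccResult
    kappa_pairwise: dict[tuple[str, str], KappaResult]
    fleiss: KappaResult
    bland_altman: dict[tuple[str, str], BlandAltmanResult]
    grades: np.ndarray


# --------------------------------------------------------------------------
# counting
# --------------------------------------------------------------------------

def stromal_mask(tissue: BinaryMask, parenchyma: BinaryMask) -> BinaryMask:
    """Stroma = tissue AND NOT parenchyma (same shape and scale)."""
    if tissue.grid.shape != parenchyma.grid.shape:
        raise ValueError("tissue and parenchyma masks must share a shape")
    if tissue.scale != parenchyma.scale:
        raise ValueError("tissue and parenchyma masks must share a scale")
    return BinaryMask(tissue.grid & (1 - parenchyma.grid), scale=tissue.scale)


def count_in_fields(boxes, stroma: BinaryMask, hpf: HPFSpec,
                    n_fields: int = 5, seed: int = 0,
                    hotspot: bool = False) -> list[int]:
    """Counts in ``n_fields`` HPF-sized square windows over stroma.

    Windows are centered on seeded random stromal pixels (or, with
    ``hotspot=True``, on the highest-count candidate windows).  A box is
    counted when its center lies in the window (boundaries inclusive) and
    on a stromal pixel.
    """
    side_src = hpf.side_px  # in source-image pixels
    scale = stroma.scale
    sh, sw = stroma.grid.shape
    stroma_mm2 = stroma.grid.sum() * (hpf.mpp * scale / 1000.0) ** 2
    if stroma_mm2 < hpf.field_area_mm2:
        raise ValueError(
            f"stroma too small to host a field: required {hpf.field_area_mm2} "
            f"mm^2, available {stroma_mm2:.4f} mm^2"
        )
    centers = [b.center if hasattr(b, "center") else
               ((b[0] + b[2]) / 2.0, (b[1] + b[3]) / 2.0) for b in boxes]
    in_stroma = []
    for cx, cy in centers:
        mr = min(max(int(cy / scale), 0), sh - 1)
        mc = min(max(int(cx / scale), 0), sw - 1)
        in_stroma.append(stroma.grid[mr, mc] == 1)

    ys, xs = np.nonzero(stroma.grid)
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    def window_count(x0, y0):
        n = 0
        for (cx, cy), ok in zip(centers, in_stroma):
            if ok and x0 <= cx <= x0 + side_src and y0 <= cy <= y0 + side_src:
                n += 1
        return n

    if hotspot:
        cand = []
        pick = rng.integers(0, len(ys), min(len(ys), 256))
        for i in pick:
            x0 = xs[i] * scale - side_src / 2.0
            y0 = ys[i] * scale - side_src / 2.0
            cand.append((window_count(x0, y0), x0, y0))
        cand.sort(key=lambda t: -t[0])
        return [c for c, _, _ in cand[:n_fields]]

    counts = []
    pick = rng.integers(0, len(ys), n_fields)
    for i in pick:
        x0 = xs[i] * scale - side_src / 2.0
        y0 = ys[i] * scale - side_src / 2.0
        counts.append(window_count(x0, y0))
    return counts


def grade(count_per_hpf: float, thr: GradeThresholds | None = None) -> str:
    """Map a per-HPF count to {low, moderate, high}."""
    thr = thr or GradeThresholds()
    if count_per_hpf < 0:
        raise ValueError("count must be >= 0")
    if count_per_hpf < thr.low_max:
        return "low"
    if count_per_hpf <= thr.high_min:
        return "moderate"
    return "high"


# --------------------------------------------------------------------------
# agreement statistics
# --------------------------------------------------------------------------

def _as_matrix(r) -> np.ndarray:
    if isinstance(r, RatingsMatrix):
        return np.asarray(r.values, dtype=np.float64)
    return np.asarray(r, dtype=np.float64)


def icc_strength(icc: float) -> str:
    if icc < 0.40:
        return "poor"
    if icc < 0.60:
        return "fair"
    if icc < 0.75:
        return "good"
    return "excellent"


def kappa_strength(k: float) -> str:
    if k <= 0:
        return "poor"
    if k <= 0.20:
        return "slight"
    if k <= 0.40:
        return "fair"
    if k <= 0.60:
        return "moderate"
    if k <= 0.80:
        return "substantial"
    return "almost perfect"


def icc_absolute(ratings, alpha: float = 0.05) -> IccResult:
    """ICC(A,1): single-measures, two-way random effects, absolute
    agreement, with the exact F-based confidence interval."""
    x = _as_matrix(ratings)
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("need >= 2 subjects and >= 2 raters")
    grand = x.mean()
    if np.allclose(x, grand):
        raise ValueError("zero total variance: ICC undefined")
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * ((row_means - grand) ** 2).sum()
    ssc = n * ((col_means - grand) ** 2).sum()
    sst = ((x - grand) ** 2).sum()
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    icc = (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))

    # McGraw & Wong F-based CI for ICC(A,1)
    if mse <= 0:
        return IccResult(float(icc), float(icc), float(icc),
                         icc_strength(float(icc)))
    a = (k * icc) / (n * (1.0 - icc)) if icc < 1 else np.inf
    b = 1.0 + (k * icc * (n - 1)) / (n * (1.0 - icc)) if icc < 1 else np.inf
    if np.isfinite(a) and np.isfinite(b):
        num = (a * msc + b * mse) ** 2
        den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        v = num / den
    else:
        v = (n - 1) * (k - 1)
    f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lo = n * (msr - f_l * mse) / (
        f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
    hi = n * (f_u * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_u * msr)
    lo, hi = min(lo, icc), max(hi, icc)
    return IccResult(float(icc), float(lo), float(min(hi, 1.0)),
                     icc_strength(float(icc)))


def _kappa_point(a: np.ndarray, b: np.ndarray) -> tuple[float, bool]:
    cats = sorted(set(a.tolist()) | set(b.tolist()))
    idx = {c: i for i, c in enumerate(cats)}
    m = len(cats)
    table = np.zeros((m, m))
    for x, y in zip(a, b):
        table[idx[x], idx[y]] += 1
    nn_ = table.sum()
    po = np.trace(table) / nn_
    pe = float((table.sum(axis=1) * table.sum(axis=0)).sum()) / nn_ ** 2
    if pe >= 1.0 - 1e-12:
        return 1.0, True  # both raters constant with the same label
    return float((po - pe) / (1.0 - pe)), False


def cohens_kappa(a, b, n_boot: int = 2000, seed: int = 0,
                 alpha: float = 0.05) -> KappaResult:
    """Cohen's kappa with a seeded bootstrap percentile CI."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length label vectors of length >= 2")
    k, degen = _kappa_point(a, b)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n = len(a)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, n, n)
        boots[i], _ = _kappa_point(a[idx], b[idx])
    lo, hi = np.percentile(boots, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    lo, hi = min(lo, k), max(hi, k)
    return KappaResult(k, float(lo), float(hi), degen, kappa_strength(k))


def _fleiss_point(labels: np.ndarray) -> tuple[float, bool]:
    n, k = labels.shape
    cats = sorted({v for row in labels for v in row.tolist()})
    counts = np.zeros((n, len(cats)))
    for j, c in enumerate(cats):
        counts[:, j] = (labels == c).sum(axis=1)
    p_j = counts.sum(axis=0) / (n * k)
    p_i = (np.square(counts).sum(axis=1) - k) / (k * (k - 1))
    p_bar = p_i.mean()
    p_e = float(np.square(p_j).sum())
    if p_e >= 1.0 - 1e-12:
        return 1.0, True
    return float((p_bar - p_e) / (1.0 - p_e)), False


def fleiss_kappa(labels, n_boot: int = 2000, seed: int = 0,
                 alpha: float = 0.05) -> KappaResult:
    """Fleiss' kappa (subjects x raters categorical matrix) with a seeded
    bootstrap percentile CI over subjects."""
    labels = np.asarray(labels)
    if labels.ndim != 2 or labels.shape[0] < 2 or labels.shape[1] < 2:
        raise ValueError("need an n>=2 x k>=2 label matrix")
    k, degen = _fleiss_point(labels)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n = labels.shape[0]
    boots = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, n, n)
        boots[i], _ = _fleiss_point(labels[idx])
    lo, hi = np.percentile(boots, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    lo, hi = min(lo, k), max(hi, k)
    return KappaResult(k, float(lo), float(hi), degen, kappa_strength(k))


def bland_altman(a, b) -> BlandAltmanResult:
    """Mean bias of a-b and 95% limits of agreement (bias +/- 1.96 SD)."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(bias, bias - 1.96 * sd, bias + 1.96 * sd, d)


def agreement_report(counts_by_rater, thr: GradeThresholds | None = None,
                     seed: int = 0) -> AgreementReport:
    """Full agreement battery on an n_subjects x k_raters count matrix:
    ICC on the continuous counts, per-rater grading, pairwise Cohen's
    kappa and Bland-Altman, and overall Fleiss' kappa on the grades."""
    thr = thr or GradeThresholds()
    rm = counts_by_rater if isinstance(counts_by_rater, RatingsMatrix) \
        else RatingsMatrix(np.asarray(counts_by_rater))
    x = np.asarray(rm.values, dtype=np.float64)
    names = rm.rater_names
    icc = icc_absolute(x)
    grades = np.empty(x.shape, dtype=object)
    for i in range(x.shape[0]):
        for j in range(x.shape[1]):
            grades[i, j] = grade(x[i, j], thr)
    kappas, bas = {}, {}
    for j1, j2 in combinations(range(x.shape[1]), 2):
        key = (names[j1], names[j2])
        kappas[key] = cohens_kappa(grades[:, j1], grades[:, j2], seed=seed)
        bas[key] = bland_altman(x[:, j1], x[:, j2])
    fl = fleiss_kappa(grades, seed=seed)
    return AgreementReport(icc=icc, kappa_pairwise=kappas, fleiss=fl,
                           bland_altman=bas, grades=grades)
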