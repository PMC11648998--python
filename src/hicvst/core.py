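"""Replicate-based variance-stabilizing transformation for contact counts.

The transform is learned from two biological replicates in four stages:

1. **Base–aux table.** One replicate is designated the *base*, the other the
   *auxiliary*. Every included bin pair contributes one row
   ``(base value, aux value)``: the upper triangle including the diagonal for
   intra-chromosomal maps, the whole matrix for inter-chromosomal maps.
2. **Sort and bin.** Rows are sorted by the base value (stable) and grouped
   into consecutive bins of ``s`` rows (the last bin may be smaller),
   ``B = ceil(BP / s)`` bins in total. Bin pairs with similar base values are
   assumed to share an underlying signal distribution.
3. **Empirical moments and curve fit.** Per bin, the mean and standard
   deviation of the *aux* column are computed with the population divisor,
   and a cubic smoothing spline is fitted through the ``(mu_b, sigma_b)``
   points to give the mean–stdev relationship ``sigma = h(mu)``.
4. **Delta-method integral.** By the first-order delta method,
   ``Var[g(X)] ≈ h(mu)^2 g'(mu)^2``; demanding a constant standard deviation
   ``C`` gives ``t(x) = ∫_0^x C / h(u) du``, evaluated by cumulative
   trapezoidal quadrature on an asinh-spaced grid.

The resulting map is strictly increasing, fixes 0, and — when the learned
``h`` matches the data — leaves the transformed signal with standard
deviation ``C`` (default 1) across the whole intensity range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.interpolate import make_smoothing_spline

from .io import ContactMatrix

__all__ = [
    "BaseAuxTable",
    "BinnedMoments",
    "MeanSdCurve",
    "TransformFunction",
    "build_base_aux",
    "sort_and_bin",
    "estimate_moments",
    "fit_mean_sd_curve",
    "derive_transform",
    "apply_transform",
    "rescale_log_converge",
    "learn_transform",
    "effective_bin_rows",
]

# Default rows per moment-estimation bin. Deliberately small: the per-bin
# stdev's sampling noise (~ 1/sqrt(2(s-1)) relative) is averaged away by the
# second-stage smoothing spline over thousands of bins, whereas the upward
# bias from true-mean heterogeneity *within* a bin grows with bin width and
# no amount of smoothing removes it. Undersmooth the first stage, smooth the
# second.
DEFAULT_S = 10
MIN_BINS_TARGET = 50


@dataclass
class BaseAuxTable:
    """Paired observations: one row per genomic bin pair, columns (base, aux)."""

    base: np.ndarray
    aux: np.ndarray

    def __post_init__(self) -> None:
        self.base = np.asarray(self.base, dtype=float)
        self.aux = np.asarray(self.aux, dtype=float)
        if self.base.shape != self.aux.shape or self.base.ndim != 1:
            raise ValueError("base and aux must be 1-D arrays of equal length")
        if self.bp < 2:
            raise ValueError("need at least 2 bin pairs")
        for a in (self.base, self.aux):
            if not np.all(np.isfinite(a)) or np.any(a < 0):
                raise ValueError("values must be finite and non-negative")

    @property
    def bp(self) -> int:
        """Number of bin-pair rows (BP)."""
        return len(self.base)


@dataclass
class BinnedMoments:
    """Per-bin empirical moments of the aux column after sorting by base.

    ``mu`` and ``sigma`` use the population divisor (the bin's actual row
    count). ``counts[i] == s`` for all bins except possibly the last.
    """

    s: int
    mu: np.ndarray
    sigma: np.ndarray
    counts: np.ndarray
    # retained so moments can be recomputed on transformed values
    sorted_aux: np.ndarray | None = None

    @property
    def b(self) -> int:
        """Number of bins (B)."""
        return len(self.mu)


@dataclass
class MeanSdCurve:
    """The fitted mean -> stdev map ``h`` with its binned support points.

    ``h`` is a cubic smoothing spline fitted on an asinh-scaled mean axis
    (count data crowd near zero; the rescaling spreads the abscissae evenly,
    matching the asinh-spaced integration grid downstream), clipped below at
    ``floor_eps`` and extended as a constant outside ``[mu_min, mu_max]``
    (``h`` sits in a denominator, so it must stay positive and bounded).
    """

    support_mu: np.ndarray
    support_sigma: np.ndarray
    support_counts: np.ndarray
    floor_eps: float
    _spline: object = None

    @property
    def mu_min(self) -> float:
        return float(self.support_mu.min())

    @property
    def mu_max(self) -> float:
        return float(self.support_mu.max())

    def __call__(self, mu) -> np.ndarray:
        mu = np.clip(np.asarray(mu, dtype=float), self.mu_min, self.mu_max)
        out = np.asarray(self._spline(np.arcsinh(mu)), dtype=float)
        return np.maximum(out, self.floor_eps)

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({
            "mu": self.support_mu,
            "sigma": self.support_sigma,
        }).to_csv(path, sep="\t", index=False)


@dataclass
class TransformFunction:
    """Monotone variance-stabilizing map tabulated on an asinh-spaced grid.

    Evaluation between knots is piecewise-linear (exactly monotone); beyond
    the last knot it extrapolates with the final segment's slope.
    """

    grid: np.ndarray
    values: np.ndarray
    c: float = 1.0
    params: dict | None = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.grid) < 3:
            raise ValueError("grid needs at least 3 points")
        if self.grid[0] != 0:
            raise ValueError("grid must start at 0")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if np.any(np.diff(self.values) <= 0):
            raise ValueError("transform values must be strictly increasing")

    @property
    def x_max(self) -> float:
        return float(self.grid[-1])

    def __call__(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if np.any(x < 0):
            raise ValueError("transform input must be non-negative")
        out = np.interp(x, self.grid, self.values)
        beyond = x > self.x_max
        if np.any(beyond):
            slope = (self.values[-1] - self.values[-2]) / (self.grid[-1] - self.grid[-2])
            out = np.where(beyond, self.values[-1] + slope * (x - self.x_max), out)
        return out

    def to_tsv(self, path) -> None:
        """Serialize as two-column TSV with a ``#``-header of parameters."""
        lines = []
        if self.params:
            for k, v in self.params.items():
                lines.append(f"# {k}={v}")
        lines.append(f"# C={self.c}")
        lines.append("raw_value\ttransformed_value")
        for x, y in zip(self.grid, self.values):
            lines.append(f"{x:.10g}\t{y:.10g}")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")

    @classmethod
    def from_tsv(cls, path) -> "TransformFunction":
        params: dict = {}
        grid, values = [], []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    body = line[1:].strip()
                    if "=" in body:
                        k, v = body.split("=", 1)
                        params[k.strip()] = v.strip()
                    continue
                if line.startswith("raw_value"):
                    continue
                x, y = line.split("\t")
                grid.append(float(x))
                values.append(float(y))
        c = float(params.pop("C", 1.0))
        return cls(np.array(grid), np.array(values), c=c, params=params or None)


# ----------------------------------------------------------------------
# Stage 1: base-aux table
# ----------------------------------------------------------------------

def build_base_aux(m1: ContactMatrix, m2: ContactMatrix,
                   zero_policy: str = "union_nonzero") -> BaseAuxTable:
    """Pair up the two replicates' values per bin pair.

    ``m1`` supplies the base column, ``m2`` the aux column. Intra maps use
    each unordered pair once (upper triangle with diagonal); inter maps use
    every cell. ``zero_policy`` controls double zeros: ``union_nonzero``
    keeps pairs nonzero in at least one replicate (Hi-C maps are dominated
    by structural/sampling zeros), ``all_pairs`` keeps everything.
    """
    if (m1.chrom1, m1.chrom2) != (m2.chrom1, m2.chrom2):
        raise ValueError("replicates must cover the same chromosome pair")
    if (m1.n_bins1, m1.n_bins2, m1.bin_size) != (m2.n_bins1, m2.n_bins2, m2.bin_size):
        raise ValueError("replicates must share dimensions and bin size")
    if zero_policy not in ("union_nonzero", "all_pairs"):
        raise ValueError(f"unknown zero_policy {zero_policy!r}")

    n1, n2 = m1.n_bins1, m1.n_bins2

    def keys(m: ContactMatrix) -> np.ndarray:
        return m.bin1 * n2 + m.bin2

    k1, k2 = keys(m1), keys(m2)
    if zero_policy == "union_nonzero":
        union = np.union1d(k1[m1.value != 0], k2[m2.value != 0])
    else:
        if m1.is_intra:
            iu = np.triu_indices(n1)
            union = iu[0] * n2 + iu[1]
        else:
            union = np.arange(n1 * n2, dtype=np.int64)

    def lookup(k: np.ndarray, v: np.ndarray) -> np.ndarray:
        out = np.zeros(len(union))
        order = np.argsort(k)
        pos = np.searchsorted(k, union, sorter=order)
        pos_ok = pos < len(k)
        hit = np.zeros(len(union), dtype=bool)
        hit[pos_ok] = k[order][pos[pos_ok]] == union[pos_ok]
        out[hit] = v[order][pos[hit]]
        return out

    return BaseAuxTable(lookup(k1, m1.value), lookup(k2, m2.value))


# ----------------------------------------------------------------------
# Stages 2-3: sort, bin, moments
# ----------------------------------------------------------------------

def sort_and_bin(x: BaseAuxTable, s: int) -> BinnedMoments:
    """Sort rows by base value (stable) and compute per-bin aux moments.

    Bins are consecutive runs of ``s`` sorted rows; ``B = ceil(BP / s)``,
    with the final bin holding the remainder. Ties in the base column keep
    their original row order (stable mergesort), making binning
    deterministic.
    """
    if s < 2:
        raise ValueError("bin size s must be >= 2")
    if s > x.bp:
        raise ValueError(f"bin size s={s} exceeds BP={x.bp}")
    order = np.argsort(x.base, kind="stable")
    sorted_aux = x.aux[order]
    bp = x.bp
    b = -(-bp // s)  # ceil
    edges = np.minimum(np.arange(1, b + 1) * s, bp)
    counts = np.diff(np.concatenate([[0], edges]))
    return estimate_moments(BinnedMoments(s, np.empty(0), np.empty(0),
                                          counts, sorted_aux))


def estimate_moments(binned: BinnedMoments) -> BinnedMoments:
    """Per-bin mean and population stdev of the aux column.

    The divisor is each bin's actual row count (``s`` for full bins, the
    remainder for the last), so every row contributes. Points are returned
    in ascending order of the bin mean.
    """
    aux = binned.sorted_aux
    if aux is None:
        raise ValueError("binned moments lack the sorted aux column")
    counts = binned.counts
    edges = np.concatenate([[0], np.cumsum(counts)])
    # Two-pass computation: a one-pass E[x^2] - E[x]^2 form cancels
    # catastrophically on near-constant bins. Both passes stay vectorized.
    mu = np.add.reduceat(aux, edges[:-1]) / counts
    sq_dev = (aux - np.repeat(mu, counts)) ** 2
    var = np.add.reduceat(sq_dev, edges[:-1]) / counts
    sigma = np.sqrt(var)
    order = np.argsort(mu, kind="stable")
    return BinnedMoments(binned.s, mu[order], sigma[order], counts[order],
                         sorted_aux=aux)


def effective_bin_rows(bp: int, s: int = DEFAULT_S,
                       min_bins: int = MIN_BINS_TARGET) -> int:
    """Shrink the requested bin size so at least ``min_bins`` bins exist.

    A stable spline fit needs enough support points; with small inputs the
    default ``s`` would collapse everything into a handful of bins.
    """
    if bp < 2 * 2:
        raise ValueError("too few bin pairs to bin")
    s_eff = min(s, max(2, bp // min_bins))
    return max(2, min(s_eff, bp // 2))


# ----------------------------------------------------------------------
# Stage 3b: mean-stdev curve
# ----------------------------------------------------------------------

def fit_mean_sd_curve(points: BinnedMoments, smoothing: float | None = None,
                      floor_eps: float | None = None) -> MeanSdCurve:
    """Fit a cubic smoothing spline ``sigma = h(mu)`` through the bin moments.

    The spline is fitted to ``sigma_b`` against ``asinh(mu_b)`` with the bin
    row counts as weights; ``smoothing`` is the penalty ``lam`` (``None``
    selects it by generalized cross-validation). ``floor_eps`` clips the fit
    away from zero — ``h`` appears in a denominator — and defaults to
    ``max(1e-8, 0.01 * median(sigma_b))``.
    """
    mu, sigma, counts = points.mu, points.sigma, points.counts
    uniq_mu, inv = np.unique(mu, return_inverse=True)
    if len(uniq_mu) < 4:
        raise ValueError(
            f"only {len(uniq_mu)} distinct bin means; reduce the bin size s "
            "to obtain at least 4 support points"
        )
    # collapse duplicated abscissae (count-weighted); spline needs strict increase
    sig_u = np.zeros(len(uniq_mu))
    cnt_u = np.zeros(len(uniq_mu))
    np.add.at(sig_u, inv, sigma * counts)
    np.add.at(cnt_u, inv, counts.astype(float))
    sigma_fit = sig_u / cnt_u
    if floor_eps is None:
        floor_eps = max(1e-8, 0.01 * float(np.median(sigma)))
    spline = make_smoothing_spline(np.arcsinh(uniq_mu), sigma_fit,
                                   w=cnt_u, lam=smoothing)
    return MeanSdCurve(mu, sigma, counts, floor_eps, spline)


# ----------------------------------------------------------------------
# Stage 4: delta-method transform
# ----------------------------------------------------------------------

def asinh_grid(x_max: float, n_grid: int) -> np.ndarray:
    """Strictly increasing grid 0..x_max with asinh (log-like) spacing.

    Dense near zero where count data are crowded, sparse in the tail.
    """
    k = np.arange(n_grid + 1)
    return np.sinh(k * np.arcsinh(x_max) / n_grid)


def derive_transform(curve, x_max: float, n_grid: int = 1000,
                     c: float = 1.0, params: dict | None = None) -> TransformFunction:
    """Integrate ``t(x) = ∫_0^x C / h(u) du`` on an asinh-spaced grid.

    ``curve`` is any callable ``mu -> sigma`` returning strictly positive
    values (a fitted :class:`MeanSdCurve` or an analytic mean–stdev law).
    The cumulative trapezoid rule is applied after the substitution
    ``u = w**2`` (integrand ``2w C / h(w^2)``): count-noise laws behave like
    ``h ~ sqrt(u)`` near zero, where the raw integrand has an integrable
    singularity the plain rule cannot resolve, while the substituted
    integrand is flat. The first cell uses the midpoint rule, exact both for
    square-root laws and for curves held constant below their support. The
    result is strictly increasing whenever ``h > 0``.
    """
    if x_max <= 0:
        raise ValueError("x_max must be positive")
    if n_grid < 100:
        raise ValueError("n_grid must be >= 100")
    grid = asinh_grid(x_max, n_grid)
    w = np.sqrt(grid)
    h = np.asarray(curve(w * w), dtype=float)
    if np.any(h <= 0) or not np.all(np.isfinite(h)):
        raise RuntimeError("mean-stdev curve must be positive and finite on the grid")
    values = cumulative_trapezoid(2.0 * w * c / h, w, initial=0.0)
    wm = w[1] / 2.0
    hm = float(np.asarray(curve(np.array([wm * wm])))[0])
    values += w[1] * (2.0 * wm * c / hm) - (values[1] - values[0])
    values[0] = 0.0
    return TransformFunction(grid, values, c=c, params=params)


def apply_transform(t, m: ContactMatrix) -> ContactMatrix:
    """Apply a transform to every pixel value of a contact matrix.

    ``t`` may be a :class:`TransformFunction` or any vectorized monotone
    callable. Because the map is monotone increasing, the ranking of pixel
    values is preserved exactly.
    """
    return m.with_values(t(m.value))


def rescale_log_converge(t: TransformFunction,
                         tail_quantile: float = 0.5) -> TransformFunction:
    """Affinely rescale a transform to track ``ln(x)`` in the high-signal tail.

    Fits ``a, b`` minimizing ``sum (a t(x_k) + b - ln x_k)^2`` over grid
    points above the ``tail_quantile`` of the grid. The output values match
    the familiar scale of log-transformed signals asymptotically while the
    shape (and any rank statistic) is untouched; ``a > 0`` keeps it monotone.
    """
    if not 0 < tail_quantile < 1:
        raise ValueError("tail_quantile must be in (0, 1)")
    thresh = np.quantile(t.grid, tail_quantile)
    sel = (t.grid >= thresh) & (t.grid > 0)
    if sel.sum() < 2:
        raise ValueError("tail contains fewer than 2 usable grid points")
    y = np.log(t.grid[sel])
    x = t.values[sel]
    a, b = np.polyfit(x, y, 1)
    if a <= 0:
        raise RuntimeError("degenerate rescale: non-positive slope")
    return TransformFunction(t.grid, a * t.values + b, c=t.c * a,
                             params={**(t.params or {}),
                                     "log_converge_a": float(a),
                                     "log_converge_b": float(b)})


# ----------------------------------------------------------------------
# End-to-end convenience
# ----------------------------------------------------------------------

def pool_base_aux(m1_list, m2_list, zero_policy: str = "union_nonzero",
                  symmetrize: bool = False) -> BaseAuxTable:
    """Concatenate base-aux rows over one or more chromosome pairs."""
    if isinstance(m1_list, ContactMatrix):
        m1_list = [m1_list]
    if isinstance(m2_list, ContactMatrix):
        m2_list = [m2_list]
    if len(m1_list) != len(m2_list) or not m1_list:
        raise ValueError("need equal-length, non-empty replicate lists")
    bases, auxes = [], []
    for m1, m2 in zip(m1_list, m2_list):
        tab = build_base_aux(m1, m2, zero_policy)
        bases.append(tab.base)
        auxes.append(tab.aux)
        if symmetrize:
            swapped = build_base_aux(m2, m1, zero_policy)
            bases.append(swapped.base)
            auxes.append(swapped.aux)
    return BaseAuxTable(np.concatenate(bases), np.concatenate(auxes))


def learn_transform(m1_list, m2_list, s: int = DEFAULT_S,
                    zero_policy: str = "union_nonzero",
                    smoothing: float | None = None,
                    floor_eps: float | None = None,
                    n_grid: int = 1000, c: float = 1.0,
                    x_max: float | None = None,
                    symmetrize: bool = False) -> TransformFunction:
    """Learn a variance-stabilizing transform from paired replicate matrices.

    Pools base-aux rows across all supplied chromosome pairs, then chains
    sort-and-bin, moment estimation, spline fitting and the delta-method
    integral. ``x_max`` defaults to the pooled maximum raw value.
    """
    table = pool_base_aux(m1_list, m2_list, zero_policy, symmetrize)
    s_eff = effective_bin_rows(table.bp, s)
    moments = sort_and_bin(table, s_eff)
    curve = fit_mean_sd_curve(moments, smoothing=smoothing, floor_eps=floor_eps)
    if x_max is None:
        x_max = float(max(table.base.max(), table.aux.max()))
        if x_max <= 0:
            raise ValueError("all values are zero; nothing to transform")
    params = {"s": s_eff, "zero_policy": zero_policy,
              "floor_eps": curve.floor_eps, "N": n_grid, "x_max": x_max}
    return derive_transform(curve, x_max, n_grid=n_grid, c=c, params=params)
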