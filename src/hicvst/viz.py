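"""Heatmap and mean–stdev diagnostics plotting.

Linear-color-scale heatmaps are the visual motivation for variance
stabilization: on raw counts the color map is dominated by the diagonal,
while unit-variance signals expose both short- and long-range structure
without switching to a log color scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .io import ContactMatrix, to_dense

__all__ = ["PlotSpec", "plot_heatmap", "plot_mean_sd", "parse_region"]


@dataclass(frozen=True)
class PlotSpec:
    """Rendering options for a heatmap: optional region, linear scale, clip.

    ``region`` is ``(chrom, start_bp, end_bp)`` with 0-based half-open
    coordinates, or ``None`` for the full matrix. ``vmax_quantile`` clips
    the upper end of the linear color range (raw counts need this: a few
    outliers otherwise own the entire scale).
    """

    region: tuple[str, int, int] | None = None
    vmax_quantile: float = 0.98
    output_path: str = "heatmap.png"
    cmap: str = "Reds"
    dpi: int = 100

    def __post_init__(self) -> None:
        if not 0 < self.vmax_quantile <= 1:
            raise ValueError("vmax_quantile must be in (0, 1]")
        if self.region is not None and self.region[1] >= self.region[2]:
            raise ValueError("region start must be < end")


def parse_region(region: str) -> tuple[str, int, int]:
    """Parse ``chrom:start-end`` (1-based inclusive, as displayed in
    genome browsers) into 0-based half-open coordinates."""
    chrom, _, span = region.partition(":")
    lo, _, hi = span.partition("-")
    start1, end1 = int(lo.replace(",", "")), int(hi.replace(",", ""))
    if start1 < 1 or end1 < start1:
        raise ValueError(f"malformed region {region!r}")
    return chrom, start1 - 1, end1


def _slice_bins(m: ContactMatrix, spec: PlotSpec) -> tuple[np.ndarray, tuple]:
    dense = to_dense(m)
    if spec.region is None:
        return dense, (0, m.n_bins1 * m.bin_size)
    chrom, start, end = spec.region
    if chrom not in (m.chrom1, m.chrom2):
        raise ValueError(f"region chromosome {chrom!r} not in matrix")
    lo = start // m.bin_size
    hi = -(-end // m.bin_size)
    if lo < 0 or hi > max(m.n_bins1, m.n_bins2):
        raise ValueError("region outside matrix bounds")
    if m.is_intra:
        return dense[lo:hi, lo:hi], (lo * m.bin_size, hi * m.bin_size)
    if chrom == m.chrom1:
        return dense[lo:hi, :], (lo * m.bin_size, hi * m.bin_size)
    return dense[:, lo:hi], (lo * m.bin_size, hi * m.bin_size)


def plot_heatmap(m: ContactMatrix, spec: PlotSpec) -> str:
    """Render a (sub)matrix as a linear-color-scale heatmap PNG/SVG.

    The color range tops out at the ``vmax_quantile`` of the plotted values
    (disclosed in the figure title). Deterministic for fixed inputs: no
    timestamps are embedded in the output.
    """
    sub, (bp_lo, bp_hi) = _slice_bins(m, spec)
    finite = sub[np.isfinite(sub)]
    vmax = float(np.quantile(finite, spec.vmax_quantile)) if finite.size else 1.0
    if vmax <= 0:
        vmax = 1.0
    fig, ax = plt.subplots(figsize=(6, 5))
    extent = (bp_lo / 1e6, bp_hi / 1e6, bp_hi / 1e6, bp_lo / 1e6)
    im = ax.imshow(sub, cmap=spec.cmap, vmin=0, vmax=vmax,
                   interpolation="nearest", extent=extent, aspect="auto")
    ax.set_xlabel(f"{m.chrom2} position (Mb)")
    ax.set_ylabel(f"{m.chrom1} position (Mb)")
    ax.set_title(f"linear color scale, clipped at q={spec.vmax_quantile:g}")
    fig.colorbar(im, ax=ax, label="signal")
    fig.savefig(spec.output_path, dpi=spec.dpi, metadata=_no_date(spec.output_path))
    plt.close(fig)
    return spec.output_path


def plot_mean_sd(mu: np.ndarray, sigma: np.ndarray, output_path: str,
                 curve=None, oracle=None, title: str = "") -> str:
    """Scatter per-bin (mean, stdev) points with optional fitted/analytic overlays.

    ``curve`` is typically a fitted mean–stdev spline and ``oracle`` an
    analytic law such as ``sqrt(mu + alpha mu^2)``; both are drawn over the
    support range of the points.
    """
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    fig, ax = plt.subplots(figsize=(5.5, 4.5))
    ax.scatter(mu, sigma, s=8, alpha=0.5, label="binned moments", color="#444")
    if mu.size:
        grid = np.linspace(mu.min(), mu.max(), 400)
        if curve is not None:
            ax.plot(grid, curve(grid), lw=2, color="crimson", label="fitted h")
        if oracle is not None:
            ax.plot(grid, oracle(grid), lw=2, ls="--", color="navy",
                    label="analytic")
    ax.set_xlabel("mean")
    ax.set_ylabel("stdev")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False)
    fig.savefig(output_path, dpi=100, metadata=_no_date(output_path))
    plt.close(fig)
    return output_path


def _no_date(path: str) -> dict:
    """Metadata suppressing embedded timestamps so outputs are byte-stable."""
    if str(path).endswith(".svg"):
        return {"Date": None}
    return {"Software": None}
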