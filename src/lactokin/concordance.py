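"""Agreement between dependency panels via Lin's concordance correlation.

Lin's CCC measures how far paired values stray from the 45-degree line of
perfect agreement, penalizing both imprecision (scatter) and inaccuracy
(location/scale shift):

    ccc = 2 s_xy / (s_x^2 + s_y^2 + (xbar - ybar)^2)

with population (divide-by-n) moments, as in Lin (1989).  The standard
error is Lin's asymptotic variance of the Fisher-z-transformed estimate,
mapped back by the delta method.  The reduced major axis — the symmetric
line with slope sign(r) s_y/s_x through the centroid — displays the
concordance structure alongside the identity line.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import KeyMismatchError, ParameterDomainError

__all__ = [
    "ConcordanceResult",
    "lin_ccc",
    "reduced_major_axis",
    "compare_models",
    "concordance_plot",
]


@dataclass(frozen=True)
class ConcordanceResult:
    ccc: float
    se_ccc: float
    rma_slope: float
    rma_intercept: float
    n_pairs: int


def _moments(x: np.ndarray, y: np.ndarray, population: bool = True):
    n = len(x)
    ddof = 0 if population else 1
    sx2 = np.var(x, ddof=ddof)
    sy2 = np.var(y, ddof=ddof)
    sxy = np.sum((x - x.mean()) * (y - y.mean())) / (n - ddof)
    return sx2, sy2, sxy


def lin_ccc(
    x, y, population: bool = True
) -> ConcordanceResult:
    """Lin's concordance correlation coefficient with asymptotic SE.

    ``population=True`` (default) uses divide-by-n moments; the sample
    (n-1) variant is available behind the flag.  Requires >= 3 finite pairs
    and nonzero variance in at least one input.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterDomainError("x and y must be 1-d arrays of equal length")
    n = len(x)
    if n < 3:
        raise ParameterDomainError("need >= 3 pairs")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ParameterDomainError("inputs must be finite")
    sx2, sy2, sxy = _moments(x, y, population)
    dloc = x.mean() - y.mean()
    denom = sx2 + sy2 + dloc**2
    if denom == 0:
        raise ParameterDomainError("both inputs constant: CCC undefined")
    ccc = 2.0 * sxy / denom

    # Lin's asymptotic variance of z = atanh(ccc), delta-mapped back
    if sx2 > 0 and sy2 > 0:
        r = sxy / np.sqrt(sx2 * sy2)
    else:
        r = 0.0
    if abs(ccc) >= 1.0 - 1e-12 or r == 0.0:
        se = 0.0 if abs(ccc) >= 1.0 - 1e-12 else np.nan
    else:
        u = dloc / (sx2 * sy2) ** 0.25
        c2, r2 = ccc**2, r**2
        var_z = (
            (1.0 - r2) * c2 / ((1.0 - c2) * r2)
            + 2.0 * ccc**3 * (1.0 - ccc) * u**2 / (r * (1.0 - c2) ** 2)
            - ccc**4 * u**4 / (2.0 * r2 * (1.0 - c2) ** 2)
        ) / (n - 2)
        se = float(np.sqrt(max(var_z, 0.0)) * (1.0 - c2))  # delta method

    slope, intercept = reduced_major_axis(x, y)
    return ConcordanceResult(
        ccc=float(ccc),
        se_ccc=se,
        rma_slope=slope,
        rma_intercept=intercept,
        n_pairs=n,
    )


def reduced_major_axis(x, y) -> tuple[float, float]:
    """Reduced-major-axis line: slope sign(r) s_y/s_x through the centroid."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sx2, sy2, sxy = _moments(x, y)
    if sx2 == 0:
        raise ParameterDomainError("zero variance in x: RMA slope undefined")
    sign = 1.0 if sxy >= 0 else -1.0
    slope = sign * np.sqrt(sy2 / sx2)
    intercept = y.mean() - slope * x.mean()
    return float(slope), float(intercept)


def compare_models(
    deps_a: dict[str, float],
    deps_b: dict[str, float],
    transform: str = "log",
) -> tuple[ConcordanceResult, pd.DataFrame]:
    """Concordance between two dependency panels matched by key.

    Dependencies span several orders of magnitude, so pairs are
    log-transformed by default (``transform="raw"`` compares raw values).
    Returns the concordance result and the paired table.
    """
    keys_a, keys_b = set(deps_a), set(deps_b)
    if keys_a != keys_b:
        raise KeyMismatchError(
            f"key mismatch: only in first {sorted(keys_a - keys_b)}, "
            f"only in second {sorted(keys_b - keys_a)}"
        )
    keys = sorted(keys_a)
    x = np.array([deps_a[k] for k in keys], dtype=float)
    y = np.array([deps_b[k] for k in keys], dtype=float)
    table = pd.DataFrame({"dependency": keys, "x": x, "y": y})
    if transform == "log":
        if np.any(x <= 0) or np.any(y <= 0):
            raise ParameterDomainError("log transform requires positive values")
        x, y = np.log(x), np.log(y)
    elif transform != "raw":
        raise ParameterDomainError(f"unknown transform {transform!r}")
    result = lin_ccc(x, y)
    return result, table


def concordance_plot(
    deps_a: dict[str, float],
    deps_b: dict[str, float],
    transform: str = "log",
    labels: tuple[str, str] = ("U model", "N model"),
    path: str | None = None,
):
    """Scatter of paired dependencies with the RMA and identity lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    result, table = compare_models(deps_a, deps_b, transform)
    x = table["x"].to_numpy()
    y = table["y"].to_numpy()
    if transform == "log":
        x, y = np.log(x), np.log(y)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(x, y, color="tab:blue", zorder=3)
    lo, hi = min(x.min(), y.min()), max(x.max(), y.max())
    line = np.linspace(lo, hi, 2)
    ax.plot(line, line, "k--", label="perfect concordance")
    ax.plot(
        line,
        result.rma_slope * line + result.rma_intercept,
        "r-",
        label="reduced major axis",
    )
    scale = "log " if transform == "log" else ""
    ax.set_xlabel(f"{scale}dependency, {labels[0]}")
    ax.set_ylabel(f"{scale}dependency, {labels[1]}")
    ax.set_title(f"CCC = {result.ccc:.3f} ± {result.se_ccc:.3f}")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
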